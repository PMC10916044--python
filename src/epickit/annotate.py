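"""Genic, CpG-island and regulatory-element context for probe locations.

Positions are 1-based plus-strand cytosine coordinates.  Genic labels follow
the precedence TSS > gene body > intergenic, with the TSS window taken
strand-aware around each transcript start ([-1500, +500] by default — the
window is a convention, not a biological constant, and is configurable).
CpG context: island if inside an island interval, shore within 2000 bp of an
island edge, open sea beyond.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import gffutils
from intervaltree import IntervalTree

from .errors import EpickitError

SHORE_BP = 2000


@dataclass
class AnnotationContext:
    genic: str                      # TSS | gene_body | intergenic
    cpg: str                        # island | shore | open_sea
    feature_overlaps: list[tuple[str, str]]


def _build_trees(intervals):
    """chrom -> IntervalTree over 0-based half-open intervals with data."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for chrom, start, end, data in intervals:
        if end > start:
            trees[chrom].addi(start, end, data)
    return dict(trees)


def read_bed(path):
    """Minimal BED4/6 reader: yields (chrom, start, end, name)."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2]),
                        parts[3] if len(parts) > 3 else f"feature{i}"))
    return out


def load_transcripts(gtf_path):
    """Transcript (chrom, start0, end0, strand, transcript_id) from a GTF."""
    db = gffutils.create_db(
        str(gtf_path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    transcripts = []
    for t in db.features_of_type("transcript"):
        tid = (t.attributes.get("transcript_id") or [t.id])[0]
        transcripts.append((t.seqid, t.start - 1, t.end, t.strand, tid))
    if not transcripts:
        raise EpickitError("GTF contains no transcript features")
    return transcripts


def assign_genic_context(positions, gtf_path, tss_upstream=1500, tss_downstream=500):
    """Label each (chrom, pos) as TSS, gene_body or intergenic.

    Returns ``(labels, summary)``; *summary* holds per-category counts and
    the number of unique TSSs covered by at least one position.
    """
    transcripts = load_transcripts(gtf_path)
    tss_iv, body_iv = [], []
    for chrom, start0, end0, strand, tid in transcripts:
        if strand == "-":
            tss0 = end0 - 1
            lo, hi = tss0 - tss_downstream, tss0 + tss_upstream + 1
        else:
            tss0 = start0
            lo, hi = tss0 - tss_upstream, tss0 + tss_downstream + 1
        tss_iv.append((chrom, max(lo, 0), hi, (chrom, tss0, strand)))
        body_iv.append((chrom, start0, end0, tid))
    tss_trees = _build_trees(tss_iv)
    body_trees = _build_trees(body_iv)

    labels = []
    covered_tss = set()
    for chrom, pos in positions:
        p0 = pos - 1
        hits = tss_trees.get(chrom, IntervalTree())[p0]
        if hits:
            labels.append("TSS")
            covered_tss.update(iv.data for iv in hits)
        elif body_trees.get(chrom, IntervalTree())[p0]:
            labels.append("gene_body")
        else:
            labels.append("intergenic")
    summary = {
        "TSS": labels.count("TSS"),
        "gene_body": labels.count("gene_body"),
        "intergenic": labels.count("intergenic"),
        "unique_tss_covered": len(covered_tss),
    }
    return labels, summary


def assign_cpg_context(positions, islands, shore_bp=SHORE_BP):
    """Label each (chrom, pos): island, shore (<= *shore_bp* of an edge) or open_sea.

    *islands* is an iterable of (chrom, start0, end0[, name]) 0-based
    half-open intervals.
    """
    edges = defaultdict(list)
    trees = _build_trees(
        (iv[0], iv[1], iv[2], iv[3] if len(iv) > 3 else None) for iv in islands
    )
    for iv in islands:
        edges[iv[0]].append((iv[1], iv[2]))
    labels = []
    for chrom, pos in positions:
        p0 = pos - 1
        tree = trees.get(chrom)
        if tree is not None and tree[p0]:
            labels.append("island")
            continue
        dist = min(
            (start - p0 if p0 < start else p0 - (end - 1)
             for start, end in edges.get(chrom, [])),
            default=None,
        )
        labels.append("shore" if dist is not None and dist <= shore_bp else "open_sea")
    return labels


def feature_overlap_summary(positions, features, label="features"):
    """Overlap of positions with a feature BED (enhancers, super-enhancers...).

    Deduplicated (identical-interval) features are used so "unique features
    covered" is well defined.  Returns a dict with per-position overlap
    flags, per-feature probe counts, the count of features covered, and the
    histogram {k probes: number of features}.
    """
    unique = {}
    for iv in features:
        key = (iv[0], iv[1], iv[2])
        unique.setdefault(key, iv[3] if len(iv) > 3 else f"{iv[0]}:{iv[1]}-{iv[2]}")
    trees = _build_trees((c, s, e, (c, s, e)) for (c, s, e) in unique)
    per_feature = {key: 0 for key in unique}
    flags, overlaps = [], []
    for chrom, pos in positions:
        p0 = pos - 1
        hits = trees.get(chrom, IntervalTree())[p0]
        flags.append(bool(hits))
        names = []
        for iv in hits:
            per_feature[iv.data] += 1
            names.append((label, unique[iv.data]))
        overlaps.append(names)
    histogram: dict[int, int] = {}
    for k in per_feature.values():
        histogram[k] = histogram.get(k, 0) + 1
    return {
        "flags": flags,
        "overlaps": overlaps,
        "per_feature_counts": {unique[k]: v for k, v in per_feature.items()},
        "n_features": len(unique),
        "n_features_covered": sum(v > 0 for v in per_feature.values()),
        "n_positions_overlapping": sum(flags),
        "histogram": histogram,
    }
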