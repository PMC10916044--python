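"""Matching EPICv2 probes against EPICv1/450K/27K and provenance categories.

Probes are matched by 1) Name prefix, 2) hg38 target location and 3) probe
sequence (both alleles must agree).  Every EPICv2 replicate is treated
independently: one output row per (v2 probe, other-platform probe) pair, so
older-array internal replicates yield multiple rows rather than collapsing.

Provenance partitions the unique EPICv2 target locations (rs/nv removed):
``new`` (EPICv2 only), ``retained`` (also on EPICv1) and ``reinstated``
(on 450K and/or 27K but not EPICv1); ``excluded`` lists EPICv1 locations
absent from EPICv2.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .errors import EpickitError
from .manifest import ManifestTable

PLATFORM_TAGS = ("EPICv1", "K450", "K27")


@dataclass
class CrossVersionMatch:
    v2_ilmn_id: str
    other_platform: str
    other_probe_id: str
    matched_by_name: bool
    matched_by_location: bool
    matched_by_sequence: bool


def _cpg_interval(rec):
    """Reconciled 0-based half-open CpG dinucleotide interval for a record."""
    beg = rec.extras.get("CpG_beg", rec.mapinfo - 1)
    end = rec.extras.get("CpG_end", beg + 2)
    return rec.chrom, beg, end


def match_probes(v2: ManifestTable, other: ManifestTable, platform_tag: str):
    """All cross-version matches between *v2* and one older-array table.

    Location equality intersects the reconciled CpG dinucleotide intervals
    (as ranges, not points).  Sequence matching requires both Allele A and
    Allele B to agree; tables without sequence columns yield no sequence
    matches.
    """
    if v2.assembly != other.assembly:
        raise EpickitError(
            f"assembly mismatch: {v2.assembly!r} vs {other.assembly!r}"
        )
    by_name = defaultdict(list)
    by_seq = defaultdict(list)
    by_chrom: dict[str, list] = defaultdict(list)
    for rec in other:
        by_name[rec.name].append(rec)
        if rec.allele_a_seq:
            by_seq[rec.sequence_key].append(rec)
        if rec.located:
            by_chrom[rec.chrom].append(rec)

    matches: list[CrossVersionMatch] = []
    for rec in v2:
        partners: dict[str, list[bool]] = {}
        for cand in by_name.get(rec.name, []):
            partners.setdefault(cand.ilmn_id, [False, False, False])[0] = True
        if rec.located:
            chrom, beg, end = _cpg_interval(rec)
            for cand in by_chrom.get(chrom, []):
                _, cbeg, cend = _cpg_interval(cand)
                if max(beg, cbeg) < min(end, cend):
                    partners.setdefault(cand.ilmn_id, [False, False, False])[1] = True
        if rec.allele_a_seq:
            for cand in by_seq.get(rec.sequence_key, []):
                partners.setdefault(cand.ilmn_id, [False, False, False])[2] = True
        for other_id, (mn, ml, ms) in partners.items():
            matches.append(CrossVersionMatch(rec.ilmn_id, platform_tag, other_id, mn, ml, ms))
    return matches


def match_fields(matches, platform_tag: str):
    """Fold match rows into augmented-manifest columns for one platform.

    Returns {column: {v2_ilmn_id: value}} with columns
    ``<tag>probeID`` / ``<tag>locmatch`` / ``<tag>seqmatch``.
    """
    ids = defaultdict(list)
    loc = defaultdict(bool)
    seq = defaultdict(bool)
    for m in matches:
        if m.other_platform != platform_tag:
            continue
        ids[m.v2_ilmn_id].append(m.other_probe_id)
        loc[m.v2_ilmn_id] |= m.matched_by_location
        seq[m.v2_ilmn_id] |= m.matched_by_sequence
    return {
        f"{platform_tag}probeID": {k: ";".join(v) for k, v in ids.items()},
        f"{platform_tag}locmatch": {k: "Y" if loc[k] else "N" for k in ids},
        f"{platform_tag}seqmatch": {k: "Y" if seq[k] else "N" for k in ids},
    }


@dataclass
class ProvenanceLabel:
    location: tuple[str, int]
    category: str  # new | retained | reinstated


def assign_provenance(v2_locations, epicv1_locations, k450_locations, k27_locations):
    """Set-algebra provenance of unique EPICv2 locations.

    Inputs are sets of (chrom, 1-based C position) built with rs/nv probes
    removed.  Returns ``(labels, summary)`` where *labels* maps location ->
    category and *summary* carries the four counts plus the excluded set.
    """
    v2 = set(v2_locations)
    v1 = set(epicv1_locations)
    older = set(k450_locations) | set(k27_locations)
    retained = v2 & v1
    reinstated = (v2 & older) - v1
    new = v2 - v1 - older
    excluded = v1 - v2
    labels = {loc: "retained" for loc in retained}
    labels.update({loc: "reinstated" for loc in reinstated})
    labels.update({loc: "new" for loc in new})
    summary = {
        "new": len(new),
        "retained": len(retained),
        "reinstated": len(reinstated),
        "excluded": len(excluded),
        "excluded_locations": excluded,
    }
    return labels, summary
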