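"""In-silico cross-hybridisation mapping at single-nucleotide resolution.

Probe 50-mers are aligned against four variants of the reference genome —
plus strand (``fwd``), fully bisulphite-converted plus strand (``fwd_bis``,
every C -> T, the unmethylated limit), reverse complement (``rev``) and
converted reverse complement (``rev_bis``) — on *both* query strands, as a
local aligner does.  Alignments with >= 47 matching nucleotides and BLAT
score >= 44 count as cross-hybridising; the score is the common BLAT/PSL
convention

    score = matches - mismatches - query_gap_openings - target_gap_openings.

For each passing off-target, the interrogated cytosine's offset within the
on-target alignment is transposed through the off-target's blocks to a
plus-strand single-nucleotide coordinate, and the base there is classified
(CpG / CpH / non-C) from the unconverted genome in alignment orientation.

The built-in aligner is exhaustive at toy-genome scale (vectorised Hamming
scan for ungapped hits; seed-and-extend with edlib for indel hits) —
correctness over speed.  Genome-scale runs are delegated to external BLAT
via :func:`read_psl`.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np

from ._seq import EQUIV, VALID_PROBE, check_alphabet, complement, revcomp
from .errors import AlignmentInputError

PROBE_LENGTH = 50
MIN_MATCHES_DEFAULT = 47
MIN_SCORE_DEFAULT = 44

VARIANT_KEYS = ("fwd", "fwd_bis", "rev", "rev_bis")

_EDLIB_EQUALITIES = [("R", "A"), ("R", "G"), ("Y", "C"), ("Y", "T")]


def _bis(seq: str) -> str:
    return seq.replace("C", "T")


class GenomeVariantSet:
    """The four genome variants with coordinate maps back to the plus strand."""

    def __init__(self, genome: dict[str, str]):
        if not genome or any(len(s) == 0 for s in genome.values()):
            raise AlignmentInputError("empty genome sequence")
        self.plus = {c: s.upper() for c, s in genome.items()}
        for seq in self.plus.values():
            check_alphabet(seq, frozenset("ACGTN"), "genome")
        self.variants = {
            "fwd": self.plus,
            "fwd_bis": {c: _bis(s) for c, s in self.plus.items()},
            "rev": {c: revcomp(s) for c, s in self.plus.items()},
            "rev_bis": {c: _bis(revcomp(s)) for c, s in self.plus.items()},
        }
        self._kmer_cache: dict = {}

    def kmer_index(self, variant: str, chrom: str, k: int):
        """Cached exact k-mer position index of one variant sequence."""
        key = (variant, chrom, k)
        idx = self._kmer_cache.get(key)
        if idx is None:
            seq = self.variants[variant][chrom]
            idx = defaultdict(list)
            for i in range(len(seq) - k + 1):
                idx[seq[i : i + k]].append(i)
            self._kmer_cache[key] = idx
        return idx

    @classmethod
    def from_fasta(cls, path) -> "GenomeVariantSet":
        from pyfaidx import Fasta

        fa = Fasta(str(path))
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def length(self, chrom: str) -> int:
        return len(self.plus[chrom])

    def to_plus(self, variant: str, chrom: str, vpos: int) -> int:
        """Map a 0-based variant coordinate to a 1-based plus-strand coordinate."""
        if variant.startswith("fwd"):
            return vpos + 1
        return self.length(chrom) - vpos

    def orientation(self, variant: str, strand: str) -> str:
        """Plus-strand orientation of an alignment: which genomic strand the
        aligned bases are read from ('+' or '-')."""
        fwd_variant = variant.startswith("fwd")
        return "+" if (fwd_variant == (strand == "+")) else "-"


@dataclass
class Alignment:
    """One probe-to-genome-variant alignment in PSL-like block form.

    ``blocks`` are (query_start, target_start, length) runs, 0-based,
    monotone and non-overlapping; query coordinates refer to the aligned
    query (the reverse complement of the probe for ``strand == '-'``),
    target coordinates to the named genome variant.
    """

    probe_id: str
    variant: str
    chrom: str
    strand: str                       # query strand aligned to the variant
    blocks: list[tuple[int, int, int]]
    matches: int
    mismatches: int
    query_gap_openings: int = 0
    target_gap_openings: int = 0
    query_length: int = PROBE_LENGTH
    is_on_target: bool = field(default=False, compare=False)

    @property
    def score(self) -> int:
        return (self.matches - self.mismatches
                - self.query_gap_openings - self.target_gap_openings)

    @property
    def target_span(self) -> tuple[int, int]:
        """0-based half-open span in variant coordinates."""
        return self.blocks[0][1], self.blocks[-1][1] + self.blocks[-1][2]

    def plus_span(self, variants: GenomeVariantSet) -> tuple[int, int]:
        """1-based inclusive plus-strand span."""
        lo, hi = self.target_span
        a = variants.to_plus(self.variant, self.chrom, lo)
        b = variants.to_plus(self.variant, self.chrom, hi - 1)
        return (min(a, b), max(a, b))

    def probe_offset_to_variant(self, probe_offset: int) -> int | None:
        """Variant coordinate aligned to a probe offset, or None if gapped.

        Offsets up to two bases beyond either query end are extrapolated
        from the terminal block: designs whose 50-mer abuts rather than
        covers the interrogated cytosine (Type II, and opposite-strand
        windows, which sit beyond the CpG's G on the bottom strand) anchor
        the transposition just outside the aligned footprint.
        """
        q = probe_offset if self.strand == "+" else self.query_length - 1 - probe_offset
        for qs, ts, ln in self.blocks:
            if qs <= q < qs + ln:
                return ts + (q - qs)
        qs0, ts0, _ = self.blocks[0]
        if qs0 - 2 <= q < qs0:
            return ts0 - (qs0 - q)
        qsn, tsn, lnn = self.blocks[-1]
        if qsn + lnn <= q <= qsn + lnn + 1:
            return tsn + lnn + (q - qsn - lnn)
        return None

    def covers_plus(self, variants: GenomeVariantSet, pos_1based: int) -> bool:
        lo, hi = self.plus_span(variants)
        return lo <= pos_1based <= hi


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _ungapped_scan(probe: str, target: str, min_matches: int):
    """All ungapped windows with >= min_matches degenerate-aware matches.

    Vectorised over window starts: one boolean comparison per probe offset.
    """
    n = len(target) - len(probe) + 1
    if n <= 0:
        return []
    tarr = _encode(target)
    acc = np.zeros(n, dtype=np.int16)
    for k, pc in enumerate(probe):
        allowed = np.frombuffer("".join(sorted(EQUIV[pc])).encode(), dtype=np.uint8)
        if allowed.size == 1:
            acc += tarr[k : k + n] == allowed[0]
        elif allowed.size:
            acc += np.isin(tarr[k : k + n], allowed)
    starts = np.nonzero(acc >= min_matches)[0]
    return [(int(s), int(acc[s])) for s in starts]


def _cigar_to_alignment(cigar: str, query: str, target_window: str, window_offset: int,
                        loc_start: int):
    """Parse an edlib extended cigar into blocks and PSL-style counts.

    ``I`` consumes query only (a query base over a target gap -> target gap
    opening); ``D`` consumes target only (query gap opening).
    """
    blocks = []
    matches = mismatches = qgap = tgap = 0
    q = 0
    t = window_offset + loc_start
    num = ""
    cur_qs = cur_ts = cur_len = None
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        ln = int(num)
        num = ""
        if ch in "=X":
            if cur_len is None:
                cur_qs, cur_ts, cur_len = q, t, 0
            cur_len += ln
            if ch == "=":
                matches += ln
            else:
                mismatches += ln
            q += ln
            t += ln
        elif ch == "I":
            if cur_len is not None:
                blocks.append((cur_qs, cur_ts, cur_len))
                cur_len = None
            tgap += 1
            q += ln
        elif ch == "D":
            if cur_len is not None:
                blocks.append((cur_qs, cur_ts, cur_len))
                cur_len = None
            qgap += 1
            t += ln
        else:
            raise AlignmentInputError(f"unexpected cigar op {ch!r}")
    if cur_len is not None:
        blocks.append((cur_qs, cur_ts, cur_len))
    return blocks, matches, mismatches, qgap, tgap


def _gapped_candidates(query: str, target: str, min_matches: int, max_edits: int,
                       seed_len: int = 10, index=None):
    """Seed-and-extend gapped search; yields parsed local alignments.

    A qualifying alignment of a 50-mer with >= 47 matches has edit distance
    <= *max_edits*, so by pigeonhole it contains an exact *seed_len*-mer.
    Degenerate probe bases expand into their alternatives when seeding.
    """
    if index is None:
        index = defaultdict(list)
        for i in range(len(target) - seed_len + 1):
            index[target[i : i + seed_len]].append(i)

    def expand(seed: str):
        outs = [""]
        for ch in seed:
            alts = sorted(EQUIV[ch]) if ch in "RY" else [ch]
            outs = [o + a for o in outs for a in alts]
            if len(outs) > 64:
                return []
        return outs

    seen_windows = set()
    results = []
    n = len(query)
    for qpos in range(0, n - seed_len + 1):
        for seed in expand(query[qpos : qpos + seed_len]):
            for tpos in index.get(seed, ()):
                diag = tpos - qpos
                lo = max(0, diag - max_edits)
                hi = min(len(target), diag + n + max_edits)
                if (lo, hi) in seen_windows:
                    continue
                seen_windows.add((lo, hi))
                res = edlib.align(query, target[lo:hi], mode="HW", task="path",
                                  k=max_edits, additionalEqualities=_EDLIB_EQUALITIES)
                if res["editDistance"] < 0:
                    continue
                # the reported cigar belongs to the first location
                loc = res["locations"][0]
                blocks, m, mm, qg, tg = _cigar_to_alignment(
                    res["cigar"], query, target, lo, loc[0])
                if m >= min_matches:
                    results.append((blocks, m, mm, qg, tg))
    return results


def align_probe(probe_seq: str, variants: GenomeVariantSet,
                min_matches: int = MIN_MATCHES_DEFAULT, probe_id: str = "",
                max_indel_edits: int = 6) -> list[Alignment]:
    """All alignments of a probe (both strands, all four variants) with
    ``matches >= min_matches``, substitutions and indels allowed."""
    if len(probe_seq) != PROBE_LENGTH:
        raise AlignmentInputError(
            f"probe length {len(probe_seq)} != {PROBE_LENGTH}")
    check_alphabet(probe_seq, VALID_PROBE, "probe")
    out: list[Alignment] = []
    seen = set()

    def add(variant, chrom, strand, blocks, m, mm, qg, tg):
        key = (variant, chrom, strand, tuple(blocks))
        if key in seen:
            return
        seen.add(key)
        out.append(Alignment(probe_id, variant, chrom, strand, list(blocks),
                             m, mm, qg, tg))

    for variant in VARIANT_KEYS:
        for chrom, target in variants.variants[variant].items():
            for strand, query in (("+", probe_seq), ("-", revcomp(probe_seq))):
                for start, m in _ungapped_scan(query, target, min_matches):
                    add(variant, chrom, strand,
                        [(0, start, PROBE_LENGTH)], m, PROBE_LENGTH - m, 0, 0)
                for blocks, m, mm, qg, tg in _gapped_candidates(
                        query, target, min_matches, max_indel_edits,
                        index=variants.kmer_index(variant, chrom, 10)):
                    if qg + tg == 0:
                        continue  # ungapped hits come from the Hamming scan
                    add(variant, chrom, strand, blocks, m, mm, qg, tg)
    return out


def read_psl(path) -> list[Alignment]:
    """Read a BLAT PSL file (with or without the 5-line header).

    Minus-strand records keep PSL semantics: block query starts refer to the
    reverse-complemented query, target starts to the plus strand of the
    database sequence — the same convention as the built-in aligner with
    ``variant='fwd'``.  The database sequence name is used as the variant
    key when it matches a known variant tag suffix (``<chrom>|<variant>``),
    else ``fwd``.
    """
    alignments = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    body = lines
    if lines and lines[0].startswith("psLayout"):
        body = lines[5:]
    for lineno, line in enumerate(body, 1):
        if not line.strip() or line.startswith(("match", "-")):
            continue
        parts = line.split("\t")
        if len(parts) < 21:
            raise AlignmentInputError(
                f"PSL line {lineno}: expected 21 columns, got {len(parts)}")
        (match, mismatch, repmatch, ncount, qnumins, qbaseins, tnumins, tbaseins,
         strand, qname, qsize, qstart, qend, tname, tsize, tstart, tend,
         blockcount, blocksizes, qstarts, tstarts) = parts[:21]
        sizes = [int(x) for x in blocksizes.rstrip(",").split(",")]
        qss = [int(x) for x in qstarts.rstrip(",").split(",")]
        tss = [int(x) for x in tstarts.rstrip(",").split(",")]
        if not (len(sizes) == len(qss) == len(tss) == int(blockcount)):
            raise AlignmentInputError(f"PSL line {lineno}: block count mismatch")
        chrom, variant = tname, "fwd"
        if "|" in tname:
            chrom, maybe = tname.rsplit("|", 1)
            if maybe in VARIANT_KEYS:
                variant = maybe
        alignments.append(Alignment(
            probe_id=qname, variant=variant, chrom=chrom, strand=strand[0],
            blocks=list(zip(qss, tss, sizes)),
            matches=int(match) + int(repmatch), mismatches=int(mismatch),
            query_gap_openings=int(qnumins), target_gap_openings=int(tnumins),
            query_length=int(qsize),
        ))
    return alignments


def write_psl(alignments, path, variants: GenomeVariantSet | None = None) -> None:
    """Write alignments as headerless PSL (target names ``<chrom>|<variant>``)."""
    with open(path, "w") as fh:
        for a in alignments:
            sizes = ",".join(str(ln) for _, _, ln in a.blocks) + ","
            qss = ",".join(str(qs) for qs, _, _ in a.blocks) + ","
            tss = ",".join(str(ts) for _, ts, _ in a.blocks) + ","
            tsize = variants.length(a.chrom) if variants else 0
            qaligned = sum(ln for _, _, ln in a.blocks)
            fh.write("\t".join(map(str, [
                a.matches, a.mismatches, 0, 0,
                a.query_gap_openings, max(0, a.query_length - qaligned),
                a.target_gap_openings, 0,
                a.strand, a.probe_id, a.query_length,
                a.blocks[0][0], a.blocks[-1][0] + a.blocks[-1][2],
                f"{a.chrom}|{a.variant}", tsize,
                a.blocks[0][1], a.blocks[-1][1] + a.blocks[-1][2],
                len(a.blocks), sizes, qss, tss,
            ])) + "\n")


def filter_alignments(alignments, target_location=None,
                      min_matches: int = MIN_MATCHES_DEFAULT,
                      min_score: int = MIN_SCORE_DEFAULT,
                      variants: GenomeVariantSet | None = None):
    """Apply the match/score thresholds and flag cross-hybridisation.

    *target_location* is the manifest (chrom, MAPINFO) for the probe (or
    None for unlocated probes).  Returns a dict with the passing alignments,
    the identified on-target alignment (covering or abutting MAPINFO), the
    off-targets, and a category:

    ``no_homology`` (nothing passes anywhere), ``no_mapinfo_homology``
    (passing hits, none at MAPINFO), ``cross_hybridising`` (>= 1 passing hit
    beyond the on-target) or ``not_cross_hybridising``.
    """
    passing = [a for a in alignments
               if a.matches >= min_matches and a.score >= min_score]
    on_target = None
    if target_location is not None and variants is not None:
        chrom, mapinfo = target_location
        for a in passing:
            if a.chrom != chrom:
                continue
            lo, hi = a.plus_span(variants)
            # abutting designs sit up to 2 nt from the MAPINFO cytosine
            if lo - 2 <= mapinfo <= hi + 2:
                if a.covers_plus(variants, mapinfo) or on_target is None:
                    on_target = a
    off_targets = [a for a in passing if a is not on_target]
    if not passing:
        category = "no_homology"
    elif target_location is not None and on_target is None:
        category = "no_mapinfo_homology"
    elif off_targets:
        category = "cross_hybridising"
    else:
        category = "not_cross_hybridising"
    if on_target is not None:
        on_target.is_on_target = True
    return {
        "passing": passing,
        "on_target": on_target,
        "off_targets": off_targets,
        "category": category,
        "ch_blat": category == "cross_hybridising",
    }


@dataclass
class OffTargetHit:
    probe_id: str
    chrom: str
    coord: int                       # 1-based plus-strand
    variant: str
    orientation: str                 # strand whose 5'->3' reading the probe follows
    base: str                        # base read from the unconverted genome, oriented
    dinucleotide_class: str          # CpG | CpH | nonC
    is_on_target: bool
    ambiguous: bool = False          # successor unavailable (contig end)


def classify_offtarget_base(genome: dict[str, str], chrom: str, coord: int,
                            orientation: str):
    """Base and dinucleotide class at a 1-based plus-strand coordinate.

    The base is read from the unconverted genome in the alignment
    orientation ('-' complements).  A cytosine followed (in that
    orientation) by G is CpG, otherwise CpH; a missing successor at a
    contig end leaves CpG-vs-CpH undecidable (flagged).
    """
    seq = genome[chrom]
    if not (1 <= coord <= len(seq)):
        raise AlignmentInputError(f"coordinate {coord} outside {chrom}")
    b = seq[coord - 1]
    if orientation == "-":
        base = complement(b)
        nxt = complement(seq[coord - 2]) if coord >= 2 else None
    else:
        base = b
        nxt = seq[coord] if coord < len(seq) else None
    if base != "C":
        return base, "nonC", False
    if nxt is None:
        return base, "CpH", True
    return base, ("CpG" if nxt == "G" else "CpH"), False


def transpose_target_to_offtargets(on_target: Alignment, target_coord: int,
                                   off_targets, variants: GenomeVariantSet,
                                   genome: dict[str, str] | None = None):
    """Map the target nucleotide through each off-target alignment.

    The query offset of *target_coord* (1-based plus strand) is computed
    from the on-target blocks, then walked through each off-target's blocks
    (indel-aware).  Hits whose offset falls in an unaligned gap are skipped
    and counted.  Returns ``(hits, n_skipped_in_gap)``.
    """
    genome = genome if genome is not None else variants.plus
    tv = target_coord - 1 if on_target.variant.startswith("fwd") \
        else variants.length(on_target.chrom) - target_coord
    # invert the offset map: find the probe offset aligned to tv
    probe_offset = None
    for qs, ts, ln in on_target.blocks:
        if ts <= tv < ts + ln:
            q = qs + (tv - ts)
            probe_offset = q if on_target.strand == "+" \
                else on_target.query_length - 1 - q
            break
    if probe_offset is None:
        # the target may abut the alignment (Type II / opposite-strand
        # designs sit up to 2 nt away): extrapolate from the terminal block
        qs0, ts0, _ = on_target.blocks[0]
        qsn, tsn, lnn = on_target.blocks[-1]
        if ts0 - 2 <= tv < ts0:
            q = qs0 - (ts0 - tv)
        elif tsn + lnn <= tv <= tsn + lnn + 1:
            q = qsn + lnn + (tv - tsn - lnn)
        else:
            raise AlignmentInputError(
                "target coordinate outside all on-target blocks")
        probe_offset = q if on_target.strand == "+" \
            else on_target.query_length - 1 - q

    # The manifest MAPINFO names the plus-strand C of the target CpG, so the
    # on-target anchor reads C in '+' orientation; an off-target aligned on
    # the opposite effective strand reads the complementary base.
    on_orient = variants.orientation(on_target.variant, on_target.strand)
    hits, skipped = [], 0
    for aln in [on_target] + list(off_targets):
        vcoord = aln.probe_offset_to_variant(probe_offset)
        if vcoord is None:
            skipped += 1
            continue
        if not (0 <= vcoord < variants.length(aln.chrom)):
            skipped += 1
            continue
        coord = variants.to_plus(aln.variant, aln.chrom, vcoord)
        same = variants.orientation(aln.variant, aln.strand) == on_orient
        orientation = "+" if same else "-"
        base, dinuc, ambiguous = classify_offtarget_base(
            genome, aln.chrom, coord, orientation)
        hits.append(OffTargetHit(
            probe_id=aln.probe_id, chrom=aln.chrom, coord=coord,
            variant=aln.variant, orientation=orientation, base=base,
            dinucleotide_class=dinuc, is_on_target=aln is on_target,
            ambiguous=ambiguous,
        ))
    return hits, skipped


def scan_manifest(table, variants: GenomeVariantSet,
                  min_matches: int = MIN_MATCHES_DEFAULT,
                  min_score: int = MIN_SCORE_DEFAULT):
    """Full cross-hybridisation scan of every non-control probe in a table.

    Returns a dict per probe: filter result + transposed off-target hits.
    Allele A is the hybridising sequence scanned (Allele B of a Type I pair
    shares the genomic footprint).
    """
    results = {}
    for rec in table:
        if rec.target_class == "control" or not rec.allele_a_seq:
            continue
        alns = align_probe(rec.allele_a_seq, variants,
                           min_matches=min_matches, probe_id=rec.ilmn_id)
        res = filter_alignments(
            alns, rec.location, min_matches, min_score, variants)
        hits, skipped = [], 0
        if res["on_target"] is not None and rec.located:
            hits, skipped = transpose_target_to_offtargets(
                res["on_target"], rec.mapinfo, res["off_targets"], variants)
        res["hits"] = hits
        res["n_skipped_in_gap"] = skipped
        results[rec.ilmn_id] = res
    return results
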