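"""Bisulphite-conversion probe design engine.

Recomputes Infinium Allele A/B probe sequences from a manifest row's
``Forward_Sequence`` genomic context and the four-character IlmnID suffix,
and reports single-base-extension semantics.

Model
-----
Sodium bisulphite converts unmethylated cytosines to uracil (read as T after
amplification) and leaves methylated cytosines intact.  Methylation is
assumed to occur only at CpG dinucleotides, so conversion of a context
window has three modes:

``methylated``    non-CpG C -> T, CpG C kept as C (fully methylated epitype);
``unmethylated``  every C -> T;
``degenerate``    non-CpG C -> T, CpG C -> Y (either state; Type II bodies).

A probe targets the cytosine of one CpG.  The *top/bottom* suffix character
selects the strand carrying the interrogated C (``T`` = the strand shown in
``Forward_Sequence``, ``B`` = its reverse complement); the *converted/
opposite* character selects whether the probe hybridises to the bisulphite-
converted strand itself (``C``) or to the strand synthesised opposite it
(``O``).  Working in target-strand space ``S`` with the target C at index
``u``:

* Type I,  C-strand: window ``S[u : u+50]``; the probe is the reverse
  complement of the converted window, so its 3' terminus sits on the target
  C and extension reads the next base (``S[u-1]`` on the template).
* Type I,  O-strand: window ``S[u-50 : u]``; the probe equals the converted
  window (it pairs the opposite strand), its 3' terminus abuts the target
  and extension reads the converted target C itself.
* Type II, C-strand: window ``S[u+1 : u+51]`` (the G side plus 49 bases);
  single probe, degenerate body, extension reads the target C one position
  beyond the 3' terminus.
* Type II, O-strand: window ``S[u-50 : u]``; degenerate body, extension
  reads the converted target C.

Type I emits two probes (Allele A = unmethylated, Allele B = methylated);
Type II emits one degenerate probe (Allele A; Allele B empty).
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import VALID_GENOME, check_alphabet, complement, revcomp
from .errors import UndesignableError
from .manifest import ManifestTable, ProbeRecord

PROBE_LENGTH = 50


def bisulphite_convert_window(seq: str, mode: str, next_after: str | None = None) -> str:
    """Bisulphite-convert *seq* (given 5'->3' in genomic orientation).

    CpG status of a window-terminal C is decided by *next_after*, the
    genomic base following the window, because conversion depends on the
    genome, not on where the window was cut.  ``None`` means unknown: a
    terminal C is then treated as non-CpG (converted).

    >>> bisulphite_convert_window("ACGACCGT", "methylated")
    'ACGATCGT'
    >>> bisulphite_convert_window("ACGACCGT", "unmethylated")
    'ATGATTGT'
    >>> bisulphite_convert_window("ACGACCGT", "degenerate")
    'AYGATYGT'
    """
    if mode not in ("methylated", "unmethylated", "degenerate"):
        raise ValueError(f"unknown conversion mode {mode!r}")
    check_alphabet(seq, VALID_GENOME)
    if next_after is not None and next_after not in VALID_GENOME:
        next_after = None
    cpg_char = {"methylated": "C", "unmethylated": "T", "degenerate": "Y"}[mode]
    out = []
    n = len(seq)
    for i, base in enumerate(seq):
        if base != "C":
            out.append(base)
            continue
        nxt = seq[i + 1] if i + 1 < n else next_after
        out.append(cpg_char if nxt == "G" else "T")
    return "".join(out)


@dataclass
class DesignWindow:
    """The 50-nt design window for one probe, in target-strand orientation."""

    template_strand: str          # top_converted | bottom_converted | top_opposite | bottom_opposite
    window_seq: str               # 50 nt, genomic (target-strand) orientation
    target_offset: int            # index of the target C (O designs: one past the end)
    body_cpg_offsets: list[int]   # non-target CpG cytosines within the window
    next_after: str | None        # genomic base following the window (CpG context)


def _parse_forward_sequence(forward_sequence: str) -> tuple[str, int]:
    """Return (unbracketed plus-strand context, index of the target base)."""
    lo = forward_sequence.find("[")
    hi = forward_sequence.find("]")
    if lo < 0 or hi < lo:
        raise UndesignableError("Forward_Sequence has no bracketed target")
    target = forward_sequence[lo + 1 : hi]
    if len(target) != 2:
        raise UndesignableError(
            f"bracketed target {target!r} is not a dinucleotide (rs/nv chemistry is pass-through)"
        )
    seq = forward_sequence[:lo] + target + forward_sequence[hi + 1 :]
    check_alphabet(seq, VALID_GENOME, "Forward_Sequence")
    return seq, lo


def select_design_window(record_or_fwd, strand_tb=None, strand_co=None,
                         design_type=None) -> DesignWindow:
    """Locate the 50-nt design window implied by (strand_tb, strand_co, type).

    Accepts a :class:`ProbeRecord` (suffix fields parsed) or an explicit
    ``Forward_Sequence`` string plus the three design fields.
    """
    if isinstance(record_or_fwd, ProbeRecord):
        rec = record_or_fwd
        forward_sequence = rec.forward_sequence
        strand_tb, strand_co, design_type = rec.strand_tb, rec.strand_co, rec.design_type
    else:
        forward_sequence = record_or_fwd
    if strand_tb not in ("T", "B") or strand_co not in ("C", "O") or design_type not in ("I", "II"):
        raise UndesignableError(
            f"design fields unavailable or unknown: tb={strand_tb!r} co={strand_co!r} type={design_type!r}"
        )
    plus, t = _parse_forward_sequence(forward_sequence)
    if strand_tb == "T":
        s, u = plus, t
    else:
        s, u = revcomp(plus), len(plus) - t - 2
    if s[u] != "C":
        raise UndesignableError(
            f"target base on the {strand_tb} strand is {s[u]!r}, not C"
        )
    if strand_co == "C":
        lo, hi = (u, u + PROBE_LENGTH) if design_type == "I" else (u + 1, u + 1 + PROBE_LENGTH)
    else:
        lo, hi = u - PROBE_LENGTH, u
    if lo < 0 or hi > len(s):
        raise UndesignableError("Forward_Sequence flank too short for a 50-nt window")
    window = s[lo:hi]
    next_after = s[hi] if hi < len(s) else None
    strand_name = ("top" if strand_tb == "T" else "bottom") + (
        "_converted" if strand_co == "C" else "_opposite"
    )
    target_offset = u - lo  # may equal 50 for O designs (one past the window end)
    body = [
        i for i in range(PROBE_LENGTH)
        if window[i] == "C"
        and (window[i + 1] if i + 1 < PROBE_LENGTH else next_after) == "G"
        and i != target_offset
    ]
    return DesignWindow(strand_name, window, target_offset, body, next_after)


def _probe_from_window(win: DesignWindow, mode: str) -> str:
    converted = bisulphite_convert_window(win.window_seq, mode, win.next_after)
    if win.template_strand.endswith("_converted"):
        return revcomp(converted)
    return converted


def recompute_probe_sequences(record: ProbeRecord) -> tuple[str, str]:
    """Recompute (allele_a, allele_b) from Forward_Sequence + suffix.

    Type I: allele A assumes the unmethylated epitype, allele B the
    methylated one.  Type II: a single degenerate probe, allele B empty.
    """
    if record.strand_tb == "unknown" or record.design_type is None:
        raise UndesignableError(f"{record.ilmn_id}: no parsed suffix")
    win = select_design_window(record)
    if record.design_type == "I":
        return _probe_from_window(win, "unmethylated"), _probe_from_window(win, "methylated")
    return _probe_from_window(win, "degenerate"), ""


@dataclass
class SequenceVerification:
    ilmn_id: str
    attempted: bool
    matched: bool
    expected_a: str = ""
    recomputed_a: str = ""
    expected_b: str = ""
    recomputed_b: str = ""
    error: str = ""

    @property
    def first_mismatch_offset(self) -> int:
        for exp, got in ((self.expected_a, self.recomputed_a), (self.expected_b, self.recomputed_b)):
            for i, (e, g) in enumerate(zip(exp, got)):
                if e != g:
                    return i
            if len(exp) != len(got):
                return min(len(exp), len(got))
        return -1


def verify_manifest_sequences(table: ManifestTable):
    """Check every recomputable probe's alleles against the manifest columns.

    Returns ``(results, fraction)``: per-probe flags and the fraction of
    attempted probes whose recomputed sequences match character-for-character
    (both alleles where present).  Undesignable probes count as unmatched;
    rs/nv probes (pass-through chemistry) are not attempted.
    """
    results = []
    n_attempted = n_matched = 0
    for rec in table:
        if rec.target_class in ("rs", "nv", "control"):
            results.append(SequenceVerification(rec.ilmn_id, False, False, error="not attempted"))
            continue
        n_attempted += 1
        try:
            a, b = recompute_probe_sequences(rec)
        except (UndesignableError, ValueError) as exc:
            results.append(SequenceVerification(
                rec.ilmn_id, True, False,
                expected_a=rec.allele_a_seq, expected_b=rec.allele_b_seq, error=str(exc),
            ))
            continue
        ok = a == rec.allele_a_seq and b == rec.allele_b_seq
        n_matched += ok
        results.append(SequenceVerification(
            rec.ilmn_id, True, ok, rec.allele_a_seq, a, rec.allele_b_seq, b,
        ))
    fraction = n_matched / n_attempted if n_attempted else float("nan")
    return results, fraction


def channel_for_base(base: str) -> str:
    """Fluorescence channel of an incorporated ddNTP: A/T red, C/G green."""
    if base in "AT":
        return "Red"
    if base in "CG":
        return "Grn"
    raise ValueError(f"not a nucleotide: {base!r}")


def infer_extension_site(record: ProbeRecord):
    """Where single-base extension reads relative to the target CpG.

    Returns ``(site, expected_channel)`` with ``site`` in {"target_C",
    "next_base"}.  Type I probes designed on the converted (C) strand extend
    at the base next to the target; O-strand Type I and all Type II designs
    read the converted target C itself.  Type II channel is epitype-dependent
    (not applicable, returned as None).
    """
    if record.design_type is None:
        raise UndesignableError(f"{record.ilmn_id}: no parsed suffix")
    if record.design_type == "II":
        return "target_C", None
    if record.strand_co == "C":
        channel = channel_for_base(record.next_base) if record.next_base else ""
        return "next_base", channel
    if record.strand_co == "O":
        channel = channel_for_base(record.next_base) if record.next_base else ""
        return "target_C", channel
    raise UndesignableError(f"{record.ilmn_id}: unknown converted/opposite strand")


def next_base_for_design(s: str, u: int, strand_co: str) -> str:
    """Extension base for a Type I design in target-strand space ``S``.

    C-strand: template base ``S[u-1]`` after conversion (its successor is the
    target C, so a C here is non-CpG and always converts), complemented into
    probe orientation.  O-strand: the converted target C read under the
    methylated template.
    """
    if strand_co == "O":
        return "C"
    prev = s[u - 1]
    return complement("T" if prev == "C" else prev)
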