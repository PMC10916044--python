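"""Low-level nucleotide-string helpers shared across modules.

All sequences are plain upper-case Python strings.  The complement table
covers the IUPAC codes actually produced by bisulphite probe design:
A/C/G/T plus the two-fold degenerate R (A|G) and Y (C|T), and N.
"""

from __future__ import annotations

COMPLEMENT = str.maketrans("ACGTRYN", "TGCAYRN")

#: genome bases compatible with each probe base (degenerate-aware matching)
EQUIV: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "N": frozenset(),
}

VALID_GENOME = frozenset("ACGT")
VALID_PROBE = frozenset("ACGTRYN")


def complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement; an involution that maps Y<->R consistently."""
    return seq.translate(COMPLEMENT)[::-1]


def bases_match(probe_base: str, genome_base: str) -> bool:
    """Degenerate-aware equality: R matches A or G, Y matches C or T."""
    return genome_base in EQUIV.get(probe_base, frozenset())


def check_alphabet(seq: str, alphabet: frozenset[str], what: str = "sequence") -> None:
    bad = set(seq) - alphabet
    if bad:
        raise ValueError(f"invalid {what} characters: {sorted(bad)!r}")
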