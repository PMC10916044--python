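"""Detection and grouping of the three EPICv2 replicate-probe classes.

* ``exact``          — identical probe name AND identical allele sequences;
* ``location``       — identical target coordinate, >= 2 distinct sequences
  (name agreement is recorded, covering both published phrasings);
* ``sequence_only``  — identical allele sequences, >= 2 distinct names.

Location keying uses the reconciled (chrom, 1-based C coordinate); probes at
chr0/MAPINFO 0 are excluded from location sets but may still be sequence
members.  Sequence keying uses the (Allele A, Allele B) pair.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .manifest import ManifestTable


@dataclass
class ReplicateSet:
    set_id: str
    replicate_class: str                 # exact | location | sequence_only
    member_ilmn_ids: list[str]
    key: tuple
    names_agree: bool = True             # location sets: do all members share a Name?
    strands_agree: bool = True           # location sets: same top/bottom strand?

    def __len__(self):
        return len(self.member_ilmn_ids)


def classify_replicates(table: ManifestTable):
    """Group replicate probes and emit per-probe augmented-manifest fields.

    Returns ``(sets, fields)`` where *sets* is a list of :class:`ReplicateSet`
    (maximal, keys unique per class) and *fields* a DataFrame indexed by
    IlmnID with namerep / posrep / posrep_IlmnIDs / posrep_RepNum /
    seqrep_IlmnIDs / seqrep_RepNum columns.
    """
    by_name = defaultdict(list)
    by_loc = defaultdict(list)
    by_seq = defaultdict(list)
    for rec in table:
        by_name[rec.name].append(rec)
        if rec.located:
            by_loc[rec.location].append(rec)
        if rec.allele_a_seq:
            by_seq[rec.sequence_key].append(rec)

    sets: list[ReplicateSet] = []
    n = 0
    # exact: same name and same sequence pair
    for name, recs in by_name.items():
        groups = defaultdict(list)
        for r in recs:
            groups[r.sequence_key].append(r)
        for seqkey, members in groups.items():
            if len(members) >= 2:
                n += 1
                sets.append(ReplicateSet(
                    f"exact{n:05d}", "exact", [m.ilmn_id for m in members], (name, seqkey),
                ))
    # location: shared coordinate with >= 2 distinct sequences
    n = 0
    for loc, recs in by_loc.items():
        if len(recs) < 2 or len({r.sequence_key for r in recs}) < 2:
            continue
        n += 1
        sets.append(ReplicateSet(
            f"loc{n:05d}", "location", [r.ilmn_id for r in recs], loc,
            names_agree=len({r.name for r in recs}) == 1,
            strands_agree=len({r.strand_tb for r in recs}) == 1,
        ))
    # sequence_only: shared sequence pair with >= 2 distinct names
    n = 0
    for seqkey, recs in by_seq.items():
        if len({r.name for r in recs}) < 2:
            continue
        n += 1
        sets.append(ReplicateSet(
            f"seq{n:05d}", "sequence_only", [r.ilmn_id for r in recs], seqkey,
        ))

    rows = []
    for rec in table:
        loc_mates = [r for r in by_loc.get(rec.location, [])] if rec.located else []
        seq_mates = by_seq.get(rec.sequence_key, []) if rec.allele_a_seq else []
        rows.append({
            "IlmnID": rec.ilmn_id,
            "namerep": len(by_name[rec.name]),
            "posrep": len(loc_mates) if loc_mates else 1,
            "posrep_IlmnIDs": ";".join(r.ilmn_id for r in loc_mates if r.ilmn_id != rec.ilmn_id),
            "posrep_RepNum": len(loc_mates) if loc_mates else 1,
            "seqrep_IlmnIDs": ";".join(r.ilmn_id for r in seq_mates if r.ilmn_id != rec.ilmn_id),
            "seqrep_RepNum": len(seq_mates) if seq_mates else 1,
        })
    fields = pd.DataFrame(rows).set_index("IlmnID")
    return sets, fields


def replicate_size_histogram(sets) -> dict[str, dict[int, int]]:
    """Per class, a mapping of set size -> number of sets of that size."""
    out: dict[str, dict[int, int]] = {}
    for s in sets:
        hist = out.setdefault(s.replicate_class, {})
        hist[len(s)] = hist.get(len(s), 0) + 1
    return out
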