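"""Reading, writing and reconciling Infinium methylation-array manifests.

Two dialects are supported:

* the Illumina CSV layout (``[Assay]`` / ``[Controls]`` sections, 1-based
  MAPINFO giving the plus-strand coordinate of the interrogated cytosine);
* the SeSAMe tab-delimited layout (hg38, BED-convention 0-based half-open
  two-nucleotide CpG interval).

Internally every located probe carries the 1-based plus-strand position of the
interrogated cytosine (``mapinfo``); BED intervals are converted at the
boundary.  Probes with ``CHR == chr0`` / ``MAPINFO == 0`` are retained in
tables but must be skipped by location-keyed operations.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import IlmnIDParseError, ManifestFormatError

_SUFFIX_RE = re.compile(r"^[TB][CO][12][1-9]$")
# anything shaped like a four-character suffix triggers strict validation
_SUFFIX_SHAPE_RE = re.compile(r"^[A-Z]{2}\d{2}$")

_TARGET_CLASSES = ("cg", "ch", "rs", "nv")

#: assay columns an Illumina-dialect manifest must provide
MANDATORY_ILLUMINA_COLUMNS = (
    "IlmnID",
    "Name",
    "AlleleA_ProbeSeq",
    "AlleleB_ProbeSeq",
    "Infinium_Design_Type",
    "Next_Base",
    "Color_Channel",
    "CHR",
    "MAPINFO",
    "Forward_Sequence",
)

#: augmented-manifest annotation columns, in output order
AUGMENTED_COLUMNS = (
    "posrep",
    "posrep_IlmnIDs",
    "posrep_RepNum",
    "namerep",
    "seqrep_IlmnIDs",
    "seqrep_RepNum",
    "EPICv1probeID",
    "EPICv1locmatch",
    "EPICv1seqmatch",
    "K450probeID",
    "K450locmatch",
    "K450seqmatch",
    "K27probeID",
    "K27locmatch",
    "K27seqmatch",
    "CH_BLAT",
    "Num_offtargets",
    "CH_WGBS_evidence",
    "Suggested_offtarget",
    "Rep_results_by_NAME",
    "Rep_results_by_SEQUENCE",
    "Rep_results_by_LOCATION",
)


def parse_ilmnid(ilmn_id: str):
    """Decompose an EPICv2-style IlmnID into its design components.

    Returns ``(name, target_class, strand_tb, strand_co, design_type,
    rep_num)``.  IDs without a four-character suffix (older-array dialects)
    return ``unknown`` strand fields, ``None`` design type and ``rep_num`` 1.

    >>> parse_ilmnid("cg09617579_BC12")
    ('cg09617579', 'cg', 'B', 'C', 'I', 2)
    """
    if not ilmn_id:
        raise IlmnIDParseError("empty IlmnID")
    name, suffix = ilmn_id, None
    if "_" in ilmn_id:
        head, _, tail = ilmn_id.rpartition("_")
        if _SUFFIX_SHAPE_RE.match(tail):
            if not _SUFFIX_RE.match(tail):
                raise IlmnIDParseError(
                    f"IlmnID {ilmn_id!r}: suffix {tail!r} does not match [TB][CO][12][1-9]"
                )
            name, suffix = head, tail
    target_class = next((c for c in _TARGET_CLASSES if name.startswith(c)), "control")
    if suffix is None:
        return name, target_class, "unknown", "unknown", None, 1
    design_type = "I" if suffix[2] == "1" else "II"
    return name, target_class, suffix[0], suffix[1], design_type, int(suffix[3])


def compose_ilmnid(name: str, strand_tb: str, strand_co: str, design_type: str, rep_num: int) -> str:
    return f"{name}_{strand_tb}{strand_co}{'1' if design_type == 'I' else '2'}{rep_num}"


@dataclass
class ProbeRecord:
    """One manifest assay row."""

    ilmn_id: str
    name: str = ""
    target_class: str = "cg"
    strand_tb: str = "unknown"
    strand_co: str = "unknown"
    design_type: str | None = None
    rep_num: int = 1
    chrom: str = "chr0"
    mapinfo: int = 0
    forward_sequence: str = ""
    allele_a_seq: str = ""
    allele_b_seq: str = ""
    next_base: str = ""
    color_channel: str = ""
    extras: dict = field(default_factory=dict, compare=False, repr=False)

    @classmethod
    def from_ilmnid(cls, ilmn_id: str, **kw) -> "ProbeRecord":
        name, tclass, tb, co, dtype, rep = parse_ilmnid(ilmn_id)
        return cls(
            ilmn_id=ilmn_id, name=name, target_class=tclass, strand_tb=tb,
            strand_co=co, design_type=dtype, rep_num=rep, **kw,
        )

    @property
    def located(self) -> bool:
        return self.chrom != "chr0" and self.mapinfo > 0

    @property
    def location(self) -> tuple[str, int] | None:
        return (self.chrom, self.mapinfo) if self.located else None

    @property
    def sequence_key(self) -> tuple[str, str]:
        return (self.allele_a_seq, self.allele_b_seq)


class ManifestTable:
    """Ordered collection of :class:`ProbeRecord` with unique IlmnIDs.

    Order is preserved because downstream tie-breaks ("first in manifest")
    depend on it.  Control probes, when parsed, live in a separate partition
    and are never counted among the assay records.
    """

    def __init__(self, records, source_dialect="illumina", assembly="hg38", controls=None):
        self.records: list[ProbeRecord] = list(records)
        self.source_dialect = source_dialect
        self.assembly = assembly
        self.controls: list[dict] = list(controls) if controls else []
        self._index: dict[str, ProbeRecord] = {}
        for rec in self.records:
            if rec.ilmn_id in self._index:
                raise ManifestFormatError(f"duplicate IlmnID {rec.ilmn_id!r}")
            self._index[rec.ilmn_id] = rec

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, ilmn_id):
        return ilmn_id in self._index

    def __getitem__(self, ilmn_id) -> ProbeRecord:
        return self._index[ilmn_id]

    def __eq__(self, other):
        return (
            isinstance(other, ManifestTable)
            and self.records == other.records
            and self.source_dialect == other.source_dialect
        )

    def manifest_order(self, ilmn_id: str) -> int:
        """Rank of a probe in file order (used for first-in-manifest tie-breaks)."""
        return next(i for i, r in enumerate(self.records) if r.ilmn_id == ilmn_id)

    def counts_by_class(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for rec in self.records:
            out[rec.target_class] = out.get(rec.target_class, 0) + 1
        return out

    def located_records(self):
        return [r for r in self.records if r.located]

    def unique_locations(self, exclude_classes=("rs", "nv")) -> set[tuple[str, int]]:
        return {
            r.location
            for r in self.records
            if r.located and r.target_class not in exclude_classes
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "IlmnID": r.ilmn_id,
                "Name": r.name,
                "target_class": r.target_class,
                "strand_tb": r.strand_tb,
                "strand_co": r.strand_co,
                "Infinium_Design_Type": r.design_type or "",
                "Rep_Num": r.rep_num,
                "CHR": r.chrom,
                "MAPINFO": r.mapinfo,
                "Forward_Sequence": r.forward_sequence,
                "AlleleA_ProbeSeq": r.allele_a_seq,
                "AlleleB_ProbeSeq": r.allele_b_seq,
                "Next_Base": r.next_base,
                "Color_Channel": r.color_channel,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)


@dataclass
class CoordinateDiscrepancy:
    """Illumina point vs SeSAMe BED-range (dis)agreement for one probe."""

    ilmn_id: str
    illumina_pos: int            # 1-based cytosine coordinate
    sesame_range: tuple[int, int]  # 0-based half-open, width 2
    agrees: bool


def _point_range_agree(pos_1based: int, beg0: int, end0: int) -> bool:
    """True iff the 1-nt point, widened to its CpG dinucleotide, intersects
    the 0-based half-open range.

    The point may follow either CpG-strand convention (the C or the paired G
    position), so both candidate dinucleotides are tried; the test is
    therefore symmetric in convention.
    """
    p0 = pos_1based - 1
    for lo, hi in ((p0, p0 + 2), (p0 - 1, p0 + 1)):
        if max(lo, beg0) < min(hi, end0):
            return True
    return False


def _sections(lines):
    """Split an Illumina CSV into named sections ('' for any preamble)."""
    current, out = "", {"": []}
    for line in lines:
        stripped = line.strip().strip(",")
        if stripped.startswith("[") and stripped.endswith("]"):
            current = stripped[1:-1]
            out.setdefault(current, [])
        else:
            out.setdefault(current, []).append(line)
    return out


def read_illumina_manifest(path, include_controls: bool = False) -> ManifestTable:
    """Read an Illumina-dialect CSV manifest (EPIC-8v2-0_A1.csv layout).

    Assay rows become :class:`ProbeRecord`; the optional ``[Controls]``
    section is parsed into ``table.controls`` when *include_controls*.
    """
    with open(path) as fh:
        sections = _sections(fh.read().splitlines())
    if "Assay" not in sections or not sections["Assay"]:
        raise ManifestFormatError("no [Assay] section found")
    assay = pd.read_csv(
        io.StringIO("\n".join(sections["Assay"])), dtype=str, keep_default_na=False
    )
    missing = [c for c in MANDATORY_ILLUMINA_COLUMNS if c not in assay.columns]
    if missing:
        raise ManifestFormatError(f"missing mandatory column(s): {', '.join(missing)}")

    records = []
    known = set(MANDATORY_ILLUMINA_COLUMNS) | {"Rep_Num"}
    extra_cols = [c for c in assay.columns if c not in known]
    for idx, row in enumerate(assay.itertuples(index=False)):
        row = row._asdict()
        try:
            rec = ProbeRecord.from_ilmnid(row["IlmnID"])
            chrom = row["CHR"] or "chr0"
            mapinfo = int(float(row["MAPINFO"])) if row["MAPINFO"] != "" else 0
            rec.chrom = chrom if mapinfo > 0 else "chr0"
            rec.mapinfo = mapinfo
            rec.forward_sequence = row["Forward_Sequence"]
            rec.allele_a_seq = row["AlleleA_ProbeSeq"]
            rec.allele_b_seq = row["AlleleB_ProbeSeq"]
            rec.next_base = row["Next_Base"]
            rec.color_channel = row["Color_Channel"]
            if row["Infinium_Design_Type"]:
                rec.design_type = row["Infinium_Design_Type"]
            if row.get("Rep_Num", ""):
                rec.rep_num = int(row["Rep_Num"])
            rec.extras = {c: row[c] for c in extra_cols if row[c] != ""}
        except (ValueError, IlmnIDParseError) as exc:
            raise ManifestFormatError(f"malformed assay row {idx}: {exc}") from exc
        records.append(rec)

    controls = []
    if include_controls and sections.get("Controls"):
        for idx, line in enumerate(sections["Controls"]):
            if not line.strip():
                continue
            parts = line.split(",")
            if len(parts) < 3:
                raise ManifestFormatError(f"malformed control row {idx}: {line!r}")
            controls.append(
                {"Address_ID": parts[0], "Type": parts[1], "Color": parts[2],
                 "Name": parts[3] if len(parts) > 3 else ""}
            )
    return ManifestTable(records, source_dialect="illumina", controls=controls)


_SESAME_COLUMNS = ["Probe_ID", "CpG_chrm", "CpG_beg", "CpG_end", "strand", "col"]


def read_sesame_manifest(path) -> ManifestTable:
    """Read a SeSAMe-dialect TSV manifest (hg38, BED-convention coordinates).

    Coordinates are stored as the 0-based half-open CpG interval in
    ``extras`` plus a derived 1-based cytosine point in ``mapinfo``.
    """
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if not lines:
        return ManifestTable([], source_dialect="sesame")
    header = lines[0].split("\t")
    if "Probe_ID" in header:
        cols, body = header, lines[1:]
    else:
        cols, body = _SESAME_COLUMNS[: len(lines[0].split("\t"))], lines
    records = []
    for lineno, line in enumerate(body, start=2 if cols is header else 1):
        parts = line.split("\t")
        row = dict(zip(cols, parts))
        try:
            beg = int(row["CpG_beg"]) if row.get("CpG_beg") not in (None, "", "NA") else None
            end = int(row["CpG_end"]) if row.get("CpG_end") not in (None, "", "NA") else None
        except ValueError as exc:
            raise ManifestFormatError(f"non-numeric coordinate at line {lineno}") from exc
        rec = ProbeRecord.from_ilmnid(row["Probe_ID"])
        chrom = row.get("CpG_chrm") or "chr0"
        if beg is not None and chrom not in ("chr0", "NA", ""):
            rec.chrom = chrom
            rec.mapinfo = beg + 1          # C base of the BED dinucleotide
            rec.extras["CpG_beg"] = beg
            rec.extras["CpG_end"] = end if end is not None else beg + 2
        if row.get("strand"):
            rec.extras["strand"] = row["strand"]
        if row.get("col"):
            rec.color_channel = row["col"]
        if row.get("AlleleA_ProbeSeq"):
            rec.allele_a_seq = row["AlleleA_ProbeSeq"]
        if row.get("AlleleB_ProbeSeq"):
            rec.allele_b_seq = row["AlleleB_ProbeSeq"]
        records.append(rec)
    return ManifestTable(records, source_dialect="sesame")


def compare_manifests(illumina: ManifestTable, sesame: ManifestTable):
    """Compare an Illumina-dialect table with a SeSAMe-dialect table.

    Returns ``(discrepancies, report)`` where *discrepancies* is a list of
    :class:`CoordinateDiscrepancy` for shared, located probes, and *report*
    is a dict with absent-probe lists and summary counts.  Probes at
    chr0/MAPINFO 0 on either side are skipped (no location to compare).
    """
    ill_ids = {r.ilmn_id for r in illumina}
    ses_ids = {r.ilmn_id for r in sesame}
    absent_from_sesame = sorted(ill_ids - ses_ids)
    absent_from_illumina = sorted(ses_ids - ill_ids)

    discrepancies = []
    for rec in illumina:
        if rec.ilmn_id not in sesame or not rec.located:
            continue
        other = sesame[rec.ilmn_id]
        if not other.located:
            continue
        beg = other.extras.get("CpG_beg", other.mapinfo - 1)
        end = other.extras.get("CpG_end", beg + 2)
        agrees = rec.chrom == other.chrom and _point_range_agree(rec.mapinfo, beg, end)
        discrepancies.append(
            CoordinateDiscrepancy(rec.ilmn_id, rec.mapinfo, (beg, end), agrees)
        )
    n_disagree = sum(not d.agrees for d in discrepancies)
    report = {
        "absent_from_sesame": absent_from_sesame,
        "absent_from_illumina": absent_from_illumina,
        "n_compared": len(discrepancies),
        "n_discrepant": n_disagree,
    }
    return discrepancies, report


def write_augmented_manifest(table: ManifestTable, annotations, path) -> None:
    """Write an Illumina-layout CSV with extra annotation columns.

    *annotations* maps column name -> {ilmn_id: value}.  Annotation keys not
    present in *table* trigger a warning listing the orphans; rows without a
    value for a column get an empty field.  The file round-trips through
    :func:`read_illumina_manifest`.
    """
    annotations = annotations or {}
    known = {r.ilmn_id for r in table}
    orphans = sorted({k for block in annotations.values() for k in block} - known)
    if orphans:
        warnings.warn(f"annotation keys not in manifest: {orphans[:10]}"
                      f"{'...' if len(orphans) > 10 else ''}")
    frame = table.to_frame().drop(columns=["target_class", "strand_tb", "strand_co"])
    for col in AUGMENTED_COLUMNS:
        if col in annotations:
            frame[col] = [annotations[col].get(r.ilmn_id, "") for r in table]
    for col in annotations:
        if col not in frame.columns:
            frame[col] = [annotations[col].get(r.ilmn_id, "") for r in table]
    with open(path, "w") as fh:
        fh.write("[Assay]\n")
        frame.to_csv(fh, index=False)
        if table.controls:
            fh.write("[Controls]\n")
            for c in table.controls:
                fh.write(f"{c['Address_ID']},{c['Type']},{c['Color']},{c['Name']}\n")


def write_sesame_manifest(table: ManifestTable, path) -> None:
    """Write a SeSAMe-dialect TSV (BED-convention CpG intervals)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_SESAME_COLUMNS + ["AlleleA_ProbeSeq", "AlleleB_ProbeSeq"]) + "\n")
        for r in table:
            if r.located:
                beg = r.extras.get("CpG_beg", r.mapinfo - 1)
                end = r.extras.get("CpG_end", beg + 2)
                chrom = r.chrom
            else:
                beg, end, chrom = "NA", "NA", "NA"
            fh.write("\t".join(map(str, [
                r.ilmn_id, chrom, beg, end, r.extras.get("strand", "+"),
                r.color_channel, r.allele_a_seq, r.allele_b_seq,
            ])) + "\n")
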