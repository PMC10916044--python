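"""Seeded generators for toy genomes, designed manifests, planted off-target
homologies and matched multi-platform methylation data.

The generators define the study conditions every other module is exercised
under: a matched design of 18 samples across EPICv1, EPICv2 and WGBS
(mirroring the matched cross-platform design), latent per-site methylation
drawn from a bimodal-plus-intermediate mixture (the intermediate component
mimics enhancer-like sites), array observations M = alpha_p + beta_p*mu_M +
Gaussian noise, binomial WGBS counts at Poisson-distributed coverage, and
Bernoulli detection-p dropouts.  Identical config + seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import design as _design
from .errors import EpickitError, UndesignableError
from .evaluate import MethylMatrix, beta_from_m, m_from_beta, wgbs_logit
from .manifest import ManifestTable, ProbeRecord, compose_ilmnid

FLANK = 60
PROBE_LENGTH = _design.PROBE_LENGTH
DESIGN_COMBOS = [(tb, co, dt) for tb in "TB" for co in "CO" for dt in ("I", "II")]


@dataclass
class PlatformModel:
    """Generative model of one platform's M-value readout."""

    offset: float = 0.0       # alpha_p
    slope: float = 1.0        # beta_p, vs the latent methylation M-value
    noise_sd: float = 0.15    # sigma_p


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 20_000
    cpg_density: float = 0.04          # expected CG starts per position
    n_probes: int = 48
    n_samples: int = 18                # matched-design sample count
    replicate_plantings: dict = field(default_factory=lambda: {
        "exact": 2, "location": 2, "sequence_only": 1})
    offtarget_plantings: list = field(default_factory=lambda: [(0, 0), (3, 0), (2, 1)])
    platforms: dict = field(default_factory=lambda: {
        "EPICv1": PlatformModel(0.0, 1.0, 0.15),
        "EPICv2": PlatformModel(0.0, 1.0, 0.15),
        "WGBS": PlatformModel(0.0, 1.3, 0.45),
    })
    wgbs_mean_coverage: float = 12.0
    detection_fail_rate: float = 0.01
    zero_coverage_rate: float = 0.01
    mixture_weights: tuple = (0.4, 0.4, 0.2)   # near-0, near-1, intermediate
    mixture_params: tuple = ((1.0, 12.0), (12.0, 1.0), (6.0, 6.0))


def _rng(config_or_seed) -> np.random.Generator:
    seed = config_or_seed.seed if isinstance(config_or_seed, SimulationConfig) \
        else config_or_seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# toy genomes

def generate_toy_genome(config: SimulationConfig | None = None, *,
                        length: int | None = None, cpg_density: float | None = None,
                        seed: int | None = None, chrom: str = "chr1") -> dict[str, str]:
    """Deterministic toy chromosome with a requested CpG density.

    The backbone is sampled CG-free (no G ever follows a C), then a
    binomially-drawn number of CG dinucleotides is planted at uniform
    non-adjacent positions, so the realised count is Binomial(length,
    density) up to placement collisions.
    """
    config = config or SimulationConfig()
    length = length if length is not None else config.genome_length
    density = cpg_density if cpg_density is not None else config.cpg_density
    rng = _rng(seed if seed is not None else config)
    if length < 200:
        raise EpickitError("genome_length must be >= 200")
    if not 0 <= density <= 0.45:
        raise EpickitError(f"infeasible CpG density {density}")
    bases = "ACGT"
    seq = []
    prev = ""
    probs = np.full(4, 0.25)
    for draw in rng.integers(0, 4, size=length):
        b = bases[draw]
        if prev == "C" and b == "G":
            b = "T"   # keep the backbone CG-free
        seq.append(b)
        prev = b
    n_cpg = rng.binomial(length, density)
    taken = set()
    positions = rng.integers(0, length - 1, size=4 * max(n_cpg, 1))
    planted = 0
    for p in positions:
        if planted >= n_cpg:
            break
        p = int(p)
        if any(q in taken for q in (p - 1, p, p + 1)):
            continue
        seq[p], seq[p + 1] = "C", "G"
        taken.update((p, p + 1))
        planted += 1
    return {chrom: "".join(seq)}


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def cpg_positions(genome: dict[str, str], min_flank: int = FLANK):
    """1-based plus-strand C positions of CpGs with adequate flanks."""
    out = []
    for chrom, seq in genome.items():
        for i in range(min_flank, len(seq) - min_flank - 2):
            if seq[i] == "C" and seq[i + 1] == "G":
                out.append((chrom, i + 1))
    return out


# ---------------------------------------------------------------------------
# probe design

def design_probe(genome: dict[str, str], chrom: str, target_pos: int,
                 strand_tb: str, strand_co: str, design_type: str,
                 rep_num: int = 1, name: str | None = None) -> ProbeRecord:
    """Design one probe against a toy genome.

    *target_pos* is the 1-based plus-strand C of a CpG with >= 60 nt flanks.
    The emitted record round-trips through
    :func:`epickit.design.recompute_probe_sequences` exactly.
    """
    seq = genome[chrom]
    t0 = target_pos - 1
    if seq[t0 : t0 + 2] != "CG":
        raise UndesignableError(f"{chrom}:{target_pos} is not a CpG cytosine")
    if t0 < FLANK or t0 + 2 + FLANK > len(seq):
        raise UndesignableError("insufficient flank for Forward_Sequence")
    forward = seq[t0 - FLANK : t0] + "[CG]" + seq[t0 + 2 : t0 + 2 + FLANK]
    name = name or f"cg{target_pos:08d}"
    ilmn_id = compose_ilmnid(name, strand_tb, strand_co, design_type, rep_num)
    rec = ProbeRecord.from_ilmnid(ilmn_id)
    rec.chrom = chrom
    rec.mapinfo = target_pos
    rec.forward_sequence = forward
    rec.allele_a_seq, rec.allele_b_seq = _design.recompute_probe_sequences(
        replace_fields(rec, forward))
    if design_type == "I":
        win = _design.select_design_window(rec)
        plus, t = _design._parse_forward_sequence(forward)
        s, u = (plus, t) if strand_tb == "T" else (
            _design.revcomp(plus), len(plus) - t - 2)
        rec.next_base = _design.next_base_for_design(s, u, strand_co)
        rec.color_channel = _design.channel_for_base(rec.next_base)
    return rec


def replace_fields(rec: ProbeRecord, forward: str) -> ProbeRecord:
    out = ProbeRecord.from_ilmnid(rec.ilmn_id)
    out.forward_sequence = forward
    return out


def design_manifest(genome: dict[str, str], n_probes: int,
                    rng: np.random.Generator | None = None,
                    seed: int = 0, combos=None) -> ManifestTable:
    """A designed manifest cycling through the requested (TB x CO x type)
    combinations over randomly chosen CpG targets."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    combos = combos or DESIGN_COMBOS
    targets = cpg_positions(genome)
    if len(targets) < n_probes:
        raise EpickitError(
            f"genome has only {len(targets)} designable CpGs, need {n_probes}")
    picks = rng.choice(len(targets), size=n_probes, replace=False)
    records = []
    for i, pick in enumerate(picks):
        chrom, pos = targets[int(pick)]
        tb, co, dt = combos[i % len(combos)]
        records.append(design_probe(genome, chrom, pos, tb, co, dt))
    return ManifestTable(records)


# ---------------------------------------------------------------------------
# planted off-target homologies

@dataclass
class PlantedOffTarget:
    probe_id: str
    chrom: str
    start0: int                 # 0-based plus-strand start of the planted window
    length: int
    n_mismatches: int
    n_indels: int
    expected_matches: int
    expected_score: int
    expected_coord: int         # transposed plus-strand coordinate of the target base
    target_offset_in_probe: int


def _probe_target_offset(rec: ProbeRecord) -> int:
    """Probe-sequence offset whose template position is transposed.

    The anchor is the base aligned to (or abutting) the plus-strand MAPINFO
    cytosine; returned in probe (Allele A) coordinates.
    """
    win = _design.select_design_window(rec)
    off = win.target_offset
    if win.template_strand.endswith("_converted"):
        # probe is the reverse complement of the window
        return _design.PROBE_LENGTH - 1 - off if off < _design.PROBE_LENGTH else -1
    return off if off < _design.PROBE_LENGTH else _design.PROBE_LENGTH


def _window_accept_sets(record: ProbeRecord) -> list[set]:
    """Per plus-window position, the genome bases the probe still matches.

    Matching happens on a bisulphite-converted genome variant, whose
    per-position map is 2-to-1 (both C and T read as T on the converted
    strand; both A and G read as T on the converted opposite strand), and
    degenerate probe bases (R/Y) accept either alternative.  Used to detect
    ambiguous homolog plantings.
    """
    from ._seq import EQUIV

    from ._seq import complement

    probe = record.allele_a_seq
    # plus-window offset i pairs probe offset j: reversed for top-converted
    # and bottom-opposite geometries; converted-strand (C) designs align the
    # reverse complement of the probe, so the compared base is complemented
    plus_reversed = (record.strand_tb == "T") == (record.strand_co == "C")
    if record.strand_tb == "T":
        # variant = bisulphite(plus): T <- {C, T}
        preimage = {"A": "A", "C": "", "G": "G", "T": "CT"}
    else:
        # variant = bisulphite(complement(plus)): T <- {A, G}
        preimage = {"A": "T", "C": "", "G": "C", "T": "AG"}
    accepts = []
    for i in range(PROBE_LENGTH):
        j = PROBE_LENGTH - 1 - i if plus_reversed else i
        base = complement(probe[j]) if record.strand_co == "C" else probe[j]
        acc: set = set()
        for variant_base in EQUIV[base]:
            acc.update(preimage[variant_base])
        accepts.append(acc)
    return accepts


def _clip_ambiguous(accepts, region: str, region_offset: int,
                    homolog_len: int, n_indels: int,
                    expected_matches: int) -> bool:
    """True when a rival alignment interpretation ties or beats the intended
    gapped one, leaving the transposed anchor ambiguous.

    *region* is the final genome sequence around the planting, starting at
    plus offset ``dest - region_offset``.  Rivals enumerated: indel-free
    windows at small shifts, probe-end clips, and single target-skip
    ("deletion in query") alignments that recruit flanking bases.
    """

    def run(start: int, skip_at: int | None = None, skip_len: int = 0) -> int:
        m = 0
        for i in range(PROBE_LENGTH):
            t = start + i + (skip_len if skip_at is not None and i >= skip_at else 0)
            if 0 <= t < len(region) and region[t] in accepts[i]:
                m += 1
        return m

    shift = PROBE_LENGTH - homolog_len
    base = region_offset  # region index of the homolog start
    # indel-free windows around the planting
    for o in range(base - n_indels - 1, base + n_indels + 2):
        if run(o) >= expected_matches:
            return True
    # probe-end clips (gapped query tail hanging off the homolog)
    if shift > 0:
        clip_end = sum(1 for i in range(homolog_len)
                       if region[base + i] in accepts[i])
        clip_start = sum(1 for i in range(homolog_len)
                         if region[base + i] in accepts[i + shift])
        if max(clip_end, clip_start) >= expected_matches:
            return True
    # single target-skip alignments recruiting flank bases
    for s in range(1, n_indels + 2):
        for o in range(base - s, base + s + 1):
            for g in range(1, PROBE_LENGTH):
                if run(o, skip_at=g, skip_len=s) >= expected_matches:
                    return True
    return False


def plant_offtarget(genome: dict[str, str], record: ProbeRecord,
                    n_mismatches: int = 0, n_indels: int = 0,
                    location: tuple[str, int] | None = None,
                    rng: np.random.Generator | None = None,
                    seed: int = 0):
    """Insert a homolog of a probe's on-target footprint into the genome.

    The plus-strand genomic window the probe was designed against is copied
    to *location* (0-based start; chosen clear of the on-target site), with
    *n_mismatches* substitutions and *n_indels* single-base deletions placed
    away from the anchor base and block edges.  Returns ``(genome, truth)``
    with a modified copy of the genome and a :class:`PlantedOffTarget`
    truth record.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    chrom = record.chrom
    seq = genome[chrom]
    t0 = record.mapinfo - 1
    plus, t = _design._parse_forward_sequence(record.forward_sequence)
    # design-window bounds in target-strand space S (S = plus for T designs,
    # revcomp(plus context) for B designs), then mapped to the plus strand
    u = t if record.strand_tb == "T" else len(plus) - t - 2
    if record.strand_co == "C":
        wlo, whi = (u, u + 50) if record.design_type == "I" else (u + 1, u + 51)
    else:
        wlo, whi = u - 50, u
    if record.strand_tb == "T":
        plus_lo = (t0 - t) + wlo
    else:
        # S[k] pairs the plus base at genomic index (t0 - t) + (len(plus) - 1 - k)
        plus_lo = (t0 - t) + (len(plus) - whi)
    window_plus = seq[plus_lo : plus_lo + 50]
    # offset of the MAPINFO cytosine inside the plus window (-1/50 when the
    # design abuts rather than covers the target)
    anchor_in_window = t0 - plus_lo

    if location is None:
        location = (chrom, len(seq) - 200)
    dest_chrom, dest = location
    if dest_chrom == chrom and not (dest + 60 < plus_lo or dest > plus_lo + 110):
        raise EpickitError("planting location overlaps the on-target site")

    protected = {i for i in (anchor_in_window, anchor_in_window + 1,
                             anchor_in_window - 1) if 0 <= i < 50}
    editable = [i for i in range(3, 47) if i not in protected]
    others = {"A": "C", "C": "A", "G": "T", "T": "G"}
    expected_matches = 50 - n_mismatches - n_indels
    accepts = _window_accept_sets(record) if record.allele_a_seq else None
    target_seq = genome[dest_chrom]
    pad = 8

    homolog = shift_before_anchor = None
    for _ in range(200):
        cand = list(window_plus)
        mut_sites = sorted(int(i) for i in rng.choice(
            editable, size=n_mismatches + n_indels, replace=False))
        for i in mut_sites[:n_mismatches]:
            cand[i] = others[cand[i]]
        shift = 0
        for i in sorted(mut_sites[n_mismatches:], reverse=True):
            if i < anchor_in_window:
                shift += 1
            del cand[i]
        cand = "".join(cand)
        # an indel planting must not admit a tying rival interpretation,
        # which would leave the transposed anchor ambiguous
        if n_indels and accepts is not None:
            region = (target_seq[dest - pad : dest] + cand
                      + target_seq[dest + len(cand) : dest + len(cand) + pad])
            if _clip_ambiguous(accepts, region, pad, len(cand),
                               n_indels, expected_matches):
                continue
        homolog, shift_before_anchor = cand, shift
        break
    if homolog is None:
        raise EpickitError("could not plant an unambiguous indel homolog here")
    new_seq = target_seq[:dest] + homolog + target_seq[dest + len(homolog):]
    new_genome = dict(genome)
    new_genome[dest_chrom] = new_seq

    expected_matches = 50 - n_mismatches - n_indels
    expected_score = expected_matches - n_mismatches - n_indels
    expected_coord = dest + anchor_in_window - shift_before_anchor + 1
    truth = PlantedOffTarget(
        probe_id=record.ilmn_id, chrom=dest_chrom, start0=dest,
        length=len(homolog), n_mismatches=n_mismatches, n_indels=n_indels,
        expected_matches=expected_matches, expected_score=expected_score,
        expected_coord=expected_coord,
        target_offset_in_probe=_probe_target_offset(record),
    )
    return new_genome, truth


# ---------------------------------------------------------------------------
# matched methylation datasets

def simulate_methylation_dataset(config: SimulationConfig, sites,
                                 offtarget_driven: dict | None = None):
    """Matched EPICv1 / EPICv2 / WGBS measurements over *sites*.

    *sites* is a list of site keys (probe ids or coordinates).  Latent
    per-site/sample methylation is drawn from the configured beta mixture;
    each platform observes ``M = offset + slope * mu_M + noise``.  WGBS
    counts are binomial at Poisson coverage and logit-transformed.
    *offtarget_driven* optionally maps a site key to another site key whose
    latent methylation actually drives the probe (cross-hybridisation
    truth).  Returns ``(matrices, truth)``.
    """
    if config.n_samples < 3:
        raise EpickitError("need >= 3 samples")
    rng = _rng(config)
    sites = list(sites)
    n_sites, n_samp = len(sites), config.n_samples
    samples = [f"S{j+1:02d}" for j in range(n_samp)]

    comp = rng.choice(len(config.mixture_weights), size=n_sites,
                      p=np.asarray(config.mixture_weights) / sum(config.mixture_weights))
    a = np.array([config.mixture_params[c][0] for c in comp])
    b = np.array([config.mixture_params[c][1] for c in comp])
    mu_beta = rng.beta(a[:, None], b[:, None], size=(n_sites, n_samp))
    mu_beta = np.clip(mu_beta, 1e-4, 1 - 1e-4)
    mu_m = m_from_beta(mu_beta)

    site_index = {s: i for i, s in enumerate(sites)}
    drive = np.arange(n_sites)
    for probe_site, source_site in (offtarget_driven or {}).items():
        drive[site_index[probe_site]] = site_index[source_site]

    matrices = {}
    for platform, pm in config.platforms.items():
        src = mu_m[drive] if platform == "EPICv2" else mu_m
        if platform == "WGBS":
            cov = rng.poisson(config.wgbs_mean_coverage, size=(n_sites, n_samp))
            zero_mask = rng.random((n_sites, n_samp)) < config.zero_coverage_rate
            cov = np.where(zero_mask, 0, cov)
            meth = rng.binomial(cov, beta_from_m(pm.offset + pm.slope * src))
            vals = wgbs_logit(meth, cov - meth)
            vals = np.where(cov == 0, np.nan, vals)
            matrices[platform] = MethylMatrix(
                platform,
                pd.DataFrame(vals, index=sites, columns=samples),
                "logit",
                coverage=pd.DataFrame(cov, index=sites, columns=samples),
            )
        else:
            noise = rng.normal(0.0, pm.noise_sd, size=(n_sites, n_samp))
            vals = pm.offset + pm.slope * src + noise
            detp = np.where(
                rng.random((n_sites, n_samp)) < config.detection_fail_rate,
                rng.uniform(0.06, 1.0, size=(n_sites, n_samp)),
                rng.uniform(0.0, 0.04, size=(n_sites, n_samp)),
            )
            matrices[platform] = MethylMatrix(
                platform,
                pd.DataFrame(vals, index=sites, columns=samples),
                "M",
                detection_p=pd.DataFrame(detp, index=sites, columns=samples),
            )
    truth = {
        "mu_m": pd.DataFrame(mu_m, index=sites, columns=samples),
        "mixture_component": pd.Series(comp, index=sites),
        "driven_by": {s: sites[drive[site_index[s]]] for s in sites},
    }
    return matrices, truth
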