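"""Cross-platform and replicate evaluation of methylation measurements.

Value transforms
----------------
Array methylation is summarised as the beta value

    beta = C / (C + T + 100)

(C, T: methylated and unmethylated signal; the +100 offset guards against
division by near-zero totals) and analysed on the M-value scale
``M = logit2(beta)``.  Per-CpG WGBS read counts are placed on the same scale
via ``logit2((C + 0.5) / (C + T + 1)) = log2((C + 0.5) / (T + 0.5))``.

Row-linear consensus fit
------------------------
For one CpG site measured by p platforms across n matched samples, the
consensus value of sample j is the across-platform mean m_j.  Each
platform's measurements are regressed on the consensus,

    x_pj = alpha_p + beta_p * m_j + eps_pj,

an adaptation of the interlaboratory-consistency analysis of ASTM standard
E691 with platforms in the role of laboratories.  The slope beta_p is the
platform's *sensitivity* to methylation change, and the residual scatter
(root mean squared residual, denominator n - 2) its *precision* (smaller is
better).  When every platform contributes to the consensus the slopes
average to 1 by construction.
"""

from __future__ import annotations

import math
import operator
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateFitError, EpickitError

DETECTION_P_THRESHOLD = 0.05
MIN_PAIRS_DEFAULT = 12
N_SAMPLES_DEFAULT = 18


# ---------------------------------------------------------------------------
# value transforms

def beta_from_intensities(C, T, offset: float = 100.0):
    """Methylation beta value C / (C + T + offset); bounded in [0, 1)."""
    C = np.asarray(C, dtype=float)
    T = np.asarray(T, dtype=float)
    if (C < 0).any() or (T < 0).any():
        raise ValueError("negative signal intensity")
    out = C / (C + T + offset)
    return out.item() if out.ndim == 0 else out

def m_from_beta(beta, clip: float | None = None):
    """M-value logit2(beta) = log2(beta / (1 - beta)).

    *clip* (e.g. 1e-6) squeezes exact 0/1 into the open interval; without it
    boundary values raise.
    """
    b = np.asarray(beta, dtype=float)
    if (b < 0).any() or (b > 1).any():
        raise ValueError("beta outside [0, 1]")
    if clip is not None:
        b = np.clip(b, clip, 1.0 - clip)
    elif ((b == 0) | (b == 1)).any():
        raise ValueError("beta exactly 0 or 1; pass clip= to squeeze")
    out = np.log2(b / (1.0 - b))
    return out.item() if out.ndim == 0 else out

def beta_from_m(m):
    m = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + 2.0 ** (-m))
    return out.item() if out.ndim == 0 else out

def wgbs_logit(C, T):
    """WGBS logit2((C+0.5)/(C+T+1)) = log2((C+0.5)/(T+0.5)) for read counts."""
    C = np.asarray(C, dtype=float)
    T = np.asarray(T, dtype=float)
    if (C < 0).any() or (T < 0).any():
        raise ValueError("negative read count")
    out = np.log2((C + 0.5) / (T + 0.5))
    return out.item() if out.ndim == 0 else out

def rmse(x, y):
    """Root mean squared error over pairwise-complete entries."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    if not keep.any():
        raise ValueError("no pairwise-complete observations")
    d = x[keep] - y[keep]
    return float(np.sqrt(np.mean(d * d)))

def paired_cohens_d(x, y):
    """Paired Cohen's d: mean(x - y) / sd(x - y), sample sd (n - 1)."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 pairs")
    s = d.std(ddof=1)
    if s == 0:
        raise ValueError("zero standard deviation of differences")
    return float(d.mean() / s)

def rlm_deviations(matrix: pd.DataFrame) -> pd.DataFrame:
    """Relative Log Methylation: per-site deviation from the across-sample
    median M-value.  Rows are sites, columns samples; the per-sample
    deviation distributions are the columns of the result."""
    if matrix.shape[1] < 2:
        raise EpickitError("RLM needs at least 2 samples")
    med = matrix.median(axis=1)
    return matrix.sub(med, axis=0)


# ---------------------------------------------------------------------------
# containers

@dataclass
class MethylMatrix:
    """Sites x samples measurements for one platform.

    ``values`` carries beta or M (``space``); arrays have a detection-p
    companion, WGBS a read-coverage companion, aligned to ``values``.
    """

    platform: str
    values: pd.DataFrame
    space: str = "M"                         # beta | M | logit
    detection_p: pd.DataFrame | None = None
    coverage: pd.DataFrame | None = None

    def __post_init__(self):
        if self.space not in ("beta", "M", "logit"):
            raise ValueError(f"unknown value space {self.space!r}")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("site/sample keys must be unique")
        if self.space == "beta":
            v = self.values.to_numpy(dtype=float)
            if np.nanmin(v) < 0 or np.nanmax(v) > 1:
                raise ValueError("beta-space values outside [0, 1]")

    def to_m(self, clip: float = 1e-6) -> "MethylMatrix":
        if self.space in ("M", "logit"):
            return self
        m = pd.DataFrame(
            m_from_beta(self.values.to_numpy(dtype=float), clip=clip),
            index=self.values.index, columns=self.values.columns,
        )
        return MethylMatrix(self.platform, m, "M", self.detection_p, self.coverage)


def choose_technical_replicate(candidates: dict[str, pd.DataFrame],
                               threshold: float = DETECTION_P_THRESHOLD) -> str:
    """Pick the technical replicate with the fewest probes failing the
    detection-p threshold.  *candidates* maps replicate name -> detection-p
    frame (or single-column series)."""
    def failures(obj):
        arr = np.asarray(obj, dtype=float)
        return int((arr > threshold).sum())
    return min(candidates, key=lambda k: (failures(candidates[k]), k))


def match_cross_platform(matrices, manifest=None,
                         det_p_threshold: float = DETECTION_P_THRESHOLD):
    """Build the full-complement sites x samples x platforms block.

    Array matrices keyed by probe id are re-keyed to "chrom:pos" coordinates
    through *manifest*; duplicate-location probes resolve to the probe
    appearing first in the manifest.  A site is dropped if any sample on any
    array has detection p > threshold, or any WGBS sample has zero coverage.
    Returns ``(block, exclusions)``: {platform: DataFrame} sharing index and
    columns, and a DataFrame logging every dropped site with its reason.
    """
    matrices = list(matrices)
    if len(matrices) < 2:
        raise EpickitError("need at least two platforms")
    samples = None
    for mm in matrices:
        cols = set(mm.values.columns)
        samples = cols if samples is None else samples & cols
    if not samples:
        raise EpickitError("no shared samples across platforms")
    samples = sorted(samples)

    exclusions = []
    keyed: dict[str, pd.DataFrame] = {}
    companions: dict[str, pd.DataFrame | None] = {}
    for mm in matrices:
        vals = mm.to_m().values[samples]
        comp = mm.detection_p if mm.detection_p is not None else mm.coverage
        if comp is not None:
            comp = comp[samples]
        if manifest is not None and mm.platform != "WGBS" \
                and any(pid in manifest for pid in vals.index[:50]):
            order, coord_of = {}, {}
            for rank, rec in enumerate(manifest):
                order[rec.ilmn_id] = rank
                if rec.located:
                    coord_of[rec.ilmn_id] = f"{rec.chrom}:{rec.mapinfo}"
            chosen: dict[str, str] = {}
            for pid in vals.index:
                coord = coord_of.get(pid)
                if coord is None:
                    exclusions.append((mm.platform, pid, "unlocated probe"))
                    continue
                prev = chosen.get(coord)
                if prev is None or order.get(pid, 1 << 30) < order.get(prev, 1 << 30):
                    if prev is not None:
                        exclusions.append(
                            (mm.platform, prev, "duplicate location, later in manifest"))
                    chosen[coord] = pid
                else:
                    exclusions.append(
                        (mm.platform, pid, "duplicate location, later in manifest"))
            keep = list(chosen.values())
            vals = vals.loc[keep]
            if comp is not None:
                comp = comp.loc[keep]
            newindex = [coord_of[pid] for pid in keep]
            vals = vals.set_axis(newindex)
            if comp is not None:
                comp = comp.set_axis(newindex)
        keyed[mm.platform] = vals
        companions[mm.platform] = comp

    shared = None
    for vals in keyed.values():
        idx = set(vals.index)
        shared = idx if shared is None else shared & idx
    if not shared:
        raise EpickitError(
            "no shared sites across platforms (are all matrices keyed the "
            "same way — probe ids, or coordinates via the manifest)?")
    for mm in matrices:
        for site in set(keyed[mm.platform].index) - (shared or set()):
            exclusions.append((mm.platform, site, "absent from another platform"))

    bad = set()
    for mm in matrices:
        comp = companions[mm.platform]
        if comp is None:
            continue
        sub = comp.loc[comp.index.intersection(list(shared))]
        if mm.platform == "WGBS" or mm.coverage is not None:
            fail = sub.index[(sub <= 0).any(axis=1)]
            reason = "zero WGBS coverage"
        else:
            fail = sub.index[(sub > det_p_threshold).any(axis=1)]
            reason = f"detection p > {det_p_threshold}"
        for site in fail:
            bad.add(site)
            exclusions.append((mm.platform, site, reason))
    final = sorted(shared - bad)
    block = {p: v.loc[final] for p, v in keyed.items()}
    log = pd.DataFrame(exclusions, columns=["platform", "site", "reason"])
    return block, log


# ---------------------------------------------------------------------------
# row-linear consensus fit

@dataclass
class RowLinearFit:
    """Per-platform sensitivity/precision for one site."""

    site: str
    platform: str
    alpha: float
    sensitivity: float
    precision: float
    n: int


def rowlinear_fit(site_block, platforms=None, site: str = "", center: bool = False):
    """Row-linear consensus fit for one site.

    *site_block* is platforms x samples (2-D array or DataFrame).  Returns a
    list of :class:`RowLinearFit`.  ``center=True`` uses the Mandel
    parameterisation (consensus mean subtracted), which changes only alpha.
    """
    if isinstance(site_block, pd.DataFrame):
        platforms = list(site_block.index) if platforms is None else platforms
        x = site_block.to_numpy(dtype=float)
    else:
        x = np.asarray(site_block, dtype=float)
        platforms = platforms or [f"P{i+1}" for i in range(x.shape[0])]
    p, n = x.shape
    if p < 2:
        raise DegenerateFitError("need >= 2 platforms")
    if n < 3:
        raise DegenerateFitError("need >= 3 samples")
    m = x.mean(axis=0)
    mc = m - m.mean() if center else m
    var = ((mc - mc.mean()) ** 2).sum()
    if var == 0:
        raise DegenerateFitError("zero variance in the consensus values")
    fits = []
    for i in range(p):
        xi = x[i]
        slope = ((mc - mc.mean()) * (xi - xi.mean())).sum() / var
        alpha = xi.mean() - slope * mc.mean()
        resid = xi - (alpha + slope * mc)
        precision = math.sqrt((resid ** 2).sum() / (n - 2))
        fits.append(RowLinearFit(site, platforms[i], float(alpha), float(slope),
                                 float(precision), n))
    return fits


class RowLinearModel:
    """Consensus row-linear model over a matched multi-platform block.

    Parameters
    ----------
    block : mapping platform -> DataFrame (sites x samples)
        As produced by :func:`match_cross_platform`; indexes and columns
        must agree across platforms.  Values must be on the M/logit scale.
    center : bool
        Mandel parameterisation (centred consensus); slopes and precisions
        are invariant to this choice.

    Examples
    --------
    >>> block = {"P1": pd.DataFrame([[0, 1, 2]], index=["s"]),
    ...          "P2": pd.DataFrame([[0, 2, 4]], index=["s"])}
    >>> res = RowLinearModel(block).fit()
    >>> sorted(res.fits.sensitivity.round(4))
    [0.6667, 1.3333]
    """

    def __init__(self, block: dict[str, pd.DataFrame], center: bool = False):
        platforms = list(block)
        if len(platforms) < 2:
            raise DegenerateFitError("need >= 2 platforms")
        first = block[platforms[0]]
        for p in platforms[1:]:
            if not first.index.equals(block[p].index) or \
               not first.columns.equals(block[p].columns):
                raise EpickitError("platform frames are not aligned")
        self.block = block
        self.platforms = platforms
        self.center = center
        self.exog_names = list(first.columns)

    def fit(self) -> "RowLinearResults":
        rows = []
        skipped = []
        arr = np.stack([self.block[p].to_numpy(dtype=float) for p in self.platforms])
        sites = list(self.block[self.platforms[0]].index)
        for k, site in enumerate(sites):
            try:
                fits = rowlinear_fit(arr[:, k, :], self.platforms, str(site),
                                     center=self.center)
            except DegenerateFitError as exc:
                skipped.append((site, str(exc)))
                continue
            rows.extend(fits)
        frame = pd.DataFrame(
            [(f.site, f.platform, f.alpha, f.sensitivity, f.precision, f.n)
             for f in rows],
            columns=["site", "platform", "alpha", "sensitivity", "precision", "n"],
        )
        return RowLinearResults(self, frame, skipped)


class RowLinearResults:
    """Fitted per-site, per-platform sensitivities and precisions."""

    def __init__(self, model: RowLinearModel, fits: pd.DataFrame, skipped):
        self.model = model
        self.fits = fits
        self.skipped = skipped

    @property
    def n_sites(self) -> int:
        return self.fits["site"].nunique()

    def platform_summary(self) -> pd.DataFrame:
        g = self.fits.groupby("platform")
        out = pd.DataFrame({
            "mean_sensitivity": g["sensitivity"].mean(),
            "sd_sensitivity": g["sensitivity"].std(ddof=1),
            "mean_precision": g["precision"].mean(),
            "sd_precision": g["precision"].std(ddof=1),
            "n_sites": g["site"].nunique(),
        })
        return out.loc[self.model.platforms]

    def summary(self) -> str:
        lines = [
            "Row-linear consensus fit",
            "=" * 64,
            f"sites: {self.n_sites}    samples: {len(self.model.exog_names)}"
            f"    platforms: {len(self.model.platforms)}"
            f"    degenerate sites skipped: {len(self.skipped)}",
            "-" * 64,
            f"{'platform':<12}{'sensitivity':>14}{'sd':>9}{'precision':>12}{'sd':>9}",
        ]
        s = self.platform_summary()
        for platform, row in s.iterrows():
            lines.append(
                f"{platform:<12}{row.mean_sensitivity:>14.4f}"
                f"{row.sd_sensitivity:>9.4f}{row.mean_precision:>12.4f}"
                f"{row.sd_precision:>9.4f}"
            )
        lines.append("=" * 64)
        lines.append("sensitivity: slope vs across-platform consensus mean; "
                     "precision: residual scatter (smaller is better)")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# WGBS-based cross-hybridisation evidence

@dataclass
class CrossHybEvidence:
    probe_id: str
    flag: str                               # Y | N | not_evaluated
    rmse_on_target: float = float("nan")
    best_off_rmse: float = float("nan")
    best_off_coordinate: str = ""
    num_offtargets: int = 0
    n_pairs: int = 0


def crosshyb_wgbs_evidence(probe_id, probe_values, on_target_wgbs,
                           offtarget_wgbs: dict, min_pairs: int = MIN_PAIRS_DEFAULT):
    """Empirical cross-reactivity call for one probe.

    All inputs are per-sample vectors on the M/logit scale (NaN = dropout).
    Evaluation requires >= 1 CpG off-target and >= *min_pairs* complete
    array/WGBS pairs; the flag is Y iff some off-target tracks the probe
    (lower RMSE) better than the stated target, and the best such off-target
    coordinate is suggested.
    """
    num_off = len(offtarget_wgbs)
    x = np.asarray(probe_values, dtype=float)
    y = np.asarray(on_target_wgbs, dtype=float)
    pairs = int((~(np.isnan(x) | np.isnan(y))).sum())
    if num_off == 0 or pairs < min_pairs:
        return CrossHybEvidence(probe_id, "not_evaluated",
                                num_offtargets=num_off, n_pairs=pairs)
    on_rmse = rmse(x, y)
    best_coord, best_rmse = "", float("inf")
    for coord, w in offtarget_wgbs.items():
        w = np.asarray(w, dtype=float)
        if int((~(np.isnan(x) | np.isnan(w))).sum()) < min_pairs:
            continue
        r = rmse(x, w)
        if r < best_rmse:
            best_coord, best_rmse = str(coord), r
    if not best_coord:
        return CrossHybEvidence(probe_id, "not_evaluated", on_rmse,
                                num_offtargets=num_off, n_pairs=pairs)
    flag = "Y" if best_rmse < on_rmse else "N"
    return CrossHybEvidence(probe_id, flag, on_rmse, best_rmse, best_coord,
                            num_off, pairs)


# ---------------------------------------------------------------------------
# competitive evaluation of replicate sets

@dataclass
class ReplicateVerdict:
    probe_id: str
    grouping: str                           # name | sequence | location
    label: str
    sensitivity: float = float("nan")
    precision: float = float("nan")
    rmse_wgbs: float = float("nan")


def _complete_pairs(frames):
    mask = None
    for f in frames:
        m = ~np.isnan(np.asarray(f, dtype=float))
        mask = m if mask is None else (mask & m)
    return mask


def evaluate_replicate_set(member_values: dict[str, np.ndarray],
                           wgbs: np.ndarray,
                           epicv1: np.ndarray | None = None,
                           grouping: str = "location",
                           min_pairs: int = MIN_PAIRS_DEFAULT,
                           member_order: list[str] | None = None,
                           ties_log: list | None = None):
    """Adjudicate a replicate probe set; one verdict per member.

    With matched EPICv1 data, each member and the probe-set sample mean get
    a sensitivity and precision by regressing on a *shared* consensus: the
    across-platform mean of the set mean, EPICv1 and WGBS, over the samples
    complete in every member and platform.  Sharing the regressor makes the
    slope linear in the response, so the set-mean sensitivity is exactly the
    member average — by definition intermediate of the member extremes.
    The member beating every other member *and* the set mean on both
    sensitivity and precision is ``superior`` (the symmetric worst is
    ``inferior``).  With no superior member, best slope earns
    ``best_sensitivity`` and the best scatter either ``best_precision``
    (a member) or, when the set mean is the most precise,
    ``best_precision_by_group_mean`` for members without the best slope.
    Without EPICv1, minimum RMSE against WGBS decides ``superior_by_WGBS``
    / ``inferior_by_WGBS``, upgraded to ``superior_group_mean_WGBS`` when
    the sample-mean beats every member.  Sets with fewer than *min_pairs*
    complete samples are ``insufficient``.
    """
    members = member_order or list(member_values)
    if len(members) < 2:
        raise EpickitError("a replicate set needs >= 2 members")
    wgbs = np.asarray(wgbs, dtype=float)
    mem = {k: np.asarray(v, dtype=float) for k, v in member_values.items()}
    # plain mean: the set mean is only read through the common complete-pair
    # mask, where every member is observed
    set_mean = np.stack([mem[k] for k in members]).mean(axis=0)

    def verdicts(labels, sens=None, prec=None, rms=None):
        return [ReplicateVerdict(
            k, grouping, labels.get(k, "none"),
            (sens or {}).get(k, float("nan")),
            (prec or {}).get(k, float("nan")),
            (rms or {}).get(k, float("nan")),
        ) for k in members]

    if epicv1 is not None:
        v1 = np.asarray(epicv1, dtype=float)
        mask = _complete_pairs([v1, wgbs] + [mem[k] for k in members])
        if mask.sum() < min_pairs:
            return verdicts({k: "insufficient" for k in members})
        consensus = (set_mean[mask] + v1[mask] + wgbs[mask]) / 3.0
        cvar = ((consensus - consensus.mean()) ** 2).sum()
        if cvar == 0:
            return verdicts({k: "insufficient" for k in members})
        n = int(mask.sum())
        sens, prec = {}, {}
        for key, values in list(mem.items()) + [("__mean__", set_mean)]:
            xi = values[mask]
            slope = ((consensus - consensus.mean()) * (xi - xi.mean())).sum() / cvar
            alpha = xi.mean() - slope * consensus.mean()
            resid = xi - (alpha + slope * consensus)
            sens[key] = float(slope)
            prec[key] = float(np.sqrt((resid ** 2).sum() / (n - 2)))
        evaluable = [k for k in members if k in sens]
        if len(evaluable) < 2 or "__mean__" not in sens:
            return verdicts({k: "insufficient" for k in members})

        # ties in sensitivity: better precision, then manifest order
        ranked = sorted(evaluable,
                        key=lambda k: (-sens[k], prec[k], members.index(k)))
        best_s = ranked[0]
        if ties_log is not None:
            tied = [k for k in evaluable if sens[k] == sens[best_s]]
            if len(tied) > 1:
                ties_log.append(("sensitivity", tuple(tied)))
        best_p_member = min(evaluable, key=lambda k: (prec[k], members.index(k)))
        labels = {k: "insufficient" for k in members if k not in sens}

        def strictly_best(k, score, cmp):
            others = [score[o] for o in evaluable if o != k] + [score["__mean__"]]
            return all(cmp(score[k], v) for v in others)

        superior = best_s if (
            strictly_best(best_s, sens, operator.gt)
            and strictly_best(best_s, prec, operator.lt)
        ) else None
        if superior is not None:
            labels[superior] = "superior"
        for k in evaluable:
            if k is not superior and strictly_best(k, sens, operator.lt) \
                    and strictly_best(k, prec, operator.gt):
                labels[k] = "inferior"
        if superior is None:
            labels[best_s] = "best_sensitivity"
            if prec["__mean__"] < min(prec[k] for k in evaluable):
                # the set mean is the most precise entity
                for k in evaluable:
                    if k != best_s and k not in labels:
                        labels[k] = "best_precision_by_group_mean"
            elif best_p_member not in labels:
                labels[best_p_member] = "best_precision"
        return verdicts(labels, sens, prec)

    # WGBS-only route: minimum RMSE over the common complete samples
    mask = _complete_pairs([wgbs] + [mem[k] for k in members])
    if mask.sum() < min_pairs:
        return verdicts({k: "insufficient" for k in members})
    rms = {key: rmse(values[mask], wgbs[mask])
           for key, values in list(mem.items()) + [("__mean__", set_mean)]}
    evaluable = [k for k in members if k in rms]
    if len(evaluable) < 2:
        return verdicts({k: "insufficient" for k in members})
    best = min(evaluable, key=lambda k: (rms[k], members.index(k)))
    labels = {k: "insufficient" for k in members if k not in rms}
    for k in evaluable:
        labels[k] = "superior_by_WGBS" if k == best else "inferior_by_WGBS"
    if "__mean__" in rms and rms["__mean__"] < min(rms[k] for k in evaluable):
        labels[best] = "superior_group_mean_WGBS"
    return verdicts(labels, rms=rms)
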