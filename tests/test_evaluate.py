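"""Transforms, cross-platform matching, row-linear fits and verdicts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epickit import (
    MethylMatrix,
    RowLinearModel,
    beta_from_intensities,
    beta_from_m,
    choose_technical_replicate,
    crosshyb_wgbs_evidence,
    evaluate_replicate_set,
    m_from_beta,
    match_cross_platform,
    paired_cohens_d,
    rlm_deviations,
    rmse,
    rowlinear_fit,
    wgbs_logit,
)
from epickit.errors import DegenerateFitError, EpickitError


class TestTransforms:
    def test_beta_worked_examples(self):
        assert beta_from_intensities(0, 0) == 0
        assert beta_from_intensities(100, 100) == pytest.approx(1 / 3)
        assert beta_from_intensities(900, 0) == pytest.approx(0.9)

    def test_beta_negative_signal_raises(self):
        with pytest.raises(ValueError):
            beta_from_intensities(-1, 10)

    def test_m_value_examples(self):
        assert m_from_beta(0.5) == pytest.approx(0.0)
        assert m_from_beta(0.8) == pytest.approx(2.0)

    def test_m_boundary_requires_clip(self):
        with pytest.raises(ValueError):
            m_from_beta(0.0)
        assert m_from_beta(0.0, clip=1e-6) < -19
        with pytest.raises(ValueError):
            m_from_beta(1.5)

    @given(st.floats(0.01, 0.99))
    @settings(max_examples=60, deadline=None)
    def test_m_antisymmetry_and_inverse(self, b):
        assert m_from_beta(1 - b) == pytest.approx(-m_from_beta(b), abs=1e-9)
        assert beta_from_m(m_from_beta(b)) == pytest.approx(b, abs=1e-12)

    def test_wgbs_logit_examples(self):
        assert wgbs_logit(5, 5) == 0
        assert wgbs_logit(3, 0) == pytest.approx(np.log2(7))
        assert wgbs_logit(0, 3) == pytest.approx(-np.log2(7))

    def test_wgbs_negative_counts_raise(self):
        with pytest.raises(ValueError):
            wgbs_logit(-1, 2)

    def test_rmse_examples_and_symmetry(self, rng):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0
        assert rmse([0, 0], [3, 4]) == pytest.approx(np.sqrt(12.5))
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert rmse(x, y) == rmse(y, x)

    def test_rmse_empty_after_filtering_raises(self):
        with pytest.raises(ValueError):
            rmse([np.nan], [1.0])

    def test_cohens_d_examples(self, rng):
        assert paired_cohens_d([2, 4, 6], [1, 2, 3]) == pytest.approx(2.0)
        y = rng.normal(size=50)
        noise = rng.normal(0, 0.5, size=50)
        d = paired_cohens_d(y + 3 + noise, y)
        assert d == pytest.approx((3 + noise.mean()) / np.std(3 + noise, ddof=1))

    def test_cohens_d_zero_sd_raises(self):
        with pytest.raises(ValueError):
            paired_cohens_d([1, 2, 3], [1, 2, 3])


class TestRLM:
    def test_constant_matrix_all_zero(self):
        m = pd.DataFrame(np.full((4, 5), 2.0))
        assert (rlm_deviations(m) == 0).all().all()

    def test_median_deviation_example(self):
        m = pd.DataFrame([[1.0, 2.0, 9.0]])
        assert rlm_deviations(m).iloc[0].tolist() == [-1.0, 0.0, 7.0]

    def test_shifting_one_sample_leaves_above_median_rows_untouched(self, rng):
        m = pd.DataFrame(rng.normal(size=(50, 5)))
        shifted = m.copy()
        shifted[0] = shifted[0] + 10
        base = rlm_deviations(m)
        out = rlm_deviations(shifted)
        # where sample 0 already sat above the row median, the median (and
        # hence every other sample's deviation) is unchanged and sample 0's
        # deviation moves by exactly the shift
        above = m[0] > m.median(axis=1)
        pd.testing.assert_frame_equal(out.loc[above].drop(columns=[0]),
                                      base.loc[above].drop(columns=[0]))
        assert np.allclose(out.loc[above, 0], base.loc[above, 0] + 10)

    def test_single_sample_raises(self):
        with pytest.raises(EpickitError):
            rlm_deviations(pd.DataFrame([[1.0]]))


class TestRowLinear:
    def test_closed_form_two_platforms(self):
        fits = rowlinear_fit(np.array([[0, 1, 2], [0, 2, 4]], float))
        assert fits[0].sensitivity == pytest.approx(2 / 3)
        assert fits[1].sensitivity == pytest.approx(4 / 3)
        assert fits[0].precision == pytest.approx(0.0, abs=1e-12)
        assert fits[1].precision == pytest.approx(0.0, abs=1e-12)

    def test_identical_platforms_slope_one_precision_zero(self, rng):
        x = rng.normal(size=10)
        fits = rowlinear_fit(np.stack([x, x, x]))
        for f in fits:
            assert f.sensitivity == pytest.approx(1.0)
            assert f.precision == pytest.approx(0.0, abs=1e-9)

    def test_slopes_average_to_one(self, rng):
        block = rng.normal(size=(4, 18))
        fits = rowlinear_fit(block)
        assert np.mean([f.sensitivity for f in fits]) == pytest.approx(1.0)

    def test_centering_changes_only_alpha(self, rng):
        block = rng.normal(size=(3, 12)) + 5
        plain = rowlinear_fit(block)
        centred = rowlinear_fit(block, center=True)
        for a, b in zip(plain, centred):
            assert a.sensitivity == pytest.approx(b.sensitivity)
            assert a.precision == pytest.approx(b.precision)
        assert plain[0].alpha != pytest.approx(centred[0].alpha)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateFitError):
            rowlinear_fit(np.ones((2, 5)))           # zero consensus variance
        with pytest.raises(DegenerateFitError):
            rowlinear_fit(np.zeros((1, 5)))          # one platform
        with pytest.raises(DegenerateFitError):
            rowlinear_fit(np.zeros((2, 2)))          # two samples

    def test_model_results_and_summary(self, rng):
        sites = [f"s{i}" for i in range(6)]
        samples = [f"c{i}" for i in range(8)]
        base = rng.normal(size=(6, 8))
        block = {
            "P1": pd.DataFrame(base + rng.normal(0, .1, (6, 8)), sites, samples),
            "P2": pd.DataFrame(base + rng.normal(0, .1, (6, 8)), sites, samples),
        }
        res = RowLinearModel(block).fit()
        assert res.n_sites == 6
        assert set(res.fits.platform) == {"P1", "P2"}
        text = res.summary()
        assert "sensitivity" in text and "P1" in text
        per_site = res.fits.groupby("site").sensitivity.mean()
        assert np.allclose(per_site, 1.0)

    def test_misaligned_block_raises(self, rng):
        a = pd.DataFrame(rng.normal(size=(3, 4)))
        b = pd.DataFrame(rng.normal(size=(3, 4)), index=[9, 10, 11])
        with pytest.raises(EpickitError):
            RowLinearModel({"P1": a, "P2": b})


def _matrices(rng, n_sites=30, n_samples=6, fail_cells=(), zero_cov=()):
    sites = [f"site{i}" for i in range(n_sites)]
    samples = [f"S{j}" for j in range(n_samples)]
    base = rng.normal(0, 2, size=(n_sites, n_samples))
    out = []
    for platform in ("EPICv1", "EPICv2"):
        vals = pd.DataFrame(base + rng.normal(0, .1, base.shape), sites, samples)
        detp = pd.DataFrame(np.full(base.shape, 0.01), sites, samples)
        for (s, c) in fail_cells:
            if platform == "EPICv2":
                detp.iloc[s, c] = 0.2
        out.append(MethylMatrix(platform, vals, "M", detection_p=detp))
    cov = pd.DataFrame(np.full(base.shape, 10), sites, samples)
    for (s, c) in zero_cov:
        cov.iloc[s, c] = 0
    wvals = pd.DataFrame(base + rng.normal(0, .3, base.shape), sites, samples)
    out.append(MethylMatrix("WGBS", wvals, "logit", coverage=cov))
    return out


class TestMatchCrossPlatform:
    def test_no_dropouts_full_block(self, rng):
        block, log = match_cross_platform(_matrices(rng))
        assert all(v.shape == (30, 6) for v in block.values())
        assert log.empty

    def test_planted_detection_failure_dropped_and_logged(self, rng):
        block, log = match_cross_platform(_matrices(rng, fail_cells=[(4, 2)]))
        assert "site4" not in block["EPICv2"].index
        row = log[log.site == "site4"]
        assert not row.empty and "detection p" in row.reason.iloc[0]

    def test_zero_coverage_dropped(self, rng):
        block, log = match_cross_platform(_matrices(rng, zero_cov=[(7, 0)]))
        assert "site7" not in block["WGBS"].index
        assert "zero WGBS coverage" in log[log.site == "site7"].reason.iloc[0]

    def test_duplicate_location_resolved_by_manifest_order(
            self, rng, toy_genome, cpg_targets):
        from epickit.manifest import ManifestTable
        from epickit.simulate import design_probe

        chrom, pos = cpg_targets[70]
        first = design_probe(toy_genome, chrom, pos, "T", "C", "II", rep_num=1)
        second = design_probe(toy_genome, chrom, pos, "B", "C", "I")
        other = design_probe(toy_genome, *cpg_targets[71], "T", "C", "II")
        manifest = ManifestTable([first, second, other])
        sites = [first.ilmn_id, second.ilmn_id, other.ilmn_id]
        samples = list("abcd")
        base = rng.normal(size=(3, 4))
        v2 = MethylMatrix("EPICv2", pd.DataFrame(base, sites, samples), "M",
                          detection_p=pd.DataFrame(np.zeros((3, 4)), sites, samples))
        coords = [f"{chrom}:{pos}", f"{chrom}:{cpg_targets[71][1]}"]
        w = MethylMatrix("WGBS", pd.DataFrame(rng.normal(size=(2, 4)),
                                              coords, samples), "logit")
        block, log = match_cross_platform([v2, w], manifest=manifest)
        assert list(block["EPICv2"].index) == sorted(coords)
        dropped = log[log.reason.str.contains("duplicate")]
        assert dropped.site.tolist() == [second.ilmn_id]
        # the retained row carries the first probe's values
        assert block["EPICv2"].loc[f"{chrom}:{pos}"].tolist() \
            == pytest.approx(base[0].tolist())

    def test_no_shared_samples_raises(self, rng):
        mats = _matrices(rng)
        mats[1] = MethylMatrix("EPICv2",
                               mats[1].values.rename(columns=lambda c: "x" + c),
                               "M")
        with pytest.raises(EpickitError):
            match_cross_platform(mats)

    def test_beta_input_transformed_at_boundary(self, rng):
        sites, samples = ["s1", "s2", "s3"], list("abc")
        beta = pd.DataFrame(rng.uniform(.1, .9, (3, 3)), sites, samples)
        m1 = MethylMatrix("EPICv1", beta, "beta")
        m2 = MethylMatrix("EPICv2", beta.copy(), "beta")
        block, _ = match_cross_platform([m1, m2])
        assert np.allclose(block["EPICv1"].to_numpy(),
                           m_from_beta(beta.to_numpy()))


class TestTechnicalReplicateChoice:
    def test_fewest_detection_failures_wins(self):
        a = pd.DataFrame([[0.01, 0.2], [0.3, 0.01]])
        b = pd.DataFrame([[0.01, 0.01], [0.3, 0.01]])
        assert choose_technical_replicate({"rep1": a, "rep2": b}) == "rep2"


class TestCrossHybEvidence:
    def test_zero_cpg_offtargets_not_evaluated(self, rng):
        x = rng.normal(size=18)
        ev = crosshyb_wgbs_evidence("p", x, x, {})
        assert ev.flag == "not_evaluated"

    def test_too_few_pairs_not_evaluated(self, rng):
        x = rng.normal(size=18)
        x[:10] = np.nan
        ev = crosshyb_wgbs_evidence("p", x, x, {"chr1:5": x})
        assert ev.flag == "not_evaluated"

    def test_offtarget_driven_probe_flagged_with_planted_coordinate(self, rng):
        mu_on = rng.normal(0, 2, 18)
        mu_off = rng.normal(0, 2, 18)
        probe = mu_off + rng.normal(0, 0.1, 18)
        ev = crosshyb_wgbs_evidence(
            "p", probe, mu_on,
            {"chr9:100": mu_off, "chr9:900": rng.normal(0, 2, 18)})
        assert ev.flag == "Y"
        assert ev.best_off_coordinate == "chr9:100"
        assert ev.best_off_rmse < ev.rmse_on_target

    def test_on_target_driven_probe_flag_n(self, rng):
        mu_on = rng.normal(0, 2, 18)
        probe = mu_on + rng.normal(0, 0.1, 18)
        ev = crosshyb_wgbs_evidence("p", probe, mu_on,
                                    {"chr9:100": rng.normal(0, 2, 18)})
        assert ev.flag == "N"


class TestReplicateVerdicts:
    def _set(self, rng, specs, n=18):
        mu = rng.normal(0, 2, n)
        v1 = mu + rng.normal(0, 0.1, n)
        w = 1.2 * mu + rng.normal(0, 0.3, n)
        members = {name: slope * mu + rng.normal(0, sd, n)
                   for name, (slope, sd) in specs.items()}
        return members, v1, w

    def test_superior_and_inferior(self, rng):
        members, v1, w = self._set(rng, {"A": (1.0, 0.04), "B": (0.4, 0.9)})
        labels = {v.probe_id: v.label
                  for v in evaluate_replicate_set(members, w, epicv1=v1)}
        assert labels == {"A": "superior", "B": "inferior"}

    def test_split_best_sensitivity_and_precision(self, rng):
        # A steepest but noisy, B flatter but clean -> split labels
        members, v1, w = self._set(rng, {"A": (1.2, 0.8), "B": (0.7, 0.02)})
        labels = {v.probe_id: v.label
                  for v in evaluate_replicate_set(members, w, epicv1=v1)}
        assert labels["A"] == "best_sensitivity"
        assert labels["B"] in ("best_precision", "best_precision_by_group_mean")

    def test_verdicts_agree_with_bruteforce_rule_table(self, rng):
        for _ in range(40):
            specs = {k: (rng.uniform(.3, 1.2), rng.uniform(.02, .8))
                     for k in "ABC"}
            members, v1, w = self._set(rng, specs)
            verdicts = evaluate_replicate_set(members, w, epicv1=v1)
            sens = {v.probe_id: v.sensitivity for v in verdicts}
            prec = {v.probe_id: v.precision for v in verdicts}
            labels = {v.probe_id: v.label for v in verdicts}
            mean_sens = np.mean(list(sens.values()))
            for k in "ABC":
                others = [o for o in "ABC" if o != k]
                if labels[k] == "superior":
                    assert all(sens[k] > sens[o] for o in others)
                    assert sens[k] > mean_sens
                    assert all(prec[k] < prec[o] for o in others)
                if labels[k] == "inferior":
                    assert all(sens[k] < sens[o] for o in others)
                    assert all(prec[k] > prec[o] for o in others)

    def test_set_mean_sensitivity_is_member_average(self, rng):
        # shared consensus makes the intermediacy exact
        for _ in range(50):
            specs = {k: (rng.uniform(.3, 1.3), rng.uniform(.02, .9))
                     for k in "ABCD"}
            members, v1, w = self._set(rng, specs)
            verdicts = evaluate_replicate_set(members, w, epicv1=v1)
            s = [v.sensitivity for v in verdicts]
            assert min(s) - 1e-9 <= np.mean(s) <= max(s) + 1e-9

    def test_insufficient_below_min_pairs(self, rng):
        members, v1, w = self._set(rng, {"A": (1, .1), "B": (1, .1)})
        members = {k: np.where(np.arange(18) < 10, v, np.nan)
                   for k, v in members.items()}
        labels = {v.probe_id: v.label
                  for v in evaluate_replicate_set(members, w, epicv1=v1)}
        assert set(labels.values()) == {"insufficient"}

    def test_wgbs_only_route(self, rng):
        members, _, w = self._set(rng, {"A": (1.2, 0.05), "B": (1.2, 0.9)})
        labels = {v.probe_id: v.label
                  for v in evaluate_replicate_set(members, w)}
        assert labels["A"] in ("superior_by_WGBS", "superior_group_mean_WGBS")
        assert labels["B"] == "inferior_by_WGBS"

    def test_wgbs_group_mean_upgrade(self, rng):
        # anticorrelated member errors cancel in the set mean, which then
        # tracks WGBS better than either member alone
        mu = rng.normal(0, 2, 18)
        w = mu
        eps = rng.normal(0, 0.5, 18)
        members = {"A": mu + eps, "B": mu - eps}
        labels = {v.probe_id: v.label
                  for v in evaluate_replicate_set(members, w)}
        assert "superior_group_mean_WGBS" in labels.values()

    def test_singleton_set_raises(self, rng):
        with pytest.raises(EpickitError):
            evaluate_replicate_set({"A": rng.normal(size=18)},
                                   rng.normal(size=18))
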