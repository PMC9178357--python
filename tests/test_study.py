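"""Framerate study: record table, regressions, slope test, summaries."""

import numpy as np
import pytest
from scipy import stats

from ciliabeat import (
    PopulationSpec,
    StudyRecord,
    group_summary,
    nyquist_margin,
    pairwise_regression,
    preset_population,
    run_study,
    slope_vs_identity_test,
)
from ciliabeat.study import RegressionResult, _subset, records_to_frame

from conftest import NOISELESS


def small_population(n=6, label="test", mean=20.0, sd=5.0, noise=None):
    return PopulationSpec(label=label, mean_cbf=mean, sd_cbf=sd, n=n,
                          noise_profile=dict(noise if noise is not None
                                             else NOISELESS))


def synthetic_records(x, y, fps=100.0, method="fft", group="g"):
    """Records with given reference (x) and estimate (y) arrays."""
    return [
        StudyRecord(cilium_id=f"c{i}", group=group, true_cbf=None, fps=fps,
                    method=method, cbf=float(yi), failed=False,
                    reference_cbf=float(xi))
        for i, (xi, yi) in enumerate(zip(x, y))
    ]


class TestRunStudy:
    def test_record_cardinality(self):
        records = run_study([small_population(4)], fps_grid=(300, 150, 30),
                            seed=0)
        # 4 cilia x 3 rates x 2 methods
        assert len(records) == 4 * 3 * 2

    def test_reference_join_consistency(self):
        records = run_study([small_population(5)], fps_grid=(300, 60), seed=1)
        by_key = {(r.cilium_id, r.fps, r.method): r for r in records}
        for r in records:
            ref = by_key[(r.cilium_id, 300.0, r.method)]
            assert r.reference_cbf == ref.cbf

    def test_noiseless_population_recovers_truth_at_reference(self):
        records = run_study([small_population(8)], fps_grid=(300, 150), seed=2)
        at_ref = [r for r in records if r.fps == 300]
        for r in at_ref:
            assert not r.failed
            assert r.cbf == pytest.approx(r.true_cbf, abs=1.0)  # one bin

    def test_reference_must_be_on_grid(self):
        with pytest.raises(ValueError, match="reference_fps"):
            run_study([small_population(2)], fps_grid=(150, 30),
                      reference_fps=300, seed=0)

    def test_seeded_reproducibility(self):
        a = run_study([small_population(3)], fps_grid=(300, 60), seed=9)
        b = run_study([small_population(3)], fps_grid=(300, 60), seed=9)
        assert [(r.cilium_id, r.cbf) for r in a] == \
               [(r.cilium_id, r.cbf) for r in b]

    def test_ordering_invariance_of_noise_free_analysis(self):
        records = run_study([small_population(6)], fps_grid=(300, 100), seed=3)
        fit1 = pairwise_regression(records, 100.0, "fft", (0, 50))
        fit2 = pairwise_regression(records[::-1], 100.0, "fft", (0, 50))
        assert fit1.slope == pytest.approx(fit2.slope)
        assert fit1.r_squared == pytest.approx(fit2.r_squared)


class TestPairwiseRegression:
    def test_identity_data(self):
        x = np.linspace(5, 45, 20)
        fit = pairwise_regression(synthetic_records(x, x), 100.0, "fft")
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_half_slope_data(self):
        x = np.linspace(5, 45, 20)
        fit = pairwise_regression(synthetic_records(x, 0.5 * x), 100.0, "fft")
        assert fit.slope == pytest.approx(0.5)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(4, 50, 40)
        y = 0.8 * x + 1.5 + rng.normal(0, 2, 40)
        fit = pairwise_regression(synthetic_records(x, y), 100.0, "fft")
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-9)
        assert fit.slope == pytest.approx(beta[1], abs=1e-9)
        assert fit.r_squared == pytest.approx(r2, abs=1e-9)

    def test_band_filters_on_reference_only(self):
        x = np.array([6.0, 10.0, 14.0, 20.0, 40.0])
        y = np.array([5.0, 9.0, 35.0, 19.0, 12.0])
        recs = synthetic_records(x, y)
        fit = pairwise_regression(recs, 100.0, "fft", cbf_band=(0, 15))
        assert fit.n == 3  # refs 6, 10, 14; y=35 not filtered by its value

    def test_insufficient_data_raises(self):
        recs = synthetic_records([10.0, 12.0], [10.0, 12.0])
        with pytest.raises(ValueError, match="insufficient"):
            pairwise_regression(recs, 100.0, "fft")

    def test_filtering_conservation(self):
        x = np.array([5.0, 10.0, 20.0, 40.0, 49.0])
        y = np.array([5.0, 10.0, 20.0, 40.0, 49.0])
        recs = synthetic_records(x, y)
        recs[1].failed, recs[1].cbf = True, None
        _, _, counts = _subset(recs, 100.0, "fft", (0, 15))
        assert counts["n_used"] + counts["n_failed"] \
            + counts["n_out_of_band"] == len(recs)


class TestSlopeVsIdentity:
    def test_perfect_identity_gives_p_one(self):
        x = np.linspace(5, 45, 30)
        recs = synthetic_records(x, x)
        fit = pairwise_regression(recs, 100.0, "fft")
        assert slope_vs_identity_test(fit, recs) == pytest.approx(1.0)

    def test_half_slope_is_overwhelmingly_significant(self, rng):
        x = rng.uniform(5, 45, 50)
        y = 0.5 * x + rng.normal(0, 1.0, 50)
        recs = synthetic_records(x, y)
        fit = pairwise_regression(recs, 100.0, "fft")
        p = slope_vs_identity_test(fit, recs)
        assert p < 1e-3

    def test_agrees_with_permutation_oracle(self, rng):
        # label-permutation null for the two-group slope difference
        x = rng.uniform(5, 45, 50)
        y = 0.5 * x + rng.normal(0, 1.0, 50)
        obs = np.column_stack([x, y])
        ideal = np.column_stack([x, x])
        both = np.vstack([obs, ideal])

        def slope_diff(a, b):
            return stats.linregress(a[:, 0], a[:, 1]).slope - \
                stats.linregress(b[:, 0], b[:, 1]).slope

        observed = abs(slope_diff(obs, ideal))
        n = len(obs)
        hits = 0
        n_perm = 300
        for _ in range(n_perm):
            perm = rng.permutation(2 * n)
            d = abs(slope_diff(both[perm[:n]], both[perm[n:]]))
            hits += d >= observed
        p_perm = (hits + 1) / (n_perm + 1)
        recs = synthetic_records(x, y)
        fit = pairwise_regression(recs, 100.0, "fft")
        p_analytic = slope_vs_identity_test(fit, recs)
        assert p_analytic < 1e-3 and p_perm < 0.01

    def test_consistent_with_wald_test_at_large_n(self, rng):
        # pooled statistic ~ Wald (slope-1)/SE for large n
        x = rng.uniform(5, 45, 400)
        y = 0.95 * x + rng.normal(0, 2.0, 400)
        recs = synthetic_records(x, y)
        fit = pairwise_regression(recs, 100.0, "fft")
        t_pooled = stats.t.isf(slope_vs_identity_test(fit, recs) / 2,
                               2 * (len(x) - 2))
        t_wald = abs(fit.slope - 1.0) / fit.slope_standard_error
        assert t_pooled == pytest.approx(t_wald, rel=0.25)

    def test_zero_reference_variance_rejected(self):
        recs = synthetic_records([10.0] * 5, [10.0] * 5)
        fit = RegressionResult(fps=100.0, method="fft", cbf_band=(0, 50), n=5,
                               slope=1.0, intercept=0.0, r_squared=1.0,
                               slope_standard_error=0.0)
        with pytest.raises(ValueError, match="variance"):
            slope_vs_identity_test(fit, recs)


class TestGroupSummary:
    def test_failures_counted_but_excluded_from_mean(self):
        recs = synthetic_records(np.full(10, 20.0), np.full(10, 18.0))
        for r in recs[:3]:
            r.failed, r.cbf = True, None
        (summ,) = group_summary(recs)
        assert summ.failure_fraction == pytest.approx(0.3)
        assert summ.n == 10
        assert summ.mean_cbf == pytest.approx(18.0)

    def test_single_record_sd_is_null(self):
        recs = synthetic_records([20.0], [19.0])
        (summ,) = group_summary(recs)
        assert summ.sd_cbf is None

    def test_matches_direct_recomputation(self):
        records = run_study([small_population(6, noise={"noise_sd": 0.1})],
                            fps_grid=(300, 60), seed=5)
        df = records_to_frame(records)
        for s in group_summary(records):
            sub = df[(df.fps == s.fps) & (df.method == s.method)]
            ok = sub.loc[~sub.failed, "cbf_hz"]
            if len(ok):
                assert s.mean_cbf == pytest.approx(ok.mean())
            assert s.failure_fraction == pytest.approx(sub.failed.mean())

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            group_summary([])


class TestNyquistMargin:
    def test_oversampled_records_have_tiny_error(self):
        x = np.linspace(5, 10, 10)
        recs = synthetic_records(x, x, fps=300.0)  # ratio >= 30
        table = nyquist_margin(recs)
        row = table[table.ratio_low == 4.0].iloc[0]
        assert row.n == 10
        assert abs(row.mean_rel_error) < 1e-12

    def test_undersampled_tones_alias_downward(self):
        # noiseless tones below the Nyquist ratio of 2 alias to lower bins
        from ciliabeat import cbf_fft, downsample_kymograph, simulate_kymograph
        from conftest import pure_tone_model

        recs = []
        for f in (20.0, 25.0, 40.0):
            k = simulate_kymograph(pure_tone_model(f), 600, 1.0, 8)
            est = cbf_fft(downsample_kymograph(k, 30))
            recs.append(StudyRecord(
                cilium_id=f"c{f}", group="g", true_cbf=f, fps=30.0,
                method="fft", cbf=est.cbf, failed=est.failed,
                reference_cbf=f))
        table = nyquist_margin(recs)
        low = table[table.ratio_high <= 2.0]
        assert low.n.sum() == 3
        assert (low.dropna().mean_rel_error < 0).all()

    def test_bin_counts_partition_usable_records(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(5, 50, 40)
        recs = synthetic_records(x, x, fps=60.0)
        recs[0].failed, recs[0].cbf = True, None
        table = nyquist_margin(recs)
        assert table.n.sum() == 39
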