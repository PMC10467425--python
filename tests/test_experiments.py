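"""Sweeps, alpha-rise bookkeeping, calibration scaffolding, robust
regression and the Wilcoxon/Holm statistics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from tacsnet import fixtures as fx
from tacsnet.engine import simulate
from tacsnet.experiments import (
    PREDICTORS,
    CollinearityError,
    MLRResult,
    RegressionTable,
    alpha_rise,
    classify_sync_state,
    holm_step_down,
    lowered_subset_mlr,
    robust_mlr,
    single_node_sweep,
    standardize,
    wilcoxon_holm,
)
from tacsnet.metrics import band_power, iaf, psd


class TestSyncClassification:
    @pytest.mark.parametrize("ratio,expected", [
        (1.02, "one-to-one"),
        (2.0, "two-to-one"),
        (1.92, "two-to-one"),
        (1.5, "faster"),
        (1.2, "faster"),
        (0.8, "slower"),
        (0.94, "slower"),
        (2.2, "unlocked"),
    ])
    def test_boundaries(self, ratio, expected):
        assert classify_sync_state(ratio, tol=0.05) == expected

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            classify_sync_state(0.0)


class TestAlphaRise:
    def test_identical_runs_give_zero_rise(self, baseline_run):
        assert alpha_rise(baseline_run, baseline_run) == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_independent_integration_oracle(self, default_node, baseline_run):
        stim_run = simulate(default_node, None, 12.0, seed=5)
        rise = alpha_rise(baseline_run, stim_run)
        # independent recomputation: fine-grid Riemann integral of the same
        # normalized spectra around the baseline IAF
        def riemann_band(series, center):
            spec = psd(series, 0.1)
            fine = np.linspace(center - 0.5, center + 0.5, 4001)
            return np.sum(np.interp(fine, spec.freqs, spec.raw_power)) * (fine[1] - fine[0])

        f0 = iaf(psd(baseline_run.lfp[0], 0.1))
        pb = riemann_band(baseline_run.lfp[0], f0)
        ps = riemann_band(stim_run.lfp[0], f0)
        oracle = 100 * (ps - pb) / pb
        assert rise == pytest.approx(oracle, abs=0.1)

    def test_layout_mismatch_rejected(self, baseline_run):
        from dataclasses import replace

        other = replace(baseline_run, lfp=baseline_run.lfp[:, :100])
        with pytest.raises(ValueError):
            alpha_rise(baseline_run, other)


class TestSweep:
    def test_zero_intensity_reproduces_baseline_peak(self, default_node, natural_freq):
        sweep = single_node_sweep(
            np.array([0.1]), freqs=np.array([6.0, 14.0]),
            intensities=np.array([0.0]), reps=1, seed=0,
            model=default_node,
        )
        # unstimulated cells all peak at the node's natural frequency,
        # independent of the nominal stimulation frequency
        assert np.allclose(sweep.peak_freq[:, 0], natural_freq, atol=0.5)
        assert sweep.ratio[0, 0] == pytest.approx(sweep.peak_freq[0, 0] / 6.0)


class TestRegression:
    @staticmethod
    def make_table(n=80, seed=0, beta=None, outlier_frac=0.0, noise=0.05):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, len(PREDICTORS)))
        beta = np.zeros(len(PREDICTORS)) if beta is None else np.asarray(beta)
        df = pd.DataFrame(X, columns=PREDICTORS)
        df.insert(0, "region", np.arange(n))
        df.insert(0, "subject", "S0")
        df["response"] = 0.0
        df = standardize(df)
        y = df[PREDICTORS].to_numpy() @ beta + noise * rng.normal(size=n)
        if outlier_frac > 0:
            k = int(outlier_frac * n)
            y[rng.choice(n, k, replace=False)] += rng.choice([-1, 1], k) * 10.0
        df["response"] = y
        return RegressionTable(df)

    def test_planted_coefficients_recovered_and_noise_dropped(self):
        beta = np.zeros(len(PREDICTORS))
        beta[0], beta[1] = 0.5, -0.2
        table = self.make_table(beta=beta, seed=1)
        res = robust_mlr(table, stepwise=True)
        assert set(res.retained) == {PREDICTORS[0], PREDICTORS[1]}
        assert abs(res.params[PREDICTORS[0]] - 0.5) < 2 * res.bse[PREDICTORS[0]]
        assert abs(res.params[PREDICTORS[1]] + 0.2) < 2 * res.bse[PREDICTORS[1]]

    def test_constant_response_drops_everything(self):
        table = self.make_table(noise=0.0)
        table.data["response"] = 3.0
        res = robust_mlr(table)
        assert res.retained == []
        assert np.allclose(res.params.to_numpy(), 0.0, atol=1e-8)

    def test_huber_beats_ols_under_gross_outliers(self):
        """With 5% gross outliers, Huber IRLS coefficient error is below the
        ordinary-least-squares error (paired simulation)."""
        beta = np.zeros(len(PREDICTORS))
        beta[0], beta[2] = 0.6, 0.3
        hub_err, ols_err = [], []
        for seed in range(5):
            table = self.make_table(n=120, beta=beta, seed=seed, outlier_frac=0.05)
            res = robust_mlr(table, stepwise=False)
            X = sm.add_constant(table.data[PREDICTORS])
            ols = sm.OLS(table.data["response"], X).fit()
            hub_err.append(np.abs(res.params.to_numpy()[:len(PREDICTORS)]
                                  - beta).sum())
            ols_err.append(np.abs(ols.params.drop("const").to_numpy() - beta).sum())
        assert np.mean(hub_err) < np.mean(ols_err)

    def test_collinear_design_names_offenders(self):
        table = self.make_table(seed=3)
        table.data[PREDICTORS[1]] = table.data[PREDICTORS[0]]
        with pytest.raises(CollinearityError) as err:
            robust_mlr(table)
        assert any(p in err.value.columns for p in PREDICTORS[:2])

    def test_standardization_is_idempotent_and_scale_invariant(self):
        table = self.make_table(seed=4)
        once = standardize(table.data)
        twice = standardize(once)
        assert np.allclose(once[PREDICTORS].to_numpy(),
                           twice[PREDICTORS].to_numpy(), atol=1e-12)
        rescaled = table.data.copy()
        rescaled[PREDICTORS[0]] *= 1000.0
        assert np.allclose(standardize(rescaled)[PREDICTORS[0]],
                           once[PREDICTORS[0]], atol=1e-9)
        assert np.allclose(once[PREDICTORS].mean(), 0.0, atol=1e-9)
        assert np.allclose(once[PREDICTORS].std(ddof=0), 1.0, atol=1e-9)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            robust_mlr(self.make_table(n=10))


class TestLoweredSubset:
    def test_empty_subset_gives_explicit_empty_result(self):
        table = TestRegression.make_table(seed=5)
        table.data["response"] = np.abs(table.data["response"]) + 1.0
        res = lowered_subset_mlr(table)
        assert res.empty and res.n_obs == 0

    def test_subset_selection_equals_filter_oracle(self):
        beta = np.zeros(len(PREDICTORS))
        beta[5] = -0.8
        table = TestRegression.make_table(n=200, beta=beta, seed=6, noise=0.3)
        res = lowered_subset_mlr(table)
        n_neg = int((table.data["response"] < 0).sum())
        assert res.n_obs == n_neg

    def test_planted_negative_mechanism_recovered(self):
        beta = np.zeros(len(PREDICTORS))
        beta[5] = -0.8  # baseline connectivity drives lowering
        table = TestRegression.make_table(n=400, beta=beta, seed=7, noise=0.1)
        res = lowered_subset_mlr(table)
        assert PREDICTORS[5] in res.retained
        assert res.params[PREDICTORS[5]] < 0


class TestCalibration:
    def test_zero_target_selects_zero_intensity(self):
        """With V = 0 in the grid, a zero target rise selects it: no
        stimulation yields no rise by construction."""
        from tacsnet.experiments import calibrate_intensity, make_synthetic_cohort

        cohort = make_synthetic_cohort(n_subjects=1, n_regions=2, seed=0,
                                       coupling=0.0, mesh_resolution=24)
        cal = calibrate_intensity(cohort, target_rise=0.0,
                                  V_grid=np.array([0.0, 8.0]), reps=1, seed=0,
                                  duration_s=6.0)
        assert cal.V_star == 0.0
        assert cal.achieved_rise == 0.0

    def test_selection_is_monotone_on_a_rising_response_curve(self):
        """On a stored monotone response curve, larger targets select V* at
        least as large."""
        from tacsnet.experiments import CalibrationResult

        V = np.array([0.0, 10.0, 20.0, 30.0])
        rises = np.array([0.0, 4.0, 9.0, 15.0]).reshape(4, 1, 1)
        stars = []
        for target in (0.0, 5.0, 8.0, 14.0):
            cal = CalibrationResult(V, rises, 0.0, target)
            k = int(np.argmin(np.abs(cal.group_mean - target)))
            stars.append(V[k])
        assert all(a <= b for a, b in zip(stars, stars[1:]))


class TestWilcoxonHolm:
    def test_all_positive_differences_give_w_zero_rbc_one(self):
        rng = np.random.default_rng(0)
        base = rng.normal(10, 1, 30)
        stim = base + rng.uniform(0.5, 2.0, 30)
        df = wilcoxon_holm([(base, stim)])
        assert df.loc[0, "W"] == 0.0
        assert df.loc[0, "rbc"] == 1.0
        assert df.loc[0, "p"] < 0.05
        assert bool(df.loc[0, "significant"])

    def test_identical_samples_are_undefined_with_cles_half(self):
        x = np.arange(10.0)
        df = wilcoxon_holm([(x, x.copy())])
        assert bool(df.loc[0, "undefined"])
        assert df.loc[0, "cles"] == pytest.approx(0.5)

    def test_cles_counts_favorable_cross_pairs(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        stim = np.array([10.0, 10.0, 10.0, 0.0, 0.0])
        expected = np.mean(stim[:, None] > base[None, :])
        df = wilcoxon_holm([(base, stim)])
        assert df.loc[0, "cles"] == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(8))
    def test_holm_flags_equal_brute_force_and_statsmodels(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 0.2, size=rng.integers(2, 12))
        flags = holm_step_down(p, alpha=0.05)
        # brute-force step-down: thresholds alpha/(m-i+1) in ascending order
        m = len(p)
        order = np.argsort(p)
        brute = np.zeros(m, bool)
        for i, idx in enumerate(order):
            if p[idx] <= 0.05 / (m - i):
                brute[idx] = True
            else:
                break
        assert np.array_equal(flags, brute)
        sm_flags = multipletests(p, alpha=0.05, method="holm")[0]
        assert np.array_equal(flags, sm_flags)

    def test_too_few_repetitions_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_holm([(np.arange(3.0), np.arange(3.0))])


def test_synthetic_cohort_structure():
    from tacsnet.experiments import make_synthetic_cohort

    cohort = make_synthetic_cohort(n_subjects=2, n_regions=4, seed=0,
                                   mesh_resolution=24)
    assert len(cohort) == 2
    for sub in cohort:
        assert sub.model.n_regions == 4
        assert len(sub.distributions) == 4
        assert all(d.n >= 3 for d in sub.distributions)
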