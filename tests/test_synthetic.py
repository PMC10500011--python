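"""Generator contracts: determinism, coupling calibration, planted-effect
power, null behaviour, survival simulation, and mixture consistency."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snfomics import (
    CohortConfig,
    calibrate_coupling,
    estimate_fractions,
    differential_features,
    residual_coupling,
    simulate_cohort,
    simulate_survival,
)
from snfomics.clinical import SurvivalTable, logrank_test

from conftest import equal_fraction_config


class TestCouplingCalibration:
    @pytest.mark.parametrize("target", [0.0, 1.0, -1.0, 0.168])
    def test_closed_form_identity(self, target):
        assert calibrate_coupling(target) == target

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            calibrate_coupling(1.01)

    def test_monte_carlo_at_half(self):
        """rho=0.5 construction: empirical mean Pearson over 10,000 pairs of
        length 100 sits in [0.48, 0.52]."""
        rho = calibrate_coupling(0.5)
        rng = np.random.default_rng(0)
        z = rng.standard_normal((10_000, 100))
        e = rng.standard_normal((10_000, 100))
        y = rho * z + np.sqrt(1 - rho**2) * e
        zc = z - z.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (zc * yc).sum(axis=1) / np.sqrt((zc**2).sum(axis=1) * (yc**2).sum(axis=1))
        assert 0.48 <= r.mean() <= 0.52

    def test_residual_coupling_compensates_group_shift(self):
        """With the group ratio shift active, the inflated residual coupling
        restores the pooled-sample correlation to the target."""
        target, delta, sigma = 0.168, 0.5, 0.8
        rho = residual_coupling(target, delta, sigma)
        rng = np.random.default_rng(1)
        n_pairs, n = 4000, 28
        c = np.concatenate([np.full(14, 0.5), np.full(14, -0.5)])
        z = rng.standard_normal((n_pairs, n))
        e = rng.standard_normal((n_pairs, n))
        x = sigma * z + delta * (c > 0)
        y = sigma * (rho * z + np.sqrt(1 - rho**2) * e) + delta * (c < 0)
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (xc * yc).sum(axis=1) / np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
        assert abs(np.median(r) - target) < 0.02

    def test_unreachable_target_errors(self):
        with pytest.raises(ValueError, match="unreachable"):
            residual_coupling(0.99, 1.5, 0.3)


class TestSimulateCohort:
    def test_seeded_determinism(self):
        a = simulate_cohort(CohortConfig(), seed=1)
        b = simulate_cohort(CohortConfig(), seed=1)
        pd.testing.assert_frame_equal(a.mrna.values, b.mrna.values)
        pd.testing.assert_frame_equal(a.protein.values, b.protein.values)
        pd.testing.assert_frame_equal(a.methylation.values, b.methylation.values)
        pd.testing.assert_frame_equal(a.clinical.data, b.clinical.data)
        pd.testing.assert_series_equal(a.true_labels, b.true_labels)

    def test_null_configuration_has_no_group_signal(self):
        """With every group-informative knob off, per-feature t-test p-values
        are uniform (KS test not rejected at 0.01)."""
        cohort = simulate_cohort(CohortConfig.null(), seed=2)
        genes = [f for f in cohort.mrna.feature_ids if f.startswith("G")]
        table = differential_features(cohort.mrna.subset_features(genes), cohort.true_labels)
        assert stats.kstest(table["p"], "uniform").pvalue > 0.01

    def test_planted_feature_recovery(self):
        """Planted genes recovered at p<=0.05 and |FC|>=2.

        The group ratio shift adds a background log2 contrast of delta to
        every feature, so planted features whose direction opposes the
        layer shift sit at a net |log2FC| of effect - delta = 1.0 — exactly
        the fold-change boundary — and only about half of them clear it.
        The expected recovery under the default construction is therefore
        ~0.75 (analytic power), not higher.
        """
        rates = []
        for seed in (10, 11):
            cohort = simulate_cohort(CohortConfig(), seed=seed)
            for layer in ("mrna", "protein"):
                table = differential_features(cohort.layers[layer], cohort.true_labels)
                called = set(table.loc[table["significant"], "feature_id"])
                planted = [f for f in cohort.true_de_features[layer] if f.startswith("G")]
                rates.append(len(called & set(planted)) / len(planted))
        assert np.mean(rates) >= 0.70

    def test_validation_errors_before_sampling(self):
        with pytest.raises(ValueError):
            CohortConfig(n_matched_pairs=3000, n_genes=2000)
        with pytest.raises(ValueError):
            CohortConfig(coupling_rho=1.5)
        with pytest.raises(ValueError):
            CohortConfig(group_proportions=(0.7, 0.5))

    def test_layers_share_samples_and_fractions_sum_to_one(self, default_cohort):
        c = default_cohort
        assert c.mrna.sample_ids == c.protein.sample_ids == c.methylation.sample_ids
        assert np.allclose(c.true_fractions.sum(axis=1), 1.0)

    def test_marker_architecture_shared_across_seeds(self):
        a = simulate_cohort(CohortConfig(), seed=3)
        b = simulate_cohort(CohortConfig(), seed=4)
        assert a.true_de_features == b.true_de_features
        assert not np.allclose(a.mrna.values, b.mrna.values)

    def test_mixture_consistency_noiseless(self):
        """In the noiseless limit, NNLS on the signature genes recovers the
        generating fractions almost exactly."""
        cohort = simulate_cohort(equal_fraction_config(mixture_noise_sd=0.0), seed=5)
        bulk = cohort.mrna.subset_features(cohort.signature.feature_ids)
        result = estimate_fractions(bulk, cohort.signature)
        rmse = np.sqrt(((result.fractions - cohort.true_fractions) ** 2).to_numpy().mean())
        assert rmse < 0.05


class TestSimulateSurvival:
    def test_type_one_error_under_equal_hazards(self):
        """Equal hazards in both groups: log-rank rejects at ~5%."""
        labels = pd.Series(["group1"] * 20 + ["group2"] * 20)
        rng = np.random.default_rng(6)
        hits = 0
        reps = 400
        for _ in range(reps):
            surv = simulate_survival(labels, (0.02, 0.02), censor_rate=0.005, seed=rng)
            table = SurvivalTable(pd.DataFrame({"time": surv["pfs_time"], "event": surv["pfs_event"], "group": labels}))
            if table.data["event"].sum() == 0:
                continue
            _, p = logrank_test(table)
            hits += p <= 0.05
        assert 0.02 <= hits / reps <= 0.09

    def test_power_at_hazard_ratio_three(self):
        labels = pd.Series(["group1"] * 100 + ["group2"] * 100)
        rng = np.random.default_rng(7)
        hits = 0
        reps = 300
        for _ in range(reps):
            surv = simulate_survival(labels, (0.06, 0.02), censor_rate=0.0, seed=rng)
            table = SurvivalTable(pd.DataFrame({"time": surv["pfs_time"], "event": surv["pfs_event"], "group": labels}))
            _, p = logrank_test(table)
            hits += p <= 0.05
        assert hits / reps >= 0.95

    def test_extreme_censoring_yields_no_events(self):
        labels = pd.Series(["group1", "group1", "group2", "group2"])
        surv = simulate_survival(labels, (0.01, 0.01), censor_rate=1e9, seed=0)
        assert (surv["pfs_event"] == 0).all()

    def test_nonpositive_hazard_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            simulate_survival(pd.Series(["a", "b"]), (0.0, 0.1), 0.0, seed=0)
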