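import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from snfomics import (
    build_signature,
    differential_features,
    extend_groups_hcl,
    simulate_cohort,
    submap,
)
from snfomics.groups import FeatureSignature

from conftest import equal_fraction_config, make_matrix

LABELS4 = pd.Series(["a", "a", "b", "b"], index=["s0", "s1", "s2", "s3"])


class TestDifferentialFeatures:
    def test_null_feature(self):
        m = make_matrix([[1.0, 1.0, 1.0, 1.0]])
        t = differential_features(m, LABELS4)
        assert t.loc[0, "t"] == 0 and t.loc[0, "p"] == 1 and t.loc[0, "fold_change"] == 1

    def test_closed_form_fold_change(self):
        m = make_matrix([[0.0, 0.0, 0.0, 2.0, 2.0, 2.0], [1.0, 1.1, 0.9, 1.0, 1.1, 0.9]])
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=[f"s{i}" for i in range(6)])
        t = differential_features(m, labels).set_index("feature_id")
        # first sorted group minus second: 0 - 2 = -2 in log2 => |FC| = 4
        assert t.loc["f0", "log2_fc"] == -2
        assert t.loc["f0", "fold_change"] == pytest.approx(0.25)
        assert bool(t.loc["f0", "significant"])
        assert not bool(t.loc["f1", "significant"])

    def test_bh_monotone_in_rank(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(size=(100, 10)))
        labels = pd.Series(["a"] * 5 + ["b"] * 5, index=[f"s{i}" for i in range(10)])
        t = differential_features(m, labels)
        assert (np.diff(t["q"]) >= -1e-12).all()
        assert (t["q"] >= t["p"] - 1e-12).all()

    def test_small_group_rejected(self):
        m = make_matrix(np.ones((2, 3)))
        labels = pd.Series(["a", "b", "b"], index=["s0", "s1", "s2"])
        with pytest.raises(ValueError, match="2 samples"):
            differential_features(m, labels)


class TestBuildSignature:
    def _table(self, n_up=10, n_down=10, n_null=20):
        rows = []
        for i in range(n_up):
            rows.append(("up%02d" % i, 1.5, (i + 1) * 1e-5, True))
        for i in range(n_down):
            rows.append(("dn%02d" % i, -1.5, (i + 1) * 1.5e-5, True))
        for i in range(n_null):
            rows.append(("nul%02d" % i, 0.1, 0.5 + i * 0.01, False))
        df = pd.DataFrame(rows, columns=["feature_id", "log2_fc", "p", "significant"])
        return df.sort_values(["p", "feature_id"]).reset_index(drop=True)

    def test_top_by_p_per_direction(self):
        sig = build_signature(self._table(), 5)
        assert sig.up_features == [f"up{i:02d}" for i in range(5)]
        assert sig.down_features == [f"dn{i:02d}" for i in range(5)]

    def test_shortfall_warns(self):
        t = self._table(n_up=3)
        with pytest.warns(UserWarning, match="3 significant up"):
            sig = build_signature(t, 5)
        assert len(sig.up_features) == 3

    def test_invariant_to_nonsignificant_relabeling(self):
        t = self._table()
        sig1 = build_signature(t, 5)
        t2 = t.copy()
        t2.loc[~t2["significant"], "feature_id"] = ["x%02d" % i for i in range((~t2["significant"]).sum())]
        sig2 = build_signature(t2, 5)
        assert sig1.up_features == sig2.up_features and sig1.down_features == sig2.down_features

    def test_purity_on_default_cohort(self, default_cohort):
        for layer in ("mrna", "protein"):
            table = differential_features(default_cohort.layers[layer], default_cohort.true_labels)
            sig = build_signature(table, 50, layer=layer)
            planted = set(default_cohort.true_de_features[layer])
            purity = len([f for f in sig.features if f in planted]) / len(sig.features)
            assert purity >= 0.9


class TestExtendGroups:
    def test_duplicate_samples_inherit_core_labels(self):
        rng = np.random.default_rng(1)
        core = rng.normal(size=(10, 4))
        core[:5, :2] += 3.0  # features up in first two samples
        vals = np.hstack([core, core])  # extensions are exact copies
        m = make_matrix(vals, samples=[f"c{i}" for i in range(4)] + [f"e{i}" for i in range(4)])
        sig = FeatureSignature([f"f{i}" for i in range(5)], [f"f{i}" for i in range(5, 10)], 5)
        core_labels = pd.Series(["g1", "g1", "g2", "g2"], index=[f"c{i}" for i in range(4)])
        ext = extend_groups_hcl(m, sig, core_labels)
        for i in range(4):
            assert ext[f"e{i}"] == ext[f"c{i}"]

    def test_two_perfect_pairs(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        vals = np.column_stack([a, a, b, b])
        m = make_matrix(vals, samples=["s0", "s1", "s2", "s3"])
        sig = FeatureSignature([f"f{i}" for i in range(5)], [f"f{i}" for i in range(5, 10)], 5)
        ext = extend_groups_hcl(m, sig, pd.Series({"s0": "g1", "s1": "g1", "s2": "g2", "s3": "g2"}))
        assert ext["s0"] == ext["s1"] != ext["s2"] == ext["s3"]

    def test_full_cohort_extension_recovers_truth(self):
        """28 core + 20 extension samples: the signature-based extension
        reproduces the planted groups exactly at the default effect size."""
        cohort = simulate_cohort(equal_fraction_config(n_samples=48), seed=42)
        core_ids = cohort.mrna.sample_ids[:28]
        core = cohort.true_labels.loc[core_ids]
        table = differential_features(cohort.mrna.subset_samples(core_ids), core)
        sig = build_signature(table, 50, layer="mrna")
        ext = extend_groups_hcl(cohort.mrna, sig, core)
        assert adjusted_rand_score(cohort.true_labels, ext.reindex(cohort.true_labels.index)) == 1.0

    def test_nonseparable_cores_rejected(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=10), rng.normal(size=10)
        vals = np.column_stack([a, a, b, b])
        m = make_matrix(vals, samples=["s0", "s1", "s2", "s3"])
        sig = FeatureSignature([f"f{i}" for i in range(5)], [f"f{i}" for i in range(5, 10)], 5)
        # cores disagree with the correlation structure: both clusters map to g1
        with pytest.raises(ValueError, match="separable|core"):
            extend_groups_hcl(m, sig, pd.Series({"s0": "g1", "s2": "g1", "s1": "g2", "s3": "g2"}))


class TestSubmap:
    def test_self_mapping_diagonal_minimal(self, default_cohort):
        res = submap(
            default_cohort.mrna,
            default_cohort.true_labels,
            default_cohort.mrna,
            default_cohort.true_labels,
            n_markers=200,
            n_permutations=200,
            seed=0,
        )
        sa = res.sa_matrix
        diag = np.diag(sa.to_numpy())
        off = sa.to_numpy()[~np.eye(2, dtype=bool)]
        assert diag.max() < off.min()
        assert (diag <= 0.05).all()

    def test_role_swap_symmetric_to_permutation_resolution(self):
        a = simulate_cohort(equal_fraction_config(), seed=50)
        b = simulate_cohort(equal_fraction_config(), seed=51)
        res_ab = submap(a.mrna, a.true_labels, b.mrna, b.true_labels, n_markers=150, n_permutations=300, seed=1)
        res_ba = submap(b.mrna, b.true_labels, a.mrna, a.true_labels, n_markers=150, n_permutations=300, seed=2)
        assert np.allclose(res_ab.nominal_p.to_numpy(), res_ba.nominal_p.to_numpy().T, atol=0.1)

    def test_replicate_cohorts_match_groups(self):
        """Two cohorts drawn from the same configuration, different seeds:
        matched groups significant at FDR <= 0.05, mismatched not."""
        good = 0
        for s in range(5):
            a = simulate_cohort(equal_fraction_config(), seed=500 + 2 * s)
            b = simulate_cohort(equal_fraction_config(), seed=501 + 2 * s)
            sa = submap(a.mrna, a.true_labels, b.mrna, b.true_labels, n_markers=200, n_permutations=200, seed=s).sa_matrix
            good += (
                sa.loc["group1", "group1"] <= 0.05
                and sa.loc["group2", "group2"] <= 0.05
                and sa.loc["group1", "group2"] > 0.05
                and sa.loc["group2", "group1"] > 0.05
            )
        assert good >= 4

    def test_small_feature_space_rejected(self):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.normal(size=(20, 8)))
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=[f"s{i}" for i in range(8)])
        with pytest.raises(ValueError, match="50"):
            submap(m, labels, m, labels)
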