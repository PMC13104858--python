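import numpy as np
import pytest

from ictfce import TFCEParams, estimate_power, group_tstats, permutation_test
from ictfce.core import ValidationError
from ictfce.inference import GroupDataset
from ictfce.synth import SynthGroupConfig, synth_group_dataset


def toy_dataset(edge_values_a, edge_values_b, n_rois=3):
    """Datasets whose only varying edge is (0, 1)."""
    subs = []
    for val in list(edge_values_a) + list(edge_values_b):
        m = np.zeros((n_rois, n_rois))
        m[0, 1] = m[1, 0] = val
        subs.append(m)
    groups = np.repeat([0, 1], [len(edge_values_a), len(edge_values_b)])
    return GroupDataset(subjects=np.array(subs), groups=groups)


class TestGroupTstats:
    def test_hand_computed_pooled_t(self):
        a, b = [1.0, 2.0], [4.0, 6.0]
        d = toy_dataset(a, b)
        # pooled t for 2+2 samples: means 1.5 vs 5, sp2 = (0.5 + 2)/2
        sp2 = (np.var(a, ddof=1) + np.var(b, ddof=1)) / 2
        expected = (np.mean(b) - np.mean(a)) / np.sqrt(sp2 * (0.5 + 0.5))
        t = group_tstats(d)
        assert t.values[0, 1] == pytest.approx(expected)
        assert t.values[1, 0] == pytest.approx(expected)

    def test_zero_variance_edge_becomes_zero(self, caplog):
        d = toy_dataset([2.0, 2.0], [5.0, 5.0])
        with caplog.at_level("WARNING"):
            t = group_tstats(d)
        assert t.values[0, 1] == 0.0
        assert any("zero variance" in r.message for r in caplog.records)

    def test_null_tstats_center_on_zero(self):
        d = synth_group_dataset(
            SynthGroupConfig(n_per_group=20, n_rois=46, effect_size=0.0, seed=5)
        )
        t = group_tstats(d)
        iu, iv = np.triu_indices(46, k=1)
        assert abs(t.values[iu, iv].mean()) < 0.1  # 1035 edges

    def test_one_sample_design(self):
        rng = np.random.default_rng(0)
        subs = rng.normal(0.5, 1.0, size=(12, 4, 4))
        subs = (subs + subs.transpose(0, 2, 1)) / 2
        for s in subs:
            np.fill_diagonal(s, 0)
        d = GroupDataset(subjects=subs, groups=None)
        t = group_tstats(d)
        x = subs[:, 0, 1]
        expected = x.mean() / (x.std(ddof=1) / np.sqrt(12))
        assert t.values[0, 1] == pytest.approx(expected)

    def test_design_validation(self):
        with pytest.raises(ValidationError, match="at least 4"):
            GroupDataset(subjects=np.zeros((3, 4, 4)), groups=None)
        with pytest.raises(ValidationError, match="at least 2"):
            GroupDataset(subjects=np.zeros((5, 4, 4)), groups=np.array([0, 0, 0, 0, 1]))


@pytest.fixture(scope="module")
def null_data():
    return synth_group_dataset(
        SynthGroupConfig(n_per_group=10, n_rois=15, effect_size=0.0, seed=3)
    )


class TestPermutationTest:
    def test_pvalues_in_valid_range(self, null_data):
        res = permutation_test(null_data, TFCEParams(), n_perm=99, seed=1)
        iu, iv = np.triu_indices(15, k=1)
        p = res.p_values[iu, iv]
        assert (p >= 1 / 100).all() and (p <= 1.0).all()

    def test_p_monotone_in_observed_tfce(self, null_data):
        res = permutation_test(null_data, TFCEParams(), n_perm=99, seed=1)
        iu, iv = np.triu_indices(15, k=1)
        tfce = res.observed_tfce.values[iu, iv]
        p = res.p_values[iu, iv]
        order = np.argsort(tfce)
        assert (np.diff(p[order]) <= 1e-12).all()

    def test_zero_tfce_edge_has_p_one(self, null_data):
        res = permutation_test(null_data, TFCEParams(), n_perm=49, seed=2)
        iu, iv = np.triu_indices(15, k=1)
        zero = res.observed_tfce.values[iu, iv] == 0
        assert zero.any()
        assert (res.p_values[iu, iv][zero] == 1.0).all()

    def test_engines_agree_given_same_seed(self, null_data):
        kwargs = dict(n_perm=30, seed=7)
        res_ref = permutation_test(null_data, TFCEParams(), engine="reference", **kwargs)
        res_inc = permutation_test(null_data, TFCEParams(), engine="incremental", **kwargs)
        np.testing.assert_allclose(
            res_inc.observed_tfce.values, res_ref.observed_tfce.values, rtol=1e-9
        )
        np.testing.assert_array_equal(res_inc.p_values, res_ref.p_values)

    def test_exhausted_relabelings_warn(self):
        d = toy_dataset([1.0, 2.0], [4.0, 6.0])
        with pytest.warns(UserWarning, match="distinct relabelings"):
            permutation_test(d, TFCEParams(), n_perm=50, seed=0)

    def test_sign_flip_null_for_one_sample(self):
        rng = np.random.default_rng(4)
        subs = rng.normal(0.0, 1.0, size=(16, 10, 10))
        subs = (subs + subs.transpose(0, 2, 1)) / 2
        for s in subs:
            np.fill_diagonal(s, 0)
        d = GroupDataset(subjects=subs, groups=None)
        res = permutation_test(d, TFCEParams(), n_perm=60, seed=5)
        assert res.null.max_tfce.shape == (60,)
        assert (res.null.max_tfce >= 0).all()

    def test_two_sided_doubles_the_smaller_tail(self, null_data):
        one = permutation_test(null_data, TFCEParams(), n_perm=40, seed=9, tails="pos")
        both = permutation_test(null_data, TFCEParams(), n_perm=40, seed=9, tails="both")
        assert (both.p_values >= one.p_values - 1e-12).all()


class TestEstimatePower:
    def test_power_increases_with_effect_size(self):
        params = TFCEParams()
        powers = []
        for effect in (0.0, 1.0, 2.0):
            cfg = SynthGroupConfig(
                n_per_group=10, n_rois=12, effect_block=(0, 1, 2), effect_size=effect
            )
            res = estimate_power(cfg, params, n_reps=20, alpha=0.05, n_perm=50, seed=11)
            block = res.rejection_freq[np.ix_((0, 1, 2), (0, 1, 2))]
            iu, iv = np.triu_indices(3, k=1)
            powers.append(block[iu, iv].mean())
        assert powers[0] <= powers[1] <= powers[2]
        assert powers[2] > powers[0]

    def test_shared_draws_across_param_sets(self):
        cfg = SynthGroupConfig(n_per_group=8, n_rois=10, effect_size=1.0)
        p1 = TFCEParams(dh=0.1)
        p2 = TFCEParams(dh=0.1)
        res = estimate_power(cfg, [p1, p2], n_reps=5, n_perm=30, seed=2)
        # identical parameter values must give identical results on shared draws
        np.testing.assert_array_equal(
            res[p1].rejection_freq, res[p2].rejection_freq
        )

    def test_per_network_power_and_ranking(self):
        cfg = SynthGroupConfig(
            n_per_group=10, n_rois=10, effect_block=(0, 1, 2, 3), effect_size=2.5
        )
        networks = np.array(["signal"] * 4 + ["rest"] * 6)
        res = estimate_power(
            cfg, TFCEParams(), n_reps=10, n_perm=50, seed=3, networks=networks
        )
        assert set(res.per_network) == {"signal", "rest"}
        assert res.top_networks()[0][0] == "signal"
        assert 0 <= res.overall_average_power <= 1
        assert ((res.rejection_freq >= 0) & (res.rejection_freq <= 1)).all()

    def test_hundred_rep_binomial_precision_bound(self):
        # SE of a proportion from 100 repetitions is at most sqrt(0.25/100) = 5%
        se = np.sqrt(0.5 * 0.5 / 100)
        assert se == pytest.approx(0.05)
        grid = np.linspace(0, 1, 101)
        assert np.sqrt(grid * (1 - grid) / 100).max() == pytest.approx(0.05)
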