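import numpy as np
import pytest

from ictfce import TFCEParams, VoxelImage
from ictfce.core import ValidationError
from ictfce.voxel import (
    connectivity_offsets,
    ic_tfce_voxel,
    tfce_exact_voxel,
    voxel_clusters_reference,
    voxel_tfce_reference,
    voxel_to_graph,
)

from .oracles import exact_voxel_interval_oracle, voxel_graph_components


def strip_image(values, connectivity=26):
    return VoxelImage(stats=np.array(values, dtype=float)[None, None, :], connectivity=connectivity)


def random_image(shape, seed, connectivity=26, mask_density=None):
    rng = np.random.default_rng(seed)
    stats = rng.normal(0.5, 1.0, size=shape)
    mask = None
    if mask_density is not None:
        mask = rng.random(shape) < mask_density
    return VoxelImage(stats=stats, mask=mask, connectivity=connectivity)


class TestVoxelToGraph:
    def test_strip_pairwise_minima(self):
        g = voxel_to_graph(strip_image([2.0, 5.0, 3.0]))
        assert g.n_nodes == 3
        assert list(zip(g.iu, g.iv, g.weights)) == [(0, 1, 2.0), (1, 2, 3.0)]

    @pytest.mark.parametrize("connectivity,degree", [(6, 6), (18, 18), (26, 26)])
    def test_interior_voxel_degree(self, connectivity, degree):
        img = VoxelImage(stats=np.ones((3, 3, 3)), connectivity=connectivity)
        g = voxel_to_graph(img)
        center = 13  # flat index of (1,1,1) in a 3x3x3 block
        assert g.degrees()[center] == degree
        assert g.degrees().max() <= degree

    def test_link_count_is_half_degree_sum(self):
        img = random_image((5, 6, 4), seed=0)
        g = voxel_to_graph(img)
        assert g.n_links == g.degrees().sum() // 2

    def test_masked_voxel_breaks_adjacency(self):
        stats = np.array([2.0, 5.0, 3.0])[None, None, :]
        mask = np.array([True, False, True])[None, None, :]
        g = voxel_to_graph(VoxelImage(stats=stats, mask=mask, connectivity=26))
        assert g.n_nodes == 2
        assert g.n_links == 0

    def test_empty_mask_empty_graph(self):
        img = VoxelImage(stats=np.ones((2, 2, 2)), mask=np.zeros((2, 2, 2), bool))
        g = voxel_to_graph(img)
        assert g.n_nodes == 0 and g.n_links == 0

    def test_edge_weight_bounded_by_activations(self):
        img = random_image((6, 5, 4), seed=3)
        g = voxel_to_graph(img)
        assert (g.weights <= g.node_activation[g.iu]).all()
        assert (g.weights <= g.node_activation[g.iv]).all()

    def test_offsets_counts(self):
        assert len(connectivity_offsets(6)) == 3
        assert len(connectivity_offsets(18)) == 9
        assert len(connectivity_offsets(26)) == 13
        with pytest.raises(ValidationError):
            connectivity_offsets(10)


class TestClusterEquivalence:
    """Graph-based clusters must equal 3D connected-component labels."""

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    @pytest.mark.parametrize("seed", range(3))
    def test_graph_clusters_match_volume_labels(self, connectivity, seed):
        img = random_image((8, 7, 6), seed=seed, connectivity=connectivity, mask_density=0.85)
        g = voxel_to_graph(img)
        rng = np.random.default_rng(seed + 100)
        for h in rng.uniform(0.05, img.stats[img.mask].max(), size=10):
            ref = voxel_clusters_reference(img, h)
            got = sorted(voxel_graph_components(g, h), key=sorted)
            expected = sorted(ref.voxel_sets(), key=sorted)
            assert got == expected

    def test_reference_examples(self):
        img = strip_image([2.0, 5.0, 3.0, 0.5])
        part = voxel_clusters_reference(img, 3.0)
        assert part.n_clusters == 1
        assert part.voxel_sets() == [frozenset({1, 2})]
        assert voxel_clusters_reference(img, 6.0).n_clusters == 0
        two = voxel_clusters_reference(strip_image([5.0, 0.5, 5.0]), 1.0)
        assert two.n_clusters == 2
        assert sorted(two.sizes.values()) == [1, 1]


class TestVoxelTfce:
    def test_strip_hand_value(self, unit_params):
        out = ic_tfce_voxel(strip_image([2.0, 5.0, 3.0, 0.5]), unit_params)
        # the stat-5 voxel: c = 3,3,2,1,1 at h = 1..5
        assert out[0, 0, 1] == pytest.approx(24.0)
        assert out[0, 0, 3] == 0.0  # below dh

    def test_singleton_approaches_closed_form(self):
        t, E, H = 3.0, 1.0, 1.0
        img = strip_image([t])
        out = ic_tfce_voxel(img, TFCEParams(E, H, 0.001))
        assert out[0, 0, 0] == pytest.approx(t ** (H + 1) / (H + 1), rel=1e-2)

    def test_all_subthreshold_is_zero(self):
        out = ic_tfce_voxel(strip_image([0.2, 0.4, 0.1]), TFCEParams(1.0, 1.0, 0.5))
        assert not out.any()

    @pytest.mark.parametrize("connectivity", [6, 26])
    @pytest.mark.parametrize("seed", range(3))
    def test_incremental_matches_brute_force(self, connectivity, seed):
        img = random_image((7, 6, 5), seed=seed, connectivity=connectivity, mask_density=0.9)
        p = TFCEParams(0.5, 2.0, 0.2)
        np.testing.assert_allclose(
            ic_tfce_voxel(img, p), voxel_tfce_reference(img, p), rtol=1e-9, atol=1e-12
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_exact_matches_interval_oracle(self, seed):
        img = random_image((5, 5, 4), seed=seed, connectivity=26, mask_density=0.9)
        E, H = 0.5, 2.0
        expected = exact_voxel_interval_oracle(img.stats, img.mask, 26, E, H)
        np.testing.assert_allclose(
            tfce_exact_voxel(img, E, H), expected, rtol=1e-9, atol=1e-12
        )

    def test_discrete_converges_to_exact(self):
        img = random_image((5, 4, 4), seed=9, connectivity=26)
        E, H = 0.5, 2.0
        exact = tfce_exact_voxel(img, E, H)
        errs = [
            np.abs(ic_tfce_voxel(img, TFCEParams(E, H, dh)) - exact).max()
            for dh in (0.05, 0.005)
        ]
        assert errs[1] < errs[0]
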