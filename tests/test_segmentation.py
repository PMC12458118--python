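"""Tests of the hierarchical region split and its classification rules."""

import numpy as np
import pytest

from hiquant.relaxometry import T2Map, fit_t2_map
from hiquant.segmentation import (
    CORE,
    PENUMBRA,
    UNINJURED,
    LesionMask,
    SegmentationParams,
    build_histogram,
    classify_leaves,
    find_valley,
    hierarchical_split,
    segment_lesion,
)
from hiquant.synthetic import PhantomSpec, make_phantom

from _oracles import oracle_segment, oracle_valley


def map_from_values(values: np.ndarray, shape=None) -> T2Map:
    """Wrap a value array into a trivially valid T2 map."""
    values = np.asarray(values, dtype=float)
    if shape is None:
        shape = (values.size, 1, 1)
    t2 = values.reshape(shape)
    ones = np.ones_like(t2)
    return T2Map(t2=t2, s0=ones, r2=ones, valid=np.ones(shape, dtype=bool),
                 voxel_size=(1.0, 1.0, 1.0))


class TestHistogram:
    def test_two_value_histogram_counts(self):
        hist = build_histogram([40, 40, 40, 70, 70, 70], bin_width=10, smoothing_bandwidth=0)
        occupied = hist.counts[hist.counts > 0]
        assert occupied.tolist() == [3, 3]
        assert hist.counts.sum() == 6
        assert hist.centers[0] == pytest.approx(40.0)
        assert hist.centers[-1] == pytest.approx(70.0)

    @pytest.mark.parametrize("bandwidth", [0.0, 1.0, 2.0, 5.0])
    def test_raw_counts_conserve_mass_for_any_bandwidth(self, bandwidth, rng):
        values = rng.normal(50, 5, 500)
        hist = build_histogram(values, 1.0, bandwidth)
        assert hist.counts.sum() == 500

    def test_bimodal_mixture_yields_exactly_two_prominent_modes(self, rng):
        values = np.concatenate([rng.normal(45, 3, 5000), rng.normal(70, 3, 5000)])
        hist = build_histogram(values, 1.0, 2.0)
        # exhaustive scan: local maxima passing the default prominence filter
        from hiquant.segmentation import _qualifying_modes

        assert len(_qualifying_modes(hist, 0.05)) == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_histogram([], 1.0, 2.0)


class TestValley:
    def test_forced_valley_between_spikes(self):
        # zero run between the spikes; ties break toward lower T2
        hist = build_histogram([40] * 3 + [70] * 3, bin_width=10, smoothing_bandwidth=0)
        assert hist.counts.tolist() == [3, 0, 0, 3]
        assert find_valley(hist) == pytest.approx(50.0)

    def test_unimodal_returns_none(self, rng):
        hist = build_histogram(rng.normal(50, 3, 2000), 1.0, 2.0)
        assert find_valley(hist) is None

    def test_mixture_valley_matches_exhaustive_scan(self, rng):
        values = np.concatenate([rng.normal(45, 3, 5000), rng.normal(70, 3, 5000)])
        hist = build_histogram(values, 1.0, 2.0)
        valley = find_valley(hist)
        oracle, _ = oracle_valley(values.tolist(), 1.0, 2.0, 0.05)
        assert valley == pytest.approx(oracle)
        assert 50.0 <= valley <= 65.0


class TestHierarchicalSplit:
    def test_uniform_region_is_single_leaf(self):
        t2_map = map_from_values(np.full(100, 45.0))
        tree = hierarchical_split(t2_map, np.ones((100, 1, 1), dtype=bool))
        assert tree.is_leaf
        assert tree.mode_t2 == pytest.approx(45.0, abs=0.5)

    def test_two_separated_blobs_split_once(self, rng):
        values = np.concatenate([rng.normal(45, 1.5, 300), rng.normal(70, 1.5, 300)])
        t2_map = map_from_values(values)
        tree = hierarchical_split(t2_map, np.ones((600, 1, 1), dtype=bool))
        assert not tree.is_leaf
        modes = sorted(leaf.mode_t2 for leaf in tree.leaves())
        assert modes[0] == pytest.approx(45.0, abs=2.0)
        assert modes[-1] == pytest.approx(70.0, abs=2.0)

    def test_children_partition_parent(self, rng):
        values = np.concatenate([rng.normal(45, 2, 400), rng.normal(70, 2, 400)])
        t2_map = map_from_values(values)
        tree = hierarchical_split(t2_map, np.ones((800, 1, 1), dtype=bool))

        def check(node):
            if not node.is_leaf:
                merged = np.sort(np.concatenate([c.voxel_ids for c in node.children]))
                np.testing.assert_array_equal(merged, np.sort(node.voxel_ids))
                for c in node.children:
                    check(c)

        check(tree)

    def test_invalid_voxels_in_domain_rejected(self):
        t2_map = map_from_values(np.full(50, 45.0))
        t2_map.valid[10] = False
        with pytest.raises(ValueError, match="invalid"):
            hierarchical_split(t2_map, np.ones((50, 1, 1), dtype=bool))

    def test_three_component_mixture_matches_oracle_recursion(self, rng):
        values = np.concatenate(
            [rng.normal(40, 2, 330), rng.normal(55, 2, 330), rng.normal(75, 2, 340)]
        )
        params = SegmentationParams()
        t2_map = map_from_values(values)
        tree = hierarchical_split(t2_map, np.ones((1000, 1, 1), dtype=bool), params)
        labels = classify_leaves(tree, t2_map, params)
        expected = oracle_segment(
            ids=list(range(1000)),
            values=values.tolist(),
            bin_width=params.bin_width,
            bandwidth=params.smoothing_bandwidth,
            min_prom_frac=params.bimodality_min_prominence,
            min_region=params.min_region_voxels,
            max_depth=params.max_depth,
            core_threshold=params.core_mode_threshold,
            uninjured_threshold=params.uninjured_t2_threshold,
        )
        got = labels.labels.ravel()
        for i in range(1000):
            assert got[i] == expected[i]


class TestClassification:
    def leaf_labels_for_mode(self, values):
        params = SegmentationParams(min_region_voxels=1)
        t2_map = map_from_values(np.asarray(values, dtype=float))
        tree = hierarchical_split(t2_map, np.ones((len(values), 1, 1), dtype=bool), params)
        return classify_leaves(tree, t2_map, params).labels.ravel()

    def test_mode_above_56_is_core_at_56_is_penumbra(self):
        # strict inequality at the core threshold
        assert np.all(self.leaf_labels_for_mode([60.0] * 50) == CORE)
        assert np.all(self.leaf_labels_for_mode([56.0] * 50) == PENUMBRA)
        assert np.all(self.leaf_labels_for_mode([56.2] * 50) == CORE)

    def test_voxel_below_33_overridden_to_uninjured(self):
        values = np.array([30.0] + [45.0] * 60)
        labels = self.leaf_labels_for_mode(values)
        assert labels[0] == UNINJURED
        assert np.all(labels[1:] == PENUMBRA)

    def test_voxel_exactly_33_keeps_leaf_class(self):
        values = np.array([33.0] + [45.0] * 60)
        labels = self.leaf_labels_for_mode(values)
        assert labels[0] == PENUMBRA


class TestSegmentLesion:
    def test_noiseless_phantom_recovers_truth_voxelwise(self, noiseless_phantom):
        spec, vol, truth, lesion = noiseless_phantom
        t2_map = fit_t2_map(vol, brain_mask=lesion.mask)
        labels = segment_lesion(t2_map, lesion)
        sel = lesion.mask
        np.testing.assert_array_equal(labels.labels[sel], truth.labels.labels[sel])
        assert np.all(labels.labels[~sel] == 0)

    def test_mask_without_core_yields_pure_penumbra(self, noiseless_phantom):
        spec, vol, truth, lesion = noiseless_phantom
        pen_only = LesionMask(
            mask=truth.labels.labels == PENUMBRA, voxel_size=spec.voxel_size
        )
        t2_map = fit_t2_map(vol, brain_mask=pen_only.mask)
        labels = segment_lesion(t2_map, pen_only)
        assert (labels.labels == CORE).sum() == 0
        assert (labels.labels == PENUMBRA).sum() == pen_only.mask.sum()

    def test_empty_effective_mask_rejected(self, noiseless_phantom):
        spec, vol, _, lesion = noiseless_phantom
        t2_map = fit_t2_map(vol, brain_mask=lesion.mask)
        empty = LesionMask(mask=np.zeros(vol.grid_shape, dtype=bool), voxel_size=spec.voxel_size)
        with pytest.raises(ValueError, match="no usable voxels"):
            segment_lesion(t2_map, empty)

    def test_masked_valid_voxels_get_exactly_one_nonzero_label(self, noisy_phantom):
        _, vol, _, lesion = noisy_phantom
        t2_map = fit_t2_map(vol, brain_mask=lesion.mask)
        labels = segment_lesion(t2_map, lesion)
        domain = lesion.mask & t2_map.valid
        assert np.all(labels.labels[domain] > 0)
        assert np.all(labels.labels[~domain] == 0)

    def test_raising_core_threshold_never_increases_core_volume(self, noisy_phantom):
        _, vol, _, lesion = noisy_phantom
        t2_map = fit_t2_map(vol, brain_mask=lesion.mask)
        previous = np.inf
        for thr in (40.0, 56.0, 70.0, 90.0):
            labels = segment_lesion(t2_map, lesion, SegmentationParams(core_mode_threshold=thr))
            core = int((labels.labels == CORE).sum())
            assert core <= previous
            previous = core

    def test_permutation_invariance_of_domain_order(self, rng):
        values = np.concatenate([rng.normal(45, 2, 200), rng.normal(70, 2, 200)])
        t2_map = map_from_values(values)
        ids = np.arange(400)
        tree_a = hierarchical_split(t2_map, ids)
        tree_b = hierarchical_split(t2_map, rng.permutation(ids))
        la = classify_leaves(tree_a, t2_map).labels
        lb = classify_leaves(tree_b, t2_map).labels
        np.testing.assert_array_equal(la, lb)

    def test_noisy_phantom_volumes_within_5_percent(self, noisy_phantom):
        spec, vol, truth, lesion = noisy_phantom
        t2_map = fit_t2_map(vol, brain_mask=lesion.mask)
        labels = segment_lesion(t2_map, lesion)
        vv = spec.voxel_volume_mm3
        for code, name in ((PENUMBRA, "penumbra"), (CORE, "core")):
            est = float((labels.labels == code).sum()) * vv
            true = truth.true_volumes_mm3[name]
            assert abs(est - true) / true < 0.05


def test_boundary_phantom_strictness():
    """A uniform 56 ms lesion region is penumbra; 56+eps becomes core."""
    params = SegmentationParams(min_region_voxels=1)
    for value, expected in ((56.0, PENUMBRA), (56.0 + 1e-6, CORE), (32.9, UNINJURED)):
        t2_map = map_from_values(np.full(40, value))
        tree = hierarchical_split(t2_map, np.ones((40, 1, 1), dtype=bool), params)
        labels = classify_leaves(tree, t2_map, params)
        assert np.all(labels.labels.ravel() == expected)
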