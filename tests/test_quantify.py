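"""2-D components, γ-offset stitching, volumes and cohort summaries."""

import numpy as np
import pytest

from isletseg.quantify import (Islet3D, IsletComponent2D, cohort_report,
                               count_islets_above, islet_volume,
                               quantify_stack, size_distribution,
                               slice_components, stitch_islets)


def flood_fill_labels(mask):
    """Independent 8-connectivity labelling by explicit flood fill."""
    mask = np.asarray(mask).astype(bool)
    labels = np.zeros(mask.shape, dtype=int)
    nxt = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        nxt += 1
        stack = [start]
        labels[start] = nxt
        while stack:
            r, c = stack.pop()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]
                            and mask[rr, cc] and not labels[rr, cc]):
                        labels[rr, cc] = nxt
                        stack.append((rr, cc))
    return labels


def comp(z, pixels):
    return IsletComponent2D.from_pixels(z, pixels)


class TestSliceComponents:
    def test_empty_mask(self):
        assert slice_components(np.zeros((8, 8)), 0) == []

    def test_diagonal_pixels_joined_under_8_connectivity(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        comps = slice_components(mask, 3)
        assert len(comps) == 1
        assert comps[0].area_px == 2
        assert comps[0].slice_index == 3
        assert comps[0].centroid == (1.5, 1.5)
        # the 4-connectivity option splits them
        assert len(slice_components(mask, 3, connectivity=4)) == 2

    def test_partition_matches_flood_fill_oracle(self, rng):
        mask = rng.random((32, 32)) > 0.7
        comps = slice_components(mask, 0)
        oracle = flood_fill_labels(mask)
        oracle_sets = {frozenset(zip(*np.nonzero(oracle == lab)))
                       for lab in range(1, oracle.max() + 1)}
        ours = {frozenset(c.pixel_set) for c in comps}
        assert ours == oracle_sets

    def test_centroid_is_pixel_mean(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[2, 2:5] = True
        (c,) = slice_components(mask, 0)
        assert c.centroid == (2.0, 3.0)


class TestStitching:
    def test_close_centroids_merge(self):
        # distance sqrt(13) ≈ 3.61 < 5
        per_slice = [[comp(0, [(10, 10)])], [comp(1, [(12, 13)])]]
        assert len(stitch_islets(per_slice, gamma=5.0)) == 1

    def test_distance_exactly_gamma_does_not_merge(self):
        # (10,10) -> (13,14): distance exactly 5.0; the rule is strict <
        per_slice = [[comp(0, [(10, 10)])], [comp(1, [(13, 14)])]]
        assert len(stitch_islets(per_slice, gamma=5.0)) == 2

    def test_just_under_gamma_merges(self):
        per_slice = [[comp(0, [(10, 10)])], [comp(1, [(10, 14)])]]
        # distance 4.0 < 5
        assert len(stitch_islets(per_slice, gamma=5.0)) == 1

    def test_non_adjacent_slices_never_merge(self):
        per_slice = [[comp(0, [(10, 10)])], [], [comp(2, [(10, 10)])]]
        assert len(stitch_islets(per_slice, gamma=5.0)) == 2

    def test_transitive_closure_chains_components(self):
        per_slice = [[comp(0, [(10, 10)])],
                     [comp(1, [(13, 10)])],
                     [comp(2, [(16, 10)])]]
        islets = stitch_islets(per_slice, gamma=5.0)
        assert len(islets) == 1
        assert [c.slice_index for c in islets[0].components] == [0, 1, 2]

    def test_one_component_linking_two_keeps_all_links(self):
        # both upper components are within gamma of the single lower one
        per_slice = [[comp(0, [(10, 10)])],
                     [comp(1, [(8, 10)]), comp(1, [(12, 10)])]]
        assert len(stitch_islets(per_slice, gamma=5.0)) == 1

    def test_invariant_to_component_enumeration_order(self, rng):
        comps = [[comp(z, [(int(r), int(r))])
                  for r in rng.integers(0, 60, size=3)] for z in range(4)]
        a = stitch_islets([list(c) for c in comps], gamma=5.0)
        b = stitch_islets([list(reversed(c)) for c in comps], gamma=5.0)
        key = lambda isls: sorted(
            tuple(sorted((c.slice_index, tuple(sorted(c.pixel_set)))
                         for c in i.components)) for i in isls)
        assert key(a) == key(b)

    def test_increasing_gamma_never_increases_islet_count(self, rng):
        per_slice = [[comp(z, [(int(r), int(c))])
                      for r, c in rng.integers(0, 40, size=(4, 2))]
                     for z in range(5)]
        counts = [len(stitch_islets([list(c) for c in per_slice], g))
                  for g in (1.0, 3.0, 5.0, 10.0, 40.0)]
        assert counts == sorted(counts, reverse=True)


class TestVolumes:
    def test_hundred_voxels_at_pitch(self):
        islet = Islet3D(components=[comp(0, [(r, c) for r in range(10)
                                             for c in range(10)])])
        assert islet_volume(islet, 7.8) == pytest.approx(47455.2)

    def test_unit_voxel_unit_pitch(self):
        islet = Islet3D(components=[comp(0, [(0, 0)])])
        assert islet_volume(islet, 1.0) == 1.0

    def test_three_slices_of_fifty(self):
        comps = [comp(z, [(r, c) for r in range(5) for c in range(10)])
                 for z in range(3)]
        islet = Islet3D(components=comps)
        assert islet.voxel_count == 150
        assert islet_volume(islet, 7.8) == pytest.approx(150 * 7.8 ** 3)

    def test_voxel_conservation_on_random_stack(self, rng):
        mask = rng.random((6, 40, 40)) > 0.92
        islets = quantify_stack(mask, gamma=5.0)
        assert sum(i.voxel_count for i in islets) == int(mask.sum())


class TestSizeDistribution:
    def test_empty(self):
        d = size_distribution([], [0, 10, 20])
        assert d.counts.tolist() == [0, 0] and d.overflow == 0

    def test_counting_hand_case(self):
        islets = []
        for v in (10, 20, 30):
            isl = Islet3D(components=[comp(0, [(0, 0)])])
            isl.volume_um3 = float(v)
            islets.append(isl)
        d = size_distribution(islets, [0, 15, 35])
        assert d.counts.tolist() == [1, 2]

    def test_conservation_with_overflow(self, rng):
        islets = []
        for v in rng.uniform(0, 100, size=20):
            isl = Islet3D(components=[comp(0, [(0, 0)])])
            isl.volume_um3 = float(v)
            islets.append(isl)
        d = size_distribution(islets, [10, 30, 50])
        assert d.counts.sum() + d.overflow == 20

    def test_decreasing_edges_rejected(self):
        with pytest.raises(ValueError):
            size_distribution([], [10, 5])


class TestCountAbove:
    def _with_volumes(self, volumes):
        out = []
        for v in volumes:
            isl = Islet3D(components=[comp(0, [(0, 0)])])
            isl.volume_um3 = float(v)
            out.append(isl)
        return out

    def test_zero_threshold_counts_all(self):
        islets = self._with_volumes([1, 2, 3])
        assert count_islets_above(islets, 0) == 3

    def test_inclusive_boundary_default_strict_option(self):
        islets = self._with_volumes([1499e3, 1500e3, 1501e3])
        assert count_islets_above(islets, 1500e3) == 2
        assert count_islets_above(islets, 1500e3, strict=True) == 1


class TestCohortReport:
    def _sample(self, n):
        return [Islet3D(components=[comp(0, [(0, 0)])]) for _ in range(n)]

    def test_single_sample_sem_is_nan(self):
        df = cohort_report({"wt": [self._sample(3)]})
        assert df.loc[0, "islet_count_mean"] == 3
        assert np.isnan(df.loc[0, "islet_count_sem"])

    def test_mean_and_sem_hand_case(self):
        df = cohort_report({"gk": [self._sample(4), self._sample(6)]})
        assert df.loc[0, "islet_count_mean"] == pytest.approx(5.0)
        assert df.loc[0, "islet_count_sem"] == pytest.approx(1.0)

    def test_group_labels_preserved(self):
        df = cohort_report({"Wistar wt": [self._sample(1)],
                            "GK diabetic": [self._sample(2)]})
        assert set(df["group"]) == {"Wistar wt", "GK diabetic"}
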