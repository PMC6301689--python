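"""Lesion detection, distance maps and region construction.

Connected components and distance transforms are checked against exhaustive
brute-force oracles (flood fill over the 26-neighbourhood; all-pairs nearest
voxel-center search) on many small random grids.
"""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from pvccs import (
    anisotropic_distance_map,
    define_background,
    detect_lesions,
    extend_lesion,
    score_scan,
    segment_lesions,
)
from pvccs.evaluation import match_scores_to_inserts

from conftest import make_volume


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def flood_fill_components(binary):
    """Exhaustive 26-connected labelling by BFS over all voxels."""
    binary = np.asarray(binary, dtype=bool)
    labels = np.zeros(binary.shape, dtype=int)
    current = 0
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    for start in zip(*np.nonzero(binary)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            x, y, z = stack.pop()
            for dx, dy, dz in offsets:
                n = (x + dx, y + dy, z + dz)
                if all(0 <= n[a] < binary.shape[a] for a in range(3)):
                    if binary[n] and not labels[n]:
                        labels[n] = current
                        stack.append(n)
    return labels, current


def nearest_distance(mask, spacing, direction):
    """All-pairs voxel-center distance search (O(n^2), small grids only)."""
    mask = np.asarray(mask, dtype=bool)
    inside = np.argwhere(mask) * np.asarray(spacing)
    outside = np.argwhere(~mask) * np.asarray(spacing)
    out = np.zeros(mask.shape)
    if direction == "interior":
        d = cdist(inside, outside).min(axis=1)
        out[mask] = d
    else:
        d = cdist(outside, inside).min(axis=1)
        out[~mask] = d
    return out


def as_sets(labels, n):
    return {frozenset(map(tuple, np.argwhere(labels == lab + 1))) for lab in range(n)}


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

class TestDetectLesions:
    def test_all_below_threshold_gives_no_lesions(self):
        volume = make_volume(np.full((4, 4, 4), 100.0))
        assert detect_lesions(volume) == []

    def test_corner_touching_voxels_form_one_lesion(self):
        hu = np.zeros((2, 2, 2))
        hu[0, 0, 0] = hu[1, 1, 1] = 200.0  # touch only at a corner
        lesions = detect_lesions(make_volume(hu))
        assert len(lesions) == 1
        assert lesions[0].sum() == 2

    def test_components_match_flood_fill_oracle_on_random_grids(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            shape = tuple(rng.integers(3, 13, size=3))
            hu = np.where(rng.random(shape) < 0.35, 200.0, 0.0)
            found = detect_lesions(make_volume(hu))
            oracle_labels, n = flood_fill_components(hu >= 130.0)
            assert len(found) == n
            found_sets = {frozenset(map(tuple, np.argwhere(m))) for m in found}
            assert found_sets == as_sets(oracle_labels, n)
            # sorted by size, largest first
            sizes = [int(m.sum()) for m in found]
            assert sizes == sorted(sizes, reverse=True)

    def test_raising_threshold_never_adds_voxels(self):
        rng = np.random.default_rng(5)
        hu = rng.uniform(0.0, 400.0, size=(10, 10, 4))
        volume = make_volume(hu)
        counts = [
            sum(int(m.sum()) for m in detect_lesions(volume, thr))
            for thr in (90.0, 130.0, 200.0, 300.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_min_voxel_filter(self):
        hu = np.zeros((6, 6, 1))
        hu[0:2, 0:2, 0] = 200.0  # 4 voxels
        hu[5, 5, 0] = 200.0  # singleton
        volume = make_volume(hu)
        assert len(detect_lesions(volume)) == 2
        assert len(detect_lesions(volume, min_voxels=3)) == 1


class TestDistanceMaps:
    def test_single_voxel_interior_distance_is_in_plane_spacing(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        d = anisotropic_distance_map(mask, (1.0, 1.0, 3.0), "interior")
        assert d[1, 1, 1] == pytest.approx(1.0)

    def test_plane_center_distance(self):
        # 3x3 in-plane square in a 5x5x1 grid: center is 2 voxels from outside
        mask = np.zeros((5, 5, 1), dtype=bool)
        mask[1:4, 1:4, 0] = True
        d = anisotropic_distance_map(mask, (1.0, 1.0, 3.0), "interior")
        assert d[2, 2, 0] == pytest.approx(2.0)

    def test_exterior_distance_across_slice_is_slice_spacing(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        d = anisotropic_distance_map(mask, (1.0, 1.0, 3.0), "exterior")
        assert d[1, 1, 2] == pytest.approx(3.0)
        assert d[1, 1, 1] == 0.0

    def test_empty_interior_rejected(self):
        with pytest.raises(ValueError):
            anisotropic_distance_map(np.zeros((3, 3, 3), bool), (1, 1, 1), "interior")

    @pytest.mark.parametrize("direction", ["interior", "exterior"])
    def test_matches_exhaustive_search_on_random_grids(self, direction):
        rng = np.random.default_rng(99)
        for _ in range(50):
            shape = tuple(rng.integers(3, 9, size=3))
            mask = rng.random(shape) < 0.4
            if not mask.any() or mask.all():
                continue
            spacing = tuple(rng.choice([0.5, 1.0, 2.0, 3.0], size=3))
            got = anisotropic_distance_map(mask, spacing, direction)
            want = nearest_distance(mask, spacing, direction)
            np.testing.assert_allclose(got, want, atol=1e-9)


class TestExtendLesion:
    def test_no_candidates_gives_empty_extension(self):
        hu = np.zeros((5, 5, 1))
        hu[2, 2, 0] = 300.0
        volume = make_volume(hu, spacing=(1.0, 1.0, 3.0))
        extended, d1 = extend_lesion(volume, hu >= 130.0)
        assert not extended.any()
        assert d1 == pytest.approx(1.0)

    def test_distance_bound_prunes_far_candidates(self):
        # chain 200 -> 100 -> 100: d1 = 1 keeps only the adjacent candidate
        hu = np.zeros((7, 5, 1))
        hu[2, 2, 0] = 200.0
        hu[3, 2, 0] = 100.0
        hu[4, 2, 0] = 100.0
        volume = make_volume(hu, spacing=(1.0, 1.0, 3.0))
        extended, d1 = extend_lesion(volume, hu >= 130.0)
        assert d1 == pytest.approx(1.0)
        assert extended[3, 2, 0] and not extended[4, 2, 0]
        assert extended.sum() == 1

    def test_disconnected_bright_voxels_not_annexed(self):
        hu = np.zeros((9, 5, 1))
        hu[2, 2, 0] = 200.0
        hu[6, 2, 0] = 100.0  # above 90 HU but not connected to the lesion
        volume = make_volume(hu, spacing=(1.0, 1.0, 3.0))
        extended, _ = extend_lesion(volume, hu >= 130.0)
        assert not extended.any()


class TestDefineBackground:
    def test_single_voxel_background_is_face_neighbours(self):
        calc = np.zeros((5, 5, 5), dtype=bool)
        calc[2, 2, 2] = True
        volume = make_volume(np.zeros((5, 5, 5)))
        background, d2 = define_background(volume, calc)
        assert d2 == pytest.approx(1.0)
        assert background.sum() == 6  # diagonals are sqrt(2) > 1 away
        assert not background[2, 2, 2]

    def test_clipped_at_volume_border(self):
        calc = np.zeros((4, 4, 2), dtype=bool)
        calc[0, 0, 0] = True
        volume = make_volume(np.zeros((4, 4, 2)), spacing=(1.0, 1.0, 1.0))
        background, _ = define_background(volume, calc)
        assert background.sum() == 3  # the in-bounds face neighbours only

    def test_other_lesions_excluded_from_background(self):
        hu = np.zeros((7, 5, 1))
        hu[1, 2, 0] = 300.0
        hu[3, 2, 0] = 300.0  # second lesion 2 voxels away
        volume = make_volume(hu, spacing=(1.0, 1.0, 3.0))
        lesions = segment_lesions(volume)
        assert len(lesions) == 2
        for lesion in lesions:
            for other in lesions:
                if other.label_id != lesion.label_id:
                    assert not (lesion.background_mask & other.calcification_mask).any()


class TestRegionInvariants:
    def test_nesting_and_disjointness_on_simulated_phantom(self, ceora_noiseless):
        _, volume, gt = ceora_noiseless
        lesions = segment_lesions(volume)
        assert lesions
        for lesion in lesions:
            calc = lesion.calcification_mask
            assert (lesion.initial_mask & calc).sum() == lesion.initial_mask.sum()
            assert not (lesion.extended_mask & lesion.initial_mask).any()
            assert not (lesion.background_mask & calc).any()
            assert lesion.d1_mm > 0 and lesion.d2_mm > 0
            # every extension voxel is bright and within d1 of the initial mask
            ext_dist = anisotropic_distance_map(lesion.initial_mask, volume.spacing_mm, "exterior")
            assert np.all(volume.intensities[lesion.extended_mask] > 90.0)
            assert np.all(ext_dist[lesion.extended_mask] <= lesion.d1_mm + 1e-6)

    def test_each_detectable_insert_maps_to_one_lesion(self, ceora_noiseless):
        # a noiseless phantom must not split or merge insert components
        _, volume, gt = ceora_noiseless
        result = score_scan(volume)
        df = match_scores_to_inserts(result, gt)
        detected = df[df.detected]
        assert len(detected) == len(result.scores)  # no unmatched lesions
        assert detected.insert_id.is_unique
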