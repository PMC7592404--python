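"""Per-voxel 26-neighbour co-occurrence entropy against brute-force oracles."""

import itertools

import numpy as np
import pytest

from lungtex import (
    MAX_ENTROPY_BITS,
    compute_entropy_map,
    entropy_of,
    local_cooccurrence,
)
from conftest import make_quantised

ALL_OFFSETS = [
    off for off in itertools.product((-1, 0, 1), repeat=3) if off != (0, 0, 0)
]


def oracle_matrix(levels, mask, voxel, n_levels=16):
    """Explicit 26-offset enumeration of one voxel's co-occurrence counts
    (order-free pairs accumulated in the upper triangle, the declared
    convention)."""
    z, y, x = voxel
    counts = np.zeros((n_levels, n_levels))
    for dz, dy, dx in ALL_OFFSETS:
        zz, yy, xx = z + dz, y + dy, x + dx
        if not (0 <= zz < mask.shape[0] and 0 <= yy < mask.shape[1]
                and 0 <= xx < mask.shape[2]):
            continue
        if not mask[zz, yy, xx]:
            continue
        a, b = levels[z, y, x] - 1, levels[zz, yy, xx] - 1
        counts[min(a, b), max(a, b)] += 1
    return counts


def oracle_entropy(counts):
    total = counts.sum()
    if total == 0:
        return None
    h = 0.0
    for p in (counts / total).ravel():
        if p > 0:
            h -= p * np.log2(p)
    return h


class TestLocalCooccurrence:
    def test_constant_volume_gives_single_cell(self):
        q = make_quantised(np.full((3, 3, 3), 7))
        m = local_cooccurrence(q, (1, 1, 1))
        assert m[6, 6] == 1.0
        assert m.sum() == 1.0

    def test_corner_voxel_uses_seven_neighbours(self, rng):
        levels = rng.integers(1, 17, size=(4, 4, 4))
        q = make_quantised(levels)
        m = local_cooccurrence(q, (0, 0, 0))
        oracle = oracle_matrix(levels, np.ones((4, 4, 4), bool), (0, 0, 0))
        assert oracle.sum() == 7  # exactly 7 neighbours contribute
        np.testing.assert_allclose(m, oracle / oracle.sum(), atol=1e-15)

    def test_matches_offset_enumeration_oracle(self, rng):
        levels = rng.integers(1, 17, size=(5, 5, 5))
        mask = rng.random((5, 5, 5)) < 0.7
        mask[2, 2, 2] = True
        q = make_quantised(levels, mask)
        m = local_cooccurrence(q, (2, 2, 2))
        oracle = oracle_matrix(levels, mask, (2, 2, 2))
        np.testing.assert_allclose(m, oracle / oracle.sum(), atol=1e-15)

    def test_out_of_mask_voxel_rejected(self):
        mask = np.ones((3, 3, 3), bool)
        mask[0, 0, 0] = False
        q = make_quantised(np.ones((3, 3, 3)), mask)
        with pytest.raises(ValueError, match="not inside"):
            local_cooccurrence(q, (0, 0, 0))


class TestEntropyOf:
    def test_single_cell_matrix_is_zero(self):
        m = np.zeros((16, 16))
        m[3, 3] = 1.0
        assert entropy_of(m) == 0.0

    def test_two_symmetric_half_cells_give_one_bit(self):
        m = np.zeros((16, 16))
        m[1, 2] = m[2, 1] = 0.5
        assert entropy_of(m) == pytest.approx(1.0, abs=1e-15)

    def test_matches_direct_sum_oracle(self, rng):
        m = rng.random((16, 16))
        m /= m.sum()
        direct = -sum(p * np.log2(p) for p in m.ravel() if p > 0)
        assert entropy_of(m) == pytest.approx(direct, abs=1e-12)

    def test_rejects_unnormalised_matrix(self):
        with pytest.raises(ValueError, match="normalised"):
            entropy_of(np.full((16, 16), 1.0))


class TestComputeEntropyMap:
    def test_constant_voi_gives_zero_map(self):
        q = make_quantised(np.full((5, 5, 5), 9))
        emap = compute_entropy_map(q)
        np.testing.assert_array_equal(emap.values, 0.0)
        assert emap.scored.sum() == 125

    def test_matches_per_voxel_oracle_exactly(self, rng):
        levels = rng.integers(1, 17, size=(8, 8, 8))
        mask = rng.random((8, 8, 8)) < 0.6
        mask[4, 4, 4] = True
        q = make_quantised(levels, mask)
        emap = compute_entropy_map(q)
        for z, y, x in np.argwhere(mask):
            oracle = oracle_entropy(oracle_matrix(levels, mask, (z, y, x)))
            if oracle is None:
                assert not emap.scored[z, y, x]
            else:
                assert emap.entropy[z, y, x] == pytest.approx(oracle, abs=1e-12)

    def test_entropy_bounded_by_log2_26(self, rng):
        levels = rng.integers(1, 17, size=(10, 10, 10))
        emap = compute_entropy_map(make_quantised(levels))
        assert np.all(emap.values <= MAX_ENTROPY_BITS + 1e-12)
        assert np.all(emap.values >= 0.0)
        assert emap.valid_pairs[emap.scored].min() >= 1
        assert emap.valid_pairs[emap.scored].max() <= 26

    def test_isolated_voxel_excluded(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[0, 0, 0] = True
        mask[4, 4, 4] = True
        mask[4, 4, 3] = True
        q = make_quantised(np.full((5, 5, 5), 3), mask)
        emap = compute_entropy_map(q)
        assert not emap.scored[0, 0, 0]
        assert np.isnan(emap.entropy[0, 0, 0])
        assert emap.scored[4, 4, 4] and emap.scored[4, 4, 3]

    def test_level_label_permutation_invariance(self, rng):
        levels = rng.integers(1, 17, size=(6, 6, 6))
        perm = rng.permutation(16) + 1
        emap = compute_entropy_map(make_quantised(levels))
        emap_perm = compute_entropy_map(make_quantised(perm[levels - 1]))
        np.testing.assert_allclose(emap_perm.entropy[emap.scored],
                                   emap.entropy[emap.scored], atol=1e-12)

    @pytest.mark.parametrize("rot", [1, 2, 3])
    def test_rotation_leaves_entropy_multiset_unchanged(self, rng, rot):
        levels = rng.integers(1, 17, size=(6, 6, 6))
        emap = compute_entropy_map(make_quantised(levels))
        rotated = np.rot90(levels, k=rot, axes=(1, 2)).copy()
        emap_rot = compute_entropy_map(make_quantised(rotated))
        np.testing.assert_allclose(np.sort(emap_rot.values), np.sort(emap.values),
                                   atol=1e-12)

    def test_mean_entropy_increases_with_level_count(self, rng):
        means = []
        for k in (2, 4, 8, 16):
            levels = rng.integers(1, k + 1, size=(10, 10, 10))
            emap = compute_entropy_map(make_quantised(levels))
            means.append(emap.values.mean())
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_two_block_volume_has_entropy_only_at_interface(self):
        levels = np.full((6, 6, 12), 2)
        levels[:, :, 6:] = 11
        emap = compute_entropy_map(make_quantised(levels))
        interior = emap.entropy[:, :, [0, 1, 2, 9, 10, 11]]
        interface = emap.entropy[:, :, [5, 6]]
        np.testing.assert_array_equal(interior, 0.0)
        assert np.all(interface > 0.0)

    def test_aggregated_pairs_match_skimage_glcm(self, rng):
        """Summing every voxel's count matrix over a single-slice volume must
        match the symmetric scikit-image GLCM over the 4 in-plane directions:
        each adjacent pair is seen from both of its endpoints, so the folded
        per-voxel aggregate equals the upper-triangularised symmetric GLCM."""
        skimage_feature = pytest.importorskip("skimage.feature")
        levels = rng.integers(1, 17, size=(1, 12, 12))
        q = make_quantised(levels)
        emap = compute_entropy_map(q)
        n = 16
        total = np.zeros((n, n))
        for z, y, x in np.argwhere(q.mask.mask):
            # un-normalise: the matrix was built from valid_pairs increments
            m = local_cooccurrence(q, (z, y, x)) * emap.valid_pairs[z, y, x]
            total += m
        img = (levels[0] - 1).astype(np.uint8)
        glcm = skimage_feature.graycomatrix(
            img, distances=[1], angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
            levels=16, symmetric=True,
        )
        sk = glcm[:, :, 0, :].sum(axis=2).astype(float)
        expected = np.triu(sk + sk.T, 1) + np.diag(np.diag(sk))
        np.testing.assert_allclose(total, expected, atol=1e-9)
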