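"""Voxel-wise grey-level co-occurrence entropy over a quantised VOI.

Each in-mask voxel gets its own co-occurrence matrix, accumulated from
the 26 voxels that surround it (the 13 direction vectors of the 3-D
Moore neighbourhood and their negatives, displacement 1 voxel in index
space).  For every neighbour that lies inside both the grid and the VOI
mask, the level pair (level(voxel), level(neighbour)) is counted
order-free: the symmetric mass is merged into the upper-triangular cell
(min, max), so the matrix describes the distribution of UNORDERED level
pairs.  It is normalised to a probability distribution and its Shannon
entropy in bits,

    H = -sum_{p > 0} p * log2(p),

becomes the voxel's texture score.  Homogeneous surroundings give H = 0;
the 26 pairs occupy at most 26 distinct cells, bounding H above by
log2(26) ~= 4.700 bits.  Healthy
parenchyma — a mix of airways, vessels and alveoli — scores high;
internally uniform low-density bullae score near zero.

Neighbours outside the grid or outside the mask are simply skipped, so
voxels near the thin cylinder's wall use fewer pairs rather than padded
ones; a voxel with no valid neighbour at all cannot be scored and is
excluded from the map.  The computation is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy.special import xlogy

from .quantise import QuantisedVolume

__all__ = [
    "NEIGHBOUR_OFFSETS",
    "MAX_ENTROPY_BITS",
    "EntropyMap",
    "local_cooccurrence",
    "entropy_of",
    "compute_entropy_map",
]

# the 26 offsets of the 3-D Moore neighbourhood: 13 directions and their negatives
NEIGHBOUR_OFFSETS: np.ndarray = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ],
    dtype=np.int64,
)

MAX_ENTROPY_BITS: float = float(np.log2(26.0))


@dataclass
class EntropyMap:
    """Per-voxel entropy scores over a VOI mask.

    ``entropy`` is NaN outside ``scored``; ``valid_pairs`` counts the
    neighbour pairs each voxel's matrix was built from (1..26 for scored
    voxels).  ``scored`` is the VOI mask minus any isolated voxels.
    """

    entropy: np.ndarray
    valid_pairs: np.ndarray
    scored: np.ndarray
    voi_mask: np.ndarray
    spacing: tuple[float, float, float]

    @property
    def values(self) -> np.ndarray:
        """Entropy scores of the scored voxels, lexicographic order."""
        return self.entropy[self.scored]

    def write_nifti(self, path: str) -> None:
        affine = np.diag(list(self.spacing) + [1.0]).astype(float)
        data = np.where(self.scored, self.entropy, 0.0)
        nib.save(nib.Nifti1Image(data.T.astype(np.float64), affine), path)


def local_cooccurrence(q: QuantisedVolume, voxel: tuple[int, int, int]) -> np.ndarray:
    """Co-occurrence probability matrix of one voxel's 26-neighbourhood.

    Counts the unordered pair {level(voxel), level(neighbour)} in the
    upper-triangular cell for each valid neighbour, then normalises to
    sum to 1.  Raises if the voxel is outside the mask or has no valid
    neighbour (isolated).
    """
    z, y, x = (int(c) for c in voxel)
    mask = q.mask.mask
    if not mask[z, y, x]:
        raise ValueError(f"voxel {voxel} is not inside the VOI mask")
    n = q.scheme.n_levels
    shape = mask.shape
    counts = np.zeros((n, n), dtype=np.float64)
    lc = q.levels[z, y, x]
    for dz, dy, dx in NEIGHBOUR_OFFSETS:
        zz, yy, xx = z + dz, y + dy, x + dx
        if not (0 <= zz < shape[0] and 0 <= yy < shape[1] and 0 <= xx < shape[2]):
            continue
        if not mask[zz, yy, xx]:
            continue
        ln = q.levels[zz, yy, xx]
        counts[min(lc, ln) - 1, max(lc, ln) - 1] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError(f"voxel {voxel} is isolated: no valid neighbours")
    return counts / total


def entropy_of(matrix: np.ndarray) -> float:
    """Shannon entropy in bits of a co-occurrence probability matrix."""
    m = np.asarray(matrix, dtype=np.float64)
    total = m.sum()
    if not np.isclose(total, 1.0, rtol=0, atol=1e-8):
        raise ValueError(f"matrix must be normalised (sums to {total})")
    return float(-xlogy(m, m).sum() / np.log(2.0))


def compute_entropy_map(q: QuantisedVolume) -> EntropyMap:
    """Entropy of every in-mask voxel's local co-occurrence matrix.

    Vectorised equivalent of calling :func:`local_cooccurrence` +
    :func:`entropy_of` per voxel: pair counts for all voxels and all 26
    offsets are accumulated in one bincount pass.
    """
    mask = q.mask.mask
    if not mask.any():
        raise ValueError("empty VOI mask")
    n = q.scheme.n_levels
    nz, ny, nx = mask.shape
    n_vox = int(mask.sum())

    vox_id = np.full(mask.shape, -1, dtype=np.int64)
    vox_id[mask] = np.arange(n_vox)
    levels = q.levels.astype(np.int64)

    chunks: list[np.ndarray] = []
    for dz, dy, dx in NEIGHBOUR_OFFSETS:
        src = (
            slice(max(0, -dz), min(nz, nz - dz)),
            slice(max(0, -dy), min(ny, ny - dy)),
            slice(max(0, -dx), min(nx, nx - dx)),
        )
        dst = (
            slice(max(0, dz), min(nz, nz + dz)),
            slice(max(0, dy), min(ny, ny + dy)),
            slice(max(0, dx), min(nx, nx + dx)),
        )
        valid = mask[src] & mask[dst]
        if not valid.any():
            continue
        cid = vox_id[src][valid]
        lc = levels[src][valid] - 1
        ln = levels[dst][valid] - 1
        lo = np.minimum(lc, ln)
        hi = np.maximum(lc, ln)
        chunks.append(cid * (n * n) + lo * n + hi)

    if not chunks:
        raise ValueError("no valid neighbour pairs anywhere in the VOI")
    flat = np.concatenate(chunks)
    counts = np.bincount(flat, minlength=n_vox * n * n).reshape(n_vox, n, n)

    totals = counts.sum(axis=(1, 2))
    scored_flat = totals > 0
    safe_tot = np.where(scored_flat, totals, 1)
    # H = log2(T) - (1/T) * sum c*log2(c): counts are small integers, so a
    # lookup table beats evaluating xlogy on the dense probability array
    cmax = int(counts.max())
    table = xlogy(np.arange(cmax + 1), np.arange(cmax + 1)) / np.log(2.0)
    sum_clog = table[counts].sum(axis=(1, 2))
    h_flat = np.log2(safe_tot) - sum_clog / safe_tot
    # snap ~1e-16 cancellation residue of degenerate (single-cell) matrices to
    # exact 0: the smallest real nonzero entropy of <=26 integer counts is ~0.33
    h_flat[np.abs(h_flat) < 1e-9] = 0.0

    entropy = np.full(mask.shape, np.nan)
    valid_pairs = np.zeros(mask.shape, dtype=np.int32)
    scored = np.zeros(mask.shape, dtype=bool)
    entropy[mask] = np.where(scored_flat, h_flat, np.nan)
    valid_pairs[mask] = totals.astype(np.int32)
    scored[mask] = scored_flat
    return EntropyMap(entropy, valid_pairs, scored, mask.copy(), q.mask.spacing)
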