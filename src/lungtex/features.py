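"""Per-patient summary features of the density and entropy signals.

Density statistics are computed on RAW grey levels from the original
volume (the density axis of the 2-D histogram); entropy statistics on
the GLCM entropy map, which is itself built from the quantised volume.
The mode of a continuous signal is defined via binning: the most
populated bin's midpoint, ties resolved to the lowest bin.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .entropy import MAX_ENTROPY_BITS, EntropyMap
from .quantise import QuantisationScheme

__all__ = [
    "FeatureRecord",
    "Histogram2D",
    "FEATURE_COLUMNS",
    "summary_stats",
    "moments",
    "histogram2d",
    "subregion_count",
    "default_entropy_edges",
    "build_feature_record",
]

FEATURE_COLUMNS = [
    "density_mean",
    "density_median",
    "density_mode",
    "entropy_mean",
    "entropy_median",
    "entropy_mode",
    "density_skewness",
    "density_kurtosis",
    "entropy_skewness",
    "entropy_kurtosis",
    "subregion_count",
    "subregion_fraction",
]


@dataclass
class FeatureRecord:
    """One patient's VOI reduced to its summary features."""

    patient_id: str
    density_mean: float
    density_median: float
    density_mode: float
    entropy_mean: float
    entropy_median: float
    entropy_mode: float
    density_skewness: float
    density_kurtosis: float
    entropy_skewness: float
    entropy_kurtosis: float
    subregion_count: int
    subregion_fraction: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class Histogram2D:
    """2-D density (x) x entropy (y) histogram of one VOI."""

    density_edges: np.ndarray
    entropy_edges: np.ndarray
    counts: np.ndarray  # shape (len(density_edges)-1, len(entropy_edges)-1)


def summary_stats(
    values: np.ndarray, bin_edges: np.ndarray | None = None
) -> tuple[float, float, float]:
    """Arithmetic mean, median (midpoint convention) and binned mode.

    The mode of a continuous signal is the midpoint of the most populated
    bin under ``bin_edges`` (16 equal bins over the data range if none
    given); ties go to the lowest bin.  Out-of-range values count toward
    the end bins.
    """
    vals = np.asarray(values, dtype=np.float64).ravel()
    if vals.size == 0:
        raise ValueError("summary_stats requires a non-empty input")
    if bin_edges is None:
        lo, hi = float(vals.min()), float(vals.max())
        if hi == lo:  # constant input: its own mode
            return float(vals.mean()), float(np.median(vals)), lo
        bin_edges = np.linspace(lo, hi, 17)
    bin_edges = np.asarray(bin_edges, dtype=np.float64)
    clipped = np.clip(vals, bin_edges[0], bin_edges[-1])
    counts, _ = np.histogram(clipped, bins=bin_edges)
    k = int(np.argmax(counts))  # argmax returns the first (lowest) max bin
    mode = float((bin_edges[k] + bin_edges[k + 1]) / 2.0)
    return float(vals.mean()), float(np.median(vals)), mode


def moments(values: np.ndarray) -> tuple[float, float]:
    """Fisher–Pearson skewness and excess kurtosis, population form.

    skewness = m3 / m2^1.5, kurtosis = m4 / m2^2 - 3, with m_k the biased
    central sample moments (no small-sample correction).
    """
    vals = np.asarray(values, dtype=np.float64).ravel()
    if vals.size < 3:
        raise ValueError("moments require at least 3 values")
    if np.all(vals == vals[0]):
        raise ValueError("moments undefined for constant input (zero variance)")
    skew = float(stats.skew(vals, bias=True))
    kurt = float(stats.kurtosis(vals, fisher=True, bias=True))
    return skew, kurt


def histogram2d(
    density: np.ndarray,
    entropy: np.ndarray,
    density_edges: np.ndarray,
    entropy_edges: np.ndarray,
) -> Histogram2D:
    """Joint density-entropy histogram; out-of-range points go to end bins."""
    d = np.asarray(density, dtype=np.float64).ravel()
    e = np.asarray(entropy, dtype=np.float64).ravel()
    if d.size != e.size:
        raise ValueError(f"length mismatch: {d.size} density vs {e.size} entropy")
    density_edges = np.asarray(density_edges, dtype=np.float64)
    entropy_edges = np.asarray(entropy_edges, dtype=np.float64)
    d = np.clip(d, density_edges[0], density_edges[-1])
    e = np.clip(e, entropy_edges[0], entropy_edges[-1])
    counts, _, _ = np.histogram2d(d, e, bins=(density_edges, entropy_edges))
    return Histogram2D(density_edges, entropy_edges, counts)


def subregion_count(
    density: np.ndarray,
    entropy: np.ndarray,
    density_max: float,
    entropy_max: float,
) -> tuple[int, float]:
    """Count voxels in the low-density low-entropy subregion.

    Emphysematous bullae are both dark and internally uniform, so their
    voxels pile up below both thresholds; the count (and its fraction of
    the VOI) is a candidate burden score.
    """
    d = np.asarray(density, dtype=np.float64).ravel()
    e = np.asarray(entropy, dtype=np.float64).ravel()
    if d.size != e.size:
        raise ValueError(f"length mismatch: {d.size} density vs {e.size} entropy")
    count = int(np.count_nonzero((d < density_max) & (e < entropy_max)))
    fraction = count / d.size if d.size else 0.0
    return count, fraction


def default_entropy_edges(n_bins: int = 16) -> np.ndarray:
    """Histogram/mode bins for the entropy axis: equal bins on [0, log2 26]."""
    return np.linspace(0.0, MAX_ENTROPY_BITS, n_bins + 1)


def build_feature_record(
    patient_id: str,
    density_values: np.ndarray,
    entropy_map: EntropyMap,
    scheme: QuantisationScheme,
    density_max: float | None = None,
    entropy_max: float = 1.0,
) -> FeatureRecord:
    """Assemble one patient's FeatureRecord.

    ``density_values`` are the raw grey levels of the VOI (same mask the
    entropy map was computed on); entropy summaries use scored voxels
    only.  The subregion density threshold defaults to the edge between
    quantisation levels 4 and 5, the entropy threshold to 1 bit.
    """
    density = np.asarray(density_values, dtype=np.float64).ravel()
    entropy = entropy_map.values
    if density_max is None:
        density_max = float(scheme.edges[4])

    if density.size != int(entropy_map.voi_mask.sum()):
        raise ValueError(
            f"density vector has {density.size} values but the VOI mask "
            f"covers {int(entropy_map.voi_mask.sum())} voxels"
        )
    d_mean, d_median, d_mode = summary_stats(density, scheme.edges)
    e_mean, e_median, e_mode = summary_stats(entropy, default_entropy_edges())
    # a degenerate (constant) signal has no shape to describe: moments are 0
    if np.all(density == density[0]):
        d_skew, d_kurt = 0.0, 0.0
    else:
        d_skew, d_kurt = moments(density)
    if np.all(entropy == entropy[0]):
        e_skew, e_kurt = 0.0, 0.0
    else:
        e_skew, e_kurt = moments(entropy)
    # subregion membership is voxel-wise, so align density with the scored
    # subset of the VOI (both vectors are in lexicographic voxel order)
    density_scored = density[entropy_map.scored[entropy_map.voi_mask]]
    count, fraction = subregion_count(
        density_scored, entropy, density_max, entropy_max
    )
    return FeatureRecord(
        patient_id=patient_id,
        density_mean=d_mean,
        density_median=d_median,
        density_mode=d_mode,
        entropy_mean=e_mean,
        entropy_median=e_median,
        entropy_mode=e_mode,
        density_skewness=d_skew,
        density_kurtosis=d_kurt,
        entropy_skewness=e_skew,
        entropy_kurtosis=e_kurt,
        subregion_count=count,
        subregion_fraction=fraction,
    )
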