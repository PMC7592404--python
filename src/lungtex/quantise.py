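"""Fixed uniform grey-level quantisation.

The texture stage works on 16 grey levels whose bin edges are derived
ONCE, from the VOI of a single healthy reference subject, and then
applied unchanged to every other VOI.  Fixing the edges is what makes
entropy comparable across patients: two VOIs with different dynamic
ranges are binned on the same absolute grey-level scale rather than each
being stretched to its own min-max.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .roi import ROIMask
from .volumes import CTVolume

__all__ = [
    "QuantisationScheme",
    "QuantisedVolume",
    "derive_levels",
    "quantise_values",
    "apply_quantisation",
]


@dataclass
class QuantisationScheme:
    """``n_levels`` equal-width grey-level bins with fixed edges.

    ``edges`` has ``n_levels + 1`` strictly increasing entries, equally
    spaced (to within 1 part in 1e9 of the bin width); ``provenance``
    records which reference VOI produced them.
    """

    n_levels: int
    edges: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.float64)
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.edges.shape != (self.n_levels + 1,):
            raise ValueError(
                f"expected {self.n_levels + 1} edges, got {self.edges.shape}"
            )
        widths = np.diff(self.edges)
        if np.any(widths <= 0):
            raise ValueError("edges must be strictly increasing")
        if np.any(np.abs(widths - widths[0]) > 1e-9 * widths[0]):
            raise ValueError("edges must be uniformly spaced")

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def midpoints(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_levels": self.n_levels,
            "edges": self.edges.tolist(),
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "QuantisationScheme":
        payload = json.loads(Path(path).read_text())
        return cls(payload["n_levels"], np.asarray(payload["edges"]), payload["provenance"])


@dataclass
class QuantisedVolume:
    """Integer levels 1..n over a VOI mask (0 outside the mask)."""

    levels: np.ndarray
    mask: ROIMask
    scheme: QuantisationScheme

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int32)
        if self.levels.shape != self.mask.shape:
            raise ValueError("levels array must match mask shape")
        inmask = self.levels[self.mask.mask]
        if inmask.size and (inmask.min() < 1 or inmask.max() > self.scheme.n_levels):
            raise ValueError("in-mask levels must lie in [1, n_levels]")


def derive_levels(
    reference_values: np.ndarray, n_levels: int = 16, provenance: str = ""
) -> QuantisationScheme:
    """Derive equal-width bin edges spanning the reference VOI's range.

    Edges run from min(reference) to max(reference) in ``n_levels`` equal
    steps; a constant reference has zero range and is rejected.
    """
    vals = np.asarray(reference_values, dtype=np.float64).ravel()
    if vals.size < 2 or np.unique(vals).size < 2:
        raise ValueError("reference must contain at least 2 distinct values")
    lo, hi = float(vals.min()), float(vals.max())
    edges = np.linspace(lo, hi, n_levels + 1)
    return QuantisationScheme(n_levels, edges, provenance)


def quantise_values(values: np.ndarray, scheme: QuantisationScheme) -> np.ndarray:
    """Map grey levels to integer levels 1..n_levels.

    Bins are half-open ``edges[k-1] <= v < edges[k]``; the top edge itself
    maps to the top level.  Values outside the reference range are clipped
    to the end levels, with a warning stating the out-of-range fraction —
    other patients' VOIs may legitimately exceed the reference range.
    """
    vals = np.asarray(values, dtype=np.float64)
    out_of_range = (vals < scheme.edges[0]) | (vals > scheme.edges[-1])
    if out_of_range.any():
        frac = float(out_of_range.mean())
        warnings.warn(
            f"{frac:.1%} of values fall outside the quantisation range "
            f"[{scheme.edges[0]:g}, {scheme.edges[-1]:g}]; clipping to end levels",
            stacklevel=2,
        )
    levels = np.searchsorted(scheme.edges, vals, side="right")
    return np.clip(levels, 1, scheme.n_levels).astype(np.int32)


def apply_quantisation(
    volume: CTVolume, mask: ROIMask, scheme: QuantisationScheme
) -> QuantisedVolume:
    """Quantise the in-mask voxels of a volume under a fixed scheme."""
    if volume.shape != mask.shape:
        raise ValueError(f"volume shape {volume.shape} != mask shape {mask.shape}")
    levels = np.zeros(volume.shape, dtype=np.int32)
    levels[mask.mask] = quantise_values(volume.voxels[mask.mask], scheme)
    return QuantisedVolume(levels, mask, scheme)
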