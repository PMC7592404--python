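"""End-to-end orchestration: volumes -> VOI -> quantise -> entropy ->
features -> fit/unfit comparison.

Stage order is fixed: read (optionally averaging a phase series first),
mask the apical cylinder, extract raw densities, derive the quantisation
scheme ONCE from the reference patient, quantise every VOI under that
same scheme, build entropy maps, reduce to feature records, label
patients from lung function and compare the groups.  A run manifest
(config hash, seed, library versions, scheme provenance) is written next
to the outputs so a run can be reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import compare_cohorts, correlate_with_lung_function, label_table
from .entropy import EntropyMap, compute_entropy_map
from .features import (
    FeatureRecord,
    build_feature_record,
    default_entropy_edges,
    histogram2d,
)
from .quantise import QuantisationScheme, apply_quantisation, derive_levels
from .roi import CylinderSpec, extract_roi, make_cylinder_mask
from .volumes import CTVolume, read_lung_function, read_volume

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "analyse_patient",
    "analyse_cohort",
    "run_pipeline",
    "render_maps",
]


@dataclass
class PipelineConfig:
    """File-level configuration of a pipeline run."""

    volumes_dir: str
    lung_function_csv: str
    output_dir: str
    cylinder: CylinderSpec | None = None  # None -> centred study cylinder
    reference_id: str = ""  # empty -> first patient alphabetically
    n_levels: int = 16
    density_max: float | None = None  # subregion threshold; None -> edges[4]
    entropy_max: float = 1.0
    threshold_pct: float = 50.0
    seed: int = 0

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    features: pd.DataFrame
    comparison: pd.DataFrame
    correlations: pd.DataFrame
    labels: pd.DataFrame
    scheme: QuantisationScheme
    entropy_maps: dict[str, EntropyMap] = field(default_factory=dict)


def analyse_patient(
    patient_id: str,
    volume: CTVolume,
    spec: CylinderSpec,
    scheme: QuantisationScheme,
    density_max: float | None = None,
    entropy_max: float = 1.0,
) -> tuple[FeatureRecord, EntropyMap, np.ndarray]:
    """One patient through mask -> extract -> quantise -> entropy -> features."""
    mask = make_cylinder_mask(volume, spec)
    density, _ = extract_roi(volume, mask)
    q = apply_quantisation(volume, mask, scheme)
    emap = compute_entropy_map(q)
    record = build_feature_record(
        patient_id, density, emap, scheme, density_max, entropy_max
    )
    return record, emap, density


def analyse_cohort(
    volumes: dict[str, CTVolume],
    lung_function: pd.DataFrame,
    spec: CylinderSpec,
    reference_id: str,
    n_levels: int = 16,
    density_max: float | None = None,
    entropy_max: float = 1.0,
    threshold_pct: float = 50.0,
    keep_maps: bool = False,
) -> PipelineResult:
    """Run the full analysis on in-memory volumes.

    The quantisation scheme is derived exactly once, from the reference
    patient's VOI, and applied unchanged to every other patient.
    """
    if reference_id not in volumes:
        raise ValueError(f"reference patient {reference_id!r} not in cohort")
    ref_mask = make_cylinder_mask(volumes[reference_id], spec)
    ref_values, _ = extract_roi(volumes[reference_id], ref_mask)
    scheme = derive_levels(ref_values, n_levels, provenance=reference_id)

    records = []
    maps: dict[str, EntropyMap] = {}
    for pid in sorted(volumes):
        try:
            record, emap, _ = analyse_patient(
                pid, volumes[pid], spec, scheme, density_max, entropy_max
            )
        except Exception as exc:
            raise RuntimeError(f"patient {pid}, feature stage: {exc}") from exc
        records.append(record.as_dict())
        if keep_maps:
            maps[pid] = emap
    features = pd.DataFrame(records)

    labels = label_table(lung_function, threshold_pct)
    comparison = compare_cohorts(features, labels)
    correlations = correlate_with_lung_function(features, lung_function)
    return PipelineResult(features, comparison, correlations, labels, scheme, maps)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based run: read volumes + lung function, analyse, write outputs.

    Writes features.csv, comparison.csv, correlations.csv, labels.csv,
    quantisation_scheme.json and manifest.json under ``output_dir``.
    """
    vol_dir = Path(config.volumes_dir)
    lung_function = read_lung_function(config.lung_function_csv)
    volumes: dict[str, CTVolume] = {}
    for pid in lung_function["patient_id"]:
        candidates = [vol_dir / f"{pid}.nii.gz", vol_dir / f"{pid}.nii", vol_dir / pid]
        path = next((c for c in candidates if c.exists()), None)
        if path is None:
            raise FileNotFoundError(f"patient {pid}, read stage: no volume in {vol_dir}")
        volumes[pid] = read_volume(path)

    first = next(iter(volumes.values()))
    spec = config.cylinder
    if spec is None:
        nz, ny, nx = first.shape
        dx, dy, dz = first.spacing
        spec = CylinderSpec(
            center_xy=((nx - 1) * dx / 2.0, (ny - 1) * dy / 2.0),
            top_slice=(nz - min(10, nz)) // 2,
            diameter_mm=min(40.0, (nx - 2) * dx, (ny - 2) * dy),
            n_slices=min(10, nz),
            expected_slice_thickness_mm=dz,
        )
    reference_id = config.reference_id or sorted(volumes)[0]

    result = analyse_cohort(
        volumes,
        lung_function,
        spec,
        reference_id,
        n_levels=config.n_levels,
        density_max=config.density_max,
        entropy_max=config.entropy_max,
        threshold_pct=config.threshold_pct,
    )

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.features.to_csv(out / "features.csv", index=False)
    result.comparison.to_csv(out / "comparison.csv", index=False)
    result.correlations.to_csv(out / "correlations.csv", index=False)
    result.labels.to_csv(out / "labels.csv", index=False)
    result.scheme.to_json(out / "quantisation_scheme.json")
    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "reference_id": reference_id,
        "scheme_provenance": result.scheme.provenance,
        "scheme_derivations": 1,
        "n_patients": len(result.features),
        "versions": {"lungtex": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result


def render_maps(
    emap: EntropyMap,
    output_dir: str | Path,
    density: np.ndarray | None = None,
    scheme: QuantisationScheme | None = None,
    prefix: str = "patient",
) -> list[Path]:
    """Write per-slice entropy PNGs and, when density is given, the 2-D
    density (x) vs entropy (y) histogram PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    slices = np.where(emap.scored.any(axis=(1, 2)))[0]
    display = np.where(emap.scored, emap.entropy, np.nan)
    for z in slices:
        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(display[z], vmin=0, vmax=np.log2(26), cmap="viridis")
        ax.set_title(f"{prefix} entropy, slice {z}")
        fig.colorbar(im, ax=ax, label="entropy (bits)")
        p = out / f"{prefix}_entropy_z{z:03d}.png"
        fig.savefig(p, dpi=80)
        plt.close(fig)
        written.append(p)

    if density is not None:
        density = np.asarray(density, dtype=np.float64).ravel()
        d_scored = density[emap.scored[emap.voi_mask]]
        if scheme is not None:
            d_edges = np.linspace(scheme.edges[0], scheme.edges[-1], 33)
        else:
            d_edges = np.linspace(d_scored.min(), d_scored.max() + 1e-9, 33)
        h = histogram2d(d_scored, emap.values, d_edges, default_entropy_edges(32))
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.pcolormesh(h.density_edges, h.entropy_edges, h.counts.T, cmap="magma")
        ax.set_xlabel("density (grey level)")
        ax.set_ylabel("entropy (bits)")
        ax.set_title(f"{prefix} density vs entropy")
        p = out / f"{prefix}_hist2d.png"
        fig.savefig(p, dpi=80)
        plt.close(fig)
        written.append(p)
    return written
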