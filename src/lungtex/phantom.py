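"""Synthetic apical-lung phantoms and simulated cohorts.

No real patient data ship with the package, so testing needs phantoms
that reproduce the two tissue regimes the analysis discriminates:

* healthy parenchyma — a mid-density, spatially correlated random field
  (alveoli) threaded by bright tubular vessels, so neighbouring voxels
  differ and local co-occurrence entropy is high;
* emphysema — Poisson-placed spherical bullae that overwrite tissue
  with a near-air grey level and very little internal spread, giving
  dark, homogeneous, hence low-entropy regions.

A single severity parameter s in [0, 1] is the bulla volume fraction;
it also drives a noisy monotone-decreasing mapping to FEV1 and TLCO
% predicted, so simulated cohorts can be labelled fit/unfit exactly as
real ones.  Each phantom represents the apical VOI itself (a grid a
little larger than the 4 cm x 2.5 cm cylinder); apex localisation is
not simulated.

Default grey levels (healthy mean 250, bulla 60) are arbitrary-offset
scanner units, chosen so a ~35 % bulla fraction pulls the VOI mean into
the low 190s, as severe emphysema does on this scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .roi import CylinderSpec
from .volumes import CTVolume

__all__ = [
    "PhantomParams",
    "LungFunctionMapping",
    "CohortSimParams",
    "PatientSim",
    "SimulatedCohort",
    "generate_phantom",
    "severity_to_lungfunction",
    "generate_cohort",
    "default_cylinder_spec",
]


@dataclass
class PhantomParams:
    """Parameters of one synthetic apical VOI volume.

    shape is (slices, rows, cols); spacing is (dx, dy, dz) in mm.
    severity is the target bulla volume fraction.
    """

    shape: tuple[int, int, int] = (12, 44, 44)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.5)
    severity: float = 0.0
    base_density: float = 250.0  # healthy parenchyma mean grey level
    texture_spread: float = 40.0  # parenchyma field std dev
    correlation_mm: float = 1.5  # Gaussian smoothing length of the field
    vessel_density: float = 0.25  # tubular structures per cm^3
    vessel_brightness: float = 120.0
    vessel_radius_mm: tuple[float, float] = (0.7, 1.4)
    bulla_value: float = 60.0  # near-air grey level
    bulla_radius_mm: tuple[float, float] = (2.0, 6.0)
    bulla_interior_noise: float = 6.0  # << texture_spread
    noise: float = 5.0  # additive acquisition noise
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")
        if self.bulla_interior_noise >= self.texture_spread:
            raise ValueError("bulla interior noise must be < parenchyma spread")
        if self.bulla_value >= self.base_density:
            raise ValueError("bulla grey level must be below parenchyma mean")


@dataclass
class LungFunctionMapping:
    """Noisy monotone severity -> (FEV1, TLCO) % predicted.

    fev1 = clamp(fev1_intercept - fev1_slope * s + eps, 10, 130), and
    likewise for TLCO with independent noise.  Defaults put a severity-0
    subject near a typical fit cohort's means (FEV1 ~85 %, TLCO ~74 %)
    and severe emphysema near the unfit means.
    """

    fev1_intercept: float = 88.0
    fev1_slope: float = 80.0
    tlco_intercept: float = 76.0
    tlco_slope: float = 85.0
    noise_sd: float = 6.0
    lo: float = 10.0
    hi: float = 130.0


@dataclass
class CohortSimParams:
    """A simulated cohort: 29 fit low-severity and 32 unfit high-severity
    patients, severities uniform within each group's range."""

    n_fit: int = 29
    n_unfit: int = 32
    fit_severity_range: tuple[float, float] = (0.0, 0.12)
    unfit_severity_range: tuple[float, float] = (0.35, 0.60)
    phantom: PhantomParams = field(default_factory=PhantomParams)
    mapping: LungFunctionMapping = field(default_factory=LungFunctionMapping)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fit < 2 or self.n_unfit < 2:
            raise ValueError("group sizes must be >= 2")


@dataclass
class PatientSim:
    patient_id: str
    volume: CTVolume
    bulla_mask: np.ndarray
    severity: float
    intended_group: str  # "fit" | "unfit" by simulation design


@dataclass
class SimulatedCohort:
    patients: list[PatientSim]
    lung_function: pd.DataFrame
    reference_id: str  # severity-0 subject used to fix quantisation levels

    def truth(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [p.patient_id for p in self.patients],
                "severity": [p.severity for p in self.patients],
                "intended_group": [p.intended_group for p in self.patients],
            }
        )


def default_cylinder_spec(params: PhantomParams) -> CylinderSpec:
    """The protocol cylinder centred in the phantom: 40 mm circle, 10 slices."""
    nz, ny, nx = params.shape
    dx, dy, dz = params.spacing
    center = ((nx - 1) * dx / 2.0, (ny - 1) * dy / 2.0)
    n_slices = min(10, nz)
    top = (nz - n_slices) // 2
    diameter = min(40.0, (nx - 2) * dx, (ny - 2) * dy)
    return CylinderSpec(
        center_xy=center,
        top_slice=top,
        diameter_mm=diameter,
        n_slices=n_slices,
        expected_slice_thickness_mm=dz,
    )


def generate_phantom(params: PhantomParams) -> tuple[CTVolume, np.ndarray]:
    """Generate one phantom volume and its ground-truth bulla mask.

    Construction: correlated Gaussian parenchyma field + bright vessel
    tubes, then spheres of near-air tissue placed at random until the
    bulla volume fraction reaches the severity target, then additive
    acquisition noise.  Deterministic given the seed.
    """
    rng = np.random.default_rng(params.seed)
    nz, ny, nx = params.shape
    dx, dy, dz = params.spacing

    # parenchyma: smoothed white noise rescaled to (base_density, texture_spread)
    white = rng.standard_normal(params.shape)
    sigma_vox = (
        params.correlation_mm / dz,
        params.correlation_mm / dy,
        params.correlation_mm / dx,
    )
    fld = gaussian_filter(white, sigma=sigma_vox, mode="nearest")
    fld_std = fld.std()
    if fld_std > 0:
        fld = fld / fld_std
    voxels = params.base_density + params.texture_spread * fld

    # physical voxel-centre coordinates (z, y, x) in mm
    zc = np.arange(nz) * dz
    yc = np.arange(ny) * dy
    xc = np.arange(nx) * dx
    Z, Y, X = np.meshgrid(zc, yc, xc, indexing="ij")

    # bright tubular vessels: Gaussian-profile infinite lines
    volume_cm3 = (nz * dz) * (ny * dy) * (nx * dx) / 1000.0
    n_vessels = rng.poisson(params.vessel_density * volume_cm3)
    for _ in range(n_vessels):
        point = np.array(
            [rng.uniform(0, nz * dz), rng.uniform(0, ny * dy), rng.uniform(0, nx * dx)]
        )
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        radius = rng.uniform(*params.vessel_radius_mm)
        rel = np.stack([Z - point[0], Y - point[1], X - point[2]], axis=-1)
        t = rel @ direction
        d2 = (rel**2).sum(axis=-1) - t**2
        voxels += params.vessel_brightness * np.exp(-np.maximum(d2, 0.0) / (2 * radius**2))

    # bullae: spheres of homogeneous near-air tissue until fraction >= severity
    bulla_mask = np.zeros(params.shape, dtype=bool)
    target_voxels = params.severity * bulla_mask.size
    attempts = 0
    while bulla_mask.sum() < target_voxels:
        attempts += 1
        if attempts > 5000:
            raise ValueError(
                f"bulla volume fraction {params.severity} unreachable in shape "
                f"{params.shape} after {attempts - 1} placements"
            )
        centre = np.array(
            [rng.uniform(0, nz * dz), rng.uniform(0, ny * dy), rng.uniform(0, nx * dx)]
        )
        radius = rng.uniform(*params.bulla_radius_mm)
        sphere = (Z - centre[0]) ** 2 + (Y - centre[1]) ** 2 + (
            X - centre[2]
        ) ** 2 <= radius**2
        bulla_mask |= sphere
    if bulla_mask.any():
        voxels[bulla_mask] = params.bulla_value + rng.normal(
            0.0, params.bulla_interior_noise, size=int(bulla_mask.sum())
        )

    voxels += rng.normal(0.0, params.noise, size=params.shape)
    return CTVolume(voxels, params.spacing), bulla_mask


def severity_to_lungfunction(
    severity: float,
    mapping: LungFunctionMapping | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Draw (FEV1 %, TLCO %) for a given emphysema severity."""
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    mapping = mapping or LungFunctionMapping()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    eps_f, eps_t = rng.normal(0.0, mapping.noise_sd, size=2)
    fev1 = np.clip(
        mapping.fev1_intercept - mapping.fev1_slope * severity + eps_f,
        mapping.lo,
        mapping.hi,
    )
    tlco = np.clip(
        mapping.tlco_intercept - mapping.tlco_slope * severity + eps_t,
        mapping.lo,
        mapping.hi,
    )
    return float(fev1), float(tlco)


def generate_cohort(params: CohortSimParams) -> SimulatedCohort:
    """Simulate a full cohort of phantoms with lung-function records.

    Patient 1 is the reference subject: severity forced to 0 (healthy,
    analogous to a fit non-smoker) and flagged as the VOI whose
    grey-level range fixes the quantisation scheme for everyone.
    """
    rng = np.random.default_rng(params.seed)
    severities: list[tuple[float, str]] = []
    for _ in range(params.n_fit):
        severities.append((rng.uniform(*params.fit_severity_range), "fit"))
    for _ in range(params.n_unfit):
        severities.append((rng.uniform(*params.unfit_severity_range), "unfit"))
    severities[0] = (0.0, "fit")  # reference subject

    patients: list[PatientSim] = []
    lf_rows = []
    for i, (s, group) in enumerate(severities, start=1):
        pid = f"P{i:03d}"
        # independent, reproducible per-patient seed (stay below 2**31)
        pseed = int(rng.integers(0, 2**31 - 1))
        vol, bmask = generate_phantom(replace(params.phantom, severity=s, seed=pseed))
        fev1, tlco = severity_to_lungfunction(s, params.mapping, rng)
        patients.append(PatientSim(pid, vol, bmask, s, group))
        lf_rows.append({"patient_id": pid, "fev1_pct": fev1, "tlco_pct": tlco})
    return SimulatedCohort(patients, pd.DataFrame(lf_rows), patients[0].patient_id)
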