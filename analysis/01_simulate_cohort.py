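"""Simulate a full cohort: 29 fit and 32 unfit apical-VOI phantoms.

Writes per-patient NIfTI volumes and ground-truth bulla masks under
scratch/cohort/ (large, regenerable), and lung_function.csv plus
truth.json under results/.

Run from the repository root:  python analysis/01_simulate_cohort.py [--seed 1]
"""

import argparse
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from lungtex import CohortSimParams, default_cylinder_spec, generate_cohort, write_lung_function, write_volume

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    params = CohortSimParams(seed=args.seed)
    sim = generate_cohort(params)

    vol_dir = ROOT / "scratch" / "cohort" / "volumes"
    mask_dir = ROOT / "scratch" / "cohort" / "bulla_masks"
    vol_dir.mkdir(parents=True, exist_ok=True)
    mask_dir.mkdir(parents=True, exist_ok=True)
    for p in sim.patients:
        write_volume(p.volume, vol_dir / f"{p.patient_id}.nii.gz")
        affine = np.diag(list(p.volume.spacing) + [1.0])
        nib.save(
            nib.Nifti1Image(p.bulla_mask.T.astype(np.uint8), affine),
            str(mask_dir / f"{p.patient_id}_bullae.nii.gz"),
        )

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    write_lung_function(sim.lung_function, out / "lung_function.csv")
    truth = {
        "seed": args.seed,
        "reference_id": sim.reference_id,
        "cylinder": vars(default_cylinder_spec(params.phantom)),
        "patients": sim.truth().to_dict(orient="records"),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, default=str))

    sev = sim.truth()["severity"]
    print(f"simulated {len(sim.patients)} patients "
          f"({sum(1 for p in sim.patients if p.intended_group == 'fit')} fit / "
          f"{sum(1 for p in sim.patients if p.intended_group == 'unfit')} unfit)")
    print(f"severity range {sev.min():.3f}-{sev.max():.3f}; "
          f"reference subject {sim.reference_id} (severity 0)")
    print(f"volumes -> {vol_dir}")


if __name__ == "__main__":
    main()
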