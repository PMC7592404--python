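"""Render texture maps: per-slice entropy images and the 2-D
density-entropy histogram for one healthy and one emphysematous patient.

Writes PNGs under results/maps/.  Bullae appear as dark, low-entropy
patches; healthy parenchyma is bright and disordered.

Run from the repository root:  python analysis/04_render_maps.py
"""

import json
import warnings
from pathlib import Path

import pandas as pd

from lungtex import (
    CylinderSpec,
    QuantisationScheme,
    analyse_patient,
    read_volume,
    render_maps,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    truth = json.loads((ROOT / "results" / "truth.json").read_text())
    sev = pd.DataFrame(truth["patients"]).set_index("patient_id")["severity"]
    picks = {"healthy": sev.idxmin(), "emphysema": sev.idxmax()}

    cyl = truth["cylinder"]
    spec = CylinderSpec(
        center_xy=tuple(cyl["center_xy"]),
        top_slice=int(cyl["top_slice"]),
        diameter_mm=float(cyl["diameter_mm"]),
        n_slices=int(cyl["n_slices"]),
        expected_slice_thickness_mm=float(cyl["expected_slice_thickness_mm"]),
    )
    scheme = QuantisationScheme.from_json(
        ROOT / "results" / "pipeline" / "quantisation_scheme.json"
    )
    out = ROOT / "results" / "maps"
    for tag, pid in picks.items():
        volume = read_volume(ROOT / "scratch" / "cohort" / "volumes" / f"{pid}.nii.gz")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            record, emap, density = analyse_patient(pid, volume, spec, scheme)
        written = render_maps(emap, out, density=density, scheme=scheme,
                              prefix=f"{tag}_{pid}")
        print(f"{tag} {pid} (severity {sev[pid]:.2f}): mean density "
              f"{record.density_mean:.1f}, median entropy {record.entropy_median:.2f} "
              f"bits; {len(written)} images -> {out}")


if __name__ == "__main__":
    main()
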