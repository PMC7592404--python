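"""Compare fit vs unfit feature distributions and correlate with lung function.

Reads results/pipeline/ from 02_extract_features.py and prints the
per-feature two-sided Mann-Whitney table (written by the pipeline as
comparison.csv) plus Spearman correlations against FEV1 and TLCO.

Run from the repository root:  python analysis/03_compare_cohorts.py
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
HEADLINE = ["density_mean", "density_median", "entropy_mean", "entropy_median",
            "subregion_count"]


def main() -> None:
    out = ROOT / "results" / "pipeline"
    comparison = pd.read_csv(out / "comparison.csv").set_index("feature")
    correlations = pd.read_csv(out / "correlations.csv").set_index("feature")

    print("fit vs unfit, two-sided Mann-Whitney (raw p; Holm alongside):")
    cols = ["fit_mean", "unfit_mean", "U", "p_value", "p_holm"]
    print(comparison.loc[HEADLINE, cols].to_string(float_format=lambda v: f"{v:.4g}"))
    sig = comparison[comparison["p_value"] < 0.05].index.tolist()
    print(f"\nfeatures with p < 0.05: {', '.join(sig) if sig else 'none'}")

    print("\nSpearman correlation with lung function:")
    print(correlations.loc[HEADLINE, ["rho_fev1", "rho_tlco"]]
          .to_string(float_format=lambda v: f"{v:.3f}"))


if __name__ == "__main__":
    main()
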