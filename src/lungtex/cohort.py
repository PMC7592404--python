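"""Fitness labelling, cohort comparison and lung-function correlation.

A patient is *fit* for radical radiotherapy when both FEV1 and TLCO are
at least 50 % of predicted; *unfit* when either falls below.  Feature
distributions are skewed, so groups are compared with the two-sided
Mann–Whitney U test and correlations use Spearman ranks.  Raw p-values
are the headline output (one pre-specified texture feature, so no
correction is assumed); a Holm-adjusted column is emitted alongside for
transparency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .features import FEATURE_COLUMNS

__all__ = [
    "FitnessLabel",
    "label_fitness",
    "label_table",
    "mann_whitney_u",
    "correlate",
    "compare_cohorts",
    "correlate_with_lung_function",
]

EXACT_MAX_N = 12  # pooled size up to which the exact null distribution is used


@dataclass
class FitnessLabel:
    patient_id: str
    label: str  # "fit" | "unfit"
    threshold_pct: float = 50.0


def label_fitness(
    patient_id: str, fev1_pct: float, tlco_pct: float, threshold_pct: float = 50.0
) -> FitnessLabel:
    """Fit iff BOTH lung-function values are >= the threshold (default 50 %)."""
    fit = fev1_pct >= threshold_pct and tlco_pct >= threshold_pct
    return FitnessLabel(patient_id, "fit" if fit else "unfit", threshold_pct)


def label_table(lung_function: pd.DataFrame, threshold_pct: float = 50.0) -> pd.DataFrame:
    """Label every row of a lung-function table; returns patient_id + label."""
    labels = [
        label_fitness(r.patient_id, r.fev1_pct, r.tlco_pct, threshold_pct).label
        for r in lung_function.itertuples()
    ]
    return pd.DataFrame(
        {"patient_id": lung_function["patient_id"].to_numpy(), "label": labels}
    )


def mann_whitney_u(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns (U of sample a, p).

    The exact null distribution is used for small pooled samples
    (n_a + n_b <= 12) without ties; otherwise the normal approximation
    with midrank tie-corrected variance and continuity correction.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= EXACT_MAX_N and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


def correlate(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with midrank ties; NaN (with a warning)
    when either input is constant."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("correlation requires at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("rank correlation undefined for a constant input", stacklevel=2)
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def compare_cohorts(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    feature_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Per-feature fit-vs-unfit Mann–Whitney comparison.

    ``features`` holds one row per patient (``patient_id`` + feature
    columns); ``labels`` maps patient_id -> fit/unfit.  Returns one row
    per feature with U, raw two-sided p, Holm-adjusted p, group means
    and medians and group sizes.
    """
    feature_columns = feature_columns or [
        c for c in FEATURE_COLUMNS if c in features.columns
    ]
    merged = features.merge(labels, on="patient_id", how="left", validate="1:1")
    if merged["label"].isna().any():
        missing = merged.loc[merged["label"].isna(), "patient_id"].tolist()
        raise ValueError(f"no fitness label for patient(s) {missing}")
    fit = merged[merged["label"] == "fit"]
    unfit = merged[merged["label"] == "unfit"]
    if len(fit) == 0 or len(unfit) == 0:
        raise ValueError(
            f"both groups must be non-empty (fit={len(fit)}, unfit={len(unfit)})"
        )
    rows = []
    for col in feature_columns:
        u, p = mann_whitney_u(fit[col].to_numpy(), unfit[col].to_numpy())
        rows.append(
            {
                "feature": col,
                "U": u,
                "p_value": p,
                "fit_mean": float(fit[col].mean()),
                "fit_median": float(fit[col].median()),
                "unfit_mean": float(unfit[col].mean()),
                "unfit_median": float(unfit[col].median()),
                "n_fit": len(fit),
                "n_unfit": len(unfit),
            }
        )
    out = pd.DataFrame(rows)
    out.insert(3, "p_holm", multipletests(out["p_value"].to_numpy(), method="holm")[1])
    return out


def correlate_with_lung_function(
    features: pd.DataFrame,
    lung_function: pd.DataFrame,
    feature_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Spearman correlation of each feature with FEV1 and TLCO % predicted."""
    feature_columns = feature_columns or [
        c for c in FEATURE_COLUMNS if c in features.columns
    ]
    merged = features.merge(lung_function, on="patient_id", how="inner", validate="1:1")
    rows = []
    for col in feature_columns:
        rows.append(
            {
                "feature": col,
                "rho_fev1": correlate(merged[col], merged["fev1_pct"]),
                "rho_tlco": correlate(merged[col], merged["tlco_pct"]),
                "n": len(merged),
            }
        )
    return pd.DataFrame(rows)
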