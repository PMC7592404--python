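"""Fitness labelling, Mann-Whitney, Spearman, cohort comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lungtex import (
    compare_cohorts,
    correlate,
    correlate_with_lung_function,
    label_fitness,
    label_table,
    mann_whitney_u,
)


def enumeration_p(a, b):
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    mu = n_a * len(b) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        u = ranks[list(combo)].sum() - n_a * (n_a + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestLabelFitness:
    @pytest.mark.parametrize(
        "fev1,tlco,expected",
        [
            (85, 74, "fit"),      # study fit-group means
            (53, 43, "unfit"),    # study unfit-group means
            (50, 50, "fit"),      # boundary: "50% predicted value or greater"
            (110, 29, "unfit"),   # good FEV1 cannot rescue a failing TLCO
            (27, 71, "unfit"),
        ],
    )
    def test_both_values_must_reach_threshold(self, fev1, tlco, expected):
        assert label_fitness("p", fev1, tlco).label == expected

    def test_monotone_in_lung_function(self, rng):
        for _ in range(50):
            fev1, tlco = rng.uniform(10, 130, 2)
            base = label_fitness("p", fev1, tlco).label
            better = label_fitness("p", fev1 + rng.uniform(0, 40), tlco).label
            if base == "fit":
                assert better == "fit"

    def test_alternative_threshold(self):
        assert label_fitness("p", 55, 55, threshold_pct=60).label == "unfit"


class TestMannWhitney:
    def test_exact_p_for_fully_separated_triples(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)
        assert p == pytest.approx(enumeration_p([1, 2, 3], [4, 5, 6]), abs=1e-12)

    def test_identical_samples_give_p_one(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_matches_hand_normal_approximation_at_study_sizes(self, rng):
        """At n=29 vs 32 the implementation must agree to 1e-6 with an
        independently coded tie-corrected normal approximation with
        continuity correction."""
        for _ in range(20):
            a = rng.normal(0, 1, 29)
            b = rng.normal(0.4, 1.2, 32)
            u_impl, p_impl = mann_whitney_u(a, b)
            pooled = np.concatenate([a, b])
            ranks = stats.rankdata(pooled)
            n1, n2 = 29, 32
            u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
            assert u_impl == pytest.approx(u, abs=1e-9)
            mu = n1 * n2 / 2
            n = n1 + n2
            _, t = np.unique(pooled, return_counts=True)
            tie_term = ((t**3 - t).sum()) / (n * (n - 1))
            sigma = np.sqrt(n1 * n2 / 12 * ((n + 1) - tie_term))
            z = (abs(u - mu) - 0.5) / sigma
            p_hand = 2 * stats.norm.sf(z)
            assert p_impl == pytest.approx(p_hand, abs=1e-6)

    def test_symmetry_and_u_complement(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.5, 1, 18)
        u_ab, p_ab = mann_whitney_u(a, b)
        u_ba, p_ba = mann_whitney_u(b, a)
        assert p_ab == pytest.approx(p_ba, abs=1e-12)
        assert u_ab + u_ba == 15 * 18  # no ties in continuous draws

    def test_invariant_under_monotone_transform(self, rng):
        a = rng.uniform(1, 2, 12)
        b = rng.uniform(1.2, 2.5, 14)
        _, p = mann_whitney_u(a, b)
        _, p_t = mann_whitney_u(np.exp(a), np.exp(b))
        assert p_t == pytest.approx(p, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1.0])


class TestSpearman:
    def test_monotone_data_gives_plus_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert correlate(x, np.exp(x)) == pytest.approx(1.0)
        assert correlate(x, -(x**3)) == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        x = rng.normal(0, 1, 100)
        y = 0.5 * x + rng.normal(0, 1, 100)
        rho = correlate(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-10)

    def test_constant_input_flagged_as_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


def _feature_frame(fit_vals, unfit_vals):
    n = len(fit_vals) + len(unfit_vals)
    ids = [f"P{i:03d}" for i in range(n)]
    features = pd.DataFrame(
        {"patient_id": ids, "density_mean": np.concatenate([fit_vals, unfit_vals])}
    )
    labels = pd.DataFrame(
        {"patient_id": ids, "label": ["fit"] * len(fit_vals) + ["unfit"] * len(unfit_vals)}
    )
    return features, labels


class TestCompareCohorts:
    def test_null_calibration_over_200_replicates(self):
        rng = np.random.default_rng(42)
        rejections = 0
        for _ in range(200):
            features, labels = _feature_frame(rng.normal(0, 1, 29), rng.normal(0, 1, 32))
            out = compare_cohorts(features, labels, ["density_mean"])
            if out["p_value"].iloc[0] < 0.05:
                rejections += 1
        assert rejections <= 20  # ~5% expected under the null

    def test_separated_groups_detected(self, rng):
        features, labels = _feature_frame(rng.normal(3, 1, 29), rng.normal(0, 1, 32))
        out = compare_cohorts(features, labels, ["density_mean"])
        assert out["p_value"].iloc[0] < 1e-6
        assert out["fit_mean"].iloc[0] > out["unfit_mean"].iloc[0]
        assert out["n_fit"].iloc[0] == 29 and out["n_unfit"].iloc[0] == 32

    def test_single_class_cohort_rejected(self, rng):
        features, labels = _feature_frame(rng.normal(0, 1, 10), rng.normal(0, 1, 0))
        with pytest.raises(ValueError, match="non-empty"):
            compare_cohorts(features, labels, ["density_mean"])

    def test_missing_label_rejected(self, rng):
        features, labels = _feature_frame(rng.normal(0, 1, 5), rng.normal(0, 1, 5))
        labels = labels.iloc[:-1]
        with pytest.raises(ValueError, match="label"):
            compare_cohorts(features, labels, ["density_mean"])

    def test_holm_adjustment_never_below_raw_p(self, rng):
        ids = [f"P{i}" for i in range(20)]
        features = pd.DataFrame(
            {
                "patient_id": ids,
                "density_mean": rng.normal(0, 1, 20),
                "entropy_median": rng.normal(0, 1, 20),
            }
        )
        labels = pd.DataFrame({"patient_id": ids, "label": ["fit"] * 10 + ["unfit"] * 10})
        out = compare_cohorts(features, labels)
        assert (out["p_holm"] >= out["p_value"] - 1e-15).all()


class TestLungFunctionLabelsAndCorrelations:
    def test_label_table_applies_rule_rowwise(self):
        lf = pd.DataFrame(
            {
                "patient_id": ["A", "B", "C"],
                "fev1_pct": [85.0, 49.0, 60.0],
                "tlco_pct": [74.0, 80.0, 45.0],
            }
        )
        out = label_table(lf)
        assert out["label"].tolist() == ["fit", "unfit", "unfit"]

    def test_feature_lung_function_correlation_recovers_monotone_link(self, rng):
        n = 40
        sev = rng.uniform(0, 1, n)
        lf = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "fev1_pct": 90 - 60 * sev + rng.normal(0, 2, n),
                "tlco_pct": 80 - 55 * sev + rng.normal(0, 2, n),
            }
        )
        features = pd.DataFrame(
            {"patient_id": [f"P{i}" for i in range(n)], "density_mean": 250 - 180 * sev}
        )
        out = correlate_with_lung_function(features, lf, ["density_mean"])
        assert out["rho_fev1"].iloc[0] > 0.9
        assert out["rho_tlco"].iloc[0] > 0.9
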