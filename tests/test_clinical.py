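"""EDSS linkage, the progression rule, MI / R-squared and group summaries."""

import numpy as np
import pandas as pd
import pytest
from sklearn.feature_selection import mutual_info_regression

from mepmorph import (
    edss_distribution_summary,
    link_edss,
    mutual_information,
    progression_auc,
    progression_label,
    r_squared,
    select_t1,
)
from mepmorph.clinical import bivariate_r_squared


def _visits(rows):
    return pd.DataFrame(rows, columns=["visit_id", "patient_id", "date"])


def _records(rows):
    return pd.DataFrame(rows, columns=["patient_id", "date", "edss"])


class TestLinkEdss:
    def test_record_11_months_after_is_linked(self):
        visits = _visits([("v1", "p1", "2020-01-01")])
        records = _records([("p1", "2020-12-01", 3.0)])
        assert link_edss(visits, records) == {"v1": 3.0}

    def test_only_in_window_record_chosen(self):
        visits = _visits([("v1", "p1", "2020-01-01")])
        records = _records([("p1", "2018-11-01", 5.0), ("p1", "2020-03-01", 2.5)])
        assert link_edss(visits, records) == {"v1": 2.5}

    def test_equidistant_tie_goes_to_earlier_record(self):
        visits = _visits([("v1", "p1", "2020-07-01")])
        records = _records([("p1", "2020-01-01", 1.5), ("p1", "2020-12-30", 4.0)])
        # 182 days before vs 182 days after
        assert link_edss(visits, records) == {"v1": 1.5}

    def test_no_record_in_window_excludes_visit(self):
        visits = _visits([("v1", "p1", "2020-01-01")])
        records = _records([("p1", "2023-01-01", 6.0)])
        assert link_edss(visits, records) == {}

    def test_never_links_outside_window(self):
        rng = np.random.default_rng(0)
        base = pd.Timestamp("2019-01-01")
        visits = _visits([(f"v{i}", "p1", str((base + pd.Timedelta(days=int(d))).date()))
                          for i, d in enumerate(rng.integers(0, 2000, 30))])
        records = _records([("p1", str((base + pd.Timedelta(days=int(d))).date()), 3.0)
                            for d in rng.integers(0, 2000, 30)])
        linked = link_edss(visits, records)
        rec_dates = pd.to_datetime(records["date"])
        for _, v in visits.iterrows():
            if v["visit_id"] in linked:
                dt = (rec_dates - pd.Timestamp(v["date"])).dt.days.abs().min()
                assert dt <= 365.25


class TestProgressionRule:
    @pytest.mark.parametrize(
        "t0,t1,expected",
        [(4.0, 5.0, 1), (5.5, 6.0, 0), (6.0, 6.5, 1), (2.0, 2.5, 0), (7.0, 7.0, 0)],
    )
    def test_worked_examples(self, t0, t1, expected):
        assert progression_label(t0, t1) == expected

    def test_exhaustive_truth_table(self):
        """All 441 half-step EDSS pairs against an independent evaluation
        of the rule."""
        grid = np.arange(0.0, 10.5, 0.5)
        n_checked = 0
        for t0 in grid:
            for t1 in grid:
                expected = int(t1 - t0 >= (1.0 if t0 <= 5.5 else 0.5))
                assert progression_label(t0, t1) == expected
                n_checked += 1
        assert n_checked == 441

    def test_off_grid_values_rejected(self):
        with pytest.raises(ValueError, match="half-step"):
            progression_label(4.25, 5.0)
        with pytest.raises(ValueError, match="half-step"):
            progression_label(4.0, 11.0)

    def test_t1_selector_closest_to_two_years(self):
        records = _records(
            [("p1", "2021-09-01", 4.0), ("p1", "2022-02-01", 5.0), ("p1", "2022-11-01", 6.0)]
        )
        edss, dt = select_t1(records, "2020-01-01")
        assert edss == 5.0  # 2.08 years out, closest to the 2-year mark
        assert 1.5 <= dt <= 3.0

    def test_t1_selector_ignores_records_outside_window(self):
        records = _records([("p1", "2020-06-01", 4.0), ("p1", "2024-01-01", 8.0)])
        assert select_t1(records, "2020-01-01") is None


class TestMutualInformation:
    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(42)
        assert mutual_information(rng.standard_normal(5000), rng.standard_normal(5000)) <= 0.02

    def test_identity_is_large(self):
        x = np.random.default_rng(1).standard_normal(5000)
        assert mutual_information(x, x) >= 2.0

    def test_quadratic_dependence_seen_by_mi_not_r2(self):
        """y = x^2 with symmetric x: linear R2 ~ 0 but MI is large —
        the reason to report MI alongside R2."""
        x = np.random.default_rng(3).uniform(-1, 1, 5000)
        y = x**2
        assert r_squared(x, y) <= 0.05
        assert mutual_information(x, y) >= 0.5

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(400)
        y = 0.5 * x + rng.standard_normal(400)
        assert abs(mutual_information(x, y) - mutual_information(y, x)) <= 1e-9

    def test_agrees_with_sklearn_ksg(self):
        """Same estimator family as scikit-learn's regression MI."""
        rng = np.random.default_rng(5)
        x = rng.standard_normal(2000)
        y = x + rng.standard_normal(2000)
        ours = mutual_information(x, y, k=3)
        theirs = float(
            mutual_info_regression(x[:, None], y, n_neighbors=3, random_state=0)[0]
        )
        assert ours == pytest.approx(theirs, abs=0.1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            mutual_information(np.zeros(100), np.zeros(99))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 50"):
            mutual_information(np.arange(10), np.arange(10))


class TestRSquared:
    def test_exact_linear_relation(self):
        x = np.linspace(0, 1, 100)
        assert r_squared(x, 2 * x + 1) == pytest.approx(1.0, abs=1e-12)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(0)
        assert r_squared(rng.standard_normal(5000), rng.standard_normal(5000)) <= 0.01

    def test_equal_signal_and_noise_variance_gives_half(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(5000)
        y = x + rng.standard_normal(5000)
        assert 0.45 <= r_squared(x, y) <= 0.55

    def test_bivariate_fit(self):
        rng = np.random.default_rng(2)
        x1, x2 = rng.standard_normal((2, 2000))
        y = 0.8 * x1 - 0.5 * x2 + 0.3 * rng.standard_normal(2000)
        r2 = bivariate_r_squared(np.column_stack([x1, x2]), y)
        assert r2 > 0.85

    def test_zero_variance_target_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            r_squared(np.arange(10.0), np.ones(10))


class TestEdssSummary:
    def test_single_group_reports_own_mean(self):
        out = edss_distribution_summary([0.1, 0.2, 0.3], [2.0, 2.0, 2.0])
        assert len(out) == 1
        assert out.loc[0, "mean"] == pytest.approx(0.2)
        assert out.loc[0, "n"] == 3

    def test_high_edss_rows_excluded(self):
        out = edss_distribution_summary([0.1, 0.9, 0.5], [2.0, 8.0, 3.0])
        assert 8.0 not in set(out["edss"])
        assert out["n"].sum() == 2

    def test_group_means_track_severity_in_cohort(self, cohort120):
        """Foot-trace ApEn rises with the EDSS bin on synthetic data."""
        from mepmorph import ApEnParams, apen

        truth = cohort120.truth
        foot = truth[(truth["limb"] == "AH") & (truth["artifact"] == "")]
        edss0 = cohort120.patients.set_index("patient_id")["edss_t0"]
        params = ApEnParams()
        scores, levels = [], []
        for _, row in foot.iterrows():
            scores.append(apen(cohort120.trace_by_id(row["trace_id"]).samples, params).normalized)
            levels.append(edss0[row["patient_id"]])
        out = edss_distribution_summary(scores, levels)
        coarse = {
            "low": out[out["edss"] <= 2]["mean"].mean(),
            "mid": out[(out["edss"] >= 3) & (out["edss"] <= 4)]["mean"].mean(),
            "high": out[(out["edss"] >= 5) & (out["edss"] <= 6)]["mean"].mean(),
        }
        assert coarse["low"] <= coarse["mid"] <= coarse["high"]


class TestProgressionAuc:
    def test_outcome_identical_feature_is_perfect(self):
        y = np.array([0, 1] * 20)
        assert progression_auc(y.astype(float), y) == 1.0

    def test_independent_feature_near_half(self):
        rng = np.random.default_rng(0)
        auc = progression_auc(rng.uniform(size=2000), rng.integers(0, 2, 2000))
        assert abs(auc - 0.5) <= 0.04

    def test_foot_apen_beats_hand_apen_for_progression(self):
        """Progression is driven by foot abnormality in the generator, so
        foot ApEn must be the better predictor."""
        from mepmorph import ApEnParams, apen, generate_cohort

        co = generate_cohort(150, rng_seed=31)
        params = ApEnParams()
        truth = co.truth[co.truth["artifact"] == ""]
        apen_by_trace = {
            row["trace_id"]: apen(co.trace_by_id(row["trace_id"]).samples, params).normalized
            for _, row in truth.iterrows()
        }
        df = truth.assign(apen=[apen_by_trace[t] for t in truth["trace_id"]])
        per_patient = df.pivot_table(index="patient_id", columns="limb", values="apen")
        merged = per_patient.join(co.patients.set_index("patient_id")["progressed"]).dropna()
        auc_foot = progression_auc(merged["AH"], merged["progressed"].astype(int))
        auc_hand = progression_auc(merged["APB"], merged["progressed"].astype(int))
        assert auc_foot > auc_hand

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both outcome classes"):
            progression_auc([0.1, 0.2], [1, 1])
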