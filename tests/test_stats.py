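"""Cohort statistics: Mann-Whitney, ROC, dose equivalents, drug screen."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cfbrain import stats


def mw_enumeration_p(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration of labelings."""
    x, y = list(x), list(y)
    pooled, n1 = x + y, len(x)

    def u_of(xs, ys):
        return sum(
            1.0 if a > b else (0.5 if a == b else 0.0) for a in xs for b in ys
        )

    mu = n1 * len(y) / 2
    obs = abs(u_of(x, y) - mu)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        total += 1
        if abs(u_of(xs, ys) - mu) >= obs - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        res = stats.mann_whitney([1, 2, 3], [4, 5, 6])
        assert res["U"] == 0.0
        assert res["p"] == pytest.approx(0.1)  # 2/20 labelings as extreme
        assert res["method"] == "exact"

    def test_identical_samples_give_p_one(self):
        res = stats.mann_whitney([1, 2, 3], [1, 2, 3])
        assert res["p"] == pytest.approx(1.0)

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(0)
        for n1, n2 in [(2, 3), (4, 4), (5, 3), (6, 6)]:
            x = rng.normal(size=n1)
            y = rng.normal(0.5, size=n2)
            res = stats.mann_whitney(x, y)
            assert res["method"] == "exact"
            assert res["p"] == pytest.approx(mw_enumeration_p(x, y), abs=1e-12)

    def test_ties_or_large_samples_use_asymptotic(self):
        rng = np.random.default_rng(1)
        assert stats.mann_whitney([1, 1, 2], [2, 3, 3])["method"] == "asymptotic"
        big = stats.mann_whitney(rng.normal(size=25), rng.normal(size=25))
        assert big["method"] == "asymptotic"

    def test_nan_dropped_empty_group_raises(self):
        res = stats.mann_whitney([1.0, np.nan, 2.0], [3.0, 4.0])
        assert res["n_x"] == 2
        with pytest.raises(ValueError):
            stats.mann_whitney([np.nan], [1.0])


class TestRoc:
    def test_perfect_separation(self):
        r = stats.roc([1, 2, 10, 20], [False, False, True, True])
        assert r.auc == pytest.approx(1.0)
        sens, _ = stats.sensitivity_at_specificity(r, 0.90)
        assert sens == pytest.approx(1.0)

    def test_three_of_four_pairs_concordant(self):
        # controls [1, 2], patients [1.5, 3]: wins 3, losses 1 -> AUC 0.75
        r = stats.roc([1, 2, 1.5, 3], [False, False, True, True])
        assert r.auc == pytest.approx(0.75)

    def test_auc_equals_tie_halved_concordance(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n1, n2 = rng.integers(3, 15, 2)
            scores = np.round(rng.normal(size=n1 + n2), 1)  # rounding makes ties
            labels = np.r_[np.ones(n1, bool), np.zeros(n2, bool)]
            r = stats.roc(scores, labels)
            u = stats.mann_whitney(scores[labels], scores[~labels])["U"]
            assert r.auc == pytest.approx(u / (n1 * n2), abs=1e-12)

    def test_delong_ci_brackets_auc_and_bootstrap_agrees(self):
        rng = np.random.default_rng(3)
        scores = np.r_[rng.normal(1, 1, 30), rng.normal(0, 1, 30)]
        labels = np.r_[np.ones(30, bool), np.zeros(30, bool)]
        r = stats.roc(scores, labels)
        lo, hi = r.ci_95
        assert lo < r.auc < hi
        rb = stats.roc(scores, labels, ci_method="bootstrap", n_boot=500, seed=0)
        assert rb.ci_95[0] == pytest.approx(lo, abs=0.08)
        assert rb.ci_95[1] == pytest.approx(hi, abs=0.08)

    def test_orientation_is_never_flipped(self):
        # scores anti-correlated with case status -> AUC below 0.5
        r = stats.roc([3, 4, 1, 2], [False, False, True, True])
        assert r.auc == pytest.approx(0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            stats.roc([1, 2], [True, True])

    def test_degenerate_equal_scores_zero_sensitivity(self):
        r = stats.roc([5.0] * 8, [True] * 4 + [False] * 4)
        sens, _ = stats.sensitivity_at_specificity(r, 0.90)
        assert sens == 0.0

    def test_rank_invariance_under_monotone_rescaling(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        labels[:2], labels[-2:] = True, False
        r1 = stats.roc(scores, labels)
        r2 = stats.roc(np.exp(scores * 3), labels)
        assert r1.auc == pytest.approx(r2.auc)
        s1, _ = stats.sensitivity_at_specificity(r1)
        s2, _ = stats.sensitivity_at_specificity(r2)
        assert s1 == s2


class TestOlanzapineEquivalent:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "drug_name", "dose_mg", "when"])

    def test_identity_factor(self):
        rec = self._records([("P1", "olanzapine", 10.0, "day_of_draw")])
        out = stats.olanzapine_equivalent(rec)
        assert out.loc[0, "dose_day_olz_eq"] == pytest.approx(10.0)

    def test_empty_records(self):
        out = stats.olanzapine_equivalent(self._records([]))
        assert out.empty

    def test_two_drugs_sum_linearly(self):
        table = {"druga": 2.0, "drugb": 0.5}
        rec = self._records(
            [("P1", "drugA", 3.0, "day_of_draw"), ("P1", "drugB", 8.0, "day_of_draw")]
        )
        out = stats.olanzapine_equivalent(rec, table)
        assert out.loc[0, "dose_day_olz_eq"] == pytest.approx(3 * 2.0 + 8 * 0.5)

    def test_windows_kept_separate(self):
        rec = self._records(
            [
                ("P1", "olanzapine", 10.0, "day_of_draw"),
                ("P1", "olanzapine", 300.0, "cumulative_hospitalization"),
            ]
        )
        out = stats.olanzapine_equivalent(rec)
        assert out.loc[0, "dose_day_olz_eq"] == 10.0
        assert out.loc[0, "dose_cumulative_olz_eq"] == 300.0

    def test_unknown_drug_named_in_error(self):
        rec = self._records([("P1", "notadrug", 1.0, "day_of_draw")])
        with pytest.raises(KeyError, match="notadrug"):
            stats.olanzapine_equivalent(rec)

    def test_negative_dose_rejected(self):
        rec = self._records([("P1", "olanzapine", -1.0, "day_of_draw")])
        with pytest.raises(ValueError):
            stats.olanzapine_equivalent(rec)

    def test_shipped_table_has_reference_drug(self):
        table = stats.load_dose_table()
        assert table["olanzapine"] == 1.0


class TestDrugScreen:
    def _cohort(self, rng, n=29):
        df = pd.DataFrame(
            {f"ge_m{i}": rng.lognormal(0, 0.5, n) for i in range(13)}
        )
        for t in ("neuron", "astrocyte", "oligodendrocyte", "whole_brain"):
            df[f"ge_{t}"] = rng.lognormal(0, 0.5, n)
        df["total_cfdna_ng_per_ml"] = rng.lognormal(1.5, 0.4, n)
        df["dose_day_olz_eq"] = rng.lognormal(2.3, 0.6, n)
        df["dose_cumulative_olz_eq"] = rng.lognormal(5.5, 0.8, n)
        return df

    def test_grid_covers_18_variables_and_both_windows(self):
        df = self._cohort(np.random.default_rng(0))
        out = stats.drug_correlation_screen(df)
        assert out.variable.nunique() == 18
        assert set(out.dose_variable) == {"dose_day_olz_eq", "dose_cumulative_olz_eq"}
        assert set(out.test) == {"pearson", "spearman", "t_test", "mann_whitney"}

    def test_dose_copy_of_marker_detected(self):
        df = self._cohort(np.random.default_rng(1))
        df["dose_day_olz_eq"] = df["ge_m0"]
        out = stats.drug_correlation_screen(df)
        row = out[
            (out.variable == "ge_m0")
            & (out.dose_variable == "dose_day_olz_eq")
            & (out.test == "spearman")
        ].iloc[0]
        assert row.estimate == pytest.approx(1.0)
        assert row.significant_adjusted

    def test_constant_dose_flagged_missing(self):
        df = self._cohort(np.random.default_rng(2))
        df["dose_day_olz_eq"] = 5.0
        out = stats.drug_correlation_screen(df)
        sub = out[out.dose_variable == "dose_day_olz_eq"]
        assert sub.p_value.isna().all()
        assert (sub.note == "constant input").all()

    def test_too_few_pairs_flagged(self):
        df = self._cohort(np.random.default_rng(3)).iloc[:2]
        out = stats.drug_correlation_screen(df)
        assert out.p_value.isna().all()
        assert (out.note == "insufficient pairs").all()


def test_headline_statistics_shape():
    rng = np.random.default_rng(9)
    n1, n0 = 29, 31
    cohort = pd.DataFrame(
        {
            "group": ["patient"] * n1 + ["control"] * n0,
            "combined_brain_score": np.r_[
                rng.lognormal(1, 0.5, n1), rng.lognormal(0.3, 0.5, n0)
            ],
            "ge_neuron": np.r_[rng.lognormal(0.6, 0.5, n1), rng.lognormal(0, 0.5, n0)],
            "total_cfdna_ng_per_ml": rng.lognormal(1.5, 0.4, n1 + n0),
        }
    )
    out = stats.headline_statistics(cohort)
    assert out["n_patients"] == n1 and out["n_controls"] == n0
    assert 0 <= out["auc_combined"] <= 1
    assert out["auc_ci_95"][0] <= out["auc_combined"] <= out["auc_ci_95"][1]
    assert 0 <= out["sensitivity_at_specificity"] <= 1
    assert "mw_p_neuron" in out and "auc_neuron" in out


def test_load_cohort_table_with_column_map(tmp_path):
    df = pd.DataFrame({"Group": ["patient", "control"], "Brain score": [2.0, 1.0]})
    df.to_csv(tmp_path / "t.csv", index=False)
    out = stats.load_cohort_table(
        tmp_path / "t.csv", {"Group": "group", "Brain score": "combined_brain_score"}
    )
    assert list(out.columns) == ["group", "combined_brain_score"]
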