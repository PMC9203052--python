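"""Cohort-level statistics.

Group comparisons use the two-sided Mann-Whitney U test (exact null
distribution for small tie-free samples, normal approximation with tie
and continuity correction otherwise).  Classifier performance is
summarised by the empirical ROC curve: the trapezoidal AUC equals the
Mann-Whitney concordance U/(n1*n2) with ties counted one half, its 95%
confidence interval comes from DeLong's method (bootstrap available),
and the p-value against AUC = 0.5 is the Mann-Whitney p on the same
scores.  Sensitivity at fixed specificity is read off the empirical
curve without interpolation: the best sensitivity among thresholds whose
specificity meets the target.

The antipsychotic-exposure screen converts heterogeneous drug records to
olanzapine-equivalent milligrams via an editable consensus factor table,
then tests each cfDNA variable (individual markers, cell-type averages,
total cfDNA) against each dose variable with Pearson and Spearman
correlations plus t-test / Mann-Whitney on a median dose split, applying
Benjamini-Hochberg correction across the whole grid.
"""

from __future__ import annotations

import dataclasses
import math
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.multitest import multipletests

from .panel import BRAIN_CELL_TYPES


# --------------------------------------------------------------------------
# Mann-Whitney
# --------------------------------------------------------------------------


def mann_whitney(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> dict:
    """Two-sided Mann-Whitney U test of ``x`` vs ``y``.

    Reports ``U`` for the first sample under the convention
    U = #{(i, j): x_i > y_j} + 0.5 * #{ties}.  The p-value is exact
    (full enumeration of the null permutation distribution) whenever
    ``n_x * n_y <= 400`` and the pooled data carry no ties; otherwise the
    normal approximation with tie and continuity correction is used.
    NaN values are dropped within each sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("each group needs at least one non-missing value")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    exact = (x.size * y.size <= 400) and not has_ties
    res = sps.mannwhitneyu(
        x,
        y,
        alternative=alternative,
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return {
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "n_x": int(x.size),
        "n_y": int(y.size),
        "method": "exact" if exact else "asymptotic",
    }


# --------------------------------------------------------------------------
# ROC / AUC
# --------------------------------------------------------------------------


@dataclasses.dataclass
class RocResult:
    points: pd.DataFrame  # threshold, fpr, tpr
    auc: float
    ci_95: tuple[float, float]
    p_vs_chance: float
    n_cases: int
    n_controls: int


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_variance(cases: np.ndarray, controls: np.ndarray) -> tuple[float, float]:
    """DeLong estimate of AUC and its sampling variance (single curve)."""
    m, n = cases.size, controls.size
    all_r = _midrank(np.concatenate([cases, controls]))
    r_cases = _midrank(cases)
    r_controls = _midrank(controls)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - r_cases) / n  # structural components over cases
    v01 = 1.0 - (all_r[m:] - r_controls) / m  # over controls
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc(
    scores: Sequence[float],
    labels: Sequence[bool],
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> RocResult:
    """Empirical ROC with AUC, 95% CI and p-value against chance.

    ``labels`` is True for cases (patients); a higher score must indicate
    a case — the orientation is fixed, never auto-flipped.  AUC is the
    trapezoidal area under the empirical curve, identical to the
    tie-halved Mann-Whitney concordance.  The CI is DeLong by default or
    a seeded stratified bootstrap (``ci_method="bootstrap"``); the
    p-value against AUC = 0.5 is the two-sided Mann-Whitney p computed on
    the same scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    keep = ~np.isnan(scores)
    scores, labels = scores[keep], labels[keep]
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    cases, controls = scores[labels], scores[~labels]

    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    if ci_method == "delong":
        auc_d, var = _delong_variance(cases, controls)
        half = 1.959963984540054 * math.sqrt(max(var, 0.0))
        ci = (max(0.0, auc_d - half), min(1.0, auc_d + half))
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            ca = rng.choice(cases, cases.size, replace=True)
            co = rng.choice(controls, controls.size, replace=True)
            boots[b] = _delong_variance(ca, co)[0]
        ci = tuple(np.quantile(boots, [0.025, 0.975]))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    p = mann_whitney(cases, controls)["p"]
    points = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return RocResult(points, auc, (float(ci[0]), float(ci[1])), p, cases.size, controls.size)


def sensitivity_at_specificity(
    roc_result: RocResult, target_specificity: float = 0.90
) -> tuple[float, float]:
    """Best sensitivity among empirical thresholds meeting the specificity.

    No interpolation: only operating points with specificity
    (= 1 - FPR) >= target qualify; returns ``(sensitivity, threshold)``.
    Always defined — in the degenerate case only the all-negative
    threshold qualifies and sensitivity is 0.
    """
    pts = roc_result.points
    ok = pts[1.0 - pts.fpr >= target_specificity]
    if ok.empty:  # pragma: no cover - (0,0) always qualifies
        return 0.0, float("inf")
    best = ok.loc[ok.tpr.idxmax()]
    return float(best.tpr), float(best.threshold)


# --------------------------------------------------------------------------
# Dose equivalents and the drug screen
# --------------------------------------------------------------------------


def load_dose_table(path: str | Path | None = None) -> dict[str, float]:
    """Olanzapine-equivalence factors (mg olanzapine per mg drug).

    The shipped default is editable config data derived from published
    expert-consensus daily dose equivalents (olanzapine 20 mg/day as the
    reference); supply ``path`` to use a custom YAML mapping.
    """
    if path is None:
        text = resources.files("cfbrain.data").joinpath(
            "olanzapine_equivalents.yaml"
        ).read_text()
    else:
        text = Path(path).read_text()
    table = yaml.safe_load(text)
    return {str(k).lower(): float(v) for k, v in table.items()}


def olanzapine_equivalent(
    records: pd.DataFrame, table: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """Convert drug dose records to olanzapine-equivalent mg per sample.

    ``records`` needs columns ``sample_id``, ``drug_name``, ``dose_mg``,
    ``when`` (``day_of_draw`` | ``cumulative_hospitalization``).  Unknown
    drugs raise, naming the offenders — a silent zero would fabricate an
    untreated patient.  Returns one row per sample with columns
    ``dose_day_olz_eq`` and ``dose_cumulative_olz_eq`` (0 for samples
    with no records in a window).
    """
    table = dict(table) if table is not None else load_dose_table()
    if len(records) == 0:
        return pd.DataFrame(columns=["sample_id", "dose_day_olz_eq", "dose_cumulative_olz_eq"])
    rec = records.copy()
    rec["drug_name"] = rec.drug_name.str.lower()
    unknown = sorted(set(rec.drug_name) - set(table))
    if unknown:
        raise KeyError(f"no olanzapine-equivalence factor for: {', '.join(unknown)}")
    if (rec.dose_mg < 0).any():
        raise ValueError("negative dose_mg in records")
    bad_when = set(rec["when"]) - {"day_of_draw", "cumulative_hospitalization"}
    if bad_when:
        raise ValueError(f"unknown dose window(s): {sorted(bad_when)}")
    rec["olz_eq"] = rec.dose_mg * rec.drug_name.map(table)
    wide = (
        rec.pivot_table(index="sample_id", columns="when", values="olz_eq", aggfunc="sum")
        .reindex(columns=["day_of_draw", "cumulative_hospitalization"])
        .fillna(0.0)
        .reset_index()
    )
    return wide.rename(
        columns={
            "day_of_draw": "dose_day_olz_eq",
            "cumulative_hospitalization": "dose_cumulative_olz_eq",
        }
    )[["sample_id", "dose_day_olz_eq", "dose_cumulative_olz_eq"]]


def drug_correlation_screen(
    cohort: pd.DataFrame,
    variables: Sequence[str] | None = None,
    dose_columns: Sequence[str] = ("dose_day_olz_eq", "dose_cumulative_olz_eq"),
    alpha: float = 0.05,
    adjust_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Screen cfDNA variables against dose variables, with FDR control.

    Restricted to rows with a non-missing dose (patients).  For each
    variable x dose pair runs Pearson and Spearman correlations and, on a
    median split of the dose, Welch's t-test and Mann-Whitney.  P-values
    are adjusted across the complete grid (Benjamini-Hochberg by default;
    ``adjust_method="bonferroni"`` available).  Degenerate inputs
    (constant vectors, fewer than 3 complete pairs, an empty split group)
    yield a missing result with a reason, never a silent drop.
    """
    if variables is None:
        variables = _default_screen_variables(cohort)
    rows = []
    for dose_col in dose_columns:
        if dose_col not in cohort.columns:
            raise ValueError(f"dose column {dose_col!r} absent from cohort table")
        for var in variables:
            sub = cohort[[var, dose_col]].dropna()
            v, d = sub[var].to_numpy(float), sub[dose_col].to_numpy(float)
            for test in ("pearson", "spearman", "t_test", "mann_whitney"):
                est, p, note = _screen_test(test, v, d)
                rows.append(
                    {
                        "variable": var,
                        "dose_variable": dose_col,
                        "test": test,
                        "estimate": est,
                        "p_value": p,
                        "n": len(sub),
                        "note": note,
                    }
                )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = np.nan
    mask = out.p_value.notna()
    if mask.any():
        out.loc[mask, "p_adjusted"] = multipletests(
            out.loc[mask, "p_value"], alpha=alpha, method=adjust_method
        )[1]
    out["significant_nominal"] = out.p_value < alpha
    out["significant_adjusted"] = out.p_adjusted < alpha
    return out


def _default_screen_variables(cohort: pd.DataFrame) -> list[str]:
    """13 individual markers + 4 cell-type averages + total cfDNA."""
    marker_cols = [
        c
        for c in cohort.columns
        if c.startswith("ge_")
        and c not in {f"ge_{t}" for t in (*BRAIN_CELL_TYPES, "whole_brain")}
    ]
    celltype_cols = [
        f"ge_{t}" for t in (*BRAIN_CELL_TYPES, "whole_brain") if f"ge_{t}" in cohort.columns
    ]
    out = marker_cols + celltype_cols
    if "total_cfdna_ng_per_ml" in cohort.columns:
        out.append("total_cfdna_ng_per_ml")
    return out


def _screen_test(test: str, v: np.ndarray, d: np.ndarray):
    if v.size < 3:
        return np.nan, np.nan, "insufficient pairs"
    if np.unique(v).size < 2 or np.unique(d).size < 2:
        return np.nan, np.nan, "constant input"
    if test == "pearson":
        r, p = sps.pearsonr(v, d)
        return float(r), float(p), ""
    if test == "spearman":
        r, p = sps.spearmanr(v, d)
        return float(r), float(p), ""
    hi = d > np.median(d)
    a, b = v[hi], v[~hi]
    if a.size < 2 or b.size < 2:
        return np.nan, np.nan, "degenerate dose split"
    if test == "t_test":
        t, p = sps.ttest_ind(a, b, equal_var=False)
        return float(t), float(p), ""
    res = mann_whitney(a, b)
    return res["U"], res["p"], ""


# --------------------------------------------------------------------------
# Headline cohort statistics
# --------------------------------------------------------------------------


def headline_statistics(
    cohort: pd.DataFrame,
    group_col: str = "group",
    score_col: str = "combined_brain_score",
    target_specificity: float = 0.90,
    seed: int = 0,
) -> dict:
    """The cohort's headline numbers in one dictionary.

    Mann-Whitney patients-vs-controls p-values for total cfDNA and each
    cell-type signal, the combined-score ROC (AUC, 95% CI, p vs chance),
    sensitivity at the target specificity, and per-cell-type AUCs.
    """
    is_patient = cohort[group_col].astype(str).str.lower().isin(
        {"patient", "case", "cases", "patients", "1", "true"}
    )
    out: dict = {"n_patients": int(is_patient.sum()), "n_controls": int((~is_patient).sum())}

    def _mw(col: str) -> float:
        return mann_whitney(
            cohort.loc[is_patient, col], cohort.loc[~is_patient, col]
        )["p"]

    for cell_type in (*BRAIN_CELL_TYPES, "whole_brain"):
        col = f"ge_{cell_type}"
        if col in cohort.columns:
            out[f"mw_p_{cell_type}"] = _mw(col)
            r = roc(cohort[col], is_patient, seed=seed)
            out[f"auc_{cell_type}"] = r.auc
    if "total_cfdna_ng_per_ml" in cohort.columns:
        out["mw_p_total_cfdna"] = _mw("total_cfdna_ng_per_ml")
    r = roc(cohort[score_col], is_patient, seed=seed)
    sens, thr = sensitivity_at_specificity(r, target_specificity)
    out.update(
        {
            "mw_p_combined": _mw(score_col),
            "auc_combined": r.auc,
            "auc_ci_95": list(r.ci_95),
            "auc_p_vs_chance": r.p_vs_chance,
            "sensitivity_at_specificity": sens,
            "specificity_target": target_specificity,
            "threshold": thr,
        }
    )
    return out


def load_cohort_table(
    path: str | Path, column_map: Mapping[str, str] | str | Path | None = None
) -> pd.DataFrame:
    """Read an external cohort table (CSV/TSV/XLSX) into the canonical layout.

    ``column_map`` maps source column names to canonical names (``group``,
    ``total_cfdna_ng_per_ml``, ``combined_brain_score``, ``ge_<cell type>``,
    per-marker ``ge_*`` columns, dose columns); pass a YAML path or a
    mapping.  Rows keep their order; values are taken as-is.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep, na_values=["."])
    if column_map is not None:
        if not isinstance(column_map, Mapping):
            column_map = yaml.safe_load(Path(column_map).read_text())
        df = df.rename(columns=dict(column_map))
    return df
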