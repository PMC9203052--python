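"""Cell-type-specific marker selection from methylation-array beta values.

Given a loci x samples matrix of beta values (fraction methylated, in
[0, 1]) with a cell-type label per sample, a locus qualifies as a marker
for a target class when it is unmethylated in *every* sample of that
class (max beta <= ``t_low``) and methylated in *every* sample of every
other class (min beta >= ``t_high``).  Worst-case aggregation (max over
target, min over background) enforces the absolutist criterion —
"unmethylated specifically in X, methylated in all other cell types" —
rather than a difference of group means.

Candidates are ranked by margin: background minimum minus target
maximum.  Whole-brain markers are loci unmethylated across the union of
the brain cell classes; a locus that also qualifies for a single class
is assigned to the most specific class it supports.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import BRAIN_CELL_TYPES

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class BetaMatrix:
    """Beta values (loci rows x sample columns) plus per-sample labels."""

    beta: pd.DataFrame
    labels: pd.Series  # index = sample ids, values = cell-type/tissue label

    def __post_init__(self) -> None:
        missing = set(self.beta.columns) - set(self.labels.index)
        if missing:
            raise ValueError(f"samples without label: {sorted(missing)[:5]}")
        labels = self.labels.loc[list(self.beta.columns)]
        object.__setattr__(self, "labels", labels)
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and ((finite < 0).any() or (finite > 1).any()):
            raise ValueError("beta values must lie in [0, 1]")
        if labels.nunique() < 2:
            raise ValueError("beta matrix must carry at least two distinct labels")

    @classmethod
    def read(cls, beta_tsv: str, labels_tsv: str) -> "BetaMatrix":
        """Read a beta TSV (loci rows, sample columns) and a two-column
        label TSV (sample_id, label)."""
        beta = pd.read_csv(beta_tsv, sep="\t", index_col=0, na_values=["."])
        lab = pd.read_csv(labels_tsv, sep="\t")
        labels = pd.Series(lab.iloc[:, 1].values, index=lab.iloc[:, 0].values)
        return cls(beta, labels)

    def samples_of(self, label: str | Iterable[str]) -> list[str]:
        wanted = {label} if isinstance(label, str) else set(label)
        return [s for s in self.beta.columns if self.labels[s] in wanted]


def select_specific_loci(
    m: BetaMatrix,
    target_label: str | Iterable[str],
    t_low: float = 0.2,
    t_high: float = 0.8,
) -> pd.DataFrame:
    """Loci unmethylated in the target class and methylated everywhere else.

    Parameters
    ----------
    m
        The beta matrix.
    target_label
        A label, or a collection of labels treated as one joint target
        class (used for whole-brain selection).
    t_low, t_high
        A locus passes when max beta over target samples <= ``t_low``
        and min beta over every background sample >= ``t_high``.

    Returns
    -------
    DataFrame with columns ``locus``, ``target_max_beta``,
    ``background_min_beta``, ``margin`` sorted by descending margin.
    Loci with a missing beta in any deciding sample are excluded (and
    counted in the log); no imputation is attempted.
    """
    if not (t_low < t_high):
        raise ValueError(f"require t_low < t_high, got {t_low} >= {t_high}")
    targets = [target_label] if isinstance(target_label, str) else list(target_label)
    known = set(m.labels.unique())
    unknown = set(targets) - known
    if unknown:
        raise ValueError(f"unknown label(s): {sorted(unknown)}")
    target_cols = m.samples_of(targets)
    background_cols = [c for c in m.beta.columns if c not in set(target_cols)]
    if not background_cols:
        raise ValueError("no background samples: target labels cover the whole matrix")

    t = m.beta[target_cols].to_numpy(dtype=float)
    b = m.beta[background_cols].to_numpy(dtype=float)
    complete = ~(np.isnan(t).any(axis=1) | np.isnan(b).any(axis=1))
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info(
            "select_specific_loci(%s): %d loci dropped for missing betas",
            targets,
            n_dropped,
        )
    target_max = t.max(axis=1, initial=-np.inf, where=~np.isnan(t))
    background_min = b.min(axis=1, initial=np.inf, where=~np.isnan(b))
    hit = complete & (target_max <= t_low) & (background_min >= t_high)
    out = pd.DataFrame(
        {
            "locus": m.beta.index[hit],
            "target_max_beta": target_max[hit],
            "background_min_beta": background_min[hit],
        }
    )
    out["margin"] = out.background_min_beta - out.target_max_beta
    return out.sort_values(
        ["margin", "locus"], ascending=[False, True], ignore_index=True
    )


def merge_group_selections(
    m: BetaMatrix,
    brain_labels: Sequence[str] = BRAIN_CELL_TYPES,
    t_low: float = 0.2,
    t_high: float = 0.8,
) -> pd.DataFrame:
    """Build a panel skeleton: per-cell-type plus whole-brain candidates.

    Whole-brain candidates pass selection with the union of
    ``brain_labels`` as the target class; a locus passing both a single
    class and the whole-brain union is assigned to the single class (the
    most specific assignment).  Returns a DataFrame with columns
    ``locus``, ``cell_type``, ``target_max_beta``, ``background_min_beta``,
    ``margin``.
    """
    brain_labels = list(brain_labels)
    if len(set(brain_labels)) != len(brain_labels):
        raise ValueError("overlapping label definitions in brain_labels")
    present = [lab for lab in brain_labels if lab in set(m.labels.unique())]
    per_class = {
        lab: select_specific_loci(m, lab, t_low, t_high).assign(cell_type=lab)
        for lab in present
    }
    whole = pd.DataFrame(
        columns=["locus", "target_max_beta", "background_min_beta", "margin"]
    )
    if len(present) == len(brain_labels) and len(present) > 1:
        whole = select_specific_loci(m, brain_labels, t_low, t_high)
    class_hits = set().union(*(set(df.locus) for df in per_class.values())) if per_class else set()
    whole = whole[~whole.locus.isin(class_hits)].assign(cell_type="whole_brain")

    frames = [df for df in per_class.values() if len(df)] + ([whole] if len(whole) else [])
    if not frames:
        logger.warning("merge_group_selections: no locus passed any class")
        return pd.DataFrame(
            columns=["locus", "cell_type", "target_max_beta", "background_min_beta", "margin"]
        )
    out = pd.concat(frames, ignore_index=True)
    return out[["locus", "cell_type", "target_max_beta", "background_min_beta", "margin"]]
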