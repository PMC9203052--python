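"""Quantification: unmethylated fractions, genome equivalents/mL, and
cell-type / combined brain scores.

The counting unit of tissue-derived signal is the *fully unmethylated
molecule*: a passing read whose every expected CpG reads TG.  Per
marker::

    fraction   = n_fully_unmethylated / n_pass          (missing if n_pass == 0)
    GE/mL      = fraction * total_cfdna_ng_per_ml * 1000 / pg_per_haploid_genome

where total cfDNA is the concentration measured *before* bisulfite
conversion (so bisulfite-induced degradation, which thins methylated and
unmethylated molecules alike, does not bias the absolute scale).  The
genome-mass constant defaults to 3.3 pg per haploid genome.

Cell-type signals are unweighted means of GE/mL over the markers of each
class; the combined brain score is the sum of the neuron, astrocyte and
oligodendrocyte means.  Whole-brain markers are reported as their own
signal but excluded from the sum by default, since they respond to the
same brain DNA the cell-type markers already count.  A parallel
fraction-based aggregate (no concentration multiplication) is emitted
alongside.  Markers with zero passing molecules propagate as missing,
never as zero.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import BRAIN_CELL_TYPES, MarkerPanel

logger = logging.getLogger(__name__)

PG_PER_HAPLOID_GENOME = 3.3


def fraction_fully_unmethylated(n_fully_unmethylated: int, n_pass: int) -> float:
    """Fraction of passing molecules with every CpG unmethylated.

    Returns NaN (missing, with a log warning) when no molecule passed;
    zero coverage carries no information and must not deflate a signal.
    """
    if n_pass < 0 or n_fully_unmethylated < 0 or n_fully_unmethylated > n_pass:
        raise ValueError(
            f"invalid counts: {n_fully_unmethylated} unmethylated of {n_pass} passing"
        )
    if n_pass == 0:
        logger.warning("zero passing molecules: fraction is missing, not 0")
        return float("nan")
    return n_fully_unmethylated / n_pass


def fraction_from_calls(calls: Sequence) -> float:
    """Fraction of fully unmethylated molecules among passing calls."""
    passing = [c for c in calls if c.status == "pass"]
    n_full = sum(1 for c in passing if c.fully_unmethylated)
    return fraction_fully_unmethylated(n_full, len(passing))


def genome_equivalents_per_ml(
    fraction: float,
    total_cfdna_ng_per_ml: float,
    pg_per_haploid_genome: float = PG_PER_HAPLOID_GENOME,
) -> float:
    """Absolute tissue signal: fraction x total genome concentration.

    ``total_cfdna_ng_per_ml * 1000 / pg_per_haploid_genome`` is the total
    number of haploid genomes per mL of plasma; multiplying by the
    unmethylated fraction gives the genomes contributed by the target
    tissue.  NaN fraction propagates.
    """
    if math.isnan(fraction):
        return float("nan")
    if fraction < 0 or total_cfdna_ng_per_ml < 0 or pg_per_haploid_genome <= 0:
        raise ValueError("fraction and concentrations must be non-negative")
    return fraction * total_cfdna_ng_per_ml * 1000.0 / pg_per_haploid_genome


@dataclasses.dataclass
class SampleQuant:
    """Per-sample quantification: tidy per-marker table + summary row."""

    sample_id: str
    per_marker: pd.DataFrame  # marker_id, cell_type, n_pass, n_fully_unmethylated, fraction, ge_per_ml
    summary: dict  # sample_id, total cfDNA, per-cell-type signals, combined scores


def aggregate_cell_types(
    per_marker: pd.DataFrame,
    include_whole_brain_in_score: bool = False,
) -> dict:
    """Cell-type means and combined brain scores from a per-marker table.

    Missing markers (NaN fraction) are excluded from their cell-type
    mean; a cell type with no informative marker is missing, and a
    missing component makes the combined score missing.
    """
    out: dict = {}
    score_types = list(BRAIN_CELL_TYPES) + (
        ["whole_brain"] if include_whole_brain_in_score else []
    )
    for measure, col in (("ge", "ge_per_ml"), ("frac", "fraction")):
        for cell_type, grp in per_marker.groupby("cell_type"):
            vals = grp[col].dropna()
            n_missing = grp[col].isna().sum()
            if n_missing:
                logger.info(
                    "%s: %d/%d markers missing for %s", cell_type, n_missing, len(grp), col
                )
            out[f"{measure}_{cell_type}"] = float(vals.mean()) if len(vals) else float("nan")
        components = [out.get(f"{measure}_{t}", float("nan")) for t in score_types]
        score = sum(components) if not any(math.isnan(c) for c in components) else float("nan")
        key = "combined_brain_score" if measure == "ge" else "combined_brain_fraction"
        out[key] = score
    return out


def quantify_sample(
    marker_counts: Mapping[str, tuple[int, int]],
    total_cfdna_ng_per_ml: float,
    panel: MarkerPanel,
    sample_id: str = "sample",
    pg_per_haploid_genome: float = PG_PER_HAPLOID_GENOME,
    include_whole_brain_in_score: bool = False,
) -> SampleQuant:
    """Quantify one sample from per-marker (n_pass, n_fully_unmethylated).

    Markers of the panel absent from ``marker_counts`` are treated as
    zero-coverage (missing).
    """
    if total_cfdna_ng_per_ml < 0:
        raise ValueError("total cfDNA concentration must be non-negative")
    rows = []
    for template in panel:
        n_pass, n_full = marker_counts.get(template.marker_id, (0, 0))
        frac = fraction_fully_unmethylated(n_full, n_pass) if n_pass else float("nan")
        ge = genome_equivalents_per_ml(frac, total_cfdna_ng_per_ml, pg_per_haploid_genome)
        rows.append(
            {
                "sample_id": sample_id,
                "marker_id": template.marker_id,
                "cell_type": template.cell_type,
                "n_pass": n_pass,
                "n_fully_unmethylated": n_full,
                "fraction": frac,
                "ge_per_ml": ge,
            }
        )
    per_marker = pd.DataFrame(rows)
    summary = {
        "sample_id": sample_id,
        "total_cfdna_ng_per_ml": total_cfdna_ng_per_ml,
    }
    for _, r in per_marker.iterrows():
        summary[f"ge_{r.marker_id}"] = r.ge_per_ml
    summary.update(aggregate_cell_types(per_marker, include_whole_brain_in_score))
    return SampleQuant(sample_id, per_marker, summary)


def cohort_table(sample_quants: Sequence[SampleQuant]) -> pd.DataFrame:
    """Stack per-sample summaries into one cohort row-per-sample table."""
    return pd.DataFrame([q.summary for q in sample_quants])
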