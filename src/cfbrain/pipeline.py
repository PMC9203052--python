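"""Pipeline orchestration: from FASTQ + panel + metadata to cohort stats.

``run_pipeline`` executes the stages in order — demultiplex, quality
filter, amplicon assignment, CpG calling, quantification, cohort
statistics — logging every stage's record counts and writing the
resolved configuration into the output directory so a run is fully
reproducible.  ``run_dilution_series`` is the controlled-spike
experiment used to establish assay sensitivity.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import quant, stats
from .panel import MarkerPanel
from .reads import (
    AmpliconMatcher,
    ReadProcessingConfig,
    demultiplex,
    parse_fastq,
    process_sample,
    write_run_report,
)
from .simulate import SimulationConfig, simulate_sample_reads

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Paths plus every module default, serialisable to YAML."""

    panel_dir: str
    fastq_dir: str
    metadata: str
    barcodes: str
    output_dir: str
    panel_name: str = "panel"
    reads: ReadProcessingConfig = dataclasses.field(default_factory=ReadProcessingConfig)
    pg_per_haploid_genome: float = quant.PG_PER_HAPLOID_GENOME
    include_whole_brain_in_score: bool = False
    target_specificity: float = 0.90
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        reads = ReadProcessingConfig(**raw.pop("reads", {}))
        return cls(reads=reads, **raw)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the output directory.

    Inputs are validated up front and failures abort with a consolidated
    message before any stage runs.  Deterministic outputs are
    byte-identical across re-runs with identical config and inputs.
    """
    errors = []
    panel_dir, fastq_dir = Path(config.panel_dir), Path(config.fastq_dir)
    meta_path, bc_path = Path(config.metadata), Path(config.barcodes)
    for p, what in ((panel_dir, "panel directory"), (fastq_dir, "fastq directory"),
                    (meta_path, "metadata table"), (bc_path, "barcode table")):
        if not p.exists():
            errors.append(f"{what} not found: {p}")
    if errors:
        raise FileNotFoundError("; ".join(errors))

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))

    panel = MarkerPanel.read(panel_dir, config.panel_name)
    meta = pd.read_csv(meta_path, sep="\t")
    barcodes = pd.read_csv(bc_path, sep="\t")
    barcode_map = dict(zip(barcodes.sample_id, barcodes.barcode))
    matcher = AmpliconMatcher(panel, config.reads)

    fastqs = sorted(fastq_dir.glob("*.fastq"))
    results = {}
    n_unassigned = 0
    for fq in fastqs:
        bins, unassigned = demultiplex(
            parse_fastq(fq), barcode_map, config.reads.barcode_mode,
            config.reads.barcode_mismatches,
        )
        n_unassigned += len(unassigned)
        for sample_id, records in bins.items():
            if not records:
                continue
            res = process_sample(records, matcher, sample_id)
            if sample_id in results:
                results[sample_id].status_counts.update(res.status_counts)
                for m, c in res.marker_counts.items():
                    for k, v in c.items():
                        results[sample_id].marker_counts[m][k] += v
            else:
                results[sample_id] = res
            logger.info("%s: %d reads, %s", sample_id, res.n_reads, dict(res.status_counts))
    write_run_report(results, n_unassigned, out_dir / "run_report.json")

    sample_quants = []
    per_marker_frames = []
    for _, row in meta.iterrows():
        sid = row.sample_id
        counts = results[sid].pass_counts() if sid in results else {}
        q = quant.quantify_sample(
            counts,
            float(row.total_cfdna_ng_per_ml),
            panel,
            sample_id=sid,
            pg_per_haploid_genome=config.pg_per_haploid_genome,
            include_whole_brain_in_score=config.include_whole_brain_in_score,
        )
        sample_quants.append(q)
        per_marker_frames.append(q.per_marker)
    pd.concat(per_marker_frames, ignore_index=True).to_csv(
        out_dir / "per_marker.tsv", sep="\t", index=False, na_rep="."
    )
    cohort = quant.cohort_table(sample_quants)
    cohort = cohort.merge(
        meta.drop(columns=["total_cfdna_ng_per_ml"]), on="sample_id", how="left"
    )
    cohort.to_csv(out_dir / "cohort.tsv", sep="\t", index=False, na_rep=".")

    informative = (
        "group" in cohort.columns
        and cohort["group"].nunique() == 2
        and len(cohort) >= 4
        and cohort.groupby("group")["combined_brain_score"].apply(lambda s: s.notna().any()).all()
    )
    if informative:
        headline = stats.headline_statistics(
            cohort, target_specificity=config.target_specificity, seed=config.seed
        )
        (out_dir / "stats.json").write_text(json.dumps(headline, indent=2, sort_keys=True))
    return out_dir


def run_dilution_series(
    panel: MarkerPanel,
    fractions: Sequence[float],
    n_molecules_per_marker: int,
    seeds: Sequence[int],
    conversion_rate: float = 0.99,
    inappropriate_rate: float = 0.005,
    seq_error_rate: float = 0.001,
    read_config: ReadProcessingConfig | None = None,
) -> pd.DataFrame:
    """Spike-in dilution experiment through the full read pipeline.

    For every seed, simulates one multiplexed run containing one sample
    per spiked fraction (each at ``n_molecules_per_marker`` molecules per
    panel marker), demultiplexes it, processes every read, and pools the
    fully-unmethylated counts across all markers.

    Returns a tidy DataFrame: seed, fraction, n_pass,
    n_fully_unmethylated, pooled_fraction.
    """
    matcher = AmpliconMatcher(panel, read_config)
    barcode_map = {f"f{i}": _dilution_barcode(i) for i in range(len(fractions))}
    rows = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        records_all: list[tuple[str, str, str]] = []
        for i, f in enumerate(fractions):
            cfg = SimulationConfig(
                seed=seed,
                n_molecules_per_marker=n_molecules_per_marker,
                target_fraction=f,
                bisulfite_conversion_rate=conversion_rate,
                inappropriate_conversion_rate=inappropriate_rate,
                seq_error_rate=seq_error_rate,
            )
            recs, _ = simulate_sample_reads(panel, f"f{i}", barcode_map[f"f{i}"], cfg, rng)
            records_all.extend(recs)
        bins, unassigned = demultiplex(records_all, barcode_map)
        if unassigned:
            logger.warning("seed %d: %d unassigned reads", seed, len(unassigned))
        for i, f in enumerate(fractions):
            res = process_sample(bins[f"f{i}"], matcher, f"f{i}")
            n_pass = sum(c["n_pass"] for c in res.marker_counts.values())
            n_full = sum(c["n_fully_unmethylated"] for c in res.marker_counts.values())
            rows.append(
                {
                    "seed": seed,
                    "fraction": f,
                    "n_pass": n_pass,
                    "n_fully_unmethylated": n_full,
                    "pooled_fraction": n_full / n_pass if n_pass else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def _dilution_barcode(i: int) -> str:
    alphabet = "ACGT"
    return "".join(alphabet[(i >> (2 * k)) & 3] for k in range(4)) + "ACGT"[i % 4] * 4
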