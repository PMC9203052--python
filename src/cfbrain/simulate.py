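"""Synthetic targeted bisulfite-amplicon data.

This module generates everything the downstream pipeline consumes, from a
marker panel down to barcoded FASTQ reads and full case/control cohorts,
with every quantity controlled and recorded so that recovered values can
be checked against the simulation truth.

The generative model mirrors the assay:

* Each plasma sample is a mixture of molecules per marker.  A molecule is
  drawn from the *target tissue* (brain) with probability
  ``target_fraction`` and is then fully unmethylated at every CpG of the
  amplicon; otherwise it comes from the *background* (dominated by
  leukocytes) and is fully methylated.
* Bisulfite chemistry converts unmethylated cytosines to thymine with
  probability ``bisulfite_conversion_rate`` and (inappropriately)
  converts methylated CpG cytosines with probability
  ``inappropriate_conversion_rate``.
* Sequencing introduces per-base substitution errors at
  ``seq_error_rate``; reads are single-end, top strand, one read per
  molecule, with the sample barcode carried in the read header (Illumina
  index convention) or as an inline prefix.
* A cohort draws, per sample, a true brain-derived concentration
  (genome equivalents per mL plasma) and a total cfDNA concentration
  (ng/mL) from group-specific log-normal distributions; the per-marker
  spiked fraction follows from their ratio.

All randomness flows through :class:`numpy.random.Generator` objects
seeded from explicit integers; identical seeds give identical output.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .panel import BRAIN_CELL_TYPES, AmpliconTemplate, MarkerPanel

METHYLATED = "M"
UNMETHYLATED = "U"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = (ord(b) for b in "ACGT")


@dataclasses.dataclass(frozen=True)
class MoleculePattern:
    """Per-CpG methylation states of one template molecule."""

    marker_id: str
    cpg_states: tuple[str, ...]  # "M" / "U", one per CpG of the amplicon
    origin: str  # "target_tissue" | "background"

    @property
    def fully_unmethylated(self) -> bool:
        return all(s == UNMETHYLATED for s in self.cpg_states)


@dataclasses.dataclass
class LognormalParams:
    """Log-normal distribution given by its median and log-space sigma."""

    median: float
    sigma_log: float

    def validate(self) -> None:
        if self.median < 0 or self.sigma_log < 0:
            raise ValueError("log-normal parameters must be non-negative")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.median * np.exp(self.sigma_log * rng.standard_normal(n))


@dataclasses.dataclass
class CohortConfig:
    """Case/control cohort design.

    Defaults emulate the study conditions this toolkit reproduces: 29
    patients with a first psychotic episode vs 31 healthy controls, a
    roughly two-fold elevation of brain-derived cfDNA in patients on a
    background of ~1.5 genome equivalents/mL in controls, and a ~1.3-fold
    elevation of total cfDNA (healthy plasma carries a few ng/mL).
    Inter-individual spread is log-normal, the usual shape for plasma
    cfDNA concentrations.
    """

    n_cases: int = 29
    n_controls: int = 31
    control_brain_ge_per_ml: LognormalParams = dataclasses.field(
        default_factory=lambda: LognormalParams(1.5, 0.5)
    )
    case_brain_ge_per_ml: LognormalParams = dataclasses.field(
        default_factory=lambda: LognormalParams(3.0, 0.5)
    )
    control_total_cfdna_ng_per_ml: LognormalParams = dataclasses.field(
        default_factory=lambda: LognormalParams(4.0, 0.4)
    )
    case_total_cfdna_ng_per_ml: LognormalParams = dataclasses.field(
        default_factory=lambda: LognormalParams(5.2, 0.4)
    )
    # Antipsychotic exposure, already on the olanzapine-equivalent scale
    # (mg).  Independent of the brain signal by default: the null that the
    # drug screen is calibrated against.
    dose_day_olz_eq: LognormalParams = dataclasses.field(
        default_factory=lambda: LognormalParams(10.0, 0.6)
    )
    dose_cumulative_olz_eq: LognormalParams = dataclasses.field(
        default_factory=lambda: LognormalParams(250.0, 0.8)
    )

    def validate(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be non-negative")
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, LognormalParams):
                v.validate()


@dataclasses.dataclass
class SimulationConfig:
    """All knobs of the read simulator.

    ``target_fraction`` is the probability that a molecule originates from
    the unmethylated (brain) class; it emulates spiking brain DNA into
    leukocyte DNA at a known dilution.  ``n_molecules_per_marker``
    defaults to 30,000 sequenced molecules per amplicon per sample.
    """

    seed: int = 0
    n_molecules_per_marker: int = 30_000
    target_fraction: float = 0.0
    bisulfite_conversion_rate: float = 0.99
    inappropriate_conversion_rate: float = 0.005
    seq_error_rate: float = 0.001
    background_flip_rate: float = 0.0  # per-CpG M->U noise in background molecules
    quality_q: int = 37
    barcode_mode: str = "header"  # "header" | "inline"
    barcode_map: dict[str, str] | None = None
    cohort: CohortConfig | None = None

    def validate(self) -> None:
        rates = {
            "target_fraction": self.target_fraction,
            "bisulfite_conversion_rate": self.bisulfite_conversion_rate,
            "inappropriate_conversion_rate": self.inappropriate_conversion_rate,
            "seq_error_rate": self.seq_error_rate,
            "background_flip_rate": self.background_flip_rate,
        }
        for name, r in rates.items():
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {r}")
        if self.n_molecules_per_marker < 1:
            raise ValueError("n_molecules_per_marker must be >= 1")
        if self.barcode_mode not in ("header", "inline"):
            raise ValueError(f"unknown barcode mode {self.barcode_mode!r}")
        if self.barcode_map is not None:
            codes = list(self.barcode_map.values())
            if len(codes) != len(set(codes)):
                raise ValueError("barcodes must be unique")
        if self.cohort is not None:
            self.cohort.validate()


# --------------------------------------------------------------------------
# Panel generation
# --------------------------------------------------------------------------


def generate_marker_panel(
    n_per_cell_type: Mapping[str, int],
    n_cpgs_range: tuple[int, int] = (3, 6),
    amplicon_length: int = 100,
    seed: int = 0,
) -> MarkerPanel:
    """Generate a random synthetic marker panel.

    Each amplicon is a random sequence of the requested length carrying a
    random number of CpG sites in ``n_cpgs_range`` (inclusive) and at
    least one non-CpG cytosine (needed so that incomplete bisulfite
    conversion is observable).  CpG dinucleotides occur exactly at the
    declared offsets and nowhere else.

    Raises
    ------
    ValueError
        If the geometry is infeasible (too many CpGs for the length) or
        the length is below 40 bp.
    """
    if amplicon_length < 40:
        raise ValueError("amplicon_length must be >= 40 bp")
    lo, hi = int(n_cpgs_range[0]), int(n_cpgs_range[1])
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid n_cpgs_range {n_cpgs_range}")
    # CpGs are planted at even spacing >= 3 bp apart, away from both ends.
    if hi > (amplicon_length - 4) // 3:
        raise ValueError(
            f"cannot place up to {hi} CpGs in a {amplicon_length} bp amplicon"
        )

    rng = np.random.default_rng(seed)
    amplicons: list[AmpliconTemplate] = []
    cursor = 0
    for cell_type, count in n_per_cell_type.items():
        for i in range(int(count)):
            marker_id = f"{cell_type}_{i + 1}"
            k = int(rng.integers(lo, hi + 1))
            seq, offsets = _random_amplicon(rng, amplicon_length, k)
            amplicons.append(
                AmpliconTemplate(
                    marker_id=marker_id,
                    cell_type=cell_type,
                    genomic_ref_seq=seq,
                    cpg_offsets=offsets,
                    chrom="chrSim",
                    start=cursor,
                )
            )
            cursor += amplicon_length + 100
    return MarkerPanel(tuple(amplicons))


def _random_amplicon(
    rng: np.random.Generator, length: int, n_cpgs: int
) -> tuple[str, tuple[int, ...]]:
    seq = rng.choice(_BASES, size=length).astype(np.uint8)
    # candidate CpG positions: spaced >= 3 apart, clear of both ends
    candidates = np.arange(2, length - 3)
    offsets: list[int] = []
    taken = np.zeros(length, dtype=bool)
    order = rng.permutation(candidates)
    for pos in order:
        if len(offsets) == n_cpgs:
            break
        if not taken[max(0, pos - 2) : pos + 3].any():
            offsets.append(int(pos))
            taken[pos : pos + 2] = True
    if len(offsets) < n_cpgs:  # pragma: no cover - spacing guard above prevents this
        raise ValueError("could not place requested CpGs")
    offsets.sort()
    for o in offsets:
        seq[o] = _C
        seq[o + 1] = _G
    planted = set(offsets)
    # remove accidental CG dinucleotides (mutate the G; cannot touch a
    # planted C, and C->A never creates a new CG)
    while True:
        is_cg = (seq[:-1] == _C) & (seq[1:] == _G)
        accidental = [p for p in np.flatnonzero(is_cg) if p not in planted]
        if not accidental:
            break
        for p in accidental:
            seq[p + 1] = _A
    # guarantee a non-CpG cytosine for conversion QC
    non_cpg_c = [i for i in np.flatnonzero(seq == _C) if i not in planted]
    if not non_cpg_c:
        for i in range(length - 1):
            if i in planted or (i + 1) in planted or i - 1 in planted:
                continue
            if seq[i + 1] != _G:
                seq[i] = _C
                break
    return seq.tobytes().decode("ascii"), tuple(offsets)


# --------------------------------------------------------------------------
# Molecule and read simulation
# --------------------------------------------------------------------------


def simulate_molecules(panel: MarkerPanel, cfg: SimulationConfig) -> list[MoleculePattern]:
    """Draw ``n_molecules_per_marker`` molecules for every panel marker.

    Each molecule is target-tissue (all CpGs unmethylated) with
    probability ``cfg.target_fraction``, else background (all CpGs
    methylated, optionally with per-CpG noise flips).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    out: list[MoleculePattern] = []
    for template in panel:
        k = template.n_cpgs
        all_u = (UNMETHYLATED,) * k
        all_m = (METHYLATED,) * k
        is_target = rng.random(cfg.n_molecules_per_marker) < cfg.target_fraction
        for t in is_target:
            if t:
                out.append(MoleculePattern(template.marker_id, all_u, "target_tissue"))
            elif cfg.background_flip_rate > 0:
                flips = rng.random(k) < cfg.background_flip_rate
                states = tuple(
                    UNMETHYLATED if f else METHYLATED for f in flips
                )
                out.append(MoleculePattern(template.marker_id, states, "background"))
            else:
                out.append(MoleculePattern(template.marker_id, all_m, "background"))
    return out


def bisulfite_convert(
    template: AmpliconTemplate,
    pattern: MoleculePattern,
    conversion_rate: float,
    inappropriate_rate: float,
    rng: np.random.Generator,
) -> str:
    """Bisulfite-convert one molecule, returning its read-out sequence.

    Every non-CpG cytosine converts to T with probability
    ``conversion_rate`` (they are unmethylated in somatic DNA).  A CpG
    cytosine converts with probability ``conversion_rate`` if the
    molecule is unmethylated there, or ``inappropriate_rate`` if
    methylated.  A, G and T are untouched; length is preserved.
    """
    if pattern.marker_id != template.marker_id:
        raise ValueError(
            f"pattern for {pattern.marker_id} does not match template {template.marker_id}"
        )
    if len(pattern.cpg_states) != template.n_cpgs:
        raise ValueError(
            f"{template.marker_id}: pattern has {len(pattern.cpg_states)} states, "
            f"template has {template.n_cpgs} CpGs"
        )
    state_at = dict(zip(template.cpg_offsets, pattern.cpg_states))
    out = []
    for i, b in enumerate(template.genomic_ref_seq):
        if b != "C":
            out.append(b)
            continue
        if i in state_at:
            p = conversion_rate if state_at[i] == UNMETHYLATED else inappropriate_rate
        else:
            p = conversion_rate
        out.append("T" if rng.random() < p else "C")
    return "".join(out)


def _convert_batch(
    template: AmpliconTemplate,
    unmeth_rows: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised conversion + sequencing error for ``len(unmeth_rows)``
    molecules of one marker.

    ``unmeth_rows`` is a boolean (n, n_cpgs) matrix of per-CpG
    unmethylated states.  Returns a uint8 (n, L) base matrix.  Same
    per-base rules as :func:`bisulfite_convert` followed by uniform
    substitution errors at ``cfg.seq_error_rate``.
    """
    n = unmeth_rows.shape[0]
    base = np.frombuffer(template.genomic_ref_seq.encode("ascii"), dtype=np.uint8)
    mat = np.tile(base, (n, 1))
    cpg_pos = np.asarray(template.cpg_offsets, dtype=np.intp)
    non_cpg_c = np.asarray(
        [i for i in np.flatnonzero(base == _C) if i not in set(template.cpg_offsets)],
        dtype=np.intp,
    )
    if non_cpg_c.size:
        conv = rng.random((n, non_cpg_c.size)) < cfg.bisulfite_conversion_rate
        cols = np.broadcast_to(non_cpg_c, conv.shape)
        mat[np.nonzero(conv)[0], cols[conv]] = _T
    if cpg_pos.size:
        p = np.where(
            unmeth_rows, cfg.bisulfite_conversion_rate, cfg.inappropriate_conversion_rate
        )
        conv = rng.random((n, cpg_pos.size)) < p
        cols = np.broadcast_to(cpg_pos, conv.shape)
        mat[np.nonzero(conv)[0], cols[conv]] = _T
    if cfg.seq_error_rate > 0:
        err = rng.random(mat.shape) < cfg.seq_error_rate
        if err.any():
            idx = np.searchsorted(_BASES, mat[err])
            shift = rng.integers(1, 4, size=idx.size)
            mat[err] = _BASES[(idx + shift) % 4]
    return mat


def simulate_sample_reads(
    panel: MarkerPanel,
    sample_id: str,
    barcode: str,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[tuple[str, str, str]], dict[str, tuple[int, int]]]:
    """Simulate one sample's reads entirely in memory.

    Returns ``(records, truth)`` where ``records`` is a list of FASTQ-style
    ``(title, sequence, quality)`` triples (title carries the barcode as
    the last colon-separated field, Illumina index convention) and
    ``truth`` maps marker_id to ``(n_molecules, n_truly_unmethylated)``.

    This is the scalable path used for deep simulations; it draws the
    per-marker unmethylated count binomially and converts molecules in a
    vectorised batch, which is distributionally identical to building
    individual :class:`MoleculePattern` objects.
    """
    cfg.validate()
    qual = chr(cfg.quality_q + 33)
    records: list[tuple[str, str, str]] = []
    truth: dict[str, tuple[int, int]] = {}
    for template in panel:
        n = cfg.n_molecules_per_marker
        n_u = int(rng.binomial(n, cfg.target_fraction))
        unmeth = np.zeros((n, template.n_cpgs), dtype=bool)
        unmeth[:n_u] = True
        if cfg.background_flip_rate > 0 and n > n_u:
            unmeth[n_u:] = rng.random((n - n_u, template.n_cpgs)) < cfg.background_flip_rate
        mat = _convert_batch(template, unmeth, cfg, rng)
        qline = qual * template.amplicon_length
        for j in range(n):
            title = f"SIM:{sample_id}:{template.marker_id}:{j} 1:N:0:{barcode}"
            seq = mat[j].tobytes().decode("ascii")
            if cfg.barcode_mode == "inline":
                title = f"SIM:{sample_id}:{template.marker_id}:{j}"
                seq = barcode + seq
                records.append((title, seq, qual * len(seq)))
            else:
                records.append((title, seq, qline))
        truth[template.marker_id] = (n, n_u)
    return records, truth


def emit_fastq(
    molecules_by_sample: Mapping[str, Sequence[MoleculePattern]],
    panel: MarkerPanel,
    cfg: SimulationConfig,
    out_dir: str | Path,
    name: str = "reads",
) -> dict[str, Path]:
    """Write one multiplexed FASTQ plus a truth table for explicit molecules.

    One read per molecule; barcodes from ``cfg.barcode_map`` are placed in
    the header (field after the last colon) or as an inline prefix
    depending on ``cfg.barcode_mode``.  Per-base substitution errors are
    applied at ``cfg.seq_error_rate``.  The truth TSV records every
    molecule's sample, marker, origin and CpG states ("M"/"U" string) —
    it is the oracle for downstream recovery tests, not an assay output.
    """
    cfg.validate()
    if cfg.barcode_map is None:
        raise ValueError("cfg.barcode_map is required to emit FASTQ")
    missing = set(molecules_by_sample) - set(cfg.barcode_map)
    if missing:
        raise ValueError(f"samples without barcode: {sorted(missing)}")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fastq_path = out_dir / f"{name}.fastq"
    truth_path = out_dir / f"{name}.truth.tsv"
    rng = np.random.default_rng(cfg.seed)
    qual_char = chr(cfg.quality_q + 33)

    try:
        with fastq_path.open("w") as fq, truth_path.open("w") as tr:
            tr.write("read_id\tsample_id\tmarker_id\torigin\tcpg_states\n")
            for sample_id, molecules in molecules_by_sample.items():
                barcode = cfg.barcode_map[sample_id]
                for j, mol in enumerate(molecules):
                    template = panel[mol.marker_id]
                    unmeth = np.array(
                        [[s == UNMETHYLATED for s in mol.cpg_states]], dtype=bool
                    )
                    seq = _convert_batch(template, unmeth, cfg, rng)[0].tobytes().decode()
                    read_id = f"SIM:{sample_id}:{j}"
                    if cfg.barcode_mode == "inline":
                        title = read_id
                        seq = barcode + seq
                    else:
                        title = f"{read_id} 1:N:0:{barcode}"
                    fq.write(f"@{title}\n{seq}\n+\n{qual_char * len(seq)}\n")
                    tr.write(
                        f"{read_id}\t{sample_id}\t{mol.marker_id}\t{mol.origin}\t"
                        f"{''.join(mol.cpg_states)}\n"
                    )
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"failed writing FASTQ output under {out_dir}: {exc}") from exc
    return {"fastq": fastq_path, "truth": truth_path}


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

PG_PER_HAPLOID_GENOME = 3.3  # pg of DNA per haploid human genome


def _draw_cohort_truth(cfg: SimulationConfig, rng: np.random.Generator):
    """Per-sample ground truth: group, brain GE/mL, total cfDNA, doses."""
    import pandas as pd

    cohort = cfg.cohort
    rows = []
    groups = [("patient", cohort.n_cases), ("control", cohort.n_controls)]
    idx = 0
    for group, n in groups:
        brain = (
            cohort.case_brain_ge_per_ml if group == "patient" else cohort.control_brain_ge_per_ml
        ).sample(rng, n)
        total = (
            cohort.case_total_cfdna_ng_per_ml
            if group == "patient"
            else cohort.control_total_cfdna_ng_per_ml
        ).sample(rng, n)
        age = np.clip(np.round(rng.normal(24, 5, n)), 18, 60).astype(int)
        sex = rng.choice(["F", "M"], size=n, p=[0.55, 0.45])
        dose_day = cohort.dose_day_olz_eq.sample(rng, n)
        dose_cum = cohort.dose_cumulative_olz_eq.sample(rng, n)
        for i in range(n):
            idx += 1
            rows.append(
                {
                    "sample_id": f"S{idx:03d}",
                    "group": group,
                    "age": int(age[i]),
                    "sex": sex[i],
                    "total_cfdna_ng_per_ml": float(total[i]),
                    "true_brain_ge_per_ml": float(brain[i]),
                    "dose_day_olz_eq": float(dose_day[i]) if group == "patient" else np.nan,
                    "dose_cumulative_olz_eq": float(dose_cum[i])
                    if group == "patient"
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _target_fraction(brain_ge_per_ml: float, total_cfdna_ng_per_ml: float) -> float:
    """Fraction of molecules that are brain-derived, given concentrations."""
    total_ge = total_cfdna_ng_per_ml * 1000.0 / PG_PER_HAPLOID_GENOME
    if total_ge <= 0:
        return 0.0
    return min(1.0, brain_ge_per_ml / total_ge)


def simulate_cohort_table(
    panel: MarkerPanel, cfg: SimulationConfig, seed: int | None = None
):
    """Fast cohort simulation at the molecule-count level (no reads).

    Draws per-sample concentrations, then per-marker fully-unmethylated
    molecule counts ``Binomial(n, f * c^k)`` where ``f`` is the sample's
    brain fraction, ``c`` the bisulfite conversion rate and ``k`` the
    marker's CpG count (a truly unmethylated molecule is *called* fully
    unmethylated only if every CpG converted).  Quantification then runs
    through the same code as the read-level pipeline.

    Returns ``(cohort, truth)`` DataFrames; ``cohort`` has one row per
    sample with per-marker GE/mL, cell-type signals, combined score and
    dose covariates.
    """
    from . import quant

    cfg.validate()
    if cfg.cohort is None:
        raise ValueError("cfg.cohort is required")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    truth = _draw_cohort_truth(cfg, rng)

    rows = []
    for _, s in truth.iterrows():
        f = _target_fraction(s.true_brain_ge_per_ml, s.total_cfdna_ng_per_ml)
        marker_counts = {}
        for template in panel:
            detect = f * cfg.bisulfite_conversion_rate**template.n_cpgs
            n = cfg.n_molecules_per_marker
            n_u = int(rng.binomial(n, min(1.0, detect)))
            marker_counts[template.marker_id] = (n, n_u)
        summary = quant.quantify_sample(
            marker_counts, float(s.total_cfdna_ng_per_ml), panel, sample_id=s.sample_id
        ).summary
        row = dict(summary)
        for col in (
            "group",
            "age",
            "sex",
            "dose_day_olz_eq",
            "dose_cumulative_olz_eq",
        ):
            row[col] = s[col]
        rows.append(row)

    import pandas as pd

    cohort = pd.DataFrame(rows)
    return cohort, truth


def simulate_cohort(
    panel: MarkerPanel, cfg: SimulationConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Simulate a full cohort to disk: per-sample FASTQ + tables.

    Writes ``<sample>.fastq`` per sample, ``metadata.tsv`` (group, age,
    sex, total cfDNA ng/mL), ``barcodes.tsv``, ``doses.tsv`` (per-patient
    drug records) and ``truth.tsv`` (simulation ground truth).
    """
    cfg.validate()
    if cfg.cohort is None:
        raise ValueError("cfg.cohort is required")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    truth = _draw_cohort_truth(cfg, rng)

    barcodes = _default_barcodes(list(truth.sample_id), rng)
    fastq_dir = out_dir / "fastq"
    fastq_dir.mkdir(exist_ok=True)
    marker_truth_rows = []
    for _, s in truth.iterrows():
        f = _target_fraction(s.true_brain_ge_per_ml, s.total_cfdna_ng_per_ml)
        sample_cfg = dataclasses.replace(cfg, target_fraction=f)
        records, m_truth = simulate_sample_reads(
            panel, s.sample_id, barcodes[s.sample_id], sample_cfg, rng
        )
        with (fastq_dir / f"{s.sample_id}.fastq").open("w") as fq:
            for title, seq, q in records:
                fq.write(f"@{title}\n{seq}\n+\n{q}\n")
        for marker_id, (n, n_u) in m_truth.items():
            marker_truth_rows.append(
                {"sample_id": s.sample_id, "marker_id": marker_id, "n_molecules": n,
                 "n_unmethylated": n_u}
            )

    import pandas as pd

    meta = truth[["sample_id", "group", "age", "sex", "total_cfdna_ng_per_ml"]]
    meta.to_csv(out_dir / "metadata.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"sample_id": list(barcodes), "barcode": list(barcodes.values())}
    ).to_csv(out_dir / "barcodes.tsv", sep="\t", index=False)
    doses = truth.loc[truth.group == "patient", ["sample_id"]].copy()
    doses = pd.concat(
        [
            doses.assign(
                drug_name="olanzapine",
                dose_mg=truth.loc[truth.group == "patient", "dose_day_olz_eq"].values,
                when="day_of_draw",
            ),
            doses.assign(
                drug_name="olanzapine",
                dose_mg=truth.loc[truth.group == "patient", "dose_cumulative_olz_eq"].values,
                when="cumulative_hospitalization",
            ),
        ]
    )
    doses.to_csv(out_dir / "doses.tsv", sep="\t", index=False)
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    pd.DataFrame(marker_truth_rows).to_csv(out_dir / "truth_markers.tsv", sep="\t", index=False)
    return {
        "fastq_dir": fastq_dir,
        "metadata": out_dir / "metadata.tsv",
        "barcodes": out_dir / "barcodes.tsv",
        "doses": out_dir / "doses.tsv",
        "truth": out_dir / "truth.tsv",
    }


def _default_barcodes(sample_ids: Sequence[str], rng: np.random.Generator) -> dict[str, str]:
    """Deterministic distinct 8-mers (Hamming distance >= 3 apart)."""
    codes: dict[str, str] = {}
    chosen: list[np.ndarray] = []
    for sid in sample_ids:
        while True:
            cand = rng.choice(_BASES, size=8)
            if all(int((cand != c).sum()) >= 3 for c in chosen):
                chosen.append(cand)
                codes[sid] = cand.tobytes().decode("ascii")
                break
    return codes
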