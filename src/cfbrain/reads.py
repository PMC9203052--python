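"""Read processing: demultiplex, quality filter, amplicon assignment,
CpG methylation calling.

The pipeline turns raw single-end bisulfite amplicon reads into
per-molecule methylation calls:

1.  **Demultiplex** by barcode (exact match by default), from the read
    header's last colon-separated field (Illumina index convention) or
    from an inline prefix.
2.  **Quality filter**: mean Phred score >= ``min_mean_quality``.
3.  **Amplicon assignment**: edit-distance similarity against each
    target's fully bisulfite-converted sequence, with CpG cytosines as
    the ambiguity code Y (matching C or T) so that methylation state
    cannot bias assignment.  A read passes with similarity >= 0.8
    against its best target.
4.  **CpG calling**: each expected CpG position is mapped through the
    alignment; the read dinucleotide CG calls methylated, TG calls
    unmethylated, anything else (CA, TA, a gap, ...) is ambiguous.  A
    read must cover every expected CpG, and by default any ambiguous
    call discards the molecule — protecting the fully-unmethylated
    statistic from miscalls.

Every read ends in exactly one status category and category counts are
reported, so input reads are conserved across the pipeline.
"""

from __future__ import annotations

import dataclasses
import json
import re
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .panel import AmpliconTemplate, MarkerPanel

STATUS_PASS = "pass"
STATUS_FAIL_QUALITY = "fail_quality"
STATUS_FAIL_SIMILARITY = "fail_similarity"
STATUS_FAIL_MISSING_CPG = "fail_missing_cpg"
STATUS_FAIL_AMBIGUOUS_CPG = "fail_ambiguous_cpg"
STATUS_UNASSIGNED = "unassigned"
ALL_STATUSES = (
    STATUS_PASS,
    STATUS_FAIL_QUALITY,
    STATUS_FAIL_SIMILARITY,
    STATUS_FAIL_MISSING_CPG,
    STATUS_FAIL_AMBIGUOUS_CPG,
    STATUS_UNASSIGNED,
)

#: Equalities handed to edlib so Y matches either pyrimidine.
_Y_EQUALITIES = [("Y", "C"), ("Y", "T")]

_CIGAR_RE = re.compile(r"(\d+)([=XMID])")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclasses.dataclass
class ReadProcessingConfig:
    """Thresholds and modes of the read pipeline (all config-exposed)."""

    min_mean_quality: float = 30.0
    min_similarity: float = 0.8
    barcode_mode: str = "header"  # "header" | "inline"
    barcode_mismatches: int = 0
    lenient_ambiguous: bool = False  # ambiguous CpG -> drop site instead of read
    search_reverse_complement: bool = False


@dataclasses.dataclass(frozen=True)
class MoleculeCall:
    """One read's methylation call with provenance.

    ``pattern`` is a string over {C, T, ?} in CpG order: C = methylated
    (CG read), T = unmethylated (TG read), ? = ambiguous.
    """

    read_id: str
    sample_id: str
    marker_id: str | None
    status: str
    similarity: float
    pattern: str

    @property
    def fully_unmethylated(self) -> bool:
        return self.status == STATUS_PASS and set(self.pattern) <= {"T"} and self.pattern != ""


# --------------------------------------------------------------------------
# FASTQ input and demultiplexing
# --------------------------------------------------------------------------


def parse_fastq(path: str | Path) -> Iterable[tuple[str, str, str]]:
    """Yield ``(title, sequence, quality)`` triples from a FASTQ file."""
    with open(path) as fh:
        yield from FastqGeneralIterator(fh)


def demultiplex(
    records: Iterable[tuple[str, str, str]],
    barcode_map: Mapping[str, str],
    mode: str = "header",
    mismatches: int = 0,
) -> tuple[dict[str, list[tuple[str, str, str]]], list[tuple[str, str, str]]]:
    """Split reads by barcode; returns ``(per_sample, unassigned)``.

    ``mode="header"`` takes the barcode from the last colon-separated
    field of the read title; ``mode="inline"`` matches a fixed-length
    prefix of the sequence and strips it (with its qualities) from the
    assigned read.  Assignment is exact by default; ``mismatches=1``
    accepts a unique barcode within Hamming distance 1.
    """
    codes = list(barcode_map.values())
    if len(codes) != len(set(codes)):
        raise ValueError("duplicate barcodes in barcode map")
    if mode not in ("header", "inline"):
        raise ValueError(f"unknown demultiplex mode {mode!r}")
    if mode == "inline" and len({len(c) for c in codes}) > 1:
        raise ValueError("inline barcodes must share one length")
    by_code = {v: k for k, v in barcode_map.items()}
    blen = len(codes[0]) if codes else 0

    bins: dict[str, list[tuple[str, str, str]]] = {s: [] for s in barcode_map}
    unassigned: list[tuple[str, str, str]] = []
    for title, seq, qual in records:
        observed = title.rsplit(":", 1)[-1] if mode == "header" else seq[:blen]
        sample = by_code.get(observed)
        if sample is None and mismatches > 0 and observed:
            near = [c for c in codes if _hamming(observed, c) <= mismatches]
            if len(near) == 1:
                sample = by_code[near[0]]
        if sample is None:
            unassigned.append((title, seq, qual))
        elif mode == "inline":
            bins[sample].append((title, seq[blen:], qual[blen:]))
        else:
            bins[sample].append((title, seq, qual))
    return bins, unassigned


def _hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(x != y for x, y in zip(a, b))


def mean_quality(qualities: str) -> float:
    """Mean Phred score of a Phred+33 quality string (NaN when empty)."""
    if not qualities:
        return float("nan")
    arr = np.frombuffer(qualities.encode("ascii"), dtype=np.uint8)
    return float(arr.mean()) - 33.0


def quality_filter(qualities: str, min_mean_q: float = 30.0) -> bool:
    """Pass iff mean Phred >= threshold (boundary value passes)."""
    q = mean_quality(qualities)
    return bool(q >= min_mean_q)


# --------------------------------------------------------------------------
# Amplicon matching and CpG calling
# --------------------------------------------------------------------------


def _cigar_target_to_query(cigar: str) -> dict[int, int | None]:
    """Map target positions to query positions through an edlib cigar.

    Deleted target positions (op ``D``) map to None.  Query-only bases
    (op ``I``) advance the query cursor.
    """
    mapping: dict[int, int | None] = {}
    qpos = tpos = 0
    for count, op in _CIGAR_RE.findall(cigar):
        n = int(count)
        if op in "=XM":
            for _ in range(n):
                mapping[tpos] = qpos
                tpos += 1
                qpos += 1
        elif op == "D":  # present in target, absent from read
            for _ in range(n):
                mapping[tpos] = None
                tpos += 1
        else:  # "I": present in read only
            qpos += n
    return mapping


class AmpliconMatcher:
    """Assigns reads to panel amplicons and calls their CpG states.

    Results are memoised per distinct read sequence: amplicon reads are
    highly redundant (most molecules convert cleanly and sequence without
    error), so deep samples hit the cache for the large majority of
    reads.
    """

    def __init__(self, panel: MarkerPanel, config: ReadProcessingConfig | None = None):
        if len(panel) == 0:
            raise ValueError("empty marker panel")
        self.panel = panel
        self.config = config or ReadProcessingConfig()
        self._targets = [(a.marker_id, a.converted_target()) for a in panel]
        self._templates = {a.marker_id: a for a in panel}
        self._cache: dict[str, tuple[str | None, str, float, str]] = {}

    # -- matching ----------------------------------------------------------

    def match(self, sequence: str) -> tuple[str | None, float]:
        """Best marker and edit-distance similarity for one read.

        similarity = 1 - edit_distance / target_length, computed against
        the Y-converted target.  Returns ``(None, 0.0)`` when the read is
        shorter than half of every target.  Ties go to panel order.
        """
        best_id, best_sim = None, -1.0
        candidates = [sequence]
        if self.config.search_reverse_complement:
            candidates.append(sequence.translate(_COMPLEMENT)[::-1])
        for marker_id, target in self._targets:
            if all(len(c) < 0.5 * len(target) for c in candidates):
                continue
            for cand in candidates:
                res = edlib.align(
                    cand, target, mode="NW", task="distance",
                    additionalEqualities=_Y_EQUALITIES,
                )
                sim = 1.0 - res["editDistance"] / len(target)
                if sim > best_sim:
                    best_id, best_sim = marker_id, sim
        if best_id is None:
            return None, 0.0
        return best_id, best_sim

    # -- calling -----------------------------------------------------------

    def call_cpgs(self, sequence: str, template: AmpliconTemplate) -> tuple[str, str]:
        """Call CpG states for a read assigned to ``template``.

        Returns ``(pattern, status)`` with pattern over {C, T, ?}: CG at
        an expected site reads methylated (C), TG unmethylated (T),
        anything else ambiguous (?).  Status is ``pass``,
        ``fail_missing_cpg`` (read does not cover every expected CpG) or
        ``fail_ambiguous_cpg`` (strict mode) per the configured policy.
        """
        seq = sequence
        if self.config.search_reverse_complement:
            fwd = edlib.align(
                seq, template.converted_target(), mode="NW", task="distance",
                additionalEqualities=_Y_EQUALITIES,
            )["editDistance"]
            rc = seq.translate(_COMPLEMENT)[::-1]
            rev = edlib.align(
                rc, template.converted_target(), mode="NW", task="distance",
                additionalEqualities=_Y_EQUALITIES,
            )["editDistance"]
            if rev < fwd:
                seq = rc
        res = edlib.align(
            seq, template.converted_target(), mode="NW", task="path",
            additionalEqualities=_Y_EQUALITIES,
        )
        mapping = _cigar_target_to_query(res["cigar"])
        qlen = len(seq)
        states: list[str] = []
        missing = False
        for o in template.cpg_offsets:
            qc, qg = mapping.get(o), mapping.get(o + 1)
            if qc is None or qg is None:
                # distinguish "read too short to reach the site" from an
                # internal gap: leading/trailing deletions mean no query
                # base anywhere past the site
                if _is_boundary_gap(mapping, o) or _is_boundary_gap(mapping, o + 1):
                    missing = True
                    states.append("?")
                else:
                    states.append("?")
                continue
            dinuc = seq[qc] + (seq[qg] if qg < qlen else "")
            if dinuc == "CG":
                states.append("C")
            elif dinuc == "TG":
                states.append("T")
            else:
                states.append("?")
        pattern = "".join(states)
        if missing:
            return pattern, STATUS_FAIL_MISSING_CPG
        if "?" in pattern:
            if self.config.lenient_ambiguous and pattern.count("?") < len(pattern):
                return pattern, STATUS_PASS
            return pattern, STATUS_FAIL_AMBIGUOUS_CPG
        return pattern, STATUS_PASS

    def call(self, sequence: str) -> tuple[str | None, str, float, str]:
        """Memoised match + CpG call: ``(marker_id, status, similarity, pattern)``."""
        hit = self._cache.get(sequence)
        if hit is not None:
            return hit
        marker_id, sim = self.match(sequence)
        if marker_id is None:
            out = (None, STATUS_UNASSIGNED, 0.0, "")
        elif sim < self.config.min_similarity:
            out = (marker_id, STATUS_FAIL_SIMILARITY, sim, "")
        else:
            pattern, status = self.call_cpgs(sequence, self._templates[marker_id])
            out = (marker_id, status, sim, pattern)
        self._cache[sequence] = out
        return out


def _is_boundary_gap(mapping: dict[int, int | None], tpos: int) -> bool:
    """True when target position ``tpos`` is deleted and lies outside the
    aligned span of the read (i.e. the read simply does not reach it)."""
    if mapping.get(tpos) is not None:
        return False
    before = any(v is not None for k, v in mapping.items() if k < tpos)
    after = any(v is not None for k, v in mapping.items() if k > tpos)
    return not (before and after)


# --------------------------------------------------------------------------
# Per-sample processing
# --------------------------------------------------------------------------


@dataclasses.dataclass
class SampleReadResult:
    """Aggregated per-sample outcome of the read pipeline."""

    sample_id: str
    status_counts: Counter
    marker_counts: dict[str, dict[str, int]]  # marker -> {n_pass, n_fully_unmethylated, ...}
    calls: list[MoleculeCall] | None = None

    @property
    def n_reads(self) -> int:
        return sum(self.status_counts.values())

    def pass_counts(self) -> dict[str, tuple[int, int]]:
        """marker_id -> (n_pass, n_fully_unmethylated)."""
        return {
            m: (c["n_pass"], c["n_fully_unmethylated"]) for m, c in self.marker_counts.items()
        }


def process_sample(
    records: Iterable[tuple[str, str, str]],
    matcher: AmpliconMatcher,
    sample_id: str = "sample",
    collect_calls: bool = False,
) -> SampleReadResult:
    """Run quality filtering, amplicon assignment and CpG calling.

    ``records`` are demultiplexed ``(title, sequence, quality)`` triples.
    Aggregates per-marker pass / fully-unmethylated counts; set
    ``collect_calls`` to also retain one :class:`MoleculeCall` per read
    (memory-heavy for deep samples).
    """
    cfg = matcher.config
    status_counts: Counter = Counter()
    marker_counts: dict[str, dict[str, int]] = {
        a.marker_id: {s: 0 for s in ALL_STATUSES} | {"n_pass": 0, "n_fully_unmethylated": 0}
        for a in matcher.panel
    }
    calls: list[MoleculeCall] | None = [] if collect_calls else None
    qual_cache: dict[str, bool] = {}

    for title, seq, qual in records:
        read_id = title.split(" ", 1)[0]
        ok = qual_cache.get(qual)
        if ok is None:
            ok = quality_filter(qual, cfg.min_mean_quality)
            qual_cache[qual] = ok
        if not ok:
            status_counts[STATUS_FAIL_QUALITY] += 1
            if calls is not None:
                calls.append(MoleculeCall(read_id, sample_id, None, STATUS_FAIL_QUALITY, 0.0, ""))
            continue
        marker_id, status, sim, pattern = matcher.call(seq)
        status_counts[status] += 1
        if marker_id is not None:
            mc = marker_counts[marker_id]
            mc[status] += 1
            if status == STATUS_PASS:
                mc["n_pass"] += 1
                if pattern and set(pattern) <= {"T"}:
                    mc["n_fully_unmethylated"] += 1
        if calls is not None:
            calls.append(MoleculeCall(read_id, sample_id, marker_id, status, sim, pattern))
    return SampleReadResult(sample_id, status_counts, marker_counts, calls)


def write_calls_tsv(calls: Sequence[MoleculeCall], path: str | Path) -> Path:
    """Per-read molecule-call TSV: read_id, marker, status, similarity, pattern."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("read_id\tsample_id\tmarker_id\tstatus\tsimilarity\tpattern\n")
        for c in calls:
            fh.write(
                f"{c.read_id}\t{c.sample_id}\t{c.marker_id or '.'}\t{c.status}\t"
                f"{c.similarity:.4f}\t{c.pattern or '.'}\n"
            )
    return path


def write_run_report(
    results: Mapping[str, SampleReadResult], n_unassigned: int, path: str | Path
) -> Path:
    """JSON run report with per-sample status category counts."""
    payload = {
        "n_unassigned_reads": n_unassigned,
        "samples": {
            sid: {
                "n_reads": r.n_reads,
                "status_counts": dict(r.status_counts),
            }
            for sid, r in results.items()
        },
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path
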