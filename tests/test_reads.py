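"""Demultiplexing, quality filtering, amplicon matching and CpG calling."""

import numpy as np
import pytest

from cfbrain.reads import (
    STATUS_FAIL_AMBIGUOUS_CPG,
    STATUS_FAIL_MISSING_CPG,
    STATUS_FAIL_SIMILARITY,
    STATUS_PASS,
    AmpliconMatcher,
    ReadProcessingConfig,
    demultiplex,
    mean_quality,
    process_sample,
    quality_filter,
)
from cfbrain.simulate import SimulationConfig, simulate_sample_reads

Q37 = chr(37 + 33)


def _rec(seq, barcode="AAAATTTT", qual=None, rid="R1"):
    return (f"{rid} 1:N:0:{barcode}", seq, qual if qual is not None else Q37 * len(seq))


class TestDemultiplex:
    BC = {"S1": "AAAATTTT", "S2": "CCCCGGGG"}

    def test_assignment_and_unassigned_conserve_reads(self):
        records = [
            _rec("ACGT", "AAAATTTT"),
            _rec("ACGT", "CCCCGGGG"),
            _rec("ACGT", "GGGGGGGG"),
        ]
        bins, unassigned = demultiplex(records, self.BC)
        assert len(bins["S1"]) == 1 and len(bins["S2"]) == 1 and len(unassigned) == 1
        assert sum(map(len, bins.values())) + len(unassigned) == len(records)

    def test_duplicate_barcodes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            demultiplex([], {"S1": "AAAA", "S2": "AAAA"})

    def test_inline_mode_strips_prefix(self):
        records = [("R1", "AAAATTTTACGT", "I" * 12)]
        bins, unassigned = demultiplex(records, self.BC, mode="inline")
        assert bins["S1"] == [("R1", "ACGT", "IIII")]
        assert not unassigned

    def test_one_mismatch_tolerance(self):
        rec = _rec("ACGT", "AAAATTTA")  # one substitution off S1's barcode
        assert demultiplex([rec], self.BC)[1] == [rec]  # exact mode: unassigned
        bins, unassigned = demultiplex([rec], self.BC, mismatches=1)
        assert len(bins["S1"]) == 1 and not unassigned


class TestQualityFilter:
    def test_q37_passes_q2_fails_default_threshold(self):
        assert quality_filter(Q37 * 50, 30.0)
        assert not quality_filter(chr(2 + 33) * 50, 30.0)

    def test_boundary_mean_passes(self):
        assert quality_filter(chr(30 + 33) * 10, 30.0)

    def test_empty_read_fails(self):
        assert np.isnan(mean_quality(""))
        assert not quality_filter("", 30.0)


class TestMatchToAmplicon:
    def test_error_free_read_self_matches(self, small_panel, small_matcher):
        for a in small_panel:
            read = a.converted_target().replace("Y", "T")
            marker, sim = small_matcher.match(read)
            assert marker == a.marker_id
            assert sim >= 0.99

    def test_methylation_state_does_not_change_similarity(self, small_panel, small_matcher):
        a = small_panel.amplicons[0]
        unmeth = a.converted_target().replace("Y", "T")
        meth = a.converted_target().replace("Y", "C")
        assert small_matcher.match(unmeth)[1] == small_matcher.match(meth)[1]

    def test_heavily_corrupted_read_fails_similarity(self, small_panel, small_matcher):
        a = small_panel.amplicons[0]
        read = list(a.converted_target().replace("Y", "T"))
        rng = np.random.default_rng(0)
        pos = rng.choice(len(read), size=int(0.3 * len(read)), replace=False)
        for p in pos:  # force substitutions at 30% of positions
            read[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[p]]
        read = "".join(read)
        marker, sim = small_matcher.match(read)
        assert sim < 0.8
        result = small_matcher.call(read)
        assert result[1] == STATUS_FAIL_SIMILARITY

    def test_short_fragment_unassigned(self, small_matcher):
        assert small_matcher.call("ACGTACGT")[1] == "unassigned"


class TestCallCpgs:
    def _read(self, template, cpg_base, mutate=None):
        chars = list(template.converted_target().replace("Y", cpg_base))
        if mutate:
            for pos, b in mutate.items():
                chars[pos] = b
        return "".join(chars)

    def test_all_cg_calls_methylated(self, small_panel, small_matcher):
        a = small_panel.amplicons[0]
        pattern, status = small_matcher.call_cpgs(self._read(a, "C"), a)
        assert status == STATUS_PASS
        assert pattern == "C" * a.n_cpgs

    def test_all_tg_calls_unmethylated(self, small_panel, small_matcher):
        a = small_panel.amplicons[0]
        pattern, status = small_matcher.call_cpgs(self._read(a, "T"), a)
        assert status == STATUS_PASS
        assert pattern == "T" * a.n_cpgs

    def test_ca_dinucleotide_is_ambiguous_and_fails(self, small_panel, small_matcher):
        a = small_panel.amplicons[0]
        read = self._read(a, "C", mutate={a.cpg_offsets[0] + 1: "A"})
        pattern, status = small_matcher.call_cpgs(read, a)
        assert status == STATUS_FAIL_AMBIGUOUS_CPG
        assert pattern[0] == "?"

    def test_lenient_mode_keeps_partially_called_molecule(self, small_panel):
        lenient = AmpliconMatcher(small_panel, ReadProcessingConfig(lenient_ambiguous=True))
        a = small_panel.amplicons[0]
        read = self._read(a, "T", mutate={a.cpg_offsets[0] + 1: "A"})
        pattern, status = lenient.call_cpgs(read, a)
        assert status == STATUS_PASS and pattern[0] == "?"

    def test_truncated_read_missing_terminal_cpg(self, small_panel, small_matcher):
        a = small_panel.amplicons[0]
        read = self._read(a, "T")[: a.cpg_offsets[-1]]  # stops before last CpG
        pattern, status = small_matcher.call_cpgs(read, a)
        assert status == STATUS_FAIL_MISSING_CPG

    def test_internal_deletion_at_cpg_is_ambiguous(self, small_panel, small_matcher):
        a = small_panel.amplicons[0]
        o = a.cpg_offsets[0]
        full = self._read(a, "T")
        read = full[:o] + full[o + 1 :]  # drop the CpG's pyrimidine base
        pattern, status = small_matcher.call_cpgs(read, a)
        assert "?" in pattern
        assert status in (STATUS_FAIL_AMBIGUOUS_CPG, STATUS_FAIL_MISSING_CPG)


class TestProcessSample:
    def _simulate(self, panel, **overrides):
        cfg = SimulationConfig(
            seed=17,
            n_molecules_per_marker=300,
            target_fraction=0.2,
            bisulfite_conversion_rate=1.0,
            inappropriate_conversion_rate=0.0,
            seq_error_rate=0.0,
        )
        for k, v in overrides.items():
            setattr(cfg, k, v)
        rng = np.random.default_rng(17)
        return simulate_sample_reads(panel, "S1", "AAAATTTT", cfg, rng)

    def test_error_free_data_fully_recovered(self, small_panel, small_matcher):
        records, truth = self._simulate(small_panel)
        res = process_sample(records, small_matcher, "S1")
        assert res.status_counts == {STATUS_PASS: len(records)}
        assert res.pass_counts() == truth

    def test_status_counts_conserve_reads(self, small_panel, small_matcher):
        records, _ = self._simulate(
            small_panel, bisulfite_conversion_rate=0.9, seq_error_rate=0.02
        )
        res = process_sample(records, small_matcher, "S1")
        assert res.n_reads == len(records)

    def test_raising_quality_threshold_never_increases_passes(self, small_panel):
        rng = np.random.default_rng(1)
        records, _ = self._simulate(small_panel)
        # mixed quality strings around the threshold
        records = [
            (t, s, chr(int(q) + 33) * len(s))
            for (t, s, _), q in zip(records, rng.integers(20, 40, len(records)))
        ]
        passes = []
        for min_q in (20, 30, 35, 41):
            matcher = AmpliconMatcher(
                small_panel, ReadProcessingConfig(min_mean_quality=min_q)
            )
            res = process_sample(records, matcher, "S1")
            passes.append(res.status_counts.get(STATUS_PASS, 0))
        assert passes == sorted(passes, reverse=True)

    def test_collect_calls_returns_one_call_per_read(self, small_panel, small_matcher):
        records, _ = self._simulate(small_panel)
        res = process_sample(records[:10], small_matcher, "S1", collect_calls=True)
        assert len(res.calls) == 10
        assert all(c.status == STATUS_PASS for c in res.calls)


def test_empty_panel_rejected():
    from cfbrain.panel import MarkerPanel

    with pytest.raises(ValueError):
        AmpliconMatcher(MarkerPanel(()))
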