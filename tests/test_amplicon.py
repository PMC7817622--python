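"""Amplicon read calling: alignment, QC, summaries, pattern maps."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import reverse_complement

from epiedit.amplicon import (
    ReadCall,
    ReadCallMatrix,
    UnalignableReadError,
    align_read,
    call_read,
    classify_reads,
    convert_reference,
    filter_reads,
    pattern_map,
    summarize,
)
from epiedit.simulate import ReadSimConfig, simulate_bisulfite_reads


def converted_reference(design):
    return design.reference.replace("C", "T")


def fully_methylated_read(design):
    """All CpG Cs intact, all other Cs converted."""
    cpgs = set(design.cpg_positions)
    return "".join(
        b if b != "C" or i in cpgs else "T" for i, b in enumerate(design.reference)
    )


class TestConvertReference:
    def test_all_cs_become_ts_and_length_preserved(self, tsdr_design):
        conv = convert_reference(tsdr_design)
        assert "C" not in conv
        assert len(conv) == len(tsdr_design.reference)

    def test_non_c_bases_untouched(self, tsdr_design):
        conv = convert_reference(tsdr_design)
        for a, b in zip(tsdr_design.reference, conv):
            assert b == ("T" if a == "C" else a)


class TestAlignRead:
    def test_perfect_read_full_score(self, tsdr_design):
        read = converted_reference(tsdr_design)
        aln = align_read(read, tsdr_design)
        assert aln.score == len(tsdr_design.reference)
        assert aln.strand == "+"
        assert all(aln.ref_to_read[i] == i for i in range(len(read)))

    def test_single_substitution_identity(self, tsdr_design):
        read = list(fully_methylated_read(tsdr_design))
        # substitute one non-C reference column (an A) by G
        pos = tsdr_design.reference.index("A")
        read[pos] = "G"
        call = call_read(align_read("".join(read), tsdr_design), tsdr_design)
        ref = tsdr_design.reference
        n_non_c = sum(1 for b in ref if b != "C")
        assert call.identity == pytest.approx((n_non_c - 1) / n_non_c)

    def test_junk_read_unalignable(self, tsdr_design):
        rng = np.random.default_rng(0)
        junk = "".join(rng.choice(list("ACGT"), 120))
        with pytest.raises(UnalignableReadError):
            align_read(junk, tsdr_design)

    def test_too_short_read_rejected(self, tsdr_design):
        with pytest.raises(UnalignableReadError, match="shorter"):
            align_read("ACGTACGT", tsdr_design)

    def test_reverse_complement_read_recovered(self, tsdr_design):
        read = reverse_complement(fully_methylated_read(tsdr_design))
        aln = align_read(read, tsdr_design)
        assert aln.strand == "-"
        call = call_read(aln, tsdr_design)
        assert set(call.calls) == {"M"}


class TestCallRead:
    def test_fully_methylated_calls(self, tsdr_design):
        call = call_read(
            align_read(fully_methylated_read(tsdr_design), tsdr_design), tsdr_design
        )
        assert set(call.calls) == {"M"}
        assert call.conversion_rate == 1.0
        assert call.cpg_coverage == 1.0

    def test_fully_converted_calls_all_u(self, tsdr_design):
        call = call_read(
            align_read(converted_reference(tsdr_design), tsdr_design), tsdr_design
        )
        assert set(call.calls) == {"U"}

    def test_partial_conversion_rate(self, tsdr_design):
        # leave 3 of the 15 non-CpG Cs unconverted: rate = 12/15 = 0.8
        cpgs = set(tsdr_design.cpg_positions)
        non_cpg_c = [i for i, b in enumerate(tsdr_design.reference) if b == "C" and i not in cpgs]
        keep_c = set(non_cpg_c[:3])
        read = "".join(
            b if b != "C" or i in cpgs or i in keep_c else "T"
            for i, b in enumerate(tsdr_design.reference)
        )
        call = call_read(align_read(read, tsdr_design), tsdr_design)
        assert call.conversion_rate == pytest.approx(12 / 15)


def _matrix(design, rows, ids=None):
    ids = ids or [f"r{i}" for i in range(len(rows))]
    return ReadCallMatrix.from_calls(ids, rows, design)


def _row(design, calls, conv=1.0, ident=1.0):
    cov = sum(c != "." for c in calls) / len(calls)
    return ReadCall(tuple(calls), conv, ident, cov)


class TestFilterReads:
    def test_clean_rows_all_retained(self, tsdr_design):
        rows = [_row(tsdr_design, ["M"] * 15) for _ in range(4)]
        filtered, report = filter_reads(_matrix(tsdr_design, rows))
        assert filtered.n_reads == 4
        assert report["rejected"] == 0

    def test_incomplete_conversion_rejected(self, tsdr_design):
        rows = [_row(tsdr_design, ["M"] * 15, conv=0.5)]
        filtered, report = filter_reads(_matrix(tsdr_design, rows))
        assert filtered.n_reads == 0
        assert report["incomplete_conversion"] == 1

    def test_zero_thresholds_keep_everything(self, tsdr_design):
        rows = [_row(tsdr_design, ["."] * 15, conv=0.0, ident=0.0)]
        filtered, report = filter_reads(
            _matrix(tsdr_design, rows), 0.0, 0.0, 0.0
        )
        assert filtered.n_reads == 1

    def test_idempotent_and_conserving(self, tsdr_design):
        rows = [
            _row(tsdr_design, ["M"] * 15),
            _row(tsdr_design, ["U"] * 15, conv=0.2),
            _row(tsdr_design, ["M"] * 7 + ["."] * 8),
        ]
        m = _matrix(tsdr_design, rows)
        once, report = filter_reads(m)
        assert report["retained"] + report["rejected"] == m.n_reads
        twice, report2 = filter_reads(once)
        pd.testing.assert_frame_equal(once.calls, twice.calls)
        assert report2["rejected"] == 0


class TestSummarize:
    def test_all_methylated(self, tsdr_design):
        m = _matrix(tsdr_design, [_row(tsdr_design, ["M"] * 15)] * 3)
        s = summarize(m)
        assert s.overall == pytest.approx(100.0)
        assert s.per_cpg == pytest.approx((100.0,) * 15)

    def test_half_methylated_overall(self, tsdr_design):
        rows = [
            _row(tsdr_design, ["M", "U"] + ["."] * 13),
            _row(tsdr_design, ["U", "M"] + ["."] * 13),
            _row(tsdr_design, ["M", "U"] + ["."] * 13),
        ]
        s = summarize(_matrix(tsdr_design, rows))
        assert s.overall == pytest.approx(50.0)

    def test_uncovered_column_reported_nan(self, tsdr_design):
        m = _matrix(tsdr_design, [_row(tsdr_design, ["M"] * 14 + ["."])] * 2)
        s = summarize(m)
        assert np.isnan(s.per_cpg[-1])
        assert s.per_cpg[0] == pytest.approx(100.0)

    def test_empty_matrix_raises(self, tsdr_design):
        m = _matrix(tsdr_design, [])
        with pytest.raises(ValueError, match="empty"):
            summarize(m)

    def test_parameter_recovery_per_cpg(self, tsdr_design):
        # per-CpG truth probabilities recovered within 3 binomial SEs
        from epiedit.amplicon import call_fastq

        p = np.linspace(0.1, 0.9, 15)
        cfg = ReadSimConfig(
            n_reads=5000, components=[(1.0, tuple(p))], seed=21
        )
        records, _ = simulate_bisulfite_reads(tsdr_design, cfg)
        matrix, _ = call_fastq(records, tsdr_design)
        est = np.array(summarize(matrix).per_cpg) / 100
        se = np.sqrt(p * (1 - p) / matrix.n_reads)
        assert np.all(np.abs(est - p) < 3 * se)


class TestPatternMap:
    def test_single_read(self, tsdr_design):
        m = _matrix(tsdr_design, [_row(tsdr_design, ["M"] * 15)])
        assert len(pattern_map(m)) == 1

    def test_multiset_preserved(self, tsdr_design):
        rows = [
            _row(tsdr_design, ["M", "U"] * 7 + ["M"]),
            _row(tsdr_design, ["U"] * 15),
            _row(tsdr_design, ["M"] * 15),
        ]
        m = _matrix(tsdr_design, rows)
        table = pattern_map(m)
        orig = sorted("".join(r) for _, r in m.calls.iterrows())
        new = sorted("".join(r) for _, r in table.iterrows())
        assert orig == new

    def test_methylated_reads_first(self, tsdr_design):
        rows = [_row(tsdr_design, ["U"] * 15), _row(tsdr_design, ["M"] * 15)]
        table = pattern_map(_matrix(tsdr_design, rows))
        assert "".join(table.iloc[0]) == "M" * 15

    def test_summary_invariant_under_reordering(self, tsdr_design):
        rng = np.random.default_rng(5)
        rows = [
            _row(tsdr_design, list(rng.choice(["M", "U"], 15))) for _ in range(20)
        ]
        m = _matrix(tsdr_design, rows)
        reordered = ReadCallMatrix(pattern_map(m), m.qc.loc[pattern_map(m).index])
        assert summarize(m).overall == pytest.approx(summarize(reordered).overall)


class TestClassifyReads:
    def test_extremes_and_heterogeneous(self, tsdr_design):
        rows = [
            _row(tsdr_design, ["U"] * 15),
            _row(tsdr_design, ["M"] * 15),
            _row(tsdr_design, ["M"] * 7 + ["U"] * 8),
        ]
        profile = classify_reads(_matrix(tsdr_design, rows))
        assert profile.fully_demethylated == pytest.approx(1 / 3)
        assert profile.fully_methylated == pytest.approx(1 / 3)
        assert profile.heterogeneous == pytest.approx(1 / 3)

    def test_fractions_sum_to_one(self, tsdr_design):
        rng = np.random.default_rng(6)
        rows = [
            _row(tsdr_design, list(rng.choice(["M", "U"], 15))) for _ in range(30)
        ]
        profile = classify_reads(_matrix(tsdr_design, rows))
        total = (
            profile.fully_demethylated
            + profile.fully_methylated
            + profile.heterogeneous
        )
        assert total == pytest.approx(1.0)
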