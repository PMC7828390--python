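"""Spectral-change scoring: CSP/LBE classification, aggregation filter,
specificity calls and peak-list I/O."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragscreen.nmr import (
    CALL_A_SPECIFIC,
    CALL_AGGREGATOR,
    CALL_B_SPECIFIC,
    CALL_DUAL,
    CALL_NON_BINDER,
    PeakList,
    PeakListFormatError,
    ScoringParameters,
    classify_csp,
    classify_lbe,
    classify_specificity,
    compute_csp,
    detect_aggregation,
    read_peak_list,
    score_fragment,
    write_peak_list_csv,
)

from conftest import make_peak

PARAMS = ScoringParameters()


class TestComputeCsp:
    @pytest.mark.parametrize(
        "d_h, d_n, expected",
        [
            (0.0, 0.0, 0.0),
            (0.025, 0.0, 0.025 / math.sqrt(2)),          # 0.01768 ppm
            (0.03, 0.15, math.sqrt(0.5 * (0.03**2 + (0.14 * 0.15) ** 2))),
        ],
    )
    def test_combined_shift_values(self, d_h, d_n, expected):
        ref = make_peak(9)
        bound = make_peak(9, delta_h=8.2 + d_h, delta_n=118.0 + d_n)
        assert compute_csp(ref, bound, PARAMS) == pytest.approx(expected, abs=1e-9)

    def test_hand_checked_magnitudes(self):
        ref = make_peak(9)
        assert compute_csp(ref, make_peak(9, delta_h=8.225), PARAMS) == pytest.approx(
            0.01768, abs=5e-6
        )
        bound = make_peak(9, delta_h=8.23, delta_n=118.15)
        assert compute_csp(ref, bound, PARAMS) == pytest.approx(0.02589, abs=5e-6)

    def test_mismatched_keys_rejected(self):
        with pytest.raises(ValueError, match="keys differ"):
            compute_csp(make_peak(9), make_peak(10), PARAMS)

    @given(
        d_h=st.floats(-0.5, 0.5),
        d_n=st.floats(-3.0, 3.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetry_properties(self, d_h, d_n):
        """CSP is invariant under ref/bound exchange and shift-sign flips,
        and collapses to |dH|/sqrt(2) when the nitrogen shift is unchanged."""
        ref = make_peak(5, delta_h=8.0, delta_n=115.0)
        bound = make_peak(5, delta_h=8.0 + d_h, delta_n=115.0 + d_n)
        flipped = make_peak(5, delta_h=8.0 - d_h, delta_n=115.0 - d_n)
        forward = compute_csp(ref, bound, PARAMS)
        assert forward == pytest.approx(compute_csp(bound, ref, PARAMS), rel=1e-12)
        assert forward == pytest.approx(compute_csp(ref, flipped, PARAMS), rel=1e-12)
        assert forward >= 0
        h_only = make_peak(5, delta_h=8.0 + d_h, delta_n=115.0)
        assert compute_csp(ref, h_only, PARAMS) == pytest.approx(
            abs(d_h) / math.sqrt(2), rel=1e-12
        )


class TestClassifyCsp:
    @pytest.mark.parametrize(
        "csp, expected",
        [
            (0.005, "none"),
            (0.01, "none"),        # weak bound is strict
            (0.0100001, "weak"),
            (0.017678, "weak"),
            (0.0249999, "weak"),
            (0.025, "strong"),     # strong bound is inclusive
            (0.02589, "strong"),
        ],
    )
    def test_band_edges(self, csp, expected):
        assert classify_csp(csp, PARAMS) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_csp(-0.001, PARAMS)

    def test_thresholds_come_from_parameters(self):
        custom = ScoringParameters(csp_weak_low=0.02, csp_strong=0.05)
        assert classify_csp(0.025, custom) == "weak"
        assert classify_csp(0.015, custom) == "none"
        assert classify_csp(0.05, custom) == "strong"


class TestClassifyLbe:
    @pytest.mark.parametrize(
        "ref_i, bound_i, expected_dec, expected_cls",
        [
            (100.0, 100.0, 0.0, "none"),
            (100.0, 60.0001, None, "none"),   # exactly-40% band edge is strict
            (100.0, 50.0, 0.50, "weak"),
            (100.0, 10.0, 0.90, "weak"),      # exactly 90% stays weak
            (100.0, 5.0, 0.95, "strong"),
            (100.0, 0.0, 1.0, "strong"),
            (100.0, 120.0, 0.0, "none"),      # intensity gain clamps to 0
        ],
    )
    def test_band_edges(self, ref_i, bound_i, expected_dec, expected_cls):
        decrease, cls = classify_lbe(ref_i, bound_i, PARAMS)
        if expected_dec is not None:
            assert decrease == pytest.approx(expected_dec)
        assert cls == expected_cls

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            classify_lbe(0.0, 10.0, PARAMS)


class TestScoreFragment:
    def test_null_perturbation(self, reference_peaklist):
        result = score_fragment(
            reference_peaklist,
            PeakList(peaks=dict(reference_peaklist.peaks), label="frag"),
            PARAMS,
        )
        assert result.total_score == 0
        assert result.perturbed_fraction == 0.0
        assert not result.aggregator

    def test_single_strong_lbe_scores_two(self, reference_peaklist):
        peaks = dict(reference_peaklist.peaks)
        peaks[("A", 3)] = make_peak(3, intensity=5.0)
        result = score_fragment(
            reference_peaklist, PeakList(peaks=peaks, label="frag"), PARAMS
        )
        assert result.total_score == 2
        assert result.perturbed_fraction == pytest.approx(0.1)

    def test_missing_peak_counts_as_full_broadening(self, reference_peaklist):
        peaks = dict(reference_peaklist.peaks)
        del peaks[("A", 7)]
        result = score_fragment(
            reference_peaklist, PeakList(peaks=peaks, label="frag"), PARAMS
        )
        rec = next(r for r in result.records if r.key == ("A", 7))
        assert rec.intensity_decrease == 1.0
        assert rec.lbe_class == "strong"
        assert result.total_score == 2

    def test_simultaneous_csp_and_lbe_score_once(self, reference_peaklist):
        # one correlation both shifts strongly and broadens strongly:
        # a single physical binding event, scored once at the strong level
        peaks = dict(reference_peaklist.peaks)
        peaks[("A", 2)] = make_peak(2, delta_h=8.25, intensity=4.0)
        result = score_fragment(
            reference_peaklist, PeakList(peaks=peaks, label="frag"), PARAMS
        )
        assert result.total_score == 2

    def test_extra_perturbed_peaks_ignored(self, reference_peaklist):
        peaks = dict(reference_peaklist.peaks)
        peaks[("A", 99)] = make_peak(99)
        result = score_fragment(
            reference_peaklist, PeakList(peaks=peaks, label="frag"), PARAMS
        )
        assert result.total_score == 0
        assert len(result.records) == len(reference_peaklist)

    def test_score_additive_over_disjoint_residue_subsets(self, reference_peaklist):
        peaks = dict(reference_peaklist.peaks)
        peaks[("A", 1)] = make_peak(1, delta_h=8.25)   # strong CSP
        peaks[("A", 6)] = make_peak(6, intensity=40.0)  # weak LBE
        perturbed = PeakList(peaks=peaks, label="frag")
        full = score_fragment(reference_peaklist, perturbed, PARAMS)

        lo_keys = [("A", i) for i in range(1, 6)]
        hi_keys = [("A", i) for i in range(6, 11)]
        parts = 0
        for keys in (lo_keys, hi_keys):
            sub_ref = PeakList(
                peaks={k: reference_peaklist.peaks[k] for k in keys}, label="reference"
            )
            sub_per = PeakList(peaks={k: perturbed.peaks[k] for k in keys}, label="f")
            parts += score_fragment(sub_ref, sub_per, PARAMS).total_score
        assert full.total_score == parts == 3

    def test_no_shared_keys_rejected(self, reference_peaklist):
        other = PeakList.from_assignments([make_peak(50)], label="frag")
        with pytest.raises(ValueError, match="no shared"):
            score_fragment(reference_peaklist, other, PARAMS)

    def test_missing_intensity_scores_csp_only(self, reference_peaklist):
        peaks = dict(reference_peaklist.peaks)
        peaks[("A", 4)] = make_peak(4, delta_h=8.25, intensity=None)
        result = score_fragment(
            reference_peaklist, PeakList(peaks=peaks, label="frag"), PARAMS
        )
        rec = next(r for r in result.records if r.key == ("A", 4))
        assert rec.csp_class == "strong" and rec.lbe_class == "none"


class TestAggregation:
    @pytest.mark.parametrize("n_broad, n_total, expected", [
        (0, 90, False),
        (27, 90, False),   # exactly 30% is not aggregation
        (28, 90, True),    # 31.1% is
    ])
    def test_strict_30_percent_cutoff(self, n_broad, n_total, expected):
        ref = PeakList.from_assignments(
            [make_peak(i) for i in range(1, n_total + 1)], label="reference"
        )
        peaks = dict(ref.peaks)
        for i in range(1, n_broad + 1):
            peaks[("A", i)] = make_peak(i, intensity=20.0)
        result = score_fragment(ref, PeakList(peaks=peaks, label="frag"), PARAMS)
        assert detect_aggregation(result, PARAMS) is expected
        assert result.aggregator is expected


class TestClassifySpecificity:
    def _result(self, score_each, n=10, fragment_id="frag", protein="A"):
        ref = PeakList.from_assignments(
            [make_peak(i) for i in range(1, n + 1)], label="reference"
        )
        peaks = dict(ref.peaks)
        for i in range(1, score_each // 2 + 1):
            peaks[("A", i)] = make_peak(i, delta_h=8.25)
        return score_fragment(
            ref, PeakList(peaks=peaks, label=fragment_id), PARAMS,
            fragment_id=fragment_id, protein_id=protein,
        )

    def test_calls(self):
        binder = self._result(12)
        silent = self._result(0)
        assert classify_specificity(silent, silent, 2) == CALL_NON_BINDER
        assert classify_specificity(binder, silent, 2) == CALL_A_SPECIFIC
        assert classify_specificity(silent, binder, 2) == CALL_B_SPECIFIC
        assert classify_specificity(binder, binder, 2) == CALL_DUAL

    def test_aggregator_overrides_scores(self):
        binder = self._result(12)
        agg = self._result(12)
        agg.aggregator = True
        assert classify_specificity(binder, agg, 2) == CALL_AGGREGATOR
        assert classify_specificity(agg, binder, 2) == CALL_AGGREGATOR

    def test_fragment_mismatch_rejected(self):
        a = self._result(0, fragment_id="x")
        b = self._result(0, fragment_id="y")
        with pytest.raises(ValueError):
            classify_specificity(a, b, 2)


class TestPeakListIO:
    def test_csv_round_trip(self, tmp_path, reference_peaklist):
        path = tmp_path / "peaks.csv"
        write_peak_list_csv(reference_peaklist, path)
        back = read_peak_list(path, format="csv", label="reference")
        assert len(back) == len(reference_peaklist)
        for key, pk in reference_peaklist.peaks.items():
            other = back.peaks[key]
            assert other.delta_H == pytest.approx(pk.delta_H, abs=1e-4)
            assert other.delta_N == pytest.approx(pk.delta_N, abs=1e-4)
            assert other.intensity == pytest.approx(pk.intensity, rel=1e-5)

    def test_sparky_line_parsing(self, tmp_path):
        path = tmp_path / "peaks.list"
        path.write_text(
            "Assignment w1 w2 height\nA9N-H 115.2 8.31 1.0e6\nG12N-H 109.8 8.02 9.1e5\n"
        )
        peaks = read_peak_list(path, format="sparky")
        assert len(peaks) == 2
        pk = peaks.peaks[("A", 9)]
        assert pk.delta_N == 115.2 and pk.delta_H == 8.31
        assert pk.residue_name == "A" and pk.intensity == 1.0e6

    def test_duplicate_keys_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "chain_id,residue_index,residue_name,delta_N_ppm,delta_H_ppm,intensity\n"
            "A,9,A,115.2,8.31,100\nA,9,G,110.0,8.00,90\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_peak_list(path, format="csv")

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("chain_id,residue_index,delta_H_ppm\nA,9,8.31\n")
        with pytest.raises(PeakListFormatError, match="delta_N_ppm"):
            read_peak_list(path, format="csv")

    def test_row_count_preserved(self, tmp_path):
        path = tmp_path / "three.csv"
        path.write_text(
            "chain_id,residue_index,residue_name,delta_N_ppm,delta_H_ppm,intensity\n"
            "A,9,A,115.2,8.31,100\nA,11,I,121.0,8.8,95\nA,12,D,117.5,8.1,102\n"
        )
        assert len(read_peak_list(path, format="csv")) == 3
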