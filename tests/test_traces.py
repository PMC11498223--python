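"""Concentration conversion, phase annotation, alignment, fold change."""

import math

import numpy as np
import pytest

from rbdyn.synthetic import CellTrace
from rbdyn.traces import (
    ConcentrationTrace,
    align_and_normalize,
    annotate_phases,
    concentration_trace,
    fold_change,
)

DT = 1.0 / 3.0


def make_trace(
    rb=None, geminin=None, n=30, area=400.0, bg=10.0, cell_id="c0"
) -> CellTrace:
    for arr in (rb, geminin):
        if arr is not None:
            n = len(arr)
            break
    times = np.arange(n) * DT
    areas = np.full(n, area)
    bgs = np.full(n, bg)
    zeros = np.zeros(n)
    return CellTrace(
        cell_id=cell_id,
        times=times,
        nuclear_area=areas,
        raw_intensity={
            "rb": np.asarray(rb, dtype=float) if rb is not None else zeros.copy(),
            "geminin": np.asarray(geminin, dtype=float) if geminin is not None else zeros.copy(),
            "hdhb_nuc": np.full(n, 1.0),
            "hdhb_cyt": np.full(n, 1.0),
        },
        background_median=bgs,
    )


class TestConcentration:
    def test_worked_arithmetic(self):
        trace = make_trace(rb=np.full(30, 8000.0), area=400.0, bg=10.0)
        conc = concentration_trace(trace, "rb")
        assert conc.corrected_intensity[0] == pytest.approx(4000.0)
        assert conc.concentration[0] == pytest.approx(4000.0 / 400.0**1.5)
        assert conc.concentration[0] == pytest.approx(0.5)

    def test_zero_background_is_identity(self):
        trace = make_trace(rb=np.full(30, 8000.0), bg=0.0)
        conc = concentration_trace(trace, "rb")
        assert np.allclose(conc.concentration, 8000.0 / 400.0**1.5)

    def test_noise_free_decay_matches_closed_form(self, noise_free_decay_cohort):
        """conc(t)/conc(0) = exp(-k t) * (area(0)/area(t))^{3/2}."""
        trace = noise_free_decay_cohort[0]
        conc = concentration_trace(trace, "rb")
        k = trace.truth["k"]
        expected = np.exp(-k * trace.times) * (
            trace.nuclear_area[0] / trace.nuclear_area
        ) ** 1.5
        np.testing.assert_allclose(conc.concentration / conc.concentration[0], expected, rtol=1e-9)

    def test_homogeneous_in_intensity_scale(self):
        """Rescaling raw intensities and backgrounds by one constant rescales
        concentration by exactly that constant (linearity)."""
        rng = np.random.default_rng(0)
        raw = rng.uniform(5000, 9000, 30)
        t1 = make_trace(rb=raw)
        t2 = make_trace(rb=raw * 3.5, bg=10.0 * 3.5)
        c1 = concentration_trace(t1, "rb").concentration
        c2 = concentration_trace(t2, "rb").concentration
        np.testing.assert_allclose(c2, 3.5 * c1, rtol=1e-12)

    def test_negative_corrected_is_floored_and_flagged(self):
        trace = make_trace(rb=np.full(30, 1000.0), bg=10.0)  # bg*area = 4000 > raw
        conc = concentration_trace(trace, "rb")
        assert conc.floored_frames == 30
        assert np.all(conc.concentration == 0.0)

    def test_missing_channel_raises(self):
        with pytest.raises(KeyError, match="nope"):
            concentration_trace(make_trace(), "nope")


class TestPhaseAnnotation:
    def _gem(self, hours_negative, n=45):
        """Geminin trace negative (100 a.u.) then strongly positive."""
        n_neg = int(round(hours_negative / DT))
        sig = np.full(n, 20000.0)
        sig[:n_neg] = 100.0
        return make_trace(geminin=sig + 10.0 * 400.0)  # add back background

    def test_nine_hour_negative_run_is_early_g1(self):
        ann = annotate_phases(self._gem(9.0), geminin_threshold=1000.0)
        early = ann.interval("earlyG1")
        assert early is not None
        assert early[0] == 0.0
        assert early[1] == pytest.approx(9.0)
        assert ann.interval("SG2")[0] == pytest.approx(9.0)

    def test_five_hour_negative_run_does_not_qualify(self):
        ann = annotate_phases(self._gem(5.0), geminin_threshold=1000.0)
        assert ann.interval("earlyG1") is None
        assert ann.interval("G1") is not None  # still a (short) G1 interval

    def test_positive_from_birth_is_single_sg2(self):
        ann = annotate_phases(self._gem(0.0), geminin_threshold=1000.0)
        assert ann.interval("earlyG1") is None and ann.interval("G1") is None
        labels = [lab for _, _, lab in ann.intervals]
        assert labels == ["SG2"]

    def test_fully_negative_trace_is_all_g1(self):
        ann = annotate_phases(self._gem(45 * DT + 1), geminin_threshold=1000.0)
        assert ann.interval("SG2") is None
        assert ann.interval("earlyG1") is not None

    def test_annotation_idempotent_and_threshold_monotone(self):
        """Raising the geminin threshold never shortens the G1 interval."""
        trace = self._gem(6.0)
        prev_end = -np.inf
        for thr in [200.0, 1000.0, 5000.0, 19000.0]:
            ann = annotate_phases(trace, geminin_threshold=thr)
            again = annotate_phases(trace, geminin_threshold=thr)
            assert ann.intervals == again.intervals
            g1 = ann.interval("G1") or ann.interval("earlyG1")
            end = g1[1] if g1 else 0.0
            assert end >= prev_end
            prev_end = end


class TestAlignAndNormalize:
    def _const_trace(self, cell_id, value, n=12):
        times = np.arange(n) * DT
        return ConcentrationTrace(
            cell_id=cell_id,
            times=times,
            concentration=np.full(n, float(value)),
            corrected_intensity=np.full(n, float(value)),
            volume_proxy=np.ones(n),
        )

    def test_single_constant_cell_normalizes_to_one(self):
        aligned, summary, dropped = align_and_normalize(
            [self._const_trace("a", 7.0)], {"a": 0.0}
        )
        assert dropped == 0
        np.testing.assert_allclose(aligned.loc["a"].to_numpy(), 1.0)

    def test_two_constant_cells_normalize_around_mean(self):
        aligned, _, _ = align_and_normalize(
            [self._const_trace("a", 1.0), self._const_trace("b", 3.0)],
            {"a": 0.0, "b": 0.0},
        )
        np.testing.assert_allclose(aligned.loc["a"].to_numpy(), 0.5)
        np.testing.assert_allclose(aligned.loc["b"].to_numpy(), 1.5)

    def test_grand_mean_preserved(self):
        rng = np.random.default_rng(1)
        traces, anchors = [], {}
        for i in range(5):
            n = 12
            tr = self._const_trace(f"c{i}", 1.0, n)
            tr.concentration = rng.uniform(0.5, 2.0, n)
            traces.append(tr)
            anchors[f"c{i}"] = float(rng.choice([0.0, DT, 2 * DT]))
        aligned, _, _ = align_and_normalize(traces, anchors)
        assert np.nanmean(aligned.to_numpy()) == pytest.approx(1.0, abs=1e-9)

    def test_cells_without_anchor_dropped_and_counted(self):
        aligned, _, dropped = align_and_normalize(
            [self._const_trace("a", 1.0), self._const_trace("b", 2.0)], {"a": 0.0}
        )
        assert dropped == 1
        assert list(aligned.index) == ["a"]

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="empty group"):
            align_and_normalize([self._const_trace("a", 1.0)], {})

    def test_aligned_cohort_dips_then_recovers_around_s_entry(self, cycling_cohort):
        """Mean aligned concentration decreases before the G1-S anchor and
        increases after it (dilution then recovery)."""
        from rbdyn.traces import annotate_phases, cohort_geminin_threshold, concentration_trace

        thr = cohort_geminin_threshold(cycling_cohort)
        conc_traces, anchors = [], {}
        for trace in cycling_cohort:
            ann = annotate_phases(trace, thr)
            sg2 = ann.interval("SG2")
            if sg2 is None or (ann.interval("earlyG1") or ann.interval("G1")) is None:
                continue
            conc_traces.append(concentration_trace(trace, "rb"))
            anchors[trace.cell_id] = sg2[0]
        _, summary, _ = align_and_normalize(conc_traces, anchors)
        dense = summary[summary["n"] >= 20]
        before = dense[(dense.index >= -5.0) & (dense.index < 0.0)]["mean"]
        after = dense[(dense.index >= 0.0) & (dense.index <= 5.0)]["mean"]
        assert np.polyfit(before.index, before.to_numpy(), 1)[0] < 0
        assert np.polyfit(after.index, after.to_numpy(), 1)[0] > 0


class TestFoldChange:
    @pytest.mark.parametrize("treated,control,expected", [(2.0, 1.0, 2.0), (1.0, 1.0, 1.0)])
    def test_ratios(self, treated, control, expected):
        assert fold_change(treated, control) == pytest.approx(expected)

    def test_scaled_cohort_recovers_scale(self):
        rng = np.random.default_rng(2)
        control = float(np.mean(rng.uniform(0.5, 1.5, 100)))
        assert fold_change(1.5 * control, control) == pytest.approx(1.5)

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)
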