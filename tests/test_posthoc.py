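"""Confidence index, archetypal cycle, phase fitting and disruption flags."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from estrocycle.io import CellCounts
from estrocycle.posthoc import (
    ArchetypalCycle,
    build_archetypal_cycle,
    circular_stage_distance,
    confidence_index,
    default_cycle,
    detect_anestrus_from_counts,
    detect_pseudopregnancy,
    fit_cycle_phase,
    resolve_prediction,
)
from estrocycle.results import ClassificationResult, StageProbabilities
from estrocycle.stages import (
    CANONICAL_STAGES,
    number_to_stage,
    stage_to_number,
)


class TestConfidenceIndex:
    def test_all_mass_on_one_stage_gives_one(self):
        assert confidence_index((1.0, 0.0, 0.0, 0.0)) == 1.0

    def test_tied_top_two_gives_zero(self):
        assert confidence_index((0.5, 0.5, 0.0, 0.0)) == 0.0

    def test_margin_formula(self):
        assert confidence_index((0.6, 0.2, 0.1, 0.1)) == pytest.approx(0.5)

    def test_all_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            confidence_index((0.0, 0.0, 0.0, 0.0))

    @given(
        st.lists(st.floats(0.001, 1.0), min_size=4, max_size=4),
    )
    def test_bounded_in_unit_interval(self, raw):
        p = np.asarray(raw) / np.sum(raw)
        ci = confidence_index(tuple(p))
        assert 0.0 <= ci <= 1.0

    def test_strictly_increasing_in_margin_at_fixed_sum(self):
        # p_max + p_runner fixed at 0.8; larger margin -> larger CI
        cis = [
            confidence_index((0.4 + m, 0.4 - m, 0.1, 0.1))
            for m in (0.0, 0.1, 0.2, 0.3)
        ]
        assert all(b > a for a, b in zip(cis, cis[1:]))


class TestStageEncoding:
    def test_forward_encoding(self):
        assert stage_to_number("proestrus") == 1.5
        assert [stage_to_number(s) for s in CANONICAL_STAGES] == [0.5, 1.5, 2.5, 3.5]

    def test_inverse(self):
        assert number_to_stage(0.5) == "diestrus"
        assert number_to_stage(3.9) == "metestrus"

    def test_out_of_range_reduced_modulo_four(self):
        assert number_to_stage(4.7) == "diestrus"
        assert number_to_stage(-0.5) == "metestrus"

    def test_integer_boundary_names_transition_when_requested(self):
        assert number_to_stage(0.0, as_transition_at_integer=True) == "metestrus/diestrus"
        assert number_to_stage(2.0, as_transition_at_integer=True) == "proestrus/estrus"


class TestArchetypalCycle:
    def test_waveform_passes_through_stage_midpoints(self):
        cycle = default_cycle()
        mids = cycle.midpoints()
        for stage, value in zip(CANONICAL_STAGES, (0.5, 1.5, 2.5, 3.5)):
            assert cycle.waveform(mids[stage]) == pytest.approx(value, abs=1e-9)

    def test_periodic_with_default_period(self, rng):
        cycle = default_cycle()
        t = rng.uniform(0, 40, 50)
        assert np.allclose(cycle.waveform(t), cycle.waveform(t + 4.8), atol=1e-9)

    def test_equal_fractions_put_boundaries_at_1p2_day_multiples(self):
        cycle = build_archetypal_cycle([0.25, 0.25, 0.25, 0.25])
        bounds = cycle.boundaries()
        starts = [bounds[s][0] for s in CANONICAL_STAGES]
        assert starts == pytest.approx([0.0, 1.2, 2.4, 3.6])

    def test_wrap_anchor_is_metestrus_diestrus_boundary(self):
        cycle = default_cycle()
        assert cycle.waveform(0.0) == pytest.approx(0.0, abs=1e-9)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            build_archetypal_cycle([0.5, 0.3, 0.3, 0.1])

    def test_sinusoid_mode_is_periodic_too(self, rng):
        cycle = ArchetypalCycle(mode="sinusoid")
        t = rng.uniform(0, 20, 20)
        assert np.allclose(cycle.waveform(t), cycle.waveform(t + 4.8), atol=1e-9)


class TestFitCyclePhase:
    def _noiseless(self, phase, n_days=10, cycle=None):
        cycle = cycle or default_cycle()
        times = np.arange(n_days, dtype=float)
        stages = [
            number_to_stage(cycle.waveform(t + phase * cycle.period_days))
            for t in times
        ]
        return times, stages, cycle

    def test_noiseless_recovery_at_grid_phase(self):
        times, stages, cycle = self._noiseless(0.3)
        fit = fit_cycle_phase(times, stages, cycle)
        assert fit.best_phase == pytest.approx(0.3)
        assert fit.pearson_r > 0.9

    def test_constant_sequence_is_degenerate(self):
        times = np.arange(10, dtype=float)
        with pytest.raises(ValueError, match="degenerate"):
            fit_cycle_phase(times, ["diestrus"] * 10)

    def test_too_short_sequence_advises_more_data(self):
        with pytest.raises(ValueError, match="4 days"):
            fit_cycle_phase(np.arange(4.0), ["diestrus", "proestrus", "estrus",
                                             "metestrus"])

    def test_off_grid_phase_matches_dense_brute_force(self):
        # independent dense-grid oracle at phi step 0.001
        cycle = default_cycle()
        times = np.arange(10, dtype=float)
        stages = [
            number_to_stage(cycle.waveform(t + 0.25 * cycle.period_days))
            for t in times
        ]
        fit = fit_cycle_phase(times, stages, cycle)
        y = [stage_to_number(s) for s in stages]
        dense = np.arange(0, 1, 0.001)
        rs = [
            stats.pearsonr(
                y,
                np.floor(cycle.waveform(times + p * cycle.period_days) % 4.0) + 0.5,
            )[0]
            for p in dense
        ]
        best_dense = dense[int(np.argmax(rs))]
        assert fit.best_phase in (0.2, 0.3)
        assert abs(fit.best_phase - round(best_dense, 1) % 1.0) <= 0.1 + 1e-9

    def test_invariant_to_whole_period_time_shifts(self):
        times, stages, cycle = self._noiseless(0.6)
        a = fit_cycle_phase(times, stages, cycle)
        b = fit_cycle_phase(times + 3 * cycle.period_days, stages, cycle)
        assert a.best_phase == b.best_phase
        assert a.pearson_r == pytest.approx(b.pearson_r, abs=1e-12)

    def test_r_by_phase_covers_the_grid(self):
        times, stages, cycle = self._noiseless(0.0)
        fit = fit_cycle_phase(times, stages, cycle)
        assert len(fit.phases) == 10
        assert fit.pearson_r == pytest.approx(max(fit.r_by_phase))


class TestResolvePrediction:
    def _net(self, stage, ci, probs=None):
        if probs is None:
            base = {s: (1 - 0.9) / 3 for s in CANONICAL_STAGES}
            base[stage] = 0.9
            probs = StageProbabilities(tuple(base[s] for s in CANONICAL_STAGES))
        return ClassificationResult(
            image_path="x.png", stage=stage, probabilities=probs,
            confidence_index=ci,
        )

    def _fit(self, phase=0.0):
        cycle = default_cycle()
        times = np.arange(10, dtype=float)
        stages = [number_to_stage(cycle.waveform(t)) for t in times]
        return fit_cycle_phase(times, stages, cycle)

    def test_agreement_passes_through_unflagged(self):
        fit = self._fit()
        t = fit.cycle.midpoints()["estrus"]
        out = resolve_prediction(self._net("estrus", 0.9), fit, t)
        assert out.stage == "estrus"
        assert not out.outlier_flag and out.transition_suggestion is None

    def test_confident_disagreement_raises_outlier_flag(self):
        fit = self._fit()
        t = fit.cycle.midpoints()["metestrus"]
        out = resolve_prediction(self._net("proestrus", 0.5), fit, t)
        assert out.outlier_flag
        assert out.stage == "proestrus"  # non-interactive default keeps the net
        assert out.cyclicity_stage == "metestrus"

    def test_low_ci_disagreement_suggests_nearest_transition(self):
        fit = self._fit()
        cycle = fit.cycle
        # find a time where the waveform sits at position ~1.95 (P/E boundary)
        grid = np.linspace(0, cycle.period_days, 20001)
        t = grid[int(np.argmin(np.abs(cycle.waveform(grid) - 1.95)))]
        out = resolve_prediction(self._net("metestrus", 0.1), fit, t)
        assert out.transition_suggestion == "proestrus/estrus"

    def test_never_suggests_transition_when_ci_at_or_above_threshold(self):
        fit = self._fit()
        for t in np.linspace(0, 4.7, 12):
            for stage in CANONICAL_STAGES:
                out = resolve_prediction(self._net(stage, 0.30), fit, t)
                assert out.transition_suggestion is None


class TestPseudopregnancy:
    @staticmethod
    def _seq(run_lengths, dt=1.0, trailing_diestrus=0):
        """Alternate diestrus runs (given lengths, in samples) with one estrus."""
        labels, t, times = [], 0.0, []
        for n in run_lengths:
            for _ in range(n):
                labels.append("diestrus")
                times.append(t)
                t += dt
            labels.append("estrus")
            times.append(t)
            t += dt
        for _ in range(trailing_diestrus):
            labels.append("diestrus")
            times.append(t)
            t += dt
        return np.asarray(times), labels

    def test_flags_run_exceeding_factor_times_baseline(self):
        # baseline runs of 2.0 days; current run 3.5 days > 3.0
        times, labels = self._seq([4], dt=0.5, trailing_diestrus=7)
        out = detect_pseudopregnancy(times, labels)
        assert out.flag and out.status == "flagged"

    def test_no_flag_at_exactly_factor_times_baseline(self):
        times, labels = self._seq([4], dt=0.5, trailing_diestrus=6)  # 3.0 == 1.5*2.0
        out = detect_pseudopregnancy(times, labels)
        assert not out.flag

    def test_modest_current_run_not_flagged(self):
        times, labels = self._seq([2], dt=1.0, trailing_diestrus=2)  # 2.0 vs 2.0
        assert not detect_pseudopregnancy(times, labels).flag

    def test_no_prior_complete_cycle_reports_insufficient_history(self):
        times = np.arange(5.0)
        labels = ["diestrus"] * 5
        out = detect_pseudopregnancy(times, labels)
        assert not out.flag and out.status == "insufficient history"

    def test_flag_fires_at_first_qualifying_sample(self):
        times, labels = self._seq([2], dt=1.0, trailing_diestrus=6)
        out = detect_pseudopregnancy(times, labels)
        # baseline 2.0 days; threshold 3.0; 4th sample of the run reaches 4.0 > 3.0
        run_start = labels.index("estrus") + 1
        assert out.flag and out.onset_index == run_start + 3


class TestAnestrus:
    def _counts(self, fracs):
        return [CellCounts(f, (1 - f) / 2, (1 - f) / 2) for f in fracs]

    def test_three_high_days_flag(self):
        out = detect_anestrus_from_counts(
            [1.0, 2.0, 3.0], self._counts([0.95, 0.95, 0.95])
        )
        assert out.flag

    def test_run_of_two_days_is_not_enough(self):
        out = detect_anestrus_from_counts(
            [1.0, 2.0, 3.0, 4.0], self._counts([0.95, 0.5, 0.95, 0.95])
        )
        assert not out.flag

    def test_empty_counts_do_not_flag(self):
        assert not detect_anestrus_from_counts([], []).flag

    def test_threshold_is_strict(self):
        out = detect_anestrus_from_counts(
            [1.0, 2.0, 3.0], self._counts([0.9, 0.9, 0.9])
        )
        assert not out.flag


def test_circular_stage_distance_wraps():
    assert circular_stage_distance(0.5, 3.5) == pytest.approx(1.0)
    assert circular_stage_distance(0.5, 2.5) == pytest.approx(2.0)
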