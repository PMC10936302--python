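"""Tests for the real-time intent classifier."""

import numpy as np
import pandas as pd
import pytest

import gaitintent as gi
from gaitintent.identify import (
    ClassifierConfig,
    Direction,
    FirstOrderLowpass,
    IntentIdentifier,
    IntentLabel,
)
from gaitintent.model import GaitModelResults, GaussianCell, PhaseTimingStats
from gaitintent.segmentation import PHASE_ORDER, GaitPhase, PhaseTimestep


def toy_results(max_k=40, std=3.0, cycle_mean=1.03, m=2) -> GaitModelResults:
    """A hand-built model: unit-variance cells at every (phase, k)."""
    cells = {
        (p, k): GaussianCell(10, np.zeros(m), np.eye(m))
        for p in PHASE_ORDER
        for k in range(1, max_k + 1)
    }
    timing = PhaseTimingStats(
        {p: float(max_k) for p in PHASE_ORDER},
        {p: std for p in PHASE_ORDER},
        {p: max_k for p in PHASE_ORDER},
        cycle_mean,
        0.01,
        100,
    )
    return GaitModelResults(m=m, dt=0.01, cells=cells, timing=timing)


class TestFirstOrderLowpass:
    def test_constant_input_passes_through(self):
        f = FirstOrderLowpass(1.2, 0.01)
        assert all(f.step(7.5) == pytest.approx(7.5) for _ in range(50))

    def test_step_response_time_constant(self):
        # continuous first-order response reaches 1 - 1/e after 1/(2 pi fc)
        fc, dt = 1.2, 0.01
        f = FirstOrderLowpass(fc, dt)
        f.step(0.0)
        tau = 1.0 / (2 * np.pi * fc)
        n = int(round(tau / dt))
        out = [f.step(1.0) for _ in range(n + 1)][n - 1]
        assert out == pytest.approx(1 - np.exp(-1), abs=0.06)

    def test_near_nyquist_cutoff_tracks_input(self):
        # a cutoff far above the signal band passes the signal unchanged,
        # and the residual shrinks as the cutoff approaches Nyquist
        t = np.arange(300) * 0.01
        x = np.sin(2 * np.pi * 2.0 * t)
        devs = []
        for fc in (10.0, 30.0, 49.0):
            f = FirstOrderLowpass(fc, 0.01)
            y = np.array([f.step(v) for v in x])
            devs.append(np.max(np.abs(y - x)))
        assert devs[0] > devs[1] > devs[2]
        assert devs[-1] < 0.05

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            FirstOrderLowpass(60.0, 0.01)  # beyond Nyquist


class TestTimingQuestions:
    def test_question_a_arithmetic(self):
        res = toy_results(max_k=40, std=3.0)
        assert gi.question_a(PhaseTimestep(GaitPhase.LSS, 45), res)  # 5 > 3
        assert not gi.question_a(PhaseTimestep(GaitPhase.LSS, 42), res)  # 2 <= 3
        assert not gi.question_a(PhaseTimestep(GaitPhase.LSS, 40), res)

    def test_question_a_never_flags_within_model_range(self):
        res = toy_results(max_k=40, std=3.0)
        assert not any(
            gi.question_a(PhaseTimestep(GaitPhase.RSS, k), res) for k in range(1, 41)
        )

    def test_question_b_arithmetic(self):
        res = toy_results(max_k=40, std=3.0)
        assert gi.question_b(GaitPhase.LSS, 30, res)  # 10 > 3
        assert not gi.question_b(GaitPhase.LSS, 38, res)  # 2 <= 3
        assert not gi.question_b(GaitPhase.LSS, 40, res)

    def test_question_c_direction(self):
        timing = toy_results(cycle_mean=1.03).timing
        assert gi.question_c(0.95, timing) == Direction.FASTER
        assert gi.question_c(1.20, timing) == Direction.SLOWER
        assert gi.question_c(1.03, timing) == Direction.UNCHANGED


class TestClassifyStep:
    def test_large_distance_with_faster_cycle_is_su(self):
        ident = IntentIdentifier(toy_results())
        ident.state.direction = Direction.FASTER
        label, diag = ident.classify_step(
            np.array([5.0, 5.0]), PhaseTimestep(GaitPhase.LDS, 1)
        )
        assert diag["raw_d2"] == pytest.approx(50.0, rel=1e-6)
        assert diag["trigger_md"]
        assert label == IntentLabel.SU

    def test_large_distance_with_slower_cycle_is_sd(self):
        ident = IntentIdentifier(toy_results())
        ident.state.direction = Direction.SLOWER
        label, _ = ident.classify_step(
            np.array([5.0, 5.0]), PhaseTimestep(GaitPhase.LDS, 1)
        )
        assert label == IntentLabel.SD

    def test_small_distance_is_nc(self):
        ident = IntentIdentifier(toy_results())
        ident.state.direction = Direction.FASTER
        label, diag = ident.classify_step(
            np.array([0.5, 0.5]), PhaseTimestep(GaitPhase.LDS, 1)
        )
        assert not (diag["trigger_md"] or diag["trigger_a"] or diag["trigger_b"])
        assert label == IntentLabel.NC

    def test_flag_without_completed_cycle_is_unresolvable_nc(self):
        ident = IntentIdentifier(toy_results())
        label, diag = ident.classify_step(
            np.array([5.0, 5.0]), PhaseTimestep(GaitPhase.LDS, 1)
        )
        assert diag["trigger_md"]
        assert label == IntentLabel.NC
        assert diag["note"] == "type-unresolvable"

    def test_beyond_model_range_freezes_filter_and_flags_a(self):
        ident = IntentIdentifier(toy_results(max_k=40, std=3.0))
        ident.state.direction = Direction.SLOWER
        ident.classify_step(np.array([1.0, 1.0]), PhaseTimestep(GaitPhase.LSS, 40))
        frozen = ident.state.filter.value
        label, diag = ident.classify_step(
            np.array([9.9, 9.9]), PhaseTimestep(GaitPhase.LSS, 50)
        )
        assert np.isnan(diag["raw_d2"])  # no cell to score against
        assert diag["filtered_d2"] == pytest.approx(frozen)
        assert diag["trigger_a"] and label == IntentLabel.SD

    def test_standing_frames_are_nc(self):
        ident = IntentIdentifier(toy_results())
        label, diag = ident.classify_step(
            np.array([50.0, 50.0]), PhaseTimestep(GaitPhase.LDS, 1), standing=True
        )
        assert label == IntentLabel.NC
        assert diag["note"] == "standing"


class TestRunStream:
    def test_empty_stream_gives_empty_output(self, trained_results):
        out = gi.run_stream(pd.DataFrame({"time": []}), trained_results)
        assert len(out) == 0

    def test_causality_by_truncation(self, template, trained_results):
        """Labels on a prefix equal the prefix of the full run."""
        prof = gi.build_standard_protocol(deltas=[0.3], repeats=1)
        stream = gi.simulate(template, prof, seed=9)
        full = gi.run_stream(stream.frames, trained_results)
        cut = len(stream.frames) // 2
        half = gi.run_stream(stream.frames.iloc[:cut], trained_results)
        assert (full["label"].iloc[:cut].to_numpy() == half["label"].to_numpy()).all()

    def test_infinite_threshold_and_multiplier_give_all_nc(self, template, trained_results):
        prof = gi.build_standard_protocol(deltas=[0.3], repeats=1)
        stream = gi.simulate(template, prof, seed=9)
        cfg = ClassifierConfig(squared_md_threshold=1e12, timing_std_multiplier=1e12)
        out = gi.run_stream(stream.frames, trained_results, cfg)
        assert (out["label"] == "NC").all()

    def test_self_data_rarely_flags(self, template, trained_results):
        """On data from the trained regime, under 5% of frames trigger."""
        stream = gi.simulate(template, gi.constant_speed_profile(1.4, 60.0), seed=10)
        out = gi.run_stream(stream.frames, trained_results)
        flagged = (out["trigger_md"] | out["trigger_a"] | out["trigger_b"]).mean()
        assert flagged < 0.05

    def test_speed_change_detected_within_a_cycle(self, template, trained_results):
        prof = gi.build_standard_protocol(deltas=[0.3], repeats=1)
        stream = gi.simulate(template, prof, seed=9)
        out = gi.run_stream(stream.frames, trained_results)
        delays = gi.time_delays(out["label"], out["time"], prof.trials)
        assert all(d.delay is not None and d.delay < 1.5 for d in delays)

    def test_raising_threshold_never_adds_flags(self, template, trained_results):
        stream = gi.simulate(template, gi.build_standard_protocol(deltas=[0.2], repeats=1), seed=9)
        pts = gi.segment_stream(stream.frames)
        counts = []
        for thr in (5.0, 13.5, 30.0):
            cfg = ClassifierConfig(squared_md_threshold=thr)
            out = gi.run_stream(stream.frames, trained_results, cfg, pts)
            counts.append(int((out["trigger_md"] | out["trigger_a"] | out["trigger_b"]).sum()))
        assert counts[0] >= counts[1] >= counts[2]

    def test_config_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            "squared_md_threshold: 20.0\nfilter_cutoff: 2.0\n"
            "timing_std_multiplier: 1.5\nreference_phase: RDS\n"
        )
        cfg = ClassifierConfig.from_yaml(path)
        assert cfg.squared_md_threshold == 20.0
        assert cfg.reference_phase == GaitPhase.RDS

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ClassifierConfig(squared_md_threshold=-1.0)
        with pytest.raises(ValueError):
            ClassifierConfig(filter_cutoff=80.0, dt=0.01)
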