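"""S1S2 outcome classification and vulnerable-window scans (surrogate)."""

import numpy as np
import pytest

from atrialsim.fixtures import FixtureSpec, generate
from atrialsim.models import surrogate_model
from atrialsim.tissue import TissueGeometry, run_s1s2
from atrialsim.vulnerability import (OutcomeClass, TruncatedRecording,
                                     classify_outcome, scan_vulnerable_window)


@pytest.fixture(scope="module")
def geom():
    return TissueGeometry(nx=60, ny=60, dx=0.05, diffusion=4e-3)


@pytest.fixture(scope="module")
def model():
    return surrogate_model(120.0)


@pytest.fixture(scope="module")
def reentry_recording(model, geom):
    """An S1S2 episode inside the surrogate's vulnerable window."""
    return run_s1s2(model, None, geom, 170.0, 1500.0, dt=0.05,
                    frame_stride_ms=2.0)


class TestClassification:
    def test_late_s2_wave_extinguishes_no_reentry(self, model, geom):
        rec = run_s1s2(model, None, geom, 400.0, 1200.0, dt=0.05)
        out, dur = classify_outcome(rec, horizon=1200.0)
        assert out is OutcomeClass.NO_REENTRY
        assert dur == 0.0
        assert rec.meta["quiescent"]

    def test_refractory_s2_no_capture(self, model, geom):
        rec = run_s1s2(model, None, geom, 60.0, 800.0, dt=0.05)
        out, _ = classify_outcome(rec, horizon=800.0)
        assert out is OutcomeClass.NO_CAPTURE

    def test_activity_at_horizon_is_stable_reentry(self, reentry_recording):
        out, dur = classify_outcome(reentry_recording, horizon=1500.0)
        assert out is OutcomeClass.STABLE_REENTRY
        assert dur > 1000.0

    def test_fixture_truth_roundtrip(self):
        """Outcome and last-activation time agree with the generator's own
        inspection of the activation log."""
        rec, truth = generate(FixtureSpec("surrogate_reentry"))
        out, dur = classify_outcome(rec, horizon=1500.0)
        assert out.value == truth["outcome"]
        if out.is_reentry and out is OutcomeClass.TRANSIENT_REENTRY:
            expected = truth["last_activation_ms"] - truth["s2_onset_ms"]
            assert dur == pytest.approx(expected, abs=rec.stride_ms + 1e-6)

    def test_truncated_recording_refused(self, model, geom):
        rec = run_s1s2(model, None, geom, 170.0, 600.0, dt=0.05)
        if not rec.meta["quiescent"]:
            with pytest.raises(TruncatedRecording):
                classify_outcome(rec, horizon=12_000.0)

    def test_larger_horizon_only_downgrades_stable(self, reentry_recording):
        """Raising the horizon can reclassify STABLE to TRANSIENT but can
        never create a reentry record from a non-reentrant recording."""
        out_short, _ = classify_outcome(reentry_recording, horizon=1500.0)
        with pytest.raises(TruncatedRecording):
            # not enough data for the longer claim: refused, not invented
            classify_outcome(reentry_recording, horizon=5000.0)
        assert out_short.is_reentry

    def test_missing_metadata_rejected(self, reentry_recording):
        import copy

        rec = copy.copy(reentry_recording)
        rec.meta = {}
        with pytest.raises(ValueError, match="metadata"):
            classify_outcome(rec, horizon=1500.0)


class TestVulnerableWindow:
    def test_grid_above_recovery_has_zero_size(self, model, geom):
        vw = scan_vulnerable_window(model, None, [350.0, 420.0], geom,
                                    duration=1000.0, dt=0.05)
        assert vw.size == 0.0
        assert all(r.outcome is OutcomeClass.NO_REENTRY for r in vw.records)
        assert np.isnan(vw.window_start)

    def test_window_brackets_reentrant_intervals(self, model, geom):
        vw = scan_vulnerable_window(model, None, [60.0, 170.0, 400.0], geom,
                                    duration=1500.0, dt=0.05)
        outcomes = {r.interval: r.outcome for r in vw.records}
        assert outcomes[60.0] is OutcomeClass.NO_CAPTURE
        assert outcomes[170.0].is_reentry
        assert outcomes[400.0] is OutcomeClass.NO_REENTRY
        assert vw.window_start == vw.window_end == 170.0
        assert vw.size == 0.0  # single reentrant interval spans no width

    def test_scan_is_deterministic(self, model, geom):
        a = scan_vulnerable_window(model, None, [170.0], geom,
                                   duration=900.0, dt=0.05)
        b = scan_vulnerable_window(model, None, [170.0], geom,
                                   duration=900.0, dt=0.05)
        assert [r.outcome for r in a.records] == \
            [r.outcome for r in b.records]
        assert [r.reentry_duration for r in a.records] == \
            [r.reentry_duration for r in b.records]

    def test_decreasing_grid_rejected(self, model, geom):
        with pytest.raises(ValueError):
            scan_vulnerable_window(model, None, [200.0, 200.0], geom)
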