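"""Phase mapping, singularity detection, core tracking on fixtures."""

import numpy as np
import pytest

from atrialsim.fixtures import FixtureSpec, generate
from atrialsim.rotor import compute_phase, detect_singularities, track_cores


@pytest.fixture(scope="module")
def sinusoid():
    return generate(FixtureSpec("sinusoid_field"))


@pytest.fixture(scope="module")
def spiral():
    return generate(FixtureSpec("archimedean_spiral"))


class TestPhase:
    def test_sinusoid_phase_advances_2pi_per_period(self, sinusoid):
        rec, truth = sinusoid
        pm = compute_phase(rec)
        # measure over an integer number of periods to avoid endpoint bias
        period = truth["period_ms"]
        n_per = int((pm.times[-1] - pm.times[0]) // period)
        t_end = pm.times[0] + n_per * period
        k_end = int(np.argmin(np.abs(pm.times - t_end)))
        unwrapped = np.unwrap(pm.phase[: k_end + 1, 15, 25])
        advance = abs(unwrapped[-1] - unwrapped[0]) / n_per
        assert advance == pytest.approx(2.0 * np.pi, rel=0.02)

    def test_quiescent_nodes_are_masked(self, sinusoid):
        rec, _ = sinusoid
        rec2 = rec
        frames = rec2.frames.copy()
        frames[:, :5, :5] = -80.0  # silence a corner
        import dataclasses

        rec2 = dataclasses.replace(rec2, frames=frames)
        pm = compute_phase(rec2)
        assert not pm.mask[:4, :4].any()
        assert pm.mask[10:, 10:].all()

    def test_coarse_stride_refused(self, sinusoid):
        import dataclasses

        rec, _ = sinusoid
        coarse = dataclasses.replace(rec, frames=rec.frames[::5],
                                     frame_times=rec.frame_times[::5])
        with pytest.raises(ValueError, match="stride"):
            compute_phase(coarse)


class TestSingularities:
    def test_uniform_phase_field_has_none(self, sinusoid):
        rec, _ = sinusoid
        pm = compute_phase(rec)
        assert detect_singularities(pm, 300.0) == []

    def test_planar_wave_has_none(self):
        rec, _ = generate(FixtureSpec("planar_wave"))
        pm = compute_phase(rec)
        for t in (150.0, 250.0, 350.0):
            assert detect_singularities(pm, t) == []

    def test_spiral_core_localized_within_one_node(self, spiral):
        rec, truth = spiral
        pm = compute_phase(rec)
        (cx, cy, ch) = truth["cores"][0]
        for t in (300.0, 500.0, 700.0):
            found = detect_singularities(pm, t)
            assert len(found) == 1
            x, y, s = found[0]
            assert np.hypot(x - cx, y - cy) <= 1.0
            assert s == ch

    def test_figure_of_eight_pair_with_zero_net_charge(self):
        rec, truth = generate(FixtureSpec("figure_of_eight"))
        pm = compute_phase(rec)
        found = detect_singularities(pm, 500.0)
        assert len(found) == 2
        assert sum(s for _, _, s in found) == 0
        for cx, cy, ch in truth["cores"]:
            assert any(np.hypot(x - cx, y - cy) <= 1.6 and s == ch
                       for x, y, s in found)

    def test_charge_is_conserved_across_frames(self):
        rec, _ = generate(FixtureSpec("figure_of_eight"))
        pm = compute_phase(rec)
        charges = {sum(s for _, _, s in detect_singularities(pm, int(k)))
                   for k in range(10, len(pm.times), 25)}
        assert charges == {0}


class TestTracking:
    def test_anchored_spiral_core_barely_meanders(self, spiral):
        rec, _ = spiral
        tracks = track_cores(rec, t_max=1000.0)
        assert len(tracks) == 1
        assert tracks[0].meander_extent < 2 * rec.dx

    def test_drifting_core_path_matches_velocity(self):
        rec, truth = generate(FixtureSpec("drifting_spiral"))
        tracks = track_cores(rec, t_max=3000.0)
        assert len(tracks) == 1
        tk = tracks[0]
        v = truth["drift_cm_per_s"]
        assert tk.path_length == pytest.approx(v * tk.lifetime / 1000.0,
                                               rel=0.10)
        assert tk.lifetime > 2500.0

    def test_chirality_constant_along_track(self, spiral):
        rec, truth = spiral
        tk = track_cores(rec, t_max=1000.0)[0]
        assert tk.chirality == truth["cores"][0][2]
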