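"""Monodomain solver: diffusion correctness, boundaries, CV scaling."""

import numpy as np
import pytest

from atrialsim import ConductanceScaling
from atrialsim.models.base import IntegrationError
from atrialsim.tissue import (StimulusRegion, TissueGeometry, calibrate_cv,
                              make_tissue, measure_strip_cv, run, s1_mask,
                              s2_mask, step)

FROZEN = ConductanceScaling({c: 0.0 for c in
                             ("INa", "Ito", "ICaL", "IKur", "IKr",
                              "IKs", "IK1", "INCX", "INaK")})


class TestGeometry:
    def test_grid_and_spacing_validation(self):
        with pytest.raises(ValueError):
            TissueGeometry(nx=2, ny=10)
        with pytest.raises(ValueError):
            TissueGeometry(dx=-0.01)

    def test_default_matches_4cm_square(self):
        g = TissueGeometry()
        assert g.size_cm == (4.0, 4.0)

    def test_cfl_bound_enforced(self, surrogate):
        g = TissueGeometry(nx=10, ny=10, dx=0.02, diffusion=4e-3)
        tis = make_tissue(surrogate, g)
        with pytest.raises(ValueError, match="stability"):
            step(tis, dt=1.0)

    def test_empty_stimulus_mask_rejected(self):
        g = TissueGeometry(nx=10, ny=10)
        with pytest.raises(ValueError):
            StimulusRegion(np.zeros((10, 10), bool), 0.0, 2.0, 10.0)


class TestDiffusion:
    def test_uniform_resting_tissue_stays_uniform(self, surrogate):
        g = TissueGeometry(nx=20, ny=20, dx=0.02, diffusion=1e-3)
        tis = make_tissue(surrogate, g)
        run(tis, 100.0, 0.05)
        assert np.abs(tis.v - (-80.0)).max() < 1e-6

    def test_zero_diffusion_decouples_nodes(self, surrogate):
        g = TissueGeometry(nx=9, ny=9, dx=0.02, diffusion=0.0)
        tis = make_tissue(surrogate, g)
        tis.y[4, 4, 0] = -20.0  # suprathreshold kick at the center node
        step(tis, 0.05, n_steps=200)
        center = tis.v[4, 4]
        others = np.delete(tis.v.ravel(), 4 * 9 + 4)
        assert center > -60.0          # the kicked node fires
        assert np.abs(others - (-80.0)).max() < 1e-6

    def test_voltage_sum_conserved_under_pure_diffusion(self, surrogate, rng):
        """No-flux boundaries: the discrete Laplacian redistributes charge
        but conserves total V when the reaction is frozen."""
        g = TissueGeometry(nx=12, ny=9, dx=0.02, diffusion=1e-3)
        tis = make_tissue(surrogate, g)
        tis.y[:, :, 0] = rng.uniform(-80, 20, size=(9, 12))
        total0 = tis.v.sum()
        step(tis, 0.05, scaling=FROZEN, n_steps=400)
        assert tis.v.sum() == pytest.approx(total0, rel=1e-9)

    def test_step_matches_dense_laplacian_oracle(self, surrogate, rng):
        """One diffusion step equals the dense mirror-boundary Laplacian
        matrix applied to the voltage field (independent construction)."""
        ny, nx = 5, 6
        g = TissueGeometry(nx=nx, ny=ny, dx=0.02, diffusion=1e-3)
        v0 = rng.uniform(-80, 20, size=(ny, nx))

        def mirror(i, n):
            return 0 if i < 0 else (n - 1 if i > n - 1 else i)

        lap = np.zeros((ny * nx, ny * nx))
        for i in range(ny):
            for j in range(nx):
                row = i * nx + j
                lap[row, row] -= 4.0
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    lap[row, mirror(i + di, ny) * nx + mirror(j + dj, nx)] += 1.0
        assert np.abs(lap.sum(axis=1)).max() == 0.0  # null row sums

        dt = 0.05
        expected = v0 + dt * g.diffusion / g.dx ** 2 \
            * (lap @ v0.ravel()).reshape(ny, nx)
        tis = make_tissue(surrogate, g)
        tis.y[:, :, 0] = v0
        step(tis, dt, scaling=FROZEN, n_steps=1)
        assert np.allclose(tis.v, expected, atol=1e-12)


class TestStimulusMasks:
    def test_s1_is_leftmost_columns(self):
        g = TissueGeometry(nx=10, ny=8)
        m = s1_mask(g)
        assert m[:, :2].all() and not m[:, 2:].any()

    def test_s2_is_upper_left_quadrant_with_shared_edges(self):
        g = TissueGeometry(nx=10, ny=8)
        m = s2_mask(g)
        assert m[:5, :6].all()
        assert not m[5:, :].any() and not m[:, 6:].any()


class TestWaves:
    def test_planar_wave_does_not_reflect_at_the_boundary(self, surrogate):
        """After the wave passes, boundary nodes are not re-activated
        within 50 ms (no-flux correctness)."""
        g = TissueGeometry(nx=80, ny=9, dx=0.05, diffusion=4e-3)
        tis = make_tissue(surrogate, g)
        stim = StimulusRegion(s1_mask(g), 0.0, 2.0, 60.0)
        rec = run(tis, 600.0, 0.05, stimuli=[stim], frame_stride_ms=2.0)
        right = rec.activation_xy[:, 0] >= 78
        t_right = rec.activation_times[right]
        assert t_right.size > 0
        counts = rec.activation_counts[:, 78:]
        assert counts.max() == 1  # exactly one activation per boundary node

    def test_cv_scales_as_sqrt_of_diffusion(self, surrogate):
        cv1 = measure_strip_cv(surrogate, None, 2e-3, n_len=160, n_wid=7,
                               dx=0.05, stim_amplitude=60.0)
        cv2 = measure_strip_cv(surrogate, None, 4e-3, n_len=160, n_wid=7,
                               dx=0.05, stim_amplitude=60.0)
        assert cv2 / cv1 == pytest.approx(np.sqrt(2.0), rel=0.05)

    def test_reduced_sodium_slows_conduction(self, crn, crn_steady):
        y0 = crn_steady.final_state
        cv_base = measure_strip_cv(crn, None, 1.1e-3, initial_state=y0,
                                   stim_amplitude=44.0)
        cv_low = measure_strip_cv(
            crn, ConductanceScaling({"INa": 0.25}), 1.1e-3,
            initial_state=y0, stim_amplitude=44.0)
        assert cv_low < cv_base

    def test_calibration_hits_target_band(self, surrogate):
        cal = calibrate_cv(surrogate, None, (40.0, 50.0),
                           n_len=160, n_wid=7, dx=0.05,
                           stim_amplitude=60.0,
                           d_bracket=(5e-4, 2e-2))
        assert 40.0 <= cal.cv <= 50.0
        assert cal.diffusion > 0


def test_nonfinite_voltage_aborts_with_node_coordinates(surrogate):
    g = TissueGeometry(nx=10, ny=10, dx=0.02, diffusion=1e-3)
    tis = make_tissue(surrogate, g)
    tis.y[3, 7, 0] = np.inf
    with pytest.raises(IntegrationError, match="non-finite V at node"):
        run(tis, 1.0, 0.05)
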