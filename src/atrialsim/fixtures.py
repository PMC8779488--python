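"""Synthetic test inputs with analytically known ground truth.

Every fixture emits its data in the same containers the solvers produce
(:class:`~atrialsim.protocols0d.APTrace` for single-cell waveforms,
:class:`~atrialsim.recording.Recording` for tissue movies) together with a
ground-truth dictionary, so every analysis stage can be validated without
running an ionic model:

``triangle_ap``
    an AP-like waveform with an instantaneous upstroke and a linear
    repolarization ramp — APD_x is known in closed form;
``sinusoid_field``
    every node oscillates sinusoidally — the phase advances uniformly by
    2*pi per period and the field has no singularities;
``planar_wave``
    a rightward-travelling pulse — smooth phase field, no singularities,
    known conduction velocity;
``archimedean_spiral``
    a rotating Archimedean-spiral wave with the singularity at a known
    node (optionally drifting at a constant velocity, or mirrored into a
    figure-of-eight pair with zero net topological charge);
``surrogate_reentry``
    a genuine S1S2 reentry episode in the surrogate excitable tissue; its
    ground truth (outcome class, last-activation time) is derived by
    direct inspection of the activation log.

Deterministic for a fixed seed; the seed only feeds optional amplitude
jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import Recording

__all__ = ["FixtureSpec", "generate", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("triangle_ap", "sinusoid_field", "planar_wave",
                 "archimedean_spiral", "drifting_spiral", "figure_of_eight",
                 "surrogate_reentry")


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(
                f"unknown fixture kind {self.kind!r}; one of {FIXTURE_KINDS}")


def generate(spec: FixtureSpec):
    """Build the fixture: returns (data, ground_truth dict)."""
    p = dict(spec.params)
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "triangle_ap":
        return _triangle_ap(p)
    if spec.kind == "sinusoid_field":
        return _sinusoid_field(p, rng)
    if spec.kind == "planar_wave":
        return _planar_wave(p)
    if spec.kind == "archimedean_spiral":
        return _spiral(p, drift=(0.0, 0.0), mirrored=False)
    if spec.kind == "drifting_spiral":
        v = p.pop("drift_cm_per_s", 1.0)
        ang = p.pop("drift_angle_rad", 0.0)
        # defaults sized so the core stays inside the grid for the whole run
        p.setdefault("dx_cm", 0.05)
        p.setdefault("nx", 90)
        p.setdefault("ny", 64)
        p.setdefault("core_x", 10)
        p.setdefault("core_y", 32)
        p.setdefault("duration_ms", 3000.0)
        p.setdefault("wavelength_nodes", 24.0)
        return _spiral(p, drift=(v * np.cos(ang), v * np.sin(ang)),
                       mirrored=False)
    if spec.kind == "figure_of_eight":
        return _spiral(p, drift=(0.0, 0.0), mirrored=True)
    if spec.kind == "surrogate_reentry":
        return _surrogate_reentry(p)
    raise AssertionError(spec.kind)


# ----------------------------------------------------------------------

def _triangle_ap(p):
    from .protocols0d import APTrace

    v_rest = p.get("v_rest", -80.0)
    v_peak = p.get("v_peak", 20.0)
    rise = p.get("rise_ms", 0.0)
    fall = p.get("fall_ms", 300.0)
    bcl = p.get("bcl_ms", 1000.0)
    onset = p.get("onset_ms", 50.0)
    dt = p.get("dt_ms", 0.1)
    t = np.arange(0.0, bcl, dt)
    v = np.full_like(t, v_rest)
    # the upstroke completes one sample after the onset, so the onset
    # sample itself is still diastolic
    tr = t - onset - dt
    rising = (tr >= 0) & (tr < rise)
    if rise > 0:
        v[rising] = v_rest + (v_peak - v_rest) * tr[rising] / rise
    falling = (tr >= rise) & (tr < rise + fall)
    v[falling] = v_peak - (v_peak - v_rest) * (tr[falling] - rise) / fall
    trace = APTrace(t=t, v=v, stim_onsets=np.array([onset]), bcl=bcl,
                    stim_duration=max(rise, dt), final_state=np.array([v[-1]]),
                    model_name="fixture:triangle_ap")
    truth = {
        "apd20": rise + 0.2 * fall, "apd50": rise + 0.5 * fall,
        "apd90": rise + 0.9 * fall,
        "v_peak": v_peak, "rmp": v_rest, "amplitude": v_peak - v_rest,
    }
    return trace, truth


def _empty_activation(ny, nx):
    return (np.empty((0, 2), dtype=np.int32), np.empty(0),
            np.zeros((ny, nx), dtype=np.int32))


def _activations_from_frames(frames, times, thr=-40.0, rearm=-60.0):
    """Scan a frame stack for upward threshold crossings per node."""
    T, ny, nx = frames.shape
    armed = frames[0] < rearm
    counts = np.zeros((ny, nx), dtype=np.int32)
    xs, ys, ts = [], [], []
    for k in range(1, T):
        cross = armed & (frames[k - 1] < thr) & (frames[k] >= thr)
        iy, ix = np.nonzero(cross)
        for x, y in zip(ix, iy):
            xs.append(x), ys.append(y), ts.append(times[k])
        counts[cross] += 1
        armed = np.where(cross, False, armed)
        armed |= frames[k] < rearm
    xy = np.array([xs, ys], dtype=np.int32).T if xs else \
        np.empty((0, 2), dtype=np.int32)
    return xy, np.asarray(ts, dtype=float), counts


def _recording(frames, times, dx, dt, name, meta=None, with_activations=True):
    frames = np.asarray(frames, dtype=np.float32)
    if with_activations:
        xy, ts, counts = _activations_from_frames(frames, times)
    else:
        xy, ts, counts = _empty_activation(frames.shape[1], frames.shape[2])
    return Recording(frames=frames, frame_times=np.asarray(times, float),
                     activation_xy=xy, activation_times=ts,
                     activation_counts=counts, dx=dx, dt=dt,
                     model_name=name, meta=dict(meta or {}))


def _sinusoid_field(p, rng):
    nx, ny = p.get("nx", 40), p.get("ny", 40)
    period = p.get("period_ms", 150.0)
    stride = p.get("stride_ms", 2.0)
    duration = p.get("duration_ms", 600.0)
    amp = p.get("amplitude_mv", 40.0)
    offset = p.get("offset_mv", -40.0)
    jitter = p.get("amplitude_jitter", 0.0)
    times = np.arange(0.0, duration, stride)
    amp_map = amp * (1.0 + jitter * rng.standard_normal((ny, nx)))
    frames = offset + amp_map[None] * np.sin(
        2.0 * np.pi * times[:, None, None] / period)
    rec = _recording(frames, times, p.get("dx_cm", 0.02), stride,
                     "fixture:sinusoid_field", with_activations=False)
    truth = {"period_ms": period, "n_singularities": 0,
             "phase_advance_per_period": 2.0 * np.pi}
    return rec, truth


def _planar_wave(p):
    nx, ny = p.get("nx", 60), p.get("ny", 40)
    dx = p.get("dx_cm", 0.02)
    cv = p.get("cv_cm_per_s", 50.0)
    apd = p.get("apd_ms", 120.0)
    stride = p.get("stride_ms", 2.0)
    duration = p.get("duration_ms", 400.0)
    v_rest, v_peak = p.get("v_rest", -80.0), p.get("v_peak", 20.0)
    times = np.arange(0.0, duration, stride)
    x_cm = np.arange(nx) * dx
    frames = np.full((times.size, ny, nx), v_rest)
    for k, t in enumerate(times):
        front = cv / 1000.0 * t  # cm
        age = (front - x_cm) / (cv / 1000.0)  # ms since activation
        prof = np.where((age >= 0) & (age < apd),
                        v_peak - (v_peak - v_rest) * age / apd, v_rest)
        frames[k, :, :] = prof[None, :]
    rec = _recording(frames, times, dx, stride, "fixture:planar_wave")
    truth = {"cv_cm_per_s": cv, "n_singularities": 0, "apd_ms": apd}
    return rec, truth


def _spiral(p, drift, mirrored):
    nx, ny = p.get("nx", 80), p.get("ny", 80)
    dx = p.get("dx_cm", 0.02)
    stride = p.get("stride_ms", 2.0)
    duration = p.get("duration_ms", 1000.0)
    period = p.get("period_ms", 120.0)
    wavelength_nodes = p.get("wavelength_nodes", 30.0)
    chirality = p.get("chirality", 1)
    cx = p.get("core_x", nx // 2)
    cy = p.get("core_y", ny // 2)
    v_mid = p.get("v_mid", -30.0)
    amp = p.get("amplitude_mv", 50.0)
    times = np.arange(0.0, duration, stride)
    jx = np.arange(nx)[None, :]
    iy = np.arange(ny)[:, None]
    omega = 2.0 * np.pi / period
    kk = 2.0 * np.pi / wavelength_nodes
    frames = np.empty((times.size, ny, nx))
    vx, vy = drift  # cm/s
    for k, t in enumerate(times):
        cxt = cx + vx * t / 1000.0 / dx
        cyt = cy + vy * t / 1000.0 / dx
        r = np.hypot(jx - cxt, iy - cyt)
        ang = np.arctan2(iy - cyt, jx - cxt)
        if mirrored:
            # one smooth phase field with exactly two opposite-chirality
            # singularities (angle difference has windings +1 and -1)
            r2 = np.hypot(jx - (nx - 1 - cxt), iy - cyt)
            ang2 = np.arctan2(iy - cyt, jx - (nx - 1 - cxt))
            arg = omega * t - kk * 0.5 * (r + r2) \
                - chirality * (ang - ang2)
        else:
            arg = omega * t - kk * r - chirality * ang
        v = v_mid + amp * np.cos(arg)
        frames[k] = v
    rec = _recording(frames, times, dx, stride, "fixture:spiral")
    core_x_end = cx + vx * times[-1] / 1000.0 / dx
    core_y_end = cy + vy * times[-1] / 1000.0 / dx
    drift_speed = float(np.hypot(vx, vy))
    # chirality convention: sign of the phase winding around the core,
    # matching the detector's output
    truth = {
        "cores": ([(cx, cy, chirality)] if not mirrored else
                  [(cx, cy, chirality), (nx - 1 - cx, cy, -chirality)]),
        "n_singularities": 1 if not mirrored else 2,
        "net_chirality": 0 if mirrored else None,
        "period_ms": period,
        "drift_cm_per_s": drift_speed,
        "core_end": (core_x_end, core_y_end),
        "expected_path_length_cm": drift_speed * times[-1] / 1000.0,
    }
    return rec, truth


def _surrogate_reentry(p):
    from .models import surrogate_model
    from .tissue import TissueGeometry, run_s1s2

    apd = p.get("apd_ms", 120.0)
    n = p.get("n_nodes", 60)
    dx = p.get("dx_cm", 0.05)
    diffusion = p.get("diffusion", 4.0e-3)
    interval = p.get("s1s2_interval_ms", None)
    duration = p.get("duration_ms", 1500.0)
    model = surrogate_model(apd)
    geometry = TissueGeometry(nx=n, ny=n, dx=dx, diffusion=diffusion)
    if interval is None:
        # sits inside the surrogate's vulnerable window at default APD/CV
        interval = apd * 1.4
    rec = run_s1s2(model, None, geometry, float(interval), duration,
                   dt=min(model.dt_default, geometry.cfl_dt_max()),
                   frame_stride_ms=p.get("stride_ms", 2.0))
    # ground truth by direct inspection of the activation log
    s2_end = float(interval) + rec.meta["stim_duration_ms"]
    xy_c, t_c = rec.activation_after(float(interval))
    captured = np.any(
        (t_c <= s2_end + 10.0) & (xy_c[:, 0] <= geometry.nx // 2)
        & (xy_c[:, 1] <= geometry.ny // 2))
    xy, ts = rec.activation_after(s2_end)
    if not captured or ts.size == 0:
        outcome = "NO_CAPTURE"
    else:
        flat = xy[:, 1].astype(np.int64) * (geometry.nx + 1) + xy[:, 0]
        _, counts = np.unique(flat, return_counts=True)
        if (counts >= 2).any():
            outcome = ("STABLE_REENTRY" if not rec.meta.get("quiescent")
                       else "TRANSIENT_REENTRY")
        else:
            outcome = "NO_REENTRY"
    truth = {
        "outcome": outcome,
        "last_activation_ms": float(ts.max()) if ts.size else 0.0,
        "s2_onset_ms": float(interval),
        "quiescent": bool(rec.meta.get("quiescent", False)),
    }
    return rec, truth
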