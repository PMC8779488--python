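"""Single-cell pacing, AP biomarker extraction and conductance scans.

The quasi-steady-state protocol of the study: 1 Hz pacing (BCL 1000 ms),
100 beats of pre-pacing, biomarkers measured on the final beat.  The
stimulus is a 2 ms rectangular pulse at twice the diastolic threshold; the
threshold is found once per model by bisection at baseline and reused under
perturbation, so that conductance scans change the substrate but not the
drive.

APD_x is measured from AP onset (the time of maximal dV/dt after the
stimulus) to the first downward crossing of
``V_peak - x% * (V_peak - V_onset)`` with linear interpolation, where
``V_onset`` is the membrane potential immediately before the stimulus.
Repolarization failure (plateau arrest) is flagged when the 90% level is
never crossed before the next stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from numba import njit
from scipy.integrate import solve_ivp

from .currents import ConductanceScaling, CurrentID
from .models import ModelDefinition, get_model
from .models.base import IntegrationError

__all__ = [
    "PacingProtocol",
    "APTrace",
    "Biomarkers",
    "diastolic_threshold",
    "pace",
    "measure_biomarkers",
    "conductance_scan",
]

#: minimum upstroke amplitude (mV) for an AP to count as detected
_AP_AMPLITUDE_MIN = 30.0


@dataclass(frozen=True)
class PacingProtocol:
    """Rectangular-pulse pacing protocol.

    ``stim_amplitude=None`` means twice the model's diastolic threshold
    (determined once per model at baseline).  ``solver`` selects the
    adaptive stiff integrator (LSODA, default) or the fixed-step
    Rush–Larsen scheme used by the tissue kernels.
    """

    bcl: float = 1000.0          # ms
    n_beats: int = 100
    stim_amplitude: float | None = None  # pA/pF
    stim_duration: float = 2.0   # ms
    record_last_n: int = 2
    solver: str = "adaptive"     # "adaptive" | "fixed"
    rtol: float = 1e-6
    atol: float = 1e-8
    dt: float | None = None      # fixed-step dt; None -> model default
    dt_record: float = 0.1       # ms, output sampling of recorded beats

    def __post_init__(self) -> None:
        if not (self.bcl > self.stim_duration > 0):
            raise ValueError("need BCL > stim_duration > 0")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if not (1 <= self.record_last_n <= self.n_beats):
            object.__setattr__(
                self, "record_last_n", min(self.record_last_n, self.n_beats))
        if self.solver not in ("adaptive", "fixed"):
            raise ValueError(f"unknown solver {self.solver!r}")


@dataclass
class APTrace:
    """Recorded membrane-potential trace of the final pacing beats."""

    t: np.ndarray                # ms, strictly increasing
    v: np.ndarray                # mV
    stim_onsets: np.ndarray      # ms, onsets within the recorded window
    bcl: float
    stim_duration: float
    final_state: np.ndarray      # full state at the end of the run
    model_name: str = ""
    states: np.ndarray | None = None   # optional (n_t, n_state) samples
    current_traces: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    def beat_window(self, beat_index: int) -> tuple[float, float]:
        """(start, end) times of the indexed recorded beat (negative ok)."""
        onsets = np.asarray(self.stim_onsets, dtype=float)
        onset = onsets[beat_index]
        later = onsets[onsets > onset + 1e-9]
        end = later.min() if later.size else onset + self.bcl
        return float(onset), float(end)


@dataclass(frozen=True)
class Biomarkers:
    """Per-beat action-potential biomarkers (ms / mV)."""

    apd20: float
    apd50: float
    apd90: float
    rmp: float
    v_peak: float
    amplitude: float
    dvdt_max: float
    repolarization_failure: bool
    ap_detected: bool = True

    def as_dict(self) -> dict:
        return {
            "APD20_ms": self.apd20, "APD50_ms": self.apd50,
            "APD90_ms": self.apd90, "RMP_mV": self.rmp,
            "Vpeak_mV": self.v_peak, "amplitude_mV": self.amplitude,
            "dVdt_max_mV_per_ms": self.dvdt_max,
            "repolarization_failure": self.repolarization_failure,
            "ap_detected": self.ap_detected,
        }


# ----------------------------------------------------------------------
# stimulus threshold
# ----------------------------------------------------------------------

def _captures(model: ModelDefinition, scale: np.ndarray, amplitude: float,
              stim_duration: float, n_beats: int = 10,
              bcl: float = 1000.0) -> bool:
    """Does every beat of a 1 Hz train elicit a regenerative upstroke?

    A short train rather than a single pulse from rest: diastolic Na+
    channel availability at the pacing steady state is lower than at full
    rest (markedly so in the Grandi model, whose resting potential is
    around -74 mV), so single-pulse capture does not guarantee 1:1 capture
    during the 100-beat protocol.
    """
    y = model.initial_state()
    f_on = lambda t, yy: model.rhs(t, yy, scale, amplitude)
    f_off = lambda t, yy: model.rhs(t, yy, scale, 0.0)
    tt = np.linspace(stim_duration, min(400.0, bcl - 1.0), 300)
    for _ in range(n_beats):
        s = solve_ivp(f_on, (0.0, stim_duration), y, method="LSODA",
                      rtol=1e-6, atol=1e-8, max_step=0.5)
        s = solve_ivp(f_off, (stim_duration, bcl), s.y[:, -1],
                      method="LSODA", rtol=1e-6, atol=1e-8, max_step=5.0,
                      dense_output=True)
        if s.sol(tt)[model.v_index].max() <= -20.0:
            return False
        y = s.y[:, -1]
    return True


def diastolic_threshold(model: ModelDefinition, stim_duration: float = 2.0,
                        tol: float = 0.25) -> float:
    """Baseline diastolic threshold amplitude (pA/pF) by bisection.

    The threshold is the smallest amplitude sustaining 1:1 capture of a
    10-beat 1 Hz conditioning train at baseline.  Cached per (model, pulse
    duration) and reused unchanged under conductance perturbations.
    """
    key = ("threshold", round(stim_duration, 6))
    if key in model._threshold_cache:
        return model._threshold_cache[key]
    scale = np.ones(len(CurrentID))
    lo, hi = 0.0, 8.0
    while not _captures(model, scale, hi, stim_duration):
        lo, hi = hi, hi * 2.0
        if hi > 512.0:
            raise IntegrationError(
                f"{model.name}: no capture even at {hi} pA/pF")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _captures(model, scale, mid, stim_duration):
            hi = mid
        else:
            lo = mid
    model._threshold_cache[key] = hi
    return hi


def _resolve_amplitude(model: ModelDefinition, protocol: PacingProtocol) -> float:
    if protocol.stim_amplitude is not None:
        return float(protocol.stim_amplitude)
    return 2.0 * diastolic_threshold(model, protocol.stim_duration)


# ----------------------------------------------------------------------
# pacing drivers
# ----------------------------------------------------------------------

def _pace_adaptive(model, scale, protocol, amp, y0):
    y = y0.copy()
    bcl, dur = protocol.bcl, protocol.stim_duration
    rec_from = protocol.n_beats - protocol.record_last_n
    ts, vs, states = [], [], []
    t_grid = np.arange(0.0, bcl, protocol.dt_record)
    for beat in range(protocol.n_beats):
        record = beat >= rec_from
        try:
            s1 = solve_ivp(lambda t, yy: model.rhs(t, yy, scale, amp),
                           (0.0, dur), y, method="LSODA",
                           rtol=protocol.rtol, atol=protocol.atol,
                           max_step=0.5, dense_output=record)
            s2 = solve_ivp(lambda t, yy: model.rhs(t, yy, scale, 0.0),
                           (dur, bcl), s1.y[:, -1], method="LSODA",
                           rtol=protocol.rtol, atol=protocol.atol,
                           max_step=5.0, dense_output=record)
        except Exception as exc:  # solver blow-up
            raise IntegrationError(
                f"{model.name}: solver failure at beat {beat}: {exc}",
                beat=beat) from exc
        y = s2.y[:, -1]
        try:
            model.check_state(y, context=f"at beat {beat}")
        except IntegrationError as exc:
            exc.beat = beat
            raise
        if record:
            t0 = beat * bcl
            tg1 = t_grid[t_grid < dur]
            tg2 = t_grid[t_grid >= dur]
            yy = np.concatenate([s1.sol(tg1), s2.sol(tg2)], axis=1)
            ts.append(t0 + t_grid)
            vs.append(yy[model.v_index])
            states.append(yy.T)
    t = np.concatenate(ts)
    v = np.concatenate(vs)
    onsets = np.arange(rec_from, protocol.n_beats) * bcl
    return t, v, onsets, y, np.concatenate(states, axis=0)


@lru_cache(maxsize=8)
def _fixed_driver(model_name: str):
    step = get_model(model_name).step_rl
    v_idx = get_model(model_name).v_index

    @njit
    def drive(y, scale, amp, dur, bcl, n_beats, dt, rec_from, dt_rec,
              t_out, v_out):
        n_per_beat = int(round(bcl / dt))
        n_stim = int(round(dur / dt))
        rec_stride = max(1, int(round(dt_rec / dt)))
        k = 0
        for beat in range(n_beats):
            for i in range(n_per_beat):
                istim = amp if i < n_stim else 0.0
                if beat >= rec_from and i % rec_stride == 0 and k < t_out.size:
                    t_out[k] = beat * bcl + i * dt
                    v_out[k] = y[v_idx]
                    k += 1
                step(y, dt, scale, istim)
                if not np.isfinite(y[v_idx]):
                    return -(beat + 1)
        return k

    return drive


def _pace_fixed(model, scale, protocol, amp, y0):
    dt = protocol.dt if protocol.dt is not None else model.dt_default
    rec_from = protocol.n_beats - protocol.record_last_n
    n_rec = int(protocol.record_last_n * round(protocol.bcl / dt)
                / max(1, round(protocol.dt_record / dt))) + 2
    t_out = np.empty(n_rec)
    v_out = np.empty(n_rec)
    y = y0.copy()
    drive = _fixed_driver(model.name)
    k = drive(y, scale, amp, protocol.stim_duration, protocol.bcl,
              protocol.n_beats, dt, rec_from, protocol.dt_record,
              t_out, v_out)
    if k < 0:
        model.check_state(y, context=f"at beat {-k - 1}")
        raise IntegrationError(f"{model.name}: divergence at beat {-k - 1}",
                               beat=-k - 1)
    onsets = np.arange(rec_from, protocol.n_beats) * protocol.bcl
    return t_out[:k], v_out[:k], onsets, y, None


def pace(model: ModelDefinition,
         scaling: ConductanceScaling | None = None,
         protocol: PacingProtocol | None = None,
         initial_state: np.ndarray | None = None,
         record_states: bool = False) -> APTrace:
    """Pace a single cell and return the recorded final beats.

    The trace carries ``final_state`` (the full state at the end of the
    run) for reuse as the tissue initial condition.
    """
    protocol = protocol or PacingProtocol()
    scale = model.scale_vector(scaling)
    amp = _resolve_amplitude(model, protocol)
    y0 = model.initial_state() if initial_state is None else \
        np.asarray(initial_state, dtype=float)
    if protocol.solver == "adaptive":
        t, v, onsets, y_end, states = _pace_adaptive(
            model, scale, protocol, amp, y0)
    else:
        t, v, onsets, y_end, states = _pace_fixed(
            model, scale, protocol, amp, y0)
    model.check_state(y_end, context="at end of pacing")
    trace = APTrace(t=t, v=v, stim_onsets=onsets, bcl=protocol.bcl,
                    stim_duration=protocol.stim_duration,
                    final_state=y_end, model_name=model.name,
                    states=states if record_states else None)
    if record_states and states is not None:
        from .currents import CURRENT_ORDER
        vals = np.array([model.currents(s.copy(), scale) for s in states])
        trace.current_traces = pd.DataFrame(
            vals, index=t, columns=[c.value for c in CURRENT_ORDER])
    return trace


# ----------------------------------------------------------------------
# biomarkers
# ----------------------------------------------------------------------

def _cross_down(t: np.ndarray, v: np.ndarray, level: float) -> float | None:
    """First downward crossing of ``level``, linearly interpolated."""
    above = v >= level
    idx = np.flatnonzero(above[:-1] & ~above[1:])
    if idx.size == 0:
        return None
    i = int(idx[0])
    frac = (v[i] - level) / (v[i] - v[i + 1])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def measure_biomarkers(trace: APTrace, beat_index: int = -1,
                       reference: Biomarkers | None = None) -> Biomarkers:
    """Extract APD20/50/90, RMP, peak, amplitude and max dV/dt of one beat.

    By default the x%-repolarization levels are referenced to this beat's
    own peak and pre-stimulus potential.  For cross-condition sensitivity
    comparisons pass the baseline condition's ``reference`` biomarkers:
    the levels are then anchored to the reference AP's peak/onset, so that
    perturbations that merely attenuate the Na+ spike (lowering the peak,
    hence shifting the relative levels) are not mistaken for repolarization
    changes.
    """
    t = np.asarray(trace.t, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("non-monotone time grid")
    start, end = trace.beat_window(beat_index)
    pre = t < start
    if not pre.any():
        pre = t <= start
    if not pre.any() or t[-1] < start + trace.stim_duration:
        raise ValueError(f"beat at t={start} not contained in trace")
    sel = (t >= start) & (t < end)
    tb, vb = t[sel], trace.v[sel]
    v_onset = float(trace.v[pre][-1])  # V immediately before the stimulus

    if v_onset > -55.0:
        # plateau arrest on a preceding beat: the membrane never returned
        # to rest, so the x%-repolarization levels are undefined
        return Biomarkers(np.nan, np.nan, np.nan, v_onset,
                          float(vb.max()), float(vb.max()) - v_onset,
                          np.nan, repolarization_failure=True)

    dvdt = np.gradient(vb, tb)
    early = tb <= start + trace.stim_duration + 10.0
    i_on = int(np.argmax(dvdt[early]))
    t_onset = float(tb[i_on])
    dvdt_max = float(dvdt[early][i_on])

    post = tb >= t_onset
    v_peak = float(vb[post].max())
    amplitude = v_peak - v_onset
    detected = amplitude >= _AP_AMPLITUDE_MIN and dvdt_max > 1.0
    if not detected:
        return Biomarkers(np.nan, np.nan, np.nan, v_onset, v_peak, amplitude,
                          dvdt_max, repolarization_failure=False,
                          ap_detected=False)

    i_peak = int(np.argmax(vb[post]))
    t_after = tb[post][i_peak:]
    v_after = vb[post][i_peak:]
    if reference is not None and reference.ap_detected:
        ref_peak, ref_amp = reference.v_peak, reference.amplitude
    else:
        ref_peak, ref_amp = v_peak, amplitude
    apds = {}
    for x in (20, 50, 90):
        level = ref_peak - (x / 100.0) * ref_amp
        tc = _cross_down(t_after, v_after, level)
        apds[x] = (tc - t_onset) if tc is not None else np.nan
    failure = not np.isfinite(apds[90])
    return Biomarkers(apd20=apds[20], apd50=apds[50], apd90=apds[90],
                      rmp=v_onset, v_peak=v_peak, amplitude=amplitude,
                      dvdt_max=dvdt_max, repolarization_failure=failure)


# ----------------------------------------------------------------------
# conductance scans
# ----------------------------------------------------------------------

def default_scan_scales() -> np.ndarray:
    """0–400% of baseline in 25% steps."""
    return np.round(np.arange(0.0, 4.0 + 1e-9, 0.25), 2)


def conductance_scan(model: ModelDefinition,
                     current: CurrentID | str,
                     scales=None,
                     protocol: PacingProtocol | None = None,
                     base_scaling: ConductanceScaling | None = None,
                     beat_index: int = -1,
                     anchor_reference: bool = True) -> pd.DataFrame:
    """Vary one current's G_max multiplier; biomarkers per scale.

    Each row paces to quasi-steady state per ``protocol`` with all other
    currents at ``base_scaling`` (default: all ones).  Rows whose AP never
    repolarizes carry ``repolarization_failure=True`` and NaN APDs; rows
    whose simulation fails carry the error message instead of aborting the
    scan.  With ``anchor_reference`` (default) the repolarization levels of
    every row are anchored to the reference condition's AP amplitude, so
    the scan isolates repolarization effects from spike attenuation.
    """
    current = CurrentID(current)
    scales = default_scan_scales() if scales is None else np.asarray(scales, float)
    if np.any(scales < 0) or np.any(scales > 4.0 + 1e-9):
        raise ValueError("scan scales must lie in [0, 4]")
    protocol = protocol or PacingProtocol()
    base = base_scaling if base_scaling is not None else ConductanceScaling()
    reference = None
    if anchor_reference:
        try:
            reference = measure_biomarkers(
                pace(model, base, protocol), beat_index=beat_index)
        except IntegrationError:
            reference = None
    rows = []
    for s in scales:
        scaling = base.with_current(current, float(s))
        row: dict = {"scale": float(s)}
        try:
            trace = pace(model, scaling, protocol)
            bm = measure_biomarkers(trace, beat_index=beat_index,
                                    reference=reference)
            row.update(bm.as_dict())
            row["error"] = ""
        except IntegrationError as exc:
            row.update({k: np.nan for k in
                        ("APD20_ms", "APD50_ms", "APD90_ms", "RMP_mV",
                         "Vpeak_mV", "amplitude_mV", "dVdt_max_mV_per_ms")})
            row["repolarization_failure"] = True
            row["ap_detected"] = False
            row["error"] = str(exc)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("scale")
    df.attrs["model"] = model.name
    df.attrs["current"] = current.value
    return df
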