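"""Phase mapping, phase-singularity detection, and rotor-core trajectories.

The membrane potential of a reentrant wave passes through a loop in state
space once per rotation, so a per-node phase can be built from the voltage
and its time-delayed copy:

    theta(x, y, t) = atan2(V(t) - V*, V(t - tau) - V*)

with delay tau (default 5 ms) and per-node offset V* at the midpoint of
that node's voltage range.  Nodes whose voltage range is below 5 mV never
complete a loop and are masked.  A phase singularity — the rotor core —
is a point where all phases converge: the wrapped phase difference summed
around a closed loop (here every 2x2 node plaquette) is +-2*pi, the sign
giving the chirality.  Cores are linked frame-to-frame by nearest-neighbor
association into trajectories whose path length, meander extent (maximum
pairwise core distance) and lifetime quantify rotor dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import Recording

__all__ = [
    "PhaseMap",
    "RotorTrajectory",
    "compute_phase",
    "detect_singularities",
    "track_cores",
]

PHASE_TOL = 0.2 * np.pi        # tolerance on the +-2*pi winding
MIN_V_RANGE = 5.0              # mV, below which a node has no phase
MAX_STRIDE_MS = 5.0
LINK_MAX_CM = 0.3              # max core displacement per snapshot stride
LINK_GAP_STRIDES = 2


@dataclass
class PhaseMap:
    """Per-node phase in (-pi, pi] on the snapshot time grid."""

    phase: np.ndarray      # (T, ny, nx)
    mask: np.ndarray       # (ny, nx) bool, True where phase is defined
    times: np.ndarray      # (T,) ms
    dx: float              # cm

    @property
    def stride_ms(self) -> float:
        return float(np.median(np.diff(self.times))) if self.times.size > 1 \
            else float("nan")


def compute_phase(recording: Recording, tau_ms: float = 5.0) -> PhaseMap:
    """Time-delay phase of a voltage recording.

    Requires a snapshot stride <= 5 ms and at least one full rotation
    recorded (in practice: enough frames to span the delay).
    """
    stride = recording.stride_ms
    if not np.isfinite(stride) or stride > MAX_STRIDE_MS:
        raise ValueError(
            f"snapshot stride {stride} ms too coarse for phase mapping; "
            f"need <= {MAX_STRIDE_MS} ms")
    k_tau = max(1, int(round(tau_ms / stride)))
    frames = recording.frames.astype(np.float64)
    if frames.shape[0] <= k_tau:
        raise ValueError("recording too short for the phase delay")
    v_hi = frames.max(axis=0)
    v_lo = frames.min(axis=0)
    v_star = 0.5 * (v_hi + v_lo)
    mask = (v_hi - v_lo) >= MIN_V_RANGE
    cur = frames[k_tau:] - v_star
    lag = frames[:-k_tau] - v_star
    phase = np.arctan2(cur, lag)
    phase[:, ~mask] = 0.0
    return PhaseMap(phase=phase, mask=mask,
                    times=recording.frame_times[k_tau:], dx=recording.dx)


def _wrap(dp: np.ndarray) -> np.ndarray:
    return (dp + np.pi) % (2.0 * np.pi) - np.pi


def detect_singularities(phase_map: PhaseMap, t: float | int
                         ) -> list[tuple[float, float, int]]:
    """Phase singularities at one snapshot: list of (x, y, chirality).

    ``t`` is a time in ms (nearest snapshot is used) or an integer frame
    index.  Coordinates are node units at the plaquette center; chirality
    is the sign of the +-2*pi winding.  An empty list is a valid result.
    """
    if isinstance(t, (int, np.integer)):
        k = int(t)
    else:
        k = int(np.argmin(np.abs(phase_map.times - t)))
    th = phase_map.phase[k]
    m = phase_map.mask
    # winding around each 2x2 plaquette: (i,j)->(i,j+1)->(i+1,j+1)->(i+1,j)
    d1 = _wrap(th[:-1, 1:] - th[:-1, :-1])
    d2 = _wrap(th[1:, 1:] - th[:-1, 1:])
    d3 = _wrap(th[1:, :-1] - th[1:, 1:])
    d4 = _wrap(th[:-1, :-1] - th[1:, :-1])
    winding = d1 + d2 + d3 + d4
    valid = m[:-1, :-1] & m[:-1, 1:] & m[1:, :-1] & m[1:, 1:]
    hits = valid & (np.abs(np.abs(winding) - 2.0 * np.pi) <= PHASE_TOL)
    out = []
    for i, j in zip(*np.nonzero(hits)):
        out.append((j + 0.5, i + 0.5, int(np.sign(winding[i, j]))))

    # second pass on 3x3 loops: catches a core sitting exactly on a node,
    # where the phase at that node is ill-defined and all four adjacent
    # plaquettes miss the winding
    loop = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1),
            (0, -1), (-1, -1)]
    c = th[1:-1, 1:-1]
    w2 = np.zeros_like(c)
    for (ia, ja), (ib, jb) in zip(loop[:-1], loop[1:]):
        a = th[1 + ia: th.shape[0] - 1 + ia, 1 + ja: th.shape[1] - 1 + ja]
        b = th[1 + ib: th.shape[0] - 1 + ib, 1 + jb: th.shape[1] - 1 + jb]
        w2 += _wrap(b - a)
    valid2 = np.ones_like(c, dtype=bool)
    for ia, ja in loop[:-1]:
        valid2 &= m[1 + ia: m.shape[0] - 1 + ia, 1 + ja: m.shape[1] - 1 + ja]
    hits2 = valid2 & (np.abs(np.abs(w2) - 2.0 * np.pi) <= PHASE_TOL)
    for i, j in zip(*np.nonzero(hits2)):
        x, y = j + 1.0, i + 1.0
        s = int(np.sign(w2[i, j]))
        if not any((px - x) ** 2 + (py - y) ** 2 <= 2.25 and ps == s
                   for px, py, ps in out):
            out.append((x, y, s))
    return out


@dataclass
class RotorTrajectory:
    """A linked rotor-core track with summary meander metrics."""

    times: np.ndarray          # ms
    x: np.ndarray              # cm
    y: np.ndarray              # cm
    chirality: int

    @property
    def lifetime(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def path_length(self) -> float:
        """Core path length (cm), resampled at ~20 ms so that residual
        per-snapshot detection jitter does not accumulate as a random walk."""
        if self.times.size < 2:
            return 0.0
        stride = float(np.median(np.diff(self.times)))
        step = max(1, int(round(20.0 / max(stride, 1e-9))))
        idx = np.unique(np.r_[np.arange(0, self.times.size, step),
                              self.times.size - 1])
        return float(np.hypot(np.diff(self.x[idx]),
                              np.diff(self.y[idx])).sum())

    @property
    def meander_extent(self) -> float:
        """Maximum pairwise distance between core positions (cm)."""
        if self.x.size < 2:
            return 0.0
        pts = np.column_stack([self.x, self.y])
        d2max = 0.0
        # hull-free O(n^2) is fine at snapshot-rate track lengths
        for i in range(len(pts) - 1):
            d2 = ((pts[i + 1:] - pts[i]) ** 2).sum(axis=1).max()
            d2max = max(d2max, d2)
        return float(np.sqrt(d2max))

    def __len__(self) -> int:
        return int(self.times.size)


def track_cores(recording: Recording, t_max: float = 3000.0,
                tau_ms: float = 5.0,
                min_track_points: int = 3) -> list[RotorTrajectory]:
    """Detect and link phase singularities up to ``t_max`` ms.

    Nearest-neighbor linking with same-chirality matching, a maximum
    displacement of 0.3 cm per snapshot stride, and a gap tolerance of two
    strides.  Tracks shorter than ``min_track_points`` snapshots are
    dropped as detection noise.
    """
    pm = compute_phase(recording, tau_ms=tau_ms)
    stride = pm.stride_ms
    sel = pm.times <= t_max
    times = pm.times[sel]
    dx = recording.dx

    active: list[dict] = []
    finished: list[dict] = []
    for k, t in enumerate(times):
        found = detect_singularities(pm, int(k))
        pts = [(x * dx, y * dx, ch) for x, y, ch in found]
        used = [False] * len(pts)
        for tr in active:
            gap_strides = (t - tr["t"][-1]) / stride
            best, best_d = -1, LINK_MAX_CM * max(1.0, round(gap_strides))
            for idx, (x, y, ch) in enumerate(pts):
                if used[idx] or ch != tr["ch"]:
                    continue
                d = np.hypot(x - tr["x"][-1], y - tr["y"][-1])
                if d <= best_d:
                    best, best_d = idx, d
            if best >= 0:
                x, y, ch = pts[best]
                used[best] = True
                tr["t"].append(t)
                tr["x"].append(x)
                tr["y"].append(y)
        still = []
        for tr in active:
            if (t - tr["t"][-1]) / stride > LINK_GAP_STRIDES:
                finished.append(tr)
            else:
                still.append(tr)
        active = still
        for idx, (x, y, ch) in enumerate(pts):
            if not used[idx]:
                active.append({"t": [t], "x": [x], "y": [y], "ch": ch})
    finished.extend(active)

    out = []
    # ~50 ms boxcar: wide enough to flatten the node-quantization
    # staircase of the detector, short against rotor meander time scales
    smooth_win = max(3, int(round(50.0 / stride)) | 1)
    for tr in finished:
        if len(tr["t"]) < min_track_points:
            continue
        x = np.asarray(tr["x"])
        y = np.asarray(tr["y"])
        if x.size > smooth_win:
            # boxcar smoothing suppresses the half-node detection jitter,
            # which would otherwise inflate path_length as a random walk
            kern = np.ones(smooth_win) / smooth_win
            pad = smooth_win // 2
            xp = np.pad(x, pad, mode="edge")
            yp = np.pad(y, pad, mode="edge")
            x = np.convolve(xp, kern, mode="valid")
            y = np.convolve(yp, kern, mode="valid")
        out.append(RotorTrajectory(
            times=np.asarray(tr["t"]), x=x, y=y, chirality=tr["ch"]))
    out.sort(key=lambda r: -r.lifetime)
    return out
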