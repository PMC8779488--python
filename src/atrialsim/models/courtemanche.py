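"""Courtemanche et al. (1998) human atrial action potential model.

21 state variables: membrane potential, 15 Hodgkin–Huxley-type gates and 5
ionic concentrations (intracellular Na+, K+, Ca2+ and the uptake/release
compartments of the sarcoplasmic reticulum).  All voltage- and Ca2+-dependent
gates are expressed in steady-state / time-constant form so the same algebra
serves both the plain right-hand side (for adaptive solvers) and the
exponential Rush–Larsen update used by the fixed-step tissue kernels.

Units: mV, ms, mM, pA/pF.  Outward membrane current is positive; a positive
stimulus depolarizes.  Stimulus charge is booked against intracellular K+ so
that long pacing runs do not drift in total ionic content.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

N_STATE = 21
V_INDEX = 0
STATE_NAMES = (
    "V", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
    "d", "f", "fca", "u", "vrel", "w",
    "Nai", "Ki", "Cai", "Ca_up", "Ca_rel",
)
#: indices integrated with the exponential (Rush–Larsen) update and clamped to [0,1]
GATE_INDICES = np.arange(1, 16)
CONC_INDICES = np.arange(16, 21)

#: published resting-state initial conditions
Y0 = np.array([
    -81.18,      # V (mV)
    2.908e-3,    # m
    9.649e-1,    # h
    9.775e-1,    # j
    3.043e-2,    # oa
    9.992e-1,    # oi
    4.966e-3,    # ua
    9.986e-1,    # ui
    3.296e-5,    # xr
    1.869e-2,    # xs
    1.367e-4,    # d
    9.996e-1,    # f
    7.755e-1,    # fca
    0.0,         # u
    1.0,         # vrel
    9.992e-1,    # w
    1.117e1,     # Nai (mM)
    1.39e2,      # Ki (mM)
    1.013e-4,    # Cai (mM)
    1.488,       # Ca_up (mM)
    1.488,       # Ca_rel (mM)
])

# --- physical constants and cell geometry -------------------------------
R = 8.3143          # J mol^-1 K^-1
T = 310.0           # K
F = 96.4867         # C mmol^-1
CM = 100.0          # pF
V_CELL = 20100.0    # um^3
V_I = 13668.0
V_UP = 1109.52
V_REL = 96.48

KO = 5.4            # mM
NAO = 140.0
CAO = 1.8

# --- maximal conductances / fluxes --------------------------------------
G_NA = 7.8          # nS/pF
G_K1 = 0.09
G_TO = 0.1652
G_KR = 0.029411765
G_KS = 0.12941176
G_CAL = 0.12375
G_B_CA = 0.00113
G_B_NA = 0.000674

I_NAK_MAX = 0.59933874  # pA/pF
KM_NAI = 10.0
KM_KO = 1.5
I_NACA_MAX = 1600.0     # pA/pF
KM_NA = 87.5
KM_CA = 1.38
K_SAT = 0.1
GAMMA = 0.35
I_PCA_MAX = 0.275

K_REL = 30.0            # ms^-1
I_UP_MAX = 0.005        # mM/ms
K_UP = 0.00092
CA_UP_MAX = 15.0
TAU_TR = 180.0
TAU_F_CA = 2.0
TAU_U = 8.0

CMDN_MAX = 0.05
TRPN_MAX = 0.07
CSQN_MAX = 10.0
KM_CMDN = 0.00238
KM_TRPN = 0.0005
KM_CSQN = 0.8

KQ10 = 3.0  # temperature scaling of the Ito/IKur time constants

RT_F = R * T / F


@njit(cache=True, fastmath=True)
def _algebra(y, scale, i_stim, dy, ginf, gtau):
    """Derivatives plus gate (steady-state, tau) pairs.

    ``dy`` receives full derivatives (unit/ms); for the 15 gate indices
    ``ginf``/``gtau`` additionally receive the steady state and time
    constant.  ``scale`` is the 9-vector of G_max multipliers in the order
    (INa, Ito, ICaL, IKur, IKr, IKs, IK1, INCX, INaK).
    """
    v = y[0]
    m = y[1]; h = y[2]; jj = y[3]
    oa = y[4]; oi = y[5]
    ua = y[6]; ui = y[7]
    xr = y[8]; xs = y[9]
    d = y[10]; f = y[11]; fca = y[12]
    u = y[13]; vrel = y[14]; w = y[15]
    nai = y[16]; ki = y[17]; cai = y[18]
    ca_up = y[19]; ca_rel = y[20]

    e_na = RT_F * math.log(NAO / nai)
    e_k = RT_F * math.log(KO / ki)
    e_ca = 0.5 * RT_F * math.log(CAO / cai)

    # --- membrane currents (pA/pF) ---
    i_na = scale[0] * G_NA * m * m * m * h * jj * (v - e_na)
    i_k1 = scale[6] * G_K1 * (v - e_k) / (1.0 + math.exp(0.07 * (v + 80.0)))
    i_to = scale[1] * G_TO * oa * oa * oa * oi * (v - e_k)
    g_kur = 0.005 + 0.05 / (1.0 + math.exp(-(v - 15.0) / 13.0))
    i_kur = scale[3] * g_kur * ua * ua * ua * ui * (v - e_k)
    i_kr = scale[4] * G_KR * xr * (v - e_k) / (1.0 + math.exp((v + 15.0) / 22.4))
    i_ks = scale[5] * G_KS * xs * xs * (v - e_k)
    i_cal = scale[2] * G_CAL * d * f * fca * (v - 65.0)

    sigma = (math.exp(NAO / 67.3) - 1.0) / 7.0
    f_nak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * v / RT_F)
                   + 0.0365 * sigma * math.exp(-v / RT_F))
    i_nak = scale[8] * I_NAK_MAX * f_nak * (KO / (KO + KM_KO)) \
        / (1.0 + (KM_NAI / nai) ** 1.5)

    expg = math.exp(GAMMA * v / RT_F)
    expg1 = math.exp((GAMMA - 1.0) * v / RT_F)
    i_naca = scale[7] * I_NACA_MAX * (expg * nai ** 3 * CAO - expg1 * NAO ** 3 * cai) \
        / ((KM_NA ** 3 + NAO ** 3) * (KM_CA + CAO) * (1.0 + K_SAT * expg1))

    i_bna = G_B_NA * (v - e_na)
    i_bca = G_B_CA * (v - e_ca)
    i_pca = I_PCA_MAX * cai / (0.0005 + cai)

    i_ion = (i_na + i_k1 + i_to + i_kur + i_kr + i_ks + i_cal
             + i_nak + i_naca + i_bna + i_bca + i_pca)
    dy[0] = -i_ion + i_stim

    # --- gating: alpha/beta or inf/tau ---
    # m
    dvm = v + 47.13
    if abs(dvm) < 1e-10:
        a_m = 3.2
    else:
        a_m = 0.32 * dvm / (1.0 - math.exp(-0.1 * dvm))
    b_m = 0.08 * math.exp(-v / 11.0)
    ginf[1] = a_m / (a_m + b_m)
    gtau[1] = 1.0 / (a_m + b_m)
    # h, j
    if v >= -40.0:
        a_h = 0.0
        b_h = 1.0 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
        a_j = 0.0
        b_j = 0.3 * math.exp(-2.535e-7 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    else:
        a_h = 0.135 * math.exp(-(v + 80.0) / 6.8)
        b_h = 3.56 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.35 * v)
        a_j = (-1.2714e5 * math.exp(0.2444 * v) - 3.474e-5 * math.exp(-0.04391 * v)) \
            * (v + 37.78) / (1.0 + math.exp(0.311 * (v + 79.23)))
        b_j = 0.1212 * math.exp(-0.01052 * v) / (1.0 + math.exp(-0.1378 * (v + 40.14)))
    ginf[2] = a_h / (a_h + b_h)
    gtau[2] = 1.0 / (a_h + b_h)
    ginf[3] = a_j / (a_j + b_j)
    gtau[3] = 1.0 / (a_j + b_j)
    # oa, oi (Ito gates)
    a_oa = 0.65 / (math.exp(-(v + 10.0) / 8.5) + math.exp(-(v - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + math.exp((v + 82.0) / 17.0))
    gtau[4] = 1.0 / ((a_oa + b_oa) * KQ10)
    ginf[4] = 1.0 / (1.0 + math.exp(-(v + 20.47) / 17.54))
    a_oi = 1.0 / (18.53 + math.exp((v + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + math.exp(-(v + 1.26) / 7.44))
    gtau[5] = 1.0 / ((a_oi + b_oi) * KQ10)
    ginf[5] = 1.0 / (1.0 + math.exp((v + 43.1) / 5.3))
    # ua, ui (IKur gates)
    a_ua = 0.65 / (math.exp(-(v + 10.0) / 8.5) + math.exp(-(v - 30.0) / 59.0))
    b_ua = 0.65 / (2.5 + math.exp((v + 82.0) / 17.0))
    gtau[6] = 1.0 / ((a_ua + b_ua) * KQ10)
    ginf[6] = 1.0 / (1.0 + math.exp(-(v + 30.3) / 9.6))
    a_ui = 1.0 / (21.0 + math.exp(-(v - 185.0) / 28.0))
    b_ui = math.exp((v - 158.0) / 16.0)
    gtau[7] = 1.0 / ((a_ui + b_ui) * KQ10)
    ginf[7] = 1.0 / (1.0 + math.exp((v - 99.45) / 27.48))
    # xr
    dv1 = v + 14.1
    if abs(dv1) < 1e-10:
        a_xr = 0.0015
    else:
        a_xr = 0.0003 * dv1 / (1.0 - math.exp(-dv1 / 5.0))
    dv2 = v - 3.3328
    if abs(dv2) < 1e-10:
        b_xr = 3.7864e-4
    else:
        b_xr = 7.3898e-5 * dv2 / (math.exp(dv2 / 5.1237) - 1.0)
    gtau[8] = 1.0 / (a_xr + b_xr)
    ginf[8] = 1.0 / (1.0 + math.exp(-dv1 / 6.5))
    # xs
    dv3 = v - 19.9
    if abs(dv3) < 1e-10:
        a_xs = 6.8e-4
        b_xs = 3.15e-4
    else:
        a_xs = 4e-5 * dv3 / (1.0 - math.exp(-dv3 / 17.0))
        b_xs = 3.5e-5 * dv3 / (math.exp(dv3 / 9.0) - 1.0)
    gtau[9] = 0.5 / (a_xs + b_xs)
    ginf[9] = 1.0 / math.sqrt(1.0 + math.exp(-dv3 / 12.7))
    # d
    dv4 = v + 10.0
    if abs(dv4) < 1e-10:
        gtau[10] = 1.0 / (6.24 * 2.0 * 0.035)
    else:
        e4 = math.exp(-dv4 / 6.24)
        gtau[10] = (1.0 - e4) / (0.035 * dv4 * (1.0 + e4))
    ginf[10] = 1.0 / (1.0 + math.exp(-dv4 / 8.0))
    # f
    ginf[11] = 1.0 / (1.0 + math.exp((v + 28.0) / 6.9))
    gtau[11] = 9.0 / (0.0197 * math.exp(-(0.0337 ** 2) * dv4 * dv4) + 0.02)
    # fca (Ca-dependent)
    ginf[12] = 1.0 / (1.0 + cai / 0.00035)
    gtau[12] = TAU_F_CA
    # SR release gates u, vrel (Fn-dependent) and w (V-dependent)
    i_rel = K_REL * u * u * vrel * w * (ca_rel - cai)
    fn = 1e-12 * V_REL * i_rel \
        - (5e-13 / F) * (0.5 * i_cal - 0.2 * i_naca) * CM
    ginf[13] = 1.0 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    gtau[13] = TAU_U
    ginf[14] = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 6.835e-14) / 13.67e-16))
    gtau[14] = 1.91 + 2.09 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    dv5 = v - 7.9
    if abs(dv5) < 1e-10:
        gtau[15] = 6.0 / (5.0 * 1.3)
    else:
        e5 = math.exp(-dv5 / 5.0)
        gtau[15] = 6.0 * (1.0 - e5) / ((1.0 + 0.3 * e5) * dv5)
    ginf[15] = 1.0 - 1.0 / (1.0 + math.exp(-(v - 40.0) / 17.0))

    for k in range(1, 16):
        dy[k] = (ginf[k] - y[k]) / gtau[k]

    # --- intracellular concentrations ---
    i_up = I_UP_MAX / (1.0 + K_UP / cai)
    i_up_leak = I_UP_MAX * ca_up / CA_UP_MAX
    i_tr = (ca_up - ca_rel) / TAU_TR

    dy[16] = (-3.0 * i_nak - 3.0 * i_naca - i_bna - i_na) * CM / (F * V_I)
    dy[17] = (2.0 * i_nak - i_k1 - i_to - i_kur - i_kr - i_ks + i_stim) \
        * CM / (F * V_I)

    b1 = (2.0 * i_naca - i_pca - i_cal - i_bca) * CM / (2.0 * F * V_I) \
        + (V_UP * (i_up_leak - i_up) + i_rel * V_REL) / V_I
    b2 = 1.0 + TRPN_MAX * KM_TRPN / ((cai + KM_TRPN) ** 2) \
        + CMDN_MAX * KM_CMDN / ((cai + KM_CMDN) ** 2)
    dy[18] = b1 / b2
    dy[19] = i_up - i_up_leak - i_tr * V_REL / V_UP
    dy[20] = (i_tr - i_rel) / (1.0 + CSQN_MAX * KM_CSQN / ((ca_rel + KM_CSQN) ** 2))


@njit(cache=True)
def rhs(t, y, scale, i_stim):
    """Time derivatives of the full state (unit/ms)."""
    dy = np.empty(N_STATE)
    ginf = np.empty(N_STATE)
    gtau = np.empty(N_STATE)
    _algebra(y, scale, i_stim, dy, ginf, gtau)
    return dy


@njit(cache=True)
def step_rl(y, dt, scale, i_stim):
    """One fixed-step update: Rush–Larsen for gates, forward Euler otherwise.

    Operates in place; gates are clamped to [0, 1] afterwards.
    """
    dy = np.empty(N_STATE)
    ginf = np.empty(N_STATE)
    gtau = np.empty(N_STATE)
    _algebra(y, scale, i_stim, dy, ginf, gtau)
    y[0] += dt * dy[0]
    for k in range(1, 16):
        g = ginf[k] + (y[k] - ginf[k]) * math.exp(-dt / gtau[k])
        if g < 0.0:
            g = 0.0
        elif g > 1.0:
            g = 1.0
        y[k] = g
    for k in range(16, 21):
        y[k] += dt * dy[k]


@njit(cache=True)
def reaction_rl(y, dt, scale, i_stim):
    """Reaction-only update returning dV/dt instead of updating V.

    Used by the tissue kernel, which adds the diffusion term to V itself.
    """
    dy = np.empty(N_STATE)
    ginf = np.empty(N_STATE)
    gtau = np.empty(N_STATE)
    _algebra(y, scale, i_stim, dy, ginf, gtau)
    for k in range(1, 16):
        g = ginf[k] + (y[k] - ginf[k]) * math.exp(-dt / gtau[k])
        if g < 0.0:
            g = 0.0
        elif g > 1.0:
            g = 1.0
        y[k] = g
    for k in range(16, 21):
        y[k] += dt * dy[k]
    return dy[0]


# ----------------------------------------------------------------------
# voltage lookup table for the tissue kernel
# ----------------------------------------------------------------------
# All purely voltage-dependent quantities (12 gate steady states with their
# Rush–Larsen factors exp(-dt/tau), plus six current factors) are tabulated
# on a 0.05 mV grid, turning ~50 transcendental evaluations per node per
# step into ~30 linear interpolations.  The exact algebra above remains the
# reference path for the 0D solvers; a regression test holds the two paths
# together.

VT_MIN = -95.0
VT_MAX = 65.0
VT_STEP = 0.05
VT_N = int(round((VT_MAX - VT_MIN) / VT_STEP)) + 1
#: gate state indices covered by the table, in column order
_TAB_GATES = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 15)
N_TAB_COLS = 32  # 12*(inf, rl) + fk1, gkur, rkr, fnak, expg, expg1, rl_fca, rl_u


@njit(cache=True)
def _fill_v_row(v, dt, out):
    """Exact table row at potential ``v`` for step size ``dt``."""
    dy = np.empty(N_STATE)
    ginf = np.empty(N_STATE)
    gtau = np.empty(N_STATE)
    y = Y0.copy()
    y[0] = v
    _algebra(y, np.ones(9), 0.0, dy, ginf, gtau)
    col = 0
    for g in _TAB_GATES:
        out[col] = ginf[g]
        out[col + 1] = math.exp(-dt / gtau[g])
        col += 2
    out[24] = 1.0 / (1.0 + math.exp(0.07 * (v + 80.0)))
    out[25] = 0.005 + 0.05 / (1.0 + math.exp(-(v - 15.0) / 13.0))
    out[26] = 1.0 / (1.0 + math.exp((v + 15.0) / 22.4))
    sigma = (math.exp(NAO / 67.3) - 1.0) / 7.0
    out[27] = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * v / RT_F)
                     + 0.0365 * sigma * math.exp(-v / RT_F))
    out[28] = math.exp(GAMMA * v / RT_F)
    out[29] = math.exp((GAMMA - 1.0) * v / RT_F)
    out[30] = math.exp(-dt / TAU_F_CA)
    out[31] = math.exp(-dt / TAU_U)


@njit(cache=True)
def _build_table(dt):
    tab = np.empty((VT_N, N_TAB_COLS))
    for i in range(VT_N):
        _fill_v_row(VT_MIN + i * VT_STEP, dt, tab[i])
    return tab


def tissue_aux(dt: float) -> np.ndarray:
    """dt-specific voltage lookup table for the tissue reaction kernel."""
    return _build_table(float(dt))


@njit(cache=True, fastmath=True)
def reaction_ws(y, dt, scale, i_stim, w1, w2, w3, aux):
    """Workspace reaction step for the tissue kernel (no allocation).

    With a non-empty ``aux`` (from :func:`tissue_aux`) the voltage-dependent
    algebra is linearly interpolated from the table; otherwise it falls
    back to the exact algebra.  ``w1``–``w3`` are scratch arrays of length
    >= N_STATE.
    """
    if aux.shape[0] == 0:
        _algebra(y, scale, i_stim, w1, w2, w3)
        for k in range(1, 16):
            g = w2[k] + (y[k] - w2[k]) * math.exp(-dt / w3[k])
            if g < 0.0:
                g = 0.0
            elif g > 1.0:
                g = 1.0
            y[k] = g
        for k in range(16, 21):
            y[k] += dt * w1[k]
        return w1[0]

    v = y[0]
    vv = v
    if vv < VT_MIN:
        vv = VT_MIN
    elif vv > VT_MAX - VT_STEP:
        vv = VT_MAX - VT_STEP
    x = (vv - VT_MIN) / VT_STEP
    i0 = int(x)
    fr = x - i0
    for k in range(N_TAB_COLS):
        w2[k] = aux[i0, k] + fr * (aux[i0 + 1, k] - aux[i0, k])

    m = y[1]; h = y[2]; jj = y[3]
    oa = y[4]; oi = y[5]; ua = y[6]; ui = y[7]
    xr = y[8]; xs = y[9]
    d = y[10]; f = y[11]; fca = y[12]
    u = y[13]; vrel = y[14]; w = y[15]
    nai = y[16]; ki = y[17]; cai = y[18]
    ca_up = y[19]; ca_rel = y[20]

    e_na = RT_F * math.log(NAO / nai)
    e_k = RT_F * math.log(KO / ki)
    e_ca = 0.5 * RT_F * math.log(CAO / cai)

    i_na = scale[0] * G_NA * m * m * m * h * jj * (v - e_na)
    i_k1 = scale[6] * G_K1 * (v - e_k) * w2[24]
    i_to = scale[1] * G_TO * oa * oa * oa * oi * (v - e_k)
    i_kur = scale[3] * w2[25] * ua * ua * ua * ui * (v - e_k)
    i_kr = scale[4] * G_KR * xr * (v - e_k) * w2[26]
    i_ks = scale[5] * G_KS * xs * xs * (v - e_k)
    i_cal = scale[2] * G_CAL * d * f * fca * (v - 65.0)
    i_nak = scale[8] * I_NAK_MAX * w2[27] * (KO / (KO + KM_KO)) \
        / (1.0 + (KM_NAI / nai) ** 1.5)
    i_naca = scale[7] * I_NACA_MAX \
        * (w2[28] * nai ** 3 * CAO - w2[29] * NAO ** 3 * cai) \
        / ((KM_NA ** 3 + NAO ** 3) * (KM_CA + CAO) * (1.0 + K_SAT * w2[29]))
    i_bna = G_B_NA * (v - e_na)
    i_bca = G_B_CA * (v - e_ca)
    i_pca = I_PCA_MAX * cai / (0.0005 + cai)

    dv = -(i_na + i_k1 + i_to + i_kur + i_kr + i_ks + i_cal
           + i_nak + i_naca + i_bna + i_bca + i_pca) + i_stim

    # SR release and its gates (Fn-dependent, not tabulated)
    i_rel = K_REL * u * u * vrel * w * (ca_rel - cai)
    fn = 1e-12 * V_REL * i_rel \
        - (5e-13 / F) * (0.5 * i_cal - 0.2 * i_naca) * CM
    u_inf = 1.0 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    v_inf = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 6.835e-14) / 13.67e-16))
    tau_v = 1.91 + 2.09 * u_inf
    fca_inf = 1.0 / (1.0 + cai / 0.00035)

    # Rush–Larsen updates: tabulated gates ...
    col = 0
    for g in _TAB_GATES:
        gv = w2[col] + (y[g] - w2[col]) * w2[col + 1]
        if gv < 0.0:
            gv = 0.0
        elif gv > 1.0:
            gv = 1.0
        y[g] = gv
        col += 2
    # ... and the Ca2+/release gates
    y[12] = fca_inf + (fca - fca_inf) * w2[30]
    y[13] = u_inf + (u - u_inf) * w2[31]
    y[14] = v_inf + (vrel - v_inf) * math.exp(-dt / tau_v)
    for g in (12, 13, 14):
        if y[g] < 0.0:
            y[g] = 0.0
        elif y[g] > 1.0:
            y[g] = 1.0

    # concentrations (forward Euler)
    i_up = I_UP_MAX / (1.0 + K_UP / cai)
    i_up_leak = I_UP_MAX * ca_up / CA_UP_MAX
    i_tr = (ca_up - ca_rel) / TAU_TR
    y[16] += dt * (-3.0 * i_nak - 3.0 * i_naca - i_bna - i_na) * CM / (F * V_I)
    y[17] += dt * (2.0 * i_nak - i_k1 - i_to - i_kur - i_kr - i_ks + i_stim) \
        * CM / (F * V_I)
    b1 = (2.0 * i_naca - i_pca - i_cal - i_bca) * CM / (2.0 * F * V_I) \
        + (V_UP * (i_up_leak - i_up) + i_rel * V_REL) / V_I
    b2 = 1.0 + TRPN_MAX * KM_TRPN / ((cai + KM_TRPN) ** 2) \
        + CMDN_MAX * KM_CMDN / ((cai + KM_CMDN) ** 2)
    y[18] += dt * b1 / b2
    y[19] += dt * (i_up - i_up_leak - i_tr * V_REL / V_UP)
    y[20] += dt * (i_tr - i_rel) \
        / (1.0 + CSQN_MAX * KM_CSQN / ((ca_rel + KM_CSQN) ** 2))
    return dv


@njit(cache=True)
def currents(y, scale):
    """Instantaneous values of the nine scalable currents (pA/pF)."""
    v = y[0]
    nai = y[16]; ki = y[17]; cai = y[18]
    e_na = RT_F * math.log(NAO / nai)
    e_k = RT_F * math.log(KO / ki)
    out = np.empty(9)
    out[0] = scale[0] * G_NA * y[1] ** 3 * y[2] * y[3] * (v - e_na)
    out[1] = scale[1] * G_TO * y[4] ** 3 * y[5] * (v - e_k)
    out[2] = scale[2] * G_CAL * y[10] * y[11] * y[12] * (v - 65.0)
    g_kur = 0.005 + 0.05 / (1.0 + math.exp(-(v - 15.0) / 13.0))
    out[3] = scale[3] * g_kur * y[6] ** 3 * y[7] * (v - e_k)
    out[4] = scale[4] * G_KR * y[8] * (v - e_k) / (1.0 + math.exp((v + 15.0) / 22.4))
    out[5] = scale[5] * G_KS * y[9] ** 2 * (v - e_k)
    out[6] = scale[6] * G_K1 * (v - e_k) / (1.0 + math.exp(0.07 * (v + 80.0)))
    sigma = (math.exp(NAO / 67.3) - 1.0) / 7.0
    f_nak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * v / RT_F)
                   + 0.0365 * sigma * math.exp(-v / RT_F))
    out[8] = scale[8] * I_NAK_MAX * f_nak * (KO / (KO + KM_KO)) \
        / (1.0 + (KM_NAI / nai) ** 1.5)
    expg = math.exp(GAMMA * v / RT_F)
    expg1 = math.exp((GAMMA - 1.0) * v / RT_F)
    out[7] = scale[7] * I_NACA_MAX * (expg * nai ** 3 * CAO - expg1 * NAO ** 3 * cai) \
        / ((KM_NA ** 3 + NAO ** 3) * (KM_CA + CAO) * (1.0 + K_SAT * expg1))
    return out
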