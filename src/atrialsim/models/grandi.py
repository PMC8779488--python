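"""Grandi et al. (2011) human atrial cardiomyocyte model (sinus rhythm).

38 state variables: membrane potential, 13 gating variables, 3 ryanodine-
receptor states, Na+ and Ca2+ buffer occupancies, calsequestrin, SR Ca2+,
and Na+/Ca2+ in three compartments (junctional cleft, subsarcolemmal space,
bulk cytosol).  Intracellular K+ and Cl- are fixed parameters in this model.
Parameterization is the sinus-rhythm one (AF and isoproterenol flags off,
right-atrium flag off) of the published code of the original article.

The Ca2+ buffering reactions are orders of magnitude faster than the
membrane kinetics, so the fixed-step scheme splits every state's rate into
``dy = a - b*y`` with a nonnegative sink coefficient ``b`` (exact for the
buffers, the dominant linear part elsewhere) and applies the exponential
update ``y <- a/b + (y - a/b) exp(-b dt)``; this is the Rush–Larsen update
for gates and an unconditionally stable integrator for the buffer states.

Units: mV, ms, mM, A/F (= pA/pF).  Outward current positive; positive
stimulus depolarizes.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

N_STATE = 38
V_INDEX = 0
STATE_NAMES = (
    "V", "m", "h", "j", "d", "f", "fcaBj", "fcaBsl",
    "xtof", "ytof", "xkr", "xks", "xkur", "ykur",
    "RyRr", "RyRo", "RyRi",
    "NaBj", "NaBsl",
    "TnCL", "TnCHc", "TnCHm", "CaM", "Myoc", "Myom", "SRB",
    "SLLj", "SLLsl", "SLHj", "SLHsl",
    "Csqnb", "Ca_sr",
    "Naj", "Nasl", "Nai",
    "Caj", "Casl", "Cai",
)
#: fraction-type states kept in [0,1] (HH gates, Ca-dependent CaL
#: inactivation fractions, RyR states)
GATE_INDICES = np.arange(1, 17)
CONC_INDICES = np.arange(17, 38)

# --- physical constants -------------------------------------------------
R = 8314.0        # J kmol^-1 K^-1
FRDY = 96485.0    # C mol^-1
TEMP = 310.0      # K
FORT = FRDY / (R * TEMP)
CMEM = 1.10e-10   # F
QPOW = 0.0        # (T-310)/10

# cell geometry [L]
CELL_LENGTH = 100.0
CELL_RADIUS = 10.25
V_CELL = math.pi * CELL_RADIUS ** 2 * CELL_LENGTH * 1e-15
V_MYO = 0.65 * V_CELL
V_SR = 0.035 * V_CELL
V_SL = 0.02 * V_CELL
V_JUNC = 0.0539 * 0.01 * V_CELL
J_CA_JUNCSL = 1.0 / 1.2134e12   # L/ms
J_CA_SLMYO = 1.0 / 2.68510e11
J_NA_JUNCSL = 1.0 / (1.6382e12 / 3 * 100)
J_NA_SLMYO = 1.0 / (1.8308e10 / 3 * 100)

F_JUNC = 0.11
F_SL = 1.0 - F_JUNC
F_JUNC_CAL = 0.9
F_SL_CAL = 0.1

# fixed ion concentrations [mM]
KO = 5.4
NAO = 140.0
CAO = 1.8
KI = 120.0
CLI = 15.0
CLO = 150.0
MGI = 1.0

# --- membrane current parameters (sinus rhythm: AF=0, ISO=0, RA=0) ------
G_NA = 23.0            # mS/uF
G_NA_B = 0.597e-3
IBAR_NAK = 1.26        # A/F
KM_NAIP = 11.0
KM_KO = 1.5
G_KR = 0.035 * math.sqrt(KO / 5.4)
G_KS = 0.0035
P_NAK = 0.01833
G_KP = 0.002
G_TO_FAST = 0.165
G_KUR = 0.045
G_K1 = 0.0525 * math.sqrt(KO / 5.4)
G_CL_CA = 0.0548
G_CL_B = 9e-3
KD_CL_CA = 100e-3
P_NA = 0.75e-8
P_CA = 2.7e-4
P_K = 1.35e-7
IBAR_NCX = 3.15        # A/F
KM_CAI = 3.59e-3
KM_CAO = 1.3
KM_NAI = 12.29
KM_NAO = 87.5
K_SAT = 0.27
NU = 0.35
KD_ACT = 0.384e-3
IBAR_SLCAP = 0.0471
KM_PCA = 0.5e-3
G_CA_B = 6.0643e-4

# --- SR parameters ------------------------------------------------------
VMAX_SRCAP = 5.3114e-3  # mM/ms
KMF = 0.246e-3
KMR = 1.7
HILL_SRCAP = 1.787
KS_REL = 25.0           # 1/ms
KO_CA = 10.0
KOM = 0.06
KI_CA = 0.5
KIM = 0.005
EC50_SR = 0.45
MAX_SR = 15.0
MIN_SR = 1.0
LEAK = 5.348e-6

# --- buffering ----------------------------------------------------------
BMAX_NAJ = 7.561
BMAX_NASL = 1.65
KOFF_NA = 1e-3
KON_NA = 1e-4
BMAX_TNCLOW = 70e-3
KOFF_TNCL = 19.6e-3
KON_TNCL = 32.7
BMAX_TNCHIGH = 140e-3
KOFF_TNCHCA = 0.032e-3
KON_TNCHCA = 2.37
KOFF_TNCHMG = 3.33e-3
KON_TNCHMG = 3e-3
BMAX_CAM = 24e-3
KOFF_CAM = 238e-3
KON_CAM = 34.0
BMAX_MYOSIN = 140e-3
KOFF_MYOCA = 0.46e-3
KON_MYOCA = 13.8
KOFF_MYOMG = 0.057e-3
KON_MYOMG = 0.0157
BMAX_SR = 19.0 * 0.9e-3
KOFF_SR = 60e-3
KON_SR = 100.0
BMAX_SLLOWSL = 37.4e-3 * V_MYO / V_SL
BMAX_SLLOWJ = 4.6e-3 * V_MYO / V_JUNC * 0.1
BMAX_SLHIGHSL = 13.4e-3 * V_MYO / V_SL
BMAX_SLHIGHJ = 1.65e-3 * V_MYO / V_JUNC * 0.1
KOFF_SLL = 1300e-3
KON_SLL = 100.0
KOFF_SLH = 30e-3
KON_SLH = 100.0
BMAX_CSQN = 140e-3 * V_MYO / V_SR
KOFF_CSQN = 65.0
KON_CSQN = 100.0

E_CL = (1.0 / FORT) * math.log(CLI / CLO)
E_K = (1.0 / FORT) * math.log(KO / KI)

#: relaxed resting state (quiescent steady state of this implementation;
#: regenerated by scripts if the equations change)
Y0 = np.array([
    -7.38905680e+01,  # V
    1.40562700e-03, 9.86700500e-01, 9.91562000e-01,   # m h j
    7.17566200e-06, 1.00000000e+00,                   # d f
    2.42199100e-02, 1.45260500e-02,                   # fcaBj fcaBsl
    4.05157400e-03, 9.94551100e-01,                   # xtof ytof
    8.64138600e-03, 5.41203400e-03,                   # xkr xks
    5.00000000e-04, 9.90000000e-01,                   # xkur ykur
    8.88433200e-01, 8.15662800e-07, 1.02427400e-07,   # RyR r o i
    3.53989200e+00, 7.72085400e-01,                   # NaBj NaBsl
    8.77319100e-03, 1.07828300e-01, 1.52400200e-02,   # TnCL TnCHc TnCHm
    2.91191600e-04, 1.29875400e-03, 1.38198200e-01,   # CaM Myoc Myom
    2.14316500e-03,                                   # SRB
    9.56635500e-03, 1.11036300e-01,                   # SLLj SLLsl
    7.34788800e-03, 7.29737800e-02,                   # SLHj SLHsl
    1.24298800e+00, 5.54520100e-01,                   # Csqnb Ca_sr
    9.13600000e+00, 9.13600000e+00, 9.13600000e+00,   # Naj Nasl Nai
    1.73747500e-04, 1.03181200e-04, 8.59740100e-05,   # Caj Casl Cai
])


@njit(cache=True, fastmath=True)
def _algebra(y, scale, i_stim, dy, lin_b):
    """Full derivatives plus per-state sink coefficients.

    ``dy[k]`` is the exact time derivative; ``lin_b[k] >= 0`` is the
    coefficient of the ``-lin_b[k]*y[k]`` part of that derivative that the
    fixed-step scheme integrates exponentially (0 where purely explicit).
    ``scale``: 9 multipliers in order (INa, Ito, ICaL, IKur, IKr, IKs, IK1,
    INCX, INaK).
    """
    v = y[0]
    m = y[1]; h = y[2]; jg = y[3]
    d = y[4]; f = y[5]; fcabj = y[6]; fcabsl = y[7]
    xtof = y[8]; ytof = y[9]; xkr = y[10]; xks = y[11]
    xkur = y[12]; ykur = y[13]
    ryrr = y[14]; ryro = y[15]; ryri = y[16]
    nabj = y[17]; nabsl = y[18]
    tncl = y[19]; tnchc = y[20]; tnchm = y[21]
    cam = y[22]; myoc = y[23]; myom = y[24]; srb = y[25]
    sllj = y[26]; sllsl = y[27]; slhj = y[28]; slhsl = y[29]
    csqnb = y[30]; casr = y[31]
    naj = y[32]; nasl = y[33]; nai = y[34]
    caj = y[35]; casl = y[36]; cai = y[37]

    ena_junc = (1.0 / FORT) * math.log(NAO / naj)
    ena_sl = (1.0 / FORT) * math.log(NAO / nasl)
    eca_junc = (0.5 / FORT) * math.log(CAO / caj)
    eca_sl = (0.5 / FORT) * math.log(CAO / casl)
    eks = (1.0 / FORT) * math.log((KO + P_NAK * NAO) / (KI + P_NAK * nai))

    # --- INa (scale[0]) ---
    gna = scale[0] * G_NA
    i_na_junc = F_JUNC * gna * m ** 3 * h * jg * (v - ena_junc)
    i_na_sl = F_SL * gna * m ** 3 * h * jg * (v - ena_sl)

    i_nabk_junc = F_JUNC * G_NA_B * (v - ena_junc)
    i_nabk_sl = F_SL * G_NA_B * (v - ena_sl)

    # --- INaK (scale[8]) ---
    sigma = (math.exp(NAO / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * v * FORT)
                  + 0.0365 * sigma * math.exp(-v * FORT))
    ibar_nak = scale[8] * IBAR_NAK
    i_nak_junc = F_JUNC * ibar_nak * fnak * KO \
        / (1.0 + (KM_NAIP / naj) ** 4) / (KO + KM_KO)
    i_nak_sl = F_SL * ibar_nak * fnak * KO \
        / (1.0 + (KM_NAIP / nasl) ** 4) / (KO + KM_KO)
    i_nak = i_nak_junc + i_nak_sl

    # --- IKr (scale[4]) ---
    rkr = 1.0 / (1.0 + math.exp((v + 74.0) / 24.0))
    i_kr = scale[4] * G_KR * xkr * rkr * (v - E_K)

    # --- IKs (scale[5]) ---
    i_ks = scale[5] * G_KS * xks * xks * (v - eks)

    # --- IKp ---
    kp_kp = 1.0 / (1.0 + math.exp(7.488 - v / 5.98))
    i_kp = G_KP * kp_kp * (v - E_K)

    # --- Ito, fast component only (scale[1]) ---
    i_to = scale[1] * G_TO_FAST * xtof * ytof * (v - E_K)

    # --- IKur (scale[3]) ---
    i_kur = scale[3] * G_KUR * xkur * ykur * (v - E_K)

    # --- IK1 (scale[6]) ---
    aki = 1.02 / (1.0 + math.exp(0.2385 * (v - E_K - 59.215)))
    bki = (0.49124 * math.exp(0.08032 * (v + 5.476 - E_K))
           + math.exp(0.06175 * (v - E_K - 594.31))) \
        / (1.0 + math.exp(-0.5143 * (v - E_K + 4.753)))
    kiss = aki / (aki + bki)
    i_k1 = scale[6] * G_K1 * kiss * (v - E_K)

    # --- Ca-activated and background Cl- ---
    i_clca = F_JUNC * G_CL_CA / (1.0 + KD_CL_CA / caj) * (v - E_CL) \
        + F_SL * G_CL_CA / (1.0 + KD_CL_CA / casl) * (v - E_CL)
    i_clbk = G_CL_B * (v - E_CL)

    # --- ICaL (scale[2] on all three permeabilities) ---
    # GHK driving terms; v = 0 is a removable singularity, nudge past it
    vv = v if abs(v) > 1e-6 else 1e-6
    ef = vv * FRDY * FORT
    e2v = math.exp(2.0 * vv * FORT)
    e1v = math.exp(vv * FORT)
    ibarca_j = P_CA * 4.0 * ef * (0.341 * caj * e2v - 0.341 * CAO) / (e2v - 1.0)
    ibarca_sl = P_CA * 4.0 * ef * (0.341 * casl * e2v - 0.341 * CAO) / (e2v - 1.0)
    ibark = P_K * ef * (0.75 * KI * e1v - 0.75 * KO) / (e1v - 1.0)
    ibarna_j = P_NA * ef * (0.75 * naj * e1v - 0.75 * NAO) / (e1v - 1.0)
    ibarna_sl = P_NA * ef * (0.75 * nasl * e1v - 0.75 * NAO) / (e1v - 1.0)
    s_cal = scale[2] * 0.45
    i_ca_junc = F_JUNC_CAL * ibarca_j * d * f * (1.0 - fcabj) * s_cal
    i_ca_sl = F_SL_CAL * ibarca_sl * d * f * (1.0 - fcabsl) * s_cal
    i_cak = ibark * d * f * (F_JUNC_CAL * (1.0 - fcabj)
                             + F_SL_CAL * (1.0 - fcabsl)) * s_cal
    i_cana_junc = F_JUNC_CAL * ibarna_j * d * f * (1.0 - fcabj) * s_cal
    i_cana_sl = F_SL_CAL * ibarna_sl * d * f * (1.0 - fcabsl) * s_cal

    # --- INCX (scale[7]) ---
    ibar_ncx = scale[7] * IBAR_NCX
    expnu = math.exp(NU * v * FORT)
    expnu1 = math.exp((NU - 1.0) * v * FORT)
    ka_junc = 1.0 / (1.0 + (KD_ACT / caj) ** 2)
    ka_sl = 1.0 / (1.0 + (KD_ACT / casl) ** 2)
    s1_j = expnu * naj ** 3 * CAO
    s2_j = expnu1 * NAO ** 3 * caj
    s3_j = KM_CAI * NAO ** 3 * (1.0 + (naj / KM_NAI) ** 3) \
        + KM_NAO ** 3 * caj * (1.0 + caj / KM_CAI) \
        + KM_CAO * naj ** 3 + naj ** 3 * CAO + NAO ** 3 * caj
    i_ncx_junc = F_JUNC * ibar_ncx * ka_junc * (s1_j - s2_j) / s3_j \
        / (1.0 + K_SAT * expnu1)
    s1_s = expnu * nasl ** 3 * CAO
    s2_s = expnu1 * NAO ** 3 * casl
    s3_s = KM_CAI * NAO ** 3 * (1.0 + (nasl / KM_NAI) ** 3) \
        + KM_NAO ** 3 * casl * (1.0 + casl / KM_CAI) \
        + KM_CAO * nasl ** 3 + nasl ** 3 * CAO + NAO ** 3 * casl
    i_ncx_sl = F_SL * ibar_ncx * ka_sl * (s1_s - s2_s) / s3_s \
        / (1.0 + K_SAT * expnu1)

    # --- sarcolemmal Ca pump, background Ca ---
    i_pca_junc = F_JUNC * IBAR_SLCAP * caj ** 1.6 / (KM_PCA ** 1.6 + caj ** 1.6)
    i_pca_sl = F_SL * IBAR_SLCAP * casl ** 1.6 / (KM_PCA ** 1.6 + casl ** 1.6)
    i_cabk_junc = F_JUNC * G_CA_B * (v - eca_junc)
    i_cabk_sl = F_SL * G_CA_B * (v - eca_sl)

    # --- SR fluxes ---
    kcasr = MAX_SR - (MAX_SR - MIN_SR) / (1.0 + (EC50_SR / casr) ** 2.5)
    kosrca = KO_CA / kcasr
    kisrca = KI_CA * kcasr
    ri = 1.0 - ryrr - ryro - ryri
    dy[14] = (KIM * ri - kisrca * caj * ryrr) \
        - (kosrca * caj * caj * ryrr - KOM * ryro)
    dy[15] = (kosrca * caj * caj * ryrr - KOM * ryro) \
        - (kisrca * caj * ryro - KIM * ryri)
    dy[16] = (kisrca * caj * ryro - KIM * ryri) \
        - (KOM * ryri - kosrca * caj * caj * ri)
    lin_b[14] = kisrca * caj + kosrca * caj * caj + KIM
    lin_b[15] = KOM + kisrca * caj
    lin_b[16] = KIM + KOM + kosrca * caj * caj
    j_srcarel = KS_REL * ryro * (casr - caj)
    cf = (cai / KMF) ** HILL_SRCAP
    cr = (casr / KMR) ** HILL_SRCAP
    j_serca = VMAX_SRCAP * (cf - cr) / (1.0 + cf + cr)
    j_srleak = LEAK * (casr - caj)

    # --- Na buffers ---
    dy[17] = KON_NA * naj * (BMAX_NAJ - nabj) - KOFF_NA * nabj
    lin_b[17] = KON_NA * naj + KOFF_NA
    dy[18] = KON_NA * nasl * (BMAX_NASL - nabsl) - KOFF_NA * nabsl
    lin_b[18] = KON_NA * nasl + KOFF_NA

    # --- cytosolic Ca buffers ---
    dy[19] = KON_TNCL * cai * (BMAX_TNCLOW - tncl) - KOFF_TNCL * tncl
    lin_b[19] = KON_TNCL * cai + KOFF_TNCL
    dy[20] = KON_TNCHCA * cai * (BMAX_TNCHIGH - tnchc - tnchm) \
        - KOFF_TNCHCA * tnchc
    lin_b[20] = KON_TNCHCA * cai + KOFF_TNCHCA
    dy[21] = KON_TNCHMG * MGI * (BMAX_TNCHIGH - tnchc - tnchm) \
        - KOFF_TNCHMG * tnchm
    lin_b[21] = KON_TNCHMG * MGI + KOFF_TNCHMG
    dy[22] = KON_CAM * cai * (BMAX_CAM - cam) - KOFF_CAM * cam
    lin_b[22] = KON_CAM * cai + KOFF_CAM
    dy[23] = KON_MYOCA * cai * (BMAX_MYOSIN - myoc - myom) - KOFF_MYOCA * myoc
    lin_b[23] = KON_MYOCA * cai + KOFF_MYOCA
    dy[24] = KON_MYOMG * MGI * (BMAX_MYOSIN - myoc - myom) - KOFF_MYOMG * myom
    lin_b[24] = KON_MYOMG * MGI + KOFF_MYOMG
    dy[25] = KON_SR * cai * (BMAX_SR - srb) - KOFF_SR * srb
    lin_b[25] = KON_SR * cai + KOFF_SR
    # Ca actually bound/released by the Ca-binding reactions only
    j_cab_cytosol = dy[19] + dy[20] + dy[22] + dy[23] + dy[25]

    # --- junctional / SL membrane buffers ---
    dy[26] = KON_SLL * caj * (BMAX_SLLOWJ - sllj) - KOFF_SLL * sllj
    lin_b[26] = KON_SLL * caj + KOFF_SLL
    dy[27] = KON_SLL * casl * (BMAX_SLLOWSL - sllsl) - KOFF_SLL * sllsl
    lin_b[27] = KON_SLL * casl + KOFF_SLL
    dy[28] = KON_SLH * caj * (BMAX_SLHIGHJ - slhj) - KOFF_SLH * slhj
    lin_b[28] = KON_SLH * caj + KOFF_SLH
    dy[29] = KON_SLH * casl * (BMAX_SLHIGHSL - slhsl) - KOFF_SLH * slhsl
    lin_b[29] = KON_SLH * casl + KOFF_SLH
    j_cab_junction = dy[26] + dy[28]
    j_cab_sl = dy[27] + dy[29]

    # --- calsequestrin and SR Ca ---
    dy[30] = KON_CSQN * casr * (BMAX_CSQN - csqnb) - KOFF_CSQN * csqnb
    lin_b[30] = KON_CSQN * casr + KOFF_CSQN
    dy[31] = j_serca - (j_srleak * V_MYO / V_SR + j_srcarel) - dy[30]
    lin_b[31] = KS_REL * ryro + LEAK * V_MYO / V_SR \
        + KON_CSQN * (BMAX_CSQN - csqnb)

    # --- Na concentrations ---
    i_na_tot_junc = i_na_junc + i_nabk_junc + 3.0 * i_ncx_junc \
        + 3.0 * i_nak_junc + i_cana_junc
    i_na_tot_sl = i_na_sl + i_nabk_sl + 3.0 * i_ncx_sl \
        + 3.0 * i_nak_sl + i_cana_sl
    dy[32] = -i_na_tot_junc * CMEM / (V_JUNC * FRDY) \
        + J_NA_JUNCSL / V_JUNC * (nasl - naj) - dy[17]
    lin_b[32] = J_NA_JUNCSL / V_JUNC + KON_NA * (BMAX_NAJ - nabj)
    dy[33] = -i_na_tot_sl * CMEM / (V_SL * FRDY) \
        + J_NA_JUNCSL / V_SL * (naj - nasl) \
        + J_NA_SLMYO / V_SL * (nai - nasl) - dy[18]
    lin_b[33] = (J_NA_JUNCSL + J_NA_SLMYO) / V_SL + KON_NA * (BMAX_NASL - nabsl)
    dy[34] = J_NA_SLMYO / V_MYO * (nasl - nai)
    lin_b[34] = J_NA_SLMYO / V_MYO

    # --- Ca concentrations ---
    i_ca_tot_junc = i_ca_junc + i_cabk_junc + i_pca_junc - 2.0 * i_ncx_junc
    i_ca_tot_sl = i_ca_sl + i_cabk_sl + i_pca_sl - 2.0 * i_ncx_sl
    dy[35] = -i_ca_tot_junc * CMEM / (V_JUNC * 2.0 * FRDY) \
        + J_CA_JUNCSL / V_JUNC * (casl - caj) - j_cab_junction \
        + j_srcarel * V_SR / V_JUNC + j_srleak * V_MYO / V_JUNC
    lin_b[35] = J_CA_JUNCSL / V_JUNC + KS_REL * ryro * V_SR / V_JUNC \
        + LEAK * V_MYO / V_JUNC + KON_SLL * (BMAX_SLLOWJ - sllj) \
        + KON_SLH * (BMAX_SLHIGHJ - slhj)
    dy[36] = -i_ca_tot_sl * CMEM / (V_SL * 2.0 * FRDY) \
        + J_CA_JUNCSL / V_SL * (caj - casl) \
        + J_CA_SLMYO / V_SL * (cai - casl) - j_cab_sl
    lin_b[36] = (J_CA_JUNCSL + J_CA_SLMYO) / V_SL \
        + KON_SLL * (BMAX_SLLOWSL - sllsl) + KON_SLH * (BMAX_SLHIGHSL - slhsl)
    dy[37] = -j_serca * V_SR / V_MYO - j_cab_cytosol \
        + J_CA_SLMYO / V_MYO * (casl - cai)
    lin_b[37] = J_CA_SLMYO / V_MYO + KON_TNCL * (BMAX_TNCLOW - tncl) \
        + KON_TNCHCA * (BMAX_TNCHIGH - tnchc - tnchm) \
        + KON_CAM * (BMAX_CAM - cam) \
        + KON_MYOCA * (BMAX_MYOSIN - myoc - myom) + KON_SR * (BMAX_SR - srb)

    # --- gating kinetics ---
    # INa gates (steady states squared per the source formulation)
    mss = 1.0 / (1.0 + math.exp(-(56.86 + v) / 9.03)) ** 2
    taum = 0.1292 * math.exp(-((v + 45.79) / 15.54) ** 2) \
        + 0.06487 * math.exp(-((v - 4.823) / 51.12) ** 2)
    if v >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.6 * math.exp(0.057 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    else:
        ah = 0.057 * math.exp(-(v + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.3485 * v)
        aj = (-2.5428e4 * math.exp(0.2444 * v) - 6.948e-6 * math.exp(-0.04391 * v)) \
            * (v + 37.78) / (1.0 + math.exp(0.311 * (v + 79.23)))
        bj = 0.02424 * math.exp(-0.01052 * v) \
            / (1.0 + math.exp(-0.1378 * (v + 40.14)))
    hss = 1.0 / (1.0 + math.exp((v + 71.55) / 7.43)) ** 2
    jss = hss
    tauh = 1.0 / (ah + bh)
    tauj = 1.0 / (aj + bj)
    dy[1] = (mss - m) / taum
    lin_b[1] = 1.0 / taum
    dy[2] = (hss - h) / tauh
    lin_b[2] = 1.0 / tauh
    dy[3] = (jss - jg) / tauj
    lin_b[3] = 1.0 / tauj

    # ICaL gates
    dv9 = v + 9.0
    dss = 1.0 / (1.0 + math.exp(-dv9 / 6.0))
    if abs(dv9) < 1e-10:
        taud = dss / (0.035 * 6.0)  # lim (1-e^{-x/6})/x = 1/6
    else:
        taud = dss * (1.0 - math.exp(-dv9 / 6.0)) / (0.035 * dv9)
    fss = 1.0 / (1.0 + math.exp((v + 30.0) / 7.0)) \
        + 0.2 / (1.0 + math.exp((50.0 - v) / 20.0))
    tauf = 1.0 / (0.0197 * math.exp(-(0.0337 * (v + 25.0)) ** 2) + 0.02)
    dy[4] = (dss - d) / taud
    lin_b[4] = 1.0 / taud
    dy[5] = (fss - f) / tauf
    lin_b[5] = 1.0 / tauf
    dy[6] = 1.7 * caj * (1.0 - fcabj) - 11.9e-3 * fcabj
    lin_b[6] = 1.7 * caj + 11.9e-3
    dy[7] = 1.7 * casl * (1.0 - fcabsl) - 11.9e-3 * fcabsl
    lin_b[7] = 1.7 * casl + 11.9e-3

    # Ito gates
    xtoss = 1.0 / (1.0 + math.exp(-(v + 1.0) / 11.0))
    tauxtof = 3.5 * math.exp(-(v / 30.0) ** 2) + 1.5
    ytoss = 1.0 / (1.0 + math.exp((v + 40.5) / 11.5))
    tauytof = 25.635 * math.exp(-((v + 52.45) / 15.8827) ** 2) + 24.14
    dy[8] = (xtoss - xtof) / tauxtof
    lin_b[8] = 1.0 / tauxtof
    dy[9] = (ytoss - ytof) / tauytof
    lin_b[9] = 1.0 / tauytof

    # IKr / IKs gates
    xrss = 1.0 / (1.0 + math.exp(-(v + 10.0) / 5.0))
    tauxr = 550.0 / (1.0 + math.exp((-22.0 - v) / 9.0)) * 6.0 \
        / (1.0 + math.exp((v + 11.0) / 9.0)) \
        + 230.0 / (1.0 + math.exp((v + 40.0) / 20.0))
    dy[10] = (xrss - xkr) / tauxr
    lin_b[10] = 1.0 / tauxr
    xsss = 1.0 / (1.0 + math.exp(-(v + 3.8) / 14.25))
    tauxs = 990.1 / (1.0 + math.exp(-(v + 2.436) / 14.12))
    dy[11] = (xsss - xks) / tauxs
    lin_b[11] = 1.0 / tauxs

    # IKur gates
    xkurss = 1.0 / (1.0 + math.exp(-(v + 6.0) / 8.6))
    tauxkur = 9.0 / (1.0 + math.exp((v + 5.0) / 12.0)) + 0.5
    ykurss = 1.0 / (1.0 + math.exp((v + 7.5) / 10.0))
    tauykur = 590.0 / (1.0 + math.exp((v + 60.0) / 10.0)) + 3050.0
    dy[12] = (xkurss - xkur) / tauxkur
    lin_b[12] = 1.0 / tauxkur
    dy[13] = (ykurss - ykur) / tauykur
    lin_b[13] = 1.0 / tauykur

    # --- membrane potential ---
    i_na_tot = i_na_tot_junc + i_na_tot_sl
    i_cl_tot = i_clca + i_clbk
    i_ca_tot = i_ca_tot_junc + i_ca_tot_sl
    i_k_tot = i_to + i_kr + i_ks + i_k1 - 2.0 * i_nak + i_cak + i_kp + i_kur
    i_tot = i_na_tot + i_cl_tot + i_ca_tot + i_k_tot
    dy[0] = -i_tot + i_stim
    lin_b[0] = 0.0


@njit(cache=True)
def rhs(t, y, scale, i_stim):
    """Time derivatives of the full state (unit/ms)."""
    dy = np.empty(N_STATE)
    lin_b = np.zeros(N_STATE)
    _algebra(y, scale, i_stim, dy, lin_b)
    return dy


@njit(cache=True, fastmath=True)
def _exp_update(y, dy, lin_b, dt):
    """Exponential update of the linear-split rates; V handled by caller."""
    for k in range(1, N_STATE):
        b = lin_b[k]
        if b * dt > 1e-8:
            a = dy[k] + b * y[k]
            yinf = a / b
            y[k] = yinf + (y[k] - yinf) * math.exp(-b * dt)
        else:
            y[k] += dt * dy[k]
    for k in range(1, 17):
        if y[k] < 0.0:
            y[k] = 0.0
        elif y[k] > 1.0:
            y[k] = 1.0


@njit(cache=True)
def step_rl(y, dt, scale, i_stim):
    """One in-place fixed step (exponential for gates/buffers, Euler for V)."""
    dy = np.empty(N_STATE)
    lin_b = np.zeros(N_STATE)
    _algebra(y, scale, i_stim, dy, lin_b)
    y[0] += dt * dy[0]
    _exp_update(y, dy, lin_b, dt)


@njit(cache=True)
def reaction_rl(y, dt, scale, i_stim):
    """Reaction-only fixed step; returns dV/dt for the tissue kernel."""
    dy = np.empty(N_STATE)
    lin_b = np.zeros(N_STATE)
    _algebra(y, scale, i_stim, dy, lin_b)
    _exp_update(y, dy, lin_b, dt)
    return dy[0]


@njit(cache=True, fastmath=True)
def reaction_ws(y, dt, scale, i_stim, w1, w2, w3, aux):
    """Workspace variant of :func:`reaction_rl` (no per-call allocation)."""
    _algebra(y, scale, i_stim, w1, w2)
    _exp_update(y, w1, w2, dt)
    return w1[0]


@njit(cache=True)
def currents(y, scale):
    """Instantaneous values of the nine scalable currents (A/F).

    Compartment-split currents (INa, ICaL, INCX, INaK) are reported as
    junctional + subsarcolemmal totals; ICaL includes its K+ and Na+
    components.
    """
    v = y[0]
    naj = y[32]; nasl = y[33]; nai = y[34]
    caj = y[35]; casl = y[36]
    ena_junc = (1.0 / FORT) * math.log(NAO / naj)
    ena_sl = (1.0 / FORT) * math.log(NAO / nasl)
    eks = (1.0 / FORT) * math.log((KO + P_NAK * NAO) / (KI + P_NAK * nai))
    out = np.empty(9)
    gna = scale[0] * G_NA
    out[0] = gna * y[1] ** 3 * y[2] * y[3] \
        * (F_JUNC * (v - ena_junc) + F_SL * (v - ena_sl))
    out[1] = scale[1] * G_TO_FAST * y[8] * y[9] * (v - E_K)
    ef = v * FRDY * FORT if abs(v) > 1e-6 else 1e-6 * FRDY * FORT
    vv = v if abs(v) > 1e-6 else 1e-6
    e2v = math.exp(2.0 * vv * FORT)
    e1v = math.exp(vv * FORT)
    ibarca_j = P_CA * 4.0 * ef * (0.341 * caj * e2v - 0.341 * CAO) / (e2v - 1.0)
    ibarca_sl = P_CA * 4.0 * ef * (0.341 * casl * e2v - 0.341 * CAO) / (e2v - 1.0)
    ibark = P_K * ef * (0.75 * KI * e1v - 0.75 * KO) / (e1v - 1.0)
    ibarna_j = P_NA * ef * (0.75 * naj * e1v - 0.75 * NAO) / (e1v - 1.0)
    ibarna_sl = P_NA * ef * (0.75 * nasl * e1v - 0.75 * NAO) / (e1v - 1.0)
    s_cal = scale[2] * 0.45
    d = y[4]; f = y[5]; fcabj = y[6]; fcabsl = y[7]
    out[2] = (F_JUNC_CAL * (ibarca_j + ibarna_j) * (1.0 - fcabj)
              + F_SL_CAL * (ibarca_sl + ibarna_sl) * (1.0 - fcabsl)
              + ibark * (F_JUNC_CAL * (1.0 - fcabj) + F_SL_CAL * (1.0 - fcabsl))
              ) * d * f * s_cal
    out[3] = scale[3] * G_KUR * y[12] * y[13] * (v - E_K)
    rkr = 1.0 / (1.0 + math.exp((v + 74.0) / 24.0))
    out[4] = scale[4] * G_KR * y[10] * rkr * (v - E_K)
    out[5] = scale[5] * G_KS * y[11] ** 2 * (v - eks)
    aki = 1.02 / (1.0 + math.exp(0.2385 * (v - E_K - 59.215)))
    bki = (0.49124 * math.exp(0.08032 * (v + 5.476 - E_K))
           + math.exp(0.06175 * (v - E_K - 594.31))) \
        / (1.0 + math.exp(-0.5143 * (v - E_K + 4.753)))
    out[6] = scale[6] * G_K1 * aki / (aki + bki) * (v - E_K)
    expnu = math.exp(NU * v * FORT)
    expnu1 = math.exp((NU - 1.0) * v * FORT)
    ka_junc = 1.0 / (1.0 + (KD_ACT / caj) ** 2)
    ka_sl = 1.0 / (1.0 + (KD_ACT / casl) ** 2)
    s1_j = expnu * naj ** 3 * CAO
    s2_j = expnu1 * NAO ** 3 * caj
    s3_j = KM_CAI * NAO ** 3 * (1.0 + (naj / KM_NAI) ** 3) \
        + KM_NAO ** 3 * caj * (1.0 + caj / KM_CAI) \
        + KM_CAO * naj ** 3 + naj ** 3 * CAO + NAO ** 3 * caj
    s1_s = expnu * nasl ** 3 * CAO
    s2_s = expnu1 * NAO ** 3 * casl
    s3_s = KM_CAI * NAO ** 3 * (1.0 + (nasl / KM_NAI) ** 3) \
        + KM_NAO ** 3 * casl * (1.0 + casl / KM_CAI) \
        + KM_CAO * nasl ** 3 + nasl ** 3 * CAO + NAO ** 3 * casl
    out[7] = scale[7] * IBAR_NCX * (
        F_JUNC * ka_junc * (s1_j - s2_j) / s3_j
        + F_SL * ka_sl * (s1_s - s2_s) / s3_s) / (1.0 + K_SAT * expnu1)
    sigma = (math.exp(NAO / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * v * FORT)
                  + 0.0365 * sigma * math.exp(-v * FORT))
    out[8] = scale[8] * IBAR_NAK * fnak * KO / (KO + KM_KO) * (
        F_JUNC / (1.0 + (KM_NAIP / naj) ** 4)
        + F_SL / (1.0 + (KM_NAIP / nasl) ** 4))
    return out
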