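"""Synthetic stand-in for the BPS2020 human ventricular cardiomyocyte model.

The Bartolucci-Passini-Severi 2020 (BPS2020) model is one of the two
independently developed updates of the O'Hara-Rudy dynamic (ORd) model.
This module is a SYNTHETIC stand-in for it, not the published BPS2020
equation set: it implements the ORd 2011 endocardial equation set (the
common ancestor that BPS2020 updates) operated with the BPS2020
extracellular milieu ([Na+]e 144, [K+]e 5.4, [Ca2+]e 2.7 mmol/L, with
[Cl-]e computed from the extracellular charge balance; Cl- carries no
membrane current in this model family).  It thereby plays BPS2020's role
in the two-model comparison: an ORd-family endocardial cell developed
along different lines from ToR-ORd, with a roughly five-fold smaller Ito
and a larger IKs, no chloride current, and a lower intracellular Na+
load.  Quantitative biomarkers of this stand-in are its own, not those of
the published BPS2020 model.

The hypernatremia hooks are identical to the other models: scaling of
ICaL/IKr/IKs/IK1/INaCa/INaK maximal amplitudes, perturbed milieu, and
uniform scaling of all intracellular compartment volumes (capacitive
area fixed).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ..constants import F, R
from ..osmotic import ExtracellularMilieu
from .base import (
    P_CAO,
    P_FCAL,
    P_FK1,
    P_FKR,
    P_FKS,
    P_FNAK,
    P_FNCX,
    P_ISTIM,
    P_KO,
    P_MASK,
    P_NAO,
    P_VFRAC,
    ModelDef,
    register_model,
)
from .torord import ACAP, VJSR, VMYO, VNSR, VSS, _flux, _inaca, _inak
from .torord import ion_amounts  # identical geometry and buffer constants

T = 310.0
RTF = R * T / F

STATE_NAMES: tuple[str, ...] = (
    "vm",
    "nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr",
    "m", "hf", "hs", "j", "hsp", "jp",
    "mL", "hL", "hLp",
    "a", "iF", "iS", "ap", "iFp", "iSp",
    "d", "ff", "fs", "fcaf", "fcas", "jca", "ffp", "fcafp", "nca",
    "xrf", "xrs", "xs1", "xs2", "xk1",
    "jrel_np", "jrel_p",
    "camkt",
)


@njit(cache=True)
def _core(y, p, dy, cur):
    v = y[0]
    nai = y[1]
    nass = y[2]
    ki = y[3]
    kss = y[4]
    cai = y[5]
    cass = y[6]
    cansr = y[7]
    cajsr = y[8]
    m = y[9]
    hf = y[10]
    hs = y[11]
    j = y[12]
    hsp = y[13]
    jp = y[14]
    mL = y[15]
    hL = y[16]
    hLp = y[17]
    a = y[18]
    iF = y[19]
    iS = y[20]
    ap = y[21]
    iFp = y[22]
    iSp = y[23]
    d = y[24]
    ff = y[25]
    fs = y[26]
    fcaf = y[27]
    fcas = y[28]
    jca = y[29]
    ffp = y[30]
    fcafp = y[31]
    nca = y[32]
    xrf = y[33]
    xrs = y[34]
    xs1 = y[35]
    xs2 = y[36]
    xk1 = y[37]
    jrel_np = y[38]
    jrel_p = y[39]
    camkt = y[40]

    nao = p[P_NAO]
    ko = p[P_KO]
    cao = p[P_CAO]
    f_ical = p[P_FCAL]
    f_ikr = p[P_FKR]
    f_iks = p[P_FKS]
    f_ik1 = p[P_FK1]
    f_ncx = p[P_FNCX]
    f_nak = p[P_FNAK]
    vfrac = p[P_VFRAC]
    istim = p[P_ISTIM]
    mask = p[P_MASK]

    vmyo = VMYO * vfrac
    vnsr = VNSR * vfrac
    vjsr = VJSR * vfrac
    vss = VSS * vfrac

    vfrt = v / RTF

    ena = RTF * math.log(nao / nai)
    ek = RTF * math.log(ko / ki)
    pkna = 0.01833
    eks = RTF * math.log((ko + pkna * nao) / (ki + pkna * nai))

    # CaMKII
    kmcamk = 0.15
    camkb = 0.05 * (1.0 - camkt) / (1.0 + 0.0015 / cass)
    camka = camkb + camkt
    dy[40] = 0.05 * camkb * (camkb + camkt) - 0.00068 * camkt

    # ---- INa ----
    mss = 1.0 / (1.0 + math.exp(-(v + 39.57) / 9.871))
    tm = 1.0 / (
        6.765 * math.exp((v + 11.64) / 34.77) + 8.552 * math.exp(-(v + 77.42) / 5.955)
    )
    dy[9] = (mss - m) / tm
    hss = 1.0 / (1.0 + math.exp((v + 82.90) / 6.086))
    thf = 1.0 / (
        1.432e-5 * math.exp(-(v + 1.196) / 6.285)
        + 6.149 * math.exp((v + 0.5096) / 20.27)
    )
    ths = 1.0 / (
        0.009794 * math.exp(-(v + 17.95) / 28.05)
        + 0.3343 * math.exp((v + 5.730) / 56.66)
    )
    ahf = 0.99
    ahs = 0.01
    dy[10] = (hss - hf) / thf
    dy[11] = (hss - hs) / ths
    h = ahf * hf + ahs * hs
    jss = hss
    tj = 2.038 + 1.0 / (
        0.02136 * math.exp(-(v + 100.6) / 8.281)
        + 0.3052 * math.exp((v + 0.9941) / 38.45)
    )
    dy[12] = (jss - j) / tj
    hssp = 1.0 / (1.0 + math.exp((v + 89.1) / 6.086))
    dy[13] = (hssp - hsp) / (3.0 * ths)
    hp = ahf * hf + ahs * hsp
    dy[14] = (jss - jp) / (1.46 * tj)
    finap = 1.0 / (1.0 + kmcamk / camka)
    gna = 75.0
    i_na = gna * (v - ena) * m ** 3 * ((1.0 - finap) * h * j + finap * hp * jp)

    # ---- INaL ----
    mlss = 1.0 / (1.0 + math.exp(-(v + 42.85) / 5.264))
    dy[15] = (mlss - mL) / tm
    hlss = 1.0 / (1.0 + math.exp((v + 87.61) / 7.488))
    thl = 200.0
    dy[16] = (hlss - hL) / thl
    hlssp = 1.0 / (1.0 + math.exp((v + 93.81) / 7.488))
    dy[17] = (hlssp - hLp) / (3.0 * thl)
    gnal = 0.0075
    i_nal = gnal * (v - ena) * mL * ((1.0 - finap) * hL + finap * hLp)

    # ---- Ito (endocardial) ----
    ass = 1.0 / (1.0 + math.exp(-(v - 14.34) / 14.82))
    ta = 1.0515 / (
        1.0 / (1.2089 * (1.0 + math.exp(-(v - 18.4099) / 29.3814)))
        + 3.5 / (1.0 + math.exp((v + 100.0) / 29.3814))
    )
    dy[18] = (ass - a) / ta
    iss = 1.0 / (1.0 + math.exp((v + 43.94) / 5.711))
    tif = 4.562 + 1.0 / (
        0.3933 * math.exp(-(v + 100.0) / 100.0) + 0.08004 * math.exp((v + 50.0) / 16.59)
    )
    tis = 23.62 + 1.0 / (
        0.001416 * math.exp(-(v + 96.52) / 59.05)
        + 1.780e-8 * math.exp((v + 114.1) / 8.079)
    )
    aif = 1.0 / (1.0 + math.exp((v - 213.6) / 151.2))
    ais = 1.0 - aif
    dy[19] = (iss - iF) / tif
    dy[20] = (iss - iS) / tis
    i_gate = aif * iF + ais * iS
    assp = 1.0 / (1.0 + math.exp(-(v - 24.34) / 14.82))
    dy[21] = (assp - ap) / ta
    dti_develop = 1.354 + 1.0e-4 / (
        math.exp((v - 167.4) / 15.89) + math.exp(-(v - 12.23) / 0.2154)
    )
    dti_recover = 1.0 - 0.5 / (1.0 + math.exp((v + 70.0) / 20.0))
    dy[22] = (iss - iFp) / (dti_develop * dti_recover * tif)
    dy[23] = (iss - iSp) / (dti_develop * dti_recover * tis)
    ip_gate = aif * iFp + ais * iSp
    gto = 0.02
    i_to = gto * (v - ek) * ((1.0 - finap) * a * i_gate + finap * ap * ip_gate)

    # ---- ICaL (all through the subspace) ----
    dss = 1.0 / (1.0 + math.exp(-(v + 3.940) / 4.230))
    td = 0.6 + 1.0 / (math.exp(-0.05 * (v + 6.0)) + math.exp(0.09 * (v + 14.0)))
    dy[24] = (dss - d) / td
    fss = 1.0 / (1.0 + math.exp((v + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (
        0.0045 * math.exp(-(v + 20.0) / 10.0) + 0.0045 * math.exp((v + 20.0) / 10.0)
    )
    tfs = 1000.0 + 1.0 / (
        0.000035 * math.exp(-(v + 5.0) / 4.0) + 0.000035 * math.exp((v + 5.0) / 6.0)
    )
    aff = 0.6
    afs = 0.4
    dy[25] = (fss - ff) / tff
    dy[26] = (fss - fs) / tfs
    f = aff * ff + afs * fs
    fcass = fss
    tfcaf = 7.0 + 1.0 / (
        0.04 * math.exp(-(v - 4.0) / 7.0) + 0.04 * math.exp((v - 4.0) / 7.0)
    )
    tfcas = 100.0 + 1.0 / (
        0.00012 * math.exp(-v / 3.0) + 0.00012 * math.exp(v / 7.0)
    )
    afcaf = 0.3 + 0.6 / (1.0 + math.exp((v - 10.0) / 10.0))
    afcas = 1.0 - afcaf
    dy[27] = (fcass - fcaf) / tfcaf
    dy[28] = (fcass - fcas) / tfcas
    fca = afcaf * fcaf + afcas * fcas
    dy[29] = (fcass - jca) / 75.0
    dy[30] = (fss - ffp) / (2.5 * tff)
    fp = aff * ffp + afs * fs
    dy[31] = (fcass - fcafp) / (2.5 * tfcaf)
    fcap = afcaf * fcafp + afcas * fcas
    kmn = 0.002
    k2n = 1000.0
    km2n = jca * 1.0
    anca = 1.0 / (k2n / km2n + (1.0 + kmn / cass) ** 4)
    dy[32] = anca * k2n - nca * km2n

    phical = _flux(2.0, vfrt, cass, 0.341 * cao)
    phicana = _flux(1.0, vfrt, 0.75 * nass, 0.75 * nao)
    phicak = _flux(1.0, vfrt, 0.75 * kss, 0.75 * ko)
    pca = 0.0001 * f_ical
    pcap = 1.1 * pca
    pcana = 0.00125 * pca
    pcak = 3.574e-4 * pca
    pcanap = 0.00125 * pcap
    pcakp = 3.574e-4 * pcap
    ficalp = finap
    gate_np = d * (f * (1.0 - nca) + jca * fca * nca)
    gate_p = d * (fp * (1.0 - nca) + jca * fcap * nca)
    ical = (1.0 - ficalp) * pca * phical * gate_np + ficalp * pcap * phical * gate_p
    icana = (
        (1.0 - ficalp) * pcana * phicana * gate_np
        + ficalp * pcanap * phicana * gate_p
    )
    icak = (
        (1.0 - ficalp) * pcak * phicak * gate_np + ficalp * pcakp * phicak * gate_p
    )

    # ---- IKr (dual-gate Hodgkin-Huxley scheme) ----
    xrss = 1.0 / (1.0 + math.exp(-(v + 8.337) / 6.789))
    txrf = 12.98 + 1.0 / (
        0.3652 * math.exp((v - 31.66) / 3.869)
        + 4.123e-5 * math.exp(-(v - 47.78) / 20.38)
    )
    txrs = 1.865 + 1.0 / (
        0.06629 * math.exp((v - 34.70) / 7.355)
        + 1.128e-5 * math.exp(-(v - 29.74) / 25.94)
    )
    axrf = 1.0 / (1.0 + math.exp((v + 54.81) / 38.21))
    axrs = 1.0 - axrf
    dy[33] = (xrss - xrf) / txrf
    dy[34] = (xrss - xrs) / txrs
    xr = axrf * xrf + axrs * xrs
    rkr = 1.0 / (
        (1.0 + math.exp((v + 55.0) / 75.0)) * (1.0 + math.exp((v - 10.0) / 30.0))
    )
    gkr = 0.046 * f_ikr
    i_kr = gkr * math.sqrt(ko / 5.4) * xr * rkr * (v - ek)

    # ---- IKs ----
    xs1ss = 1.0 / (1.0 + math.exp(-(v + 11.60) / 8.932))
    txs1 = 817.3 + 1.0 / (
        2.326e-4 * math.exp((v + 48.28) / 17.80)
        + 0.001292 * math.exp(-(v + 210.0) / 230.0)
    )
    dy[35] = (xs1ss - xs1) / txs1
    txs2 = 1.0 / (
        0.01 * math.exp((v - 50.0) / 20.0) + 0.0193 * math.exp(-(v + 66.54) / 31.0)
    )
    dy[36] = (xs1ss - xs2) / txs2
    ksca = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    gks = 0.0034 * f_iks
    i_ks = gks * ksca * xs1 * xs2 * (v - eks)

    # ---- IK1 ----
    xk1ss = 1.0 / (
        1.0 + math.exp(-(v + 2.5538 * ko + 144.59) / (1.5692 * ko + 3.8115))
    )
    txk1 = 122.2 / (
        math.exp(-(v + 127.2) / 20.36) + math.exp((v + 236.8) / 69.33)
    )
    dy[37] = (xk1ss - xk1) / txk1
    rk1 = 1.0 / (1.0 + math.exp((v + 105.8 - 2.6 * ko) / 9.493))
    gk1 = 0.1908 * f_ik1
    i_k1 = gk1 * math.sqrt(ko) * rk1 * xk1 * (v - ek)

    # ---- INaCa (bulk 80 % / subspace 20 %) ----
    gncx = 0.0008 * f_ncx
    i_naca_i = 0.8 * _inaca(vfrt, nai, cai, nao, cao, gncx)
    i_naca_ss = 0.2 * _inaca(vfrt, nass, cass, nao, cao, gncx)

    # ---- INaK ----
    i_nak = _inak(vfrt, nai, ki, nao, ko, 30.0 * f_nak)

    # ---- background and pump currents ----
    xkb = 1.0 / (1.0 + math.exp(-(v - 14.48) / 18.34))
    i_kb = 0.003 * xkb * (v - ek)
    i_nab = 3.75e-10 * _flux(1.0, vfrt, nai, nao)
    i_cab = 2.5e-8 * _flux(2.0, vfrt, cai, 0.341 * cao)
    i_pca = 0.0005 * cai / (0.0005 + cai)

    if mask != 1.0:
        i_na *= mask
        i_nal *= mask
        i_to *= mask
        ical *= mask
        icana *= mask
        icak *= mask
        i_kr *= mask
        i_ks *= mask
        i_k1 *= mask
        i_naca_i *= mask
        i_naca_ss *= mask
        i_nak *= mask
        i_kb *= mask
        i_nab *= mask
        i_cab *= mask
        i_pca *= mask

    # ---- SR fluxes ----
    fjrelp = finap
    bt = 4.75
    a_rel = 0.5 * bt
    jrel_inf = a_rel * (-ical) / (1.0 + (1.5 / cajsr) ** 8)
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    dy[38] = (jrel_inf - jrel_np) / tau_rel
    btp = 1.25 * bt
    a_relp = 0.5 * btp
    jrel_infp = a_relp * (-ical) / (1.0 + (1.5 / cajsr) ** 8)
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    dy[39] = (jrel_infp - jrel_p) / tau_relp
    jrel = (1.0 - fjrelp) * jrel_np + fjrelp * jrel_p

    fjupp = finap
    jupnp = 0.004375 * cai / (cai + 0.00092)
    jupp = 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
    jleak = 0.0039375 * cansr / 15.0
    jup = (1.0 - fjupp) * jupnp + fjupp * jupp - jleak
    jtr = (cansr - cajsr) / 100.0

    jdiffna = (nass - nai) / 2.0
    jdiffk = (kss - ki) / 2.0
    jdiff = (cass - cai) / 0.2

    # ---- concentration balances ----
    dy[1] = (
        -(i_na + i_nal + 3.0 * i_naca_i + 3.0 * i_nak + i_nab) * ACAP / (F * vmyo)
        + jdiffna * vss / vmyo
    )
    dy[2] = -(icana + 3.0 * i_naca_ss) * ACAP / (F * vss) - jdiffna
    dy[3] = (
        -(i_to + i_kr + i_ks + i_k1 + i_kb + istim - 2.0 * i_nak)
        * ACAP
        / (F * vmyo)
        + jdiffk * vss / vmyo
    )
    dy[4] = -icak * ACAP / (F * vss) - jdiffk
    cmdnmax = 0.05
    kmcmdn = 0.00238
    trpnmax = 0.07
    kmtrpn = 0.0005
    bcai = 1.0 / (
        1.0
        + cmdnmax * kmcmdn / (kmcmdn + cai) ** 2
        + trpnmax * kmtrpn / (kmtrpn + cai) ** 2
    )
    dy[5] = bcai * (
        -(i_pca + i_cab - 2.0 * i_naca_i) * ACAP / (2.0 * F * vmyo)
        - jup * vnsr / vmyo
        + jdiff * vss / vmyo
    )
    bcass = 1.0 / (
        1.0
        + 0.047 * 0.00087 / (0.00087 + cass) ** 2
        + 1.124 * 0.0087 / (0.0087 + cass) ** 2
    )
    dy[6] = bcass * (
        -(ical - 2.0 * i_naca_ss) * ACAP / (2.0 * F * vss) + jrel * vjsr / vss - jdiff
    )
    dy[7] = jup - jtr * vjsr / vnsr
    bcajsr = 1.0 / (1.0 + 10.0 * 0.8 / (0.8 + cajsr) ** 2)
    dy[8] = bcajsr * (jtr - jrel)

    dy[0] = -(
        i_na + i_nal + i_to + ical + icana + icak + i_kr + i_ks + i_k1
        + i_naca_i + i_naca_ss + i_nak + i_nab + i_kb + i_pca + i_cab + istim
    )

    cur[0] = i_na
    cur[1] = i_nal
    cur[2] = i_to
    cur[3] = ical
    cur[4] = icana
    cur[5] = icak
    cur[6] = i_kr
    cur[7] = i_ks
    cur[8] = i_k1
    cur[9] = i_nak
    cur[10] = i_naca_i
    cur[11] = i_naca_ss
    cur[12] = i_nab
    cur[13] = i_kb
    cur[14] = i_cab
    cur[15] = i_pca
    cur[16] = 0.0  # no Ca-activated Cl current in this model family
    cur[17] = 0.0  # no background Cl current


@njit(cache=True)
def rhs(t, y, p):
    dy = np.empty(41)
    cur = np.empty(18)
    _core(y, p, dy, cur)
    return dy


@njit(cache=True)
def currents(y, p):
    dy = np.empty(41)
    cur = np.empty(18)
    _core(y, p, dy, cur)
    return cur


def _default_initial_state() -> np.ndarray:
    """Published default initial conditions of the ORd backbone."""
    y = np.zeros(len(STATE_NAMES))
    y[0] = -87.0
    y[1] = 7.0     # nai
    y[2] = 7.0     # nass
    y[3] = 145.0   # ki
    y[4] = 145.0   # kss
    y[5] = 1.0e-4  # cai
    y[6] = 1.0e-4  # cass
    y[7] = 1.2     # cansr
    y[8] = 1.2     # cajsr
    # gates: activation closed, inactivation available
    for idx, name in enumerate(STATE_NAMES):
        if name in ("hf", "hs", "j", "hsp", "jp", "hL", "hLp", "iF", "iS",
                    "iFp", "iSp", "ff", "fs", "fcaf", "fcas", "jca", "ffp",
                    "fcafp", "xk1"):
            y[idx] = 1.0
    return y


MODEL = register_model(
    ModelDef(
        model_id="bps2020",
        name="BPS2020 stand-in (synthetic, ORd-2011 backbone)",
        baseline_milieu=ExtracellularMilieu.with_charge_balance_cl(
            na_e=144.0, k_e=5.4, ca_e=2.7
        ),
        temperature=T,
        state_names=STATE_NAMES,
        y0=_default_initial_state(),
        rhs=rhs,
        currents=currents,
        ion_amounts=ion_amounts,
        conc_indices={"nai": 1, "nass": 2, "ki": 3, "kss": 4, "cai": 5,
                      "cass": 6, "cansr": 7, "cajsr": 8},
        notes="SYNTHETIC stand-in for the Bartolucci-Passini-Severi 2020 "
        "model: O'Hara-Rudy 2011 endocardial equation set with the BPS2020 "
        "extracellular milieu and charge-balance Cl-. Biomarkers are the "
        "stand-in's own, not those of the published BPS2020 model.",
    )
)
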