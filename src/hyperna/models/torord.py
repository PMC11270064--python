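"""ToR-ORd human ventricular cardiomyocyte model (endocardial variant).

Re-implementation of the Tomek-Rodriguez update of the O'Hara-Rudy dynamic
model (ToR-ORd, Tomek et al. 2019/2020 release, endocardial parameter set),
written as a flat-state ODE system.  Departures from the unmodified model
are exactly the hypernatremia hooks of the shared parameter vector:

* maximal amplitudes of ICaL, IKr, IKs, IK1, INaCa (both bulk and subspace
  components) and INaK multiplied by their scaling factors;
* extracellular Na+, K+, Ca2+ and Cl- replaced by the perturbed milieu;
* every intracellular compartment volume (myoplasm, NSR, JSR, subspace)
  multiplied by the relative cell volume; the capacitive area is fixed.

The intracellular Cl- concentration is a constant of the model (24 mmol/L)
and cannot change dynamically; extracellular Cl- follows the milieu.

At the identity condition (level 0, all factors 1, volume 1) the right-hand
side is the unmodified model.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ..constants import F, R
from ..osmotic import ExtracellularMilieu
from .base import (
    P_CAO,
    P_CLO,
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

T = 310.0
RTF = R * T / F

# cell geometry (cm, uL); capacitive area never scales with shrinkage
L_CELL = 0.01
RAD = 0.0011
VCELL = 1000.0 * 3.14 * RAD * RAD * L_CELL
AGEO = 2.0 * 3.14 * RAD * RAD + 2.0 * 3.14 * RAD * L_CELL
ACAP = 2.0 * AGEO
VMYO = 0.68 * VCELL
VNSR = 0.0552 * VCELL
VJSR = 0.0048 * VCELL
VSS = 0.02 * VCELL

CLI = 24.0  # intracellular Cl-, fixed

STATE_NAMES: tuple[str, ...] = (
    "vm",
    "nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr",
    "m", "h", "j", "hp", "jp",
    "mL", "hL", "hLp",
    "a", "iF", "iS", "ap", "iFp", "iSp",
    "d", "ff", "fs", "fcaf", "fcas", "jca", "ffp", "fcafp",
    "nca_ss", "nca_i",
    "xrf", "xrs",
    "xs1", "xs2",
    "jrel_np", "jrel_p",
    "camkt",
)

#: IKr conductance, mS/uF.  The reconstruction uses the parent ORd
#: delayed-rectifier formulation; this value is calibrated once against
#: the published ToR-ORd endocardial baseline APD90 (~276 ms at 1 Hz).
GKR = 0.0653


@njit(cache=True, inline="always")
def _flux(z: float, vfrt: float, ci_eff: float, co_eff: float) -> float:
    """GHK-type flux factor  z^2*F*vfrt*(ci*exp(z*vfrt)-co)/(exp(z*vfrt)-1),
    with the removable singularity at v=0 handled analytically."""
    u = z * vfrt
    if abs(u) < 1e-7:
        return z * F * (ci_eff - co_eff + 0.5 * u * (ci_eff + co_eff))
    ex = math.exp(u)
    return z * z * F * vfrt * (ci_eff * ex - co_eff) / (ex - 1.0)


@njit(cache=True, inline="always")
def _inaca(v_frt, na, ca, nao, cao, gncx):
    """ORd Na+/Ca2+ exchanger scheme for one compartment (A/F)."""
    kna1 = 15.0
    kna2 = 5.0
    kna3 = 88.12
    kasymm = 12.5
    wna = 6.0e4
    wca = 6.0e4
    wnaca = 5.0e3
    kcaon = 1.5e6
    kcaoff = 5.0e3
    qna = 0.5224
    qca = 0.1670
    hca = math.exp(qca * v_frt)
    hna = math.exp(qna * v_frt)
    h1 = 1.0 + na / kna3 * (1.0 + hna)
    h2 = (na * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + na / kna1 * (1.0 + na / kna2)
    h5 = na * na / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    h7 = 1.0 + nao / kna3 * (1.0 + 1.0 / hna)
    h8 = nao / (kna3 * hna * h7)
    h9 = 1.0 / h7
    h10 = kasymm + 1.0 + nao / kna1 * (1.0 + nao / kna2)
    h11 = nao * nao / (h10 * kna1 * kna2)
    h12 = 1.0 / h10
    k1 = h12 * cao * kcaon
    k2 = kcaoff
    k3p = h9 * wca
    k3pp = h8 * wnaca
    k3 = k3p + k3pp
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k5 = kcaoff
    k6 = h6 * ca * kcaon
    k7 = h5 * h2 * wna
    k8 = h8 * h11 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    s = x1 + x2 + x3 + x4
    e1 = x1 / s
    e2 = x2 / s
    e3 = x3 / s
    e4 = x4 / s
    kmcaact = 150.0e-6
    allo = 1.0 / (1.0 + (kmcaact / ca) ** 2)
    jncxna = 3.0 * (e4 * k7 - e1 * k8) + e3 * k4pp - e2 * k3pp
    jncxca = e2 * k2 - e1 * k1
    return gncx * allo * (jncxna + 2.0 * jncxca)


@njit(cache=True, inline="always")
def _inak(v_frt, nai, ki, nao, ko, pnak):
    """ORd Na+/K+ pump scheme (A/F)."""
    k1p = 949.5
    k1m = 182.4
    k2p = 687.2
    k2m = 39.4
    k3p = 1899.0
    k3m = 79300.0
    k4p = 639.0
    k4m = 40.0
    knai0 = 9.073
    knao0 = 27.78
    delta = -0.1550
    knai = knai0 * math.exp(delta * v_frt / 3.0)
    knao = knao0 * math.exp((1.0 - delta) * v_frt / 3.0)
    kki = 0.5
    kko = 0.3582
    mgadp = 0.05
    mgatp = 9.8
    kmgatp = 1.698e-7
    hp_ = 1.0e-7
    ep = 4.2
    khp = 1.698e-7
    knap = 224.0
    kxkur = 292.0
    p_ = ep / (1.0 + hp_ / khp + nai / knap + ki / kxkur)
    na_i_t = (1.0 + nai / knai) ** 3
    k_i_t = (1.0 + ki / kki) ** 2
    na_o_t = (1.0 + nao / knao) ** 3
    k_o_t = (1.0 + ko / kko) ** 2
    a1 = (k1p * (nai / knai) ** 3) / (na_i_t + k_i_t - 1.0)
    b1 = k1m * mgadp
    a2 = k2p
    b2 = (k2m * (nao / knao) ** 3) / (na_o_t + k_o_t - 1.0)
    a3 = (k3p * (ko / kko) ** 2) / (na_o_t + k_o_t - 1.0)
    b3 = (k3m * p_ * hp_) / (1.0 + mgatp / kmgatp)
    a4 = (k4p * mgatp / kmgatp) / (1.0 + mgatp / kmgatp)
    b4 = (k4m * (ki / kki) ** 2) / (na_i_t + k_i_t - 1.0)
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
    s = x1 + x2 + x3 + x4
    e1 = x1 / s
    e2 = x2 / s
    e3 = x3 / s
    e4 = x4 / s
    jnakna = 3.0 * (e1 * a3 - e2 * b3)
    jnakk = 2.0 * (e4 * b1 - e3 * a1)
    return pnak * (jnakna + jnakk)


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
    h = y[10]
    j = y[11]
    hpg = y[12]
    jp = y[13]
    mL = y[14]
    hL = y[15]
    hLp = y[16]
    a = y[17]
    iF = y[18]
    iS = y[19]
    ap = y[20]
    iFp = y[21]
    iSp = y[22]
    d = y[23]
    ff = y[24]
    fs = y[25]
    fcaf = y[26]
    fcas = y[27]
    jca = y[28]
    ffp = y[29]
    fcafp = y[30]
    nca_ss = y[31]
    nca_i = y[32]
    xrf = y[33]
    xrs = y[34]
    xs1 = y[35]
    xs2 = y[36]
    jrel_np = y[37]
    jrel_p = y[38]
    camkt = y[39]

    nao = p[P_NAO]
    ko = p[P_KO]
    cao = p[P_CAO]
    clo = p[P_CLO]
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
    ecl = RTF * math.log(CLI / clo)

    # CaMKII
    kmcamk = 0.15
    acamk = 0.05
    bcamk = 0.00068
    camko = 0.05
    kmcam = 0.0015
    camkb = camko * (1.0 - camkt) / (1.0 + kmcam / cass)
    camka = camkb + camkt
    dy[39] = acamk * camkb * (camkb + camkt) - bcamk * camkt

    # ---- INa (Grandi-type formulation with CaMK-phosphorylated gates) ----
    mss = 1.0 / (1.0 + math.exp(-(56.86 + v) / 9.03)) ** 2
    taum = 0.1292 * math.exp(-((v + 45.79) / 15.54) ** 2) + 0.06487 * math.exp(
        -((v - 4.823) / 51.12) ** 2
    )
    if v >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
        aj = 0.0
        bj = (0.6 * math.exp(0.057 * v)) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    else:
        ah = 0.057 * math.exp(-(v + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.3485 * v)
        aj = (
            (-2.5428e4 * math.exp(0.2444 * v) - 6.948e-6 * math.exp(-0.04391 * v))
            * (v + 37.78)
        ) / (1.0 + math.exp(0.311 * (v + 79.23)))
        bj = (0.02424 * math.exp(-0.01052 * v)) / (
            1.0 + math.exp(-0.1378 * (v + 40.14))
        )
    tauh = 1.0 / (ah + bh)
    hss = 1.0 / (1.0 + math.exp((v + 71.55) / 7.43)) ** 2
    tauj = 1.0 / (aj + bj)
    jss = hss
    hssp = 1.0 / (1.0 + math.exp((v + 71.55 + 6.0) / 7.43)) ** 2
    dy[9] = (mss - m) / taum
    dy[10] = (hss - h) / tauh
    dy[11] = (jss - j) / tauj
    dy[12] = (hssp - hpg) / tauh
    dy[13] = (jss - jp) / (1.46 * tauj)
    gna = 11.7802
    finap = 1.0 / (1.0 + kmcamk / camka)
    i_na = gna * (v - ena) * m ** 3 * ((1.0 - finap) * h * j + finap * hpg * jp)

    # ---- INaL ----
    mlss = 1.0 / (1.0 + math.exp(-(v + 42.85) / 5.264))
    dy[14] = (mlss - mL) / taum
    hlss = 1.0 / (1.0 + math.exp((v + 87.61) / 7.488))
    thl = 200.0
    dy[15] = (hlss - hL) / thl
    hlssp = 1.0 / (1.0 + math.exp((v + 93.81) / 7.488))
    dy[16] = (hlssp - hLp) / (3.0 * thl)
    gnal = 0.0279
    finalp = finap
    i_nal = gnal * (v - ena) * mL * ((1.0 - finalp) * hL + finalp * hLp)

    # ---- Ito ----
    ass = 1.0 / (1.0 + math.exp(-(v - 14.34) / 14.82))
    ta = 1.0515 / (
        1.0 / (1.2089 * (1.0 + math.exp(-(v - 18.4099) / 29.3814)))
        + 3.5 / (1.0 + math.exp((v + 100.0) / 29.3814))
    )
    dy[17] = (ass - a) / ta
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
    dy[18] = (iss - iF) / tif
    dy[19] = (iss - iS) / tis
    i_gate = aif * iF + ais * iS
    assp = 1.0 / (1.0 + math.exp(-(v - 24.34) / 14.82))
    dy[20] = (assp - ap) / ta
    dti_develop = 1.354 + 1.0e-4 / (
        math.exp((v - 167.4) / 15.89) + math.exp(-(v - 12.23) / 0.2154)
    )
    dti_recover = 1.0 - 0.5 / (1.0 + math.exp((v + 70.0) / 20.0))
    dy[21] = (iss - iFp) / (dti_develop * dti_recover * tif)
    dy[22] = (iss - iSp) / (dti_develop * dti_recover * tis)
    ip_gate = aif * iFp + ais * iSp
    gto = 0.16
    fitop = finap
    i_to = gto * (v - ek) * ((1.0 - fitop) * a * i_gate + fitop * ap * ip_gate)

    # ---- ICaL (subspace + myoplasmic components, GHK with Davies activity) --
    if v >= 31.4978:
        dss = 1.0
    else:
        dss = 1.0763 * math.exp(-1.0070 * math.exp(-0.0829 * v))
    td = 0.6 + 1.0 / (math.exp(-0.05 * (v + 6.0)) + math.exp(0.09 * (v + 14.0)))
    dy[23] = (dss - d) / td
    fss = 1.0 / (1.0 + math.exp((v + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (
        0.0045 * math.exp(-(v + 20.0) / 10.0) + 0.0045 * math.exp((v + 20.0) / 10.0)
    )
    tfs = 1000.0 + 1.0 / (
        0.000035 * math.exp(-(v + 5.0) / 4.0) + 0.000035 * math.exp((v + 5.0) / 6.0)
    )
    aff = 0.6
    afs = 0.4
    dy[24] = (fss - ff) / tff
    dy[25] = (fss - fs) / tfs
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
    dy[26] = (fcass - fcaf) / tfcaf
    dy[27] = (fcass - fcas) / tfcas
    fca = afcaf * fcaf + afcas * fcas
    jcass = 1.0 / (1.0 + math.exp((v + 18.08) / 2.7916))
    dy[28] = (jcass - jca) / 72.5
    dy[29] = (fss - ffp) / (2.5 * tff)
    fp = aff * ffp + afs * fs
    dy[30] = (fcass - fcafp) / (2.5 * tfcaf)
    fcap = afcaf * fcafp + afcas * fcas

    kmn = 0.002
    k2n = 500.0
    km2n = jca * 1.0
    anca_ss = 1.0 / (k2n / km2n + (1.0 + kmn / cass) ** 4)
    dy[31] = anca_ss * k2n - nca_ss * km2n
    anca_i = 1.0 / (k2n / km2n + (1.0 + kmn / cai) ** 4)
    dy[32] = anca_i * k2n - nca_i * km2n

    # Davies activity coefficients
    const_a = 1.82e6 * (74.0 * T) ** -1.5
    io_s = 0.5 * (nao + ko + clo + 4.0 * cao) / 1000.0
    iss_s = 0.5 * (nass + kss + CLI + 4.0 * cass) / 1000.0
    ii_s = 0.5 * (nai + ki + CLI + 4.0 * cai) / 1000.0
    sq_o = math.sqrt(io_s)
    sq_ss = math.sqrt(iss_s)
    sq_i = math.sqrt(ii_s)
    g1o = math.exp(-const_a * (sq_o / (1.0 + sq_o) - 0.3 * io_s))
    g1ss = math.exp(-const_a * (sq_ss / (1.0 + sq_ss) - 0.3 * iss_s))
    g1i = math.exp(-const_a * (sq_i / (1.0 + sq_i) - 0.3 * ii_s))
    g2o = g1o ** 4
    g2ss = g1ss ** 4
    g2i = g1i ** 4

    phical_ss = _flux(2.0, vfrt, g2ss * cass, g2o * cao)
    phicana_ss = _flux(1.0, vfrt, 0.75 * g1ss * nass, 0.75 * g1o * nao)
    phicak_ss = _flux(1.0, vfrt, 0.75 * g1ss * kss, 0.75 * g1o * ko)
    phical_i = _flux(2.0, vfrt, g2i * cai, g2o * cao)
    phicana_i = _flux(1.0, vfrt, 0.75 * g1i * nai, 0.75 * g1o * nao)
    phicak_i = _flux(1.0, vfrt, 0.75 * g1i * ki, 0.75 * g1o * ko)

    pca = 8.3757e-5 * f_ical
    pcap = 1.1 * pca
    pcana = 0.00125 * pca
    pcak = 3.574e-4 * pca
    pcanap = 0.00125 * pcap
    pcakp = 3.574e-4 * pcap
    ficalp = finap
    frac_ss = 0.8

    gate_np_ss = d * (f * (1.0 - nca_ss) + jca * fca * nca_ss)
    gate_p_ss = d * (fp * (1.0 - nca_ss) + jca * fcap * nca_ss)
    gate_np_i = d * (f * (1.0 - nca_i) + jca * fca * nca_i)
    gate_p_i = d * (fp * (1.0 - nca_i) + jca * fcap * nca_i)

    ical_ss = frac_ss * (
        (1.0 - ficalp) * pca * phical_ss * gate_np_ss
        + ficalp * pcap * phical_ss * gate_p_ss
    )
    icana_ss = frac_ss * (
        (1.0 - ficalp) * pcana * phicana_ss * gate_np_ss
        + ficalp * pcanap * phicana_ss * gate_p_ss
    )
    icak_ss = frac_ss * (
        (1.0 - ficalp) * pcak * phicak_ss * gate_np_ss
        + ficalp * pcakp * phicak_ss * gate_p_ss
    )
    ical_i = (1.0 - frac_ss) * (
        (1.0 - ficalp) * pca * phical_i * gate_np_i
        + ficalp * pcap * phical_i * gate_p_i
    )
    icana_i = (1.0 - frac_ss) * (
        (1.0 - ficalp) * pcana * phicana_i * gate_np_i
        + ficalp * pcanap * phicana_i * gate_p_i
    )
    icak_i = (1.0 - frac_ss) * (
        (1.0 - ficalp) * pcak * phicak_i * gate_np_i
        + ficalp * pcakp * phicak_i * gate_p_i
    )

    # ---- IKr (ORd dual-gate formulation; see module docstring) ----
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
    gkr = GKR * f_ikr
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
    gks = 0.0011 * f_iks
    i_ks = gks * ksca * xs1 * xs2 * (v - eks)

    # ---- IK1 (instantaneous rectification) ----
    ak1 = 4.094 / (1.0 + math.exp(0.1217 * (v - ek - 49.934)))
    bk1 = (
        15.72 * math.exp(0.0674 * (v - ek - 3.257))
        + math.exp(0.0618 * (v - ek - 594.31))
    ) / (1.0 + math.exp(-0.1629 * (v - ek + 14.207)))
    k1ss = ak1 / (ak1 + bk1)
    gk1 = 0.6992 * f_ik1
    i_k1 = gk1 * math.sqrt(ko / 5.0) * k1ss * (v - ek)

    # ---- INaCa (bulk 65 % / subspace 35 %) ----
    gncx = 0.0034 * f_ncx
    i_naca_i = 0.65 * _inaca(vfrt, nai, cai, nao, cao, gncx)
    i_naca_ss = 0.35 * _inaca(vfrt, nass, cass, nao, cao, gncx)

    # ---- INaK ----
    i_nak = _inak(vfrt, nai, ki, nao, ko, 15.4509 * f_nak)

    # ---- background and pump currents ----
    xkb = 1.0 / (1.0 + math.exp(-(v - 10.8968) / 23.9871))
    i_kb = 0.0189 * xkb * (v - ek)
    i_nab = 1.9239e-9 * _flux(1.0, vfrt, nai, nao)
    i_cab = 5.9194e-8 * _flux(2.0, vfrt, g2i * cai, g2o * cao)
    i_pca = 5.0e-4 * cai / (0.0005 + cai)
    i_clca = 0.2843 / (1.0 + 0.1 / cass) * (v - ecl)
    i_clb = 1.98e-3 * (v - ecl)

    if mask != 1.0:
        i_na *= mask
        i_nal *= mask
        i_to *= mask
        ical_ss *= mask
        ical_i *= mask
        icana_ss *= mask
        icana_i *= mask
        icak_ss *= mask
        icak_i *= mask
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
        i_clca *= mask
        i_clb *= mask

    ical = ical_ss + ical_i
    icana = icana_ss + icana_i
    icak = icak_ss + icak_i

    # ---- SR fluxes ----
    fjrelp = finap
    bt = 4.75
    a_rel = 0.5 * bt
    jrel_inf = a_rel * (-ical_ss) / (1.0 + (1.7 / cajsr) ** 8)
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    dy[37] = (jrel_inf - jrel_np) / tau_rel
    btp = 1.25 * bt
    a_relp = 0.5 * btp
    jrel_infp = a_relp * (-ical_ss) / (1.0 + (1.7 / cajsr) ** 8)
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    dy[38] = (jrel_infp - jrel_p) / tau_relp
    jrel = 1.5378 * ((1.0 - fjrelp) * jrel_np + fjrelp * jrel_p)

    fjupp = finap
    jupnp = 0.005425 * cai / (cai + 0.00092)
    jupp = 2.75 * 0.005425 * cai / (cai + 0.00092 - 0.00017)
    jleak = 0.0048825 * cansr / 15.0
    jup = (1.0 - fjupp) * jupnp + fjupp * jupp - jleak
    jtr = (cansr - cajsr) / 60.0

    jdiffna = (nass - nai) / 2.0
    jdiffk = (kss - ki) / 2.0
    jdiff = (cass - cai) / 0.2

    # ---- concentration balances (volumes scaled by shrinkage) ----
    dy[1] = (
        -(i_na + i_nal + 3.0 * i_naca_i + icana_i + 3.0 * i_nak + i_nab)
        * ACAP
        / (F * vmyo)
        + jdiffna * vss / vmyo
    )
    dy[2] = -(icana_ss + 3.0 * i_naca_ss) * ACAP / (F * vss) - jdiffna
    dy[3] = (
        -(i_to + i_kr + i_ks + i_k1 + i_kb + icak_i + istim - 2.0 * i_nak)
        * ACAP
        / (F * vmyo)
        + jdiffk * vss / vmyo
    )
    dy[4] = -icak_ss * ACAP / (F * vss) - jdiffk
    cmdnmax = 0.05
    kmcmdn = 0.00238
    trpnmax = 0.07
    kmtrpn = 0.0005
    bsrmax = 0.047
    kmbsr = 0.00087
    bslmax = 1.124
    kmbsl = 0.0087
    csqnmax = 10.0
    kmcsqn = 0.8
    bcai = 1.0 / (
        1.0
        + cmdnmax * kmcmdn / (kmcmdn + cai) ** 2
        + trpnmax * kmtrpn / (kmtrpn + cai) ** 2
    )
    dy[5] = bcai * (
        -(ical_i + i_pca + i_cab - 2.0 * i_naca_i) * ACAP / (2.0 * F * vmyo)
        - jup * vnsr / vmyo
        + jdiff * vss / vmyo
    )
    bcass = 1.0 / (
        1.0
        + bsrmax * kmbsr / (kmbsr + cass) ** 2
        + bslmax * kmbsl / (kmbsl + cass) ** 2
    )
    dy[6] = bcass * (
        -(ical_ss - 2.0 * i_naca_ss) * ACAP / (2.0 * F * vss)
        + jrel * vjsr / vss
        - jdiff
    )
    dy[7] = jup - jtr * vjsr / vnsr
    bcajsr = 1.0 / (1.0 + csqnmax * kmcsqn / (kmcsqn + cajsr) ** 2)
    dy[8] = bcajsr * (jtr - jrel)

    dy[0] = -(
        i_na + i_nal + i_to + ical + icana + icak + i_kr + i_ks + i_k1
        + i_naca_i + i_naca_ss + i_nak + i_nab + i_kb + i_pca + i_cab
        + i_clca + i_clb + istim
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
    cur[16] = i_clca
    cur[17] = i_clb


@njit(cache=True)
def rhs(t, y, p):
    dy = np.empty(40)
    cur = np.empty(18)
    _core(y, p, dy, cur)
    return dy


@njit(cache=True)
def currents(y, p):
    dy = np.empty(40)
    cur = np.empty(18)
    _core(y, p, dy, cur)
    return cur


def ion_amounts(y: np.ndarray, p: np.ndarray) -> dict[str, float]:
    """Total intracellular ion amounts (including buffered and SR Ca2+),
    in mmol scaled by the shrunken compartment volumes."""
    vfrac = p[P_VFRAC]
    vmyo, vnsr, vjsr, vss = VMYO * vfrac, VNSR * vfrac, VJSR * vfrac, VSS * vfrac
    nai, nass, ki, kss, cai, cass, cansr, cajsr = y[1:9]
    cmdn = 0.05 * cai / (0.00238 + cai)
    trpn = 0.07 * cai / (0.0005 + cai)
    bsr = 0.047 * cass / (0.00087 + cass)
    bsl = 1.124 * cass / (0.0087 + cass)
    csqn = 10.0 * cajsr / (0.8 + cajsr)
    return {
        "na": nai * vmyo + nass * vss,
        "k": ki * vmyo + kss * vss,
        "ca": (cai + cmdn + trpn) * vmyo
        + (cass + bsr + bsl) * vss
        + cansr * vnsr
        + (cajsr + csqn) * vjsr,
    }


def _default_initial_state() -> np.ndarray:
    """Published endocardial quasi-steady initial conditions (1 Hz pacing):
    concentrations to the precision of the released code; gating variables
    at their closed-form steady state for the initial potential."""
    y = np.zeros(len(STATE_NAMES))
    v0 = -88.76
    y[0] = v0
    y[1] = 12.1025   # nai
    y[2] = 12.1029   # nass
    y[3] = 142.30    # ki
    y[4] = 142.30    # kss
    y[5] = 8.158e-5  # cai
    y[6] = 7.031e-5  # cass
    y[7] = 1.5211    # cansr
    y[8] = 1.5214    # cajsr
    y[39] = 0.0111   # camkt

    def sig(x):
        return 1.0 / (1.0 + math.exp(x))

    y[9] = sig(-(56.86 + v0) / 9.03) ** 2                 # m
    y[10] = y[11] = sig((v0 + 71.55) / 7.43) ** 2         # h, j
    y[12] = y[13] = sig((v0 + 77.55) / 7.43) ** 2         # hp, jp
    y[14] = sig(-(v0 + 42.85) / 5.264)                    # mL
    y[15] = sig((v0 + 87.61) / 7.488)                     # hL
    y[16] = sig((v0 + 93.81) / 7.488)                     # hLp
    y[17] = sig(-(v0 - 14.34) / 14.82)                    # a
    y[18] = y[19] = y[21] = y[22] = sig((v0 + 43.94) / 5.711)  # iF, iS, ...
    y[20] = sig(-(v0 - 24.34) / 14.82)                    # ap
    y[23] = 1.0763 * math.exp(-1.0070 * math.exp(-0.0829 * v0))  # d
    fss0 = sig((v0 + 19.58) / 3.696)
    y[24] = y[25] = y[26] = y[27] = y[29] = y[30] = fss0  # f/fca family
    y[28] = sig((v0 + 18.08) / 2.7916)                    # jca
    y[31] = y[32] = 0.0                                   # nca
    y[33] = y[34] = sig(-(v0 + 8.337) / 6.789)            # xrf, xrs
    y[35] = y[36] = sig(-(v0 + 11.60) / 8.932)            # xs1, xs2
    return y


MODEL = register_model(
    ModelDef(
        model_id="torord",
        name="ToR-ORd (endocardial)",
        baseline_milieu=ExtracellularMilieu(na_e=140.0, k_e=5.0, ca_e=1.8, cl_e=150.0),
        temperature=T,
        state_names=STATE_NAMES,
        y0=_default_initial_state(),
        rhs=rhs,
        currents=currents,
        ion_amounts=ion_amounts,
        conc_indices={"nai": 1, "nass": 2, "ki": 3, "kss": 4, "cai": 5,
                      "cass": 6, "cansr": 7, "cajsr": 8},
        notes="Tomek-Rodriguez update of the O'Hara-Rudy dynamic model, "
        "endocardial parameter set, 2019/2020 release; re-implemented "
        "from the published model description.",
    )
)
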