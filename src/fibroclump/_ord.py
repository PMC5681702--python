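"""Numerical definitions of the modified O'Hara-Rudy human ventricular myocyte.

The myocyte is the O'Hara-Rudy (ORd, 2011) human ventricular cell,
endocardial variant, with the fast sodium current replaced by the
Ten Tusscher-Panfilov (2006) m^3*h*j formulation so that tissue-level
conduction velocity comes out at the physiological 65 cm/s.  All currents
are densities in uA/uF, voltages in mV, time in ms, concentrations in mM.

Everything voltage-dependent is expressed through ``rate_columns`` so that
the exact right-hand side and the tabulated (lookup-table) fast path share
one set of formulas; the lattice kernel interpolates the table, the
reference path evaluates the columns at the exact voltage.

Time stepping: membrane voltage and concentrations advance by forward
Euler; gating variables advance by the exponential (Rush-Larsen) relaxation
update y <- y_inf + (y - y_inf) exp(-dt/tau), which is required because the
TP06 activation gate has tau_m ~ 6e-4 ms at rest, far below the 0.02 ms
step.  The exp(-dt/tau) factors for voltage-dependent taus are tabulated.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# physical constants and cell geometry
# ---------------------------------------------------------------------------
R_GAS = 8314.0      # J / (kmol K)
TEMP = 310.0        # K
FARADAY = 96485.0   # C / mol
RTF = R_GAS * TEMP / FARADAY
FRT = 1.0 / RTF

NAO = 140.0  # mM
CAO = 1.8
KO = 5.4

# cell geometry (ORd): cylinder of length 0.01 cm, radius 0.0011 cm
_L = 0.01
_RAD = 0.0011
VCELL = 1000.0 * 3.14 * _RAD * _RAD * _L      # uL
AGEO = 2.0 * 3.14 * _RAD * _RAD + 2.0 * 3.14 * _RAD * _L
ACAP = 2.0 * AGEO                              # cm^2
VMYO = 0.68 * VCELL
VNSR = 0.0552 * VCELL
VJSR = 0.0048 * VCELL
VSS = 0.02 * VCELL

# CaMK
KMCAMK = 0.15
ACAMK = 0.05
BCAMK = 0.00068
CAMKO = 0.05
KMCAM = 0.0015

# maximal conductances / permeabilities (endo)
GNA_TP = 14.838      # TP06 fast sodium, nS/pF
GNAL = 0.0075
GTO = 0.02
PCA = 0.0001
GKR = 0.046
GKS = 0.0034
GK1 = 0.1908
GNCX = 0.0008
PNAK = 30.0
GKB = 0.003
PNAB = 3.75e-10
PCAB = 2.5e-8
GPCA = 0.0005

# INaCa constants
KNA1 = 15.0
KNA2 = 5.0
KNA3 = 88.12
KASYMM = 12.5
WNA = 6.0e4
WCA = 6.0e4
WNACA = 5.0e3
KCAON = 1.5e6
KCAOFF = 5.0e3
QNA = 0.5224
QCA = 0.1670
KMCAACT = 150.0e-6

_h10 = KASYMM + 1.0 + NAO / KNA1 * (1.0 + NAO / KNA2)
_h11 = NAO * NAO / (_h10 * KNA1 * KNA2)
_h12 = 1.0 / _h10
NCX_K1 = _h12 * CAO * KCAON
NCX_K2 = KCAOFF
NCX_K5 = KCAOFF

# INaK constants
NAK_K1P = 949.5
NAK_K1M = 182.4
NAK_K2P = 687.2
NAK_K2M = 39.4
NAK_K3P = 1899.0
NAK_K3M = 79300.0
NAK_K4P = 639.0
NAK_K4M = 40.0
KNAI0 = 9.073
KNAO0 = 27.78
NAK_DELTA = -0.155
KKI = 0.5
KKO = 0.3582
MGADP = 0.05
MGATP = 9.8
KMGATP = 1.698e-7
NAK_H = 1.0e-7
NAK_EP = 4.2
KHP = 1.698e-7
KNAP = 224.0
KXKUR = 292.0

# buffering (endo)
CMDNMAX = 0.05
KMCMDN = 0.00238
TRPNMAX = 0.07
KMTRPN = 0.0005
BSRMAX = 0.047
KMBSR = 0.00087
BSLMAX = 1.124
KMBSL = 0.0087
CSQNMAX = 10.0
KMCSQN = 0.8

# precomputed combinations (hot-loop constants)
SQRT_KO_54 = np.sqrt(KO / 5.4)
SQRT_KO = np.sqrt(KO)
NAK_B1 = NAK_K1M * MGADP
NAK_A4 = NAK_K4P * MGATP / KMGATP / (1.0 + MGATP / KMGATP)
NAK_B3FAC = NAK_K3M * NAK_H / (1.0 + MGATP / KMGATP)
ACF_VMYO = ACAP / FARADAY / VMYO
ACF_VSS = ACAP / FARADAY / VSS
VSS_VMYO = VSS / VMYO
VNSR_VMYO = VNSR / VMYO
VJSR_VSS = VJSR / VSS
VJSR_VNSR = VJSR / VNSR

# gate time constants that do not depend on voltage (ms)
TAU_HL = 200.0
TAU_HLP = 600.0
TAU_JCA = 75.0

# ---------------------------------------------------------------------------
# state layout (voltage is carried separately by the lattice)
# ---------------------------------------------------------------------------
STATE_NAMES = (
    "nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr", "camkt",
    "m", "h", "j",
    "ml", "hl", "hlp",
    "a", "if_", "is_", "ap", "ifp", "isp",
    "d", "ff", "fs", "fcaf", "fcas", "jca", "nca", "ffp", "fcafp",
    "xrf", "xrs", "xs1", "xs2", "xk1",
    "jrelnp", "jrelp",
)
NVARS = len(STATE_NAMES)  # 37
GATE_SLICE = slice(9, 35)  # [0,1]-bounded gates (jrelnp/jrelp are fluxes, not gates)
CONC_SLICE = slice(0, 8)

# conductance-multiplier layout
MULT_NAMES = ("gna", "gnal", "gto", "gcal", "gkr", "gks", "gk1",
              "gncx", "gnak", "gkb", "gpca", "jrel", "jup")
NMULT = len(MULT_NAMES)


def default_multipliers() -> np.ndarray:
    """Control parameter set: every multiplier 1 except gkr doubled."""
    m = np.ones(NMULT)
    m[MULT_NAMES.index("gkr")] = 2.0
    return m


# ---------------------------------------------------------------------------
# voltage-dependent rate columns
# ---------------------------------------------------------------------------
(C_MINF, C_TAUM, C_HINF, C_TAUH, C_JINF, C_TAUJ,
 C_MLINF, C_TAUML, C_HLINF, C_HLPINF,
 C_AINF, C_TAUA, C_IINF, C_TAUIF, C_TAUIS, C_AIF, C_APINF, C_TAUIFP, C_TAUISP,
 C_DINF, C_TAUD, C_FINF, C_TAUFF, C_TAUFS, C_TAUFCAF, C_TAUFCAS, C_AFCAF,
 C_XRINF, C_TAUXRF, C_TAUXRS, C_AXRF, C_RKR,
 C_XS1INF, C_TAUXS1, C_TAUXS2,
 C_XK1INF, C_TAUXK1, C_RK1,
 C_XKB,
 C_CA_A, C_E2V, C_NA_A, C_E1V,
 C_K4PFAC, C_HNA, C_NCXK3, C_NCXK8,
 C_NAKB2, C_NAKA3, C_KNAI) = range(50)
NBASE = 50

# exp(-dt/tau) factors for the Rush-Larsen gate update (appended by build_lut)
(C_E_M, C_E_H, C_E_J, C_E_ML, C_E_A, C_E_IF, C_E_IS, C_E_IFP, C_E_ISP,
 C_E_D, C_E_FF, C_E_FS, C_E_FCAF, C_E_FCAS, C_E_FFP, C_E_FCAFP,
 C_E_XRF, C_E_XRS, C_E_XS1, C_E_XS2, C_E_XK1) = range(NBASE, NBASE + 21)
NCOL = NBASE + 21

# (RL factor column, inf column, tau column) for the tabulated gates
_RL_MAP = (
    (C_E_M, C_TAUM), (C_E_H, C_TAUH), (C_E_J, C_TAUJ), (C_E_ML, C_TAUML),
    (C_E_A, C_TAUA), (C_E_IF, C_TAUIF), (C_E_IS, C_TAUIS),
    (C_E_IFP, C_TAUIFP), (C_E_ISP, C_TAUISP),
    (C_E_D, C_TAUD), (C_E_FF, C_TAUFF), (C_E_FS, C_TAUFS),
    (C_E_FCAF, C_TAUFCAF), (C_E_FCAS, C_TAUFCAS),
    (C_E_XRF, C_TAUXRF), (C_E_XRS, C_TAUXRS),
    (C_E_XS1, C_TAUXS1), (C_E_XS2, C_TAUXS2), (C_E_XK1, C_TAUXK1),
)


def rate_columns(v, dt: float | None = None):
    """All purely voltage-dependent quantities, vectorized over ``v`` (mV).

    Returns an array of shape ``v.shape + (NCOL,)``; the trailing
    Rush-Larsen columns are filled only when ``dt`` is given.
    """
    v = np.asarray(v, dtype=np.float64)
    c = np.zeros(v.shape + (NCOL,))
    with np.errstate(over="ignore"):
        exp = np.exp

        # --- TP06 fast sodium gates ---------------------------------------
        c[..., C_MINF] = 1.0 / (1.0 + exp((-56.86 - v) / 9.03)) ** 2
        am = 1.0 / (1.0 + exp((-60.0 - v) / 5.0))
        bm = (0.1 / (1.0 + exp((v + 35.0) / 5.0))
              + 0.1 / (1.0 + exp((v - 50.0) / 200.0)))
        c[..., C_TAUM] = am * bm
        c[..., C_HINF] = 1.0 / (1.0 + exp((v + 71.55) / 7.43)) ** 2
        lo = v < -40.0
        ah = np.where(lo, 0.057 * exp(-(v + 80.0) / 6.8), 0.0)
        bh = np.where(
            lo,
            2.7 * exp(0.079 * v) + 3.1e5 * exp(0.3485 * v),
            0.77 / (0.13 * (1.0 + exp(-(v + 10.66) / 11.1))),
        )
        c[..., C_TAUH] = 1.0 / (ah + bh)
        c[..., C_JINF] = c[..., C_HINF]
        vs = np.where(lo, v, -80.0)  # guard the hi-branch from overflow
        aj = np.where(
            lo,
            (-2.5428e4 * exp(0.2444 * vs) - 6.948e-6 * exp(-0.04391 * vs))
            * (vs + 37.78) / (1.0 + exp(0.311 * (vs + 79.23))),
            0.0,
        )
        bj = np.where(
            lo,
            0.02424 * exp(-0.01052 * v) / (1.0 + exp(-0.1378 * (v + 40.14))),
            0.6 * exp(0.057 * v) / (1.0 + exp(-0.1 * (v + 32.0))),
        )
        c[..., C_TAUJ] = 1.0 / (aj + bj)

        # --- late sodium ---------------------------------------------------
        c[..., C_MLINF] = 1.0 / (1.0 + exp(-(v + 42.85) / 5.264))
        c[..., C_TAUML] = 1.0 / (6.765 * exp((v + 11.64) / 34.77)
                                 + 8.552 * exp(-(v + 77.42) / 5.955))
        c[..., C_HLINF] = 1.0 / (1.0 + exp((v + 87.61) / 7.488))
        c[..., C_HLPINF] = 1.0 / (1.0 + exp((v + 93.81) / 7.488))

        # --- transient outward ---------------------------------------------
        c[..., C_AINF] = 1.0 / (1.0 + exp(-(v - 14.34) / 14.82))
        c[..., C_TAUA] = 1.0515 / (
            1.0 / (1.2089 * (1.0 + exp(-(v - 18.4099) / 29.3814)))
            + 3.5 / (1.0 + exp((v + 100.0) / 29.3814)))
        c[..., C_IINF] = 1.0 / (1.0 + exp((v + 43.94) / 5.711))
        tif = 4.562 + 1.0 / (0.3933 * exp(-(v + 100.0) / 100.0)
                             + 0.08004 * exp((v + 50.0) / 16.59))
        tis = 23.62 + 1.0 / (0.001416 * exp(-(v + 96.52) / 59.05)
                             + 1.780e-8 * exp((v + 114.1) / 8.079))
        c[..., C_TAUIF] = tif
        c[..., C_TAUIS] = tis
        c[..., C_AIF] = 1.0 / (1.0 + exp((v - 213.6) / 151.2))
        c[..., C_APINF] = 1.0 / (1.0 + exp(-(v - 24.34) / 14.82))
        dti_dev = 1.354 + 1.0e-4 / (exp((v - 167.4) / 15.89)
                                    + exp(-(v - 12.23) / 0.2154))
        dti_rec = 1.0 - 0.5 / (1.0 + exp((v + 70.0) / 20.0))
        c[..., C_TAUIFP] = dti_dev * dti_rec * tif
        c[..., C_TAUISP] = dti_dev * dti_rec * tis

        # --- L-type calcium ------------------------------------------------
        c[..., C_DINF] = 1.0 / (1.0 + exp(-(v + 3.940) / 4.230))
        c[..., C_TAUD] = 0.6 + 1.0 / (exp(-0.05 * (v + 6.0))
                                      + exp(0.09 * (v + 14.0)))
        c[..., C_FINF] = 1.0 / (1.0 + exp((v + 19.58) / 3.696))
        c[..., C_TAUFF] = 7.0 + 1.0 / (0.0045 * exp(-(v + 20.0) / 10.0)
                                       + 0.0045 * exp((v + 20.0) / 10.0))
        c[..., C_TAUFS] = 1000.0 + 1.0 / (3.5e-5 * exp(-(v + 5.0) / 4.0)
                                          + 3.5e-5 * exp((v + 5.0) / 6.0))
        c[..., C_TAUFCAF] = 7.0 + 1.0 / (0.04 * exp(-(v - 4.0) / 7.0)
                                         + 0.04 * exp((v - 4.0) / 7.0))
        c[..., C_TAUFCAS] = 100.0 + 1.0 / (1.2e-4 * exp(-v / 3.0)
                                           + 1.2e-4 * exp(v / 7.0))
        c[..., C_AFCAF] = 0.3 + 0.6 / (1.0 + exp((v - 10.0) / 10.0))

        # --- rapid delayed rectifier --------------------------------------
        c[..., C_XRINF] = 1.0 / (1.0 + exp(-(v + 8.337) / 6.789))
        c[..., C_TAUXRF] = 12.98 + 1.0 / (0.3652 * exp((v - 31.66) / 3.869)
                                          + 4.123e-5 * exp(-(v - 47.78) / 20.38))
        c[..., C_TAUXRS] = 1.865 + 1.0 / (0.06629 * exp((v - 34.70) / 7.355)
                                          + 1.128e-5 * exp(-(v - 29.74) / 25.94))
        c[..., C_AXRF] = 1.0 / (1.0 + exp((v + 54.81) / 38.21))
        c[..., C_RKR] = 1.0 / ((1.0 + exp((v + 55.0) / 75.0))
                               * (1.0 + exp((v - 10.0) / 30.0)))

        # --- slow delayed rectifier ---------------------------------------
        c[..., C_XS1INF] = 1.0 / (1.0 + exp(-(v + 11.60) / 8.932))
        c[..., C_TAUXS1] = 817.3 + 1.0 / (2.326e-4 * exp((v + 48.28) / 17.80)
                                          + 0.001292 * exp(-(v + 210.0) / 230.0))
        c[..., C_TAUXS2] = 1.0 / (0.01 * exp((v - 50.0) / 20.0)
                                  + 0.0193 * exp(-(v + 66.54) / 31.0))

        # --- inward rectifier ---------------------------------------------
        c[..., C_XK1INF] = 1.0 / (1.0 + exp(-(v + 2.5538 * KO + 144.59)
                                            / (1.5692 * KO + 3.8115)))
        c[..., C_TAUXK1] = 122.2 / (exp(-(v + 127.2) / 20.36)
                                    + exp((v + 236.8) / 69.33))
        c[..., C_RK1] = 1.0 / (1.0 + exp((v + 105.8 - 2.6 * KO) / 9.493))

        c[..., C_XKB] = 1.0 / (1.0 + exp(-(v - 14.48) / 18.34))

        # --- GHK driving-force prefactors ---------------------------------
        vfrt = v * FRT
        vffrt = v * FARADAY * FRT
        e1 = exp(vfrt)
        e2 = exp(2.0 * vfrt)
        tiny = np.abs(v) < 1.0e-9  # l'Hopital limit at v = 0
        c[..., C_E1V] = e1
        c[..., C_E2V] = e2
        with np.errstate(divide="ignore", invalid="ignore"):
            c[..., C_CA_A] = np.where(tiny, 2.0 * FARADAY,
                                      4.0 * vffrt / (e2 - 1.0))
            c[..., C_NA_A] = np.where(tiny, FARADAY, vffrt / (e1 - 1.0))

        # --- sodium-calcium exchange (voltage-only pieces) ----------------
        hca = exp(QCA * vfrt)
        hna = exp(QNA * vfrt)
        h7 = 1.0 + NAO / KNA3 * (1.0 + 1.0 / hna)
        h8 = NAO / (KNA3 * hna * h7)
        h9 = 1.0 / h7
        c[..., C_K4PFAC] = WCA / hca
        c[..., C_HNA] = hna
        c[..., C_NCXK3] = h9 * WCA + h8 * WNACA
        c[..., C_NCXK8] = h8 * _h11 * WNA

        # --- sodium-potassium pump (voltage-only pieces) ------------------
        knai = KNAI0 * exp(NAK_DELTA * vfrt / 3.0)
        knao = KNAO0 * exp((1.0 - NAK_DELTA) * vfrt / 3.0)
        nak_denom_o = (1.0 + NAO / knao) ** 3 + (1.0 + KO / KKO) ** 2 - 1.0
        c[..., C_NAKB2] = NAK_K2M * (NAO / knao) ** 3 / nak_denom_o
        c[..., C_NAKA3] = NAK_K3P * (KO / KKO) ** 2 / nak_denom_o
        c[..., C_KNAI] = knai

        if dt is not None:
            for ecol, taucol in _RL_MAP:
                c[..., ecol] = np.exp(-dt / c[..., taucol])
    return c


# ---------------------------------------------------------------------------
# lookup table
# ---------------------------------------------------------------------------
LUT_VMIN = -150.0
LUT_VMAX = 250.0
LUT_DV = 0.01

_lut_cache: dict[float, np.ndarray] = {}


def build_lut(dt: float = 0.02) -> np.ndarray:
    """Tabulated rate columns (incl. Rush-Larsen factors for ``dt``) on a
    uniform voltage grid; linear interpolation between rows."""
    if dt not in _lut_cache:
        grid = LUT_VMIN + LUT_DV * np.arange(
            int(round((LUT_VMAX - LUT_VMIN) / LUT_DV)) + 1)
        _lut_cache[dt] = np.ascontiguousarray(rate_columns(grid, dt=dt))
    return _lut_cache[dt]


@njit(cache=True, inline="always")
def _interp_rates(lut, v, out):
    x = (v - LUT_VMIN) / LUT_DV
    nmax = lut.shape[0] - 2
    if not (x >= 0.0):  # also catches NaN/-inf voltages
        x = 0.0
    elif x > nmax:      # and +inf
        x = nmax
    i = int(x)
    w = x - i
    r0 = lut[i]
    r1 = lut[i + 1]
    for k in range(NCOL):
        out[k] = r0[k] + w * (r1[k] - r0[k])


# ---------------------------------------------------------------------------
# current assembly (shared by exact path and tabulated path)
# ---------------------------------------------------------------------------
@njit(cache=True, inline="always")
def h8_term(hna):
    # h8 * wnaca, same closed form as in rate_columns
    h7 = 1.0 + NAO / KNA3 * (1.0 + 1.0 / hna)
    return NAO / (KNA3 * hna * h7) * WNACA


@njit(cache=True, fastmath=True)
def cell_currents(v, y, c, mult, istim, dy):
    """Membrane currents and the concentration/CaMK derivatives.

    ``c`` are the rate columns at voltage ``v`` (exact or interpolated),
    ``mult`` the conductance multipliers (MULT_NAMES order), ``istim`` the
    stimulus current density (uA/uF).  Fills ``dy[0:9]`` (concentrations and
    CaMK trap); gate entries are left untouched.  Returns
    ``(dv_dt, ical)`` where dv/dt excludes any diffusive coupling and
    ``ical`` feeds the SR-release gate dynamics.
    """
    nai = y[0]; nass = y[1]; ki = y[2]; kss = y[3]
    cai = y[4]; cass = y[5]; cansr = y[6]; cajsr = y[7]
    camkt = y[8]
    m = y[9]; h = y[10]; jgate = y[11]
    ml = y[12]; hl = y[13]; hlp = y[14]
    a = y[15]; i_f = y[16]; i_s = y[17]; ap = y[18]; ifp = y[19]; isp = y[20]
    d = y[21]; ff = y[22]; fs = y[23]; fcaf = y[24]; fcas = y[25]
    jca = y[26]; nca = y[27]; ffp = y[28]; fcafp = y[29]
    xrf = y[30]; xrs = y[31]; xs1 = y[32]; xs2 = y[33]; xk1 = y[34]
    jrelnp = y[35]; jrelp = y[36]

    # reversal potentials
    ena = RTF * np.log(NAO / nai)
    ek = RTF * np.log(KO / ki)
    eks = RTF * np.log((KO + 0.01833 * NAO) / (ki + 0.01833 * nai))

    # CaMK
    camkb = CAMKO * (1.0 - camkt) / (1.0 + KMCAM / cass)
    camka = camkb + camkt
    dy[8] = ACAMK * camkb * (camkb + camkt) - BCAMK * camkt
    fp = 1.0 / (1.0 + KMCAMK / camka)  # phosphorylated fraction

    # fast sodium (TP06)
    ina = mult[0] * GNA_TP * m * m * m * h * jgate * (v - ena)

    # late sodium
    inal = mult[1] * GNAL * ml * ((1.0 - fp) * hl + fp * hlp) * (v - ena)

    # transient outward
    ito_i = c[C_AIF] * i_f + (1.0 - c[C_AIF]) * i_s
    ito_ip = c[C_AIF] * ifp + (1.0 - c[C_AIF]) * isp
    ito = mult[2] * GTO * (v - ek) * ((1.0 - fp) * a * ito_i + fp * ap * ito_ip)

    # L-type calcium (GHK flux form)
    f = 0.6 * ff + 0.4 * fs
    fca = c[C_AFCAF] * fcaf + (1.0 - c[C_AFCAF]) * fcas
    f_p = 0.6 * ffp + 0.4 * fs
    fca_p = c[C_AFCAF] * fcafp + (1.0 - c[C_AFCAF]) * fcas
    phical = c[C_CA_A] * (cass * c[C_E2V] - 0.341 * CAO)
    phicana = c[C_NA_A] * (0.75 * nass * c[C_E1V] - 0.75 * NAO)
    phicak = c[C_NA_A] * (0.75 * kss * c[C_E1V] - 0.75 * KO)
    pca = mult[3] * PCA
    gate_np = d * (f * (1.0 - nca) + jca * fca * nca)
    gate_p = d * (f_p * (1.0 - nca) + jca * fca_p * nca)
    wcal = (1.0 - fp) * gate_np + fp * 1.1 * gate_p
    ical = pca * phical * wcal
    icana = 0.00125 * pca * phicana * wcal
    icak = 3.574e-4 * pca * phicak * wcal

    # rapid delayed rectifier
    xr = c[C_AXRF] * xrf + (1.0 - c[C_AXRF]) * xrs
    ikr = mult[4] * GKR * SQRT_KO_54 * xr * c[C_RKR] * (v - ek)

    # slow delayed rectifier
    ksca = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    iks = mult[5] * GKS * ksca * xs1 * xs2 * (v - eks)

    # inward rectifier
    ik1 = mult[6] * GK1 * SQRT_KO * c[C_RK1] * xk1 * (v - ek)

    # sodium-calcium exchange, myoplasmic and subspace
    hna = c[C_HNA]
    k3 = c[C_NCXK3]
    k8 = c[C_NCXK8]
    allo_i = 1.0 / (1.0 + (KMCAACT / cai) ** 2)
    allo_ss = 1.0 / (1.0 + (KMCAACT / cass) ** 2)

    h1 = 1.0 + nai / KNA3 * (1.0 + hna)
    h2 = nai * hna / (KNA3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nai / KNA1 * (1.0 + nai / KNA2)
    h5 = nai * nai / (h4 * KNA1 * KNA2)
    h6 = 1.0 / h4
    k4 = h3 * c[C_K4PFAC] + h2 * WNACA
    k6 = h6 * cai * KCAON
    k7 = h5 * h2 * WNA
    x1 = NCX_K2 * k4 * (k7 + k6) + NCX_K5 * k7 * (NCX_K2 + k3)
    x2 = NCX_K1 * k7 * (k4 + NCX_K5) + k4 * k6 * (NCX_K1 + k8)
    x3 = NCX_K1 * k3 * (k7 + k6) + k8 * k6 * (NCX_K2 + k3)
    x4 = NCX_K2 * k8 * (k4 + NCX_K5) + k3 * NCX_K5 * (NCX_K1 + k8)
    inv_s = 1.0 / (x1 + x2 + x3 + x4)
    e1n = x1 * inv_s; e2n = x2 * inv_s; e3n = x3 * inv_s; e4n = x4 * inv_s
    jncxna_i = (3.0 * (e4n * k7 - e1n * k8)
                + e3n * h2 * WNACA - e2n * h8_term(hna))
    jncxca_i = e2n * NCX_K2 - e1n * NCX_K1
    inaca_i = 0.8 * mult[7] * GNCX * allo_i * (jncxna_i + 2.0 * jncxca_i)

    h1 = 1.0 + nass / KNA3 * (1.0 + hna)
    h2 = nass * hna / (KNA3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nass / KNA1 * (1.0 + nass / KNA2)
    h5 = nass * nass / (h4 * KNA1 * KNA2)
    h6 = 1.0 / h4
    k4 = h3 * c[C_K4PFAC] + h2 * WNACA
    k6 = h6 * cass * KCAON
    k7 = h5 * h2 * WNA
    x1 = NCX_K2 * k4 * (k7 + k6) + NCX_K5 * k7 * (NCX_K2 + k3)
    x2 = NCX_K1 * k7 * (k4 + NCX_K5) + k4 * k6 * (NCX_K1 + k8)
    x3 = NCX_K1 * k3 * (k7 + k6) + k8 * k6 * (NCX_K2 + k3)
    x4 = NCX_K2 * k8 * (k4 + NCX_K5) + k3 * NCX_K5 * (NCX_K1 + k8)
    inv_s = 1.0 / (x1 + x2 + x3 + x4)
    e1n = x1 * inv_s; e2n = x2 * inv_s; e3n = x3 * inv_s; e4n = x4 * inv_s
    jncxna_ss = (3.0 * (e4n * k7 - e1n * k8)
                 + e3n * h2 * WNACA - e2n * h8_term(hna))
    jncxca_ss = e2n * NCX_K2 - e1n * NCX_K1
    inaca_ss = 0.2 * mult[7] * GNCX * allo_ss * (jncxna_ss + 2.0 * jncxca_ss)

    # sodium-potassium pump
    knai = c[C_KNAI]
    inv_denom = 1.0 / ((1.0 + nai / knai) ** 3 + (1.0 + ki / KKI) ** 2 - 1.0)
    a1 = NAK_K1P * (nai / knai) ** 3 * inv_denom
    b1 = NAK_B1
    a2 = NAK_K2P
    b2 = c[C_NAKB2]
    a3 = c[C_NAKA3]
    pfac = NAK_EP / (1.0 + NAK_H / KHP + nai / KNAP + ki / KXKUR)
    b3 = NAK_B3FAC * pfac
    a4 = NAK_A4
    b4 = NAK_K4M * (ki / KKI) ** 2 * inv_denom
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b1 * a4
    inv_s = 1.0 / (x1 + x2 + x3 + x4)
    e1n = x1 * inv_s; e2n = x2 * inv_s; e3n = x3 * inv_s; e4n = x4 * inv_s
    inak = mult[8] * PNAK * (3.0 * (e1n * a3 - e2n * b3)
                             + 2.0 * (e4n * b1 - e3n * a1))

    # background and pump currents
    ikb = mult[9] * GKB * c[C_XKB] * (v - ek)
    inab = PNAB * c[C_NA_A] * (nai * c[C_E1V] - NAO)
    icab = PCAB * c[C_CA_A] * (cai * c[C_E2V] - 0.341 * CAO)
    ipca = mult[10] * GPCA * cai / (0.0005 + cai)

    # SR fluxes
    jrel = mult[11] * ((1.0 - fp) * jrelnp + fp * jrelp)
    jupnp = 0.004375 * cai / (cai + 0.00092)
    jupp = 2.75 * 0.004375 * cai / (cai + 0.00075)
    jleak = 0.0039375 * cansr / 15.0
    jup = mult[12] * ((1.0 - fp) * jupnp + fp * jupp - jleak)
    jtr = (cansr - cajsr) / 100.0

    jdiffna = (nass - nai) / 2.0
    jdiffk = (kss - ki) / 2.0
    jdiffca = (cass - cai) / 0.2

    # concentrations
    dy[0] = -(ina + inal + 3.0 * inaca_i + 3.0 * inak + inab) * ACF_VMYO \
        + jdiffna * VSS_VMYO
    dy[1] = -(icana + 3.0 * inaca_ss) * ACF_VSS - jdiffna
    dy[2] = -(ito + ikr + iks + ik1 + ikb + istim - 2.0 * inak) * ACF_VMYO \
        + jdiffk * VSS_VMYO
    dy[3] = -icak * ACF_VSS - jdiffk
    bcai = 1.0 / (1.0 + CMDNMAX * KMCMDN / (KMCMDN + cai) ** 2
                  + TRPNMAX * KMTRPN / (KMTRPN + cai) ** 2)
    dy[4] = bcai * (-(ipca + icab - 2.0 * inaca_i) * (0.5 * ACF_VMYO)
                    - jup * VNSR_VMYO + jdiffca * VSS_VMYO)
    bcass = 1.0 / (1.0 + BSRMAX * KMBSR / (KMBSR + cass) ** 2
                   + BSLMAX * KMBSL / (KMBSL + cass) ** 2)
    dy[5] = bcass * (-(ical - 2.0 * inaca_ss) * (0.5 * ACF_VSS)
                     + jrel * VJSR_VSS - jdiffca)
    dy[6] = jup - jtr * VJSR_VNSR
    bcajsr = 1.0 / (1.0 + CSQNMAX * KMCSQN / (KMCSQN + cajsr) ** 2)
    dy[7] = bcajsr * (jtr - jrel)

    itot = (ina + inal + ito + ical + icana + icak + ikr + iks + ik1
            + inaca_i + inaca_ss + inak + inab + icab + ikb + ipca)
    return -(itot + istim), ical


@njit(cache=True)
def gate_derivs(y, c, ical, dy):
    """Exact gate derivatives d y/dt = (y_inf - y)/tau; fills dy[9:37]."""
    dy[9] = (c[C_MINF] - y[9]) / c[C_TAUM]
    dy[10] = (c[C_HINF] - y[10]) / c[C_TAUH]
    dy[11] = (c[C_JINF] - y[11]) / c[C_TAUJ]
    dy[12] = (c[C_MLINF] - y[12]) / c[C_TAUML]
    dy[13] = (c[C_HLINF] - y[13]) / TAU_HL
    dy[14] = (c[C_HLPINF] - y[14]) / TAU_HLP
    dy[15] = (c[C_AINF] - y[15]) / c[C_TAUA]
    dy[16] = (c[C_IINF] - y[16]) / c[C_TAUIF]
    dy[17] = (c[C_IINF] - y[17]) / c[C_TAUIS]
    dy[18] = (c[C_APINF] - y[18]) / c[C_TAUA]
    dy[19] = (c[C_IINF] - y[19]) / c[C_TAUIFP]
    dy[20] = (c[C_IINF] - y[20]) / c[C_TAUISP]
    dy[21] = (c[C_DINF] - y[21]) / c[C_TAUD]
    dy[22] = (c[C_FINF] - y[22]) / c[C_TAUFF]
    dy[23] = (c[C_FINF] - y[23]) / c[C_TAUFS]
    dy[24] = (c[C_FINF] - y[24]) / c[C_TAUFCAF]
    dy[25] = (c[C_FINF] - y[25]) / c[C_TAUFCAS]
    dy[26] = (c[C_FINF] - y[26]) / TAU_JCA
    jca = y[26]
    # anca*k2n written division-free (exact limit 0 as jca -> 0)
    bterm = (1.0 + 0.002 / y[5]) ** 4
    dy[27] = 1000.0 * jca / (1000.0 + jca * bterm) - y[27] * jca
    dy[28] = (c[C_FINF] - y[28]) / (2.5 * c[C_TAUFF])
    dy[29] = (c[C_FINF] - y[29]) / (2.5 * c[C_TAUFCAF])
    dy[30] = (c[C_XRINF] - y[30]) / c[C_TAUXRF]
    dy[31] = (c[C_XRINF] - y[31]) / c[C_TAUXRS]
    dy[32] = (c[C_XS1INF] - y[32]) / c[C_TAUXS1]
    dy[33] = (c[C_XS1INF] - y[33]) / c[C_TAUXS2]
    dy[34] = (c[C_XK1INF] - y[34]) / c[C_TAUXK1]
    jrel_inf = 2.375 * (-ical) / (1.0 + (1.5 / y[7]) ** 8)
    trel = 4.75 / (1.0 + 0.0123 / y[7])
    if trel < 0.001:
        trel = 0.001
    dy[35] = (jrel_inf - y[35]) / trel
    trelp = 1.25 * trel
    dy[36] = (1.25 * jrel_inf - y[36]) / trelp


@njit(cache=True, fastmath=True)
def gate_update(y, c, ical, dt, e_hl, e_hlp, e_jca):
    """In-place Rush-Larsen update of all gating variables.

    Uses the tabulated exp(-dt/tau) columns; the three voltage-independent
    taus come in as precomputed factors; the SR-release gates (state-
    dependent tau) take a runtime exponential; nca (linear, slow) advances
    by forward Euler.  Must be called before the concentrations are
    advanced (reads old cass/cajsr).
    """
    jca_old = y[26]
    # nca: d nca/dt = anca*k2n - nca*km2n with km2n = jca (division-free)
    bterm = (1.0 + 0.002 / y[5]) ** 4
    y[27] += dt * (1000.0 * jca_old / (1000.0 + jca_old * bterm)
                   - y[27] * jca_old)

    y[9] = c[C_MINF] + (y[9] - c[C_MINF]) * c[C_E_M]
    y[10] = c[C_HINF] + (y[10] - c[C_HINF]) * c[C_E_H]
    y[11] = c[C_JINF] + (y[11] - c[C_JINF]) * c[C_E_J]
    y[12] = c[C_MLINF] + (y[12] - c[C_MLINF]) * c[C_E_ML]
    y[13] = c[C_HLINF] + (y[13] - c[C_HLINF]) * e_hl
    y[14] = c[C_HLPINF] + (y[14] - c[C_HLPINF]) * e_hlp
    y[15] = c[C_AINF] + (y[15] - c[C_AINF]) * c[C_E_A]
    y[16] = c[C_IINF] + (y[16] - c[C_IINF]) * c[C_E_IF]
    y[17] = c[C_IINF] + (y[17] - c[C_IINF]) * c[C_E_IS]
    y[18] = c[C_APINF] + (y[18] - c[C_APINF]) * c[C_E_A]
    y[19] = c[C_IINF] + (y[19] - c[C_IINF]) * c[C_E_IFP]
    y[20] = c[C_IINF] + (y[20] - c[C_IINF]) * c[C_E_ISP]
    y[21] = c[C_DINF] + (y[21] - c[C_DINF]) * c[C_E_D]
    y[22] = c[C_FINF] + (y[22] - c[C_FINF]) * c[C_E_FF]
    y[23] = c[C_FINF] + (y[23] - c[C_FINF]) * c[C_E_FS]
    y[24] = c[C_FINF] + (y[24] - c[C_FINF]) * c[C_E_FCAF]
    y[25] = c[C_FINF] + (y[25] - c[C_FINF]) * c[C_E_FCAS]
    y[26] = c[C_FINF] + (y[26] - c[C_FINF]) * e_jca
    y[28] = c[C_FINF] + (y[28] - c[C_FINF]) * c[C_E_FFP]
    y[29] = c[C_FINF] + (y[29] - c[C_FINF]) * c[C_E_FCAFP]
    y[30] = c[C_XRINF] + (y[30] - c[C_XRINF]) * c[C_E_XRF]
    y[31] = c[C_XRINF] + (y[31] - c[C_XRINF]) * c[C_E_XRS]
    y[32] = c[C_XS1INF] + (y[32] - c[C_XS1INF]) * c[C_E_XS1]
    y[33] = c[C_XS1INF] + (y[33] - c[C_XS1INF]) * c[C_E_XS2]
    y[34] = c[C_XK1INF] + (y[34] - c[C_XK1INF]) * c[C_E_XK1]

    jrel_inf = 2.375 * (-ical) / (1.0 + (1.5 / y[7]) ** 8)
    trel = 4.75 / (1.0 + 0.0123 / y[7])
    if trel < 0.001:
        trel = 0.001
    y[35] = jrel_inf + (y[35] - jrel_inf) * np.exp(-dt / trel)
    jrel_infp = 1.25 * jrel_inf
    y[36] = jrel_infp + (y[36] - jrel_infp) * np.exp(-dt / (1.25 * trel))


@njit(cache=True, inline="always")
def advance_myocyte(v, y, c, mult, istim, dt, dy, e_hl, e_hlp, e_jca):
    """One full explicit step of the local myocyte dynamics (no coupling).

    Returns dv/dt; updates gates (Rush-Larsen) and concentrations (Euler)
    in place.  The caller integrates the voltage so that diffusive coupling
    can be added.
    """
    dv, ical = cell_currents(v, y, c, mult, istim, dy)
    gate_update(y, c, ical, dt, e_hl, e_hlp, e_jca)
    for q in range(9):
        y[q] += dt * dy[q]
    return dv
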