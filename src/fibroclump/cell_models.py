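"""Single-cell models: modified O'Hara-Rudy myocyte and passive fibroblast.

The myocyte is the ORd human ventricular cell (endocardial by default) with
its fast sodium current replaced by the Ten Tusscher-Panfilov m^3*h*j
formulation, and the rapid delayed-rectifier conductance doubled in the
control parameter set, which shortens the action potential enough to keep
tissue wavelengths tractable.  The fibroblast is a passive membrane with a
piecewise-constant conductance: 1 nS below -20 mV, 2 nS above, and a
reversal potential of -30 mV.

Units throughout: mV, ms, mM, nS, pF; current densities in uA/uF.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _ord
from ._kernels import fibro_steps, pair_steps, single_cell_steps
from ._ord import (CONC_SLICE, GATE_SLICE, MULT_NAMES, NVARS, STATE_NAMES,
                   build_lut, cell_currents, default_multipliers,
                   gate_derivs, rate_columns)

DT_MS = 0.02  # model time step used by every integrator in the package

# transmural presets, expressed as conductance multipliers relative to endo.
# The calmodulin-buffering difference of the M cell is not represented.
_CELLTYPE_SCALES = {
    "endo": {},
    "epi": {"gnal": 0.6, "gto": 4.0, "gcal": 1.2, "gkr": 1.3, "gks": 1.4,
            "gk1": 1.2, "gncx": 1.1, "gnak": 0.9, "gkb": 0.6},
    "mid": {"gto": 4.0, "gcal": 2.5, "gkr": 0.8, "gk1": 1.3, "gncx": 1.4,
            "gnak": 0.7, "jrel": 1.7},
}


@dataclass
class MyocyteParams:
    """Myocyte capacitance and conductance multipliers (control defaults)."""

    cm: float = 185.0           # pF
    celltype: str = "endo"
    gna_scale: float = 1.0
    gnal_scale: float = 1.0
    gto_scale: float = 1.0
    gcal_scale: float = 1.0
    gkr_scale: float = 2.0      # control set: I_Kr conductance doubled
    gks_scale: float = 1.0
    gk1_scale: float = 1.0
    gncx_scale: float = 1.0
    gnak_scale: float = 1.0
    gkb_scale: float = 1.0
    gpca_scale: float = 1.0
    jrel_scale: float = 1.0
    jup_scale: float = 1.0

    def __post_init__(self):
        if self.cm <= 0:
            raise ValueError("cm must be positive")
        if self.celltype not in _CELLTYPE_SCALES:
            raise ValueError(f"unknown celltype {self.celltype!r}")
        for name in MULT_NAMES:
            val = getattr(self, _ATTR_OF[name])
            if not np.isfinite(val) or val < 0:
                raise ValueError(f"multiplier {name} must be finite and >= 0")

    def multipliers(self) -> np.ndarray:
        """Multiplier vector in MULT_NAMES order, celltype scaling applied."""
        m = np.empty(len(MULT_NAMES))
        scales = _CELLTYPE_SCALES[self.celltype]
        for k, name in enumerate(MULT_NAMES):
            m[k] = getattr(self, _ATTR_OF[name]) * scales.get(name, 1.0)
        return m


_ATTR_OF = {"gna": "gna_scale", "gnal": "gnal_scale", "gto": "gto_scale",
            "gcal": "gcal_scale", "gkr": "gkr_scale", "gks": "gks_scale",
            "gk1": "gk1_scale", "gncx": "gncx_scale", "gnak": "gnak_scale",
            "gkb": "gkb_scale", "gpca": "gpca_scale", "jrel": "jrel_scale",
            "jup": "jup_scale"}


@dataclass
class FibroblastParams:
    """Passive fibroblast: capacitance, reversal, two-level conductance."""

    cf: float = 6.3        # pF
    ef: float = -30.0      # mV
    gf_low: float = 1.0    # nS, V_f below the switch
    gf_high: float = 2.0   # nS, V_f above the switch
    vf_switch: float = -20.0

    def __post_init__(self):
        if self.cf <= 0 or self.gf_low <= 0 or self.gf_high <= 0:
            raise ValueError("capacitance and conductances must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.cf, self.ef, self.gf_low, self.gf_high,
                         self.vf_switch])


@dataclass
class MyocyteState:
    """Full ionic state of one myocyte: membrane potential plus the ORd
    gating variables and intracellular/subspace concentrations."""

    vm: float
    y: np.ndarray  # length NVARS, STATE_NAMES order

    @property
    def gates(self) -> np.ndarray:
        return self.y[GATE_SLICE]

    @property
    def concentrations(self) -> np.ndarray:
        return self.y[CONC_SLICE]

    def __getitem__(self, name: str) -> float:
        return self.y[STATE_NAMES.index(name)]

    def validate(self) -> None:
        if not np.isfinite(self.vm):
            raise ValueError("non-finite state variable: vm")
        bad = np.flatnonzero(~np.isfinite(self.y))
        if bad.size:
            raise ValueError(
                f"non-finite state variable: {STATE_NAMES[bad[0]]}")

    def copy(self) -> "MyocyteState":
        return MyocyteState(self.vm, self.y.copy())


def initial_myocyte_state(v0: float = -87.84) -> MyocyteState:
    """Approximate quiescent state: gates at their steady values for ``v0``,
    concentrations at typical diastolic levels.  Use
    :func:`single_cell_steady_state` for a fully relaxed state."""
    y = np.empty(NVARS)
    y[STATE_NAMES.index("nai")] = 7.23
    y[STATE_NAMES.index("nass")] = 7.23
    y[STATE_NAMES.index("ki")] = 143.79
    y[STATE_NAMES.index("kss")] = 143.79
    y[STATE_NAMES.index("cai")] = 8.5e-5
    y[STATE_NAMES.index("cass")] = 8.4e-5
    y[STATE_NAMES.index("cansr")] = 1.61
    y[STATE_NAMES.index("cajsr")] = 1.56
    y[STATE_NAMES.index("camkt")] = 0.0111
    c = rate_columns(v0)
    inf_of = {
        "m": _ord.C_MINF, "h": _ord.C_HINF, "j": _ord.C_JINF,
        "ml": _ord.C_MLINF, "hl": _ord.C_HLINF, "hlp": _ord.C_HLPINF,
        "a": _ord.C_AINF, "if_": _ord.C_IINF, "is_": _ord.C_IINF,
        "ap": _ord.C_APINF, "ifp": _ord.C_IINF, "isp": _ord.C_IINF,
        "d": _ord.C_DINF, "ff": _ord.C_FINF, "fs": _ord.C_FINF,
        "fcaf": _ord.C_FINF, "fcas": _ord.C_FINF, "jca": _ord.C_FINF,
        "ffp": _ord.C_FINF, "fcafp": _ord.C_FINF,
        "xrf": _ord.C_XRINF, "xrs": _ord.C_XRINF,
        "xs1": _ord.C_XS1INF, "xs2": _ord.C_XS1INF, "xk1": _ord.C_XK1INF,
    }
    for name, col in inf_of.items():
        y[STATE_NAMES.index(name)] = c[col]
    y[STATE_NAMES.index("nca")] = 0.0
    y[STATE_NAMES.index("jrelnp")] = 0.0
    y[STATE_NAMES.index("jrelp")] = 0.0
    return MyocyteState(v0, y)


# ---------------------------------------------------------------------------
# right-hand sides
# ---------------------------------------------------------------------------
def myocyte_rhs(state: MyocyteState, params: MyocyteParams | None = None,
                i_stim: float = 0.0, i_couple: float = 0.0):
    """Exact time derivative of the myocyte state.

    ``i_stim`` is a current density (uA/uF; negative depolarizes since
    dV/dt = -(I_ion + I_stim)); ``i_couple`` is an additive voltage-rate
    contribution (mV/ms) from gap-junctional coupling.

    Returns ``(dvm_dt, dy_dt)``.
    """
    if params is None:
        params = MyocyteParams()
    state.validate()
    mult = params.multipliers()
    if not np.all(np.isfinite(mult)):
        raise ValueError("non-finite conductance multiplier")
    c = rate_columns(state.vm)
    dy = np.empty(NVARS)
    dv, ical = cell_currents(state.vm, state.y, c, mult, i_stim, dy)
    gate_derivs(state.y, c, ical, dy)
    return dv + i_couple, dy


def gf_conductance(vf: float, params: FibroblastParams | None = None) -> float:
    """Piecewise-constant fibroblast membrane conductance (nS); the switch
    voltage itself belongs to the low branch."""
    if params is None:
        params = FibroblastParams()
    if not np.isfinite(vf):
        raise ValueError("non-finite fibroblast voltage")
    return params.gf_low if vf <= params.vf_switch else params.gf_high


def fibroblast_rhs(vf: float, params: FibroblastParams | None = None) -> float:
    """dV_f/dt = -G_f(V_f) (V_f - E_f) / C_f  (mV/ms)."""
    if params is None:
        params = FibroblastParams()
    gf = gf_conductance(vf, params)
    return -gf * (vf - params.ef) / params.cf


# ---------------------------------------------------------------------------
# single-cell integrators
# ---------------------------------------------------------------------------
def _stim_train(n_steps: int, pcl_ms: float | None, amp: float,
                pulse_ms: float, dt: float, n_pulses: int | None = None):
    stim = np.zeros(n_steps)
    if pcl_ms is None:
        return stim
    t = dt * np.arange(n_steps)
    k = np.floor(t / pcl_ms)
    in_pulse = (t - k * pcl_ms) < pulse_ms
    if n_pulses is not None:
        in_pulse &= k < n_pulses
    stim[in_pulse] = amp
    return stim


def simulate_myocyte(params: MyocyteParams | None = None,
                     duration_ms: float = 1000.0,
                     pcl_ms: float | None = None,
                     stim_amp: float = -80.0, stim_ms: float = 0.5,
                     state: MyocyteState | None = None,
                     record_every_ms: float = 1.0, dt: float = DT_MS):
    """Pace (or rest) a single myocyte; returns ``(t, vm_trace, final_state)``.

    The integration path (tabulated rates, forward Euler) is the same
    compiled routine the tissue solver applies at each myocyte site.
    """
    if params is None:
        params = MyocyteParams()
    if state is None:
        state = initial_myocyte_state()
    y = state.y.copy()
    n_steps = int(round(duration_ms / dt))
    rec_every = max(1, int(round(record_every_ms / dt)))
    stim = _stim_train(n_steps, pcl_ms, stim_amp, stim_ms, dt)
    out_v = np.empty(n_steps // rec_every + (1 if n_steps % rec_every else 0))
    vend = single_cell_steps(state.vm, y, build_lut(dt), params.multipliers(),
                             stim, dt, rec_every, out_v)
    t = dt * rec_every * np.arange(out_v.size)
    return t, out_v, MyocyteState(vend, y)


def simulate_fibroblast(vf0: float, params: FibroblastParams | None = None,
                        duration_ms: float = 5000.0,
                        record_every_ms: float = 1.0, dt: float = DT_MS):
    """Free relaxation of an isolated fibroblast from ``vf0``."""
    if params is None:
        params = FibroblastParams()
    n_steps = int(round(duration_ms / dt))
    rec_every = max(1, int(round(record_every_ms / dt)))
    stim = np.zeros(n_steps)
    out_v = np.empty(n_steps // rec_every + (1 if n_steps % rec_every else 0))
    vend = fibro_steps(vf0, params.cf, params.ef, params.gf_low,
                       params.gf_high, params.vf_switch, stim, dt,
                       rec_every, out_v)
    t = dt * rec_every * np.arange(out_v.size)
    return t, out_v, vend


def simulate_pair(params: MyocyteParams | None = None,
                  fparams: FibroblastParams | None = None,
                  g_gap_ns: float = 8.0, n_fib: int = 1,
                  duration_ms: float = 2000.0, pcl_ms: float | None = 1000.0,
                  stim_amp: float = -80.0, stim_ms: float = 0.5,
                  state: MyocyteState | None = None, vf0: float = -30.0,
                  record_every_ms: float = 1.0, dt: float = DT_MS):
    """Myocyte gap-coupled to ``n_fib`` fibroblasts (two coupled ODE systems,
    written out directly; doubles as the reference for the 1x2 lattice)."""
    if params is None:
        params = MyocyteParams()
    if fparams is None:
        fparams = FibroblastParams()
    if state is None:
        state = initial_myocyte_state()
    y = state.y.copy()
    n_steps = int(round(duration_ms / dt))
    rec_every = max(1, int(round(record_every_ms / dt)))
    stim = _stim_train(n_steps, pcl_ms, stim_amp, stim_ms, dt)
    nrec = n_steps // rec_every + (1 if n_steps % rec_every else 0)
    out_vm = np.empty(nrec)
    out_vf = np.empty(nrec)
    pair_steps(state.vm, vf0, y, build_lut(dt), params.multipliers(), g_gap_ns,
               params.cm, fparams.cf, fparams.ef, fparams.gf_low,
               fparams.gf_high, fparams.vf_switch, float(n_fib), stim, dt,
               rec_every, out_vm, out_vf)
    t = dt * rec_every * np.arange(nrec)
    return t, out_vm, out_vf


def paced_cycle_states(params: MyocyteParams | None = None,
                       pcl_ms: float = 156.0, n_beats: int = 8,
                       sample_every_ms: float = 1.0,
                       state: MyocyteState | None = None):
    """Full-state samples over one steady paced cycle.

    Paces a single myocyte for ``n_beats`` beats, then samples (V, y) every
    ``sample_every_ms`` through one more cycle.  The bank of states is the
    raw material for phase-distributed initial conditions (direct rotor
    seeding in tissue).

    Returns ``(phase_times_ms, v_samples, y_samples)`` with shapes
    (n,), (n,), (n, NVARS).
    """
    if params is None:
        params = MyocyteParams()
    if state is None:
        state, _ = single_cell_steady_state("myocyte", params=params,
                                            duration_ms=20_000.0)
    _, _, state = simulate_myocyte(params, duration_ms=n_beats * pcl_ms,
                                   pcl_ms=pcl_ms, state=state)
    # continue beat-by-beat in short segments, capturing the full state
    n = int(round(pcl_ms / sample_every_ms))
    times = sample_every_ms * np.arange(n)
    vs = np.empty(n)
    ys = np.empty((n, NVARS))
    for k in range(n):
        vs[k] = state.vm
        ys[k] = state.y
        # remaining phase of the pacing cycle for the stimulus bookkeeping
        t0 = k * sample_every_ms
        stim_amp = -80.0 if t0 < 0.5 else 0.0
        _, _, state = simulate_myocyte(params, duration_ms=sample_every_ms,
                                       pcl_ms=None if stim_amp == 0 else
                                       pcl_ms, stim_amp=stim_amp,
                                       stim_ms=0.5, state=state)
    return times, vs, ys


def single_cell_steady_state(cell_kind: str = "myocyte",
                             params=None, duration_ms: float | None = None,
                             v0: float | None = None, dt: float = DT_MS):
    """Relax a quiescent cell to its resting state.

    Returns ``(state, converged)``; convergence means successive 1-s windows
    change V by less than 1e-4 mV.  For the fibroblast the returned state is
    the scalar membrane voltage.
    """
    if cell_kind == "fibroblast":
        if duration_ms is None:
            duration_ms = 5000.0
        _, trace, vend = simulate_fibroblast(
            -50.0 if v0 is None else v0, params, duration_ms,
            record_every_ms=1000.0, dt=dt)
        converged = trace.size >= 2 and abs(vend - trace[-1]) < 1e-4
        return vend, converged
    if cell_kind != "myocyte":
        raise ValueError(f"unknown cell kind {cell_kind!r}")
    if duration_ms is None:
        duration_ms = 100_000.0
    state = initial_myocyte_state(-87.84 if v0 is None else v0)
    _, trace, final = simulate_myocyte(params, duration_ms, pcl_ms=None,
                                       state=state, record_every_ms=1000.0,
                                       dt=dt)
    converged = trace.size >= 2 and abs(final.vm - trace[-1]) < 1e-4
    return final, converged
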