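"""Explicit monodomain integration of the myocyte/fibroblast lattice.

Every site evolves as

    dV/dt = -(1 - eta) I_ion/C_m - eta I_f/C_f + sum_nb G (V_nb - V) - I_stim

on a square (2D) or simple-cubic (3D) lattice with no-flux boundaries,
integrated with forward Euler for voltage and concentrations and the
exponential relaxation update for gates, at dx = 0.02 cm and dt = 0.02 ms.
Line stimuli (-150 uA/uF for 3 ms) are applied on the lower (y = 0)
boundary, either persistently (PP) or as a fixed train of pulses (TP).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _ord
from ._kernels import lattice_step
from .cell_models import (DT_MS, FibroblastParams, MyocyteParams,
                          single_cell_steady_state)
from .clump_synthesis import D_MM, CouplingField, TissueGeometry, \
    build_coupling

log = logging.getLogger(__name__)

VMAX_ABORT_MV = 300.0  # instability guard on |V| (electrode sites overshoot during pulses)


@dataclass
class StimulusProtocol:
    """Line-pacing protocol.

    mode "PP" paces for the whole run; "TP" delivers ``n_pulses`` pulses
    (20 by default) and then stops.  The electrode occupies
    ``electrode_rows`` lattice rows at the lower (y = 0) boundary and
    drives every site on them, fibroblasts included.
    """

    mode: str = "PP"
    pcl_ms: float = 152.0
    amplitude: float = -150.0   # uA/uF; negative depolarizes
    pulse_ms: float = 3.0
    n_pulses: int | None = None  # None: unbounded (PP) / 20 (TP)
    electrode_rows: int = 2
    stimulate_fibroblasts: bool = True

    def __post_init__(self):
        if self.mode not in ("PP", "TP"):
            raise ValueError(f"unknown pacing mode {self.mode!r}")
        if self.pcl_ms <= self.pulse_ms:
            raise ValueError("pcl_ms must exceed pulse_ms")
        if self.amplitude == 0:
            raise ValueError("amplitude must be nonzero")
        if self.n_pulses is None and self.mode == "TP":
            self.n_pulses = 20

    @property
    def frequency_hz(self) -> float:
        """Pacing frequency 1/PCL in Hz."""
        return 1000.0 / self.pcl_ms

    def pulse_active(self, t_ms: float) -> bool:
        """Is the stimulus on at time ``t_ms``?  Pulse k occupies
        [k*pcl, k*pcl + pulse_ms) for every allowed pulse index k."""
        if t_ms < 0:
            return False
        k = int(t_ms // self.pcl_ms)
        if self.n_pulses is not None and k >= self.n_pulses:
            return False
        return (t_ms - k * self.pcl_ms) < self.pulse_ms

    def pulse_count(self, duration_ms: float) -> int:
        """Number of pulses that begin within [0, duration_ms)."""
        k = int(np.ceil(duration_ms / self.pcl_ms))
        if self.n_pulses is not None:
            k = min(k, self.n_pulses)
        return max(k, 0)

    def last_pulse_end_ms(self, duration_ms: float) -> float:
        n = self.pulse_count(duration_ms)
        if n == 0:
            return 0.0
        return (n - 1) * self.pcl_ms + self.pulse_ms


def apply_stimulus(protocol: StimulusProtocol, t_ms: float,
                   geometry: TissueGeometry) -> np.ndarray:
    """Per-site stimulus current density (uA/uF) at time ``t_ms``."""
    fld = np.zeros(geometry.dims)
    if protocol.pulse_active(t_ms):
        sl = [slice(None)] * geometry.ndim
        sl[geometry.ndim - 2] = slice(0, protocol.electrode_rows)
        fld[tuple(sl)] = protocol.amplitude
        if not protocol.stimulate_fibroblasts:
            fld[geometry.eta.astype(bool)] = 0.0
    return fld


def default_probes(dims) -> list[tuple[int, ...]]:
    """Midpoints of the four domain quadrants (middle z-layer in 3D)."""
    ny, nx = dims[-2], dims[-1]
    pts = [(ny // 4, nx // 4), (ny // 4, 3 * nx // 4),
           (3 * ny // 4, nx // 4), (3 * ny // 4, 3 * nx // 4)]
    if len(dims) == 3:
        return [(dims[0] // 2, y, x) for (y, x) in pts]
    return pts


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one run."""

    geometry: TissueGeometry
    protocol: StimulusProtocol
    duration_ms: float
    coupling: CouplingField | None = None
    dt_ms: float = DT_MS
    d_mm: float = D_MM
    record_every_ms: float = 1.0
    snapshot_every_ms: float = 20.0
    record_snapshots: bool = False
    probes: Sequence[tuple[int, ...]] | None = None
    myocyte_params: MyocyteParams = field(default_factory=MyocyteParams)
    fibro_params: FibroblastParams = field(default_factory=FibroblastParams)
    seed: int | None = None
    # optional extra stimuli (e.g. the S2 of a cross-field spiral
    # initiation): dicts with t0_ms, duration_ms, amplitude and a half-open
    # index box region (y0, y1, x0, x1)
    extra_stimuli: list | None = None
    # optional non-quiescent start: {"v": (*dims,), "y": (n_myo, NVARS)}
    initial_state: dict | None = None

    def __post_init__(self):
        if self.duration_ms < 0:
            raise ValueError("duration_ms must be >= 0")
        d = self.geometry.ndim
        bound = self.geometry.dx_cm ** 2 / (2.0 * d * self.d_mm)
        if self.dt_ms >= bound:
            raise ValueError(
                f"dt_ms = {self.dt_ms} violates the diffusion stability "
                f"bound dx^2/(2*{d}*D_mm) = {bound:.4f} ms")
        if self.probes is None:
            self.probes = default_probes(self.geometry.dims)
        self.probes = [tuple(int(i) for i in p) for p in self.probes]

    def summary(self) -> dict:
        p = self.protocol
        mp = self.myocyte_params
        return {
            "dims": list(self.geometry.dims),
            "dx_cm": self.geometry.dx_cm,
            "geometry_seed": self.geometry.seed,
            "n_fibroblasts": int(self.geometry.eta.sum()),
            "protocol": {"mode": p.mode, "pcl_ms": p.pcl_ms,
                         "amplitude": p.amplitude, "pulse_ms": p.pulse_ms,
                         "n_pulses": p.n_pulses,
                         "electrode_rows": p.electrode_rows},
            "duration_ms": self.duration_ms,
            "dt_ms": self.dt_ms,
            "d_mm": self.d_mm,
            "record_every_ms": self.record_every_ms,
            "snapshot_every_ms": self.snapshot_every_ms,
            "probes": [list(p_) for p_ in self.probes],
            "myocyte_multipliers": list(mp.multipliers()),
            "celltype": mp.celltype,
            "seed": self.seed,
            "extra_stimuli": self.extra_stimuli,
        }

    def content_hash(self) -> str:
        payload = json.dumps(self.summary(), sort_keys=True).encode()
        h = hashlib.sha256(payload)
        h.update(self.geometry.eta.tobytes())
        h.update(self.geometry.gna_scale_field.tobytes())
        return h.hexdigest()[:16]


@dataclass
class RunRecord:
    """Probe traces, snapshot stack and event log of one simulation."""

    t_ms: np.ndarray            # probe sample times
    probe_vm: np.ndarray        # (n_probes, n_samples)
    probes: list
    snapshot_t_ms: np.ndarray
    snapshots: np.ndarray       # (n_snap, *dims) float32; may be empty
    final_v: np.ndarray         # (*dims,) float64
    events: list
    config: dict
    config_hash: str
    seed: int | None

    @property
    def dims(self) -> tuple[int, ...]:
        return tuple(self.config["dims"])

    @property
    def dx_cm(self) -> float:
        return float(self.config["dx_cm"])


_rest_cache: dict[tuple, tuple[float, np.ndarray]] = {}


def resting_myocyte(params: MyocyteParams, pcl_ms: float = 1000.0,
                    n_beats: int = 15):
    """Diastolic myocyte state after pacing to steady state at 1 Hz,
    cached per parameter set.

    This is the canonical initial condition of the ionic model; starting
    tissue from a deeply quiescent (long-unpaced) cell instead overloads
    the SR and prolongs the first action potential by ~15%.
    """
    from .cell_models import simulate_myocyte

    key = (tuple(params.multipliers()), pcl_ms, n_beats)
    if key not in _rest_cache:
        state, _ = single_cell_steady_state("myocyte", params=params,
                                            duration_ms=20_000.0)
        _, _, state = simulate_myocyte(params,
                                       duration_ms=n_beats * pcl_ms,
                                       pcl_ms=pcl_ms, state=state)
        _rest_cache[key] = (state.vm, state.y.copy())
    vm, y = _rest_cache[key]
    return vm, y.copy()


class Simulation:
    """Mutable integration state; prefer :func:`run` for whole runs."""

    def __init__(self, config: SimulationConfig):
        config.geometry.eta  # validated by the dataclass
        self.config = config
        geo = config.geometry
        self.coupling = config.coupling or build_coupling(geo, d_mm=config.d_mm)
        eta = geo.eta.ravel().astype(bool)
        self.myo_idx = np.flatnonzero(~eta).astype(np.int64)
        self.fib_idx = np.flatnonzero(eta).astype(np.int64)
        if config.initial_state is not None:
            self.v = np.asarray(config.initial_state["v"],
                                float).ravel().copy()
            self.y = np.array(config.initial_state["y"], float)
            if self.y.shape != (self.myo_idx.size, _ord.NVARS):
                raise ValueError("initial_state y has the wrong shape")
        else:
            vm0, y0 = resting_myocyte(config.myocyte_params)
            self.v = np.full(geo.n_sites, config.fibro_params.ef)
            self.v[self.myo_idx] = vm0
            self.y = np.tile(y0, (self.myo_idx.size, 1))
        self.v_next = self.v.copy()
        self.gna_site = geo.gna_scale_field.ravel().copy()
        self.mult = config.myocyte_params.multipliers()
        self.fib_par = config.fibro_params.as_array()
        self.lut = _ord.build_lut(config.dt_ms)
        proto = config.protocol
        fld = np.zeros(geo.dims)
        sl = [slice(None)] * geo.ndim
        sl[geo.ndim - 2] = slice(0, proto.electrode_rows)
        fld[tuple(sl)] = proto.amplitude
        if not proto.stimulate_fibroblasts:
            fld[geo.eta.astype(bool)] = 0.0
        self.stim_field = fld.ravel()
        self.extra = []
        for ex in (config.extra_stimuli or []):
            efld = np.zeros(geo.dims)
            y0, y1, x0, x1 = ex["region"]
            sl = [slice(None)] * geo.ndim
            sl[geo.ndim - 2] = slice(y0, y1)
            sl[geo.ndim - 1] = slice(x0, x1)
            efld[tuple(sl)] = ex["amplitude"]
            self.extra.append((float(ex["t0_ms"]),
                               float(ex["t0_ms"]) + float(ex["duration_ms"]),
                               efld.ravel()))
        self.t_ms = 0.0
        self.step_index = 0

    def step(self) -> float:
        """One explicit step; returns max |V| (instability guard)."""
        cfg = self.config
        stim_on = 1.0 if cfg.protocol.pulse_active(self.t_ms) else 0.0
        field = self.stim_field
        live = [f for (t0, t1, f) in self.extra if t0 <= self.t_ms < t1]
        if live:
            field = stim_on * field + np.sum(live, axis=0)
            stim_on = 1.0
        vmax = lattice_step(self.v, self.v_next, self.y, self.myo_idx,
                            self.fib_idx, self.coupling.weights,
                            self.coupling.nbr, self.lut, self.mult,
                            self.gna_site, field, stim_on,
                            self.fib_par, cfg.dt_ms)
        self.v, self.v_next = self.v_next, self.v
        self.step_index += 1
        self.t_ms = self.step_index * cfg.dt_ms
        return vmax


def euler_step(sim: Simulation) -> float:
    """Advance a :class:`Simulation` by one explicit step."""
    return sim.step()


def run(config: SimulationConfig, progress: bool = False) -> RunRecord:
    """Integrate for the configured duration.

    Probe traces sample every ``record_every_ms``; full-field snapshots
    (float32) every ``snapshot_every_ms`` when ``record_snapshots`` is on.
    Deterministic: identical configs give bit-identical records.
    """
    sim = Simulation(config)
    geo = config.geometry
    dt = config.dt_ms
    n_steps = int(round(config.duration_ms / dt))
    rec_every = max(1, int(round(config.record_every_ms / dt)))
    snap_every = max(1, int(round(config.snapshot_every_ms / dt)))

    probe_flat = np.array([np.ravel_multi_index(p, geo.dims)
                           for p in config.probes], dtype=np.int64)
    n_rec = n_steps // rec_every + 1
    t_out = np.empty(n_rec)
    probe_out = np.empty((probe_flat.size, n_rec))
    snaps = []
    snap_t = []
    events = []
    was_active = False
    j = 0
    for n in range(n_steps + 1):
        if n % rec_every == 0 and j < n_rec:
            t_out[j] = sim.t_ms
            probe_out[:, j] = sim.v[probe_flat]
            j += 1
        if config.record_snapshots and n % snap_every == 0:
            snaps.append(sim.v.astype(np.float32).reshape(geo.dims))
            snap_t.append(sim.t_ms)
        if n == n_steps:
            break
        active = config.protocol.pulse_active(sim.t_ms)
        if active and not was_active:
            events.append({"kind": "stimulus_on", "t_ms": sim.t_ms})
        was_active = active
        vmax = sim.step()
        if not (vmax <= VMAX_ABORT_MV):
            bad = int(np.argmax(np.abs(sim.v)))
            raise RuntimeError(
                f"instability: |V| = {vmax:.1f} mV at flat site {bad} "
                f"(t = {sim.t_ms:.2f} ms)")
        if progress and sim.step_index % 1000 == 0:
            active_sites = int((sim.v > -40.0).sum())
            log.info("step %d t=%.1f ms max|V|=%.1f active=%d",
                     sim.step_index, sim.t_ms, vmax, active_sites)
    snapshots = (np.stack(snaps) if snaps
                 else np.empty((0,) + geo.dims, dtype=np.float32))
    return RunRecord(
        t_ms=t_out, probe_vm=probe_out, probes=list(config.probes),
        snapshot_t_ms=np.array(snap_t), snapshots=snapshots,
        final_v=sim.v.reshape(geo.dims).copy(), events=events,
        config=config.summary(), config_hash=config.content_hash(),
        seed=config.seed)
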