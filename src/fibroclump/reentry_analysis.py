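"""Event detection and sweep drivers: wave-distortion onset, transient-
pacing reentry, and stability diagrams over the clump radius / fibroblast
density plane.

Wave distortion (WD) is operationalized as the first *persistent* phase
singularity: the membrane-voltage movie is embedded as
phase = atan2(V(t) - Vbar, V(t - tau_d) - Vbar) with a 10 ms delay, the
topological charge is the winding number of the phase around each 2x2
plaquette, and a singularity that survives three consecutive snapshot
frames away from the electrode marks WD onset (wavefront corrugation is
usually identified visually; the singularity surrogate makes the event
testable).

Transient-pacing (TP) reentry is any supra-threshold activity after the
last paced wave has had time to clear the domain: last stimulus end plus
one full-domain traversal at the measured conduction velocity plus a
200 ms margin.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .clump_synthesis import (ClumpSpec, generate_clump, remodeling_map,
                              uniform_geometry)
from .tissue_solver import RunRecord, SimulationConfig, StimulusProtocol, run
from .wave_metrics import activation_times

log = logging.getLogger(__name__)

DELAY_MS = 10.0          # time-delay embedding
PERSIST_FRAMES = 3       # frames a singularity must survive
MATCH_RADIUS_SITES = 5.0  # frame-to-frame track matching
EDGE_MARGIN_SITES = 2    # ignore plaquettes hugging the no-flux walls


@dataclass
class WDResult:
    """Wave-distortion detection outcome for one run."""

    occurred: bool
    tau_prime_s: float | None = None
    track: list = field(default_factory=list)  # [(t_ms, y, x), ...]
    n_singularity_frames: int = 0


@dataclass
class EnsembleResult:
    """WD statistics over independent clump realizations."""

    radius_cm: float
    pf_percent: float
    outcomes: list
    tau_s: float | None
    tau_sd_s: float | None
    n_realizations: int
    n_occurred: int


@dataclass
class StabilityDiagram:
    """Reentry counts out of n realizations on the (R, p_f) grid."""

    r_grid_cm: np.ndarray
    pf_grid_percent: np.ndarray
    counts: np.ndarray  # (n_r, n_pf) int
    n_realizations: int
    protocol: dict


def pcl_to_frequency_hz(pcl_ms: float) -> float:
    """Pacing frequency (Hz) of a cycle length (ms)."""
    return 1000.0 / pcl_ms


# ---------------------------------------------------------------------------
# phase singularities
# ---------------------------------------------------------------------------
def phase_movie(snapshots: np.ndarray, delay_frames: int) -> np.ndarray:
    """Time-delay-embedded phase of a (n_t, ny, nx) voltage movie."""
    if snapshots.shape[0] <= delay_frames:
        raise ValueError("movie shorter than the embedding delay")
    vbar = snapshots.mean(axis=0)
    a = snapshots[delay_frames:] - vbar
    b = snapshots[:-delay_frames] - vbar
    return np.arctan2(a, b)


def _wrap(x: np.ndarray) -> np.ndarray:
    return (x + np.pi) % (2.0 * np.pi) - np.pi


def singularity_charges(phase: np.ndarray) -> np.ndarray:
    """Winding number of the phase around every 2x2 plaquette.

    Returns an (ny-1, nx-1) integer field with values in {-1, 0, +1}.
    """
    p00 = phase[:-1, :-1]
    p01 = phase[:-1, 1:]
    p11 = phase[1:, 1:]
    p10 = phase[1:, :-1]
    winding = (_wrap(p01 - p00) + _wrap(p11 - p01)
               + _wrap(p10 - p11) + _wrap(p00 - p10))
    return np.rint(winding / (2.0 * np.pi)).astype(np.int8)


def find_singularities(phase: np.ndarray,
                       edge_margin: int = EDGE_MARGIN_SITES) -> list:
    """(y, x, charge) of every nonzero plaquette away from the walls."""
    q = singularity_charges(phase)
    if edge_margin > 0:
        q[:edge_margin, :] = 0
        q[-edge_margin:, :] = 0
        q[:, :edge_margin] = 0
        q[:, -edge_margin:] = 0
    ys, xs = np.nonzero(q)
    return [(int(y), int(x), int(q[y, x])) for y, x in zip(ys, xs)]


def _track_persistent(per_frame: list, times_ms: np.ndarray,
                      persist: int, radius: float):
    """First chain of singularities lasting >= persist consecutive frames.

    Greedy nearest-neighbour matching; returns (t_onset_ms, track) or None.
    """
    active: list[dict] = []
    for fi, sings in enumerate(per_frame):
        t = times_ms[fi]
        unmatched = list(sings)
        nxt = []
        for tr in active:
            y0, x0 = tr["pos"]
            best, best_d = None, radius
            for s in unmatched:
                d = np.hypot(s[0] - y0, s[1] - x0)
                if d <= best_d:
                    best, best_d = s, d
            if best is not None:
                unmatched.remove(best)
                tr["pos"] = (best[0], best[1])
                tr["hist"].append((t, best[0], best[1]))
                nxt.append(tr)
                if len(tr["hist"]) >= persist:
                    return tr["hist"][0][0], tr["hist"]
        for s in unmatched:
            nxt.append({"pos": (s[0], s[1]), "hist": [(t, s[0], s[1])]})
        active = nxt
    return None


def detect_wave_distortion(rec: RunRecord, delay_ms: float = DELAY_MS,
                           persist_frames: int = PERSIST_FRAMES,
                           exclude_rows: int | None = None,
                           match_radius: float = MATCH_RADIUS_SITES
                           ) -> WDResult:
    """Onset of wave distortion in a persistently paced run.

    Requires snapshots at <= 20 ms cadence; onset tau' is the first time a
    phase singularity persists ``persist_frames`` consecutive frames
    outside the electrode region (rows below ``exclude_rows``).
    """
    if rec.snapshots.shape[0] < persist_frames + 2:
        raise ValueError("run has too few snapshots for WD detection")
    cadence = float(np.median(np.diff(rec.snapshot_t_ms)))
    if cadence > 20.0 + 1e-9:
        raise ValueError(
            f"snapshot cadence {cadence:.1f} ms too coarse (need <= 20 ms)")
    if exclude_rows is None:
        exclude_rows = int(rec.config["protocol"]["electrode_rows"]) + 3
    delay_frames = max(1, int(round(delay_ms / cadence)))
    movie = np.asarray(rec.snapshots, float)
    if movie.ndim == 4:  # 3D: per-slice detection, earliest onset wins
        best = WDResult(occurred=False)
        for z in range(movie.shape[1]):
            sub = RunRecord(**{**rec.__dict__})
            sub.snapshots = movie[:, z]
            r = detect_wave_distortion(sub, delay_ms, persist_frames,
                                       exclude_rows, match_radius)
            if r.occurred and (not best.occurred
                               or r.tau_prime_s < best.tau_prime_s):
                best = r
        return best
    phases = phase_movie(movie, delay_frames)
    times = rec.snapshot_t_ms[delay_frames:]
    per_frame = []
    nsing = 0
    for k in range(phases.shape[0]):
        sings = [s for s in find_singularities(phases[k])
                 if s[0] >= exclude_rows]
        nsing += len(sings)
        per_frame.append(sings)
    hit = _track_persistent(per_frame, times, persist_frames, match_radius)
    if hit is None:
        return WDResult(occurred=False, n_singularity_frames=nsing)
    t_onset, track = hit
    return WDResult(occurred=True, tau_prime_s=float(t_onset) / 1000.0,
                    track=track, n_singularity_frames=nsing)


# ---------------------------------------------------------------------------
# transient-pacing reentry
# ---------------------------------------------------------------------------
def detect_reentry_tp(rec: RunRecord, cv_cm_s: float | None = None,
                      margin_ms: float = 200.0,
                      min_observation_ms: float = 2000.0,
                      threshold_mv: float = -40.0) -> bool:
    """True iff activity persists after the last paced wave has cleared.

    Clearance time = last stimulus end + domain traversal at the measured
    conduction velocity + ``margin_ms``.  The observation window after the
    last pulse must reach ``min_observation_ms``.
    """
    proto = rec.config["protocol"]
    if proto["n_pulses"] is None:
        raise ValueError("reentry detection requires a TP (finite) protocol")
    duration = float(rec.config["duration_ms"])
    last_end = (proto["n_pulses"] - 1) * proto["pcl_ms"] + proto["pulse_ms"]
    if duration < last_end + min_observation_ms:
        raise ValueError(
            f"duration {duration:.0f} ms leaves less than "
            f"{min_observation_ms:.0f} ms of observation after pacing")
    dims = rec.dims
    ny = dims[-2]
    if cv_cm_s is None:
        cv_cm_s = _measured_cv(rec)
    traversal_ms = ny * rec.dx_cm / cv_cm_s * 1000.0
    clear_ms = last_end + traversal_ms + margin_ms
    if rec.snapshots.shape[0]:
        late = rec.snapshot_t_ms > clear_ms
        if late.any() and (rec.snapshots[late] > threshold_mv).any():
            return True
    late = rec.t_ms > clear_ms
    if late.any() and (rec.probe_vm[:, late] > threshold_mv).any():
        return True
    if duration > clear_ms and (rec.final_v > threshold_mv).any():
        return True
    return False


def _measured_cv(rec: RunRecord, fallback_cm_s: float = 65.0) -> float:
    """Plane-wave speed of the first paced wave between the two probe rows;
    falls back to the control value if the probes do not both activate."""
    try:
        probes = np.asarray(rec.probes)
        ys = probes[:, -2]
        lo = int(np.argmin(ys))
        hi = int(np.argmax(ys))
        if ys[hi] == ys[lo]:
            return fallback_cm_s
        first_pcl = float(rec.config["protocol"]["pcl_ms"])
        amap = activation_times(rec.t_ms, rec.probe_vm,
                                window_ms=(0.0, min(first_pcl * 2,
                                                    rec.t_ms[-1])))
        ta, tb = amap.times_ms[lo], amap.times_ms[hi]
        if not (np.isfinite(ta) and np.isfinite(tb)) or tb <= ta:
            return fallback_cm_s
        dist_cm = (ys[hi] - ys[lo]) * rec.dx_cm
        return float(dist_cm / (tb - ta) * 1000.0)
    except Exception:  # pragma: no cover - defensive fallback
        return fallback_cm_s


# ---------------------------------------------------------------------------
# spiral initiation (cross-field S1-S2)
# ---------------------------------------------------------------------------
def cross_field_spiral_run(n: int = 160, s2_ms: float = 180.0,
                           duration_ms: float = 2000.0,
                           s2_amplitude: float = -40.0,
                           myocyte_params=None,
                           record_snapshots: bool = True,
                           snapshot_every_ms: float = 20.0,
                           record_every_ms: float = 1.0) -> RunRecord:
    """Initiate a spiral in a homogeneous n x n myocyte sheet.

    S1 is one ordinary line pulse from the lower boundary; S2 stimulates
    the left half of the domain at ``s2_ms``, timed so that its free end
    lands on the repolarization tail of S1 and curls into a rotor.  Used
    to measure the spiral frequency of a parameter set.
    """
    geo = uniform_geometry((n, n))
    proto = StimulusProtocol(mode="TP", pcl_ms=max(duration_ms, 1000.0),
                             n_pulses=1)
    kwargs = {} if myocyte_params is None else {"myocyte_params":
                                                myocyte_params}
    cfg = SimulationConfig(
        geometry=geo, protocol=proto, duration_ms=duration_ms,
        record_snapshots=record_snapshots,
        snapshot_every_ms=snapshot_every_ms,
        record_every_ms=record_every_ms,
        extra_stimuli=[{"t0_ms": s2_ms, "duration_ms": 3.0,
                        "amplitude": s2_amplitude,
                        "region": (0, n, 0, n // 2)}],
        **kwargs)
    return run(cfg)


def seeded_spiral_run(n: int = 160, duration_ms: float = 2500.0,
                      pitch_cm: float = 5.0, seed_pcl_ms: float = 250.0,
                      myocyte_params=None, record_snapshots: bool = True,
                      snapshot_every_ms: float = 20.0,
                      record_every_ms: float = 1.0) -> RunRecord:
    """Rotor from a phase-distributed initial condition.

    Every site starts from the single-cell state at cycle phase
    chi(x, y) = theta - 2 pi r / pitch (an Archimedean spiral around the
    domain centre), sampled from one steady paced beat.  The rotor forms
    within a rotation or two and relaxes to its own frequency; no
    initiation stimuli or extra domain space are needed.
    """
    from .cell_models import MyocyteParams, paced_cycle_states

    params = myocyte_params or MyocyteParams()
    times, vs, ys = paced_cycle_states(params, pcl_ms=seed_pcl_ms)
    nbank = times.size
    geo = uniform_geometry((n, n))
    c = (n - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(n) - c, np.arange(n) - c, indexing="ij")
    theta = np.arctan2(yy, xx)
    r_cm = geo.dx_cm * np.hypot(yy, xx)
    chi = (theta - 2.0 * np.pi * r_cm / pitch_cm) / (2.0 * np.pi)
    idx = np.mod(np.rint(chi * nbank).astype(int), nbank)
    v0 = vs[idx]
    y0 = ys[idx.ravel()]
    proto = StimulusProtocol(mode="TP", pcl_ms=max(duration_ms, 1000.0),
                             n_pulses=0)
    cfg = SimulationConfig(
        geometry=geo, protocol=proto, duration_ms=duration_ms,
        record_snapshots=record_snapshots,
        snapshot_every_ms=snapshot_every_ms,
        record_every_ms=record_every_ms,
        initial_state={"v": v0, "y": y0}, myocyte_params=params)
    return run(cfg)


# ---------------------------------------------------------------------------
# ensemble drivers
# ---------------------------------------------------------------------------
def _clump_run(dims, radius_cm, pf_percent, seed, protocol, duration_ms,
               myocyte_params=None, gna_scale=None, annulus_radius_cm=None,
               snapshot_every_ms=10.0, dx_cm=0.02):
    spec = ClumpSpec(radius_cm=radius_cm, pf_percent=pf_percent, seed=seed)
    geo = generate_clump(dims, spec, dx_cm=dx_cm)
    if gna_scale is not None:
        geo = remodeling_map(geo, spec, annulus_radius_cm or radius_cm * 1.4,
                             gna_scale)
    kwargs = {} if myocyte_params is None else {"myocyte_params":
                                                myocyte_params}
    cfg = SimulationConfig(geometry=geo, protocol=protocol,
                           duration_ms=duration_ms,
                           snapshot_every_ms=snapshot_every_ms,
                           record_snapshots=True, seed=seed, **kwargs)
    return run(cfg)


def mean_wd_time(dims, radius_cm: float, pf_percent: float, n: int = 8,
                 base_seed: int = 0, pcl_ms: float = 152.0,
                 duration_ms: float = 18_000.0, myocyte_params=None,
                 gna_scale=None, annulus_radius_cm=None,
                 snapshot_every_ms: float = 10.0, dx_cm: float = 0.02
                 ) -> EnsembleResult:
    """Mean WD onset time tau over ``n`` clump realizations (PP pacing).

    Seeds run base_seed .. base_seed + n - 1; tau averages tau' over the
    realizations where WD occurred (None if it never did).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    protocol = StimulusProtocol(mode="PP", pcl_ms=pcl_ms)
    outcomes = []
    for k in range(n):
        rec = _clump_run(dims, radius_cm, pf_percent, base_seed + k,
                         protocol, duration_ms, myocyte_params, gna_scale,
                         annulus_radius_cm, snapshot_every_ms, dx_cm)
        wd = detect_wave_distortion(rec)
        outcomes.append({"seed": base_seed + k, "occurred": wd.occurred,
                         "tau_prime_s": wd.tau_prime_s})
        log.info("WD seed %d: occurred=%s tau'=%s", base_seed + k,
                 wd.occurred, wd.tau_prime_s)
    taus = [o["tau_prime_s"] for o in outcomes if o["occurred"]]
    return EnsembleResult(
        radius_cm=radius_cm, pf_percent=pf_percent, outcomes=outcomes,
        tau_s=float(np.mean(taus)) if taus else None,
        tau_sd_s=float(np.std(taus, ddof=1)) if len(taus) > 1 else None,
        n_realizations=n, n_occurred=len(taus))


def stability_diagram(dims, r_grid_cm, pf_grid_percent, n: int = 10,
                      base_seed: int = 0, pcl_ms: float = 152.0,
                      n_pulses: int = 20, duration_ms: float | None = None,
                      myocyte_params=None, min_observation_ms: float = 2000.0,
                      snapshot_every_ms: float = 20.0, dx_cm: float = 0.02,
                      cache_dir: str | Path | None = None) -> StabilityDiagram:
    """Reentry count out of ``n`` TP realizations for every (R, p_f) cell.

    Per-run results are cached by config hash under ``cache_dir`` so an
    interrupted sweep resumes; individual run failures count as no-reentry
    and are logged, not fatal.
    """
    r_grid = np.atleast_1d(np.asarray(r_grid_cm, float))
    pf_grid = np.atleast_1d(np.asarray(pf_grid_percent, float))
    if r_grid.size == 0 or pf_grid.size == 0:
        raise ValueError("grids must be non-empty")
    protocol = StimulusProtocol(mode="TP", pcl_ms=pcl_ms, n_pulses=n_pulses)
    if duration_ms is None:
        duration_ms = (n_pulses - 1) * pcl_ms + 3.0 + min_observation_ms
    cache = {}
    cache_path = None
    if cache_dir is not None:
        cache_path = Path(cache_dir) / "tp_sweep_cache.json"
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        if cache_path.exists():
            cache = json.loads(cache_path.read_text())
    counts = np.zeros((r_grid.size, pf_grid.size), dtype=int)
    for i, r_cm in enumerate(r_grid):
        for j, pf in enumerate(pf_grid):
            for k in range(n):
                seed = base_seed + k
                key = f"R{r_cm:g}_pf{pf:g}_seed{seed}_pcl{pcl_ms:g}" \
                      f"_np{n_pulses}_dims{list(dims)}_dur{duration_ms:g}"
                if key in cache:
                    counts[i, j] += bool(cache[key])
                    continue
                try:
                    rec = _clump_run(dims, r_cm, pf, seed, protocol,
                                     duration_ms, myocyte_params,
                                     snapshot_every_ms=snapshot_every_ms,
                                     dx_cm=dx_cm)
                    hit = detect_reentry_tp(
                        rec, min_observation_ms=min_observation_ms)
                except Exception as exc:
                    log.warning("run failed at R=%g pf=%g seed=%d: %s",
                                r_cm, pf, seed, exc)
                    hit = False
                cache[key] = bool(hit)
                if cache_path is not None:
                    cache_path.write_text(json.dumps(cache, indent=0))
                counts[i, j] += hit
    return StabilityDiagram(
        r_grid_cm=r_grid, pf_grid_percent=pf_grid, counts=counts,
        n_realizations=n,
        protocol={"mode": "TP", "pcl_ms": pcl_ms, "n_pulses": n_pulses})
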