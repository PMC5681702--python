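"""Quantitative readouts from runs: activation, conduction velocity, APD,
wavelength, and the averaged-spectrum dominant frequency.

Conventions: the activation threshold is an upstroke crossing of -40 mV
(linearly interpolated between samples); APD is measured at 90%
repolarization of the per-beat amplitude unless stated otherwise; the
dominant frequency is the peak above 0.5 Hz of the Hann-windowed
periodogram averaged over four probe time series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

UPSTROKE_MV = -40.0


@dataclass
class ActivationMap:
    """First upstroke-crossing time per trace/site; NaN = never activated."""

    times_ms: np.ndarray
    threshold_mv: float
    window_ms: tuple[float, float]

    def activated(self) -> np.ndarray:
        return np.isfinite(self.times_ms)


@dataclass
class SpectralResult:
    """Averaged power spectrum and its dominant peak."""

    freqs_hz: np.ndarray
    power: np.ndarray
    peak_hz: float


def _first_crossing(t: np.ndarray, v: np.ndarray, thr: float) -> float:
    up = np.flatnonzero((v[:-1] < thr) & (v[1:] >= thr))
    if up.size == 0:
        return np.nan
    i = up[0]
    frac = (thr - v[i]) / (v[i + 1] - v[i])
    return t[i] + frac * (t[i + 1] - t[i])


def activation_times(t_ms: np.ndarray, traces: np.ndarray,
                     threshold_mv: float = UPSTROKE_MV,
                     window_ms: tuple[float, float] | None = None
                     ) -> ActivationMap:
    """First upward threshold crossing for each row of ``traces``.

    ``traces`` has shape (..., n_samples) with the last axis aligned to
    ``t_ms``.  Sites that never cross are marked NaN, not errors.
    """
    t_ms = np.asarray(t_ms, float)
    traces = np.asarray(traces, float)
    if window_ms is None:
        window_ms = (float(t_ms[0]), float(t_ms[-1]))
    sel = (t_ms >= window_ms[0]) & (t_ms <= window_ms[1])
    if sel.sum() < 2:
        raise ValueError("window contains fewer than two samples")
    tw = t_ms[sel]
    vw = traces[..., sel]
    flat = vw.reshape(-1, tw.size)
    out = np.array([_first_crossing(tw, row, threshold_mv) for row in flat])
    return ActivationMap(times_ms=out.reshape(vw.shape[:-1]),
                         threshold_mv=threshold_mv, window_ms=window_ms)


def conduction_velocity(amap: ActivationMap, idx_a: int, idx_b: int,
                        separation_cm: float) -> float:
    """Front speed (cm/s) between two activated probes a known distance
    apart along the propagation axis."""
    ta = amap.times_ms.ravel()[idx_a]
    tb = amap.times_ms.ravel()[idx_b]
    for name, tt in (("a", ta), ("b", tb)):
        if not np.isfinite(tt):
            raise ValueError(f"probe {name} never activated")
    if separation_cm < 1.0:
        raise ValueError("probes must be separated by at least 1 cm")
    dt = abs(tb - ta)
    if dt == 0:
        raise ValueError("identical activation times (infinite velocity)")
    return separation_cm / dt * 1000.0


def apd(t_ms: np.ndarray, v: np.ndarray, repolarization_level: float = 90.0,
        threshold_mv: float = UPSTROKE_MV) -> float:
    """Action-potential duration (ms) of the last complete beat.

    Measured from the upstroke threshold crossing to recovery of
    ``repolarization_level`` percent of the beat amplitude (peak minus the
    pre-upstroke baseline).
    """
    t_ms = np.asarray(t_ms, float)
    v = np.asarray(v, float)
    ups = np.flatnonzero((v[:-1] < threshold_mv) & (v[1:] >= threshold_mv))
    if ups.size == 0:
        raise ValueError("no action potential found in trace")
    frac = repolarization_level / 100.0
    # walk beats from the last backwards until one has fully repolarized
    for b in range(ups.size - 1, -1, -1):
        i0 = ups[b]
        i1 = ups[b + 1] if b + 1 < ups.size else v.size - 1
        baseline = v[max(0, i0 - 1)]
        seg = v[i0:i1 + 1]
        peak = seg.max()
        level = peak - frac * (peak - baseline)
        below = np.flatnonzero(seg[np.argmax(seg):] <= level)
        if below.size == 0:
            continue  # beat not fully repolarized inside the trace
        j = np.argmax(seg) + below[0] + i0
        t_up = _first_crossing(t_ms[max(0, i0 - 1):i1 + 1],
                               v[max(0, i0 - 1):i1 + 1], threshold_mv)
        # interpolate the downward crossing of the repolarization level
        tj = t_ms[j - 1] + (level - v[j - 1]) / (v[j] - v[j - 1]) \
            * (t_ms[j] - t_ms[j - 1]) if v[j] != v[j - 1] else t_ms[j]
        return float(tj - t_up)
    raise ValueError("no fully repolarized action potential in trace")


def wavelength(t_ms: np.ndarray, cable_traces: np.ndarray, dx_cm: float,
               repolarization_level: float = 90.0,
               landmark_fraction: float = 0.8) -> dict:
    """Wavelength of a solitary wave in a cable, by two estimators.

    ``cable_traces`` is (n_sites, n_samples) ordered along the cable.
    Estimator ``extent_cm``: at the instant the wavefront reaches
    ``landmark_fraction`` of the cable, the contiguous spatial extent of
    sites still above their repolarization level.  Estimator
    ``cv_apd_cm``: conduction velocity times APD at the same level.
    """
    n_sites = cable_traces.shape[0]
    amap = activation_times(t_ms, cable_traces)
    at = amap.times_ms
    landmark = int(landmark_fraction * n_sites)
    if not np.isfinite(at[landmark]):
        raise ValueError(
            "wavefront never reaches the landmark; use a longer cable "
            "or a shorter landmark fraction")
    t_mark = at[landmark]
    k = int(np.searchsorted(t_ms, t_mark))
    k = min(k, t_ms.size - 1)

    frac = repolarization_level / 100.0
    baseline = cable_traces[:, 0]
    peaks = cable_traces.max(axis=1)
    levels = peaks - frac * (peaks - baseline)
    above = cable_traces[:, k] > levels
    # contiguous excited segment that contains the wavefront
    if not above.any():
        raise ValueError("no excited segment at the landmark instant")
    runs = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8),
                                                  [0]))))
    starts, ends = runs[::2], runs[1::2]
    seg = np.argmax(ends - starts)  # longest contiguous run
    extent_cm = float((ends[seg] - starts[seg]) * dx_cm)
    if ends[seg] >= n_sites and starts[seg] <= 0:
        raise ValueError("wave fills the whole cable; use a longer cable")

    # cross-check: CV x APD (APD probed at quarter length, which has
    # activated early enough to repolarize fully within the run)
    ia, ib = int(0.15 * n_sites), int(0.55 * n_sites)
    cv = conduction_velocity(amap, ia, ib, (ib - ia) * dx_cm)
    apd_ms = apd(t_ms, cable_traces[n_sites // 4],
                 repolarization_level=repolarization_level)
    cv_apd_cm = cv * apd_ms / 1000.0
    return {"extent_cm": extent_cm, "cv_apd_cm": cv_apd_cm,
            "cv_cm_s": cv, "apd_ms": apd_ms, "t_mark_ms": float(t_mark)}


def dominant_frequency(t_ms: np.ndarray, traces: np.ndarray,
                       window_ms: tuple[float, float] | None = None,
                       min_hz: float = 0.5,
                       resolution_hz: float = 0.25) -> SpectralResult:
    """Dominant frequency of the probe set: per-trace Hann periodogram,
    arithmetic mean across probes, argmax above ``min_hz``.

    The frequency grid is refined (zero-padding) to at least
    ``resolution_hz`` spacing.  Quiescent traces raise an error.
    """
    t_ms = np.asarray(t_ms, float)
    traces = np.atleast_2d(np.asarray(traces, float))
    if window_ms is not None:
        sel = (t_ms >= window_ms[0]) & (t_ms <= window_ms[1])
        t_ms, traces = t_ms[sel], traces[:, sel]
    if t_ms.size < 16:
        raise ValueError("window too short for a spectrum")
    if float(np.ptp(traces)) < 1.0:  # mV
        raise ValueError("all probe traces quiescent; no dominant peak")
    fs_hz = 1000.0 / float(t_ms[1] - t_ms[0])
    nfft = int(2 ** np.ceil(np.log2(max(t_ms.size, fs_hz / resolution_hz))))
    freqs, p = signal.periodogram(traces - traces.mean(axis=1, keepdims=True),
                                  fs=fs_hz, window="hann", nfft=nfft, axis=1)
    mean_p = p.mean(axis=0)
    valid = freqs >= min_hz
    if not valid.any() or mean_p[valid].max() <= 0:
        raise ValueError("no spectral peak above the frequency floor")
    peak = freqs[valid][np.argmax(mean_p[valid])]
    return SpectralResult(freqs_hz=freqs, power=mean_p, peak_hz=float(peak))
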