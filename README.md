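# fibroclump

Monodomain simulations of reentry induced by localized fibroblast clumps
in human-ventricular tissue.

Regional fibrosis — a clump of electrically passive fibroblasts embedded
in working myocardium — can turn a periodically paced heart into a
source of reentrant (spiral/scroll-wave) activity. This package
implements the full in-silico study of that mechanism for researchers in
computational cardiac electrophysiology: heterogeneous myocyte–fibroblast
lattices, high- and low-frequency line-pacing protocols, and the
quantitative readouts (conduction velocity, APD, wavelength, dominant
frequency, wave-distortion onset time, reentry incidence over the
R–p_f plane) in 2D and 3D.

## Model

Each lattice site holds either a myocyte or a fibroblast
(probability p_f/100 inside a clump of radius R). The membrane potential
evolves as

    dV(i,j)/dt = -(1-η) I_ion/C_m - η I_f/C_f + Σ_<αβ> G_αβ (V(i+α,j+β) - V(i,j))

with η = 1 at fibroblast sites, and per-edge weights G_αβ: D_mm/δx² for
myocyte→myocyte (D_mm = 0.0012 cm²/ms), D_mm/10/δx² for
fibroblast→fibroblast, and G_gap/C (G_gap = 8 nS) across
myocyte–fibroblast edges. The myocyte is the O'Hara–Rudy human
ventricular cell (endo) with the Ten Tusscher–Panfilov fast sodium
current (sets CV to 65 cm/s) and doubled G_Kr (shortens the ~18 cm
wavelength to tractable size) — the "control set". The fibroblast is a
passive membrane: C_f = 6.3 pF, E_f = -30 mV, G_f = 1 nS below
-20 mV / 2 nS above. Integration: forward Euler (voltage,
concentrations) + exponential gate relaxation, δx = 0.02 cm,
δt = 0.02 ms, no-flux boundaries. See `docs/methods.md` for the full
account.

## Worked example

Measure the conduction velocity of a paced wave on a control-parameter
cable:

```python
import numpy as np
from fibroclump import clump_synthesis as cs, tissue_solver as ts
from fibroclump import wave_metrics as wm

geo = cs.uniform_geometry((512, 1))                      # 10.24 cm cable
proto = ts.StimulusProtocol(mode="TP", pcl_ms=10_000.0, n_pulses=1)
cfg = ts.SimulationConfig(geometry=geo, protocol=proto, duration_ms=200.0,
                          probes=[(100, 0), (400, 0)])   # 2 cm and 8 cm
rec = ts.run(cfg)
amap = wm.activation_times(rec.t_ms, rec.probe_vm)
print(f"activation: {amap.times_ms[0]:.1f} ms at 2 cm, "
      f"{amap.times_ms[1]:.1f} ms at 8 cm")
print(f"CV = {wm.conduction_velocity(amap, 0, 1, 6.0):.1f} cm/s")
```

prints

```
activation: 31.3 ms at 2 cm, 124.4 ms at 8 cm
CV = 64.4 cm/s
```

i.e. the stimulus at the cable end needs ~31 ms to reach the 2 cm probe
and the front then covers the 6 cm between the probes in ~93 ms — a
plane-wave speed of 65 cm/s, the physiological human value the modified
sodium current is chosen to reproduce.

A clumped geometry and a pacing study are one call each:

```python
spec = cs.ClumpSpec(radius_cm=1.0, pf_percent=30.0, seed=0)
geo = cs.generate_clump((512, 512), spec)
print(geo.summary())   # {'n_fibroblasts': 2302, 'fibroblast_fraction': 0.0088, ...}
```

The numbered scripts under `analysis/` run the study stages at desk
scale and write tables to `results/`: single-cell baselines
(`01_single_cell.py`), cable CV/wavelength (`02_cable_metrics.py`),
clump statistics and percolation (`03_clump_statistics.py`), rotor
frequency (`04_spiral_frequency.py`), wave-distortion onset under
excitability remodelling (`05_wd_onset.py`), and transient-pacing
reentry at high vs low pacing rates (`06_tp_reentry.py`). A
`fibroclump` command-line tool exposes the same stages
(`fibroclump run|generate|measure|wd-time|reentry|sweep`).

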