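"""Single-cell baselines: resting potentials, action potentials, and the
effect of gap-coupling a fibroblast onto a myocyte.

Writes results/single_cell.csv and prints what it finds.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fibroclump import cell_models as cm
from fibroclump import wave_metrics as wm

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

rows = []

vf_rest, _ = cm.single_cell_steady_state("fibroblast", v0=-50.0)
print(f"fibroblast rest from -50 mV after 5 s: {vf_rest:.4f} mV")
rows.append({"quantity": "fibroblast_rest_mV", "value": vf_rest})

for gkr, label in ((2.0, "control (gKr x2)"), (1.0, "gKr x1")):
    params = cm.MyocyteParams(gkr_scale=gkr)
    state, converged = cm.single_cell_steady_state("myocyte", params=params,
                                                   duration_ms=50_000.0)
    t, v, _ = cm.simulate_myocyte(params=params, duration_ms=3000.0,
                                  pcl_ms=1000.0, state=state)
    apd90 = wm.apd(t, v)
    print(f"{label}: rest {state.vm:.2f} mV, APD90 {apd90:.1f} ms "
          f"(relaxation converged: {converged})")
    rows.append({"quantity": f"myocyte_rest_mV_gkr{gkr:g}",
                 "value": state.vm})
    rows.append({"quantity": f"apd90_ms_gkr{gkr:g}", "value": apd90})

# isolated vs fibroblast-coupled myocyte (PCL 1000 ms, last paced beat)
params = cm.MyocyteParams()
state, _ = cm.single_cell_steady_state("myocyte", params=params,
                                       duration_ms=50_000.0)
t, vi, _ = cm.simulate_myocyte(params=params, duration_ms=3000.0,
                               pcl_ms=1000.0, state=state.copy())
t2, vmc, vfc = cm.simulate_pair(params=params, duration_ms=3000.0,
                                pcl_ms=1000.0, state=state.copy())
apd_iso = wm.apd(t, vi)
apd_cpl = wm.apd(t2, vmc)
print(f"APD90 isolated {apd_iso:.1f} ms vs fibroblast-coupled "
      f"{apd_cpl:.1f} ms (delta {apd_cpl - apd_iso:+.1f} ms)")
print(f"coupled resting Vm {vmc[990]:.2f} mV vs isolated {vi[990]:.2f} mV; "
      f"coupled fibroblast rests at {vfc[990]:.2f} mV")
rows += [{"quantity": "apd90_isolated_ms", "value": apd_iso},
         {"quantity": "apd90_coupled_ms", "value": apd_cpl},
         {"quantity": "rest_isolated_mV", "value": vi[990]},
         {"quantity": "rest_coupled_mV", "value": vmc[990]},
         {"quantity": "rest_coupled_fibroblast_mV", "value": vfc[990]}]

pd.DataFrame(rows).to_csv(OUT / "single_cell.csv", index=False)
print(f"wrote {OUT / 'single_cell.csv'}")
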