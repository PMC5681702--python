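"""Shared fixtures: expensive simulation runs are session-scoped so the
suite pays for each physical experiment once."""

from __future__ import annotations

import numpy as np
import pytest

from fibroclump import clump_synthesis as cs
from fibroclump import tissue_solver as ts
from fibroclump.cell_models import MyocyteParams, single_cell_steady_state


@pytest.fixture(scope="session")
def myocyte_rest():
    """Control-parameter quiescent myocyte (shared relaxation)."""
    vm, y = ts.resting_myocyte(MyocyteParams())
    return vm, y


@pytest.fixture(scope="session")
def control_cable_record():
    """Single paced wave on a 512-site control cable (10.24 cm), with a
    voltage trace at every fourth site."""
    geo = cs.uniform_geometry((512, 1))
    proto = ts.StimulusProtocol(mode="TP", pcl_ms=1000.0, n_pulses=1)
    cfg = ts.SimulationConfig(geometry=geo, protocol=proto,
                              duration_ms=200.0,
                              probes=[(i, 0) for i in range(0, 512, 4)])
    return ts.run(cfg)


@pytest.fixture(scope="session")
def paced_cable_record():
    """Short cable paced 1:1 at PCL 250 ms for spectral checks."""
    geo = cs.uniform_geometry((64, 1))
    proto = ts.StimulusProtocol(mode="PP", pcl_ms=250.0)
    cfg = ts.SimulationConfig(geometry=geo, protocol=proto,
                              duration_ms=2500.0,
                              probes=[(20, 0), (30, 0), (40, 0), (50, 0)])
    return ts.run(cfg)
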