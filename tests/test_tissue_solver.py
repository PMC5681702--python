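"""Lattice solver: reduction to single-cell dynamics, symmetry, stimulus
timing, stability guards, determinism, and refractoriness."""

import numpy as np
import pytest

from fibroclump import _ord
from fibroclump import cell_models as cm
from fibroclump import clump_synthesis as cs
from fibroclump import tissue_solver as ts
from fibroclump import wave_metrics as wm


def single_pulse(pcl=1000.0):
    return ts.StimulusProtocol(mode="TP", pcl_ms=pcl, n_pulses=1)


class TestSingleCellEquivalence:
    def test_1x1_lattice_matches_single_cell(self, myocyte_rest):
        """On a 1x1 domain the lattice update reduces exactly to the
        single-cell equation (coupling sum empty)."""
        vm, y = myocyte_rest
        geo = cs.uniform_geometry((1, 1))
        proto = ts.StimulusProtocol(mode="TP", pcl_ms=1000.0, n_pulses=1,
                                    amplitude=-80.0, pulse_ms=0.5)
        cfg = ts.SimulationConfig(geometry=geo, protocol=proto,
                                  duration_ms=20.0, record_every_ms=0.02,
                                  probes=[(0, 0)])
        rec = ts.run(cfg)
        t, v, _ = cm.simulate_myocyte(duration_ms=20.0, pcl_ms=1000.0,
                                      stim_amp=-80.0, stim_ms=0.5,
                                      state=cm.MyocyteState(vm, y.copy()),
                                      record_every_ms=0.02)
        n = min(v.size, rec.probe_vm.shape[1])
        assert np.max(np.abs(rec.probe_vm[0, :n] - v[:n])) < 1e-12

    def test_1x2_pair_matches_hand_written_odes(self, myocyte_rest):
        """A myocyte-fibroblast edge integrates identically to the
        explicitly written two-ODE system with G_gap/C weights."""
        vm, y = myocyte_rest
        eta = np.array([[0], [1]], np.uint8)
        geo = cs.TissueGeometry((2, 1), cs.DX_CM, eta, np.ones((2, 1)))
        proto = ts.StimulusProtocol(mode="TP", pcl_ms=1000.0, n_pulses=1,
                                    electrode_rows=1, amplitude=-80.0,
                                    pulse_ms=0.5)
        cfg = ts.SimulationConfig(geometry=geo, protocol=proto,
                                  duration_ms=400.0, record_every_ms=0.02,
                                  probes=[(0, 0), (1, 0)])
        rec = ts.run(cfg)
        t, vmc, vfc = cm.simulate_pair(
            duration_ms=400.0, pcl_ms=1000.0, stim_amp=-80.0, stim_ms=0.5,
            state=cm.MyocyteState(vm, y.copy()), vf0=-30.0,
            record_every_ms=0.02)
        n = min(vmc.size, rec.probe_vm.shape[1])
        assert np.max(np.abs(rec.probe_vm[0, :n] - vmc[:n])) < 1e-9
        assert np.max(np.abs(rec.probe_vm[1, :n] - vfc[:n])) < 1e-9


class TestSymmetryAndConservation:
    def test_resting_sheet_stays_uniform(self):
        geo = cs.uniform_geometry((16, 16))
        proto = ts.StimulusProtocol(mode="TP", pcl_ms=1000.0, n_pulses=0)
        cfg = ts.SimulationConfig(geometry=geo, protocol=proto,
                                  duration_ms=10.0)
        rec = ts.run(cfg)
        assert np.ptp(rec.final_v) < 1e-9

    def test_plane_wave_column_symmetry(self):
        """p_f = 0 with a full-width line stimulus: every column stays
        identical for the whole run (translational symmetry)."""
        geo = cs.uniform_geometry((64, 16))
        cfg = ts.SimulationConfig(geometry=geo, protocol=single_pulse(),
                                  duration_ms=150.0, record_snapshots=True,
                                  snapshot_every_ms=10.0)
        rec = ts.run(cfg)
        for snap in rec.snapshots:
            spread = np.ptp(snap, axis=1)  # across columns
            assert float(spread.max()) < 1e-9
        assert rec.final_v.max() > -80.0  # the wave actually ran

    def test_no_flux_coupling_sums_to_zero(self):
        """Discrete divergence theorem: on a homogeneous sheet the coupling
        term summed over all sites vanishes for any voltage field."""
        geo = cs.uniform_geometry((24, 24))
        cf = cs.build_coupling(geo)
        rng = np.random.default_rng(4)
        v = rng.uniform(-90.0, 40.0, geo.n_sites)
        lap = np.sum(cf.weights * (v[cf.nbr] - v[:, None]), axis=1)
        assert abs(lap.sum()) < 1e-9 * np.abs(lap).sum()


class Test3D:
    def test_3d_plane_wave_symmetry_and_bound(self, myocyte_rest):
        """A full-width line stimulus in a thin slab propagates as a plane
        wave invariant along both transverse axes; the 3D stability bound
        (6-neighbour lattice) is enforced."""
        geo = cs.uniform_geometry((4, 32, 8))
        cfg = ts.SimulationConfig(geometry=geo, protocol=single_pulse(),
                                  duration_ms=80.0, record_snapshots=True,
                                  snapshot_every_ms=20.0)
        rec = ts.run(cfg)
        final = rec.final_v
        assert final.max() > -40.0  # the wave is under way
        assert float(np.ptp(final, axis=0).max()) < 1e-9  # z-invariant
        assert float(np.ptp(final, axis=2).max()) < 1e-9  # x-invariant
        with pytest.raises(ValueError, match="stability"):
            ts.SimulationConfig(geometry=geo, protocol=single_pulse(),
                                duration_ms=10.0, dt_ms=0.06)

    def test_3d_percolation_uses_six_neighbours(self):
        eta = np.zeros((2, 3, 3), np.uint8)
        eta[:, 1, :] = 1      # blocking slab ...
        eta[0, 1, 1] = 0      # ... with a hole in one layer
        geo = cs.TissueGeometry((2, 3, 3), cs.DX_CM, eta,
                                np.ones((2, 3, 3)))
        crosses, _ = cs.myocyte_percolates(geo)
        assert crosses


class TestStimulus:
    def test_tp_pulse_count_matches_protocol(self):
        proto = ts.StimulusProtocol(mode="TP", pcl_ms=152.0)
        assert proto.n_pulses == 20
        assert proto.pulse_count(18_000.0) == 20

    def test_pp_pulse_windows(self):
        proto = ts.StimulusProtocol(mode="PP", pcl_ms=200.0)
        assert proto.pulse_active(400.5)
        assert proto.pulse_active(402.9)
        assert not proto.pulse_active(403.1)
        assert not proto.pulse_active(199.0)

    def test_field_zero_between_pulses(self):
        geo = cs.uniform_geometry((8, 8))
        proto = ts.StimulusProtocol(mode="PP", pcl_ms=200.0)
        fld = ts.apply_stimulus(proto, 100.0, geo)
        assert not fld.any()
        fld = ts.apply_stimulus(proto, 201.0, geo)
        assert np.all(fld[:2] == -150.0) and not fld[2:].any()

    def test_invalid_protocols_rejected(self):
        with pytest.raises(ValueError):
            ts.StimulusProtocol(mode="PP", pcl_ms=2.0)
        with pytest.raises(ValueError):
            ts.StimulusProtocol(mode="XX")
        with pytest.raises(ValueError):
            ts.StimulusProtocol(amplitude=0.0)

    def test_pacing_frequency_conversion(self):
        assert ts.StimulusProtocol(pcl_ms=152.0).frequency_hz == \
            pytest.approx(6.5789, abs=1e-3)


class TestGuards:
    def test_stability_bound_refused(self):
        geo = cs.uniform_geometry((8, 8))
        with pytest.raises(ValueError, match="stability"):
            ts.SimulationConfig(geometry=geo, protocol=single_pulse(),
                                duration_ms=10.0, dt_ms=0.1)

    def test_stability_bound_value_2d(self):
        # dx^2 / (4 D_mm) = 0.0833 ms; the working step is far below it
        bound = cs.DX_CM ** 2 / (4 * cs.D_MM)
        assert bound == pytest.approx(0.0833, abs=1e-3)
        assert cm.DT_MS < bound

    def test_duration_zero_initial_snapshot_only(self):
        geo = cs.uniform_geometry((8, 8))
        cfg = ts.SimulationConfig(geometry=geo, protocol=single_pulse(),
                                  duration_ms=0.0, record_snapshots=True)
        rec = ts.run(cfg)
        assert rec.t_ms.size == 1
        assert rec.snapshots.shape[0] == 1


class TestDeterminism:
    def test_identical_configs_bit_identical_records(self):
        s = cs.ClumpSpec(radius_cm=0.3, pf_percent=40.0, seed=5)
        recs = []
        for _ in range(2):
            geo = cs.generate_clump((48, 48), s)
            cfg = ts.SimulationConfig(geometry=geo, protocol=single_pulse(),
                                      duration_ms=60.0,
                                      record_snapshots=True)
            recs.append(ts.run(cfg))
        a, b = recs
        assert np.array_equal(a.probe_vm, b.probe_vm)
        assert np.array_equal(a.snapshots, b.snapshots)
        assert a.config_hash == b.config_hash


class TestCableWavePhysics:
    def test_wave_reaches_far_end_activation_monotone(
            self, control_cable_record):
        rec = control_cable_record
        amap = wm.activation_times(rec.t_ms, rec.probe_vm)
        at = amap.times_ms
        assert np.isfinite(at).all()
        assert np.all(np.diff(at) > 0)

    def test_refractoriness_bracket(self, myocyte_rest):
        """A second pulse 100 ms after the first is blocked; at 400 ms it
        propagates with CV within 5% of the first wave."""
        geo = cs.uniform_geometry((256, 1))
        probes = [(100, 0), (200, 0)]

        def count_activations(pcl):
            proto = ts.StimulusProtocol(mode="TP", pcl_ms=pcl, n_pulses=2)
            cfg = ts.SimulationConfig(geometry=geo, protocol=proto,
                                      duration_ms=pcl + 250.0, probes=probes)
            rec = ts.run(cfg)
            v = rec.probe_vm[1]
            ups = np.flatnonzero((v[:-1] < -40.0) & (v[1:] >= -40.0))
            return rec, ups

        _, ups_100 = count_activations(100.0)
        assert ups_100.size == 1  # second pulse blocked

        rec, ups_400 = count_activations(400.0)
        assert ups_400.size == 2  # second pulse propagates
        t = rec.t_ms
        v0, v1 = rec.probe_vm
        span_cm = 100 * cs.DX_CM

        def cv_of_wave(window):
            a0 = wm.activation_times(t, v0[None], window_ms=window)
            a1 = wm.activation_times(t, v1[None], window_ms=window)
            return span_cm / (a1.times_ms[0] - a0.times_ms[0]) * 1000.0

        cv1 = cv_of_wave((0.0, 380.0))
        cv2 = cv_of_wave((400.0, 650.0))
        assert cv2 == pytest.approx(cv1, rel=0.05)
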