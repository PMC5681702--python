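"""Single-cell physiology: fibroblast relaxation, myocyte resting state,
action-potential generation, and the tabulated-rate accuracy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibroclump import _ord
from fibroclump import cell_models as cm


class TestFibroblast:
    @pytest.mark.parametrize("vf, expected", [
        (-30.0, 0.0),                      # at the reversal potential
        (-25.0, -(1.0 * 5.0) / 6.3),       # low-conductance branch
        (0.0, -(2.0 * 30.0) / 6.3),        # high-conductance branch
    ])
    def test_rhs_values(self, vf, expected):
        assert cm.fibroblast_rhs(vf) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("vf, gf", [(-25.0, 1.0), (0.0, 2.0),
                                        (-20.0, 1.0)])
    def test_conductance_branches(self, vf, gf):
        assert cm.gf_conductance(vf) == gf

    def test_rhs_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            cm.fibroblast_rhs(float("nan"))

    @given(v0=st.floats(min_value=-90.0, max_value=0.0))
    @settings(max_examples=20, deadline=None)
    def test_rest_is_minus_30(self, v0):
        vend, _ = cm.single_cell_steady_state("fibroblast", v0=v0,
                                              duration_ms=3000.0)
        assert vend == pytest.approx(-30.0, abs=0.01)

    def test_fixed_point_exact(self):
        _, trace, vend = cm.simulate_fibroblast(-30.0, duration_ms=100.0)
        assert vend == -30.0
        assert np.all(trace == -30.0)

    def test_exponential_relaxation(self):
        """Within one conductance branch the discrete trajectory is exactly
        geometric, and it converges to the continuous exponential."""
        p = cm.FibroblastParams()
        t, trace, _ = cm.simulate_fibroblast(-50.0, duration_ms=3000.0,
                                             record_every_ms=1.0)
        # exact solution of the forward-Euler map (tau = Cf/Gf_low)
        factor = 1.0 - cm.DT_MS * p.gf_low / p.cf
        discrete = p.ef + (-50.0 - p.ef) * factor ** (t / cm.DT_MS)
        assert np.max(np.abs(trace - discrete)) < 1e-9
        # continuous exponential, first-order accurate in dt
        exact = p.ef + (-50.0 - p.ef) * np.exp(-p.gf_low * t / p.cf)
        assert np.max(np.abs(trace - exact)) < 0.05


class TestMyocyte:
    def test_resting_potential(self, myocyte_rest):
        vm, _ = myocyte_rest
        assert vm == pytest.approx(-90.0, abs=4.0)

    def test_rhs_near_zero_at_rest(self, myocyte_rest):
        vm, y = myocyte_rest
        dv, _ = cm.myocyte_rhs(cm.MyocyteState(vm, y.copy()))
        assert abs(dv) < 1e-3

    def test_stimulus_depolarizes(self, myocyte_rest):
        vm, y = myocyte_rest
        dv, _ = cm.myocyte_rhs(cm.MyocyteState(vm, y.copy()), i_stim=-150.0)
        assert dv > 0

    def test_rhs_rejects_nonfinite_naming_variable(self, myocyte_rest):
        vm, y = myocyte_rest
        y = y.copy()
        y[_ord.STATE_NAMES.index("cai")] = np.nan
        with pytest.raises(ValueError, match="cai"):
            cm.myocyte_rhs(cm.MyocyteState(vm, y))

    def test_action_potential_fires(self, myocyte_rest):
        vm, y = myocyte_rest
        t, v, _ = cm.simulate_myocyte(duration_ms=500.0, pcl_ms=1000.0,
                                      state=cm.MyocyteState(vm, y.copy()))
        assert v.max() > 0.0
        assert v[0] < -80.0

    def test_gates_bounded_concentrations_positive(self, myocyte_rest):
        """Along a paced trajectory every gate stays in [0, 1] and every
        concentration stays positive (relaxation-form updates)."""
        vm, y0 = myocyte_rest
        state = cm.MyocyteState(vm, y0.copy())
        for _ in range(5):  # 5 x 200 ms windows of a paced beat
            _, _, state = cm.simulate_myocyte(duration_ms=200.0,
                                              pcl_ms=1000.0, state=state)
            gates = state.gates
            assert np.all(gates >= 0.0) and np.all(gates <= 1.0)
            assert np.all(state.concentrations > 0.0)

    def test_gate_update_respects_bounds_from_extremes(self, myocyte_rest):
        """One update step from gates pinned at 0 or 1 stays inside [0, 1]."""
        vm, y0 = myocyte_rest
        for pin in (0.0, 1.0):
            y = y0.copy()
            y[_ord.GATE_SLICE] = pin
            _, _, state = cm.simulate_myocyte(duration_ms=cm.DT_MS,
                                              state=cm.MyocyteState(vm, y))
            gates = state.gates
            assert np.all(gates >= 0.0) and np.all(gates <= 1.0)

    def test_lut_matches_exact_rates(self):
        rng = np.random.default_rng(7)
        vs = rng.uniform(-95.0, 45.0, size=200)
        lut = _ord.build_lut(cm.DT_MS)
        exact = _ord.rate_columns(vs, dt=cm.DT_MS)
        out = np.empty(_ord.NCOL)
        for v, row in zip(vs, exact):
            _ord._interp_rates(lut, v, out)
            # the sharp 0.2-mV-scale feature in the phosphorylated-Ito
            # tau dominates the interpolation error; 1e-4 bounds it safely
            assert np.all(np.abs(out - row) <= 1e-4 * (1.0 + np.abs(row)))

    def test_unknown_celltype_rejected(self):
        with pytest.raises(ValueError):
            cm.MyocyteParams(celltype="apex")

    def test_negative_multiplier_rejected(self):
        with pytest.raises(ValueError):
            cm.MyocyteParams(gkr_scale=-1.0)


class TestFibroblastCoupling:
    """Electrotonic effect of a gap-coupled passive fibroblast.

    The fibroblast rests near -30 mV in isolation but is dragged close to
    the myocyte's potential by the much larger gap conductance; its net
    effect is a small leak toward -30 mV, which raises the coupled resting
    potential and slows the terminal (sub -30 mV) repolarization.
    """

    @pytest.fixture(scope="class")
    def pair_traces(self, myocyte_rest):
        vm, y = myocyte_rest
        state = cm.MyocyteState(vm, y.copy())
        t, vi, _ = cm.simulate_myocyte(duration_ms=2000.0, pcl_ms=1000.0,
                                       state=state.copy())
        t2, vmc, vfc = cm.simulate_pair(duration_ms=2000.0, pcl_ms=1000.0,
                                        state=state.copy())
        return t, vi, vmc, vfc

    def test_coupled_rest_elevated(self, pair_traces):
        t, vi, vmc, _ = pair_traces
        assert vmc[990] > vi[990] + 0.5  # diastole before beat 2

    def test_coupled_fibroblast_rests_below_isolated(self, pair_traces):
        _, _, _, vfc = pair_traces
        assert -85.0 < vfc[990] < -70.0

    def test_depolarizing_interaction_below_minus30(self, pair_traces):
        """During terminal repolarization (below E_f) the fibroblast feeds
        current back into the myocyte, slowing the approach to rest."""
        t, vi, vmc, _ = pair_traces
        # time (ms within beat 2) each trace spends between -60 and -80 mV
        seg_i = vi[1000:2000]
        seg_c = vmc[1000:2000]
        dur_i = np.sum((seg_i < -60) & (seg_i > -80))
        dur_c = np.sum((seg_c < -60) & (seg_c > -80))
        assert dur_c > dur_i
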