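"""Clump generator: occupancy statistics, coupling-weight case table,
remodelling maps, and the percolation oracle."""

import numpy as np
import pytest
from scipy import stats

from fibroclump import clump_synthesis as cs

DIMS = (128, 128)


def spec(pf, r_cm=0.5, seed=0, **kw):
    return cs.ClumpSpec(radius_cm=r_cm, pf_percent=pf, seed=seed, **kw)


class TestGenerateClump:
    def test_pf0_all_myocyte(self):
        geo = cs.generate_clump(DIMS, spec(0.0))
        assert geo.eta.sum() == 0

    def test_pf100_fills_clump_exactly(self):
        geo = cs.generate_clump(DIMS, spec(100.0))
        mask, _ = cs._clump_mask_and_radius(DIMS, geo.dx_cm, spec(100.0))
        assert np.array_equal(geo.eta.astype(bool), mask)

    def test_occupancy_within_3se(self):
        s = spec(30.0, r_cm=0.8, seed=3)
        geo = cs.generate_clump((256, 256), s)
        mask, _ = cs._clump_mask_and_radius((256, 256), geo.dx_cm, s)
        n = int(mask.sum())
        frac = geo.eta[mask].mean()
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(frac - 0.30) < 3 * se

    def test_outside_clump_all_myocyte(self):
        geo = cs.generate_clump(DIMS, spec(80.0))
        mask, _ = cs._clump_mask_and_radius(DIMS, geo.dx_cm, spec(80.0))
        assert geo.eta[~mask].sum() == 0

    def test_deterministic_per_seed(self):
        a = cs.generate_clump(DIMS, spec(40.0, seed=11))
        b = cs.generate_clump(DIMS, spec(40.0, seed=11))
        c = cs.generate_clump(DIMS, spec(40.0, seed=12))
        assert np.array_equal(a.eta, b.eta)
        assert not np.array_equal(a.eta, c.eta)

    def test_occupancy_binomial_over_seeds(self):
        """Fibroblast counts across 50 seeds behave as Binomial(n, 0.3):
        a chi-square of the standardized counts does not reject at 1%."""
        s0 = spec(30.0, r_cm=0.5)
        mask, _ = cs._clump_mask_and_radius((64, 64), cs.DX_CM,
                                            spec(30.0, r_cm=0.5))
        n = int(mask.sum())
        ks = []
        for seed in range(50):
            geo = cs.generate_clump((64, 64), spec(30.0, r_cm=0.5,
                                                   seed=seed))
            ks.append(geo.eta.sum())
        z2 = (np.array(ks) - n * 0.3) ** 2 / (n * 0.3 * 0.7)
        chi2 = z2.sum()
        lo, hi = stats.chi2.ppf([0.005, 0.995], df=50)
        assert lo < chi2 < hi

    def test_oversized_clump_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            cs.generate_clump((64, 64), spec(30.0, r_cm=1.0))

    def test_3d_cylinder_mask_invariant_draws_independent(self):
        s = spec(50.0, r_cm=0.3, seed=5)
        geo = cs.generate_clump((4, 48, 48), s)
        mask, _ = cs._clump_mask_and_radius((4, 48, 48), geo.dx_cm, s)
        # clump mask is z-invariant ...
        assert all(np.array_equal(mask[0], mask[z]) for z in range(4))
        # ... but the Bernoulli draws differ between layers
        assert not np.array_equal(geo.eta[0], geo.eta[1])
        assert geo.eta[:, ~mask[0]].sum() == 0


class TestGradientProfile:
    @pytest.mark.parametrize("r_frac, expected", [(0.0, 35.0), (1.0, 0.0),
                                                  (0.5, 17.5)])
    def test_linear_interpolation(self, r_frac, expected):
        s = spec(35.0, r_cm=1.0, profile="linear_gradient")
        assert cs.gradient_profile(r_frac * 1.0, s) == pytest.approx(expected)

    def test_outside_clump_zero(self):
        s = spec(35.0, r_cm=1.0, profile="linear_gradient")
        assert cs.gradient_profile(1.5, s) == 0.0

    def test_gradient_field_density_falls_with_radius(self):
        s = cs.ClumpSpec(radius_cm=1.0, pf_percent=35.0, seed=2,
                         profile="linear_gradient")
        geo = cs.generate_clump((128, 128), s)
        _, r = cs._clump_mask_and_radius((128, 128), geo.dx_cm, s)
        inner = geo.eta[r < 0.3].mean()
        outer = geo.eta[(r > 0.7) & (r <= 1.0)].mean()
        assert inner > outer


class TestRemodelingMap:
    def test_annulus_values(self):
        s = spec(30.0, r_cm=0.5)
        geo = cs.generate_clump(DIMS, s)
        remo = cs.remodeling_map(geo, s, annulus_radius_cm=0.8,
                                 gna_scale=0.5)
        mask, r = cs._clump_mask_and_radius(DIMS, geo.dx_cm,
                                            spec(30.0, r_cm=0.8))
        assert np.all(remo.gna_scale_field[mask] == 0.5)
        assert np.all(remo.gna_scale_field[r > 0.8] == 1.0)

    @pytest.mark.parametrize("scale", [1.1, 3.0])
    def test_enhanced_excitability_scales(self, scale):
        s = spec(30.0, r_cm=0.5)
        geo = cs.generate_clump(DIMS, s)
        remo = cs.remodeling_map(geo, s, 0.7, scale)
        mask, _ = cs._clump_mask_and_radius(DIMS, geo.dx_cm,
                                            spec(30.0, r_cm=0.7))
        assert np.all(remo.gna_scale_field[mask] == scale)

    def test_annulus_smaller_than_clump_rejected(self):
        s = spec(30.0, r_cm=0.5)
        geo = cs.generate_clump(DIMS, s)
        with pytest.raises(ValueError):
            cs.remodeling_map(geo, s, 0.4, 0.5)


class TestCouplingField:
    def test_case_table_values(self):
        """Edge weights reproduce the printed constants:
        MM 0.0012/0.02^2 = 3 /ms, MF 8/185, FM 8/6.3, FF 0.3 /ms."""
        eta = np.zeros((2, 2), np.uint8)
        eta[0, 1] = 1
        eta[1, 1] = 1
        geo = cs.TissueGeometry((2, 2), cs.DX_CM, eta, np.ones((2, 2)))
        cf = cs.build_coupling(geo)
        w = cf.weights.reshape(2, 2, 4)  # dirs: -x +x -y +y
        assert w[0, 0, 1] == pytest.approx(8.0 / 185.0)     # M <- F
        assert w[0, 1, 0] == pytest.approx(8.0 / 6.3)       # F <- M
        assert w[0, 0, 3] == pytest.approx(3.0)             # M <- M (down y)
        assert w[0, 1, 3] == pytest.approx(0.3)             # F <- F

    def test_boundary_edges_absent(self):
        geo = cs.uniform_geometry((3, 3))
        cf = cs.build_coupling(geo)
        w = cf.weights.reshape(3, 3, 4)
        assert np.all(w[:, 0, 0] == 0.0)   # -x at left wall
        assert np.all(w[:, -1, 1] == 0.0)  # +x at right wall
        assert np.all(w[0, :, 2] == 0.0)   # -y at bottom wall
        assert np.all(w[-1, :, 3] == 0.0)  # +y at top wall

    def test_mm_ff_symmetric_mf_ratio_cm_cf(self):
        s = spec(40.0, r_cm=0.4, seed=9)
        geo = cs.generate_clump((64, 64), s)
        cf = cs.build_coupling(geo)
        n = geo.n_sites
        w = cf.weights
        nbr = cf.nbr
        eta = geo.eta.ravel()
        rng = np.random.default_rng(0)
        for i in rng.integers(0, n, 500):
            for d in range(4):
                j = nbr[i, d]
                if j == i:
                    continue
                back = int(np.flatnonzero(nbr[j] == i)[0])
                if eta[i] == eta[j]:
                    assert w[i, d] == w[j, back]
                else:
                    ratio = w[i, d] / w[j, back]
                    expected = (185.0 / 6.3) if eta[i] else (6.3 / 185.0)
                    assert ratio == pytest.approx(expected, rel=1e-12)


class TestPercolation:
    def test_pf0_crosses(self):
        geo = cs.uniform_geometry((64, 64))
        crosses, stats_ = cs.myocyte_percolates(geo)
        assert crosses
        assert stats_["largest_cluster"] == 64 * 64

    def test_full_width_impenetrable_clump_blocks(self):
        # R chosen so the clump covers the full domain width at mid-height
        s = cs.ClumpSpec(radius_cm=0.638, pf_percent=100.0, seed=0)
        geo = cs.generate_clump((64, 64), s)
        crosses, _ = cs.myocyte_percolates(geo)
        assert not crosses

    def test_crossing_probability_transition(self):
        """Monte-Carlo flood fill: the crossing probability falls from ~1
        to ~0 as the myocyte fraction 1 - p_f/100 passes the square-lattice
        site-percolation threshold (~0.593; finite-size broadened here)."""
        r_cm = 0.638  # clump spans the domain width
        probs = {}
        for pf in (25.0, 40.0, 55.0):
            hits = 0
            for seed in range(100):
                geo = cs.generate_clump(
                    (64, 64), cs.ClumpSpec(radius_cm=r_cm, pf_percent=pf,
                                           seed=seed))
                hits += cs.myocyte_percolates(geo)[0]
            probs[pf] = hits / 100.0
        assert probs[25.0] >= 0.9   # myocyte fraction 0.75: well connected
        assert probs[55.0] <= 0.1   # myocyte fraction 0.45: blocked
        assert probs[25.0] > probs[40.0] > probs[55.0]
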