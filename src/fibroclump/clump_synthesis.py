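"""Synthetic tissue geometries: fibroblast clumps, remodelling maps, and
gap-junctional coupling fields.

A clump is a disc (2D) or a full-thickness cylinder (3D, axis along z) of
radius R placed in a myocyte sheet.  Inside it every lattice site is
independently a fibroblast with probability Omega_f = p_f/100 — uniformly,
or with a probability that falls linearly from the centre value to zero at
the clump edge.  Around the clump an annular remodelling map can scale the
fast-sodium conductance, emulating the reduced (or enhanced) excitability
of peri-infarct tissue.

Coupling weights per directed lattice edge follow the two-sided case table
of the monodomain update: myocyte-myocyte edges diffuse with
D_mm/dx^2, fibroblast-fibroblast with D_ff/dx^2 = D_mm/10/dx^2, and
myocyte-fibroblast edges carry the gap-junctional conductance divided by
the receiving cell's capacitance (G_gap/C_m toward the myocyte, G_gap/C_f
toward the fibroblast).  Edges leaving the domain are absent (no-flux).

Array axis convention: 2D fields are (ny, nx), 3D fields (nz, ny, nx);
pacing runs along +y from the y = 0 boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

DX_CM = 0.02          # lattice spacing
D_MM = 0.0012         # myocyte-myocyte diffusion, cm^2/ms
D_FF = D_MM / 10.0    # fibroblast-fibroblast diffusion
G_GAP_NS = 8.0        # myocyte-fibroblast gap-junctional conductance
CM_PF = 185.0         # myocyte capacitance, pF
CF_PF = 6.3           # fibroblast capacitance, pF


@dataclass
class ClumpSpec:
    """Circular (2D) or cylindrical (3D) fibroblast clump definition.

    center is given in lattice indices of the in-plane axes (y, x); None
    places the clump at the domain centre.  Radii are in cm, measured as
    dx times the Euclidean index distance; a site belongs to the clump iff
    its centre lies within R of the clump centre.
    """

    radius_cm: float
    pf_percent: float
    seed: int = 0
    center: tuple[float, float] | None = None
    profile: str = "uniform"  # "uniform" | "linear_gradient"

    def __post_init__(self):
        if not 0.0 <= self.pf_percent <= 100.0:
            raise ValueError("pf_percent must lie in [0, 100]")
        if self.radius_cm <= 0:
            raise ValueError("radius_cm must be positive")
        if self.profile not in ("uniform", "linear_gradient"):
            raise ValueError(f"unknown profile {self.profile!r}")


@dataclass
class TissueGeometry:
    """Lattice dimensions, occupancy, and per-site multiplier fields.

    eta is 1 at fibroblast sites and 0 at myocyte sites;
    gna_scale_field multiplies the fast-sodium conductance per site.
    """

    dims: tuple[int, ...]
    dx_cm: float
    eta: np.ndarray
    gna_scale_field: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        self.dims = tuple(int(d) for d in self.dims)
        if self.eta.shape != self.dims:
            raise ValueError("eta shape does not match dims")
        if self.gna_scale_field.shape != self.dims:
            raise ValueError("gna_scale_field shape does not match dims")
        if not np.isin(self.eta, (0, 1)).all():
            raise ValueError("eta must be 0 (myocyte) or 1 (fibroblast)")
        if not (self.gna_scale_field > 0).all():
            raise ValueError("multiplier fields must be positive")

    @property
    def ndim(self) -> int:
        return len(self.dims)

    @property
    def n_sites(self) -> int:
        return int(np.prod(self.dims))

    def fibroblast_fraction(self, mask: np.ndarray | None = None) -> float:
        sel = self.eta if mask is None else self.eta[mask]
        return float(np.mean(sel))

    def summary(self) -> dict:
        return {
            "dims": list(self.dims),
            "dx_cm": self.dx_cm,
            "n_sites": self.n_sites,
            "n_fibroblasts": int(self.eta.sum()),
            "fibroblast_fraction": self.fibroblast_fraction(),
            "seed": self.seed,
        }


@dataclass
class CouplingField:
    """Directed edge weights (1/ms) for every site and lattice direction.

    weights[i, d] couples flat site i to its neighbour nbr[i, d]; absent
    (boundary) edges have weight 0 and point back at the site itself.
    Directions are (-x, +x, -y, +y[, -z, +z]); rows are contiguous per
    site so one site's edges share a cache line.
    """

    weights: np.ndarray  # (n_sites, n_dirs) float64
    nbr: np.ndarray      # (n_sites, n_dirs) int64
    dims: tuple[int, ...]


def _clump_mask_and_radius(dims, dx_cm, spec):
    """Boolean in-clump mask and the in-plane radius (cm) of every site."""
    plane = dims[-2:]
    if spec.center is None:
        cy, cx = ((plane[0] - 1) / 2.0, (plane[1] - 1) / 2.0)
    else:
        cy, cx = spec.center
    yy, xx = np.meshgrid(np.arange(plane[0]), np.arange(plane[1]),
                         indexing="ij")
    r = dx_cm * np.hypot(yy - cy, xx - cx)
    mask = r <= spec.radius_cm
    if len(dims) == 3:
        r = np.broadcast_to(r, dims)
        mask = np.broadcast_to(mask, dims)
    return mask, r


def gradient_profile(r_cm: float, spec: ClumpSpec) -> float:
    """Local fibroblast percentage at radius ``r_cm`` for the linear-gradient
    profile: pf at the centre, falling linearly to 0 at the clump edge
    (and 0 beyond it)."""
    if r_cm < 0:
        raise ValueError("radius must be non-negative")
    if r_cm > spec.radius_cm:
        return 0.0
    return spec.pf_percent * (1.0 - r_cm / spec.radius_cm)


def generate_clump(dims, spec: ClumpSpec, dx_cm: float = DX_CM
                   ) -> TissueGeometry:
    """Bernoulli-populate a clump inside an otherwise all-myocyte lattice.

    Reproducible: the same (dims, spec) gives a bit-identical occupancy.
    The clump must fit inside the domain.
    """
    dims = tuple(int(d) for d in dims)
    if len(dims) not in (2, 3):
        raise ValueError("dims must be 2D (ny, nx) or 3D (nz, ny, nx)")
    mask, r = _clump_mask_and_radius(dims, dx_cm, spec)
    plane = dims[-2:]
    cy, cx = ((plane[0] - 1) / 2.0, (plane[1] - 1) / 2.0) \
        if spec.center is None else spec.center
    r_idx = spec.radius_cm / dx_cm
    if (cy - r_idx < -0.5 or cx - r_idx < -0.5
            or cy + r_idx > plane[0] - 0.5 or cx + r_idx > plane[1] - 0.5):
        raise ValueError("clump does not fit inside the domain")
    if spec.profile == "uniform":
        omega = np.where(mask, spec.pf_percent / 100.0, 0.0)
    else:
        with np.errstate(invalid="ignore"):
            local_pf = spec.pf_percent * (1.0 - r / spec.radius_cm)
        omega = np.where(mask, np.clip(local_pf, 0.0, 100.0) / 100.0, 0.0)
    rng = np.random.default_rng(spec.seed)
    draws = rng.random(dims)
    eta = (draws < omega).astype(np.uint8)
    return TissueGeometry(dims=dims, dx_cm=dx_cm, eta=eta,
                          gna_scale_field=np.ones(dims), seed=spec.seed)


def uniform_geometry(dims, dx_cm: float = DX_CM) -> TissueGeometry:
    """All-myocyte lattice (the p_f = 0 control)."""
    dims = tuple(int(d) for d in dims)
    return TissueGeometry(dims=dims, dx_cm=dx_cm,
                          eta=np.zeros(dims, dtype=np.uint8),
                          gna_scale_field=np.ones(dims))


def remodeling_map(geometry: TissueGeometry, clump: ClumpSpec,
                   annulus_radius_cm: float, gna_scale: float
                   ) -> TissueGeometry:
    """Scale the fast-sodium conductance inside the disc of radius
    ``annulus_radius_cm`` around the clump centre (clump interior included);
    outside it the multiplier stays 1."""
    if annulus_radius_cm < clump.radius_cm:
        raise ValueError("annulus radius must be >= clump radius")
    if gna_scale <= 0:
        raise ValueError("gna_scale must be positive")
    probe = ClumpSpec(radius_cm=annulus_radius_cm,
                      pf_percent=clump.pf_percent, center=clump.center,
                      seed=clump.seed)
    mask, _ = _clump_mask_and_radius(geometry.dims, geometry.dx_cm, probe)
    fld = np.ones(geometry.dims)
    fld[mask] = gna_scale
    return TissueGeometry(dims=geometry.dims, dx_cm=geometry.dx_cm,
                          eta=geometry.eta, gna_scale_field=fld,
                          seed=geometry.seed)


def build_coupling(geometry: TissueGeometry,
                   d_mm: float = D_MM, d_ff: float | None = None,
                   g_gap_ns: float = G_GAP_NS, cm_pf: float = CM_PF,
                   cf_pf: float = CF_PF) -> CouplingField:
    """Directed edge weights for every nearest-neighbour pair (Eq.-5 case
    table); boundary edges are omitted, which realizes no-flux walls."""
    if d_ff is None:
        d_ff = d_mm / 10.0
    dims = geometry.dims
    nd = len(dims)
    n = geometry.n_sites
    dx2 = geometry.dx_cm ** 2
    eta = geometry.eta.ravel().astype(bool)

    # axis order of directions: (-x, +x, -y, +y[, -z, +z]);
    # x is the last array axis, y the second-to-last, z the first (3D).
    axes = [nd - 1, nd - 2] + ([0] if nd == 3 else [])
    n_dirs = 2 * nd
    weights = np.zeros((n, n_dirs))
    nbr = np.tile(np.arange(n, dtype=np.int64)[:, None], (1, n_dirs))

    idx = np.arange(n, dtype=np.int64).reshape(dims)
    d = 0
    for ax in axes:
        for sign in (-1, +1):
            shifted = np.roll(idx, -sign, axis=ax)
            valid = np.ones(dims, dtype=bool)
            sl = [slice(None)] * nd
            sl[ax] = -1 if sign == +1 else 0
            valid[tuple(sl)] = False
            v = valid.ravel()
            tgt = shifted.ravel()
            nbr[v, d] = tgt[v]
            eta_nb = eta[tgt]
            w = np.where(
                ~eta & ~eta_nb, d_mm / dx2,
                np.where(~eta & eta_nb, g_gap_ns / cm_pf,
                         np.where(eta & ~eta_nb, g_gap_ns / cf_pf,
                                  d_ff / dx2)))
            weights[v, d] = w[v]
            d += 1
    return CouplingField(weights=weights, nbr=nbr, dims=dims)


def myocyte_percolates(geometry: TissueGeometry, axis: int | None = None):
    """Flood-fill test for a myocyte path across the domain along ``axis``
    (default: the pacing axis y), with 4-neighbour (2D) / 6-neighbour (3D)
    connectivity.

    Returns ``(crosses, stats)`` where stats holds the largest-cluster size
    and the myocyte count.
    """
    eta = geometry.eta
    nd = eta.ndim
    if axis is None:
        axis = nd - 2  # y
    structure = ndimage.generate_binary_structure(nd, 1)
    labels, nlab = ndimage.label(eta == 0, structure=structure)
    crosses = False
    if nlab:
        first = np.take(labels, 0, axis=axis)
        last = np.take(labels, -1, axis=axis)
        common = np.intersect1d(first[first > 0], last[last > 0])
        crosses = common.size > 0
    sizes = np.bincount(labels.ravel())[1:] if nlab else np.array([], int)
    stats = {
        "n_myocytes": int((eta == 0).sum()),
        "n_clusters": int(nlab),
        "largest_cluster": int(sizes.max()) if sizes.size else 0,
    }
    return crosses, stats
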