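"""Compiled explicit-update kernels for single cells and the coupled lattice.

The lattice update implements, at every site, one explicit step of

    dV/dt = -(1 - eta) I_ion/C_m - eta I_f/C_f + sum_nb G (V_nb - V)

with the neighbour sum taken over precomputed directed edge weights
(no-flux boundaries are realized by zero weights).  Myocyte sites advance
the full ionic state through the tabulated rate columns (forward Euler for
voltage and concentrations, Rush-Larsen for gates); fibroblast sites
advance only their membrane voltage.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._ord import NCOL, NVARS, TAU_HL, TAU_HLP, TAU_JCA, _interp_rates, \
    advance_myocyte, cell_currents, gate_update


@njit(cache=True, inline="always")
def fibro_dvdt(v, cf, ef, gf_low, gf_high, vf_switch):
    gf = gf_low if v <= vf_switch else gf_high
    return -gf * (v - ef) / cf


@njit(cache=True, fastmath=True)
def lattice_step(v_in, v_out, y, myo, fib, w, nbr, lut, mult, gna_site,
                 stim_field, stim_on, fib_par, dt):
    """One explicit step of the full lattice; returns max |V| after the step.

    v_in/v_out : flattened voltage fields (mV)
    y          : (n_myo, NVARS) myocyte states, rows aligned with ``myo``
    myo, fib   : flat site indices of myocytes / fibroblasts
    w, nbr     : (n_sites, n_dirs) edge weights (1/ms) and neighbour indices
    lut        : tabulated rate columns built for this ``dt``
    mult       : global conductance multipliers; gna_site scales mult[0]
    stim_field : per-site stimulus density (uA/uF), scaled by ``stim_on``
    fib_par    : (cf, ef, gf_low, gf_high, vf_switch)
    """
    rates = np.empty(NCOL)
    dy = np.empty(NVARS)
    mloc = mult.copy()
    e_hl = np.exp(-dt / TAU_HL)
    e_hlp = np.exp(-dt / TAU_HLP)
    e_jca = np.exp(-dt / TAU_JCA)
    ndir = w.shape[1]
    vmax = 0.0
    for k in range(myo.shape[0]):
        i = myo[k]
        vi = v_in[i]
        lap = 0.0
        for d in range(ndir):
            lap += w[i, d] * (v_in[nbr[i, d]] - vi)
        istim = stim_on * stim_field[i]
        _interp_rates(lut, vi, rates)
        mloc[0] = mult[0] * gna_site[i]
        dv = advance_myocyte(vi, y[k], rates, mloc, istim, dt, dy,
                             e_hl, e_hlp, e_jca)
        vn = vi + dt * (dv + lap)
        v_out[i] = vn
        if abs(vn) > vmax:
            vmax = abs(vn)
    cf = fib_par[0]; ef = fib_par[1]
    gl = fib_par[2]; gh = fib_par[3]; vsw = fib_par[4]
    for k in range(fib.shape[0]):
        i = fib[k]
        vi = v_in[i]
        lap = 0.0
        for d in range(ndir):
            lap += w[i, d] * (v_in[nbr[i, d]] - vi)
        istim = stim_on * stim_field[i]
        vn = vi + dt * (fibro_dvdt(vi, cf, ef, gl, gh, vsw) - istim + lap)
        v_out[i] = vn
        if abs(vn) > vmax:
            vmax = abs(vn)
    return vmax


@njit(cache=True)
def single_cell_steps(v0, y, lut, mult, stim, dt, rec_every, out_v):
    """Explicit integration of one myocyte; identical arithmetic to the
    lattice kernel with an empty neighbourhood.

    stim  : per-step stimulus density (uA/uF), length = number of steps
    out_v : records V every ``rec_every`` steps (out_v[0] = v0)
    """
    rates = np.empty(NCOL)
    dy = np.empty(NVARS)
    e_hl = np.exp(-dt / TAU_HL)
    e_hlp = np.exp(-dt / TAU_HLP)
    e_jca = np.exp(-dt / TAU_JCA)
    v = v0
    nrec = 0
    nsteps = stim.shape[0]
    for n in range(nsteps):
        if n % rec_every == 0:
            out_v[nrec] = v
            nrec += 1
        _interp_rates(lut, v, rates)
        dv = advance_myocyte(v, y, rates, mult, stim[n], dt, dy,
                             e_hl, e_hlp, e_jca)
        lap = 0.0
        v = v + dt * (dv + lap)
    return v


@njit(cache=True)
def fibro_steps(v0, cf, ef, gf_low, gf_high, vf_switch, stim, dt,
                rec_every, out_v):
    """Forward-Euler integration of one passive fibroblast."""
    v = v0
    nrec = 0
    for n in range(stim.shape[0]):
        if n % rec_every == 0:
            out_v[nrec] = v
            nrec += 1
        v = v + dt * (fibro_dvdt(v, cf, ef, gf_low, gf_high, vf_switch)
                      - stim[n])
    return v


@njit(cache=True)
def pair_steps(vm0, vf0, y, lut, mult, g_gap, cm, cf, ef, gf_low, gf_high,
               vf_switch, n_fib, stim, dt, rec_every, out_vm, out_vf):
    """Hand-written two-ODE myocyte + fibroblast(s) gap-junction pair.

    The myocyte sees n_fib identical fibroblasts; coupling enters the
    voltage equations as (G_gap/C) * (V_other - V_self), the same weights
    the lattice assembles for an MF edge.
    """
    rates = np.empty(NCOL)
    dy = np.empty(NVARS)
    e_hl = np.exp(-dt / TAU_HL)
    e_hlp = np.exp(-dt / TAU_HLP)
    e_jca = np.exp(-dt / TAU_JCA)
    vm = vm0
    vf = vf0
    wm = g_gap / cm
    wf = g_gap / cf
    nrec = 0
    for n in range(stim.shape[0]):
        if n % rec_every == 0:
            out_vm[nrec] = vm
            out_vf[nrec] = vf
            nrec += 1
        _interp_rates(lut, vm, rates)
        dvm = advance_myocyte(vm, y, rates, mult, stim[n], dt, dy,
                              e_hl, e_hlp, e_jca)
        lap_m = n_fib * wm * (vf - vm)
        lap_f = wf * (vm - vf)
        dvf = fibro_dvdt(vf, cf, ef, gf_low, gf_high, vf_switch)
        vm_new = vm + dt * (dvm + lap_m)
        vf_new = vf + dt * (dvf + lap_f)
        vm = vm_new
        vf = vf_new
    return vm
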