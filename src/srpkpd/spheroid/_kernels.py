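"""Numba kernel for the lattice exposure solver.

The solver works on a flat list of *active* sites (tissue sites, plus the
medium when the box is closed); each active site carries precomputed
neighbour indices and face conductances.  The extracellular field advances
explicitly (FTCS) at the diffusion-limited step; the intracellular pools
advance by an exact exponential update against the frozen extracellular
value, which keeps the scheme stable and mass-conservative.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_exposure"]


@njit(cache=True)
def run_exposure(
    ce,            # (nc, nsites) extracellular field on flat sites, uM
    act_idx,       # (na,) flat indices of evolving sites
    nb_idx,        # (na, 6) flat neighbour indices (-1 = face of the box)
    nb_g,          # (na, 6) face conductances (amount flux = g * dC)
    inv_vol,       # (na,) 1 / (eps * dx^3)
    site_vol,      # (na,) eps * dx^3
    cell_act,      # (ncells,) position of each cell within act_idx, -1 if
                   #           the cell's site is not evolving (bath mode)
    cell_flat,     # (ncells,) flat site index of each cell
    cell_line,     # (ncells,) line index
    ci, auc,       # (ncells, nc)
    k_in, k_out, k_loss,   # (nc,)
    kmet,          # (nlines, nc) effective intracellular rates
    parent,        # (nc,) parent compound index, -1 for root
    is_terminal,   # (nc,) terminal k_met routes to sink
    w_exchange,    # eps_i / eps_e volume-fraction ratio
    vol_i,         # eps_i * dx^3 intracellular amount weight per cell
    dt, nsteps,
):
    """Advance the exposure; mutates ce/ci/auc, returns the sink amount."""
    nc = ce.shape[0]
    na = act_idx.shape[0]
    ncells = cell_flat.shape[0]
    int_ci = np.zeros((ncells, nc))
    delta = np.empty(na)
    sink = 0.0
    for _ in range(nsteps):
        for n in range(nc):
            f = ce[n]
            for a in range(na):
                s = act_idx[a]
                c = f[s]
                acc = 0.0
                for d in range(6):
                    j = nb_idx[a, d]
                    if j >= 0:
                        acc += nb_g[a, d] * (f[j] - c)
                delta[a] = dt * acc * inv_vol[a]
            kl = k_loss[n]
            if kl > 0.0:
                for a in range(na):
                    s = act_idx[a]
                    sink += kl * dt * f[s] * site_vol[a]
                    delta[a] -= kl * dt * f[s]
            for a in range(na):
                f[act_idx[a]] += delta[a]
        # cellular exchange + metabolite chain (compounds ordered root-first)
        for m in range(ncells):
            s = cell_flat[m]
            a = cell_act[m]
            ln = cell_line[m]
            for n in range(nc):
                prod = 0.0
                p = parent[n]
                if p >= 0:
                    prod = kmet[ln, p] * int_ci[m, p] / dt
                cs = ce[n, s]
                inflow = k_in[n] * cs + prod
                rate = k_out[n] + kmet[ln, n]
                c_old = ci[m, n]
                if rate * dt > 1e-12:
                    e = np.exp(-rate * dt)
                    c_new = c_old * e + inflow * (1.0 - e) / rate
                    integ = (inflow * dt - (c_new - c_old)) / rate
                else:
                    c_new = c_old + inflow * dt
                    integ = c_old * dt + 0.5 * inflow * dt * dt
                if c_new < 1e-30:
                    c_new = 0.0
                ci[m, n] = c_new
                int_ci[m, n] = integ
                auc[m, n] += integ
                if a >= 0:
                    ce[n, s] += -w_exchange * (k_in[n] * cs * dt - k_out[n] * integ)
                if is_terminal[n]:
                    sink += kmet[ln, n] * integ * vol_i
    return sink
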