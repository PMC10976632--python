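"""Numba inner loop for the replica-exchange Monte Carlo sampler.

Works internally in radians.  Each replica's Hamiltonian is

    U_r(w) = V_r * sum_i 4*(1 - cos 2w_i)          (scaled prolyl torsions)
           + V_bias * sum_i (1 - cos w_i)          (one-fold trans penalty)
           + sum_s c_s * prod_i weight_{s_i}(w_i)  (state coupling)

where the trans switching weight is (1 - cos w)/2.  The torsion and bias
shapes are hard-coded to the physical co-rotating form; the generic
term-by-term evaluation lives in :mod:`wbpremd.model`.
"""

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi


@njit(cache=True)
def _coupling(c, w1, w2, w3):
    e = 0.0
    for i in range(2):
        f1 = w1 if i == 1 else 1.0 - w1
        for j in range(2):
            f2 = w2 if j == 1 else 1.0 - w2
            for k in range(2):
                f3 = w3 if k == 1 else 1.0 - w3
                e += c[i, j, k] * f1 * f2 * f3
    return e


@njit(cache=True)
def remd_sweep_kernel(omega0, levels, ctensor, bias_v, kT, sigma, n_sweeps,
                      exchange_every, save_stride, seed):
    """Propagate all replicas and return (trajectory, attempts, accepted).

    omega0 : (R, 3) start angles in radians, modified in place semantics via copy
    levels : (R,) torsion force constants, replica 1 first
    ctensor : (2, 2, 2) coupling offsets indexed by (cis=0/trans=1) per residue
    Trajectory shape: (n_sweeps // save_stride, R, 3), radians.
    One sweep proposes one wrapped-Gaussian move per angle per replica;
    neighbor exchanges (alternating even/odd pairs) swap configurations.
    """
    np.random.seed(seed)
    om = omega0.copy()
    n_rep = om.shape[0]
    beta = 1.0 / kT
    wt = np.empty((n_rep, 3))
    for r in range(n_rep):
        for a in range(3):
            wt[r, a] = 0.5 * (1.0 - np.cos(om[r, a]))

    n_save = n_sweeps // save_stride
    traj = np.empty((n_save, n_rep, 3))
    attempts = np.zeros(n_rep - 1, np.int64)
    accepted = np.zeros(n_rep - 1, np.int64)
    isave = 0

    for sweep in range(1, n_sweeps + 1):
        for r in range(n_rep):
            for a in range(3):
                old = om[r, a]
                new = old + sigma * np.random.normal()
                new = (new + np.pi) % TWO_PI - np.pi
                w_old = wt[r, a]
                w_new = 0.5 * (1.0 - np.cos(new))
                du = levels[r] * 4.0 * (np.cos(2.0 * old) - np.cos(2.0 * new))
                du += bias_v * (np.cos(old) - np.cos(new))
                if a == 0:
                    du += _coupling(ctensor, w_new, wt[r, 1], wt[r, 2]) \
                        - _coupling(ctensor, w_old, wt[r, 1], wt[r, 2])
                elif a == 1:
                    du += _coupling(ctensor, wt[r, 0], w_new, wt[r, 2]) \
                        - _coupling(ctensor, wt[r, 0], w_old, wt[r, 2])
                else:
                    du += _coupling(ctensor, wt[r, 0], wt[r, 1], w_new) \
                        - _coupling(ctensor, wt[r, 0], wt[r, 1], w_old)
                u = np.random.random()
                if du <= 0.0 or u < np.exp(-beta * du):
                    om[r, a] = new
                    wt[r, a] = w_new

        if exchange_every > 0 and n_rep > 1 and sweep % exchange_every == 0:
            parity = (sweep // exchange_every) % 2
            for p in range(parity, n_rep - 1, 2):
                t_a = 0.0
                t_b = 0.0
                for a in range(3):
                    t_a += 4.0 * (1.0 - np.cos(2.0 * om[p, a]))
                    t_b += 4.0 * (1.0 - np.cos(2.0 * om[p + 1, a]))
                delta = beta * (levels[p] - levels[p + 1]) * (t_b - t_a)
                attempts[p] += 1
                u = np.random.random()
                if delta <= 0.0 or u < np.exp(-delta):
                    accepted[p] += 1
                    for a in range(3):
                        tmp = om[p, a]
                        om[p, a] = om[p + 1, a]
                        om[p + 1, a] = tmp
                        tmp = wt[p, a]
                        wt[p, a] = wt[p + 1, a]
                        wt[p + 1, a] = tmp

        if sweep % save_stride == 0:
            traj[isave] = om
            isave += 1

    return traj, attempts, accepted
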