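"""Compiled stochastic-simulation kernels.

The exact (direct-method) SSA for the intracellular reaction network runs
inside numba-compiled kernels for speed.  All kernels draw from numba's
global legacy RNG stream; seed it once per replicate with :func:`seed_kernel`
before advancing any cells, and advance cells strictly sequentially — the
stream is global state, so reproducibility requires a fixed call order.

Reaction indices (base model, growth rate ``g`` held fixed within a step):

====  =======================  ==============
 #    reaction                 propensity
====  =======================  ==============
 0    0 -> T                   k_t
 1    0 -> A                   k_a
 2    T + A -> TA              k_b * T * A
 3    TA -> T + A              k_u * TA
 4    T -> 0   (dilution)      g * T
 5    A -> 0   (dilution)      g * A
 6    TA -> 0  (dilution)      g * TA
 7    A -> 0   (degradation)   d_a * A
====  =======================  ==============

Bimolecular propensities use raw molecule numbers without volume scaling,
matching the model's stated simplification.
"""

import numpy as np
from numba import njit

__all__ = ["seed_kernel", "ssa_base", "ssa_telegraph", "advance_cells"]


@njit(cache=True)
def seed_kernel(seed):
    """Seed the global RNG stream used by all compiled kernels."""
    np.random.seed(seed)


@njit(cache=True)
def ssa_base(T, A, TA, g, dt, k_t, k_a, k_b, k_u, d_a):
    """Advance one cell's molecule counts over ``dt`` minutes (direct method).

    The growth-mediated dilution rate ``g`` is frozen for the whole interval.
    Returns the updated (T, A, TA).
    """
    t = 0.0
    while True:
        a_bind = k_b * T * A
        a_unb = k_u * TA
        a_dil = g * (T + A + TA)
        a_deg = d_a * A
        a0 = k_t + k_a + a_bind + a_unb + a_dil + a_deg
        if a0 <= 0.0:
            break
        t += np.random.exponential(1.0 / a0)
        if t >= dt:
            break
        r = np.random.random() * a0
        if r < k_t:
            T += 1
        elif r < k_t + k_a:
            A += 1
        elif r < k_t + k_a + a_bind:
            T -= 1
            A -= 1
            TA += 1
        elif r < k_t + k_a + a_bind + a_unb:
            T += 1
            A += 1
            TA -= 1
        else:
            r -= k_t + k_a + a_bind + a_unb
            if r < g * T:
                T -= 1
            elif r < g * (T + A):
                A -= 1
            elif r < a_dil:
                TA -= 1
            else:
                A -= 1  # degradation
    return T, A, TA


@njit(cache=True)
def ssa_telegraph(T, A, TA, st, sa, g, dt, kt_on, ka_on, k_b, k_u, d_a,
                  k_on, k_off):
    """Direct-method SSA with ON/OFF (telegraph) promoters for both genes.

    ``st``/``sa`` are the toxin / antitoxin promoter states (1 = ON) and
    ``kt_on``/``ka_on`` the synthesis rates while ON.  Returns the updated
    (T, A, TA, st, sa).
    """
    t = 0.0
    while True:
        a_syn_t = kt_on if st == 1 else 0.0
        a_syn_a = ka_on if sa == 1 else 0.0
        a_bind = k_b * T * A
        a_unb = k_u * TA
        a_dil = g * (T + A + TA)
        a_deg = d_a * A
        a_ft = k_off if st == 1 else k_on
        a_fa = k_off if sa == 1 else k_on
        a0 = a_syn_t + a_syn_a + a_bind + a_unb + a_dil + a_deg + a_ft + a_fa
        if a0 <= 0.0:
            break
        t += np.random.exponential(1.0 / a0)
        if t >= dt:
            break
        r = np.random.random() * a0
        if r < a_syn_t:
            T += 1
        elif r < a_syn_t + a_syn_a:
            A += 1
        elif r < a_syn_t + a_syn_a + a_bind:
            T -= 1
            A -= 1
            TA += 1
        elif r < a_syn_t + a_syn_a + a_bind + a_unb:
            T += 1
            A += 1
            TA -= 1
        else:
            r -= a_syn_t + a_syn_a + a_bind + a_unb
            if r < g * T:
                T -= 1
            elif r < g * (T + A):
                A -= 1
            elif r < a_dil:
                TA -= 1
            elif r < a_dil + a_deg:
                A -= 1
            elif r < a_dil + a_deg + a_ft:
                st = 1 - st
            else:
                sa = 1 - sa
    return T, A, TA, st, sa


@njit(cache=True)
def advance_cells(T, A, TA, st, sa, g, vol, n, dt, k_t, k_a, k_b, k_u, d_a,
                  lam, alpha, telegraph, kt_on, ka_on, k_on, k_off):
    """Advance the first ``n`` cells of the state arrays by one report step.

    Per cell: run the SSA over ``dt`` with the cell's current growth rate
    frozen, recompute the growth rate from the new toxin count and the
    *pre-update* volume, then grow the volume exponentially at the new rate.
    Arrays are modified in place.
    """
    for i in range(n):
        if telegraph:
            Ti, Ai, TAi, sti, sai = ssa_telegraph(
                T[i], A[i], TA[i], st[i], sa[i], g[i], dt,
                kt_on, ka_on, k_b, k_u, d_a, k_on, k_off)
            st[i] = sti
            sa[i] = sai
        else:
            Ti, Ai, TAi = ssa_base(T[i], A[i], TA[i], g[i], dt,
                                   k_t, k_a, k_b, k_u, d_a)
        gi = lam * np.exp(-alpha * Ti / vol[i])
        vol[i] = vol[i] * np.exp(gi * dt)
        T[i] = Ti
        A[i] = Ai
        TA[i] = TAi
        g[i] = gi
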