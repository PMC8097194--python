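"""Numba-compiled stochastic simulation kernels.

Two engines simulate single clones of the SP model from a labelled founder
cell and record the basal size n = n_A + n_B at each requested time:

* ``simulate_markov`` — exact Gillespie simulation of the continuous-time
  Markov chain on (n_A, n_B): each A cell divides at rate ``lam`` with fates
  AA/AB/BB drawn with probabilities (r, 1-2r, r); each B cell stratifies at
  rate ``gam``.
* ``simulate_nonmarkov`` — event-driven simulation in which each A cell
  receives an independent Gamma(shape, scale=1/(lam*shape)) time-to-division
  at birth (mean division time 1/lam); B-cell stratification stays
  exponential with rate ``gam``.

Kernels take raw floats (they accept r = 0, which the public parameter type
forbids, so that the conserved-progenitor limit can be exercised directly)
and seed numba's per-thread RNG once per call, making every call
bit-reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["simulate_markov", "simulate_nonmarkov"]


@njit(cache=True)
def _record_until(out, clone, t_weeks, k, t_next, size):
    """Record ``size`` for every timepoint strictly before ``t_next``."""
    T = t_weeks.shape[0]
    while k < T and t_weeks[k] < t_next:
        out[clone, k] = size
        k += 1
    return k


@njit(cache=True)
def simulate_markov(n_clones, lam, r, gam, t_weeks, seed, init_a, init_b):
    """Gillespie simulation of ``n_clones`` independent clones.

    Returns an int64 array of shape (n_clones, len(t_weeks)) of basal sizes.
    """
    np.random.seed(seed)
    T = t_weeks.shape[0]
    out = np.zeros((n_clones, T), dtype=np.int64)
    for c in range(n_clones):
        a = init_a
        b = init_b
        t = 0.0
        k = 0
        while k < T:
            total = a * lam + b * gam
            if total <= 0.0:
                # extinct (or frozen) clone: state persists forever
                while k < T:
                    out[c, k] = a + b
                    k += 1
                break
            t_next = t + np.random.exponential(1.0 / total)
            k = _record_until(out, c, t_weeks, k, t_next, a + b)
            if k >= T:
                break
            t = t_next
            if np.random.random() * total < a * lam:
                v = np.random.random()
                if v < r:
                    a += 1  # AA
                elif v < 2.0 * r:
                    a -= 1  # BB
                    b += 2
                else:
                    b += 1  # AB
            else:
                b -= 1  # stratification
    return out


@njit(cache=True)
def _grow(arr):
    new = np.empty(arr.shape[0] * 2, dtype=arr.dtype)
    new[: arr.shape[0]] = arr
    return new


@njit(cache=True)
def simulate_nonmarkov(n_clones, lam, r, gam, shape, t_weeks, seed, init_a, init_b):
    """Event-queue simulation with Gamma-distributed division times.

    Each A cell's division time is drawn at its birth from
    Gamma(shape, scale = 1/(lam*shape)); fates are (r, 1-2r, r) as in the
    Markovian engine; B cells stratify after Exp(1/gam) waits.  With
    shape = 1 the division-time law is exponential and the engine reproduces
    the Markov chain in distribution.
    """
    np.random.seed(seed)
    scale = 1.0 / (lam * shape)
    T = t_weeks.shape[0]
    out = np.zeros((n_clones, T), dtype=np.int64)
    for c in range(n_clones):
        div = np.empty(64, dtype=np.float64)  # pending division times (A cells)
        strat = np.empty(64, dtype=np.float64)  # pending stratification times (B)
        na = 0
        nb = 0
        for _ in range(init_a):
            div[na] = np.random.gamma(shape, scale)
            na += 1
        for _ in range(init_b):
            strat[nb] = np.random.exponential(1.0 / gam) if gam > 0.0 else np.inf
            nb += 1
        k = 0
        while k < T:
            # next event = earliest pending division or stratification
            i_min = -1
            t_next = np.inf
            for i in range(na):
                if div[i] < t_next:
                    t_next = div[i]
                    i_min = i
            j_min = -1
            for j in range(nb):
                if strat[j] < t_next:
                    t_next = strat[j]
                    j_min = j
            k = _record_until(out, c, t_weeks, k, t_next, na + nb)
            if k >= T:
                break
            if j_min >= 0:
                strat[j_min] = strat[nb - 1]
                nb -= 1
                continue
            if i_min < 0:
                # no pending events at all: clone extinct, sizes stay 0
                while k < T:
                    out[c, k] = na + nb
                    k += 1
                break
            # division of A cell i_min at time t_next
            v = np.random.random()
            if v < r:  # AA: reset mother clock, add daughter A
                div[i_min] = t_next + np.random.gamma(shape, scale)
                if na >= div.shape[0]:
                    div = _grow(div)
                div[na] = t_next + np.random.gamma(shape, scale)
                na += 1
            elif v < 2.0 * r:  # BB: remove A, add two Bs
                div[i_min] = div[na - 1]
                na -= 1
                if nb + 2 > strat.shape[0]:
                    strat = _grow(strat)
                strat[nb] = t_next + (
                    np.random.exponential(1.0 / gam) if gam > 0.0 else np.inf
                )
                strat[nb + 1] = t_next + (
                    np.random.exponential(1.0 / gam) if gam > 0.0 else np.inf
                )
                nb += 2
            else:  # AB: reset mother clock, add one B
                div[i_min] = t_next + np.random.gamma(shape, scale)
                if nb >= strat.shape[0]:
                    strat = _grow(strat)
                strat[nb] = t_next + (
                    np.random.exponential(1.0 / gam) if gam > 0.0 else np.inf
                )
                nb += 1
    return out
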