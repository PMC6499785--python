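"""Numba kernels: change statistics and the Metropolis-Hastings tie sampler.

The sampler proposes uniformly random dyad toggles on the social adjacency
``A`` and accepts with probability ``min(1, exp(theta . dz))`` where ``dz``
is the change-statistic vector of the toggle; the statistic vector ``z`` is
maintained incrementally.  Cross-level and ecological ties never move: they
enter only through the precomputed shared-species matrix ``m`` and actor
attribute arrays.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["seed", "change_stats", "run_chain"]


@njit(cache=False)
def seed(s):  # pragma: no cover - trivial
    np.random.seed(s)


@njit(cache=False)
def change_stats(A, deg, i, j, kinds, lams, asite, leader, site, m, out):
    """dz for adding tie (i, j); call with the tie absent from ``A``."""
    n = A.shape[0]
    for s in range(kinds.shape[0]):
        k = kinds[s]
        if k == 0:  # edge count
            out[s] = 1.0
        elif k == 1:  # two-star
            out[s] = deg[i] + deg[j]
        elif k == 2:  # alternating k-star
            lam = lams[s]
            r = 1.0 - 1.0 / lam
            out[s] = lam * (2.0 - r ** deg[i] - r ** deg[j])
        elif k == 3:  # alternating triangle
            lam = lams[s]
            r = 1.0 - 1.0 / lam
            pij = 0
            for t in range(n):
                if A[i, t] == 1 and A[j, t] == 1:
                    pij += 1
            acc = lam * (1.0 - r ** pij)
            # the new tie adds one two-path to every tie (i,t) with t~j
            # and every tie (j,t) with t~i, i.e. t a common neighbour
            for t in range(n):
                if A[i, t] == 1 and A[j, t] == 1:
                    pit = 0
                    pjt = 0
                    for u in range(n):
                        if A[i, u] == 1 and A[t, u] == 1:
                            pit += 1
                        if A[j, u] == 1 and A[t, u] == 1:
                            pjt += 1
                    acc += r ** pit + r ** pjt
            out[s] = acc
        elif k == 4:  # leader activity
            out[s] = leader[i] + leader[j]
        elif k == 5:  # landing-site homophily
            out[s] = 1.0 if site[i] == site[j] else 0.0
        elif k == 6:  # landing-site activity for one site
            a = asite[s]
            v = 0.0
            if site[i] == a:
                v += 1.0
            if site[j] == a:
                v += 1.0
            out[s] = v
        elif k == 7:  # cross-level closure
            out[s] = m[i, j]


@njit(cache=False)
def run_chain(A, deg, theta, kinds, lams, asite, leader, site, m, n_steps, z):
    """Advance the MH chain ``n_steps`` proposals in place; ``z`` tracks the
    statistic vector incrementally.  Returns the number of accepted moves."""
    n = A.shape[0]
    p = theta.shape[0]
    dz = np.empty(p, dtype=np.float64)
    accepted = 0
    for _ in range(n_steps):
        i = np.random.randint(0, n)
        j = np.random.randint(0, n)
        if i == j:
            continue
        present = A[i, j] == 1
        if present:
            A[i, j] = 0
            A[j, i] = 0
            deg[i] -= 1
            deg[j] -= 1
        change_stats(A, deg, i, j, kinds, lams, asite, leader, site, m, dz)
        lp = 0.0
        for s in range(p):
            lp += theta[s] * dz[s]
        if present:
            lp = -lp
        if lp >= 0.0 or np.random.random() < np.exp(lp):
            accepted += 1
            if present:
                for s in range(p):
                    z[s] -= dz[s]
            else:
                A[i, j] = 1
                A[j, i] = 1
                deg[i] += 1
                deg[j] += 1
                for s in range(p):
                    z[s] += dz[s]
        else:
            if present:
                A[i, j] = 1
                A[j, i] = 1
                deg[i] += 1
                deg[j] += 1
    return accepted
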