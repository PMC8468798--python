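"""Compiled coalescent genealogy samplers.

Hudson-style single-locus genealogies, no recombination: lineages are
followed backward in time, coalescing at rate k(k-1)/2 scaled by the epoch
size, with piecewise-exponential waiting times honoring epoch boundaries
exactly.  The kernels return summed branch lengths per frequency class (and
their squares, for Monte-Carlo standard errors); multiplying mean lengths by
theta/2 gives the expected infinite-sites mutation count per class.

Time is in units of 2*N_ANC generations throughout.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["sim_branch_1d", "sim_branch_2d"]


@njit(cache=False)
def sim_branch_1d(n, nus, ts, nu_anc, reps, seed):
    """Branch lengths per derived-allele class for a single population.

    ``nus``/``ts`` list the finite epochs most-recent-first; an infinite
    ancestral epoch of size ``nu_anc`` follows.  Returns (sum, sum of
    squares) arrays of length n+1 over replicates.
    """
    np.random.seed(seed)
    n_epochs = len(ts)
    total = np.zeros(n + 1)
    totalsq = np.zeros(n + 1)
    sz = np.empty(n, dtype=np.int64)
    for rep in range(reps):
        xi = np.zeros(n + 1)
        for i in range(n):
            sz[i] = 1
        k = n
        e = 0
        t_in = 0.0
        while k > 1:
            ck = k * (k - 1) / 2.0
            E = -np.log(np.random.random())
            # spend hazard across epochs until the coalescence lands
            while True:
                if e < n_epochs:
                    remain = ts[e] - t_in
                    cap = remain * ck / nus[e]
                    if E <= cap:
                        dt = E * nus[e] / ck
                        for i in range(k):
                            xi[sz[i]] += dt
                        t_in += dt
                        break
                    for i in range(k):
                        xi[sz[i]] += remain
                    E -= cap
                    e += 1
                    t_in = 0.0
                else:
                    dt = E * nu_anc / ck
                    for i in range(k):
                        xi[sz[i]] += dt
                    break
            # coalesce a uniform pair
            i = int(np.random.random() * k)
            j = int(np.random.random() * (k - 1))
            if j >= i:
                j += 1
            lo = i if i < j else j
            hi = j if i < j else i
            sz[lo] = sz[lo] + sz[hi]
            sz[hi] = sz[k - 1]
            k -= 1
        for c in range(n + 1):
            total[c] += xi[c]
            totalsq[c] += xi[c] * xi[c]
    return total, totalsq


@njit(cache=False)
def sim_branch_2d(n1, n2, nu1, nu2, T, m12, m21, nu_anc, reps, seed):
    """Branch lengths per joint frequency class under a two-deme split model.

    Backward in time: two demes of sizes ``nu1``/``nu2`` exchange lineages
    (a deme-1 lineage hops to deme 2 at rate ``m12``) until the split time
    ``T``, after which all lineages share one ancestral deme of size
    ``nu_anc``.  Returns (sum, sum of squares) over the (n1+1, n2+1) grid.
    """
    np.random.seed(seed)
    ntot = n1 + n2
    total = np.zeros((n1 + 1, n2 + 1))
    totalsq = np.zeros((n1 + 1, n2 + 1))
    a = np.empty(ntot, dtype=np.int64)
    b = np.empty(ntot, dtype=np.int64)
    deme = np.empty(ntot, dtype=np.int64)
    for rep in range(reps):
        xi = np.zeros((n1 + 1, n2 + 1))
        for i in range(n1):
            a[i] = 1
            b[i] = 0
            deme[i] = 0
        for i in range(n1, ntot):
            a[i] = 0
            b[i] = 1
            deme[i] = 1
        k = ntot
        t = 0.0
        # structured phase, from the present back to the split at T
        while k > 1 and t < T:
            k0 = 0
            for i in range(k):
                if deme[i] == 0:
                    k0 += 1
            k1 = k - k0
            r_c0 = k0 * (k0 - 1) / 2.0 / nu1
            r_c1 = k1 * (k1 - 1) / 2.0 / nu2
            r_m0 = k0 * m12
            r_m1 = k1 * m21
            rate = r_c0 + r_c1 + r_m0 + r_m1
            if rate <= 0.0:
                for i in range(k):
                    xi[a[i], b[i]] += T - t
                t = T
                break
            dt = -np.log(np.random.random()) / rate
            if t + dt >= T:
                for i in range(k):
                    xi[a[i], b[i]] += T - t
                t = T
                break
            for i in range(k):
                xi[a[i], b[i]] += dt
            t += dt
            u = np.random.random() * rate
            if u < r_c0 + r_c1:
                d = 0 if u < r_c0 else 1
                kd = k0 if d == 0 else k1
                i = int(np.random.random() * kd)
                j = int(np.random.random() * (kd - 1))
                if j >= i:
                    j += 1
                # map within-deme indices to global indices
                gi = -1
                gj = -1
                seen = 0
                for g in range(k):
                    if deme[g] == d:
                        if seen == i:
                            gi = g
                        if seen == j:
                            gj = g
                        seen += 1
                lo = gi if gi < gj else gj
                hi = gj if gi < gj else gi
                a[lo] += a[hi]
                b[lo] += b[hi]
                a[hi] = a[k - 1]
                b[hi] = b[k - 1]
                deme[hi] = deme[k - 1]
                k -= 1
            else:
                d = 0 if u < r_c0 + r_c1 + r_m0 else 1
                kd = k0 if d == 0 else k1
                i = int(np.random.random() * kd)
                seen = 0
                for g in range(k):
                    if deme[g] == d:
                        if seen == i:
                            deme[g] = 1 - d
                            break
                        seen += 1
        # ancestral panmictic phase
        while k > 1:
            ck = k * (k - 1) / 2.0
            dt = -np.log(np.random.random()) * nu_anc / ck
            for i in range(k):
                xi[a[i], b[i]] += dt
            i = int(np.random.random() * k)
            j = int(np.random.random() * (k - 1))
            if j >= i:
                j += 1
            lo = i if i < j else j
            hi = j if i < j else i
            a[lo] += a[hi]
            b[lo] += b[hi]
            a[hi] = a[k - 1]
            b[hi] = b[k - 1]
            deme[hi] = deme[k - 1]
            k -= 1
        for ci in range(n1 + 1):
            for cj in range(n2 + 1):
                total[ci, cj] += xi[ci, cj]
                totalsq[ci, cj] += xi[ci, cj] * xi[ci, cj]
    return total, totalsq
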