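"""Numba kernels: batched coalescent simulation of microsatellite loci.

Everything here is a flat-loop re-statement of the standard n-coalescent
under piecewise-constant diploid effective size.  Per replicate: exponential
waiting times with epoch-boundary carry-over (memorylessness lets the
residual standard-exponential deviate be re-scaled by the next epoch's
rate), uniform random pair merges, then Poisson numbers of mutations per
branch propagated root-to-tips.  Node ids are assigned in coalescence order,
so a parent id always exceeds its children's ids and a single reverse sweep
resolves every tip state.

Mutation model codes: 0 = strict stepwise (SMM, +/-1), 1 = infinite alleles
(IAM, every mutation creates a novel label), 2 = generalized/two-phase
(single step with probability ``1 - p_multi``, otherwise a +/- geometric
step with parameter ``p_geom``; ``p_multi = 1`` gives the GSM).
"""

import numpy as np
from numba import njit

SMM = 0
IAM = 1
GEN = 2


@njit(cache=False)
def _geometric(p):
    u = np.random.random()
    g = int(np.ceil(np.log1p(-u) / np.log1p(-p)))
    return g if g > 0 else 1


@njit(cache=False)
def _sim_tips(n, starts, sizes, E, scale, mu, model, p_multi, p_geom,
              parent, ntime, values, active):
    """Simulate one locus genealogy + mutations; tip states in values[:n]."""
    for i in range(n):
        ntime[i] = 0.0
        active[i] = i
    t = 0.0
    ep = 0
    for step in range(n - 1):
        j = n - step
        pairs = 0.5 * j * (j - 1)
        e = np.random.exponential(1.0)
        while ep < E - 1 and t >= starts[ep + 1]:
            ep += 1
        while True:
            rate = pairs / (2.0 * sizes[ep] * scale)
            if ep < E - 1:
                cap = (starts[ep + 1] - t) * rate
                if e > cap:
                    e -= cap
                    t = starts[ep + 1]
                    ep += 1
                    continue
            t += e / rate
            break
        node = n + step
        ntime[node] = t
        a = np.random.randint(0, j)
        b = np.random.randint(0, j - 1)
        if b >= a:
            b += 1
        parent[active[a]] = node
        parent[active[b]] = node
        active[a] = node
        active[b] = active[j - 1]
    root = 2 * n - 2
    values[root] = 0
    for i in range(root - 1, -1, -1):
        blen = ntime[parent[i]] - ntime[i]
        m = np.random.poisson(mu * blen)
        if m == 0:
            values[i] = values[parent[i]]
        elif model == IAM:
            values[i] = i + 1  # novel label, unique per branch
        elif model == SMM:
            values[i] = values[parent[i]] + 2 * np.random.binomial(m, 0.5) - m
        else:
            net = 0
            for _ in range(m):
                if np.random.random() < p_multi:
                    s = _geometric(p_geom)
                else:
                    s = 1
                if np.random.random() < 0.5:
                    net -= s
                else:
                    net += s
            values[i] = values[parent[i]] + net


@njit(cache=False)
def _k_he(n, values, counts):
    """Allele count and unbiased gene diversity of tip states values[:n]."""
    lo = values[0]
    hi = values[0]
    for i in range(1, n):
        v = values[i]
        if v < lo:
            lo = v
        if v > hi:
            hi = v
    span = hi - lo + 1
    K = 0
    sumsq = 0.0
    if span <= counts.shape[0]:
        for i in range(span):
            counts[i] = 0
        for i in range(n):
            counts[values[i] - lo] += 1
        for i in range(span):
            c = counts[i]
            if c > 0:
                K += 1
                sumsq += float(c) * c
    else:  # huge allele-size span: fall back to sorting
        tips = np.sort(values[:n])
        K = 1
        c = 1
        for i in range(1, n):
            if tips[i] == tips[i - 1]:
                c += 1
            else:
                sumsq += float(c) * c
                c = 1
                K += 1
        sumsq += float(c) * c
    he = n / (n - 1.0) * (1.0 - sumsq / (float(n) * n))
    return K, he


@njit(cache=False)
def sim_msat_stats(n, starts, sizes, scale, mu, model, p_multi, p_geom, seed):
    """Batched locus simulation returning (K, He) per replicate.

    starts, sizes: (R, E) epoch start generations / diploid sizes per
    replicate; mu, p_multi, p_geom: (R,) per-replicate mutation parameters.
    """
    R, E = starts.shape
    np.random.seed(seed)
    parent = np.empty(2 * n - 1, np.int64)
    ntime = np.empty(2 * n - 1, np.float64)
    values = np.empty(2 * n - 1, np.int64)
    active = np.empty(n, np.int64)
    counts = np.zeros(4 * n + 4, np.int64)
    K = np.empty(R, np.int64)
    He = np.empty(R, np.float64)
    for r in range(R):
        _sim_tips(n, starts[r], sizes[r], E, scale, mu[r], model,
                  p_multi[r], p_geom[r], parent, ntime, values, active)
        K[r], He[r] = _k_he(n, values, counts)
    return K, He


@njit(cache=False)
def sim_msat_tips(n, starts, sizes, scale, mu, model, p_multi, p_geom, seed):
    """Batched locus simulation returning raw tip allele states (R, n)."""
    R, E = starts.shape
    np.random.seed(seed)
    parent = np.empty(2 * n - 1, np.int64)
    ntime = np.empty(2 * n - 1, np.float64)
    values = np.empty(2 * n - 1, np.int64)
    active = np.empty(n, np.int64)
    tips = np.empty((R, n), np.int64)
    for r in range(R):
        _sim_tips(n, starts[r], sizes[r], E, scale, mu[r], model,
                  p_multi[r], p_geom[r], parent, ntime, values, active)
        tips[r, :] = values[:n]
    return tips


@njit(cache=False)
def sim_tmrca(n, starts, sizes, scale, n_reps, seed):
    """Batched time-to-MRCA (generations) under a piecewise-constant scenario."""
    E = starts.shape[0]
    np.random.seed(seed)
    out = np.empty(n_reps, np.float64)
    for r in range(n_reps):
        t = 0.0
        ep = 0
        for step in range(n - 1):
            j = n - step
            pairs = 0.5 * j * (j - 1)
            e = np.random.exponential(1.0)
            while ep < E - 1 and t >= starts[ep + 1]:
                ep += 1
            while True:
                rate = pairs / (2.0 * sizes[ep] * scale)
                if ep < E - 1:
                    cap = (starts[ep + 1] - t) * rate
                    if e > cap:
                        e -= cap
                        t = starts[ep + 1]
                        ep += 1
                        continue
                t += e / rate
                break
        out[r] = t
    return out
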