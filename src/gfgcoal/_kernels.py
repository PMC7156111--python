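"""Numba-compiled inner loops.

Everything in here is an implementation detail: the public modules
(:mod:`gfgcoal.dynamics`, :mod:`gfgcoal.forward`, :mod:`gfgcoal.coalescent`)
wrap these kernels with validated, documented interfaces.

All kernels take an explicit ``seed`` and call ``np.random.seed`` on numba's
internal RNG state, so every simulation is replayable from integer seeds
derived from a master :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Guard against 0/0 in the deterministic recursion; denominators this small
# only arise when the corresponding numerator is exactly 0 (empty class).
_DENOM_TINY = 1e-300


@njit(cache=True)
def gfg_step(R, a1, s1, s2, c_h, c_p):
    """One deterministic generation of the gene-for-gene recursion.

    Returns (a2, a1_next, R_next).  A vanishing denominator with a vanishing
    numerator is an empty-class corner (e.g. all hosts resistant, no
    infective parasites) and yields frequency 0 for that class.
    """
    A1 = 1.0 - a1
    r = 1.0 - R
    # within-generation second infection cycle
    num_a = a1 * (1.0 - c_p)
    den_a = num_a + A1 * r
    a2 = num_a / den_a if den_a > _DENOM_TINY else 0.0
    A2 = 1.0 - a2
    # parasite allele frequency carried to the next host generation
    num_b = (1.0 - c_p) * (R * (A1 * a2 + a1) + r * a1)
    den_b = num_b + r * A1
    a1n = num_b / den_b if den_b > _DENOM_TINY else 0.0
    # host allele frequency after selection
    num_c = R * (1.0 - c_h) * (A1 * A2 + A1 * a2 * (1.0 - s2) + a1 * (1.0 - s1))
    den_c = num_c + r * (1.0 - s1)
    Rn = num_c / den_c if den_c > _DENOM_TINY else 0.0
    return a2, a1n, Rn


@njit(cache=True)
def forward_kernel(seed, g_max, N_H, N_P, s, c_h, c_p,
                   mu_Rtor, mu_rtoR, mu_ntoI, mu_Iton, R0, a0):
    """Stochastic frequency path: deterministic step, binomial drift,
    recurrent functional mutation, for ``g_max`` host generations.

    Returns integer count arrays (host RES, parasite INF), each of length
    ``g_max + 1``; entry ``g`` is the post-drift post-mutation count at the
    start of host generation ``g``.
    """
    np.random.seed(seed)
    host = np.empty(g_max + 1, dtype=np.int64)
    para = np.empty(g_max + 1, dtype=np.int64)
    hc = int(round(R0 * N_H))
    pc = int(round(a0 * N_P))
    host[0] = hc
    para[0] = pc
    s1 = s
    s2 = 0.5 * s
    for g in range(g_max):
        R = hc / N_H
        a1 = pc / N_P
        a2, a1n, Rn = gfg_step(R, a1, s1, s2, c_h, c_p)
        # host: drift then mutation, counts of switching individuals
        c = np.random.binomial(N_H, Rn)
        c += np.random.binomial(N_H - c, mu_rtoR) - np.random.binomial(c, mu_Rtor)
        if c < 0:
            c = 0
        elif c > N_H:
            c = N_H
        hc = c
        host[g + 1] = hc
        # parasite: drift/mutation applied once per host generation on a_{g+1,1}
        c = np.random.binomial(N_P, a1n)
        c += np.random.binomial(N_P - c, mu_ntoI) - np.random.binomial(c, mu_Iton)
        if c < 0:
            c = 0
        elif c > N_P:
            c = N_P
        pc = c
        para[g + 1] = pc
    return host, para


@njit(cache=True)
def iterate_kernel(g_max, s, c_h, c_p, R0, a0):
    """Deterministic (infinite population) iteration of the recursion.

    Returns arrays (R, a1, a2) of length ``g_max + 1``; ``a2[0]`` is the
    within-generation value computed from the initial state.
    """
    s1 = s
    s2 = 0.5 * s
    R_tr = np.empty(g_max + 1, dtype=np.float64)
    a1_tr = np.empty(g_max + 1, dtype=np.float64)
    a2_tr = np.empty(g_max + 1, dtype=np.float64)
    R = R0
    a1 = a0
    for g in range(g_max + 1):
        R_tr[g] = R
        a1_tr[g] = a1
        a2, a1n, Rn = gfg_step(R, a1, s1, s2, c_h, c_p)
        a2_tr[g] = a2
        R = Rn
        a1 = a1n
    return R_tr, a1_tr, a2_tr


@njit(cache=True)
def _no_collision_prob(k, X):
    """P(no two of k lineages pick the same of X parents)."""
    p = 1.0
    for i in range(1, k):
        f = 1.0 - i / X
        if f <= 0.0:
            return 0.0
        p *= f
    return p


@njit(cache=True)
def _merge_class(lin, cls, idxbuf, kc, Xp, parent, time, m, tau):
    """Draw a parent assignment for kc lineages among Xp parents conditioned
    on at least one collision; merge colliding groups at time ``tau``.

    Mutates lin/cls/parent/time in place; dead lineage slots get lin = -1.
    Returns the updated next-node id ``m``.
    """
    pids = np.empty(kc, dtype=np.int64)
    while True:
        dup = False
        for j in range(kc):
            pids[j] = np.random.randint(0, Xp)
        for j in range(kc):
            for j2 in range(j + 1, kc):
                if pids[j] == pids[j2]:
                    dup = True
                    break
            if dup:
                break
        if dup:
            break
    done = np.zeros(kc, dtype=np.uint8)
    for j in range(kc):
        if done[j]:
            continue
        gsize = 1
        for j2 in range(j + 1, kc):
            if pids[j2] == pids[j]:
                gsize += 1
        if gsize >= 2:
            # multifurcating WF merge: identical parent choices coalesce
            time[m] = tau
            for j2 in range(j, kc):
                if pids[j2] == pids[j]:
                    done[j2] = 1
                    parent[lin[idxbuf[j2]]] = m
                    if j2 == j:
                        lin[idxbuf[j2]] = m
                    else:
                        lin[idxbuf[j2]] = -1
            m += 1
        else:
            done[j] = 1
    return m


@njit(cache=True)
def _compact(lin, cls, k):
    """Remove dead (-1) lineage slots; returns the new lineage count."""
    w = 0
    for i in range(k):
        if lin[i] >= 0:
            lin[w] = lin[i]
            cls[w] = cls[i]
            w += 1
    return w


@njit(cache=True)
def genealogy_kernel(seed, counts, N, mu_gain, mu_loss, k_der, k_anc):
    """Structured coalescent conditioned on a derived-allele count path.

    ``counts[g]`` is the derived count at generation index ``g``; index
    ``len(counts)-1`` is the present, index 0 the oldest conditioned
    generation.  Backward per-generation steps implement, in order:
    lineage migration between allelic classes (the backward shadow of
    forward functional mutation), the allele-origin rule when a class size
    hits 0, and Wright-Fisher parent choice within classes (identical
    choices merge, forced mergers arise automatically when lineages exceed
    the class size).  Older than the path, a single panmictic class of size
    ``N`` coalesces as a discrete Kingman process, accelerated by geometric
    waiting-time sampling (exact: class size is constant between events).

    Returns (parent, time, n_nodes, root, conditioned_steps).
    """
    np.random.seed(seed)
    n = k_der + k_anc
    max_nodes = 2 * n - 1 if n > 1 else 1
    parent = np.full(max_nodes, -1, dtype=np.int64)
    time = np.zeros(max_nodes, dtype=np.float64)
    lin = np.empty(n, dtype=np.int64)
    cls = np.empty(n, dtype=np.uint8)
    idxbuf = np.empty(n, dtype=np.int64)
    for i in range(n):
        lin[i] = i
        cls[i] = 1 if i < k_der else 0
    k = n
    m = n
    G = counts.shape[0] - 1
    tau = 0.0
    steps = 0

    g = G
    while g >= 1 and k > 1:
        Xd_now = counts[g]
        Xd_prev = counts[g - 1]
        Xa_now = N - Xd_now
        Xa_prev = N - Xd_prev
        tau += 1.0
        steps += 1

        # (1) migration, evaluated on a snapshot of class membership
        kd = 0
        ka = 0
        for i in range(k):
            if cls[i] == 1:
                kd += 1
            else:
                ka += 1
        if kd > 0 and Xd_now > 0 and mu_gain > 0.0 and Xa_prev > 0:
            p = mu_gain * Xa_prev / Xd_now
            if p > 1.0:
                p = 1.0
            nmig = np.random.binomial(kd, p)
            while nmig > 0:
                i = np.random.randint(0, k)
                if cls[i] == 1:
                    cls[i] = 0
                    nmig -= 1
        if ka > 0 and Xa_now > 0 and mu_loss > 0.0 and Xd_prev > 0:
            p = mu_loss * Xd_prev / Xa_now
            if p > 1.0:
                p = 1.0
            nmig = np.random.binomial(ka, p)
            while nmig > 0:
                i = np.random.randint(0, k)
                if cls[i] == 0:
                    cls[i] = 1
                    nmig -= 1

        # (2) per class: allele origin or WF parent choice
        for c in range(2):
            cc = 1 - c  # derived class first
            Xp = Xd_prev if cc == 1 else Xa_prev
            kc = 0
            for i in range(k):
                if lin[i] >= 0 and cls[i] == cc:
                    idxbuf[kc] = i
                    kc += 1
            if kc == 0:
                continue
            if Xp == 0:
                # allele origin: coalesce to the founding mutant, which
                # migrates to the other class
                if kc >= 2:
                    time[m] = tau
                    for j in range(kc):
                        parent[lin[idxbuf[j]]] = m
                        lin[idxbuf[j]] = -1 if j > 0 else m
                    m += 1
                cls[idxbuf[0]] = 1 - cc
            elif kc >= 2:
                p_noc = _no_collision_prob(kc, Xp)
                if np.random.random() >= p_noc:
                    m = _merge_class(lin, cls, idxbuf, kc, Xp, parent, time, m, tau)
            k2 = _compact(lin, cls, k)
            # recompute on compacted arrays for the second class
            k = k2
        g -= 1

    # (3) neutral Kingman tail: single exchangeable class of size N
    while k > 1:
        p_noc = _no_collision_prob(k, N)
        p_any = 1.0 - p_noc
        if p_any < 1.0:
            u = np.random.random()
            gap = int(np.ceil(np.log(u) / np.log(p_noc)))
            if gap < 1:
                gap = 1
        else:
            gap = 1
        tau += gap
        kc = 0
        for i in range(k):
            idxbuf[kc] = i
            kc += 1
        m = _merge_class(lin, cls, idxbuf, kc, N, parent, time, m, tau)
        k = _compact(lin, cls, k)

    root = lin[0]
    return parent[:m], time[:m], m, root, steps
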