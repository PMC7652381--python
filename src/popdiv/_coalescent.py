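"""Structured-coalescent event kernels (numba-jitted).

Backward-time two-deme coalescent with piecewise-constant migration in two
epochs and a merge into a single ancestral deme at ``T_div``.  Event
scheduling uses exponential competing risks: within deme ``d`` holding
``k_d`` lineages, a coalescence occurs at rate ``k_d (k_d - 1) / (4 N_d)``
per generation, and each lineage in deme ``d`` migrates (backward) to the
other deme at the epoch's per-lineage rate.

Branch lengths are tracked by birth time, so every event costs O(1): a
lineage's branch is flushed (into the joint-SFS grid, or emitted as a
branch record) only when it coalesces.  Active lineages live in one
index list per deme with swap-removal.

Two kernels share this event loop:

* :func:`expected_sfs_kernel` tracks, per lineage, how many population-1
  and population-2 leaves it subtends and accumulates branch length into
  the joint-SFS cell ``(i, j)`` — the Monte-Carlo expected spectrum used
  by the composite likelihood.  It is the fit's hot path, run millions of
  genealogies deep.
* :func:`branches_kernel` tracks the full leaf set of every branch as a
  64-bit mask and returns (mask, length) pairs per locus, from which the
  genotype simulator drops infinite-sites mutations.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["expected_sfs_kernel", "branches_kernel"]

_INF = 1.0e30


@njit(cache=True)
def expected_sfs_kernel(
    n1h, n2h, N1, N2, Nanc, Tchange, Tdiv,
    m1_recent, m2_recent, m1_early, m2_early,
    n_genealogies, seed,
):
    """Accumulate branch length per joint-SFS cell over many genealogies.

    Returns an ``(n1h+1, n2h+1)`` float64 array of total branch length;
    cell ``(i, j)`` collects length of branches subtending ``i``
    population-1 and ``j`` population-2 leaves.  The root branch is not
    accumulated, so the monomorphic corners stay zero.
    """
    np.random.seed(seed)
    grid = np.zeros((n1h + 1, n2h + 1))
    n = n1h + n2h
    ci = np.empty(n, np.int64)
    cj = np.empty(n, np.int64)
    birth = np.empty(n, np.float64)
    # per-deme index lists with back-pointers
    lst = np.empty((2, n), np.int64)
    kd = np.empty(2, np.int64)
    deme = np.empty(n, np.int64)
    pos = np.empty(n, np.int64)

    for _ in range(n_genealogies):
        for l in range(n1h):
            ci[l] = 1
            cj[l] = 0
            deme[l] = 0
        for l in range(n1h, n):
            ci[l] = 0
            cj[l] = 1
            deme[l] = 1
        for l in range(n):
            birth[l] = 0.0
        kd[0] = n1h
        kd[1] = n2h
        for l in range(n1h):
            lst[0, l] = l
            pos[l] = l
        for l in range(n2h):
            lst[1, l] = n1h + l
            pos[n1h + l] = l
        k = n
        t = 0.0
        merged = Tdiv <= 0.0
        if merged and n2h > 0:
            # fold deme 2 into deme 1 up front
            for p in range(kd[1]):
                l = lst[1, p]
                lst[0, kd[0]] = l
                pos[l] = kd[0]
                deme[l] = 0
                kd[0] += 1
            kd[1] = 0

        while k > 1:
            if merged:
                m1 = 0.0
                m2 = 0.0
                s1 = Nanc
                s2 = Nanc
                epoch_end = _INF
            elif t < Tchange:
                m1 = m1_recent
                m2 = m2_recent
                s1 = N1
                s2 = N2
                epoch_end = Tchange
            else:
                m1 = m1_early
                m2 = m2_early
                s1 = N1
                s2 = N2
                epoch_end = Tdiv

            k1 = kd[0]
            k2 = kd[1]
            rc1 = k1 * (k1 - 1) / (4.0 * s1)
            rc2 = k2 * (k2 - 1) / (4.0 * s2)
            rm = k1 * m1 + k2 * m2
            total = rc1 + rc2 + rm
            if total <= 0.0:
                t = epoch_end
            else:
                t = t + np.random.exponential(1.0 / total)
            if t >= epoch_end:
                t = epoch_end
                if not merged and t >= Tdiv:
                    merged = True
                    for p in range(kd[1]):
                        l = lst[1, p]
                        lst[0, kd[0]] = l
                        pos[l] = kd[0]
                        deme[l] = 0
                        kd[0] += 1
                    kd[1] = 0
                continue

            u = np.random.random() * total
            if u < rc1 + rc2:
                d = 0 if u < rc1 else 1
                nd = kd[d]
                p = np.random.randint(nd)
                q = np.random.randint(nd - 1)
                if q >= p:
                    q += 1
                a = lst[d, p]
                b = lst[d, q]
                grid[ci[a], cj[a]] += t - birth[a]
                grid[ci[b], cj[b]] += t - birth[b]
                ci[a] += ci[b]
                cj[a] += cj[b]
                birth[a] = t
                # swap-remove b from deme list d
                qq = pos[b]
                last = lst[d, nd - 1]
                lst[d, qq] = last
                pos[last] = qq
                kd[d] -= 1
                k -= 1
            else:
                u -= rc1 + rc2
                d = 0 if u < k1 * m1 else 1
                nd = kd[d]
                p = np.random.randint(nd)
                l = lst[d, p]
                last = lst[d, nd - 1]
                lst[d, p] = last
                pos[last] = p
                kd[d] -= 1
                o = 1 - d
                lst[o, kd[o]] = l
                pos[l] = kd[o]
                kd[o] += 1
                deme[l] = o
    return grid


@njit(cache=True)
def branches_kernel(
    deme0, n_loci, N1, N2, Nanc, Tchange, Tdiv,
    m1_recent, m2_recent, m1_early, m2_early,
    seed,
):
    """Simulate ``n_loci`` independent genealogies, returning every branch.

    ``deme0`` assigns each of the ``n`` sampled lineages (n <= 64) to its
    deme.  Returns ``(masks, lengths)`` of shape ``(n_loci, 2n-2)``:
    branch ``b`` of a locus subtends the leaves set in ``masks[locus, b]``
    (bit ``l`` = lineage ``l``) and has total length ``lengths[locus, b]``
    in generations.  The root branch is not emitted.
    """
    n = deme0.shape[0]
    n_branches = 2 * (n - 1)
    masks = np.zeros((n_loci, n_branches), np.uint64)
    lengths = np.zeros((n_loci, n_branches), np.float64)
    np.random.seed(seed)

    mask = np.empty(n, np.uint64)
    birth = np.empty(n, np.float64)
    lst = np.empty((2, n), np.int64)
    kd = np.empty(2, np.int64)
    deme = np.empty(n, np.int64)
    pos = np.empty(n, np.int64)

    for locus in range(n_loci):
        kd[0] = 0
        kd[1] = 0
        for l in range(n):
            mask[l] = np.uint64(1) << np.uint64(l)
            birth[l] = 0.0
            d0 = deme0[l]
            deme[l] = d0
            lst[d0, kd[d0]] = l
            pos[l] = kd[d0]
            kd[d0] += 1
        k = n
        t = 0.0
        merged = Tdiv <= 0.0
        if merged:
            for p in range(kd[1]):
                l = lst[1, p]
                lst[0, kd[0]] = l
                pos[l] = kd[0]
                deme[l] = 0
                kd[0] += 1
            kd[1] = 0
        out = 0

        while k > 1:
            if merged:
                m1 = 0.0
                m2 = 0.0
                s1 = Nanc
                s2 = Nanc
                epoch_end = _INF
            elif t < Tchange:
                m1 = m1_recent
                m2 = m2_recent
                s1 = N1
                s2 = N2
                epoch_end = Tchange
            else:
                m1 = m1_early
                m2 = m2_early
                s1 = N1
                s2 = N2
                epoch_end = Tdiv

            k1 = kd[0]
            k2 = kd[1]
            rc1 = k1 * (k1 - 1) / (4.0 * s1)
            rc2 = k2 * (k2 - 1) / (4.0 * s2)
            rm = k1 * m1 + k2 * m2
            total = rc1 + rc2 + rm
            if total <= 0.0:
                t = epoch_end
            else:
                t = t + np.random.exponential(1.0 / total)
            if t >= epoch_end:
                t = epoch_end
                if not merged and t >= Tdiv:
                    merged = True
                    for p in range(kd[1]):
                        l = lst[1, p]
                        lst[0, kd[0]] = l
                        pos[l] = kd[0]
                        deme[l] = 0
                        kd[0] += 1
                    kd[1] = 0
                continue

            u = np.random.random() * total
            if u < rc1 + rc2:
                d = 0 if u < rc1 else 1
                nd = kd[d]
                p = np.random.randint(nd)
                q = np.random.randint(nd - 1)
                if q >= p:
                    q += 1
                a = lst[d, p]
                b = lst[d, q]
                masks[locus, out] = mask[a]
                lengths[locus, out] = t - birth[a]
                out += 1
                masks[locus, out] = mask[b]
                lengths[locus, out] = t - birth[b]
                out += 1
                mask[a] = mask[a] | mask[b]
                birth[a] = t
                qq = pos[b]
                last = lst[d, nd - 1]
                lst[d, qq] = last
                pos[last] = qq
                kd[d] -= 1
                k -= 1
            else:
                u -= rc1 + rc2
                d = 0 if u < k1 * m1 else 1
                nd = kd[d]
                p = np.random.randint(nd)
                l = lst[d, p]
                last = lst[d, nd - 1]
                lst[d, p] = last
                pos[last] = p
                kd[d] -= 1
                o = 1 - d
                lst[o, kd[o]] = l
                pos[l] = kd[o]
                kd[o] += 1
                deme[l] = o
    return masks, lengths
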