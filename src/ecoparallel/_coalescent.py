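"""Structured-coalescent event loop (numba-compiled).

Simulates genealogies of samples spread over up to four demes backward in
time: within-deme coalescence at rate k(k-1)/(4*Ne) (Ne diploid), backward
migration of each lineage at per-generation rate m[d, j], and deme mergers
at fixed times (a merger moves every lineage of the source deme into the
destination deme, resizes the destination and removes the source from the
migration matrix).

A lineage is represented only by its integer *configuration code*: the
number of sampled haploids of each deme descending from it, flattened with
fixed strides.  The code is linear in the configuration, so coalescence is
code addition.  Branch lengths are accumulated per code; under infinite
sites the expected number of segregating sites with a given joint allele
configuration is proportional to the accumulated length of branches with
that code.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# maximum demes handled by the fixed-width code
NDEME = 4


@njit(cache=True)
def _strides(dims):
    s = np.empty(NDEME, np.int64)
    s[NDEME - 1] = 1
    for d in range(NDEME - 2, -1, -1):
        s[d] = s[d + 1] * dims[d + 1]
    return s


@njit(cache=True)
def _one_tree(n_per, ne_in, mig_in, mtimes, msrc, mdst, mne, strides, cfg,
              max_events):
    """Simulate one genealogy; accumulate branch lengths by config code into cfg.

    Returns the TMRCA (generations), or -1.0 if the event budget was exceeded
    (runaway migration regimes), in which case cfg contributions are partial.
    """
    ne = ne_in.copy()
    mig = mig_in.copy()
    ntot = 0
    for d in range(NDEME):
        ntot += n_per[d]
    codes = np.empty(ntot, np.int64)
    deme = np.empty(ntot, np.int64)
    k = 0
    for d in range(NDEME):
        for _ in range(n_per[d]):
            codes[k] = strides[d]
            deme[k] = d
            k += 1
    cnt = np.zeros(NDEME, np.int64)
    for d in range(NDEME):
        cnt[d] = n_per[d]
    mrow = np.zeros(NDEME)
    for d in range(NDEME):
        s = 0.0
        for j in range(NDEME):
            s += mig[d, j]
        mrow[d] = s

    nact = ntot
    t = 0.0
    ev = 0
    nmerge = len(mtimes)
    coal = np.zeros(NDEME)
    n_events = 0
    while nact > 1:
        n_events += 1
        if n_events > max_events:
            return -1.0
        rtot = 0.0
        for d in range(NDEME):
            kd = cnt[d]
            c = kd * (kd - 1) / (4.0 * ne[d])
            coal[d] = c
            rtot += c + kd * mrow[d]
        tb = mtimes[ev] if ev < nmerge else np.inf
        if rtot <= 0.0:
            dt = tb - t
        else:
            dt = np.random.exponential(1.0 / rtot)
        if t + dt >= tb:
            # advance to the boundary, apply all merges scheduled there
            step = tb - t
            for li in range(nact):
                cfg[codes[li]] += step
            t = tb
            while ev < nmerge and mtimes[ev] <= t:
                src = msrc[ev]
                dst = mdst[ev]
                for li in range(nact):
                    if deme[li] == src:
                        deme[li] = dst
                cnt[dst] += cnt[src]
                cnt[src] = 0
                ne[dst] = mne[ev]
                for j in range(NDEME):
                    mig[src, j] = 0.0
                    mig[j, src] = 0.0
                for d in range(NDEME):
                    s = 0.0
                    for j in range(NDEME):
                        s += mig[d, j]
                    mrow[d] = s
                ev += 1
            continue
        for li in range(nact):
            cfg[codes[li]] += dt
        t += dt
        # pick the event
        r = np.random.random() * rtot
        d_ev = -1
        is_coal = False
        for d in range(NDEME):
            if r < coal[d]:
                d_ev = d
                is_coal = True
                break
            r -= coal[d]
            mr = cnt[d] * mrow[d]
            if r < mr:
                d_ev = d
                break
            r -= mr
        if d_ev < 0:  # numerical edge: take the last deme with lineages
            for d in range(NDEME - 1, -1, -1):
                if cnt[d] > 0:
                    d_ev = d
                    is_coal = cnt[d] > 1
                    break
        if is_coal:
            a_r = np.random.randint(cnt[d_ev])
            b_r = np.random.randint(cnt[d_ev] - 1)
            if b_r >= a_r:
                b_r += 1
            ia = -1
            ib = -1
            seen = 0
            for li in range(nact):
                if deme[li] == d_ev:
                    if seen == a_r:
                        ia = li
                    if seen == b_r:
                        ib = li
                    seen += 1
            codes[ia] += codes[ib]
            codes[ib] = codes[nact - 1]
            deme[ib] = deme[nact - 1]
            nact -= 1
            cnt[d_ev] -= 1
        else:
            # migration out of d_ev
            a_r = np.random.randint(cnt[d_ev])
            ia = -1
            seen = 0
            for li in range(nact):
                if deme[li] == d_ev:
                    if seen == a_r:
                        ia = li
                        break
                    seen += 1
            r2 = np.random.random() * mrow[d_ev]
            dest = -1
            for j in range(NDEME):
                if r2 < mig[d_ev, j]:
                    dest = j
                    break
                r2 -= mig[d_ev, j]
            if dest < 0:
                for j in range(NDEME - 1, -1, -1):
                    if mig[d_ev, j] > 0:
                        dest = j
                        break
            if dest >= 0:
                deme[ia] = dest
                cnt[d_ev] -= 1
                cnt[dest] += 1
    return t


@njit(cache=True)
def sim_branch_lengths(n_per, ne, mig, mtimes, msrc, mdst, mne, n_trees, seed,
                       max_events_per_tree=1_000_000):
    """Accumulate config-coded branch lengths over n_trees genealogies.

    Returns (cfg_lengths, tmrca) where cfg_lengths is a flat array indexed by
    config code and tmrca holds per-tree heights.  A negative tmrca[0] flags
    an exceeded per-tree event budget (the whole call should be discarded).
    """
    np.random.seed(seed)
    dims = np.empty(NDEME, np.int64)
    for d in range(NDEME):
        dims[d] = n_per[d] + 1
    strides = _strides(dims)
    ncfg = dims[0] * dims[1] * dims[2] * dims[3]
    cfg = np.zeros(ncfg)
    heights = np.empty(n_trees)
    for tr in range(n_trees):
        h = _one_tree(n_per, ne, mig, mtimes, msrc, mdst, mne, strides, cfg,
                      max_events_per_tree)
        heights[tr] = h
        if h < 0.0:
            heights[0] = -1.0
            return cfg, heights
    return cfg, heights


@njit(cache=True)
def sim_sites(n_per, ne, mig, mtimes, msrc, mdst, mne, n_loci, mu_locus, seed,
              capacity):
    """Simulate per-locus genealogies and drop infinite-sites mutations.

    mu_locus: expected mutations per generation per locus (mu * locus length).
    Returns (site_codes, site_locus, n_sites, tmrca); n_sites == -1 signals
    that `capacity` was exceeded and the caller should retry with more room.
    """
    np.random.seed(seed)
    dims = np.empty(NDEME, np.int64)
    for d in range(NDEME):
        dims[d] = n_per[d] + 1
    strides = _strides(dims)
    ncfg = dims[0] * dims[1] * dims[2] * dims[3]
    cfg = np.empty(ncfg)
    site_codes = np.empty(capacity, np.int64)
    site_locus = np.empty(capacity, np.int64)
    heights = np.empty(n_loci)
    ns = 0
    for loc in range(n_loci):
        for c in range(ncfg):
            cfg[c] = 0.0
        heights[loc] = _one_tree(n_per, ne, mig, mtimes, msrc, mdst, mne,
                                 strides, cfg, 1_000_000)
        tot = 0.0
        for c in range(ncfg):
            tot += cfg[c]
        nmut = np.random.poisson(mu_locus * tot)
        for _ in range(nmut):
            if ns >= capacity:
                return site_codes, site_locus, -1, heights
            r = np.random.random() * tot
            acc = 0.0
            code = ncfg - 1
            for c in range(ncfg):
                acc += cfg[c]
                if r < acc:
                    code = c
                    break
            site_codes[ns] = code
            site_locus[ns] = loc
            ns += 1
    return site_codes, site_locus, ns, heights


def decode_configs(codes: np.ndarray, n_per: np.ndarray) -> np.ndarray:
    """Vectorized decode of config codes into (len(codes), 4) count arrays."""
    dims = np.asarray(n_per, dtype=np.int64) + 1
    out = np.empty((len(codes), NDEME), dtype=np.int64)
    rem = np.asarray(codes, dtype=np.int64).copy()
    strides = np.empty(NDEME, dtype=np.int64)
    strides[NDEME - 1] = 1
    for d in range(NDEME - 2, -1, -1):
        strides[d] = strides[d + 1] * dims[d + 1]
    for d in range(NDEME):
        out[:, d] = rem // strides[d]
        rem = rem % strides[d]
    return out
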