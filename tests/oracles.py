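"""Independent brute-force oracles, coded before the main implementations.

These deliberately avoid the code paths of the package: the dip oracle
minimizes the sup-distance to a unimodal CDF by linear programming over
discretized unimodal fits; the TMM oracle evaluates the weighted trimmed
mean formula with plain sorted loops; the enrichment oracles expand the
posterior tracks to one value per base.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


# ---------------------------------------------------------------------------
# dip: LP minimax over discretized unimodal CDFs
# ---------------------------------------------------------------------------

def dip_bruteforce(sample) -> float:
    """Exact dip via LP.

    A unimodal CDF is convex up to its mode and concave after, with a
    jump allowed only at the mode.  For each candidate mode (each
    distinct sample value; off-sample modes reduce to these), the
    smallest achievable sup-distance d is the optimum of a linear
    program in the fitted CDF values at the distinct sample points: band
    constraints |G - F_n| <= d on either side of every jump, point
    monotonicity, discrete convexity left of the mode and concavity
    right of it.  The dip is the minimum over modes.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    t, counts = np.unique(x, return_counts=True)
    k = t.size
    cum = np.cumsum(counts) / n          # F_n at each distinct point
    cum_before = np.concatenate([[0.0], cum[:-1]])
    if k == 1:
        return 0.0  # a point mass is itself a unimodal CDF

    best = np.inf
    for mode in range(k):
        # variables: g_0..g_{k-1} (CDF at points), gl (left limit at the
        # mode), d.  Objective: minimize d.
        nv = k + 2
        d_i = k + 1
        gl_i = k
        c = np.zeros(nv)
        c[d_i] = 1.0
        A = []
        b = []

        def le(coeffs, rhs):  # sum(coeffs*vars) <= rhs
            row = np.zeros(nv)
            for idx, co in coeffs:
                row[idx] += co
            A.append(row)
            b.append(rhs)

        for i in range(k):
            if i == mode:
                # value after the jump tracks F_n at the point
                le([(i, 1.0), (d_i, -1.0)], cum[i])
                le([(i, -1.0), (d_i, -1.0)], -cum[i])
                # left limit tracks F_n just below the point
                le([(gl_i, 1.0), (d_i, -1.0)], cum_before[i])
                le([(gl_i, -1.0), (d_i, -1.0)], -cum_before[i])
            else:
                # continuous at this point: one value must satisfy both
                # the below-jump and above-jump bands
                le([(i, 1.0), (d_i, -1.0)], cum_before[i])
                le([(i, -1.0), (d_i, -1.0)], -cum[i])

        # monotone: 0 <= g_0, g_i <= g_{i+1}, g_{k-1} <= 1, and the left
        # limit sits between its neighbours
        for i in range(k - 1):
            if i + 1 == mode:
                le([(i, 1.0), (gl_i, -1.0)], 0.0)
                le([(gl_i, 1.0), (i + 1, -1.0)], 0.0)
            else:
                le([(i, 1.0), (i + 1, -1.0)], 0.0)
        if mode == 0:
            le([(gl_i, 1.0), (0, -1.0)], 0.0)

        # left list: points 0..mode-1 then the left limit at t[mode]
        left_t = list(t[:mode]) + [t[mode]]
        left_v = list(range(mode)) + [gl_i]
        for a in range(len(left_t) - 2):
            # convexity: slope(a,a+1) <= slope(a+1,a+2)
            t0, t1, t2 = left_t[a], left_t[a + 1], left_t[a + 2]
            v0, v1, v2 = left_v[a], left_v[a + 1], left_v[a + 2]
            le([(v1, (t2 - t0)), (v0, -(t2 - t1)), (v2, -(t1 - t0))], 0.0)
        # right list: points mode..k-1 (value after the jump at the mode)
        right_t = list(t[mode:])
        right_v = list(range(mode, k))
        for a in range(len(right_t) - 2):
            # concavity: slope(a,a+1) >= slope(a+1,a+2)
            t0, t1, t2 = right_t[a], right_t[a + 1], right_t[a + 2]
            v0, v1, v2 = right_v[a], right_v[a + 1], right_v[a + 2]
            le([(v1, -(t2 - t0)), (v0, (t2 - t1)), (v2, (t1 - t0))], 0.0)

        bounds = [(0.0, 1.0)] * k + [(0.0, 1.0), (0.0, 0.5)]
        res = linprog(c, A_ub=np.array(A), b_ub=np.array(b), bounds=bounds,
                      method="highs")
        if res.status == 0 and res.fun < best:
            best = res.fun
    return float(best)


# ---------------------------------------------------------------------------
# TMM: plain-loop evaluation of the weighted trimmed mean formula
# ---------------------------------------------------------------------------

def tmm_bruteforce(obs, ref, trim_m=0.30, trim_a=0.05) -> float:
    # library sizes via np.sum so that near-tied M values agree bitwise
    # with any implementation that also sums libraries with np.sum;
    # sequential summation perturbs them at 1e-16 which is enough to flip
    # the rank of proportional count pairs at a trim boundary.
    n_obs = float(np.sum(np.asarray(obs, dtype=float)))
    n_ref = float(np.sum(np.asarray(ref, dtype=float)))
    obs = [float(v) for v in obs]
    ref = [float(v) for v in ref]
    m_vals, a_vals, w_vals = [], [], []
    for o, r in zip(obs, ref):
        if o > 0 and r > 0:
            m_vals.append(np.log2((o / n_obs) / (r / n_ref)))
            a_vals.append(0.5 * np.log2((o / n_obs) * (r / n_ref)))
            var = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
            w_vals.append(1.0 / var)  # inverse asymptotic binomial variance
    nn = len(m_vals)
    if nn == 0:
        return 1.0

    def average_ranks(vals):
        order = sorted(range(nn), key=lambda i: vals[i])
        ranks = [0.0] * nn
        i = 0
        while i < nn:
            j = i
            while j + 1 < nn and vals[order[j + 1]] == vals[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1  # 1-based average rank of the tie group
            for idx in order[i:j + 1]:
                ranks[idx] = avg
            i = j + 1
        return ranks

    rm = average_ranks(m_vals)
    ra = average_ranks(a_vals)
    lo_m = np.floor(nn * trim_m) + 1
    hi_m = nn + 1 - lo_m
    lo_a = np.floor(nn * trim_a) + 1
    hi_a = nn + 1 - lo_a
    num = den = 0.0
    kept = 0
    for i in range(nn):
        if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
            num += w_vals[i] * m_vals[i]
            den += w_vals[i]
            kept += 1
    if kept == 0 or den <= 0:
        return 1.0
    return float(2.0 ** (num / den))


# ---------------------------------------------------------------------------
# enrichment: per-base expansion
# ---------------------------------------------------------------------------

def overlap_enrichment_bruteforce(tracks: dict, regions: dict) -> np.ndarray:
    """Per-state fold: mean per-base posterior in regions over the
    genome-wide per-base mean.  Tracks expanded to one row per base."""
    states = next(iter(tracks.values())).states
    per_base = {}
    for chrom, t in tracks.items():
        rows = np.repeat(t.posteriors, t.bin_size, axis=0)[:t.chrom_length]
        per_base[chrom] = rows
    genome = np.vstack(list(per_base.values()))
    gmean = genome.mean(axis=0)
    picked = []
    for chrom, ivs in regions.items():
        for s, e in np.asarray(ivs):
            e = min(int(e), per_base[chrom].shape[0])
            picked.append(per_base[chrom][max(int(s), 0):e])
    sel = np.vstack(picked)
    return (sel.mean(axis=0) / gmean).astype(float), states


def neighborhood_enrichment_bruteforce(tracks: dict, anchors, flank, step):
    """Fold profile by direct per-anchor, per-base lookup."""
    per_base = {}
    for chrom, t in tracks.items():
        per_base[chrom] = np.repeat(t.posteriors, t.bin_size, axis=0)[:t.chrom_length]
    genome = np.vstack(list(per_base.values()))
    gmean = genome.mean(axis=0)
    offsets = list(range(-flank, flank + 1, step))
    n_states = genome.shape[1]
    folds = np.zeros((n_states, len(offsets)))
    for j, o in enumerate(offsets):
        vals = []
        for chrom, pos, strand in anchors:
            p = pos + o if strand == "+" else pos - o
            if 0 <= p < per_base[chrom].shape[0]:
                vals.append(per_base[chrom][p])
        folds[:, j] = np.mean(vals, axis=0) / gmean
    return folds, offsets
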