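"""Hartigan's dip test for unimodality and reactive-gene flagging.

``dip_statistic`` implements the iterative greatest-convex-minorant /
least-concave-majorant modal-interval algorithm of Hartigan & Hartigan
(1985): the dip is the smallest sup-distance between the empirical CDF
and any unimodal CDF, lies in ``[1/(2n), 0.25]`` and is invariant under
affine transforms and reflection of the sample.  P-values come from a seeded
Monte-Carlo reference table of dips of Uniform(0,1) samples, cached per
sample size; the Benjamini-Hochberg step-up adjustment and the gating of
"reactive" flags on the indeterminate expression class live here too.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DipParams",
    "DipResult",
    "dip_statistic",
    "dip_pvalue",
    "bh_adjust",
    "flag_reactive",
]


@dataclass
class DipParams:
    alpha: float = 0.05
    null_reps: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.null_reps < 100:
            raise ValueError("null_reps must be >= 100")


@dataclass
class DipResult:
    gene_id: str
    cell_line: str
    n: int
    dip: float
    p: float
    p_adj: float


def _modal_dip(x: np.ndarray) -> float:
    # Modal-interval algorithm on sorted, strictly increasing x (1-based
    # arrays to keep the index bookkeeping close to AS 217).  Deviations
    # are tracked in count units and divided by 2n at the end: the best
    # unimodal CDF splits each deviation evenly.
    n = x.size
    xx = np.empty(n + 1)
    xx[1:] = x
    x = xx
    mn = np.empty(n + 1, dtype=np.intp)  # GCM predecessor chain
    mj = np.empty(n + 1, dtype=np.intp)  # LCM successor chain
    gcm = np.empty(n + 2, dtype=np.intp)
    lcm = np.empty(n + 2, dtype=np.intp)

    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 1 or (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj
    mj[n] = n
    for j in range(n - 1, 0, -1):
        mj[j] = j + 1
        while True:
            mjj = mj[j]
            mjmjj = mj[mjj]
            if mjj == n or (x[j] - x[mjj]) * (mjj - mjmjj) < (x[mjj] - x[mjmjj]) * (j - mjj):
                break
            mj[j] = mjmjj

    low, high = 1, n
    dip = 1.0  # one half-jump: the 1/(2n) lower bound
    while True:
        # Change points of the GCM from high down to low, LCM from low up.
        gcm[1] = high
        i = 1
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        ig = l_gcm = i
        ix = ig - 1
        lcm[1] = low
        i = 1
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        ih = l_lcm = i
        iv = 2

        # Largest distance between the GCM and LCM curves on [low, high].
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # next vertex comes from the LCM
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) \
                        - (x[lcmiv] - x[gcmi1]) * (gcmix - gcmi1) / (x[gcmix] - x[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # next vertex comes from the GCM
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (x[lcmiv] - x[lcmiv1]) \
                        - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d <= dip:
            break

        # Max deviation of the empirical CDF from the GCM fit on
        # [low, gcm[ig]] and from the LCM fit on [lcm[ih], high].
        dl = 0.0
        jb = gcm[ig]
        for j in range(ig, l_gcm):
            je = gcm[j + 1]
            if jb - je > 1 and x[jb] != x[je]:
                c = (jb - je) / (x[jb] - x[je])
                for jj in range(je, jb + 1):
                    t = (jj - je + 1) - (x[jj] - x[je]) * c
                    if dl < t:
                        dl = t
            jb = je
        du = 0.0
        jb = lcm[ih]
        for j in range(ih, l_lcm):
            je = lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    if du < t:
                        du = t
            jb = je
        dip = max(dip, dl, du)
        low = gcm[ig]
        high = lcm[ih]

    return dip / (2 * n)


def dip_statistic(values) -> float:
    """Dip statistic of a real sample (n >= 4).

    Ties are broken by a deterministic rank-epsilon jitter (1e-9 of the
    sample range) before the modal-interval computation, which assumes
    distinct order statistics; an all-identical sample returns the lower
    bound ``1/(2n)``.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 4:
        raise ValueError("dip statistic needs at least 4 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("dip statistic needs finite values")
    n = x.size
    x = np.sort(x)
    span = x[-1] - x[0]
    if span == 0.0:
        return 1.0 / (2 * n)
    if np.any(np.diff(x) == 0.0):
        x = x + np.arange(n) * (1e-9 * span)
    return _modal_dip(x)


_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _null_dips(n: int, null_reps: int, seed: int) -> np.ndarray:
    """Monte-Carlo table of dips of Uniform(0,1) samples of size n."""
    key = (n, null_reps, seed)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(np.random.SeedSequence([seed, n, null_reps]))
        u = rng.random((null_reps, n))
        _NULL_CACHE[key] = np.array([dip_statistic(row) for row in u])
    return _NULL_CACHE[key]


def dip_pvalue(dip: float, n: int, params: DipParams | None = None) -> float:
    """Add-one Monte-Carlo p-value of a dip under the Uniform(0,1) null."""
    if params is None:
        params = DipParams()
    if n < 4:
        raise ValueError("dip p-value needs n >= 4")
    null = _null_dips(n, params.null_reps, params.seed)
    return float((1 + np.count_nonzero(null >= dip)) / (params.null_reps + 1))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order restored to input order."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def flag_reactive(table, norm, meta, params: DipParams | None = None,
                  threads: int = 1):
    """Flag reactive genes: indeterminate class AND BH-adjusted dip p < alpha.

    For each cell line the dip test runs on the log2CPM distribution of
    every gene classified indeterminate in that line; BH adjustment is
    performed within the cell line across its indeterminate genes.
    Expressed / non-expressed entries are never flagged.  Returns the
    table mutated in place (dip statistics recorded on indeterminate
    entries only).
    """
    if params is None:
        params = DipParams()
    by_line: dict[str, list[str]] = {}
    for m in meta:
        by_line.setdefault(m.cell_line, []).append(m.sample_id)
    norm_index = {g: i for i, g in enumerate(norm.gene_ids)}

    for c, line in enumerate(table.cell_lines):
        if line not in by_line:
            raise ValueError(f"no metadata for cell line {line!r}")
        values = norm.sample_columns(by_line[line])
        indet = [i for i, g in enumerate(table.gene_ids)
                 if table.class_[i, c] == "indeterminate" and g in norm_index]
        if not indet:
            continue
        rows = [values[norm_index[table.gene_ids[i]]] for i in indet]
        n = rows[0].size
        _null_dips(n, params.null_reps, params.seed)  # warm cache once
        if threads > 1:
            with ThreadPoolExecutor(max_workers=threads) as pool:
                dips = list(pool.map(dip_statistic, rows))
        else:
            dips = [dip_statistic(r) for r in rows]
        ps = np.array([dip_pvalue(d, n, params) for d in dips])
        p_adj = bh_adjust(ps)
        for k, i in enumerate(indet):
            table.dip_stat[i, c] = dips[k]
            table.dip_p[i, c] = ps[k]
            table.dip_p_adj[i, c] = p_adj[k]
            table.reactive[i, c] = p_adj[k] < params.alpha
    return table
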