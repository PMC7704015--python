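"""Exact conditional (C) and exact unconditional maximization (M) tests.

The asymptotic chi-square reference is unreliable for small tables, so the
three homogeneity statistics are recalibrated exactly:

* **C approach** — condition on both margins (group sizes m_i and response
  totals S_l).  The cell counts then follow a multivariate hypergeometric
  law, and the p-value is the tail probability of tables whose statistic
  is at least the observed one.
* **M approach** — Basu's unconditional method: over the space of all
  tables with the observed group sizes, the p-value is the supremum over
  the null parameter space (free pi_i, one common gamma) of the tail
  probability.  The supremum is approximated by a parameter grid followed
  by Nelder-Mead refinement, so the reported value is a guaranteed lower
  bound on the mathematical sup.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln, xlogy

from .asymptotic import batch_statistics, homogeneity_test
from .model import DallalModel, gamma_lower_bound
from .table import BilateralTable

__all__ = [
    "TableSpace",
    "ExactResult",
    "SpaceTooLargeError",
    "enumerate_tables",
    "conditional_space",
    "conditional_pvalue",
    "m_pvalue",
    "m_pvalues_over_space",
    "exact_size",
]

TAIL_TOL = 1e-9  # guards floating-point ties in tail membership


class SpaceTooLargeError(ValueError):
    """Raised when an enumeration would exceed the configured cap."""

    def __init__(self, count, cap):
        self.count = count
        self.cap = cap
        super().__init__(
            f"table space has {count} members, exceeding the cap {cap}; "
            "consider the conditional method or raise the cap"
        )


def compositions(m: int) -> np.ndarray:
    """All (m0, m1, m2) with m0+m1+m2 = m, lexicographic in (m0, m1)."""
    out = [(m0, m1, m - m0 - m1)
           for m0 in range(m + 1) for m1 in range(m - m0 + 1)]
    return np.asarray(out, dtype=np.int64)


@dataclass
class TableSpace:
    """An enumerated set of 3 x g tables sharing the given group sizes.

    ``m1`` and ``m2`` hold, per member table, the unilateral and bilateral
    responder counts of each group; ``m0`` follows from the sizes.  With
    ``response_totals`` set, every member additionally shares the row
    margins (the conditional space) and ``probs`` carries the multivariate
    hypergeometric probability of each member.
    """

    group_sizes: np.ndarray
    m1: np.ndarray                      # (n_tables, g)
    m2: np.ndarray                      # (n_tables, g)
    response_totals: np.ndarray | None = None
    probs: np.ndarray | None = None
    _stat_cache: dict = field(default_factory=dict, repr=False)

    @property
    def size(self) -> int:
        return self.m1.shape[0]

    def statistics(self, statistic: str) -> np.ndarray:
        """Statistic values of every member (cached), with the degenerate-
        table conventions so each member has a defined value."""
        if statistic not in self._stat_cache:
            self._stat_cache[statistic] = batch_statistics(
                self.m1, self.m2, which=(statistic,))[statistic]
        return self._stat_cache[statistic]

    def member(self, k: int) -> BilateralTable:
        m0 = self.group_sizes - self.m1[k] - self.m2[k]
        return BilateralTable(np.vstack([m0, self.m1[k], self.m2[k]]))

    def index_of(self, table: BilateralTable) -> int:
        match = np.nonzero((self.m1 == table.counts[1]).all(axis=1)
                           & (self.m2 == table.counts[2]).all(axis=1))[0]
        if match.size != 1:
            raise ValueError("table is not a member of this space")
        return int(match[0])


def space_size(group_sizes) -> int:
    """Number of tables with the given column sums: prod C(m_i + 2, 2)."""
    return int(np.prod([comb(int(m) + 2, 2) for m in group_sizes]))


def enumerate_tables(group_sizes, cap: int = 10 ** 7) -> TableSpace:
    """Every table with the given group sizes, in lexicographic order."""
    sizes = np.asarray(group_sizes, dtype=np.int64)
    if np.any(sizes < 0):
        raise ValueError("group sizes must be nonnegative")
    count = space_size(sizes)
    if count > cap:
        raise SpaceTooLargeError(count, cap)
    comps = [compositions(int(m)) for m in sizes]
    grids = np.meshgrid(*[np.arange(len(c)) for c in comps], indexing="ij")
    idx = np.stack([gr.ravel() for gr in grids], axis=1)
    m1 = np.column_stack([comps[i][idx[:, i], 1] for i in range(len(comps))])
    m2 = np.column_stack([comps[i][idx[:, i], 2] for i in range(len(comps))])
    return TableSpace(sizes, m1, m2)


def _conditional_members(sizes, S1, S2):
    """Recursive enumeration of tables with both margins fixed."""
    g = len(sizes)
    out_m1, out_m2 = [], []
    cur1 = np.zeros(g, dtype=np.int64)
    cur2 = np.zeros(g, dtype=np.int64)
    # capacity of the remaining groups
    tail_cap = np.concatenate([np.cumsum(sizes[::-1])[::-1][1:], [0]])

    def rec(i, r1, r2):
        if i == g:
            if r1 == 0 and r2 == 0:
                out_m1.append(cur1.copy())
                out_m2.append(cur2.copy())
            return
        if r1 + r2 > sizes[i] + tail_cap[i]:
            return
        for a in range(min(sizes[i], r1) + 1):
            for b in range(min(sizes[i] - a, r2) + 1):
                cur1[i], cur2[i] = a, b
                rec(i + 1, r1 - a, r2 - b)
        cur1[i] = cur2[i] = 0

    rec(0, int(S1), int(S2))
    return (np.asarray(out_m1, dtype=np.int64).reshape(-1, g),
            np.asarray(out_m2, dtype=np.int64).reshape(-1, g))


def conditional_space(observed: BilateralTable) -> TableSpace:
    """All tables sharing both margins with ``observed``, with their
    multivariate hypergeometric probabilities attached.

    P(m) = [prod_i m_i! / (m0i! m1i! m2i!)] * S0! S1! S2! / N! —
    probabilities sum to one over the space.
    """
    sizes = observed.group_sizes
    S0, S1, S2 = observed.response_totals
    m1, m2 = _conditional_members(sizes, S1, S2)
    m0 = sizes[None, :] - m1 - m2
    logcoef = (np.sum(gammaln(sizes + 1.0))
               - gammaln(m0 + 1.0).sum(axis=1)
               - gammaln(m1 + 1.0).sum(axis=1)
               - gammaln(m2 + 1.0).sum(axis=1))
    lognorm = (gammaln(observed.n_total + 1.0)
               - gammaln(S0 + 1.0) - gammaln(S1 + 1.0) - gammaln(S2 + 1.0))
    probs = np.exp(logcoef - lognorm)
    totals = np.asarray([S0, S1, S2], dtype=np.int64)
    return TableSpace(sizes, m1, m2, response_totals=totals, probs=probs)


@dataclass
class ExactResult:
    """Outcome of an exact test."""

    p_value: float
    method: str                         # "C" or "M"
    statistic_name: str
    observed_statistic: float
    tail_size: int
    space_size: int
    df: int | None = None
    argmax_pi: np.ndarray | None = None
    argmax_gamma: float | None = None
    grid_points: int | None = None
    trace: dict = field(default_factory=dict)

    def __repr__(self):
        s = (f"ExactResult({self.method}/{self.statistic_name}: "
             f"p = {self.p_value:.4f}, T = {self.observed_statistic:.4f}, "
             f"tail {self.tail_size}/{self.space_size}")
        if self.method == "M" and self.argmax_gamma is not None:
            s += (f", argmax gamma = {self.argmax_gamma:.3f}")
        return s + ")"


def _observed_statistic(observed: BilateralTable, statistic: str) -> float:
    return homogeneity_test(observed, method=statistic).value


def conditional_pvalue(observed: BilateralTable,
                       statistic: str = "score") -> ExactResult:
    """Exact conditional p-value: hypergeometric probability of the tail
    {T(m) >= T(observed)} over the both-margins-fixed space."""
    if not isinstance(observed, BilateralTable):
        observed = BilateralTable(observed)
    space = conditional_space(observed)
    t_obs = _observed_statistic(observed, statistic)
    vals = space.statistics(statistic)
    tail = vals >= t_obs - TAIL_TOL
    p = float(space.probs[tail].sum())
    return ExactResult(min(p, 1.0), "C", statistic, t_obs,
                       int(tail.sum()), space.size,
                       df=observed.n_groups - 1)


# -- M approach ------------------------------------------------------------

def _trinomial_pmf(comp: np.ndarray, pi: float, gamma: float) -> np.ndarray:
    p0 = 1.0 - (2.0 - gamma) * pi
    p1 = 2.0 * pi * (1.0 - gamma)
    p2 = pi * gamma
    p = np.clip([p0, p1, p2], 0.0, 1.0)
    logcoef = (gammaln(comp.sum(axis=1) + 1.0)
               - gammaln(comp + 1.0).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = logcoef + xlogy(comp, p[None, :]).sum(axis=1)
    lp = np.where(np.any((comp > 0) & (p[None, :] == 0.0), axis=1),
                  -np.inf, lp)
    return np.exp(lp)


class _TailProbability:
    """Tail probability of an enumerated table space as a function of the
    null parameters (pi_1..pi_g, common gamma).

    Precomputes the per-group composition index of every tail member so an
    evaluation is g gathers and a product-sum; when the tail covers more
    than half the space the complement is summed instead.
    """

    def __init__(self, space: TableSpace, tail: np.ndarray):
        self.space = space
        comps = [compositions(int(m)) for m in space.group_sizes]
        self.comps = comps
        # composition index of each member per group (lexicographic key)
        keys = []
        for i, comp in enumerate(comps):
            lookup = {(int(a), int(b)): k
                      for k, (_, a, b) in enumerate(comp)}
            keys.append(np.asarray(
                [lookup[(int(a), int(b))]
                 for a, b in zip(space.m1[:, i], space.m2[:, i])],
                dtype=np.int64))
        self.member_idx = keys
        self.use_complement = tail.sum() > space.size / 2
        rows = ~tail if self.use_complement else tail
        self.idx = [k[rows] for k in keys]
        self.n_eval = 0

    def __call__(self, pi, gamma) -> float:
        self.n_eval += 1
        pvecs = [_trinomial_pmf(comp, float(p), float(gamma))
                 for comp, p in zip(self.comps, pi)]
        acc = pvecs[0][self.idx[0]].copy()
        for i in range(1, len(pvecs)):
            acc *= pvecs[i][self.idx[i]]
        s = float(acc.sum())
        return min(max(1.0 - s if self.use_complement else s, 0.0), 1.0)


def _feasible_null_grid(g: int, grid_points: int):
    """Feasible (pi_1..g, gamma) combinations on a regular grid."""
    pis = np.linspace(0.0, 1.0, grid_points)
    gammas = np.linspace(0.0, 1.0, grid_points)
    pts = []
    for combo in itertools.product(pis, repeat=g):
        lb = float(np.max(gamma_lower_bound(np.asarray(combo))))
        for gam in gammas:
            if gam >= lb - 1e-12:
                pts.append((np.asarray(combo), float(gam)))
    return pts


def _refine(objective, starts, tol=1e-10):
    """Nelder-Mead polish on unconstrained coordinates.

    pi_i = expit(u_i); gamma = lb(pi) + (1 - lb) expit(v), keeping every
    probe inside the admissible region.
    """
    best_p, best_pi, best_gam = -1.0, None, None
    trace = []
    for pi0, gam0 in starts:
        u0 = _logit(np.clip(pi0, 1e-6, 1.0 - 1e-6))
        lb0 = float(np.max(gamma_lower_bound(pi0)))
        frac = (gam0 - lb0) / (1.0 - lb0) if lb0 < 1.0 else 0.5
        v0 = _logit(np.clip(frac, 1e-6, 1.0 - 1e-6))
        x0 = np.concatenate([u0, [v0]])

        def neg(x):
            pi = expit(x[:-1])
            lb = float(np.max(gamma_lower_bound(pi)))
            gam = lb + (1.0 - lb) * expit(x[-1])
            return -objective(pi, gam)

        res = minimize(neg, x0, method="Nelder-Mead",
                       options={"xatol": tol, "fatol": tol,
                                "maxiter": 2000})
        pi = expit(res.x[:-1])
        lb = float(np.max(gamma_lower_bound(pi)))
        gam = lb + (1.0 - lb) * expit(res.x[-1])
        p = -float(res.fun)
        trace.append({"start_gamma": gam0, "p": p, "nfev": int(res.nfev)})
        if p > best_p:
            best_p, best_pi, best_gam = p, pi, gam
    return best_p, best_pi, best_gam, trace


def _logit(x):
    return np.log(np.asarray(x) / (1.0 - np.asarray(x)))


def m_pvalue(observed: BilateralTable, statistic: str = "score",
             grid_points: int = 21, refine: bool = True,
             cap: int = 10 ** 7) -> ExactResult:
    """Basu's maximization p-value.

    Tail = {m : T(m) >= T(observed) - tol} over all tables with the
    observed group sizes; the p-value is the maximum over the H0 null
    space — pi_i free in [0, 1] and one common gamma in
    [max_i lb(pi_i), 1] — of the tail probability under independent
    trinomial sampling.  The maximum is taken over a full parameter grid
    (``grid_points`` per dimension) followed, when ``refine``, by
    Nelder-Mead polish from the best 5 grid points; the result is a lower
    bound on the mathematical sup.
    """
    if not isinstance(observed, BilateralTable):
        observed = BilateralTable(observed)
    space = enumerate_tables(observed.group_sizes, cap=cap)
    t_obs = _observed_statistic(observed, statistic)
    vals = space.statistics(statistic)
    tail = vals >= t_obs - TAIL_TOL
    tail_size = int(tail.sum())
    if tail.all():
        g = observed.n_groups
        return ExactResult(1.0, "M", statistic, t_obs, tail_size,
                           space.size, df=g - 1,
                           argmax_pi=np.full(g, 0.5), argmax_gamma=0.5,
                           grid_points=grid_points,
                           trace={"note": "tail covers the whole space"})
    obj = _TailProbability(space, tail)
    grid = _feasible_null_grid(observed.n_groups, grid_points)
    scores = np.asarray([obj(pi, gam) for pi, gam in grid])
    order = np.argsort(scores)[::-1]
    best = float(scores[order[0]])
    best_pi, best_gam = grid[order[0]]
    trace = {"grid_evals": len(grid), "grid_best": best}
    if refine:
        starts = [grid[k] for k in order[:5]]
        p_ref, pi_ref, gam_ref, ref_trace = _refine(obj, starts)
        trace["refinement"] = ref_trace
        if p_ref > best:
            best, best_pi, best_gam = p_ref, pi_ref, gam_ref
    return ExactResult(min(best, 1.0), "M", statistic, t_obs, tail_size,
                       space.size, df=observed.n_groups - 1,
                       argmax_pi=np.asarray(best_pi),
                       argmax_gamma=float(best_gam),
                       grid_points=grid_points, trace=trace)


# -- whole-space M p-values and exact size ---------------------------------

def m_pvalues_over_space(space: TableSpace, statistic: str,
                         theta_grid) -> np.ndarray:
    """M p-value of every member table, maximized over ``theta_grid``.

    Exploits that tails are nested: sorting members by decreasing
    statistic turns all tail probabilities at one parameter point into a
    single cumulative sum, and the grid maximum is a running elementwise
    max.  Members tied on the statistic share a tail.
    """
    vals = space.statistics(statistic)
    order = np.argsort(-vals, kind="stable")
    sorted_vals = vals[order]
    # index of the end of each tie block: tail of member k includes every
    # member with statistic >= vals[k] - TAIL_TOL
    n = space.size
    block_end = np.empty(n, dtype=np.int64)
    j = 0
    for k in range(n):
        if j < k:
            j = k
        while j + 1 < n and sorted_vals[j + 1] >= sorted_vals[k] - TAIL_TOL:
            j += 1
        block_end[k] = j
    comps = [compositions(int(m)) for m in space.group_sizes]
    keys = []
    for i, comp in enumerate(comps):
        lookup = {(int(a), int(b)): k for k, (_, a, b) in enumerate(comp)}
        keys.append(np.asarray(
            [lookup[(int(a), int(b))]
             for a, b in zip(space.m1[order, i], space.m2[order, i])],
            dtype=np.int64))
    best = np.zeros(n)
    pmf_cache: dict = {}
    for pi, gam in theta_grid:
        joint = None
        for i, comp in enumerate(comps):
            key = (int(space.group_sizes[i]), float(pi[i]), float(gam))
            if key not in pmf_cache:
                pmf_cache[key] = _trinomial_pmf(comp, key[1], key[2])
            vec = pmf_cache[key][keys[i]]
            joint = vec.copy() if joint is None else joint * vec
        np.maximum(best, np.cumsum(joint), out=best)
    tail_probs = np.minimum(best[block_end], 1.0)
    out = np.empty(n)
    out[order] = tail_probs
    return out


def exact_size(group_sizes, statistic: str = "score", alpha: float = 0.05,
               n_grid: int = 51, null_pi=None, null_gamma=None,
               cap: int = 10 ** 6):
    """Exact size of the M test over a null grid, by full enumeration.

    The p-value maximization grid contains every evaluated null point
    (pi_i all equal), which makes size <= alpha at each evaluated point a
    mathematical identity of the maximization construction.

    Returns ``(pi_grid, gamma_grid, size)`` where ``size[j, k]`` is the
    rejection probability at (pi = pi_grid[j], gamma = gamma_grid[k]),
    NaN where (pi, gamma) is infeasible.
    """
    sizes = np.asarray(group_sizes, dtype=np.int64)
    g = len(sizes)
    space = enumerate_tables(sizes, cap=cap)
    pi_grid = np.linspace(0.0, 1.0, n_grid) if null_pi is None \
        else np.asarray(null_pi, dtype=float)
    gamma_grid = np.linspace(0.0, 1.0, n_grid) if null_gamma is None \
        else np.asarray(null_gamma, dtype=float)
    # maximization grid: free pi_i over the same axis values, so every
    # evaluated null point (common pi) is contained in the sup grid
    theta = [(np.asarray(combo, dtype=float), float(gam))
             for combo in itertools.product(pi_grid, repeat=g)
             for gam in gamma_grid
             if gam >= float(np.max(gamma_lower_bound(
                 np.asarray(combo, dtype=float)))) - 1e-12]
    pvals = m_pvalues_over_space(space, statistic, theta)
    reject = pvals < alpha
    size = np.full((pi_grid.size, gamma_grid.size), np.nan)
    comps = [compositions(int(m)) for m in sizes]
    keys = []
    for i, comp in enumerate(comps):
        lookup = {(int(a), int(b)): k for k, (_, a, b) in enumerate(comp)}
        keys.append(np.asarray(
            [lookup[(int(a), int(b))]
             for a, b in zip(space.m1[:, i], space.m2[:, i])],
            dtype=np.int64))
    for j, p in enumerate(pi_grid):
        lb = gamma_lower_bound(float(p))
        for k, gam in enumerate(gamma_grid):
            if gam < lb - 1e-12:
                continue
            pvecs = [_trinomial_pmf(comp, float(p), float(gam))
                     for comp in comps]
            joint = pvecs[0][keys[0]].copy()
            for i in range(1, g):
                joint *= pvecs[i][keys[i]]
            size[j, k] = float(joint[reject].sum())
    return pi_grid, gamma_grid, size
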