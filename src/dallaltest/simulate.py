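"""Monte-Carlo engine: type-I-error and power studies for the nine
testing procedures (asymptotic A, exact conditional C, exact
unconditional-maximization M — each built on the LRT, score and Wald
statistics).

Seeding: one master seed spawns an independent child stream per grid
point (``numpy.random.SeedSequence``), so results are bit-identical
across runs regardless of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from . import exact as exact_mod
from .asymptotic import batch_statistics
from .model import DallalParams, cell_probabilities
from .table import BilateralTable

__all__ = [
    "Scenario",
    "simulate_counts",
    "simulate_tables",
    "tie_study",
    "power_study",
    "classify_robustness",
    "monte_carlo_se",
]

ALL_TESTS = tuple(f"{a}:{s}" for a in ("A", "C", "M")
                  for s in ("lrt", "score", "wald"))


def classify_robustness(tie: float) -> str:
    """Label an empirical type-I error rate at nominal alpha = 0.05:
    liberal above 0.06, conservative below 0.04, robust otherwise."""
    if not 0.0 <= tie <= 1.0:
        raise ValueError("tie must be a proportion in [0, 1]")
    if tie > 0.06:
        return "liberal"
    if tie < 0.04:
        return "conservative"
    return "robust"


def monte_carlo_se(p: float, r: int) -> float:
    return float(np.sqrt(p * (1.0 - p) / r))


def simulate_counts(pi, gamma, group_sizes, r: int, rng) -> np.ndarray:
    """Draw ``r`` tables as an (r, 3, g) array of counts.

    Group i is trinomial M(m_i; p0i, p1i, p2i) with cell probabilities
    from the model's (pi_i, gamma_i) mapping.
    """
    rng = np.random.default_rng(rng)
    pi = np.atleast_1d(np.asarray(pi, dtype=float))
    gamma_vec = np.broadcast_to(np.asarray(gamma, dtype=float), pi.shape)
    DallalParams(pi, gamma_vec)          # validates
    p0, p1, p2 = cell_probabilities(pi, gamma_vec)
    sizes = np.asarray(group_sizes, dtype=np.int64)
    out = np.empty((r, 3, pi.size), dtype=np.int64)
    for i in range(pi.size):
        pvec = np.array([p0[i], p1[i], p2[i]])
        pvec = pvec / pvec.sum()
        out[:, :, i] = rng.multinomial(sizes[i], pvec, size=r)
    return out


def simulate_tables(pi, gamma, group_sizes, r: int, rng):
    """As :func:`simulate_counts` but yielding :class:`BilateralTable`."""
    for c in simulate_counts(pi, gamma, group_sizes, r, rng):
        yield BilateralTable(c)


@dataclass
class Scenario:
    """One simulation scenario (a parameter grid over one hypothesis).

    For a null scenario ``gamma`` is the common-gamma grid; for an
    alternative scenario ``gamma1_grid`` varies the first group's gamma
    while ``gamma_rest`` fixes the remaining groups.
    """

    group_sizes: Sequence[int]
    pi: Sequence[float] | float
    gamma: Sequence[float] | float | None = None
    gamma1_grid: Sequence[float] | None = None
    gamma_rest: float | None = None
    hypothesis: str = "null"
    replications: int = 2000
    alpha: float = 0.05
    seed: int = 0
    tests: Sequence[str] = field(default_factory=lambda: ALL_TESTS[:3])

    def __post_init__(self):
        if self.hypothesis not in ("null", "alternative"):
            raise ValueError("hypothesis must be 'null' or 'alternative'")
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        bad = [t for t in self.tests if t not in ALL_TESTS]
        if bad:
            raise ValueError(f"unknown tests {bad}; choose from {ALL_TESTS}")

    def run(self) -> pd.DataFrame:
        if self.hypothesis == "null":
            pis = np.atleast_1d(np.asarray(self.pi, dtype=float))
            gammas = np.atleast_1d(np.asarray(self.gamma, dtype=float))
            return tie_study(self.group_sizes, pis, gammas,
                             tests=self.tests, r=self.replications,
                             alpha=self.alpha, seed=self.seed)
        return power_study(self.group_sizes, self.pi, self.gamma1_grid,
                           self.gamma_rest, tests=self.tests,
                           r=self.replications, alpha=self.alpha,
                           seed=self.seed)


class _ExactRejector:
    """Cached exact-test machinery for one group-size configuration.

    The unconditional space and its statistic values are enumerated once;
    M p-values for every member come from one nested-tail sweep, C
    p-values are cached per response-margin signature.
    """

    def __init__(self, group_sizes, alpha, grid_points=21,
                 cap=10 ** 6):
        self.sizes = np.asarray(group_sizes, dtype=np.int64)
        self.alpha = alpha
        self.grid_points = grid_points
        self.space = exact_mod.enumerate_tables(self.sizes, cap=cap)
        self._index = {}
        for k in range(self.space.size):
            key = (self.space.m1[k].tobytes(), self.space.m2[k].tobytes())
            self._index[key] = k
        self._m_pvals: dict[str, np.ndarray] = {}
        self._c_cache: dict = {}

    def _member(self, counts) -> int:
        m1 = np.ascontiguousarray(counts[1], dtype=np.int64)
        m2 = np.ascontiguousarray(counts[2], dtype=np.int64)
        return self._index[(m1.tobytes(), m2.tobytes())]

    def m_reject(self, counts, statistic) -> bool:
        if statistic not in self._m_pvals:
            g = len(self.sizes)
            from .model import gamma_lower_bound
            pts = np.linspace(0.0, 1.0, self.grid_points)
            theta = [(np.asarray(combo), float(gam))
                     for combo in _pi_combos(pts, g)
                     for gam in pts
                     if gam >= float(np.max(gamma_lower_bound(
                         np.asarray(combo)))) - 1e-12]
            self._m_pvals[statistic] = exact_mod.m_pvalues_over_space(
                self.space, statistic, theta)
        return bool(self._m_pvals[statistic][self._member(counts)]
                    < self.alpha)

    def c_reject(self, counts, statistic) -> bool:
        totals = tuple(int(x) for x in counts.sum(axis=1))
        key = (totals, statistic)
        if key not in self._c_cache:
            table = BilateralTable(counts)
            space = exact_mod.conditional_space(table)
            vals = space.statistics(statistic)
            self._c_cache[key] = (space, vals)
        space, vals = self._c_cache[key]
        k = space.index_of(BilateralTable(counts))
        tail = vals >= vals[k] - exact_mod.TAIL_TOL
        return bool(space.probs[tail].sum() < self.alpha)


def _pi_combos(pts, g):
    import itertools
    return itertools.product(pts, repeat=g)


def _rejections(counts, tests, alpha, exact_rejector=None):
    """Rejection indicators, per test, for a batch of simulated counts."""
    r, _, g = counts.shape
    m1 = counts[:, 1, :].astype(float)
    m2 = counts[:, 2, :].astype(float)
    stats_needed = sorted({t.split(":")[1] for t in tests})
    batch = batch_statistics(m1, m2, which=tuple(stats_needed))
    crit = chi2.ppf(1.0 - alpha, g - 1)
    out = {}
    for t in tests:
        approach, stat = t.split(":")
        if approach == "A":
            out[t] = batch[stat] > crit
        else:
            if exact_rejector is None:
                raise ValueError(
                    f"test {t} requires exact machinery; the table space "
                    "must fit the enumeration cap")
            fn = (exact_rejector.c_reject if approach == "C"
                  else exact_rejector.m_reject)
            out[t] = np.asarray([fn(counts[j], stat) for j in range(r)])
    return out


def _study(group_sizes, param_points, tests, r, alpha, seed, extra_cols):
    """Shared driver: one child RNG stream per grid point."""
    sizes = np.asarray(group_sizes, dtype=np.int64)
    needs_exact = any(t.split(":")[0] in ("C", "M") for t in tests)
    rejector = _ExactRejector(sizes, alpha) if needs_exact else None
    children = np.random.SeedSequence(seed).spawn(len(param_points))
    rows = []
    for (pi_vec, gamma_vec, meta), ss in zip(param_points, children):
        rng = np.random.default_rng(ss)
        counts = simulate_counts(pi_vec, gamma_vec, sizes, r, rng)
        rej = _rejections(counts, tests, alpha, rejector)
        for t in tests:
            prop = float(np.mean(rej[t]))
            rows.append({**meta, "test": t, "replications": r,
                         "rejection_rate": prop,
                         "se": monte_carlo_se(prop, r),
                         "label": classify_robustness(prop)})
    df = pd.DataFrame(rows)
    return df[extra_cols + ["test", "replications", "rejection_rate",
                            "se", "label"]]


def tie_study(group_sizes, pi_grid, gamma_grid, tests=("A:score",),
              r: int = 2000, alpha: float = 0.05, seed: int = 0
              ) -> pd.DataFrame:
    """Empirical type-I error over a (pi, gamma) null grid.

    Each grid point uses common pi_i = pi and common gamma; infeasible
    (pi, gamma) combinations are skipped.
    """
    from .model import gamma_lower_bound
    g = len(group_sizes)
    points = []
    for p in np.atleast_1d(pi_grid):
        for gam in np.atleast_1d(gamma_grid):
            if gam < gamma_lower_bound(float(p)) - 1e-12:
                continue
            points.append((np.full(g, float(p)), float(gam),
                           {"pi": float(p), "gamma": float(gam)}))
    return _study(group_sizes, points, tests, r, alpha, seed,
                  ["pi", "gamma"])


def power_study(group_sizes, pi, gamma1_grid, gamma_rest,
                tests=("A:score",), r: int = 2000, alpha: float = 0.05,
                seed: int = 0) -> pd.DataFrame:
    """Empirical power across a gamma_1 grid, the remaining groups held
    at ``gamma_rest`` (setting gamma_1 = gamma_rest recovers the TIE)."""
    g = len(group_sizes)
    pi_vec = np.broadcast_to(np.asarray(pi, dtype=float), (g,)).copy()
    points = []
    for g1 in np.atleast_1d(gamma1_grid):
        gam = np.full(g, float(gamma_rest))
        gam[0] = float(g1)
        points.append((pi_vec, gam, {"gamma1": float(g1)}))
    return _study(group_sizes, points, tests, r, alpha, seed, ["gamma1"])
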