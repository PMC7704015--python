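"""Large-sample homogeneity tests of the dependence parameter gamma.

Three statistics — likelihood ratio (T_L), score (T_SC) and Wald-type
(T_W) — test H0: gamma_1 = ... = gamma_g against a two-sided alternative;
each is asymptotically chi-square with g - 1 degrees of freedom.

Degenerate-margin conventions (needed because exact-method enumeration
visits every table, including boundary ones): a statistic is 0 when
S1 = 0 or S2 = 0, i.e. when every group's gamma-hat sits on the same
boundary; Wald drops groups whose gamma-hat the data cannot identify and
reduces the degrees of freedom; a zero Wald weight combined with a
nonzero gamma-hat contrast gives +inf.  Zero encodes "no evidence of
heterogeneity", +inf "maximal evidence".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solveh_banded
from scipy.special import xlogy
from scipy.stats import chi2

from .table import BilateralTable

__all__ = [
    "TestResult",
    "likelihood_ratio_test",
    "score_test",
    "wald_test",
    "homogeneity_test",
    "asymptotic_pvalue",
    "batch_statistics",
]

_METHODS = ("lrt", "score", "wald")


@dataclass
class TestResult:
    """Outcome of one asymptotic homogeneity test."""

    statistic_name: str
    value: float
    df: int
    p_value: float
    flags: set = field(default_factory=set)

    def __repr__(self):
        return (f"TestResult({self.statistic_name}: T = {self.value:.4f}, "
                f"df = {self.df}, p = {self.p_value:.4f}"
                + (f", flags={sorted(self.flags)}" if self.flags else "")
                + ")")


def asymptotic_pvalue(statistic: float, df: int) -> float:
    """Upper-tail chi-square probability P(chi2_df >= statistic)."""
    if statistic < 0:
        raise ValueError("statistic must be nonnegative")
    if df < 1:
        raise ValueError("df must be a positive integer")
    if np.isinf(statistic):
        return 0.0
    return float(chi2.sf(statistic, df))


def _check(table: BilateralTable) -> BilateralTable:
    if not isinstance(table, BilateralTable):
        table = BilateralTable(table)
    if table.n_groups < 2:
        raise ValueError("homogeneity tests require at least 2 groups")
    return table


def likelihood_ratio_test(table: BilateralTable) -> TestResult:
    """T_L = 2 {l(pi-hat, gamma-hat) - l(pi-tilde, gamma-tilde)}.

    Computed through the simplified closed form

        T_L = 2 sum_i [ m1i ln(m1i/S1) + m2i ln(m2i/S2)
                        + (m1i+m2i) ln((S1+S2)/(m1i+m2i)) ]

    with 0 ln 0 := 0; defined as 0 when S1 = 0 or S2 = 0.
    """
    table = _check(table)
    value, flags = _lrt_value(table.counts[1].astype(float),
                              table.counts[2].astype(float))
    df = table.n_groups - 1
    return TestResult("lrt", value, df, asymptotic_pvalue(value, df), flags)


def _lrt_value(m1, m2):
    S1, S2 = m1.sum(), m2.sum()
    flags = set()
    if S1 == 0 or S2 == 0:
        return 0.0, {"degenerate-margin"}
    t = (xlogy(m1, m1 / S1) + xlogy(m2, m2 / S2)
         + xlogy(m1 + m2, S1 + S2) - xlogy(m1 + m2, np.where(m1 + m2 > 0,
                                                             m1 + m2, 1.0)))
    return float(max(2.0 * t.sum(), 0.0)), flags


def score_test(table: BilateralTable) -> TestResult:
    """T_SC = sum_i (S1 m2i - S2 m1i)^2 / (S1 S2 (m1i + m2i)).

    The score statistic U I^{-1} U' evaluated at the constrained MLEs; a
    group without responders contributes 0, and the whole statistic is 0
    when S1 = 0 or S2 = 0.
    """
    table = _check(table)
    value, flags = _score_value(table.counts[1].astype(float),
                                table.counts[2].astype(float))
    df = table.n_groups - 1
    return TestResult("score", value, df, asymptotic_pvalue(value, df), flags)


def _score_value(m1, m2):
    S1, S2 = m1.sum(), m2.sum()
    if S1 == 0 or S2 == 0:
        return 0.0, {"degenerate-margin"}
    denom = S1 * S2 * (m1 + m2)
    terms = np.where(m1 + m2 > 0,
                     (S1 * m2 - S2 * m1) ** 2 / np.where(denom > 0, denom, 1.0),
                     0.0)
    return float(terms.sum()), set()


def wald_hat_weights(m1, m2):
    """a-hat_i = 4 m1i m2i (m1i + m2i) / (m1i + 2 m2i)^4 — the integer
    closed form of the gamma-block information-inverse entry at the MLEs."""
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    denom = (m1 + 2.0 * m2) ** 4
    return np.where(denom > 0,
                    4.0 * m1 * m2 * (m1 + m2) / np.where(denom > 0, denom, 1.0),
                    np.nan)


def wald_test(table: BilateralTable) -> TestResult:
    """Wald-type statistic T_W = d' A^{-1} d.

    d is the vector of successive gamma-hat differences and A the
    symmetric tridiagonal matrix with diagonal a-hat_i + a-hat_{i+1} and
    off-diagonal -a-hat_{i+1}, solved with a banded Cholesky rather than
    an explicit elementwise inverse.  Groups with undefined gamma-hat
    (no responders) are dropped with a df reduction.
    """
    table = _check(table)
    m1 = table.counts[1].astype(float)
    m2 = table.counts[2].astype(float)
    value, df_used, flags = _wald_value(m1, m2)
    if df_used < 1:
        # fewer than two identifiable groups: no contrast to test
        df_used = 1
    return TestResult("wald", value, df_used,
                      asymptotic_pvalue(value, df_used), flags)


def _wald_value(m1, m2):
    """Return (statistic, df, flags) under the degenerate-table rules."""
    flags: set[str] = set()
    defined = (m1 + 2.0 * m2) > 0
    if not defined.all():
        flags.add("dropped-groups")
    m1d, m2d = m1[defined], m2[defined]
    k = m1d.size
    if k < 2:
        flags.add("undefined-statistic")
        return 0.0, 0, flags
    gam = 2.0 * m2d / (m1d + 2.0 * m2d)
    d = np.diff(gam)
    if np.allclose(d, 0.0, atol=0.0):
        return 0.0, k - 1, flags
    a = wald_hat_weights(m1d, m2d)
    if np.any(a == 0.0):
        flags.add("singular-information")
        return np.inf, k - 1, flags
    # banded Cholesky solve of the SPD tridiagonal system A x = d
    if k == 2:
        return float(d[0] ** 2 / (a[0] + a[1])), 1, flags
    ab = np.zeros((2, k - 1))
    ab[0, 1:] = -a[1:-1]
    ab[1] = a[:-1] + a[1:]
    x = solveh_banded(ab, d)
    return float(d @ x), k - 1, flags


def homogeneity_test(table: BilateralTable, method: str = "all"):
    """Run one or all three asymptotic tests.

    Returns a single :class:`TestResult` for ``method`` in
    ``{"lrt", "score", "wald"}`` or a dict of all three for ``"all"``.
    """
    funcs = {"lrt": likelihood_ratio_test, "score": score_test,
             "wald": wald_test}
    if method == "all":
        return {name: f(table) for name, f in funcs.items()}
    if method not in funcs:
        raise ValueError(f"method must be one of {_METHODS + ('all',)}")
    return funcs[method](table)


# -- vectorized evaluation over many tables --------------------------------

def batch_statistics(m1, m2, which=("lrt", "score", "wald")):
    """Evaluate statistics on a batch of tables with shared group sizes.

    Parameters
    ----------
    m1, m2 : ndarray, shape (R, g)
        Per-table counts of unilateral and bilateral responders (m0
        follows from the group sizes and never enters the statistics).

    Returns
    -------
    dict of name -> ndarray of shape (R,)

    Applies the same degenerate-table conventions as the scalar tests, so
    every enumerated table gets a defined (possibly 0 or +inf) value.
    """
    m1 = np.atleast_2d(np.asarray(m1, dtype=float))
    m2 = np.atleast_2d(np.asarray(m2, dtype=float))
    R, g = m1.shape
    out = {}
    S1 = m1.sum(axis=1)
    S2 = m2.sum(axis=1)
    ok = (S1 > 0) & (S2 > 0)
    S1s = np.where(ok, S1, 1.0)
    S2s = np.where(ok, S2, 1.0)
    if "lrt" in which:
        mm = m1 + m2
        t = (xlogy(m1, m1) - xlogy(m1, S1s[:, None])
             + xlogy(m2, m2) - xlogy(m2, S2s[:, None])
             + xlogy(mm, (S1s + S2s)[:, None]) - xlogy(mm, mm))
        out["lrt"] = np.where(ok, np.maximum(2.0 * t.sum(axis=1), 0.0), 0.0)
    if "score" in which:
        mm = m1 + m2
        denom = (S1s * S2s)[:, None] * np.where(mm > 0, mm, 1.0)
        terms = np.where(mm > 0,
                         (S1s[:, None] * m2 - S2s[:, None] * m1) ** 2 / denom,
                         0.0)
        out["score"] = np.where(ok, terms.sum(axis=1), 0.0)
    if "wald" in which:
        out["wald"] = _batch_wald(m1, m2)
    return out


def _batch_wald(m1, m2):
    R, g = m1.shape
    vals = np.empty(R)
    defined = (m1 + 2.0 * m2) > 0
    clean = defined.all(axis=1)
    # common path: all gamma-hat defined, tridiagonal Thomas sweep
    if clean.any():
        m1c, m2c = m1[clean], m2[clean]
        gam = 2.0 * m2c / (m1c + 2.0 * m2c)
        a = 4.0 * m1c * m2c * (m1c + m2c) / (m1c + 2.0 * m2c) ** 4
        d = np.diff(gam, axis=1)
        nonzero_d = np.any(d != 0.0, axis=1)
        azero = np.any(a == 0.0, axis=1)
        res = np.zeros(m1c.shape[0])
        res[nonzero_d & azero] = np.inf
        solve_rows = nonzero_d & ~azero
        if solve_rows.any():
            res[solve_rows] = _thomas_quadform(a[solve_rows], d[solve_rows])
        vals[clean] = res
    for i in np.nonzero(~clean)[0]:
        vals[i] = _wald_value(m1[i], m2[i])[0]
    return vals


def _thomas_quadform(a, d):
    """d' A^{-1} d for SPD tridiagonal A built from weights a, batched.

    A has diagonal a_i + a_{i+1} and off-diagonal -a_{i+1}; forward
    elimination then back substitution, vectorized across rows.
    """
    R, k = d.shape
    diag = a[:, :-1] + a[:, 1:]
    off = -a[:, 1:-1]                       # shape (R, k-1)
    cp = np.empty((R, k - 1)) if k > 1 else np.empty((R, 0))
    dp = np.empty((R, k))
    denom = diag[:, 0].copy()
    dp[:, 0] = d[:, 0] / denom
    for j in range(1, k):
        cp[:, j - 1] = off[:, j - 1] / denom
        denom = diag[:, j] - off[:, j - 1] * cp[:, j - 1]
        dp[:, j] = (d[:, j] - off[:, j - 1] * dp[:, j - 1]) / denom
    x = np.empty((R, k))
    x[:, -1] = dp[:, -1]
    for j in range(k - 2, -1, -1):
        x[:, j] = dp[:, j] - cp[:, j] * x[:, j + 1]
    return np.einsum("ij,ij->i", d, x)
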