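"""Dallal's model for bilateral binary data: likelihood, MLEs, information.

The model assumes each organ responds with group-specific marginal
probability pi_i, and that the conditional probability of response at one
organ given response at the other, gamma_i, does not depend on pi_i.  The
per-patient response count (0, 1 or 2 organs) is then trinomial with

    p0 = 1 - (2 - gamma) pi,   p1 = 2 pi (1 - gamma),   p2 = pi gamma,

valid when max{0, 1 - 1/(2 pi), 2 - 1/pi} <= gamma <= 1 (for pi > 0).
gamma = pi corresponds to independent organs, gamma = 1 to complete
dependence.  The homogeneity hypothesis of interest is
H0: gamma_1 = ... = gamma_g.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, xlogy

from .table import BilateralTable

__all__ = [
    "DallalParams",
    "DallalModel",
    "DallalResults",
    "gamma_lower_bound",
    "cell_probabilities",
    "information_matrix",
    "information_inverse",
]


def gamma_lower_bound(pi):
    """Smallest admissible gamma for marginal probability ``pi``.

    The bound max{0, 1 - 1/(2 pi), 2 - 1/pi} is exactly what forces
    p1 <= 1 and p0 >= 0.
    """
    pi = np.asarray(pi, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        lb = np.maximum.reduce([
            np.zeros_like(pi),
            np.where(pi > 0, 1.0 - 1.0 / (2.0 * pi), 0.0),
            np.where(pi > 0, 2.0 - 1.0 / pi, 0.0),
        ])
    return lb if lb.ndim else float(lb)


def cell_probabilities(pi, gamma, *, validate: bool = True):
    """Map (pi, gamma) to the trinomial cell probabilities (p0, p1, p2).

    Raises ``ValueError`` naming the violated bound when the pair is
    outside the model's admissible region.
    """
    pi = np.asarray(pi, dtype=float)
    gamma = np.broadcast_to(np.asarray(gamma, dtype=float), pi.shape).copy() \
        if pi.ndim else np.asarray(gamma, dtype=float)
    if validate:
        if np.any(pi < 0) or np.any(pi > 1):
            raise ValueError("pi must lie in [0, 1]")
        if np.any(gamma > 1):
            raise ValueError("gamma must satisfy gamma <= 1")
        lb = gamma_lower_bound(pi)
        if np.any(gamma < np.asarray(lb) - 1e-12):
            raise ValueError(
                "gamma below the admissible lower bound "
                f"max{{0, 1 - 1/(2 pi), 2 - 1/pi}} = {lb}"
            )
    p0 = 1.0 - (2.0 - gamma) * pi
    p1 = 2.0 * pi * (1.0 - gamma)
    p2 = pi * gamma
    # clip tiny negatives from float roundoff at the boundary
    p0 = np.clip(p0, 0.0, 1.0)
    p1 = np.clip(p1, 0.0, 1.0)
    p2 = np.clip(p2, 0.0, 1.0)
    return p0, p1, p2


@dataclass
class DallalParams:
    """Parameter point of the model: marginal rates and dependence.

    ``gamma`` may be a scalar (the common-gamma H0 form) or a g-vector.
    """

    pi: np.ndarray
    gamma: np.ndarray | float

    def __post_init__(self):
        self.pi = np.atleast_1d(np.asarray(self.pi, dtype=float))
        if np.ndim(self.gamma) == 0:
            self.gamma = float(self.gamma)
        else:
            self.gamma = np.asarray(self.gamma, dtype=float)
            if self.gamma.shape != self.pi.shape:
                raise ValueError("pi and gamma must have the same length")
        self.cell_probs()  # validates

    @property
    def n_groups(self) -> int:
        return self.pi.size

    @property
    def common_gamma(self) -> bool:
        return np.ndim(self.gamma) == 0

    def gamma_vector(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.gamma, dtype=float),
                               self.pi.shape).copy()

    def cell_probs(self):
        """(p0, p1, p2) per group, each a g-vector."""
        return cell_probabilities(self.pi, self.gamma_vector())


def _multinomial_logcoef(table: BilateralTable) -> float:
    m = table.group_sizes
    return float(np.sum(gammaln(m + 1)) - np.sum(gammaln(table.counts + 1)))


def log_likelihood(table: BilateralTable, params: DallalParams) -> float:
    """Multinomial log-likelihood of ``table`` at ``params``.

    Includes the multinomial coefficient so values are comparable across
    parameterizations.  Convention 0*log(0) = 0; a positive count on a
    zero-probability cell yields -inf (not an exception), so boundary
    probing by the exact-test optimizer is safe.
    """
    if params.n_groups != table.n_groups:
        raise ValueError(
            f"parameter length {params.n_groups} does not match "
            f"table with {table.n_groups} groups"
        )
    p = np.vstack(params.cell_probs())
    c = table.counts
    if np.any((p == 0) & (c > 0)):
        return -np.inf
    return float(np.sum(xlogy(c, np.where(p > 0, p, 1.0)))
                 + _multinomial_logcoef(table))


# -- information matrix ----------------------------------------------------

def information_matrix(params: DallalParams, group_sizes) -> np.ndarray:
    """Expected (Fisher) information for beta = (gamma_1..g, pi_1..g).

    The expected negative Hessian of the log-likelihood; block-diagonal up
    to the gamma_i/pi_i cross terms, positive definite for interior
    parameters.
    """
    m = np.asarray(group_sizes, dtype=float)
    pi = params.pi
    gam = params.gamma_vector()
    p0, p1, p2 = params.cell_probs()
    if np.any(p0 <= 0) or np.any(p1 <= 0) or np.any(p2 <= 0):
        raise ValueError("information requires interior parameters "
                         "(all cell probabilities positive)")
    g = pi.size
    # -E d2l/dgamma2 = m [pi/gamma + 2 pi/(1-gamma) + pi^2/p0]
    i_gg = m * (pi / gam + 2.0 * pi / (1.0 - gam) + pi ** 2 / p0)
    # -E d2l/dgamma dpi = -m / p0
    i_gp = -m / p0
    # -E d2l/dpi2 = m (2 - gamma) / (pi p0)
    i_pp = m * (2.0 - gam) / (pi * p0)
    info = np.zeros((2 * g, 2 * g))
    idx = np.arange(g)
    info[idx, idx] = i_gg
    info[g + idx, g + idx] = i_pp
    info[idx, g + idx] = i_gp
    info[g + idx, idx] = i_gp
    return info


def information_inverse(params: DallalParams, group_sizes) -> np.ndarray:
    """Closed-form inverse of the information matrix.

    Per-group blocks::

        a_i = gamma (gamma - 1)(gamma - 2) / (2 m_i pi)      [gamma, gamma]
        b_i = pi (1 + gamma - 2 pi) / (2 m_i)                [pi, pi]
        c_i = -gamma (gamma - 1) / (2 m_i)                   [gamma, pi]

    Requires interior parameters; boundary values (gamma in {0, 1} or a
    zero cell probability) make the information singular.
    """
    m = np.asarray(group_sizes, dtype=float)
    pi = params.pi
    gam = params.gamma_vector()
    p0, p1, p2 = params.cell_probs()
    if (np.any(p0 <= 0) or np.any(p1 <= 0) or np.any(p2 <= 0)
            or np.any(gam <= 0) or np.any(gam >= 1) or np.any(pi <= 0)):
        raise ValueError("information inverse undefined at boundary "
                         "parameters (gamma in {0,1} or a zero cell)")
    g = pi.size
    a = gam * (gam - 1.0) * (gam - 2.0) / (2.0 * m * pi)
    b = pi * (1.0 + gam - 2.0 * pi) / (2.0 * m)
    c = -gam * (gam - 1.0) / (2.0 * m)
    inv = np.zeros((2 * g, 2 * g))
    idx = np.arange(g)
    inv[idx, idx] = a
    inv[g + idx, g + idx] = b
    inv[idx, g + idx] = c
    inv[g + idx, idx] = c
    return inv


# -- model / results -------------------------------------------------------

class DallalModel:
    """Dallal's trinomial model bound to an observed count table.

    Examples
    --------
    >>> from dallaltest import BilateralTable, DallalModel
    >>> tab = BilateralTable.from_groups([(15, 6, 7), (7, 5, 9)])
    >>> res = DallalModel(tab).fit()
    >>> res.pi.round(4)
    array([0.3571, 0.5476])
    """

    def __init__(self, table: BilateralTable):
        if not isinstance(table, BilateralTable):
            table = BilateralTable(table)
        self.table = table

    def loglike(self, params: DallalParams) -> float:
        return log_likelihood(self.table, params)

    def fit(self, common_gamma: bool = False) -> "DallalResults":
        """Closed-form maximum likelihood fit.

        With ``common_gamma=False`` (the alternative H1), each group gets
        its own (pi_i, gamma_i):

            pi_hat_i  = (m1i + 2 m2i) / (2 m_i)
            gamma_hat_i = 2 m2i / (m1i + 2 m2i)

        gamma_hat_i is undefined (NaN, flagged) when a group has no
        responders.  With ``common_gamma=True`` (the null H0), a single
        gamma is shared:

            gamma_tilde = 2 S2 / (S1 + 2 S2)
            pi_tilde_i  = (m1i + m2i)(S1 + 2 S2) / (2 m_i (S1 + S2))
        """
        t = self.table
        m0, m1, m2 = (t.counts[l].astype(float) for l in range(3))
        m = t.group_sizes.astype(float)
        flags: set[str] = set()
        if not common_gamma:
            denom = m1 + 2.0 * m2
            pi = denom / (2.0 * m)
            with np.errstate(invalid="ignore", divide="ignore"):
                gamma = np.where(denom > 0, 2.0 * m2 / np.where(denom > 0, denom, 1.0), np.nan)
            if np.any(denom == 0):
                flags.add("undefined-gamma")
            llf = self._loglike_at(pi, gamma)
            return DallalResults(self, pi, gamma, constrained=False,
                                 llf=llf, flags=flags)
        S0, S1, S2 = (float(x) for x in t.response_totals)
        if S1 + S2 > 0:
            gamma = 2.0 * S2 / (S1 + 2.0 * S2)
            pi = (m1 + m2) * (S1 + 2.0 * S2) / (2.0 * m * (S1 + S2))
        else:
            gamma = np.nan
            pi = np.zeros_like(m)
            flags.add("undefined-gamma")
        llf = self._loglike_at(pi, np.broadcast_to(gamma, pi.shape))
        return DallalResults(self, pi, gamma, constrained=True,
                             llf=llf, flags=flags)

    def _loglike_at(self, pi, gamma) -> float:
        """Log-likelihood tolerating NaN gamma in no-responder groups."""
        gam = np.where(np.isnan(gamma), 0.0, gamma)
        p0, p1, p2 = cell_probabilities(np.clip(pi, 0, 1),
                                        np.clip(gam, gamma_lower_bound(pi), 1),
                                        validate=False)
        p = np.vstack([p0, p1, p2])
        c = self.table.counts
        if np.any((p == 0) & (c > 0)):
            return -np.inf
        return float(np.sum(xlogy(c, np.where(p > 0, p, 1.0)))
                     + _multinomial_logcoef(self.table))

    def test_homogeneity(self, method: str = "all", exact: str | None = None,
                         **kwargs):
        """Homogeneity tests of gamma across groups; see
        :mod:`dallaltest.asymptotic` and :mod:`dallaltest.exact`."""
        from . import asymptotic, exact as exact_mod
        if exact is None:
            return asymptotic.homogeneity_test(self.table, method=method)
        if exact == "C":
            return exact_mod.conditional_pvalue(self.table, statistic=method,
                                                **kwargs)
        if exact == "M":
            return exact_mod.m_pvalue(self.table, statistic=method, **kwargs)
        raise ValueError("exact must be None, 'C' or 'M'")


@dataclass
class DallalResults:
    """Maximum-likelihood fit of Dallal's model.

    Attributes
    ----------
    pi : ndarray
        Fitted marginal response probabilities per group.
    gamma : ndarray or float
        Fitted dependence parameter(s); scalar under the common-gamma
        (H0) fit.  NaN marks a group whose gamma the data cannot identify
        (no responders).
    constrained : bool
        True for the common-gamma fit.
    llf : float
        Attained log-likelihood (including the multinomial constant).
    """

    model: DallalModel
    pi: np.ndarray
    gamma: np.ndarray | float
    constrained: bool
    llf: float
    flags: set = field(default_factory=set)

    @property
    def params(self) -> DallalParams:
        gam = self.gamma
        if np.ndim(gam) > 0:
            gam = np.where(np.isnan(gam), 0.0, gam)
        return DallalParams(self.pi, gam)

    def cov_params(self) -> np.ndarray:
        """Asymptotic covariance of (gamma_1..g, pi_1..g): the closed-form
        information inverse at the fitted parameters (interior fits only)."""
        gam = self.gamma if np.ndim(self.gamma) else np.full(self.pi.shape,
                                                             self.gamma)
        return information_inverse(DallalParams(self.pi, gam),
                                   self.model.table.group_sizes)

    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params()))

    def summary(self) -> str:
        t = self.model.table
        gam = self.gamma_vector()
        kind = "common-gamma (H0)" if self.constrained else "per-group (H1)"
        lines = [
            "Dallal model fit: " + kind,
            f"groups: {t.n_groups}   N = {t.n_total}   "
            f"log-likelihood = {self.llf:.4f}",
            "",
            f"{'group':>8} {'m_i':>5} {'pi':>8} {'gamma':>8}",
        ]
        for i, lab in enumerate(t.labels):
            gtxt = "   undef" if np.isnan(gam[i]) else f"{gam[i]:8.4f}"
            lines.append(
                f"{lab:>8} {t.group_sizes[i]:>5d} {self.pi[i]:8.4f} {gtxt}")
        if self.flags:
            lines.append("flags: " + ", ".join(sorted(self.flags)))
        return "\n".join(lines)

    def gamma_vector(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.gamma, dtype=float),
                               self.pi.shape).copy()
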