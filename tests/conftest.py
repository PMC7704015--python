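import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, xlogy

from dallaltest import BilateralTable, datasets


@pytest.fixture
def rp_table():
    """The four-group retinitis pigmentosa table (the worked example)."""
    return datasets.rp_table2()


def random_tables(rng, n, g_choices=(2, 3, 4), m_range=(5, 50),
                  require_identifiable=False):
    """Random count tables drawn from random interior model parameters."""
    out = []
    while len(out) < n:
        g = int(rng.choice(g_choices))
        sizes = rng.integers(m_range[0], m_range[1] + 1, g)
        pi = rng.uniform(0.2, 0.8, g)
        lb = np.maximum(0.0, np.maximum(1 - 1 / (2 * pi), 2 - 1 / pi))
        gam = rng.uniform(lb + 0.05, 0.95)
        p0 = 1 - (2 - gam) * pi
        p1 = 2 * pi * (1 - gam)
        p2 = pi * gam
        counts = np.column_stack(
            [rng.multinomial(sizes[i], [p0[i], p1[i], p2[i]])
             for i in range(g)])
        t = BilateralTable(counts)
        if require_identifiable and np.any(counts[1] + 2 * counts[2] == 0):
            continue
        out.append(t)
    return out


# -- independent numerical MLE oracle --------------------------------------
# Profile likelihood: for fixed gamma the per-group maximizer is
# pi_i(gamma) = (m1i + m2i) / ((2 - gamma) m_i), which always yields a
# valid probability triple; the fit reduces to 1-D maximizations in gamma.

def _profile_loglik_group(m0, m1, m2, gamma):
    m = m0 + m1 + m2
    pi = (m1 + m2) / ((2.0 - gamma) * m) if m1 + m2 > 0 else 0.0
    p0 = 1.0 - (2.0 - gamma) * pi
    p1 = 2.0 * pi * (1.0 - gamma)
    p2 = pi * gamma
    if (p0 <= 0 and m0 > 0) or (p1 <= 0 and m1 > 0) or (p2 <= 0 and m2 > 0):
        return -np.inf, pi
    ll = (xlogy(m0, max(p0, 1e-300)) + xlogy(m1, max(p1, 1e-300))
          + xlogy(m2, max(p2, 1e-300)))
    return ll, pi


def numerical_mle(table, common_gamma=False):
    """Maximize the multinomial log-likelihood numerically.

    Returns (pi, gamma, loglik) with the multinomial constant included,
    accurate to ~1e-10 via bounded 1-D maximization over gamma.
    """
    c = table.counts.astype(float)
    const = float(np.sum(gammaln(table.group_sizes + 1.0))
                  - np.sum(gammaln(c + 1.0)))
    g = table.n_groups
    if not common_gamma:
        pis, gams, total = [], [], const
        for i in range(g):
            m0, m1, m2 = c[:, i]

            def neg(gam, m0=m0, m1=m1, m2=m2):
                return -_profile_loglik_group(m0, m1, m2, gam)[0]

            res = minimize_scalar(neg, bounds=(1e-12, 1.0 - 1e-12),
                                  method="bounded",
                                  options={"xatol": 1e-13})
            # boundary candidates
            cands = [(neg(x), x) for x in (1e-15, res.x, 1.0 - 1e-15)]
            best = min(cands)
            ll, pi = _profile_loglik_group(m0, m1, m2, best[1])
            pis.append(pi)
            gams.append(best[1])
            total += ll
        return np.array(pis), np.array(gams), total

    def neg_common(gam):
        tot = 0.0
        for i in range(g):
            ll, _ = _profile_loglik_group(*c[:, i], gam)
            tot += ll
        return -tot

    res = minimize_scalar(neg_common, bounds=(1e-12, 1.0 - 1e-12),
                          method="bounded", options={"xatol": 1e-13})
    cands = [(neg_common(x), x) for x in (1e-15, res.x, 1.0 - 1e-15)]
    best = min(cands)
    gam = best[1]
    pis = np.array([_profile_loglik_group(*c[:, i], gam)[1]
                    for i in range(g)])
    return pis, gam, -best[0] + const
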