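import itertools
import math

import numpy as np
import pytest

from dallaltest import (
    BilateralTable,
    DallalModel,
    SpaceTooLargeError,
    conditional_pvalue,
    conditional_space,
    enumerate_tables,
    homogeneity_test,
    m_pvalue,
)
from dallaltest.exact import (
    TAIL_TOL,
    _TailProbability,
    compositions,
    m_pvalues_over_space,
    space_size,
)

from conftest import random_tables


# -- independent naive oracle ----------------------------------------------

def naive_conditional(observed):
    """Brute-force conditional space: itertools product over per-group
    compositions, filtered on the row margins, factorial arithmetic."""
    sizes = observed.group_sizes
    S0, S1, S2 = observed.response_totals
    members, weights = [], []
    per_group = [
        [(a, b, c) for a in range(m + 1) for b in range(m + 1 - a)
         for c in [m - a - b]]
        for m in sizes
    ]
    for combo in itertools.product(*per_group):
        arr = np.array(combo).T
        if arr[0].sum() == S0 and arr[1].sum() == S1 and arr[2].sum() == S2:
            members.append(arr)
            w = 1
            for col in combo:
                w *= (math.factorial(sum(col)) // math.factorial(col[0])
                      // math.factorial(col[1]) // math.factorial(col[2]))
            weights.append(w)
    total = sum(weights)
    return members, [w / total for w in weights]


def naive_conditional_pvalue(observed, statistic):
    members, probs = naive_conditional(observed)
    t_obs = homogeneity_test(observed, method=statistic).value
    p = 0.0
    for arr, w in zip(members, probs):
        t = homogeneity_test(BilateralTable(arr), method=statistic).value
        if t >= t_obs - TAIL_TOL:
            p += w
    return p


class TestEnumeration:
    def test_counts(self):
        assert enumerate_tables([10, 10]).size == 4356
        assert space_size([10, 10, 10]) == math.comb(12, 2) ** 3 == 287496

    def test_single_patient_space(self):
        sp = enumerate_tables([1])
        rows = sorted((int(a), int(b)) for a, b in zip(sp.m1[:, 0],
                                                       sp.m2[:, 0]))
        assert rows == [(0, 0), (0, 1), (1, 0)]

    def test_duplicate_free_deterministic(self):
        sp1 = enumerate_tables([3, 4])
        sp2 = enumerate_tables([3, 4])
        assert np.array_equal(sp1.m1, sp2.m1)
        assert np.array_equal(sp1.m2, sp2.m2)
        seen = {(r1.tobytes(), r2.tobytes())
                for r1, r2 in zip(sp1.m1, sp1.m2)}
        assert len(seen) == sp1.size == space_size([3, 4])

    def test_cap_exceeded(self):
        with pytest.raises(SpaceTooLargeError) as err:
            enumerate_tables([100, 100, 100], cap=10 ** 6)
        assert err.value.count == math.comb(102, 2) ** 3

    def test_compositions_cover_simplex(self):
        comp = compositions(4)
        assert comp.shape == (15, 3)
        assert np.all(comp.sum(axis=1) == 4)


class TestConditionalSpace:
    def test_two_member_space(self):
        obs = BilateralTable.from_groups([(0, 1, 0), (0, 0, 1)])
        sp = conditional_space(obs)
        assert sp.size == 2
        assert sp.probs == pytest.approx([0.5, 0.5])

    def test_degenerate_margin_single_table(self):
        obs = BilateralTable.from_groups([(3, 0, 0), (2, 0, 0)])
        sp = conditional_space(obs)
        assert sp.size == 1
        assert sp.probs == pytest.approx([1.0])

    def test_worked_four_member_space(self):
        obs = BilateralTable.from_groups([(1, 0, 1), (0, 2, 0)])
        sp = conditional_space(obs)
        assert sp.size == 4
        assert sorted(sp.probs) == pytest.approx(
            [2 / 12, 2 / 12, 4 / 12, 4 / 12])

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(21)
        for t in random_tables(rng, 10, g_choices=(2, 3), m_range=(2, 6)):
            sp = conditional_space(t)
            assert sp.probs.sum() == pytest.approx(1.0, abs=1e-12)


class TestConditionalPvalue:
    def test_worked_example_one_third(self):
        obs = BilateralTable.from_groups([(1, 0, 1), (0, 2, 0)])
        res = conditional_pvalue(obs, statistic="score")
        assert res.p_value == pytest.approx(1 / 3)
        assert res.tail_size == 2

    def test_minimum_statistic_member_p_one(self):
        obs = BilateralTable.from_groups([(1, 1, 0), (0, 1, 1)])
        assert conditional_pvalue(obs, "score").p_value == pytest.approx(1.0)

    def test_unique_member_p_one(self):
        obs = BilateralTable.from_groups([(4, 0, 0), (3, 0, 0)])
        assert conditional_pvalue(obs, "wald").p_value == 1.0

    @pytest.mark.parametrize("statistic", ["lrt", "score", "wald"])
    def test_matches_naive_oracle(self, statistic):
        rng = np.random.default_rng(22)
        checked = 0
        for t in random_tables(rng, 12, g_choices=(2, 3), m_range=(2, 5)):
            if conditional_space(t).size > 500:
                continue
            res = conditional_pvalue(t, statistic)
            assert res.p_value == pytest.approx(
                naive_conditional_pvalue(t, statistic), abs=1e-12)
            checked += 1
        assert checked >= 5

    def test_group_permutation_invariance(self):
        rng = np.random.default_rng(23)
        for t in random_tables(rng, 5, g_choices=(3,), m_range=(2, 4)):
            perm = t.permuted(rng.permutation(3))
            for stat in ("lrt", "score"):
                assert conditional_pvalue(perm, stat).p_value == \
                    pytest.approx(conditional_pvalue(t, stat).p_value,
                                  abs=1e-12)


class TestMPvalue:
    def test_minimum_statistic_table_p_one(self):
        # both gamma-hats equal: the whole space is the tail
        obs = BilateralTable.from_groups([(1, 1, 1), (1, 1, 1)])
        res = m_pvalue(obs, "score", grid_points=5, refine=False)
        assert res.p_value == 1.0

    def test_dense_grid_oracle_on_two_patient_space(self):
        obs = BilateralTable.from_groups([(0, 0, 1), (0, 1, 0)])
        res = m_pvalue(obs, "score", grid_points=101, refine=False)
        # independent brute force: 9 tables, 101 points per parameter
        space = enumerate_tables([1, 1])
        t_obs = homogeneity_test(obs, "score").value
        tail = space.statistics("score") >= t_obs - TAIL_TOL
        grid = np.linspace(0, 1, 101)
        best = 0.0
        comp = compositions(1)
        for gam in grid:
            pv = []
            for p in grid:
                p0, p1, p2 = 1 - (2 - gam) * p, 2 * p * (1 - gam), p * gam
                if p0 < -1e-12:
                    pv.append(None)
                    continue
                probs = np.array([max(p0, 0), p1, p2])
                pv.append(np.array(
                    [probs[np.nonzero(row)[0][0]] for row in comp]))
            for pa in pv:
                if pa is None:
                    continue
                for pb in pv:
                    if pb is None:
                        continue
                    joint = np.outer(pa, pb).ravel()
                    best = max(best, joint[tail.reshape(-1)].sum())
        assert res.p_value == pytest.approx(best, abs=1e-4)

    def test_refinement_attains_analytic_supremum(self):
        # tail probability here is 4 pi1 pi2 gamma (1 - gamma) subject to
        # pi_i <= 1/(2 - gamma); substituting the active bound gives
        # 4 gamma (1 - gamma)/(2 - gamma)^2, maximized at gamma = 2/3
        # with value exactly 1/2 — off the regular 101-point grid
        obs = BilateralTable.from_groups([(0, 0, 1), (0, 1, 0)])
        res = m_pvalue(obs, "score", grid_points=21, refine=True)
        assert res.p_value == pytest.approx(0.5, abs=1e-6)
        assert res.argmax_gamma == pytest.approx(2 / 3, abs=1e-3)

    def test_dominates_tail_probability_at_constrained_mle(self):
        rng = np.random.default_rng(24)
        for t in random_tables(rng, 4, g_choices=(2,), m_range=(3, 5)):
            res = m_pvalue(t, "score", grid_points=11, refine=True)
            space = enumerate_tables(t.group_sizes)
            t_obs = homogeneity_test(t, "score").value
            tail = space.statistics("score") >= t_obs - TAIL_TOL
            fit = DallalModel(t).fit(common_gamma=True)
            obj = _TailProbability(space, tail)
            at_mle = obj(np.clip(fit.pi, 0, 1),
                         np.clip(fit.gamma, 0, 1))
            assert res.p_value >= at_mle - 1e-9

    def test_grid_refinement_monotone(self):
        obs = BilateralTable.from_groups([(0, 0, 1), (0, 1, 0)])
        p_coarse = m_pvalue(obs, "score", grid_points=11).p_value
        p_fine = m_pvalue(obs, "score", grid_points=22).p_value
        assert p_fine >= p_coarse - 1e-10

    def test_group_permutation_invariance(self):
        obs = BilateralTable.from_groups([(1, 1, 0), (0, 1, 2)])
        p1 = m_pvalue(obs, "score", grid_points=11).p_value
        p2 = m_pvalue(obs.permuted([1, 0]), "score",
                      grid_points=11).p_value
        assert p1 == pytest.approx(p2, abs=1e-8)

    def test_space_too_large_advises_conditional(self):
        obs = BilateralTable(np.full((3, 3), 40))
        with pytest.raises(SpaceTooLargeError, match="conditional"):
            m_pvalue(obs, "score", cap=1000)

    def test_sweep_matches_single_table_maximization(self):
        # the whole-space nested-tail sweep agrees with per-table grid
        # maximization at the same parameter grid
        space = enumerate_tables([2, 2])
        pts = np.linspace(0, 1, 11)
        from dallaltest.model import gamma_lower_bound
        theta = [(np.array([p1, p2]), g)
                 for p1 in pts for p2 in pts for g in pts
                 if g >= max(gamma_lower_bound(p1),
                             gamma_lower_bound(p2)) - 1e-12]
        sweep = m_pvalues_over_space(space, "score", theta)
        for k in (0, 7, 20, space.size - 1):
            vals = space.statistics("score")
            tail = vals >= vals[k] - TAIL_TOL
            obj = _TailProbability(space, tail)
            direct = max(obj(pi, g) for pi, g in theta)
            assert sweep[k] == pytest.approx(direct, abs=1e-12)
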