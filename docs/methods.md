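# Methods

## Model

Each patient in group *i* (size m_i, i = 1..g) contributes l ∈ {0, 1, 2}
responding organs. Dallal's model assumes a marginal per-organ response
probability π_i and a conditional dependence γ_i = P(one organ responds |
the other responds) that does not vary with π_i. The response-count
vector of group i, (m_0i, m_1i, m_2i), is multinomial with

    p0 = 1 − (2 − γ)π,   p1 = 2π(1 − γ),   p2 = πγ.

Requiring p1 ≤ 1 and p0 ≥ 0 forces

    max{0, 1 − 1/(2π), 2 − 1/π} ≤ γ ≤ 1,

which the package enforces everywhere (`gamma_lower_bound`). γ = π is
organ independence; γ = 1 complete dependence. The tested hypothesis is
H0: γ_1 = … = γ_g, leaving the π_i free (nuisance parameters).

All reported log-likelihoods include the multinomial coefficient, so
values are comparable across parameterizations; test statistics use
differences, in which the constant cancels. Conventions: 0·ln 0 = 0; a
positive count on a zero-probability cell yields −∞ rather than an
exception, so boundary probing (by the exact-test optimizer and the
enumeration machinery) is safe.

## Estimation

Both fits are closed form. Unconstrained: π̂_i = (m_1i + 2m_2i)/(2m_i),
γ̂_i = 2m_2i/(m_1i + 2m_2i); the fitted cell probabilities are the
saturated multinomial frequencies. γ̂_i is represented as NaN (flagged
`undefined-gamma`) when a group has no responders — the likelihood does
not identify it — rather than given an arbitrary value. Constrained
(common γ): γ̃ = 2S_2/(S_1 + 2S_2) and
π̃_i = (m_1i + m_2i)(S_1 + 2S_2)/(2m_i(S_1 + S_2)), with γ̃ undefined
when S_1 = S_2 = 0.

The Fisher information for β = (γ_1..γ_g, π_1..π_g) is the expected
negative Hessian, assembled from

    I_γγ,i = m_i [π/γ + 2π/(1 − γ) + π²/p0],
    I_γπ,i = −m_i/p0,
    I_ππ,i = m_i (2 − γ)/(π p0),

and its closed-form inverse has per-group blocks
a_i = γ(γ−1)(γ−2)/(2m_iπ), b_i = π(1 + γ − 2π)/(2m_i),
c_i = −γ(γ−1)/(2m_i). Correctness is anchored to positive definiteness
and the numerical inverse identity (tested to 1e−8), not to transcribed
signs. The inverse is defined only for interior parameters; boundaries
raise.

## Asymptotic tests

T_L (likelihood ratio, simplified closed form, verified internally
against twice the log-likelihood gap), T_SC (score,
Σ (S_1m_2i − S_2m_1i)²/(S_1S_2(m_1i+m_2i))) and T_W (Wald) are each
referred to χ²(g − 1), p = P(χ² ≥ T).

The Wald statistic is d′A⁻¹d with d the successive γ̂ differences and A
the symmetric tridiagonal matrix with diagonal â_i + â_{i+1} and
off-diagonal −â_{i+1}, where â_i = 4m_1im_2i(m_1i+m_2i)/(m_1i+2m_2i)⁴.
A⁻¹ is never formed: the system is solved with a banded Cholesky
factorization (direct ratio when only two groups are identifiable). The
explicit g = 2, 3, 4 closed forms serve as validation targets in the
test suite (agreement to 1e−10 on random tables).

Degenerate-table conventions — required because exact-method enumeration
visits every table: a statistic is 0 when S_1 = 0 or S_2 = 0 (every
group's γ̂ sits on the same boundary: no evidence of heterogeneity); a
group with m_1i + m_2i = 0 contributes 0 to the score sum; Wald drops
groups with undefined γ̂, reducing df (flagged); a zero Wald weight
combined with a nonzero γ̂ contrast yields +∞ (maximal evidence, p = 0).

## Exact tests

**Conditional (C).** Fixing both margins makes the table law multivariate
hypergeometric, P(m) = [Π_i multinom(m_i)] · S_0!S_1!S_2!/N!, which sums
to 1 over the conditional space (tested to 1e−12). The p-value is the
probability of {T(m) ≥ T(m*) − 1e−9}; the tolerance guards float ties,
and the observed table is always in its own tail, so p > 0.

**Maximization (M).** Over the unconditional space (group sizes fixed;
Π_i C(m_i+2, 2) tables, enumeration capped at 10⁷ members with an
explicit size error), the p-value is the supremum over the **null**
parameter space — π_i free in [0,1] and one *common*
γ ∈ [max_i lb(π_i), 1] — of the tail probability. The common-γ space is
used because the maximization must run over distributions satisfying H0;
allowing group-specific γ_i would inflate the supremum beyond the null.
The supremum is approximated by a full grid (default 21 points per
parameter, every feasible combination) followed by Nelder-Mead
refinement from the 5 best grid points on smooth unconstrained
coordinates (π = expit(u), γ = lb + (1 − lb)·expit(v)), convergence
tolerance 1e−10. The returned value is a guaranteed **lower bound** on
the mathematical sup; grid resolution, argmax and refinement trace are
recorded in the result. Tail probabilities are computed group-factorized
(per-group trinomial probability vectors gathered over the tail's
composition indices; the complement is summed when the tail covers more
than half the space).

**Exact size.** `exact_size` computes, by enumeration, the rejection
probability of the M test over a null grid. All member p-values come
from one sweep: sorting members by decreasing statistic makes every tail
a prefix, so one cumulative sum per parameter point yields all tail
probabilities, and the sup is a running elementwise maximum. The
maximization grid contains every evaluated null point (free π_i over the
same axis values), which makes size ≤ α at each evaluated point an
identity of the construction — the defining validity guarantee of
maximization tests.

## Simulation engine

`simulate_counts` draws tables group-wise from the trinomial law.
`tie_study` and `power_study` report rejection proportions with
Monte-Carlo standard errors sqrt(p(1−p)/R) and the robustness label at
α = 0.05 (liberal > 0.06, conservative < 0.04, robust otherwise). The
nine procedures are addressed as `A:|C:|M:` × `lrt|score|wald`; exact
procedures reuse one enumerated space per group-size configuration, with
M p-values for all members from the nested-tail sweep and C p-values
cached per response-margin signature. Either Monte-Carlo sampling or
(for the M test) exact enumeration of the size is available, since the
rejection region is computed exactly whenever the space fits the cap.

Seeding: one master seed spawns an independent child stream per grid
point (`numpy.random.SeedSequence`), so studies are bit-identical across
runs and independent of evaluation order.

Default replications are 2,000 per grid point (configurable), keeping a
full TIE surface desk-scale; the validation suite uses R = 5,000 at a
single null point (g = 2, m_i = 200, π = 0.3, γ = 0.6), where each
asymptotic test's empirical size falls in [0.04, 0.06] and the score
test sits closest to the nominal level. Power checks use the two-group
setting π = (0.2, 0.3), γ_2 = 0.1 with γ_1 varied.

## What the generator does and does not emulate

Simulated data are exactly trinomial per group — the model's own
sampling law. Real bilateral data can violate the model's core
assumption (γ independent of π), exhibit overdispersion across clinics
or time, or include unilateral-only patients by design. Passing tests
therefore certify the inference machinery *under the model*, not the
model's fit to any particular clinical dataset.

## Numerical choices and limitations

- Tail membership tolerance 1e−9; conditional probabilities normalized
  in log space (`gammaln`); statistics carried at full float precision,
  display rounded to 4 decimals.
- The M p-value grid scales as `grid_points`^(g+1); with the default 21
  it is practical for g ≤ 3 and small m_i. Larger problems should use
  the conditional method (the size error says so).
- Refinement can exceed any fixed-grid evaluation: on the two-patient
  two-group space the refined supremum is exactly 1/2 (attained at
  γ = 2/3, off a regular grid), which the test suite checks in closed
  form.
- The bundled OME dataset exists in two mutually inconsistent printed
  presentations; both are shipped (`ome_table4`, `ome_mstar`), neither
  privileged, and they are used for demonstration only.
- Confidence intervals, alternative dependence models (constant-R,
  common-ρ), small-sample corrections and one-sided alternatives are out
  of scope.
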