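# Methods

This document states the models the package implements, the parameter
conventions, the numerical methods, and the deliberate design choices and
limitations. Time is in **days** throughout; cohort ages and
post-vaccination times in years are converted with 365.25 days/year.

## 1. Label availability in body water

During a labelling study participants drink ²H₂O: a full dose during day 0–1,
half dose until day 49, then washout. Saliva enrichment (a proxy for body
water) follows the first-order uptake balance

    w'(t) = δ (u(t) − w),   u(t) = f, f/2, 0 on the three phases,

whose closed-form solution is the three-phase curve `S(t)` with plateau
fraction `f` and body-water turnover `δ` (per day): exponential rise toward
`f` before day 1, relaxation toward `f/2` until day 49, exponential washout
after. `S` is continuous with `S(0) = 0`. `fit_saliva` estimates `(f, δ)` by
least squares.

## 2. Monocyte amplification factor

Newly synthesised DNA amplifies body-water enrichment by a factor `b_w`,
estimated from blood monocytes — a population that turns over fast enough to
approach complete labelling. The model is a marrow precursor pool M feeding
blood B after a fixed post-mitotic transit delay Δ:

    L_M' = p_m b_w S(t) − r₁ L_M
    L_B'(t) = r₁ (M/B) L_M(t − Δ) − r₂ L_B(t)

Equilibrium of the precursor pool forces `p_m = r₁`, and conservation of
flow `r₁ = r₂ / (M/B)`. The pool-size ratio `M/B = 2.6` and delay
`Δ = 1.6 d` are fixed at literature values; `fit_monocyte` estimates
`(b_w, r₂)`. Because `b_w` is identified by the plateau enrichment, it is
insensitive (≤1%) to the choice of `M/B` and Δ whenever the monocyte curve
actually plateaus — the acceptance suite verifies this invariance.

## 3. Lineage models

Three pools of constant size: T_N (naive), CD95int and CD95hi T_SCM, with
pool-size ratios `R₁ = CD95int/T_N` and `R₂ = CD95hi/T_N` fixed per donor
from flow cytometry. Per-day rates: proliferation `p_N, p₁, p₂`,
disappearance `d_N, d₁, d₂`, naive differentiation `Δ_N` with clonal burst
`2^k` (a recruited naive clone divides k times before entering memory), and
inter-subset differentiation `δ₁`.

- **A** (independent, homogeneous): `d_i = p_i`.
- **B** (independent, heterogeneous): the *labelled*-cell disappearance
  rates `d*` are fitted directly and may differ from the population rates.
- **C** (forked): the burst output splits, a fraction `frac` into CD95int
  and `1 − frac` into CD95hi.
- **D** (linear, CD95int first): burst enters CD95int, which feeds CD95hi
  at rate `δ₁`.
- **E** (linear, CD95hi first): mirror image of D.

Constant pool sizes eliminate the disappearance rates, e.g. for model D:

    d_N = p_N − Δ_N
    d₁  = p₁ + Δ_N 2^k / R₁ − δ₁
    d₂  = p₂ + δ₁ R₁ / R₂

Parameter sets implying a negative rate raise `InfeasibleParameters` and are
rejected by the optimiser.

### Label enrichment

Each pool's M+1 DNA enrichment `L` obeys a linear ODE forced by
`b_w S(t)`; newly recruited burst cells contribute label
`Δ_N [(2^k − 1) b_w S + L_N] / R` per recipient pool. For the downstream
pool of models D/E the default equations conserve label mass (CD95hi label
arrives from CD95int at rate `δ₁ R₁/R₂` carrying CD95int's enrichment); the
alternative `as_printed=True` form writes the burst inflow directly into the
downstream pool instead.

For label-only fits of model C the burst exponent is not identifiable and
the model is fitted in the reparameterised space
`Π_i = p_i + Δ_N·branch_i·(2^k − 1)/R_i`, in which the label dynamics are
exactly those of the `k = 0` representative.

## 4. Observables

**Telomere difference θ** — base pairs lost per division `δ_tel = 50`.
For C–E the per-pool division-count excesses ν satisfy an affine system
`ν' = M ν + c` whose steady state gives
`θ = δ_tel (w₁ν₁ + w₂ν₂)`, `w_i = R_i/(R₁+R₂)`; the `ode` method integrates
to a 100-year horizon and verifies equilibration, the `algebraic` method
solves `Mν = −c` directly. Models A/B never equilibrate and are evaluated
at a reference age (34 years).

**Vaccine decay** — after vaccination naive inflow stops; antigen-specific
frequencies decay as a two-pool cascade. For model D the upstream pool is
`T₁ = A e^{−αt}` with `α = Δ_N 2^k / R₁`, and
`T₂ = [(γ − α − δ₁) A e^{−γt} + δ₁ A e^{−αt}] / (γ − α)` with
`γ = δ₁ R₁ / R₂` (the removable `α = γ` singularity is replaced by its
analytic limit `A e^{−αt}(1 + δ₁ t)`). Total `Y = T₁ + T₂` starts at `2A`.
Models A/B predict constant frequencies, model C two independent
exponentials.

**Clonal half-lives** — `ln 2 / (net clonal loss rate)`, e.g. model D:
`ln2 R₁/(Δ_N 2^k)` for CD95int and `ln2 R₂/(δ₁ R₁)` for CD95hi; infinite
when there is no net clonal loss, undefined for A/B.

**Residency times** (model D) — reciprocal of the total per-cell exit rate:
`1/(d₁ + δ₁)` and `1/d₂`.

## 5. Joint inference

The objective is the sum of squared residuals, each normalised by the
arithmetic mean of the observations of its data type: the three label series
pooled as one type, the telomere donors, and the (single-vaccination) YFV
cohort. Multiple vaccinees are excluded by default.

Optimisation: rates are searched in log₁₀ space inside [1e−10, 0.5]/day,
`k ∈ [0, 15]`, `frac ∈ [0, 1]`, `A ∈ (0, 1]`%. Starts are drawn from a
`SeedSequence(master_seed)` child stream — the first n children are the same
for any larger `n_starts`, so enlarging the search can only improve the
result. Each start gets a bounded Nelder–Mead burn-in followed by a
trust-region-reflective least-squares polish on the residual vector; the
winner is re-polished more deeply. Infeasible points evaluate to +inf for
the simplex and to a large finite penalty vector for the least-squares
solver.

Uncertainty: a nonparametric bootstrap resamples observation rows with
replacement within each data type (keeping each type's n), refits with the
point estimate as an extra warm start, and reports medians and
interquartile ranges over replicates; clonal half-lives are summarised from
the replicate parameter sets rather than the point estimate because the
parameters are strongly correlated.

## 6. Numerical methods

Every forcing term in the package is itself the solution of a linear ODE
with piecewise-constant inputs, so the augmented state
`[w, L_N, L₁, L₂, 1]` evolves as `z' = M_j z` on each protocol phase.
`PiecewiseLinearSystem` propagates with batched matrix exponentials — exact
up to floating point and fast enough for the optimiser's inner loop
(~1 ms per objective evaluation for 77 observations). An independent
`method="ode"` route (LSODA, rtol 1e−8 / atol 1e−10) exists for every
trajectory and the two agree to ~1e−10; the test suite keeps both routes
honest against quadrature convolution oracles.

Typical problem sizes: 13 sampling days × 3 pools of labelling data,
16 saliva points, 5 telomere donors, a 37-donor cross-sectional cohort;
7 free parameters for the joint model-D fit.

## 7. Synthetic data

`synthetic_data` defines the simulated study: the labelling protocol above
sampled at 13 days to day 140 with four analytic replicates per point
(per-point SD recorded), a 5-donor telomere cohort (ages 26–52, 150 bp
measurement noise), and a 37-donor vaccine cohort log-uniform over
0.27–35 years post-vaccination with multiplicative lognormal noise
(σ = 0.4) and four flagged multiple vaccinees. The default ground truth
uses the plausible rate scale p_N ≈ 3e−4, p₁ ≈ 8e−4, p₂ ≈ 2e−3 per day with
`Δ_N = 1e−6` (scaled so the differentiation flux is identifiable over a
140-day study) and `k = 10.3`.

What the generator does **not** emulate: GC/MS mass-spectrum shape (it
produces enrichment values directly), donor-to-donor parameter
heterogeneity within one study, cell sorting impurities, and attrition or
missed visits.

## 8. Known limitations

- `p₁` is weakly identified at this study design: the label production rate
  `Π₁ = p₁ + Δ_N 2^k/R₁` is dominated by the differentiation flux, so `p₁`
  is the difference of two much larger numbers and its estimate relies on
  the noisy cross-sectional telomere and vaccine data. Simulation studies
  show noticeable bias in single realisations; bootstrap interquartile
  ranges (nominal 50% intervals) cover the truth in only ~60–70% of
  simulated studies for the four differentiation parameters.
- Models are deterministic and pools constant; no growth, ageing or
  homeostatic drift over the study window.
- Telomere and vaccine donors are distinct from labelled donors; their
  residual blocks are attached to each labelled donor's objective, which
  double-counts the shared data if multiple donors are fitted jointly
  (donors are fitted independently, as intended).
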