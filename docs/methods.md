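# Methods

## Model

All modelling happens on normalized, accumulated series. A raw positive
series x⁽⁰⁾ = (x⁽⁰⁾(1), …, x⁽⁰⁾(n)) is first *initialized* — divided by its
first observation, so every series starts at 1 and different units become
comparable — then transformed by the first-order accumulated generating
operation (1-AGO) x⁽¹⁾(k) = Σ_{j≤k} x⁽⁰⁾(j). The *background* series
z⁽¹⁾(k) = ½(x⁽¹⁾(k) + x⁽¹⁾(k−1)) is the trapezoidal stand-in for the
one-step integral of x⁽¹⁾ when the continuous ("whitening") equation
dx₁⁽¹⁾/dt + a·x₁⁽¹⁾ = Σ bᵢ(xᵢ⁽¹⁾)^γᵢ is discretized. Equivalently
z⁽¹⁾(k) = x⁽¹⁾(k−1) + ½x⁽⁰⁾(k); both forms are computed and tested as an
identity.

The discrete models estimated here are

- **GM(1,N)** (linear): x₁⁽⁰⁾(k) + a·z₁⁽¹⁾(k) = Σᵢ bᵢ·xᵢ⁽¹⁾(k), k = 2..n;
- **NGM(1,N)** (nonlinear): the same with driver terms (xᵢ⁽¹⁾(k))^γᵢ.

Solving the nonlinear equation for x₁⁽⁰⁾(k) with z expanded gives the
*derived* model (TNGM): x₁⁽⁰⁾(k) = Σ βᵢ(xᵢ⁽¹⁾(k))^γᵢ − α·x₁⁽¹⁾(k−1) with
β = b/(1+½a), α = a/(1+½a). In this package (α, β) are a computed view of
(a, b), never independently estimated or stored, so the two
parameterizations cannot drift apart. The transform is singular at a = −2
(rejected), and with γ ≡ 1 every nonlinear operation reduces exactly to its
linear counterpart (tested to 1e-12).

### Two fitted-value conventions

Given parameters, "the fitted series" can mean two different things, and
the package exposes both explicitly:

1. **Difference-equation fit** (in-sample default):
   x̂₁⁽⁰⁾(k) = −a·z₁⁽¹⁾(k) + Σᵢ bᵢ(xᵢ⁽¹⁾(k))^γᵢ, using background values
   computed from the *actual* data. Position 1 is pinned to the actual
   value, so its error is 0 by construction.
2. **Time-response recursion** (out-of-sample):
   x̂₁⁽¹⁾(k+1) = [x₁⁽¹⁾(1) − S(k+1)/a]·e^(−ak) + S(k+1)/a with
   S(k+1) = Σᵢ bᵢ(xᵢ⁽¹⁾(k+1))^γᵢ, followed by inverse accumulation. This
   is the grey-constant approximation of the whitening-equation solution
   and needs no actual system values beyond the initial one — it is the
   forecasting mode, used by `greycast forecast` (which requires future
   driver values explicitly; nothing is extrapolated silently, though an
   exponential-trend helper for drivers is available).

The difference-equation fit and the derived-form fit
f_der(k) = (S(k) − a·x₁⁽¹⁾(k−1))/(1+½a) coincide exactly only at zero
residual; in general they satisfy the affine identity
f_diff(k) + ½a·x₁⁽⁰⁾(k) = (1+½a)·f_der(k), which the tests assert.

## Estimation

**Linear model.** Stacking k = 2..n gives B·[a, b₂..b_N]ᵀ = Y with rows
[−z₁⁽¹⁾(k), x₂⁽¹⁾(k)^γ₂, …]. `ols_estimate` handles the three rank cases:
square-and-invertible (exact solve), overdetermined (unique least-squares
solution; numerically singular designs raise an error carrying the
condition number), underdetermined (minimum-norm pseudoinverse solution).
The solve uses an SVD-based least-squares factorization, never an explicit
inverse; condition numbers above 1e8 are logged.

**Nonlinear model.** The residuals r(k) = x₁⁽⁰⁾(k) + a·z(k) − Σ bᵢ(xᵢ⁽¹⁾(k))^γᵢ
are linear in (a, b) and nonlinear in γ, which the block Gauss–Seidel
solver exploits:

1. with γ fixed, (a, b) solve in closed form by OLS on the γ-transformed
   design;
2. each γᵢ updates by bounded Brent 1-D minimization of the full residual
   sum of squares, all other parameters at their freshest values (a
   safeguard rejects any step that would increase the objective);
3. sweeps repeat until e = max|θ(j+1) − θ(j)| < tol or `max_iter` sweeps.

Every block update is an exact conditional minimization, so the objective
is non-increasing across sweeps — a tested invariant. Non-convergence is
flagged on the returned diagnostics (full per-sweep trace: parameters,
objective, deviation), not raised.

*Conditioning.* The (b, γ) blocks are nearly collinear: when the mean log
of an accumulated driver is far from zero, changing γ acts mostly as a
rescaling of b, and coordinate descent crawls along the resulting valley.
The solver therefore rescales each accumulated driver by its geometric
mean internally (b·x^γ = (b·cᵞ)·(x/c)^γ, so the transformed coordinates
decouple), and maps iterates back to the original scale for reporting.
The optimum is mathematically identical; convergence on the packaged data
drops from thousands of sweeps to a few hundred, and noiseless synthetic
parameters are recovered to better than 1e-6.

*Cross-check.* `fit_nls_lm` solves the same problem by damped Gauss–Newton
steps over the full parameter vector (trust-region reflective, so the γ
bounds are honoured). The two solvers agree to ~1e-7 on the packaged data;
the test suite requires 1e-4. Running both is the standard guard against a
block scheme stalling at a non-optimum.

### Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `init` | all zeros | starting vector [a, b, γ]; γ=0 makes the first linear block regress on constant driver columns, which is well defined |
| `tol` | 1e-8 | stopping threshold on the max absolute parameter change per sweep; the 1-D line search resolves γ to ~1e-9, so tolerances much below 1e-8 cannot be certified |
| `max_iter` | 500 | sweep cap; the packaged fits need a few hundred to ~1400 sweeps, so reproduction runs pass 5000 |
| `gamma_bounds` | [−5, 5] | guards against overflow when accumulated series are raised to large powers |
| `n_starts` / `seed` | 0 / 0 | optional seeded random restarts around the zero start (off by default; the packaged fits are unimodal as far as both solvers can tell) |
| normalization | `first` | `first` divides by the first observation (the packaged study's convention), `mean` by the series mean, `none` leaves data as-is |

## Evaluation

Signed percentage errors (actual − fitted)/actual × 100 (positive =
under-prediction). Because the base epoch's error is 0 by construction,
MAPE has two conventions: `exclude_base` (epochs 2..n; default) and
`include_base` (all n, diluting the mean by one zero term). Both are always
computed; comparisons report both to keep the choice visible.

Trend classification is descriptive only: the sign pattern of first
differences (with a relative flatness tolerance, default 1e-6 of the
series scale) maps a curve to increasing / decreasing / U_shaped /
inverted_U / mixed. At most one sign change earns a named shape. When
classifying *fitted* curves the pinned base value should be excluded
(`classify_trend(result.fitted[1:])`): fitted(1) is copied from the data,
not produced by the model, and a jump from that anchor into the model's
level would otherwise masquerade as an extra turning point.

## Synthetic data

`simulate` runs the derived recursion forward with known parameters:
x₁⁽⁰⁾(k) = [Σ bᵢ(xᵢ⁽¹⁾(k))^γᵢ − a·x₁⁽¹⁾(k−1)]/(1+½a) + ε(k), x₁⁽⁰⁾(1) = 1,
ε ~ N(0, noise_sd²), with drivers either explicit or geometric-growth
series starting at 1. Defaults are the conditions of the packaged
wastewater model: n = 20 annual points, one driver growing 12%/year (the
geometric growth rate of GDP per capita in the packaged data), (a, b₂, γ₂)
= (−0.0426, 1.0168, −0.099), no noise. A seeded generator makes every run
reproducible; parameter combinations that drive the system non-positive
are rejected (fractional exponents downstream require positivity).

What the generator does *not* emulate: measurement error in drivers,
missing values, structural breaks, or any departure from the model's own
functional form. Passing recovery tests therefore certify the estimator
(the solver finds the generating parameters), not the model's adequacy for
any particular real series.

## Numerical choices and degenerate inputs

- Real powers require positive accumulated drivers when γ is fractional;
  zero base with γ > 0 yields 0, zero/negative base with fractional or
  negative γ is an error (no complex branches).
- a = 0 invalidates the closed-form time response (degenerate-model
  error); a = −2 invalidates the derived transform.
- Series must have ≥ 4 observations, strictly increasing constant-step
  integer epochs, finite values; model series must be positive. Missing
  values enter only through `mean_substitute` (observed-mean imputation
  with a provenance mask); models reject incomplete series.
- CSV I/O writes 15 significant digits, making round-trips exact for data
  of ordinary magnitude.
- Fitted-table layout, JSON report schema and the iteration-trace CSV are
  stable and timestamp-free, so identical inputs give byte-identical
  reports.

## Known limitations

- The in-sample MAPEs quoted for the packaged study use the
  difference-equation convention; recursion-based (true forecast) errors
  are substantially larger for these series, as the accumulated drivers
  here change far too much for the grey-constant approximation to be
  accurate. Use the recursion only for genuine forecasting, and prefer
  short horizons.
- n = 20 with 3–5 parameters leaves few degrees of freedom; the fit
  quality differences between models are descriptive, not inferential (no
  standard errors or hypothesis tests are provided).
- One global exponent per driver cannot capture series with several
  regimes; heavily fluctuating series (the dust data late years) are fitted
  only in broad shape.
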