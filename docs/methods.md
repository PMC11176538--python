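# Methods

## Model and assumptions

`mmcsim` models non-muscle-invasive bladder cancer under *continuous*
intravesical mitomycin-C (MMC). Three ordinary differential equations track
the drug amount M [µM], the tumor cell count T, and a lumped effector
compartment E (dendritic cells + cytotoxic T lymphocytes):

    dM/dt = -mu1*M + m
    dT/dt = -T*(p1*M/(M+a) + p2*E) + r*T*(1 - T/k)
    dE/dt = d0 + gamma*p1*T*M/(M+a) - E*(p3*T + mu2)

Key simplifications: tumor cells are homogeneous (no stem-cell or Treg
subpopulations), there is no spatial structure, and the clinically pulsed
instillation schedule is replaced by a constant source `m` obtained by
spreading a course dose over `tau` days. The biological range of interest
is 0 ≤ T ≤ k; states above k are legal for the mathematics and trigger a
warning, never clipping.

## Parameters

| name  | meaning                                   | unit            | default   |
|-------|-------------------------------------------|-----------------|-----------|
| mu1   | MMC washout rate                          | 1/day           | 21.05     |
| m     | MMC instillation rate (0 = untreated)     | µM/day          | 6.561     |
| r     | tumor proliferation rate                  | 1/day           | 0.0275    |
| k     | tumor carrying capacity                   | cells           | 5.45e8    |
| p1    | MMC kill rate of tumor cells              | 1/day           | 0.16      |
| a     | half-saturation of the MMC kill term      | µM              | 100       |
| p2    | effector kill rate of tumor cells         | 1/(cells·day)   | 4.6e-6    |
| d0    | effector production rate                  | cells/day       | 1.032e5   |
| gamma | effector activation multiplier            | —               | 9.12      |
| mu2   | effector death rate                       | 1/day           | 9.12      |
| p3    | effector deactivation rate                | 1/(cells·day)   | 1.345e-6  |

r, k, p1, p2 and p3 are only known to literature intervals
(`mmcsim.params.PARAMETER_RANGES`); their defaults are the interval
midpoints, and every default is overridable from YAML/JSON. The default
`m = 6.561` µM/day is the standard 40 mg / 50 ml protocol (MW 334 g/mol →
2,395 µM) spread over 365 days; `mu1 = 21.05`/day corresponds to a
47.4-minute intravesical half-life.

A note on `gamma`: its catalogued unit (1/day) makes the activation term
`gamma*p1*T*M/(M+a)` dimensionally awkward for a cells/day balance. The
package treats `gamma` as a pure numeric multiplier and evaluates the
equation exactly as written; no rescaling is attempted.

## Equilibria and stability

With `I1 = p2*d0/mu2` (immune kill intensity) and
`I2 = p1*(m/mu1)/((m/mu1)+a)` (drug kill intensity, bounded by p1):

* untreated homeostasis `(0, 0, d0/mu2)` — eigenvalues
  `[-mu1, r - I1, -mu2]`, locally stable iff `r < I1`;
* treated tumor-free `(m/mu1, 0, d0/mu2)` — eigenvalues
  `[-mu1, r - I1 - I2, -mu2]`, locally stable iff `r < I1 + I2`.

"Stable" means strict negativity of all real parts; a zero real part is
reported as non-stable with a `marginal` flag. Interior (cancer)
equilibria are found by fixing `M* = m/mu1`, eliminating
`E*(T) = (d0 + gamma*c*T)/(p3*T + mu2)` (with `c` the per-cell drug kill at
`M*`), and clearing denominators from the tumor balance, which leaves a
quadratic in T — so at most two interior equilibria exist, found by
`numpy.roots` and filtered to real roots in (0, k]. This exhaustive
polynomial route avoids iterative-solver seeding; tests cross-check it
against a million-point sign-change scan of the un-cleared scalar
condition. At the defaults the unstable interior root is the cure/
persistence basin boundary and the stable one is the high-burden attractor.

## Numerics

* **Solver.** `scipy.integrate.solve_ivp` with LSODA by default. The
  effector equation relaxes at rate `p3*T + mu2`, which reaches several
  hundred per day when T approaches k, so persistence runs are stiff;
  LSODA handles the switch automatically and agrees with the explicit
  RK 5(4) option (`method="RK45"`) to well below solver tolerance (the
  drug component matches its closed form
  `m/mu1 + (M0 - m/mu1)*exp(-mu1*t)` to ~1e-10 for both). Defaults:
  rtol 1e-8, atol 1e-6.
* **Outcome classification.** Cure iff the final tumor count is strictly
  below the cure threshold (default 1 cell); a tie counts as persistence.
* **Basin-boundary bisection.** Log10-space bisection to 1% relative
  bracket width, returning the geometric midpoint. Probe runs default to a
  3,000-day horizon in the CLI: near the saddle the unstable eigenvalue is
  only ~1e-2/day, so a 400-day run cannot separate outcomes 1% on either
  side of the boundary.
* **Degenerate inputs.** The public RHS/Jacobian reject negative or
  non-finite states; the integrator's internal RHS is unchecked because
  adaptive solvers probe slightly negative states near zero. Positive
  invariance is enforced by test (trajectory minima ≥ -10·atol over 200
  random admissible runs), not by projection.

## Dose-determination algorithm

Solving the treated stability criterion for `m` gives, per parameter set,
an eligibility window `I1 < r < I1 + w` and a dose bound
`m_b = mu1*a*(I1 - r)/(r - I1 - w)`, positive exactly inside the window,
vanishing at the lower edge and diverging at the upper edge. Two window
widths are shipped:

* `scaled` (default): `w = p1/mu1`. This is the variant the
  dose-determination algorithm and the cohort experiment are built on.
* `algebraic`: `w = p1`, the width obtained by direct algebra on
  `r < I1 + I2(m)`. Because `I2` is increasing in `m`, this bound is the
  *minimum* stabilizing rate: `I1 + I2(m_b) = r` holds exactly at the
  bound and stability holds above it (verified numerically in tests).

The two variants differ by the 1/mu1 scaling of the window width and by
interpretation (the scaled variant is presented as an upper bound, the
algebraic one is mathematically a lower bound); both are exposed so the
discrepancy is visible rather than silently resolved. The recommendation
step converts `m_b` to a mg course dose through the same
tau/volume/molecular-weight chain as the unit module (so 40 mg ↔ 6.561
µM/day round-trips exactly), then classifies: bound above the 40 mg
recommended maximum → over-toxicity, capped at the maximum; growth rate
outside the window or bound below a configurable 1 mg floor ("negligible
dose") → theoretical non-responder; otherwise eligible.

## Virtual cohort

`virtual_experiment(n, seed)` draws n parameter sets with the ranged
constants (k, p1, p2, p3) uniform in their literature intervals and the
point-estimate constants fixed (the sampling law is a package choice; a
custom `variation` mapping can widen any parameter). For each patient the
growth rate is then drawn uniformly from the open eligibility window —
guaranteeing `I1 < r` — and the dose bound and classification follow. All
draws flow through one `numpy.random.Generator`, so the experiment is
reproducible from (seed, n, variation). At the defaults nearly all
patients land in the over-toxicity class; the eligible minority sits just
above the lower window edge, where the bound passes through the 1–40 mg
range.

## Sensitivity analysis

`run_sensitivity` varies all eleven parameters over [default/2, 2×default]
with uniform marginals, stratified by `scipy.stats.qmc.LatinHypercube`
(1,000 samples by default), integrates each sample to day 365 under
treatment from T0 = 1e7 cells (a mid-size tumor where the outcome is
genuinely parameter-dependent), and computes partial rank correlation
coefficients of T(365): ranks of each parameter and of the output are
residualized against all other rank-transformed parameters and the
residuals correlated, with p-values from the t distribution on
`n - 2 - (d - 1)` degrees of freedom (significance at alpha = 0.01).
Constant or perfectly collinear columns raise a named error rather than
producing silent output. The implementation is cross-checked against
pingouin's partial Spearman correlation on a small synthetic case.

Observed structure at the defaults: anti-tumor parameters (m, d0, p1, p2,
gamma) correlate negatively with tumor burden, pro-tumor parameters (r,
p3, mu2, mu1) positively, and p2, r, d0 dominate in magnitude. A
full-factorial `uncertainty_sweep` over explicit grids complements this
for the two least-constrained constants, mu1 and a.

## What the synthetic experiments do and do not show

The cohort and sensitivity experiments sample hypothetical, not observed,
patients: uniform distributions over literature intervals stand in for an
unknown population law, point-estimate parameters carry no uncertainty,
and inter-patient variability in washout and drug response is only
represented through the varied constants. Passing tests therefore
demonstrate internal consistency of the model, its analysis and its
algorithmic pipeline — not clinical validity. The parameter values are
exploratory estimates from animal, cell-line and human-tumor sources and
are not suitable for treatment decisions.

## Known limitations

* Continuous instillation only; no pulsed/periodic dosing.
* No spatial tumor structure, no tumor or immune heterogeneity, no
  pharmacokinetic compartment beyond first-order washout, no toxicity
  model beyond the mg cap.
* Basin thresholds depend on the within-range parameter choice; with the
  midpoint defaults the untreated and treated thresholds are ~6.2e6 and
  ~1.65e7 cells, and they shift with r, d0 and the other ranged constants.
* The disc geometry (3 cell layers, 1e6 cells/mm³) ties cell counts to
  clinical diameters; the "large tumor" reference pair (6.62e7 cells ↔
  26.5 mm) is only consistent if 26.5 mm is a radius, so the API takes
  explicit diameter/radius arguments.
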