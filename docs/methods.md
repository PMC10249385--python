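# Methods

## Model conventions

All three parameterizations describe one curve ln k(T) for a given compound,
stationary phase, and phase ratio. Internally everything is SI (K, J, mol,
s, Pa, m); files and CLI boundaries use °C and minutes, matching how
retention tables are published.

The Clarke–Glew coefficients stored in database files parameterize the
distribution coefficient, ln K(T) = A + B/T + C·ln(T/T₁) with T₁ = 1 K; the
retention factor follows from K = k·β as ln k = ln K − ln β₀. This
convention is deliberate and load-bearing:

* the thermodynamic conversion is then β-free and exactly
  ΔC_p = C·R, ΔH_ref = C·R·T_ref − B·R,
  ΔS_ref = A·R + C·R·(1 + ln(T_ref/T₁)),
  which reproduces published parameter tables at their printed precision
  with R = 8.31446 J mol⁻¹ K⁻¹ (both values are fixed by that calibration);
* the ABC ↔ K-centric conversion carries the ln β₀ term, because T_char and
  θ_char are defined on ln k, not ln K. The Lambert-W argument is
  x = −(B/C)·exp((A − ln β₀)/C)/T₁ and the −1 branch gives T_char;
  θ_char = T_char²/(B − C·T_char) is the negative inverse slope at the root.
  With this convention published coefficient tables yield physically
  sensible characteristic temperatures (θ_char ≈ 30 K, T_char within the
  usable column range) and the branch criterion −1/e < x < 0 holds exactly
  for the entries that pass validation.

An alternative convention — folding −ln β₀ into A — makes the same tables
produce ln k values far outside the measurable range and leaves most entries
without any real T_char, so it was rejected. With β₀ = 1 both conventions
coincide.

Degenerate inputs: |C| < 10⁻¹² selects an explicit two-parameter branch
(T_char = B/(ln β₀ − A), θ_char = T_char²/B) because the Lambert form is
singular there. C < 0 raises a conversion-domain error unless the caller
explicitly requests the two-parameter fallback; arguments x outside
(−1/e, 0) always raise — entries are flagged downstream, never silently
repaired.

## Fitting

The measurement model is additive Gaussian noise on ln k. Since the ABC
form is linear in (A, B, C), the weighted least-squares optimum is first
computed exactly by linear algebra; the nonlinear K-centric fit
(`scipy.optimize.least_squares`, xtol = ftol = 10⁻¹⁰, parameter scaling
(100, 10, 100) K/K/(J mol⁻¹ K⁻¹)) is seeded from its conversion and supplies
Jacobian-based standard errors directly on (T_char, θ_char, ΔC_p). When the
linear solution has no characteristic temperature, initialization falls back
to the interpolated ln k = 0 crossing with θ_char = 30 K and
ΔC_p = 100 J mol⁻¹ K⁻¹ (typical magnitudes for mid-polarity phases).
Points with ln k outside [−2.0, 3.5] are excluded before fitting
(boundaries inclusive — the permissive reading of the range criterion) and
reported separately from robust-fit outliers. Non-convergence flags the
result rather than raising.

### Robust fitting

Trimmed least squares: for every candidate trim count m = 0…⌊n/4⌋ the best
size-(n−m) subset is found — exhaustive enumeration of excluded sets for
n ≤ 12, seeded random elemental starts with concentration steps (FAST-LTS
style, 100 starts, ≤ 25 steps) beyond — using the exact linear ABC solution
for subset scoring. The selected m is the smallest whose unbiased scale
s_m = √(RSS_m/(n−m−3)) lies within a factor 2 of the best scale across all
m, with an absolute floor of 10⁻⁸ so numerically exact data never trims.
Rationale: removing a genuine outlier collapses the scale (far more than
2×), while trimming ordinary noise shrinks it only by ~20 %. The scheme is
a self-contained stand-in for published robust-regression packages whose
exact settings are not documented; all stochastic paths take explicit seeds.

## Validation

Criteria (a)–(g) listed in the README are evaluated independently and all
failures collected. The range criterion (b) concerns raw points and is
enforced at fit time; entry-level validation records the min/max ln k that
were used. Criterion (g) is evaluated on the converted, post-roundtrip ABC
coefficients; for entries whose conversion succeeded with C > 0 it is
mathematically implied, so a (g) failure there would indicate a conversion
bug (asserted as a cross-check in the test suite). θ_char bounds are
exclusive as printed. PCA quality control standardizes each column to unit
variance before the eigendecomposition — required because (T_char, θ_char,
ΔC_p) have incommensurate units — and reports explained-variance fractions
and scores only; no automatic exclusion is performed.

## Flow physics

Carrier viscosity uses a power law η(T) = η_ref·(T/T_ref)^ζ per gas, with
helium anchored to the literature datum 19.86 µPa·s at 298.15 K (Kestin, Ro
& Wakeham 1972) and exponents chosen to track tabulated values over
300–600 K to within ~2 %. The constants live in an overridable registry
(`gcretention.flow.GAS_PROPERTIES`), not in code paths. Pressures are
absolute throughout. Holdup time uses the compressible-laminar closed form;
its inverse (inlet pressure for a prescribed flow) is analytic. Volumetric
flow specifications like "1 mL/min" are referred to 25 °C and 1 atm by
default and configurable, since instrument conventions differ. Column
geometry estimation inverts the holdup relation per measurement and reports
the mean L/d with its standard error across measurements; a single
measurement reports the error as absent, not zero.

## Simulation

Solute migration integrates dt/dz = (1 + k(T(t)))/u(z, t) over the fixed
domain z ∈ [0, L] (`solve_ivp`, RK45, rtol 10⁻⁸ default), with u from the
parabolic pressure-squared profile. In constant-flow mode the inlet
pressure is recomputed from the viscosity at T(t) at every right-hand-side
evaluation (quasi-static assumption). The column temperature is spatially
uniform; devices with deliberate axial thermal gradients are out of scope.
Retention parameters are phase-ratio corrected from their β₀ to the
column's β before use. Compounds not eluted within 10× the program span
(or 600 min for ramp-free programs) are flagged as non-eluting rather than
raising. The chromatogram renderer (Gaussian peaks, σ_t = t_R/√N_plates,
default 10⁵ plates, unit area) is a presentation aid only; nothing
quantitative depends on it.

## Synthetic data

The generator emulates the standardized determination protocol: an
isothermal grid of 60–300 °C in 10 °C steps (the documented measurement
range), ln k from the K-centric model, homoscedastic Gaussian noise on ln k
(an optional heteroscedastic stress mode scales σ by |ln k|), and optional
truncation to the acceptable ln k window. Synthetic databases draw
(T_char, θ_char, ΔC_p) from per-category Gaussian templates — mimicking the
clustering of substance classes in the K-centric parameter space — and
complete all three parameterizations self-consistently. What the generator
does **not** emulate: peak-shape degradation, detector noise, drift between
replicate runs, co-elution, or adsorption contributions to retention; tests
passing on synthetic data therefore demonstrate correctness of the
estimation and simulation machinery, not robustness to every artifact of
real chromatograms.

The end-to-end identity anchoring the pipeline — fitting a noiseless
generated series returns the generating parameters to 10⁻⁶ relative — is
part of the test suite, as is Monte-Carlo coverage of the reported
3-standard-error intervals (100 replicates at σ = 0.02 on ln k).

## Known limitations

* Pressure dependence of K, mixed retention mechanisms, and adsorption on
  the phase surface are not modeled.
* Fitting consumes isothermal data only; estimating parameters directly
  from temperature-programmed runs is not supported.
* The thermodynamic ΔS_ref inherits the β convention of the stored A
  coefficient; comparing entropies across files requires knowing their φ0.
* Vacuum-outlet (MS) scenarios must set the outlet pressure explicitly;
  no detector-specific corrections are applied.
* Viscosity power laws are fit-for-purpose over 200–700 K; outside that
  range they extrapolate without warning.
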