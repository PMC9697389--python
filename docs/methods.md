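# Methods

## Scope and unit conventions

The package analyses three kinds of measurement series for a single
solute in a fixed solvent: solubility vs temperature, density vs
(molality, temperature) and viscosity vs (molality, temperature), plus
a solvent baseline ρ₀(T), η₀(T), V̄₁°(T). Units are fixed pipeline-wide
— K, mol·kg⁻¹, g·cm⁻³, mPa·s, cm³·mol⁻¹, dm³·mol⁻¹ (Jones–Dole B only)
and kJ·mol⁻¹ — matching how these quantities are conventionally
tabulated; SI conversions happen once, inside the operation that needs
them (the activation free energy is the only place where Pa·s and
m³·mol⁻¹ appear).

The solvent partial molar volume V̄₁°(T) is an input, not computed from
ρ₀: for a mixed solvent (water + background cosolute) it is not simply
M_w/ρ₀, and treating it as data keeps the activation chain honest about
where that number comes from.

## Dissolution thermodynamics

ln x₁ is regressed by ordinary (unweighted) least squares on
(1/T − 1/T_hm), where T_hm = n/Σ(1/T_j). Centring at the harmonic mean
makes the intercept −ΔG°/(R·T_hm) at the "average" temperature of the
study and decorrelates slope and intercept on a 1/T grid. The mole
fraction x₁ is computed over solute + water only; at a background
molality of 0.1 mol·kg⁻¹ including the cosolute would shift x₁ by
< 0.6%, well under the scatter of solubility measurements, and the
convention must simply be fixed. The default water molar mass is
18.015 g·mol⁻¹, overridable in config.

The ζ split uses magnitudes, ζ_H = |ΔH°|/(|ΔH°| + |T_hm·ΔS°|), so that
both contributions are positive fractions summing to one even when the
entropy of dissolution is negative (as it is here, where
self-aggregation orders the system). The signed form would produce a
negative "fraction" whenever ΔH° and T·ΔS° have opposite signs, which
is not interpretable as a relative contribution.

Δ_sol S° is carried in kJ·K⁻¹·mol⁻¹; reports that want the J scale
multiply by 10³ at the presentation layer. This keeps ΔH° − T·ΔS°
arithmetic in one unit system.

## Volumetrics

V_φ = M/ρ − 1000(ρ − ρ₀)/(m·ρ·ρ₀) is the standard density form of the
apparent molar volume; it is exactly inverted by the synthetic density
generator, which is what makes zero-noise round-trip testing possible.
The Masson fit is a plain OLS line in molality (the non-electrolyte
form — no √m Redlich-type term, since there is no ionic-strength
physics for a neutral solute); its reported σ is √(SSR/(n−2)).

V_φ°(T) is fitted with an OLS quadratic in absolute temperature. The
expansibility E_φ° = a₁ + 2a₂T and the Hepler coefficient 2a₂ follow
analytically from the coefficients, so the invariants
E_φ°(T) linear-in-T and slope = 2a₂ hold exactly by construction. A
negative Hepler coefficient is labelled structure-breaking by the
classic criterion, with the caveat (stated in the analysis output's
vocabulary, not silently) that the criterion is unreliable for strongly
self-aggregating solutes.

Taste classification divides V_φ° by the molar mass and places the
apparent specific volume in the Birch ranges salty [0.1, 0.3), sour
[0.3, 0.5), sweet [0.5, 0.7), bitter [0.7, 0.9]. The ranges touch, so
an edge rule is needed: intervals are half-open with the upper edge of
bitter closed, and any value within ±0.015 cm³·g⁻¹ of an edge carries a
border flag (caffeine in SS solution sits at ≈0.69, on the sweet–bitter
border — the flag is the scientifically meaningful part of that
result). A 10⁻⁹ tolerance absorbs float noise at the closed edge.

## Viscometrics and activation

The Jones–Dole fit is constrained through the origin: the relation for
a non-electrolyte has no A√c electrolyte term, and allowing an
intercept would let noise masquerade as one. Concentration c is
converted from molality with the solution density of the matching row,
c = m·ρ/(1 + m·M/1000).

Classification: B > 0 and dB/dT < 0 → structure-maker; B > 0 and
dB/dT > 0 → atypical structure-maker (the behaviour of caffeine in
pure water); B < 0 → structure-breaker; mixed signs of B across the
grid → indeterminate. dB/dT is the OLS slope of B against T.

The activation chain evaluates Δμ₁°≠ = RT ln(η₀V̄₁°/(hN_A)) with η₀ in
Pa·s and V̄₁° in m³·mol⁻¹, and
Δμ₂°≠ = Δμ₁°≠ + (RT/V̄₁°)·(1000·B + V̄₂° − V̄₁°) with all volumes in
cm³·mol⁻¹ (B converted dm³ → cm³). The grouping of the volume term is
the one consistent with the published per-temperature values of this
system to the printed precision. ΔS₂°≠ is minus the OLS slope of
Δμ₂°≠(T) (a derivative estimated over all temperatures rather than a
finite difference, which would be noisier and grid-dependent) and
ΔH₂°≠ is evaluated on the fitted line at the harmonic-mean temperature
— using the fitted line rather than a raw table value keeps ΔH₂°≠
consistent with the ΔS₂°≠ estimate.

## Hydration numbers

Volumetric route: h_n = V_φ°(elect)/(Ve° − Vb°), with both numerator
and denominator negative for a hydrated solute. The electrostriction
volume V_φ°(elect) is supplied either directly per temperature or as
V_φ° − V_intrinsic with a user-chosen intrinsic volume
(intrinsic-subtraction mode); the package ships a default
(Ve° − Vb°)(T) table ({−3.6 … −2.6} cm³·mol⁻¹ over 293–313 K) that is a
configurable literature convention, not a measured property of this
dataset. Mixed-sign inputs produce a negative h_n, passed through with
a warning rather than masked.

Viscometric route: h_n = (1000·B/shape − V_φ°)/V̄₁° with shape
factor 2.5 (Einstein's value for rigid spheres), exposed as a parameter
because conventions differ between sources. With the reference B and
V_φ° values this gives ≈3.8 bound waters at 293.15 K falling to ≈2.2 at
313.15 K; the monotone decrease with temperature is the robust,
formula-independent feature, and it is what the tests assert. Absolute
magnitudes shift with the shape-factor convention by ~10–20% and are
not treated as reproducible constants.

## Synthetic data generator

Each generator inverts its analysis relation exactly:

* densities from ρ = ρ₀(M·m + 1000)/(V_φ·m·ρ₀ + 1000) with
  V_φ = V_φ°(T) + S_v(T)·m;
* viscosities from η = η₀(1 + B·c), with c computed from the generated
  density of the same (m, T) row;
* solubilities from ln x₁ = −ΔG°/(R·T_hm) − (ΔH°/R)(1/T − 1/T_hm),
  back-converted to g per kg of water.

Noise is Gaussian, homoscedastic and additive on the measured quantity
(ln x₁ for solubility), with defaults σ_ρ = 5·10⁻⁶ g·cm⁻³,
σ_η = 5·10⁻⁴ mPa·s, σ_lnx = 0.01 — typical vibrating-tube densimeter
and rolling-ball viscometer precision and ~1% relative solubility
scatter. The default grid is the study's: five temperatures
293.15–313.15 K and eight molalities from 0.01 to 0.105 mol·kg⁻¹.
The default ground-truth parameters are the published fit parameters
of the SS system (Masson intercepts/slopes, B row, ΔH°/ΔG° pair), so
"recovery" means recovering the study conditions.

Randomness: one integer seed; each table draws from an independent
`numpy` Philox-family stream keyed by (seed, crc32(table name)), so
generating one table never perturbs another and identical seeds give
bit-identical tables across processes.

What the generator does **not** emulate: temperature-dependent or
heteroscedastic noise, systematic (bias) errors such as calibration
drift, solute volatility or decomposition, and any departure from exact
linearity of the Masson and Jones–Dole laws. Passing recovery tests
therefore demonstrates correctness of the estimation chain under the
model's own assumptions, not robustness of the laws themselves to real
measurement pathology.

## Reference tables and back-solved fixtures

The packaged CSVs carry the published per-temperature parameters of
this system (solubility tables, Masson parameters, B-coefficients,
activation rows, transfer volumes). Two derived fixtures are explicitly
synthetic/back-solved and named accordingly: the SS-solvent η₀(T)
(inverted from the published Δμ₁°≠ row — forward evaluation reproduces
that row exactly) with a synthetic ρ₀(T), and the water-system V_φ°(T)
(published SS intercepts minus published transfer volumes). They serve
the generator and consistency tests, never as independent evidence.

A known internal tension in the reference data is documented rather
than patched: the published ΔH°/ΔG° pair of the dissolution table is
not reproducible from the published solubility table by the Van 't Hoff
regression, which yields enthalpies of tens of kJ·mol⁻¹ (consistent
with the strong solubility–temperature dependence). The pipeline always
reports the value fitted from the data it was given; the packaged
ΔH°/ΔG° reference pair is used only where the derived entropy/ζ
quantities are themselves defined in terms of that pair.

## Numerical choices and degenerate inputs

All fits are closed-form OLS on ≤ 8 points, so no initialisation or
convergence questions arise. Tables validate at construction (≥3
temperatures for solubility, ≥3 nonzero molalities per temperature for
series, positivity everywhere) and reject degenerate fits (identical
molalities, < 3 points) with typed errors. R² is reported as 1 for an
exactly flat response (zero total sum of squares) rather than NaN.
Result files are JSON with full-precision floats, so write→read round
trips are bit-identical; re-running a pipeline config reproduces every
output file byte-identically.

## Problem sizes

Tests and drivers run the study-sized problem (5 temperatures ×
8 molalities) throughout; the Monte-Carlo recovery study uses 200
replicates, enough to pin the medians well inside the claimed bounds
(measured medians are ≈3× to ≈13× below them).

## Known limitations

* Activity coefficients are ignored: the Van 't Hoff treatment is an
  apparent (van 't Hoff) analysis of ideal mole-fraction solubility.
* The mixed-solvent mole-fraction convention (cosolute excluded) is a
  documented choice, not a derivation.
* The viscometric hydration formula's shape factor is a convention;
  magnitudes from different conventions differ more than their
  temperature trends do.
* The Hepler criterion's interpretation is unreliable for
  self-aggregating solutes; the package reports the number and the
  conventional label, not a verdict.
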