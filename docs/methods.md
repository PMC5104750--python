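# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of the package. Everything quantitative stated here is
computed by the test suite or the analysis drivers; nothing is quoted from
elsewhere.

## Isotope arithmetic

All δ¹³C values are per mil against a reference standard, by default VPDB
with absolute ¹³C/¹²C = 0.0111796. Conversions go δ → ratio
R = (δ/1000 + 1)·R_std → atom fraction F = R/(1+R) and back; the round trip
closes to better than 10⁻⁹ ‰ across δ ∈ [−110, +2000] ‰. δ values at or
below −1000 ‰ (non-positive ratios) are rejected at construction.

Two-end-member mixing is computed in atom-fraction space by default, which
conserves the ¹²C and ¹³C inventories exactly (weights = water fraction ×
concentration); a δ-linear mode reproduces the customary back-of-envelope
approximation and is flagged as such in the result object.

## Closed-system Rayleigh model

Forward: δ(f) = (δ₀+1000)·f^(1/α−1) − 1000 with f ∈ (0, 1], α > 0. The
inverse problem is linear in log space, and the fitter estimates the slope
m = 1/α − 1 of ln(δ+1000) − ln(δ₀+1000) on ln f by least squares through
the origin. Design choices:

* **δ₀ is supplied, not co-estimated.** The source composition is a
  measured quantity (near-bottom water); co-estimating it from the same
  small set of points trades bias for variance with no benefit at typical
  n ≤ 10.
* **Linearized estimator.** Exact on noise-free data (recovery to ≤ 10⁻¹⁰
  relative, property-tested over α ∈ [1.0005, 1.08]); with 1.4 ‰ Gaussian
  δ-noise the mean recovered α over 100 replicate five-point designs is
  within 10⁻³ of truth, so the linearization bias is negligible at the
  noise levels of isotope-ratio mass spectrometry.
* **Sign conventions.** Internally α > 1 always means residual-pool
  enrichment and ε = (1/α − 1)·1000 ≤ 0. Because part of the field
  literature prints the apparent fractionation factor as a negative number,
  the fit result also carries `alpha_signed_convention` (−α under the
  default "negative" convention). Both numbers are emitted; neither is
  guessed to be "the" intended reading of a signed literature value.

## Headspace gas back-calculation

Dissolved CH₄ is recovered from a headspace-equilibrated bottle (default
geometry 100 mL water / 20 mL initially CH₄-free N₂) as
C₀ = [x·P·V_g/(R·T) + β·x·P/V_m·V_w]/V_w, with the Bunsen coefficient
β(T, S) from the standard oceanographic ln-β fit for methane (validity
−2…30 °C, S 0–40; evaluated values are property-tested for monotone
decrease with temperature and salting-out, and pinned against 30-digit
evaluations of the same fit). Equilibration is assumed complete and
isothermal at a configurable lab temperature (default 20 °C) and 1 atm;
neither an equilibration temperature nor an altitude/pressure correction is
hard-coded, both being configurable because field metadata rarely pin them.
Phase partitioning is exactly mass-closed by construction (forward
partition → back-calculation recovers C₀ to ≤ 10⁻⁹ relative).

## Tracer-incubation rate estimation

δ¹³C-DIC(t) → F(t) → ¹³C-DIC(t) = F·DIC with the ambient pool treated as
constant (default 7.4 mM); excess over t = 0 is the oxidized label. The
maximum potential rate is the OLS slope (with intercept) of excess vs time
over a fixed 0–12 h window, in µM d⁻¹, with the regression standard error
reported — explicitly the *regression* SE, since replicate spread is a
different quantity. A fixed window is reproducible; an "initial linear
segment" chosen by eye is not. The plateau flag compares the post-window
slope to the in-window slope (default threshold 25%).

Deliberate simplifications, all configurable or documented:

* The label is treated as 100 at.% ¹³C (the actual 99 at.% spike would
  scale rates by ~1%).
* Timepoints are independent bottles (destructive sampling), so no
  autocorrelation correction is applied.
* Growth of the DIC pool by the oxidized carbon itself (≤ ~5 µM on
  7400 µM, < 0.1%) is neglected on conversion; this keeps the noise-free
  round trip with the generator exact and is far below measurement noise.
* Rate invariance to a constant δ-offset holds only to first order
  (δ → F is nonlinear); the effect is < 0.1% for ±5 ‰ offsets.

## Fluxes and the electron budget

J = −Kz·∂C/∂z with depth positive downward and fluxes positive downward;
µM m⁻¹ ≡ mmol m⁻⁴, and Kz in cm² s⁻¹ converts as 1 cm² s⁻¹ = 8.64 m² d⁻¹
(so the default 4·10⁻³ cm² s⁻¹ = 0.03456 m² d⁻¹). Gradients are the
steepest-|slope| OLS fit among contiguous windows (default 3 points for the
bare operation; the pipeline uses 11 points ≈ 1 m on the default grid to
resist concentration noise), ties broken toward the shallower window.

Electron capacities are an explicit, overridable table, and every report
names the half-reaction used — communities differ in where e.g. nitrate
reduction terminates, and the choice changes the budget:
O₂→H₂O 4; CH₄→CO₂ 8; NO₃⁻→N₂ 5 (budget context) vs NO₃⁻→NO₂⁻ 2
(stoichiometric-ratio context); NO₂⁻→N₂ 3; SO₄²⁻→H₂S 8; NH₄⁺→NO₃⁻ 8;
Fe²⁺→Fe(III) 1; Mn²⁺→Mn(IV) 2; H₂S→SO₄²⁻ 8. With CH₄→CO₂ these give the
oxidant:CH₄ mole ratios 2:1 (O₂), 4:1 (nitrate to nitrite) and 8:3
(nitrite to N₂).

Budget arithmetic: sums per role use exact summation (permutation
invariant); uncertainties propagate in quadrature assuming independent
species (verified against Monte-Carlo propagation at 10⁵ draws to ≤ 2%);
the deficit is |Σ donors| − Σ acceptors. Report rounding is one decimal at
|v| ≥ 0.1 and two below, and the *reported* deficit is computed from the
rounded sums so the printed table is internally consistent (the unrounded
sums and deficit remain on the object). The reported uncertainty on a sum
is always our quadrature value.

The pipeline restricts the gradient search to a band around the detected
methane-oxidation zone (1 m above to 2 m below, unless a band is pinned in
the config), since the budget question is what crosses *that* zone, not
what happens at the sediment interface.

## Zonation

Oxycline = midpoint of the steepest-O₂-gradient window. Anoxia onset =
shallowest depth below which O₂ stays under the threshold (default 20 nM),
linearly interpolated between bracketing samples — the simplest defensible
crossing rule. Onset is monotone in the threshold by construction.

Methane zones are classified from local OLS trends of CH₄ and δ¹³C-CH₄
over a sliding *depth* window (default 2.0 m) rather than a fixed number of
grid points: a point-count window would make the criterion depend on grid
resolution (a 2 ‰-per-two-points rule can never fire on a 0.1 m grid where
the whole enrichment is ~0.5 ‰ per pair) and would break invariance under
profile super-sampling. The 2.0 m default keeps the window-slope standard
error at the 1.4 ‰ δ reproducibility (~0.5 ‰ m⁻¹ on a 0.1 m grid) well
below both the 2 ‰-per-window criterion and the oxidation-zone signal
(~5 ‰ m⁻¹). Oxidation = δ¹³C rising upward beyond the threshold while
concentration falls upward; diffusion = concentration falling upward with
δ¹³C invariant within the threshold; source below, oxic above. A column
with no signal in either channel returns a single zone flagged
indeterminate. Measured oxidation rates corroborate but do not define the
zones here — only concentration and δ criteria are used.

## Synthetic data generator

The generator's defaults *are* the study conditions the analyses assume:
0–21 m at 0.1 m; bottom CH₄ 2.2 mM at δ¹³C −50 ‰; oxidation zone 16–12 m;
surface O₂ 260 µM with a sigmoidal oxycline centred at 13.7 m sharp enough
that O₂ < 20 nM below ~14.6 m; DIC 7.4 mM; Kz 4·10⁻³ cm² s⁻¹; noise =
stated method reproducibilities (δ¹³C-CH₄ 1.4 ‰, δ¹³C-DIC 0.1 ‰,
concentrations 2% relative). The first-order oxidation constant defaults to
k = 0.046 d⁻¹ so that the reaction–diffusion length √(Kz/k) ≈ 0.87 m
produces the observed ~100-fold CH₄ decline across the 4 m zone.
Companion species (NO₃⁻, NO₂⁻, NH₄⁺, SO₄²⁻, ΣH₂S, Fe²⁺, Mn) follow
piecewise-linear shapes after the observed column structure.

CH₄ and δ¹³C-CH₄ come from an explicit two-isotope steady-state
reaction–diffusion solve (second-order finite differences, banded direct
solver, Dirichlet boundaries; the discrete flux-divergence/sink balance
telescopes to machine precision and is tested at ≤ 0.1%). Solving the
isotopes mechanistically rather than pasting the closed form means the
Rayleigh fitter is validated against data that did not assume its model; a
`closed-form` mode exists for exact round-trip tests.

**The mechanistic column deliberately does not reproduce the closed-system
δ(f) relation.** For first-order consumption under purely diffusive
steady-state transport the apparent log-log slope is 1/√α − 1, not
1/α − 1: the expressed enrichment factor is about *half* the intrinsic one
(for α = 1.005: ε_app → −2.49 ‰ vs intrinsic −4.98 ‰; the default k gives
−2.68 ‰, between the two limits). This is physics, not estimator error —
open diffusive systems under-express microbe-level isotope effects at
ecosystem scale — and the tests assert exactly this behaviour. A
consequence worth remembering when interpreting field fits: an apparent α
from a water-column profile is a lower bound on the organism-level α.

Incubation series grow excess ¹³C-DIC linearly at the true rate until a
plateau (default 12 h; an exponential substrate-exhaustion mode with the
same initial slope is available), convert back to δ¹³C-DIC against the
constant ambient pool, and add Gaussian δ-noise. Replicates draw from
deterministic substreams of the scenario seed; identical (scenario, seed)
reproduce byte-identical data.

What passing tests on these synthetics do *not* show about real data: the
generator has no advection or sub-lacustrine spring inputs, no
time-dependence or seasonal mixing, no light/photosynthesis coupling, no
carbonate-system speciation, and its companion-species profiles are smooth
caricatures; gradients and budget magnitudes from the synthetic column are
therefore structural (signs, zone ordering, donor excess), not quantitative
reproductions of any field table.

## Numerical details and degenerate inputs

* Grid-refinement: the solver's δ¹³C converges ~first order in grid step at
  the reaction-zone edges (the k discontinuity dominates); at 0.01 m it
  agrees with a 10× finer oracle to ≤ 0.05 ‰ at the zone top.
* Residual fractions are clipped into (0, 1] before Rayleigh fitting (noise
  can push C/C_ref marginally above 1); f = 1 points carry no weight in the
  through-origin fit.
* Constant profiles give zero gradients; all-equal δ observations give
  α = 1 exactly; a profile that never crosses the anoxia threshold returns
  an explicit no-anoxia result, not an error.
* Series missing the t = 0 baseline are rejected at construction; the
  pipeline collects such problems per series and continues.
* Rate fits need ≥ 2 points in-window; Rayleigh fits ≥ 2 distinct f.

## Problem sizes

The stochastic validations use 200 incubation replicates (rate estimator)
and 100 observation sets (Rayleigh fitter), and the Monte-Carlo quadrature
check uses 10⁵ draws — sizes at which the Monte-Carlo error on the checked
means is an order of magnitude below the tolerances being asserted. The
full test suite runs in a few seconds on one CPU.

## Known limitations

* Steady-state, diffusion-only transport throughout; no advective terms.
* The electron-capacity defaults encode one defensible set of
  half-reactions; budgets are only comparable across studies when the table
  is stated, which is why every output names it.
* Regression SEs understate total uncertainty when bottle-to-bottle
  variance dominates; replicate-level statistics are left to the caller
  (the comparison table keeps replicates separate for that purpose).
* Hydrogen isotopes and open-system/steady-state fractionation *fitting*
  models are out of scope.
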