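# Methods

## The problem

Scrub mangrove stands (here the *Avicennia germinans* type: stunted,
salt-stressed trees 0.3–8 m tall) store roughly half their biomass below
ground, but below-ground biomass (BGB) cannot be measured non-destructively.
The workflow this package implements reconstructs per-tree BGB from a
partial excavation design, fits and selects per-height-class allometric
equations, and aggregates to stand-level biomass and carbon stocks:

1. **Mensuration.** Each tree carries height *h* (cm), a stem diameter *D*
   (cm; DBH at 130 cm for trees ≥ 3.5 m, basal diameter at 30 cm otherwise),
   two crown radii, and a stem-disk density sample. Derived attributes:
   crown area = (R1/2)·(R2/2)·π (cm²), crown volume = area·h (cm³), wood
   basic density ρ = M/V (g cm⁻³). Trees are stratified into height classes
   C1 [30, 120] cm, C2 (120, 250] cm, C3 > 250 cm.
2. **Root reconstruction.** The root system is compartmentalised into root
   crown, primary roots and secondary roots. Two primary roots per tree
   (with their secondaries) are excavated, washed, and weighed fresh; a
   subsample oven-dried at 105 °C gives the dry:fresh ratio that converts
   whole-root fresh mass to dry mass. Every *unexcavated* root contributes a
   dry mass predicted from its basal diameter *x* by a per-(class, root
   type) equation. Per-tree BGB = crown + primary + secondary.
3. **Allometry.** Candidate forms: power *y = a·xᵇ*, quadratic
   *y = ax² + bx + c*, multiple linear *y = a + Σcᵢxᵢ*, and multiplicative
   power *y = a·Πxᵢ^eᵢ* on (D, h, V, ρ). Fits minimise Σ(y_obs − y_pred)²
   in arithmetic (untransformed) space — the additive-error convention — so
   no log-back-transform correction applies to models fitted here.
   Published above-ground equations fitted in log space elsewhere carry an
   explicit correction factor `cf` applied at prediction time.
4. **Selection criteria.** R²adj = 1 − (1 − R²)(n − 1)/(n − k − 1);
   RMSE = √(Σe²/n) (population divisor); MPE = 100·(Σe/n)/ȳ_obs with
   e = predicted − observed, so negative MPE means underestimation;
   AIC = n·ln(SSE/n) + 2(k + 1) + c. Candidates are ranked by ascending
   AIC, ties (|ΔAIC| < 1e-9) by ascending RMSE then descending R²adj.
5. **Carbon and stocks.** Dry biomass converts to carbon with compartment
   fractions 0.426 (BGB, measured on congeneric root tissue) and 0.419
   (AGB, site-specific). Per-class densities (Mg ha⁻¹) scale to stocks as
   Gg = Mg ha⁻¹ × ha / 1000 over the 812-ha mapped stand.

## Key parameters

| parameter | default | units | notes |
|---|---|---|---|
| height strata | [30,120], (120,250], >250 | cm | C1 closed at 120, C2 half-open |
| DBH threshold | 350 | cm | taller trees measured at 130 cm |
| BGB carbon fraction | 0.426 | – | exposed on `CarbonFractions` |
| AGB carbon fraction | 0.419 | – | idem |
| stand area | 812 | ha | a constant of the accounting, not estimated |
| AIC constant c | 0 | – | additive, rank-invariant within a candidate set; exposed |
| NLS convergence | rel. SSE change < 1e-10, ≤ 500 iterations | – | 5 jittered restarts, deterministic |

All internal heights are centimetres. The fitted-equation registry stores
coefficients as their printed decimal strings (bit-exact round-trips); the
printed C1 total-BGB model line is ambiguous between a multiplicative and a
linear reading and is encoded as the linear *a + b·h + c·D + d·ρ*,
consistent with the class's other equations.

## Synthetic data: what it does and does not emulate

The generator reproduces the *design*, not the field site: 15 trees per
class (heights uniform within strata), stem diameter through a power link
D = 0.07·h^0.75 with 10 % multiplicative lognormal noise (chosen so shrub
basal diameters land near 1–2.5 cm and emergent DBH near 10 cm), crown
radii proportional to height (fraction 0.35, CV 15 %), wood density
truncated-normal 0.70 ± 0.08 on [0.40, 1.00] g cm⁻³, six primary roots per
tree with three secondaries each, exactly two primaries excavated, and
dry:fresh ratio 0.45. Root dry masses are the per-class published equations
evaluated at uniformly drawn basal diameters (primaries ~0.3–6 cm with a
roughly class-independent minimum, since primaries taper; secondaries
~0.2–1.8 cm) times noise.

Two noise conventions are available. The default is multiplicative
mean-one lognormal with configurable CV (keeps masses positive, matches
the error growth of power-law data). The `additive` option is
homoscedastic — constant sd equal to CV × the predicted mass at the
mid-range diameter, magnitude-folded to stay positive — matching the
constant-variance additive-error convention the fitted equations assume;
parameter-recovery checks use it because arithmetic-space NLS is the
efficient estimator there. Under *multiplicative* noise the same NLS
recovers steep power-law scale coefficients only to roughly ±10 % at
n = 200 and CV = 5 % (small roots carry almost no absolute residual
weight), which is a property of the estimator, not a bug.

Passing tests on these populations therefore demonstrate correctness of
the machinery (identifiability, conservation, closure, selection), not
field realism: real root systems have correlated diameters, tapering,
broken/missing roots, and spatial structure the generator does not model,
and true stem densities per class are unknown (free config parameters).

## Numerical choices

- Power-form fits are seeded from a log-log OLS pre-fit (linear forms from
  exact normal equations), then refined by `scipy.optimize.least_squares`;
  the quadratic/linear "NLS" coincides with ordinary least squares.
- R² for nonlinear fits is the pseudo-R² 1 − SSE/SStot about the observed
  mean — the convention under which R²adj is reported for power models.
- SSE = 0 (perfect fit) makes AIC −∞ with a warning; model selection then
  prefers it, which is the desired degenerate behaviour.
- Negative mass predictions (possible for the C1 secondary quadratic below
  x ≈ 0.2 cm, and for linear crown models on unusual predictor mixes) are
  clamped to 0 with a warning: dry mass is non-negative.
- Table rounding is round-half-up at each table's printed precision,
  applied only at presentation; internal arithmetic is full precision.
- Basal diameters outside a model's calibration range predict normally but
  emit an extrapolation warning.

## Reproduction of the printed tables

The per-class mean densities (BGB 3.26/15.88/64.66, AGB 4.34/17.78/66.14
Mg ha⁻¹) and the per-class crown/root stock splits are embedded as inputs;
`carbon_stand.reproduce_tables` recomputes all 79 derived cells. 69 cells
are arithmetically determined and reproduce exactly. Ten cells are flagged
as internally inconsistent in print and are reported, not forced: the
density table's BGB-carbon column (and the total-carbon column that sums
it) tracks a 0.429 fraction rather than the stated 0.426 — the 0.426 chain
is treated as authoritative because it reproduces every carbon cell of the
stock table — and two stock cells (2.64 vs computed 2.65; 68.04 vs
computed 68.05) disagree with the full-precision rounding chain by one
unit in the last place. The abstract's ≈87/91.7 Mg ha⁻¹ totals differ from
the tables' 83.80/88.26; the tables are taken as authoritative and the two
are not reconciled.

## Problem sizes

Recovery and diagnostic simulations run at n = 200 observations per fitted
model and 100 seeds for the diagnostic error-rate checks; the brute-force
oracle for the nonlinear fitter is an exhaustive (a, b) lattice at step
10⁻³ on 3-point problems. These sizes make the whole suite run in well
under a minute while leaving the statistical margins wide (observed
recovery errors < ~3 % against the 5 % bound).

## Limitations

- The 45-tree field dataset is not deposited, so the regression *fits* of
  the published equations are validated by property (recovery, oracle
  equivalence), not by reproduction.
- AGB equations live in the supplementary material and are not reprinted;
  the registry ships the AGB slot empty with a JSON schema
  (`form, predictors, coefficients, cf`) the user fills.
- No mixed-effects/Bayesian allometry, heteroscedasticity-weighted fits,
  bootstrap intervals, fine-root (soil-core) biomass, or soil carbon.
- The quadratic's small coefficients are ill-conditioned in relative terms;
  recovery guarantees are stated for the power-form coefficients.
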