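# Methods

## The perceptgene model

A perceptgene is a perceptron transplanted into the logarithmic domain,
where gene regulation natively computes: a weighted *product* replaces the
weighted sum, and a Michaelis–Menten promoter response replaces the
sigmoid.  One unit is

    y = B · ∏_i (x_i / K_i)^{n_i},        z = (y^m + β) / (1 + y^m)

with inputs x_i (inducer concentrations), input weights n_i (effective
Hill coefficients of each input's regulation stage), input scales K_i
(binding constants), bias B = α·τ/K_d (maximal transcription-factor level
over its DNA-binding dissociation constant, dimensionless), activation
weight m (Hill coefficient of the output promoter), and basal level
β ∈ (0, 1) (fractional leak of the output promoter).  The first stage is
exactly log-linear: log y = log B + Σ n_i log(x_i/K_i), which is what
lets perceptron design rules (weights, biases, thresholds) carry over.

The basal level plays a double role: it fixes the maximum fold change,
MFC = log10(1/β) (in decades), and the activation threshold Th, defined
as the collective level whose output sits at the logarithmic midpoint of
the fold-change range: √β = (Th + β)/(1 + Th + β).  `threshold_from_basal`
solves this with a bracketing root finder to 1e-12 relative tolerance; a
closed-form rearrangement exists and is used as the test oracle.

An alternative activation variant with the basal term repeated in the
denominator, z = (y^m + β)/(1 + y^m + β), appears in some presentations
of the model; it is available behind `activation(..., variant="shared")`
but the default form above is the one all fitted parameters refer to.

The collective (transcription-factor) signal obeys
dC/dt = α·P_hybrid − C/τ; `steady_state_and_dynamics` integrates this
with LSODA (rtol 1e-8, atol 1e-10) and cross-checks the constant-drive
closed form α·τ·P.  All user-facing logarithms are base 10 (decades);
natural logs appear only inside numerics.

**NonLinearity degree.** NL = m / (log MFC / log IR) compares the
circuit's activation steepness against a straight log-log ramp covering
the same input range IR and fold change MFC; it is independent of the
logarithm base.  The four characterized reference circuits give
NL = 1.33 (power-law/multiplication, two operator sites), 3.8 (sigmoid
perceptgene), 1.03 (power-law/multiplication, Lux/Tet) and 2
(positive-rectifier perceptgene).

**Feedback-shaped weights.** Auto-regulation sets the effective input
exponent.  The steady state of an auto-regulated stage obeys
P^k ∝ Input^h: for auto-negative feedback the repressor occupies
s·n_sites operator copies, so n_eff = h/(s·n_sites) (halving exactly when
the site count doubles; the calibration constant s defaults to 1); graded
auto-positive feedback re-amplifies with fractional occupancy
g = 1/(1 + n_sites), giving n_eff = h/(1−g) > h.  These are deliberately
minimal forms — only the proportionalities are constrained by data.

## Smooth min, max, and average

Driven at low inducer, the activation stage is (in log coordinates) a
*negative rectifier*: promoter activity follows log(activator) up to a
threshold u01 and saturates above it — min(u01, v) plus an offset.  At
high inducer it is a *positive rectifier*, max(u02, v) plus an offset.
Because v is a weighted sum of log-inputs, the exact shift identities
min(u, x+y) = min(u−y, x) + y (and the max analog) convert the unit into
a smooth minimum (maximum) of two log-transformed signals, offset by an
affine function of the second input.  `shift_identity_residual` evaluates
the identity in exact rational arithmetic, so it returns literal zero for
every finite float triple rather than a rounding residual.

Extraction (`extract_min_surface` / `extract_max_surface`) normalizes the
measured output by its minimum level, log10-transforms, removes the
affine offset (secondary weight × normalized log input plus the lumped
constant `const + log B`), and compares against the ideal two-branch
surface on IDR-normalized axes.  Min-normalization discards the absolute
level, so the extracted surface is re-anchored at the predicted surface's
own minimum; for a surface built exactly from ideal + offset the
round-trip residual is identically zero.

**Standard error.** The reported figure of merit is
100 × RMSE(residuals) / (log-output span of the ideal surface).  No
formula accompanies the originally reported 10%/23%/9% values, so this
definition is fixed here; reported percentages are therefore comparable
in spirit, not digit for digit.

**Simulated minimum device.** `simulate_min_circuit` composes the
measured power-law stage (weights 0.3375/0.4375) with the device's
negative rectifier carrying the published extraction constants (w1 = 0.3,
const1 = 0.6, log B2 = −1, IDRs of 2.1 decades), smoothed with the finite
activation steepness m = 2.2 and floored at the basal level β = 0.045.  A
bare sigmoid unit cannot carry the empirical cross-talk slope w1 of the
saturated branch, so the rectifier-with-crosstalk composition is the
faithful behavioral model of that circuit.  Extraction with the published
constants then shows ~11% standard error on the default 17×17 grid —
nonzero because the secondary weight printed for extraction (0.473)
differs from the circuit weight (0.4375) and because of corner smoothing.

## Majority networks and constraints

The two-layer majority design is analyzed in a linear-domain piecewise
abstraction: Y = Σ n_i I_i + B per layer, activations clamped at
thresholds γ_L (Z = 0) and γ_H (Z = 1) with linear interpolation between,
ties taking the clamp value.  `majority_constraints` evaluates the
printed eight-row constraint table with signed slacks;
`truth_table_equivalence` evaluates the same network exhaustively on the
eight binary states and checks the *full* table — saturated binary
outputs and the intermediate-layer column (Z1 = 0 for 00x, Z1 = 1 for
11x, 0 < Z1 < 1 as appropriate for single-high states).  Under that
reading the two routes are equivalent for non-negative weights, and the
package treats any disagreement on random draws as a bug (the oracle
equivalence is exercised on 10^4 draws).  A soft classifier at half the
maximum fold change in log scale (z ≥ √β, `classify_log_midpoint`) is
used for graded perceptgene outputs, e.g. the optimizer's early-stopping
criterion.  A feasible parameter set found by grid search over
(n1, n2, n3, m, B1, B2) ∈ [0, 2]^6 is pinned as `MAJORITY_FIXTURE`.

A consequence of the table (and verified in tests): feasibility requires
the internal layer-1 weight to exceed the third input's weight (m > n3).

The log-domain network engine (`NetworkSpec`/`evaluate_network`) evaluates
perceptgene units over a DAG; multiplicative junctions model
complex-forming signals (e.g. a polymerase–tRNA pair) as products of
their sources.  Evaluation is invariant to the topological order chosen.
The pinned `majority_network_fixture` uses the measured input weights
(IPTG 0.93, aTc 1.05, AHL from the promoter-variant library) with biases
chosen by log-domain constraint analysis so that the fixture actually
computes majority at its optimal weight setting; input low/high levels
follow the characterized induction ranges.

## Sequestration-programmable weights

A 1:1 titration A + D ⇌ AD with dissociation constant K_AD gives the free
activator as the positive root of A² + A(D−A_tot+K) − K·A_tot = 0.  Two
regimes matter:

- **Tight binding, unbounded drive** (K_AD small): titration thresholds
  the response — only when total activator exceeds the sequestrator does
  output rise.  This regime *reprograms logic*: the pinned two-input
  fixture flips from an OR-like corner pattern (3 of 4 high) to AND-like
  (1 of 4 high) as the sequestrator rises.
- **Moderate affinity with a saturating expression stage** (defaults in
  `sequestration_dose_response`: A_max = 10, K_AD = 10): raising the
  sequestrator pushes the activation threshold into the compressive part
  of the expression stage, which monotonically *lowers* the fitted
  apparent Hill coefficient, raises the apparent K, and reduces the
  maximum fold change — the phenomenology of a small-molecule-tunable
  internal weight.  Note that with an unbounded power-law input stage,
  pure 1:1 titration can only steepen a response (the log-log slope of
  A_free versus A_tot is ≥ 1 everywhere), so the saturating stage is
  essential to the flattening and is modeled explicitly.

`apparent_hill` fits z = ((x/K)^m + β)/(1 + (x/K)^m) by least squares on
log10 output (fold changes carry the information), bounded and with
analytic-free diagnostics on failure.

## Cost and discrete backpropagation

The cost over a truth table of N states is the logarithmic mean squared
error ⟨C⟩ = (1/2N) Σ (log10(z_Di/z_i))², base 10 by the package-wide
convention.  It is invariant to joint rescaling of observed and desired
outputs and zero exactly at a perfect match.  Observed outputs can be
normalized by the highest measured level and floored at basal
(`normalize_outputs`) before costing.

Weights live in discrete genetic libraries (six inducer levels for the
activation weight; four promoter variants, weights 0.1/0.2/0.27/0.45,
for an input weight).  `gradient_sign` differentiates the cost
analytically by the chain rule through the evaluated layer outputs
(reverse accumulation of d log z_out/d w over the DAG; the activation
log-log sensitivity is S = m·y^m(1−β)/((y^m+β)(1+y^m))) and reports only
the sign; ties below 1e-12 report zero.  For plain cost callables a
finite-difference fallback over neighboring library values is used.  The
analytic sign is validated against a finite-difference oracle over
closely spaced neighbors on 10^3 random network draws, excluding ties and
draws that bracket a stationary point (where a center sign is not defined
by secants).

`discrete_backprop` is two-phase coordinate descent: per phase the active
weight steps to the adjacent library value opposite the gradient sign,
accepting only cost-decreasing moves, until the sign vanishes, a boundary
pins it, or a move would not improve; phases repeat until a full pass
makes no move (default cap 10 passes) or every state reaches its binary
target under the log-midpoint classifier.  Accepted costs are
non-increasing by construction.  On coordinate-wise quasiconvex grids the
endpoint equals the exhaustive argmin; `exhaustive_cost_surface` computes
the full library-product grid for comparison, and `sample_count`
(states × configurations × replicates) reproduces the measurement
accounting: 8 × (6×4) × 3 = 576 for the exhaustive sweep and
8 × (3+3) = 48 for the two-phase trajectory of three values per phase.

On the pinned majority fixture the simulated cost surface has its minimum
at an intermediate activation weight (fifth of six inducer levels) and
the highest-weight promoter variant; descent from the lowest-weight
corner reaches it and stops with all eight states correctly classified.

## Data converters

Converters are *behavioral* models: stage perceptgenes plus two coupling
rules, with parameters chosen by automated search so the four codes
occupy roughly equal decades of a four-decade sweep — synthetic design
points, not estimates of the biological values.

- **Transcriptional interference** (convergent promoters) is clipped
  linear subtraction of promoter activities,
  net = max(primary − ρ·interfering, floor), with strength ρ (default 1).
  No rate law for the interference is available; the clipped-linear form
  reproduces the observed threshold shift plus maximal-activity
  repression.
- The **v1 ADC** uses one LSB unit whose interference is nullified at
  high input by a repressor arm: ρ(x) = ρ0/(1 + (y_msb/K_null)^h_null),
  keyed on the (unbounded) MSB collective so that nullification engages a
  decade above the MSB switch.  Ablating the arm reproduces the control
  circuit whose code sequence ends at 10.
- The **v2 ADC** keeps interference always on and aggregates a second,
  high-threshold LSB unit onto the same output (sum of activities,
  clipped to [β, 1]).  With interference strength exactly 1 and the
  interferer sharing the MSB drive, the LSB falls through its threshold
  at the same input where the MSB rises through its own, giving a clean
  01→10 handoff; the narrow transitional window inherent to this handoff
  is what `CodeSequence.glitches` flags (runs breaking the monotone code
  progression, each required to span under 0.1 decade).
- The **ternary switch** reads the same v2 architecture as one aggregated
  analog output, (g_m·MSB + g_l·LSB)/(g_m+g_l): across the middle of the
  range the interference hands activity from LSB to MSB, so their sum
  plateaus — low/medium/high with two thresholds (defaults 0.25/0.75).
  Fewer than three detected plateaus raises a warning, not an error.

Digitization is per-bit threshold comparison (≥ reads 1; code
2·MSB + LSB) and is invariant under joint rescaling of analog values and
thresholds.

## Synthetic measurements and fitting

`generate_measurements` emulates the flow-cytometry pipeline: per grid
point and replicate it draws `events` (default 10,000) log-normal
single-cell fluorescence values around the model output with coefficient
of variation `cv` and records the geometric median (for 1-D samples the
ordinary median, exp of the median of logs — median-unbiased under
log-normal noise).  All randomness flows through one explicitly seeded
`numpy` generator; identical seeds give bit-identical surfaces.  What
this generator does *not* emulate: cell-to-cell extrinsic correlations,
gating artifacts, autofluorescence background, day effects between
replicates, or instrument saturation — passing recovery tests therefore
demonstrate estimator correctness under the stated noise model, not
robustness to every artifact of real cytometry data.

`fit_perceptgene` runs bounded nonlinear least squares on log10 output
(weights in [0, 3], basal in (1e-6, 0.5)), for the canonical single-K_d
form and the two-constant variant with distinct numerator/denominator
scales.  An intrinsic degeneracy matters: z depends on the weights only
through m·n_i, m·log B and β, so the input weights are identifiable only
with the activation weight m fixed (the recovery harness fixes it at the
generating value); with m free, the products are what the data determine.
R² is reported in log space.  The recovery condition exercised by the
acceptance suite — all generating weights within 10% relative on CV-10%,
3-replicate surfaces in ≥ 18 of 20 seeds — holds with wide margin because
the geometric median of 10,000 events suppresses the event-level noise by
two orders of magnitude.

## Problem sizes and numerical choices

Default grids: 17×17 points for extraction surfaces, 7×7 for fitting
harnesses, 64-point four-decade sweeps for converters; oracle
equivalences run 10^4 constraint draws and 10^3 gradient draws.  These
sizes make every statistical margin in the test suite wide while keeping
the full suite and the acceptance script fast on a single core.
Degenerate inputs: zero or negative concentrations are rejected
(log-domain model); callers needing a detection floor apply one
explicitly (`NoiseModel.detection_floor`).  Tie-breaking conventions:
piecewise activations take clamp values at their thresholds; digitized
bits read 1 at exactly the threshold; cost ties below 1e-12 stop the
optimizer's active weight.

## Known limitations

- Rectifier thresholds u01/u02 are parameters, not derived from inducer
  biochemistry; extraction constants are taken as supplied.
- The interference strength ρ and the converter fixtures are synthetic
  design points; only the qualitative code-sequence phenomenology is
  claimed.
- The piecewise constraint engine operates in the linear domain once (the
  log-domain analysis yields the same constraint structure); no separate
  log-domain constraint table is maintained.
- The supD/T7-style multiplicative junction assumes no saturation of
  complex formation.
- Backprop phase schedules are fixed-order; no weight-pair coupling or
  momentum is modeled (batch is always the full truth table, N ≤ 8).
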