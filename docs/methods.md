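# Methods

## The virtual patient

The patient is a Bergman-style minimal model of glucose–insulin kinetics
extended with a two-compartment gut and a first-order interstitial lag:

    dG/dt  = −p1 (G − G_b) − X·G + f_bio·k_abs·Q2 · κ / V_G
    dX/dt  = −p2 X + p3 (I − I_b)
    dI/dt  = −n I + u(t) / V_I
    dQ1/dt = −k_abs Q1            (+ carbohydrate impulse, grams)
    dQ2/dt =  k_abs (Q1 − Q2)
    dIG/dt = (G − IG) / τ_ig

with plasma glucose G and interstitial glucose IG in mmol/L, plasma
insulin I in mU/L, remote insulin action X in 1/min, gut compartments
Q1, Q2 in grams, and insulin delivery u in mU/min. κ = 1000/180.16
mmol/g converts absorbed carbohydrate mass to glucose concentration, so
the meal term is dimensionally consistent; a 40 g meal then produces a
peak excursion of several mmol/L, as expected for an unbolused meal.

At u = n·I_b·V_I the system has the exact fixed point
(G_b, 0, I_b, 0, 0, G_b); this closed form is the patient's **optimal
basal rate** (converted to U/hr by ×60/1000) and is validated on
construction of every patient record. The **insulin sensitivity** used
to derive a patient's carb ratio is the linearised integrated disposal
of one unit, s ≈ G_b·p3·1000 / (p2·n·V_I) mmol/L per U, and the **carb
ratio** is s divided by the per-gram glucose rise f_bio·κ/V_G — for the
adult base parameters this gives ≈ 8 g/U, within the clinically typical
5–15 g/U band.

Integration is fixed-step RK4 with an internal step of at most 1 min
(deterministic; adequate for minute-scale dynamics — a 5-min step from a
non-equilibrium state agrees with a 0.001-min Euler reference to
<1e−4 mmol/L). States are clamped at zero from below after each
sub-step; X may go negative (below-basal insulin action), which is how
the minimal model represents insulin deficiency. Boluses and meals are
impulses applied at the start of a step.

### Cohort generation

Base parameter sets for child / adolescent / adult differ in body size
(V_G, V_I: 6/9/12 L) and insulin sensitivity (p3 scaled up for the
young). A seeded generator jitters each patient multiplicatively with
log-normal factors (σ = 0.08–0.12 for rates, 0.10 shared for the two
volumes so body size stays coherent, 0.03 for basal glucose, clipped to
the physiologic 4–8 mmol/L band). Output is byte-identical for a fixed
seed. The default study cohort is seed 42.

### What the generator does and does not emulate

It emulates inter-patient variability of minimal-model kinetics, meal
absorption and sensor lag — enough for parameter-sweep surfaces with
realistic structure (steep error growth at sub-basal insulin, hypo
regions at excessive basal, plateaus where suspension logic saturates).
It does **not** emulate dawn phenomenon, exercise, glucagon
counter-regulation, intra-day parameter variation, or CGM calibration
drift; sensor noise is optional white Gaussian noise (default 0 so
sweeps are deterministic). Passing tests therefore certify the method's
machinery, not the clinical performance of any controller on real
patients, and per-patient metric values are not comparable to those
obtained with a different (e.g. FDA-certified, proprietary) simulator.

## Controllers

**LGS.** Delivers the default basal b (U/hr); when the CGM reading drops
below Θ it suspends delivery for 30 min (fixed). After expiry the
threshold test resumes at the next sample, so back-to-back suspensions
occur during prolonged lows. Output is always exactly 0 or b.

**oref-like.** A transparent three-rule basal modulator in the spirit of
the OpenAPS oref0 family — not a reimplementation of it (oref0/oref1's
autotune, super-micro boluses and unannounced-meal logic are out of
scope). It predicts an eventual glucose as

    eventual = IG + 6·(IG − IG_prev) − IOB·s + COB·s/CR

(30-min linear trend at 5-min sampling; IOB/COB decay linearly over
180/240 min; CR = carb ratio, defaulting to the patient's derived
value), then: suspend if eventual is more than 1 mmol/L below the
6.66 mmol/L target; default basal within the ±1 deadband; otherwise a
temp basal b + excess/(s·0.5 h) capped at 4·b. The trend horizon,
deadband, DIA, absorption time and cap are documented constants chosen
once; they reproduce the qualitative property that matters for the
sweep — rule-based discontinuities in the error surface driven by the
two swept parameters b and s.

Neither controller ever doses a meal bolus; meals reach the oref-like
controller only as carbohydrate announcements.

## Scenario and metric

A single simulated day (1440 min), meals of 40/50/70 g at 07:00, 12:00
and 19:00, CGM sampling every 5 min (288 samples), patient started at
the fasting fixed point at midnight so no startup transient contaminates
the score. Each sampling instant: announce due meals → sample CGM →
controller decision → advance the model 5 min. The per-run score is the
mean over CGM samples of |IG − 6.66| mmol/L; it is an *error* (lower =
better) and all extremum logic downstream treats the global extremum as
the minimum.

## Sweep

Axis vectors are built by integer multiples of the increment
(L + k·S), never repeated addition, so the published axis counts
(57 × 14 = 798 for LGS; 47 × 35 = 1645 for the oref-like controller) are
exact. The evaluation grid runs one closed-loop day per cell; cells draw
per-cell noise seeds derived from (scenario seed, i, j), making serial
and parallel (process-pool) evaluation bitwise identical and
order-independent. Grid analysis assumes exactly two swept axes; the
Cartesian-table builder itself supports any dimension.

## Confidence metrics

Local extrema are cells strictly smaller than all existing
8-neighbours; strictness means flat plateaus contain no extrema, which
is the testable reading of "extremum". The spread region qualifies the
floor(0.2·|T|) best cells by ascending error rank with ties broken by
row-major index (rank-based rather than interpolated percentile, so the
ideal single-basin case gives exactly 0.2 when |T| is a multiple of 5),
and takes the BFS closure of the global minimum (ties: smallest
row-major index) within that set under 8-connectivity; the minimum
itself always belongs to the region, giving the bound
C_s ≤ floor(0.2|T|)/|T| + 1/|T|. Both metrics are invariant under
positive rescaling of the error surface. Correctness is cross-checked
in the test suite against independent oracles (scipy.ndimage
minimum-filter extrema and connected-component labelling), exhaustively
on small grids and property-based on random ones.

## Surface approximation

The binomial-sum surface is fitted on the expanded monomial basis
{x^m y^n : m+n ≤ p} (21 coefficients at the default p = 5). The nested
form Σ (A_i x + B_i y)^i is over-parameterised — the A/B pairs are not
identifiable after expansion — so least squares operates directly on the
identifiable c_{m,n}. Inputs are mapped to [0,1] per axis before
building the design matrix (a degree-5 Vandermonde on raw units of
0.2–3.0 is ill-conditioned); the minimum-norm solution is taken if the
matrix is rank-deficient. Predictions accept original units.

The regression tree uses CART with squared-error splits, best-first
growth to at most 100 leaves, midpoint thresholds, `<=` conditionals
with the true branch on the left (boundary inputs go left), leaf value =
training mean. scikit-learn's `DecisionTreeRegressor` performs the fit;
the result is converted to an explicit node structure exported as JSON
and as an indented `<parameter> <= <value>` rule dump. Unlike the
polynomial, the tree is fitted in original units: splits are invariant
under monotone per-axis maps, and unscaled thresholds keep the exported
rules directly interpretable. Small-case splits are cross-checked
against an exhaustive brute-force split search in the tests.

Model comparison uses a seeded random 33 % hold-out
(|test| = round(0.33·n)) and RMSE.

### Which surrogate wins depends on the surface

On piecewise-plateau surfaces — broad flat steps, as saturating
suspension logic produces — the 100-leaf tree nearly memorises the
training cells and clearly beats the degree-5 polynomial out of sample
(this is asserted as a property test on generated terraced surfaces).
On the built-in cohort's actual LGS surfaces the comparison is close
and can go either way: those surfaces combine plateaus with a steep
*smooth* cliff at sub-basal insulin delivery (average error rising by
roughly 20 mmol/L per U/hr at low b), where a piecewise-constant tree
with ~8 cells per leaf generalises no better than the polynomial. The
end-to-end acceptance test records this comparison on the default
three-patient cohort; with a simulator whose surfaces are more heavily
plateaued, the tree dominates.

## Problem sizes and runtime

The default test suite and the worked example use: 798-cell LGS grids,
one simulated day per cell, cohorts of 1–3 patients per category. One
closed-loop day costs ~10 ms, a full 798-cell grid ~4 s per patient, so
the complete three-patient end-to-end analysis runs in about a minute on
one core. These sizes were chosen as comfortable desk-scale defaults;
all of them scale linearly with cohort size and grid cardinality.

## Known limitations

- The ODE patient is a deliberately simple minimal model; absolute
  metric values depend on it and should only be compared within runs of
  this suite.
- IOB/COB use linear decay, not exponential-activity curves.
- Exactly two swept parameters are analysed (the approximators and
  confidence metrics are 2-D); the sweep machinery itself is n-D.
- Suspension timing is quantised to the 5-min CGM cadence, so total
  suspension time can exceed a nominal 30-min window by up to one
  sampling interval per trigger.
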