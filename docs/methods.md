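# Methods

## The model

Staged EHR maturation is modelled as diffusion through successive,
non-displacing product generations.  Each EMRAM stage *i* ∈ {0,…,7} is
a generation with three parameters:

| parameter | meaning | units | admissible range |
|---|---|---|---|
| mᵢ | incremental market potential: units whose first entry into the system is at stage i | hospitals | ≥ 0 |
| pᵢ | external-influence (innovation) coefficient | 1/year | (0, 1] |
| qᵢ | internal-influence (imitation) coefficient | 1/year | [0, 1] |
| τᵢ | launch offset relative to the base year | years | unbounded, may be negative |

The single-generation cumulative adoption is the closed-form Bass
curve; p = 0 is rejected (the curve never leaves zero) and q = 0 is
handled as an exact limit (no expression divides by q).  Occupancy and
cumulative stage curves follow the Norton–Bass recursion stated in the
README; the telescoping identity Σᵢ Sᵢ = Σᵢ mᵢFᵢ is exact and is used
as a cross-check in the tests, not enforced numerically.

Assumptions inherited from this model class: one hospital, one EHR
trajectory (no replacement sales, no exit/entry); maturation never
regresses; a stage's upgrade clock runs from the *successor
generation's launch* for all units alike, so a hospital reaching
stage i late expresses its accumulated upgrade propensity immediately
(this "common clock" is what makes the generational recursion hold in
aggregate).  Curves are real-valued; integerization happens only in
the cohort simulator.  Stage 0 is a generation with its own (m, p, q)
like any other, not a residual; hospitals that have not yet entered
any generation are *reported* at Stage 0, the observable floor of the
ladder, so panel totals equal the cohort size.

## Estimation

The loss is the plain pooled SSE between observed counts and Sᵢ(year)
over every (year, stage) cell — one model, one fit summary (adjusted
R² = 1 − (1 − R²)(n − 1)/(n − k − 1) with n the cell count and k the
number of free parameters actually optimized; SST about the grand
cell mean).  No cell weighting: a pooled objective matches a single
pooled fit summary.

The optimizer is SciPy's bounded trust-region reflective
least-squares.  Initialization is sequential: each stage's observed
"stage ≥ i" cumulative series is fitted by a scaled single-generation
curve (3 parameters at a time), market starts come from successive
differences of the fitted scales, and the joint stage then refines all
(m, p, q) together, warm-started from that solution, so joint SSE
never exceeds sequential SSE.  A deterministic multistart (default 8
restarts; log-normal multiplicative perturbations, sd 0.35, seeded)
guards against local minima; ties between restarts break to the first
found.  Bounds: p, q ∈ [1e−9, 1], m ∈ [0, 10 × the largest yearly
total].  Estimates within 1e−6 of the (p, q) range of a bound are
reported as boundary solutions; stages whose observed counts never
reach one unit are reported unconverged and their coefficients should
not be interpreted.

Launch offsets are fixed at their configured values by default:
freeing eight offsets on nine annual observations alongside 24 curve
parameters is under-determined.  An opt-in flag (`free_tau`) frees
them, bounded to [base − 30, last observed year].

Identifiability note: a deterministic-allocation cohort at n = 5200
carries a largest-remainder rounding floor (best attainable SSE of a
correctly specified model is a few counts² over 72 cells).  Parameters
of well-filled, well-curved stages recover to ~0.01–0.1 %; the Stage-0
and Stage-1 markets are nearly collinear (both saturate within the
first observation years) and recover only to ~1 %.

## Launch-offset calibration

The mid-point year of a stage is defined on cumulative entrants: the
first grid year with Aᵢ ≥ 0.5·Aᵢ(horizon).  Occupancy of a transient
stage has no stable total to halve, and the cumulative reading lets a
stage's mid-point trail its occupancy peak (observed for
early-launching generations with slow outflow).

`calibrate_launch_offsets` root-finds, per stage, the offset at which
the continuous-time mid-point equals the anchor year, sweeping stages
Gauss–Seidel until convergence (the coupling through feed-through and
direct-entry terms is weak; moving one anchor by +1 year moves
essentially only that stage's offset, by about +1 year).  For early
stages the cumulative curve is dominated by later generations' direct
entrants and no offset can reach the anchor; those stages fall back to
anchoring the generation's own curve, τ = anchor − t₅₀ with
t₅₀ = ln(2 + q/p)/(p + q), and the residual is reported (strict mode
raises instead).  On the packaged parameter set Stages 0–1 take the
fallback; Stages 2–7 hit their anchors within one grid year.

Calibrating on mid-points (rather than on peak years) keeps the
occupancy peaks genuine out-of-sample predictions.  On the packaged
parameter set those predictions land later than the published peak
years for Stages 5–6: with q₆ ≈ 0 the Stage-5 outflow hazard is the
constant p₆ = 0.064/yr, so Stage-5 occupancy can only peak once its
entrant growth falls below 6.4 %/yr — about ten years after launch —
which a 2021 mid-point anchor places in the mid-2020s, not 2019.  The
published mid-point and peak rows are not jointly reachable by this
model class; the package reports what the calibrated model implies.

## Milestones, stalling, leapfrogging

Max year is the earliest grid year attaining max Sᵢ (ties break
early); `peaked` requires the maximum to precede the horizon *and*
occupancy to have strictly declined by the horizon — a stage with no
successor therefore never peaks.  Stall counts are Sᵢ at a requested
grid year.  Years are reported as integer calendar years on the
annual grid.  All-zero stages yield missing milestone rows, not
errors.

Leapfrogging is flagged two ways.  Flag A (occupancy): a stage whose
occupancy never exceeds its predecessor's maximum — adopters passed
through or over it too fast for it to fill.  Flag B (cumulative): a
window (default ≥ 3 years) over which Aᵢ grows less than ε = 1 %/year
while Aᵢ₊₁ grows more — new arrivals above the stage while entry into
it has stalled.  Flag B is a heuristic: in the *saturated tail* of any
multi-generation system the predecessor's relative growth eventually
falls below ε while the successor still fills from the stock, so the
flag should be read on the filling phase of the data (the detector
reports the triggering interval for exactly this reason).

## Synthetic cohorts

The generator emulates the published study's conditions: 5 200
hospitals observed annually 2006–2014, each at exactly one of eight
ordered stages, aggregate shares drifting monotonically toward higher
stages, stage-skipping permitted, regression never.

*Deterministic-allocation mode* integerizes the scaled occupancy
vector (plus the not-yet-entered remainder at Stage 0) with
largest-remainder rounding per year — totals are exact — and assigns
hospital trajectories by rank against the "stage ≥ i" thresholds,
which are non-decreasing in time, so every trajectory is monotone by
construction.  This mode is used for estimator-correctness runs: the
only deviation from the model is rounding.

*Stochastic mode* draws, per hospital and generation, a uniform
adoption threshold crossed by the generation's curve; home generations
are allocated proportional to market potentials, and crossing several
thresholds between observations produces multi-stage climbs
(leapfrogging).  The implied per-year upgrade hazard is exactly
p + qF, and expected aggregates equal the generational recursion; a
two-generation run at n = 20 000 matches the curves to ~3 %
(binomial noise).  Observation noise, when requested, is
multiplicative N(0, sd) per cell, clipped at zero and rounded;
sd = 0 is the identity.

What passing tests on these cohorts do **not** show about real survey
data: the generator has constant yearly participation (real panels
have survey churn), no hospital covariates, no non-response, and its
in-sample stage mix under the calibrated offsets is sparser in the
top stages than the real 2006–2014 panel.  Estimator correctness on
the synthetic cohorts is a statement about the algorithm, not about
fit quality on proprietary data.

## Packaged fixtures and problem sizes

`table2.yaml` is the forecasting configuration: the published
per-stage (M, p, q) with offsets calibrated against the packaged
mid-point anchors, 2006 base, 2035 horizon.  `table2_insample.yaml`
shares (M, p, q) but places launches inside the observation window
(Stages 0–2 at the window start — early-stage adoption predates the
survey — then one year of stagger per stage) so that every stage has
observable adoption in 2006–2014; parameter-recovery experiments need
that identifiability, whereas under the calibrated offsets Stages 5–7
launch near or after 2014 and carry no in-sample signal.  Stages 6–7
still cross their mid-points after the window, mirroring the sparse
top-stage data of the real study period.

Default problem sizes keep everything desk-scale: recovery runs use
one 5 200-unit deterministic cohort over nine years (a full
multistart fit takes seconds); stochastic-mode validation uses
10⁵ units for the single-generation law and 2 × 10⁴ for the coupled
check; forecasts are 30 annual grid points.

## Known limitations

* The generational recursion assumes the published M values are
  incremental potentials and that top-stage entry is pure
  feed-through (m₇ = 0); other readings of the source table would
  change the curves.
* No uncertainty quantification: the estimator reports point
  estimates and a pooled adjusted R² only, matching the source
  analysis; no standard errors or forecast bands.
* Calendar years are integers on an annual grid; sub-annual timing is
  interpolated only inside the calibration root-finder.
* The 1 %/year flag-B threshold and 3-year window are conventions;
  shift them via configuration when panels are noisy or short.
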