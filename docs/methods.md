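# Methods

`mapkdual` studies a specific pharmacological question: why does combining a
MEK inhibitor with an ERK inhibitor suppress MAPK signalling synergistically
in RAS-mutant tumour cells, while the same combination is merely additive
when mutant BRAF signals independently of RAS?  The package couples a
mechanistic ordinary-differential-equation model of the cascade to the
standard quantitative apparatus of combination pharmacology (4PL
dose-response fits, Loewe/Bliss expectation surfaces, isobolograms) and of
in-vivo efficacy analysis (%TGI, progression-free survival).

## 1. The cascade model

### Topology

A clamped Grb2-SOS input (GS) catalyses Ras-GDP -> Ras-GTP exchange; Ras-GTP
activates RAF; active RAF phosphorylates MEK (single activating site); active
MEK phosphorylates ERK distributively on two sites.  Free, doubly
phosphorylated ERK (ppERK) is the pathway output — the proxy for the
p-p90RSK pharmacodynamic readout — and drives three negative feedbacks:

1. **Fast phospho-feedback** (`fb_phospho`): ppERK places inhibitory
   phosphorylations on unphosphorylated MEK and on active, CRAF-containing
   RAF.  These equilibrate on the sub-hour scale (recovery rates 2-4 /h).
2. **DUSP induction** (`fb_dusp`): ppERK induces synthesis of DUSP
   phosphatases (Hill kinetics) that dephosphorylate ERK; DUSP turns over
   with a ~3 h half-life.
3. **SPRY induction** (`fb_spry`): ppERK induces SPRY (steep Hill kinetics),
   which inhibits the Grb2-SOS input competitively
   (`GS_eff = GS / (1 + [SPRY]/K_spry)`); SPRY turns over with a ~12 h
   half-life and is the slow lever that times 24-72 h pathway reactivation.

All reactions are mass action except the two Hill synthesis terms.  Every
protein moiety (Ras, RAF, MEK, ERK) is conserved exactly by construction;
`ReactionNetwork.check_conservation()` verifies the stoichiometry matrix and
every simulation is audited for < 1e-6 relative drift.

### Drug mechanism

One MEK inhibitor and one ERK inhibitor bind reversibly to every
phosphoform of their target with state-independent affinity.  Bound protein
keeps its phosphorylation state and remains a substrate for kinases and
phosphatases, but is catalytically dead; drug-bound ppERK contributes
neither to the pathway output nor to any feedback drive.  This last point is
the mechanistic heart of the package: ERK inhibition silences output while
*relieving* negative feedback, so the upstream cascade re-activates through
the residual unbound fraction.  Free drug is clamped (no depletion), which
matches the experimental observation that replacing drug-containing media
does not change the outcome.

### RAS-coupled vs RAF-decoupled variants

`ras_coupled=True` (KRAS-mutant topology) activates RAF in proportion to
Ras-GTP, so the SPRY and CRAF feedbacks control the input to the cascade.
`ras_coupled=False` mimics a BRAF-mutant tumour: RAF activates at a
constitutive first-order rate, sized by 1-D root finding so the drug-free
steady state exactly matches the coupled twin (isolating topology from
baseline).  Constitutive mutant-BRAF-like RAF is additionally insensitive to
the CRAF-directed feedback phosphorylation, so those reactions are removed
in the decoupled variant; the MEK arm of the phospho-feedback and the DUSP
loop remain.  SPRY is still expressed but has no effect, because nothing
downstream reads Ras-GTP.

### Numerics

LSODA with rtol 1e-8, atol 1e-10 nM; concentrations floored at 0 after each
solve (floor violations beyond -1e-9 nM raise).  Steady states integrate in
growing chunks until the maximum relative rate falls below 1e-8/h or 1000 h
elapse; non-convergence is flagged on the result, never silently accepted.
Identical inputs produce identical trajectories (no stochastic elements).

### Parameter provenance and calibration

No published table fixes the rate constants, so the defaults are a
reconstruction: orders of magnitude follow the classic distributive-MAPK
modelling lineage (protein totals 100-300 nM, phosphatase rates ~1-2 /h,
transcriptional half-lives of hours), and the free constants were then
calibrated against a behavioural constraint suite that encodes the
qualitative biology the model must reproduce:

* vehicle free ppERK at least 20% of total ERK (chronic pathway activity);
* at the MEK inhibitor's output-EC50, the output nadir arrives within 6 h
  and rebounds by at least half of the suppressed amplitude by 72 h;
* that rebound collapses (< 0.05) when DUSP and SPRY induction are disabled;
* the half-dose combination's 0-72 h output integral lies strictly below
  both full-dose single agents;
* 6-h active-CRAF fold-changes order combo > MEKi >= ERKi > 1, with the
  MEKi fold inside the 2-4x band;
* the Loewe synergy score of the coupled variant exceeds ten times the
  decoupled variant's, which must sit inside the sham additivity band.

`scripts/calibrate.py` re-evaluates the full suite against any parameter
file and prints a pass/fail report; the frozen result ships as
`params_default.yaml`.  The calibrated cascade places vehicle ppERK at ~32%
of total ERK with moderate catalytic excess, a strongly suppressed
Ras/RAF input (SPRY holds the Grb2-SOS drive at ~1/16 of its naked value,
fast CRAF feedback holds ~70% of active RAF in the inhibited pool), and a
steep SPRY induction curve centred just above the drugged operating range,
which gives the feedback loop the gain it needs to restore output against
an order-of-magnitude inhibitor excess.

**Reference doses.** The single-agent reference dose ("output-EC50") is
defined as the dose halving the 0-72 h time integral of pathway output
relative to vehicle — the model analogue of a cellular EC50 measured over
the assay exposure window, and the same readout the viability link uses.  A
steady-state definition would be self-contradictory here: if the drugged
steady state were exactly half of vehicle, the rebound index
`(out(72) - nadir)/(baseline - nadir)` could never reach 0.5 (its supremum
as the nadir approaches zero), so reactivation would be unmeasurable at the
reference dose by construction.  Fractional dosing means exactly half of
each single-agent reference dose, matching the experimental design.

**Inhibitor affinities.** Effective cellular Kds are placeholders (the
measured constants for the clinical compounds are not public): 0.07 nM for
the MEK inhibitor and 30 nM for the ERK inhibitor.  The ~400x separation
matches the compounds' relative cellular potencies (the ERK inhibitor is
dosed several-fold higher in the experiments this model mirrors) and serves
a structural purpose: on the 0-1000 nM dose ladder the feedback-buffered
(RAS-coupled) variant transitions mid-grid, while the hypersensitive
decoupled variant — BRAF-mutant lines are the most drug-sensitive in the
screening data — is already saturated at the lowest tested doses, where a
combination matrix cannot deviate from additivity.

## 2. Viability link

Cell-viability simulation requires a map from pathway output to fractional
viability; no functional form is published, so the package documents its
own: with `u` the chosen readout (default: 0-72 h time integral of free
ppERK) and `v` the vehicle value,

    f(u) = K^h / (K^h + u^h)
    viability(u) = 1 - Emax * (f(u) - f(v)) / (1 - f(v))

a decreasing Hill transform normalised so viability is exactly 1 at vehicle
output and exactly `1 - Emax` at zero output; `K` is the half-effect output
level in the `v >> K` regime.  Calibrated defaults: `Emax = 0.95`,
`K = 2400 nM*h` (~35% of the vehicle integral), `h = 3.5` — steep enough
that viability demands sustained, not merely transient, pathway
suppression, which places the single-agent GI50s at sub-saturating doses
where reactivation matters.  A steady-state readout mode is selectable.

## 3. Dose-response machinery

Effects are percent (0-100) in fitting (GI50 convention) and fraction
affected (0-1) in synergy surfaces; converters are explicit.  The default
combination axis is nine half-log doses, 0.1-1000 nM.  A strict 1-1000 nM
half-log ladder contains only seven values, so the printed "9x9,
half-log, 1-1000 nM" layout is not internally consistent; the default
keeps half-log spacing and the 1000 nM top.  The alternative
`zero_anchored_dose_grid` (an explicit zero dose plus eight half-log steps
to 1000 nM) is the layout used for Loewe analyses, where observed
zero-dose margins anchor the single-agent curves exactly.

4PL fits (`E(d) = bottom + (top-bottom)/(1 + (ec50/d)^hill)`) are robust by
default: a Cauchy-loss restart (scale adapted to the MAD of a plain fit)
followed by three iteratively reweighted rounds of Tukey bisquare
(c = 4.685), a standard, reproducible stand-in for unspecified commercial
"robust outlier detection".  A plain least-squares start is not resistant:
with four free parameters a steep-hill curve will chase a single gross
outlier.  Screening mode constrains the maximal-effect asymptote to a
percent interval (e.g. 50-100%); the screening language speaks of the
viability curve's lower asymptote, which is the effect curve's upper
plateau — the constraint is applied in effect space.  GI50 is the analytic
50%-effect inverse, censored as "> max tested dose" when 50% lies outside
the fitted asymptotes.  Margins of noiseless simulated matrices are fitted
without reweighting on a dense dose ladder, extended below the grid minimum
until the low-dose plateau is resolved, because an unresolvable margin
curve corrupts the Loewe expectation.

## 4. Synergy analysis

Loewe additivity is the null for two drugs in one pathway: the expected
effect E* solves `dA/D_A(E) + dB/D_B(E) = 1` with `D_i` the analytic 4PL
inverse, found by bracketed Brent iteration on the shared achievable effect
range (machine-precision tolerances; the sham self-combination must come
out additive to 1e-6).  Saturation (dose pairs demanding more than
min(topA, topB)) returns the ceiling with a flag rather than extrapolating.
Bliss independence is `EA + EB - EA*EB`.  The synergy score is a weighted
sum of the excess (observed - expected): `uniform` (default) is the mean
excess x 100; `effect_weighted` weights by the expected effect.  Scores are
comparable only within one scheme, and neither reproduces the numerical
scores of the proprietary screening software the experiments used.

Isoboles are constant-effect contours.  Crossings are located along every
grid row and column by monotone PCHIP interpolation of logit-transformed
effects against log dose (the logit, taken relative to the surface's
observed ceiling, makes a 4PL-shaped line exactly linear in log dose);
straightness is then judged in linear dose space, where Loewe additivity
predicts straight lines.  Raw bilinear interpolation on a 9-point half-log
lattice was rejected: its mid-cell error (~1.7% of chord length for a
hill-1 sham) is comparable to the 2% straightness tolerance the sham
control must meet, so the control would have measured the interpolant, not
the surface.

### What the coupled-vs-decoupled contrast does and does not show

One structural fact deserves honesty: two inhibitors acting at different
nodes of a feedback-free cascade attenuate output *multiplicatively*, and a
product of hyperbolic dose-attenuation factors always reads as (weakly)
Loewe-synergistic — exact additivity of a product structure would require
exponential attenuation, which reversible binding cannot produce.  The
contrast between the variants therefore rests on two real mechanisms plus
one design choice: (i) feedback buffering widens the coupled variant's
resistance window by an order of magnitude, creating a broad dose region
where the combination defeats reactivation that either single agent cannot
— this is the synergy signal; (ii) the decoupled variant is hypersensitive,
so on the zero-anchored 0-1000 nM ladder its transitions are complete at
the lowest tested doses and its matrix has no room to deviate from
additivity; (iii) the explicit zero margins carry identically zero excess.
With all feedbacks disabled the two variants become dynamically identical
and share the small intrinsic multiplicative deviation — the *contrast*
vanishes, which is the invariant the test suite asserts.

## 5. Reactivation metrics

The rebound index of an output series with drug applied at t = 0 is
`(out(t_end) - out(nadir)) / (out(0) - out(nadir))`: 0 means no rebound, 1
full return to baseline; traces suppressed by less than 1% of baseline are
flagged undefined.  Transcript recovery reports DUSP/SPRY levels as percent
of their pre-drug baseline (the two species collapse the multi-gene MAPK
target panel; per-gene claims are not reproduced).  Active-CRAF fold-change
is the active, non-feedback-phosphorylated RAF pool normalised to its
vehicle steady state.  `compare_fractional_combo` runs the three-regimen
experiment (full-dose singles vs half-dose combination) and
`ras_vs_braf_contrast` re-runs identical dose matrices through both network
variants, reporting both Loewe scores plus a sham additivity band — twice
the largest |score| obtained by pushing each drug's self-combination
through the identical simulate/fit/expect pipeline, i.e. the resolution
below which a score is indistinguishable from additivity.

## 6. In-vivo efficacy metrics

Tumour growth is fitted per animal by ordinary least squares on
log2(volume) vs day (minimum three timepoints; excluded animals warn); the
group curve is the mean of animal fits.  This replaces the mixed-effects
fit used with the original caliper data — in balanced designs the group
mean slopes coincide, and the substitution is recorded in the fit's
`method` metadata.  %TGI follows the AUC-per-day formula
`100 x [1 - (AUC_treatment/day)/(AUC_vehicle/day)]` on back-transformed
(linear-scale) fitted group curves, trapezoid-integrated on a quarter-day
grid over the shared window; regressing tumours can exceed 100%.  Whether
the original AUC was taken on the log2 or linear scale is not stated; both
are selectable, default linear.  PFS is time to volume doubling
(threshold_fold x the first-day baseline, linearly interpolated between
measurements) or recorded death, whichever is earlier; animals ending the
study event-free are censored and group medians are Kaplan-Meier medians
(computed directly; log-rank testing is out of scope — event tables are
exported for external tools).

## 7. Synthetic data

Generators are pure functions of a `GeneratorSpec` (seed included) and emit
machine-readable truth alongside data.  `gen_curves` mirrors the screening
layout (8 concentrations, 3-fold dilutions from 50 uM) with additive
Gaussian noise on effects, clipped to [0, 1] — simple and documented, at
the cost of slight bias where the true effect sits near a bound.
`gen_matrix` synthesises combination matrices under a Loewe (via the same
solver the analysis uses), Bliss, or sham null, plus an optional
raised-cosine synergy bump over the mid-dose quadrant whose injected mass
is recorded for recovery tests.  `gen_cohort` mirrors the xenograft design
(10 animals/group default, twice-weekly calipers for 21 days): per-animal
exponential growth with optional slope jitter and multiplicative lognormal
measurement noise (caliper error is scale-proportional); the default
two-group scenario uses doubling times of 7 and 18.5 days, the vehicle and
combination progression medians reported for the pancreatic GEM model.

What the generators do *not* emulate: plate spatial/edge effects, batch
drift, pharmacokinetic variation, death processes coupled to tumour burden,
or inter-animal heterogeneity beyond lognormal slope jitter.  Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated statistical assumptions, not robustness to real-world artefacts.

## 8. Known limitations

* The rate constants are a calibrated reconstruction, not measured values;
  only the behavioural bands, orderings and topology contrasts are
  meaningful, never absolute concentrations or absolute synergy scores.
* The decoupled variant's additivity partly reflects grid placement (see
  section 4); a dose ladder extended far below 0.3 nM would resolve its
  transitions and recover the small intrinsic multiplicative deviation.
* The viability link is a documented invention; GI50s depend on it.
* No receptor layer, no paradoxical RAF-inhibitor activation, no
  pharmacokinetics, no spatial or stochastic effects.
* SBML export is not implemented (no SBML library in the supported
  dependency set); the reaction list is introspectable in Python instead.
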