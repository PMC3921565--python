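# Methods

This note documents the models, rules and numerical choices behind each
module, what the synthetic generators emulate (and deliberately do not), and
the design decisions taken where the procedure left genuine freedom. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Statistical engine (`stats_core`)

**Two-way between-subjects ANOVA.** Age × stress designs with 8–12 animals
per cell are mildly unbalanced, so sums of squares are Type III (sum-to-zero
contrasts, each effect adjusted for all others), computed through a
statsmodels OLS fit. The commercial packages typically used for such designs
behave the same way; the test suite pins the implementation against an
independent R `car::Anova(type=3)` computation frozen into the tests. A
vectorized variant (`two_way_anova_matrix`) factors the shared design matrix
once and evaluates the three model comparisons for hundreds of response
variables simultaneously; it is verified against the scalar route to ~1e-13.

**Mixed (between × repeated) ANOVA.** Implemented directly as the standard
partition `SS_total = SS_group + SS_subj(group) + SS_time + SS_group:time +
SS_resid`, testing the between factor against subject-within-group error and
the repeated factor and interaction against the within-subject residual.
Degrees of freedom are uncorrected — no sphericity adjustment is applied,
because the procedure being mirrored reports none; under the generators'
compound-symmetric noise this is exact. The oracle is R `aov` with
`Error(subject/time)` strata, frozen into the tests. Complete panels are
required; missing cells raise rather than impute.

**Fisher's LSD** is the protected pairwise t contrast on the omnibus MSE.
The operation itself is gate-agnostic; callers (architecture, maze, CORT,
I/O, temperature analyses) run it only when the omnibus interaction or a
relevant main effect is significant, mirroring the usual reporting pattern.

**Effect size** is (stress mean − control mean) / pooled SD with
(n−1)-weighted variances — the pooled-SD convention was not further
specified, so the df-weighted form was chosen and documented. **FDR** is
Benjamini–Hochberg step-up (via statsmodels); adjusted q-values are reported
alongside raw p-values, but panel significance calls use raw α = 0.05, the
convention of the analysis being reproduced. **Binomial agreement** tests
are exact upper tails. Degenerate inputs (zero within-cell variance) return
flagged results with p at its exact limit (0 or 1), never silent NaNs.

## Sleep staging (`sleep`)

Signals are binned in 10-s epochs. Each bin gets FFT band powers (Hann
window, no overlap, periodogram summed over half-open intervals delta
0.5–4, theta 4–8, alpha 8–12, sigma 12–16, beta 16–24 Hz), a peak-amplitude
EEG envelope and an RMS EMG envelope. Tier stratification is scale-free:
EEG "low" ≤ 50% of the recording reference maximum, EMG thirds at 33%/66%.
The reference "maximum" is the **99th percentile** of the per-bin envelope
over artifact-free bins — a literal maximum would be dominated by artifacts.
Whether the original tiering used per-recording or per-session maxima is
unknowable from the description; per-recording is the documented assumption,
and tier assignments are invariant to channel-wide gain by construction.

30-s epochs aggregate their three bins (medians for continuous features,
majority vote for flags) and pass through the rule table: locomotion with
non-basal EMG, or high EMG, → Wake; high-amplitude delta-dominant EEG with
basal-to-intermediate EMG and no locomotion → Deep; low-amplitude EEG with
intermediate EMG and no locomotion → Light; remaining intermediate-EMG
epochs → Wake (EEG variable); low-amplitude theta-dominant EEG with basal
EMG and no locomotion → REM, **only if the running prior stage is a sleep
stage** — this is the one use made of "prior assignments inform subsequent
assignments"; no other smoothing is applied. Anything else, and any epoch
containing an artifact bin (sample beyond 6× the bin's robust SD, or a flat
line), is Unscored. "High frequency EEG" for REM is operationalized as
theta power exceeding delta power in the low-amplitude tier; "basal to
light" EMG for Deep is read as the basal and intermediate tiers.

Architecture minutes are 0.5 × epoch counts within the first 4 h after
lights-off (active) and after lights-on (resting); stage plus Unscored
minutes always sum to 240 per window.

## Synthetic telemetry

Ground-truth hypnograms are drawn first, at the 30-s scoring resolution,
from a period-dependent Markov chain (wake-dominant active matrix,
sleep-dominant resting matrix; REM reachable only from sleep states), then
the signal is synthesized per epoch — so stage boundaries never fall inside
an epoch and labels are unambiguous. Group modifiers multiply target-stage
propensities: aged animals get less resting deep sleep; stressed young get a
wake-shifted, REM- and deep-poor resting period plus elevated active-period
deep sleep; stressed aged get elevated resting REM only.

Per stage the EEG is an amplitude-scaled oscillation plus broadband noise
(Deep: ~1–3 Hz, high amplitude; REM: ~5.5–7.5 Hz, low amplitude; Light/Wake:
broadband at low/high amplitude), the EMG is white noise at a tier-matched
level, and locomotor counts occur only in Wake bins. Amplitudes are
arbitrary units — no raw-signal calibration (µV, electrode gain) is modeled,
only internally consistent contrasts, which is all the scale-free classifier
uses. Artifacts are spike bursts injected per epoch at a configured rate
(default 2%) and recorded in the truth.

Temperature is a 24-h sinusoid (default 37.0 ± 0.4 °C) peaking mid-active
period, a per-animal baseline offset (SD 0.08 °C), AR(1) noise (φ = 0.9,
σ = 0.05), and an additive stress-hyperthermia offset during the resting
period for stressed animals (+0.6 °C young, +0.1 °C aged). The offset is
recovered by a difference-in-differences estimator (resting-minus-active
within animal, stress-minus-control across groups, excluding hour bins that
straddle a lights transition), which cancels both per-animal baselines and
the shared circadian profile.

Because no contiguous 8-h span under the reverse 12:12 schedule (lights off
04:30, on 16:30) contains both scoring windows, default signal-level
recordings are 8 h from lights-off (sufficient for stager fidelity
measures), while architecture analyses use 16-h spans (04:30–20:30); for
replicate-heavy pattern tests the hypnogram is generated without signal
synthesis, which is exact and orders of magnitude cheaper.

## Water maze

Geometry: 190-cm pool, 15-cm platform centered mid-quadrant (47.5 cm from
the pool center); quadrants are the four sectors about the pool center with
the goal quadrant centered on the platform. Drop points sit at the quadrant
mid-angles at radius 85.2714 cm, chosen so the mean drop-to-platform
distance is exactly the reported 91.44 cm. Probe trials start in the
quadrant opposite the goal.

Metrics are defined on the raw 10-Hz polyline with no smoothing. Segment
membership in the goal quadrant is decided by the segment midpoint (cheap
and unbiased). A platform "crossing" is an entry of the tracked point into
the former platform disc, with a debounce: after an entry, the animal must
move more than one platform diameter from the platform center before a new
entry counts — the tracker's own crossing definition is unknown, and without
a debounce boundary jitter double-counts. Goal-quadrant path length includes
the platform disc.

The trajectory generator is a discrete-time correlated random walk
(heading noise SD 0.55 rad per 0.1-s step) with a drift parameter toward the
platform ("goal bias") — the simplest model spanning chance-to-perfect
performance. Per-animal speeds are drawn at the observed group means
(young 33.7, aged 28.5 cm/s) with SD 5 cm/s, the between-animal spread
implied by the reported standard errors (~1.1 at n ≈ 20). At the wall the
animal turns toward the pool center with full step length, so realized swim
speed equals the drawn speed. Training biases rise over days (aged starting
lower and improving more, young near ceiling); probe biases encode the
planted pattern: young-control 0.14, young-stress 0.06 (the stress deficit),
aged 0.075 in both stress groups (hypo-responsive). These defaults yield
probe crossings of roughly 5–6 (young control), ~2 (young stress) and ~3
(aged), and a reliably significant interaction with a significant young
control-vs-stress LSD contrast.

## Gene panel

The packaged registry is a **synthetic stand-in** gene list (the original
panel identifiers are not redistributable here) that preserves the panel's
composition — 171 rat hippocampal-aging genes, 101 prior-up (immune,
inflammatory, glial) and 70 prior-down (neuronal, synaptic).

Normalization follows standard spike-in practice: per-lane scale factor =
(mean over lanes of positive-control geometric means) / (lane geometric
mean); lanes with a zero positive-control count are excluded and flagged;
background = mean + 2 SD of the lane's negative controls, subtracted with a
floor at zero. QC gates lanes on binding density (default 0.1–2.25) and
fields-of-view fraction (≥ 75%).

All tests run on log2(normalized + 1) values — the analysis being mirrored
does not state its scale, and the log stabilizes the multiplicative count
noise. Per-gene significance uses the any-of-three-effects rule at raw
α = 0.05, with the expected-null count reported as round-half-up of
n_genes × α (171 × 0.05 → 9); the per-test n×α convention reproduces the
printed expectation, and BH-adjusted values are reported alongside. The Venn
partition tests the young-vs-aged contrast separately within control and
within stress lanes using a pooled-variance two-sample t — the named
"pairwise contrast" statistic is not specified, and this choice is isolated
behind one function. Stress effect sizes are computed within young and
within aged lanes; a control-only gene is oppositional iff the two effects
have strictly opposite signs (an exact zero is a boundary case, counted and
excluded from the oppositional class). `cv_summary` computes per-gene CVs
**within age × stress cells** and averages the two cells of a condition;
pooling ages first would fold the large planted age effect into the
dispersion estimate and could not produce the ~12% figures it mirrors.

The generator plants: "both" genes with a ±0.8 log2 age contrast in every
condition; "control-only" genes whose stress shifts cancel the age contrast
within stressed lanes — oppositionally (±0.4/∓0.4, 33 of 42 genes = 79%) or
concordantly (1.2×/0.2× the age effect, same sign, still cancelling);
"stress-only" genes with the contrast split across stress shifts; and null
genes with no planted effect. Counts are rounded lognormal draws around
lane-scale × baseline × 2^(effects), with σ set so the within-cell CV equals
the 11.7% target (no extra Poisson layer, so the realized CV matches the
dial); positive spike-ins follow a titration series with per-lane scale and
negative spike-ins are Poisson background.

Two consequences of these conditions are worth stating. First, with 78 null
genes tested at raw α = 0.05 the recovered control-only class carries an
irreducible expectation of ~+1.5 extra genes (false positives in control
lanes minus control-only genes lost to chance stress-lane significance) and
an SD of ~2.4, so the recovered count fluctuates around 43–44 against the
planted 42; recovery is therefore assessed as a median/mode over seeds.
Second, null genes carry no age drift, so the strong direction-of-change
agreement among **non-significant** genes seen in real data is not emulated
— only the significant-stratum agreement (driven by planted effects) is
asserted. A drift large enough to matter for agreement would inflate the
Venn false positives and was rejected.

## Physiology

**Temperature** is hourly-binned (mean per clock hour, implausible samples
outside 34–41 °C flagged out) and analyzed by the mixed group × time ANOVA
with per-hour LSD contrasts when gated.

**Field potentials.** Sweeps are a 0.5-ms biphasic stimulus artifact
followed by an alpha-function EPSP (τ = 3 ms, onset 1 ms post-stimulus).
EPSP slope is the maximum-magnitude fixed-width (1 ms) linear fit sliding
over 1–8 ms post-stimulus — the original measurement window is not stated,
so slope comparisons are internal-consistency only; the measure is invariant
to baseline offset, and units are arbitrary-consistent V/s. I/O amplitudes
follow a sigmoid of stimulus step (mid-step 5.5, width 1.2) with the
aged-control curve scaled to 0.6×, per-animal multiplicative spread 0.12 and
0.5% sweep noise; the "1/3 of maximum" stimulus for paired pulse is the step
whose slope magnitude is nearest max/3. Paired-pulse facilitation scales the
second response by a delay-dependent factor (1.45/1.30/1.18/1.08 at
50/100/150/200 ms), identical across groups (no planted group difference,
matching the finding being emulated); ratios are slope(second)/slope(first),
averaged over triplicates, and invariant to uniform gain.

**Corticosterone.** Values below the 20 ng/ml quantification limit are
included at the limit with a censored flag (not dropped); an all-censored
dataset is degenerate and no test is run. Generator means (young
110 → 320 ng/ml control → stress; aged 70 → 190; SD 70) are within the
species' reported active-period range and produce the expected pattern:
significant age and stress main effects and a significant young
control-vs-stress contrast, with the aged response blunted.

## Orchestration and reproducibility

A pipeline run is a pure function of its config (seed included): every
generator derives child seeds from `numpy` `SeedSequence` spawned off the
config seed plus a module-specific constant, so modules are decoupled and
reruns are byte-identical. The report directory holds one tidy CSV per
figure-style analysis plus `report.json` with the config hash (content
fields only, not the output path) and a findings summary. Ingest of user
CSVs is supported at the module level (trajectory CSV, RCC-like panel CSV,
hypnogram/temperature CSV); telemetry I/O is CSV-based — EDF support would
require an EDF writer backend not carried as a dependency.

Problem sizes used by the test suite and acceptance script — 8 animals × 8 h
for stager fidelity, 16-h hypnogram-level cohorts for architecture
replicates, 20 seeded panels for recovery summaries, 50 replicates for
pattern rates — were chosen as the smallest sizes at which the targeted
effects are comfortably powered; all scale up by config.

## Known limitations

* EEG synthesis is phenomenological (per-stage spectra), not biophysical;
  classifier accuracy on it (~93–96%) bounds plumbing errors, not
  performance on real telemetry, where stage boundaries, gradual
  transitions and richer artifacts will lower accuracy.
* The swim model has no thigmotaxis or search-strategy taxonomy; probe
  "focus" is a single drift parameter.
* Panel noise is a single lognormal CV per dataset; real nCounter data has
  gene-dependent dispersion and occasional count saturation.
* The mixed ANOVA assumes complete panels and applies no sphericity
  correction; with strongly autocorrelated repeated measures its
  within-subject p-values would be anticonservative.
* CORT censoring is handled by substitution at the limit (as in the
  mirrored analysis), not by a censored-likelihood model.
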