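# Methods

This note documents the models, defaults, and design choices behind
`sentspec`, and what the synthetic-data tests do and do not establish
about real data.

## Task designs

Each task run contains equal numbers of trials per condition (default:
4 conditions × 10 trials per run, two runs, i.e. 20 trials per condition
per task). A trial is sentence audio (duration uniform on 2.7–4.5 s), a
2.3 s response window, and an inter-trial interval drawn from
{0, 575, 1150} ms with counts as equal as integer division allows, so
total trial duration spans 5.00–7.95 s. Condition order is rejection-
sampled (cap 10,000 attempts, then an explicit failure naming the
constraint) until no more than five consecutive trials share an expected
yes/no response. Trials are laid out back-to-back; run length is the
last trial's offset plus 10 s of rest so the hemodynamic response can
return to baseline. The repetition time defaults to 2.0 s — a typical
pediatric echo-planar value; it is configurable, and only scales the
design matrices, because no stage of the analysis depends on its
absolute value.

## Behavioral model and screening

Per-trial correctness is Bernoulli with a per-condition accuracy;
defaults emulate the performance profile of 9–10-year-olds on these
tasks (e.g. FVio 72.7 %, perceptual control near ceiling). Incorrect
trials press the wrong button, or give no response at a configurable
rate (default 0); reaction times are normal per condition, truncated to
the trial's response period, and mean RTs are computed over correct
trials only. Non-response trials count as incorrect.

Inclusion applies six criteria (completeness, handedness ≥ 3/5 right,
dialect status, standardized scores > 70, performance, motion), reporting
*every* failed criterion. The performance floor is read strictly
(accuracy > 50.0 % on PC, SCon, PVio in every run) and the response-bias
limit inclusively (|SCon − InCon| and |Gram − PVio| ≤ 40.0 points); the
sources describing these rules mix strict and inclusive phrasing at the
exact boundary, so the boundary behavior here is a declared convention.

## Motion outliers, repair, de-weighting

A volume is an outlier if any of its three translation parameters moved
more than 1.5 mm since the previous volume (the first volume is exempt)
or its within-brain-mask global mean deviates more than 4 % from the run
mean. The millimeter threshold is applied to translations only;
rotations can be converted at an assumed head radius via
`rotation_radius_mm`, off by default, because the threshold is a
translation unit. The 4 % rule uses the run mean as baseline — a
deterministic choice; running-mean variants exist in other
implementations but are not used here. Outliers are repaired by
voxelwise linear interpolation between the nearest good neighbours
(boundary outliers copy the nearest good volume) and receive weight 0.01
(versus 1.0) in the first-level fit; they are never censored. A run
fails the motion screen if more than 10 % of volumes, or more than 6
consecutive volumes, are outliers.

## First-level GLM

Condition regressors are boxcars (onset to onset + sentence duration;
the response window is deliberately not modeled separately) convolved
with the canonical double-gamma HRF (peak delay 6, undershoot delay 16,
peak:undershoot ratio 6, 32 s support), built on a 16× oversampled grid
and sampled at volume times. High-pass filtering is implemented by
including a discrete-cosine basis with floor(2T/128) regressors directly
in the design matrix rather than pre-filtering — the same projection,
and it interacts correctly with the per-volume weights. Six motion
parameters and an intercept complete the matrix; nuisance columns that
add no rank (e.g. a constant motion trace, collinear with the intercept)
are dropped and recorded, while rank deficiency among condition
regressors is an error naming the dependent columns.

Fitting is voxelwise weighted least squares: β̂ = (XᵀWX)⁻¹XᵀWy,
σ̂² = Σw e²/df with df = rows − rank(X), and
t = cᵀβ̂ / √(cᵀ(XᵀWX)⁻¹c · σ̂²). The analysis mask keeps voxels whose
temporal mean exceeds 0.5 × the grand mean; t is undefined (NaN)
elsewhere. Each run is fit separately so that per-run contrast t-maps
exist for the split-run correlations; a single multi-run fit with
run-specific regressors would be equivalent for this purpose. AR(1)
prewhitening is deliberately omitted: the t-maps enter the analysis only
through spatial correlations, which are invariant to the map-wide
rescaling whitening induces, and omitting it keeps the weighting
interaction exact. With all weights 1 the fit reduces exactly to OLS.

## ROI selection

Region masks are the intersection of an anatomical label volume with
analyzed-voxel coverage. Within a region, the selection statistic is the
all-sentences-minus-control contrast pooled across tasks and runs (the
per-run t-maps averaged); the top 250 voxels are taken regardless of
significance, ties broken by ascending voxel linear index so selection
is deterministic and storage-order independent. Regions smaller than 250
voxels return all voxels with a warning rather than failing — the budget
is a cap, not a requirement.

## Pattern model (synthetic cohort)

Voxel patterns are simulated as

    pattern(task, run) = shared + task_specific(task) + run_noise

with each component i.i.d. normal per voxel: variances σ²s (participant-
stable, common to both tasks), σ²t(task) (stable within task), σ²r
(independent per run). Expected correlations follow in closed form:

    within-task  r = (σ²s + σ²t) / (σ²s + σ²t + σ²r)
    across-task  r = σ²s / √((σ²s + σ²t_A + σ²r)(σ²s + σ²t_B + σ²r))

A consequence worth stating explicitly: whenever σ²s > 0 and one task
carries σ²t > 0, the *other* task's within-task correlation strictly
exceeds the across-task correlation (here by 0.045 at σ²s = 1, σ²t = 1,
σ²r = 2), so with adequate power a one-sidedly specialized region is
graded *weak* (sensitive to both, preferring one). Exact strong
specialization — within-other = across — is attainable in this additive
model only with σ²s = 0, i.e. when the two tasks share nothing in that
region. The validation regimes therefore check recovery of the evidence
family (syntactic / semantic / both / neither) under the shared-variance
conditions, and recovery of the strong grade under zero-shared regimes.
Default simulation conditions: 64 participants, 250 voxels per region,
σ²s = 1, σ²t ∈ {0, 1}, σ²r = 2, 200 replicates.

All components are normal; heavier-tailed alternatives are out of scope.
Condition mean amplitudes shift pattern means without affecting
correlations and feed the BOLD forward model as per-voxel betas.

The BOLD path simulates y = baseline + Σc βc·xc(t) + drift + noise with
the *same* HRF-convolved regressors the GLM uses, so a noiseless
simulation round-trips through the GLM to numerical precision (tested at
1e-8 relative) — this validates the GLM algebra, not the HRF model
itself. Motion traces are a Gaussian random walk (wander SD 0.02 mm per
step) with optional sustained step displacements at chosen volumes.

## Pattern correlations and group inference

Correlations are Pearson on raw t-values; the four across-task run-pair
correlations are averaged arithmetically. No Fisher-z transform is
applied before averaging or before group tests, matching how these
quantities are conventionally reported and tested; a `fisher_z` flag
applies z-averaging for sensitivity analyses. Correct-sentence
(Gram/SCon) and incorrect-sentence (FVio/InCon) analyses are the same
code path parameterized by condition pair; an exploratory PVio/InCon
pairing is available under the same parameterization.

Paired t-tests are two-tailed with df = n − 1; Bonferroni correction
multiplies by m = 3 — the three comparisons within one region × sentence
type, *not* 3 × 4 regions. This family size is verifiable analytically:
the reference corrected p-values (0.096, 0.249, 0.021, 0.669, …)
reproduce from their t-statistics at df = 63 only with m = 3. Corrected
p-values are capped at 1.0; reference reports show a 0.999 display
ceiling instead, which is treated as a formatting convention. Outcome
classification requires the significant comparisons to have the
direction the outcome asserts; any significant reversed direction maps
to `indeterminate`, and the mapping is total over all 27
significance/direction triples.

Cells drop incomplete participants listwise (counts recorded); duplicate
participant ids are an error, as are cells with fewer than two complete
participants.

## What the synthetic tests do and do not show

The generator reproduces the *statistical structure* the analysis
assumes — split-run stability, partial cross-task sharing, balanced
designs, motion spikes, de-weightable corrupted volumes — with known
ground truth, so the tests establish that every stage computes what it
claims and that the chain recovers planted regimes at the stated cohort
size. It does not emulate spatial autocorrelation, hemodynamic
variability across children, task-correlated motion, or registration
error, so passing tests do not certify performance on scanner data;
they certify the arithmetic and the inferential logic.

## Numerical conventions

Seeds flow from one root `numpy` SeedSequence through named substreams
per participant and stage; identical seeds give bit-identical designs,
patterns, series, and reports. Problem sizes in the test suite and the
acceptance script (e.g. 200 replicates × 64 participants × 250 voxels
for recovery; 10,000 voxels for closed-form convergence at tolerance
0.02) were chosen to make Monte-Carlo error comfortably smaller than the
assertion tolerances while keeping a full run in tens of seconds.
Degenerate inputs fail loudly: empty conditions, zero-variance vectors,
all-flagged runs, rank-deficient designs, and unsatisfiable ordering
constraints all raise errors naming the offending object.
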