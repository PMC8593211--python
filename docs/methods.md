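# Methods

## The measurement model

A test day is an event stream: lick contacts and infrared port-entry beam
breaks at two sipper ports, plus sipper extension/retraction events.
Analysis windows — phase 1 (5 min, sipper 1), inter-phase interval
(IPI, 20 s, no sipper), phase 2 (5 min, sipper 2) — are cut at the sipper
events when present and otherwise fall back to the fixed schedule
[0, 300), [300, 320), [320, 620) s. All windows are half-open, so an event
at exactly a boundary belongs to the following window; this makes window
additivity exact (every lick belongs to exactly one window or to the
reported residue — nothing is silently dropped).

Within a window, licking is segmented into **clusters**: a new cluster
starts wherever the inter-lick interval (ILI) exceeds 500 ms. The
inequality is strict — an ILI of exactly 500 ms stays inside a cluster —
and single licks count as clusters of size 1 (an optional
`min_cluster_size` parameter exists for sensitivity analyses; default 1,
so the conservation identity Σ cluster sizes = total licks always holds).
Per phase we derive: total licks, total clusters, licks per cluster
(= total licks / total clusters; *missing*, never 0, when there are no
clusters), and premature entries (entries at the non-active port; during
the IPI, both ports' entries are counted separately). Licks recorded at the
inactive port are treated as hardware noise: excluded from totals, counted
separately, and logged.

Paired sessions normalize the experimental day by its control day:
`normalized = experimental / control`, missing (flagged) when the control
value is 0. The ratio is scale-invariant, and 1 means no contrast.

## The statistical battery

Per group, metrics are analyzed with a **two-way fully within-subject
ANOVA** (Condition × Session), each effect tested against its own
subject-by-effect interaction. Sums of squares are partitioned directly
from cell means; the design is required to be balanced (subjects missing a
cell are dropped listwise, with a logged count), which makes the
decomposition exact and is asserted to 1e-8 at run time. Per-session
control-vs-experimental comparisons use paired t-tests with a Bonferroni
family of m = number of sessions (default 8, one family per metric ×
phase): p_bonf = min(1, m·p_raw), significance at α = 0.05. The
**emergence session** is the first session whose corrected comparison is
significant. Degrees of freedom for the two-way models are reported
uncorrected by default (`gg=True` is available).

The cross-group comparison runs a **three-way mixed ANOVA** on normalized
phase-1 licks: Diet (FF/FR) and Predictor (context/flavor) between
subjects, Session within. Between effects are tested on the
subjects-within-groups error; within effects on the Session ×
subjects-within-groups error. Sphericity of the Session factor is handled
with the **Greenhouse–Geisser ε**, computed from the pooled within-group
covariance S of the k repeated measures as
ε = tr(HSH)² / ((k−1)·tr((HSH)²)) with H the centering matrix; ε = 1
exactly for k = 2 and under compound symmetry, and ε ≥ 1/(k−1). By default
the correction is applied to the Session *main effect* (df multiplied by ε
in both numerator and denominator), while Session-involving interactions
are reported with uncorrected df and ε attached; `gg="all-within"` corrects
every within term, `gg="never"` none. Note the correction is conservative
in the decision-relevant regime: whenever the uncorrected p is below ~0.2
the corrected p is never smaller; for clearly null terms (F well below 1)
shrinking both df can lower p slightly, which cannot create a rejection.

Unpaired t-tests default to the pooled-variance (Student) form with a Welch
option; zero-variance inputs with equal means return t = 0, p = 1 by
convention.

## The generative simulator

The simulator produces event streams with the statistical structure the
analysis assumes, so that the pipeline's error rates can be measured.

**Cluster process.** Within a phase, candidate cluster-initiation times are
a homogeneous Poisson process at rate λ (clusters/min). Each cluster
starts at max(anchor, previous cluster end + pause) with
pause = threshold + Exp(mean 2 s); delaying rather than thinning anchors
keeps the realized cluster count rate-unbiased (only window-end truncation
loses ~1–2%) while guaranteeing every inter-cluster gap exceeds the 500-ms
threshold — so segmentation recovers the generative partition exactly.
Cluster sizes are 1 + Poisson(μ − 1) licks; within-cluster ILIs are
Gamma(shape 8, mean 0.14 s) — ~7 Hz licking, a field convention, not a
measured value — resampled (not clipped) on the rare draw above the
threshold. Clusters running past the window end are truncated at the
boundary. Expected phase licks ≈ minutes · λ · μ.

**Defaults.** Malt: μ = 6 licks/cluster, λ = 8 clusters/min (≈ 240 phase-1
licks in 5 min, a realistic total for a palatable solution); CM: μ = 12,
λ = 12 (palatability and incentive both higher). No quantitative
cluster-size or rate values exist for these solutions in the literature the
paradigm draws on; all are documented conventions, exposed as parameters.

**Contrast and learning.** On experimental days phase-1 parameters are
suppressed by a logistic learning curve s(session) = A·logistic((session −
s0)/τ) with defaults A = 0.4, s0 = 4, τ = 1 (suppression half-maximal
mid-training, near asymptote by sessions 7–8, mirroring the observed
emergence of the contrast in the second half of training). The suppression
is split by ρ (default 0.5): λ_eff = λ(1 − s(1−ρ)), μ_eff = μ(1 − s·ρ).
ρ = 1 reproduces the contextual-predictor signature (licks per cluster
carries the contrast), ρ = 0 the flavor signature (total licks change with
no licks-per-cluster change); the closed-form late-session
experimental/control licks-per-cluster ratio is 1 − A·ρ·logistic((s−s0)/τ).
Premature entries to the phase-2 port (phase 1 and IPI) are Poisson at
base 1/min plus s(session)·4/min on experimental days; port-1 entries stay
at base rate.

**Seeding.** One master seed; each (animal, day) and each preference-test
epoch gets an independent `SeedSequence` substream keyed by its indices, so
identical parameters and seed give byte-identical event streams and
enlarging a cohort never perturbs existing animals.

**Preference test.** Per epoch (pre/post): 10 forced-choice trials
(alternating flavors) then 30 free-choice trials; a trial allows licking
from first contact (latency ~ Exp(2 s)) for 10 s, capped at 30 s from
extension. Licking per flavor is the Malt cluster process scaled by that
flavor's preference weight; the post epoch multiplies both weights by 2,
emulating a general conditioned increase in intake with no flavor ×
epoch interaction.

**What the simulator does not model.** Satiation or post-ingestive feedback
within a day, body-weight/deprivation dynamics, flavor neophobia, carryover
of clusters across windows, and hardware artifacts (cross-port lick noise,
interleaved timestamps) beyond what the readers tolerate. Passing tests
therefore certify the *pipeline* — segmentation correctness, ANOVA
arithmetic, calibration of error rates under the assumed generative
structure — not any claim about real cohorts, whose raw files the reader
pipeline ingests through the documented CSV dialect.

## Validation studies and problem sizes

- **Segmentation**: 1,000 random lick trains (up to 10⁴ licks) against a
  one-lick-at-a-time reference; exact agreement plus the conservation
  identity, also enforced as hypothesis property tests.
- **ANOVA correctness**: 50 random balanced tables (4–10 subjects × 2
  conditions × 8 sessions) against an independent enumerated
  sums-of-squares oracle (agreement to 1e-8); one fixture cross-checked
  against pingouin (2-way) and the equivalent univariate mixed-model
  partition (3-way).
- **Type-I calibration**: 2,000 null-simulator cohorts (A = 0, n = 10, 8
  sessions); the Condition rejection rate must lie in 0.05 ± 0.02
  (binomial SE ≈ 0.005). The phase-1 totals are compound-Poisson sums of
  ~40 clusters, close enough to normal for the F test's nominal level.
- **Parameter recovery**: 20 animals; pooled μ̂ and λ̂ within 5% of the
  generative values, and the late-session licks-per-cluster ratio within
  3 SE of the closed form.
- **Regime dissociation**: 100 cohorts per ρ ∈ {1, 0}; the Condition ×
  Session interaction must be detected in the signature metric in ≥ 80% of
  cohorts (observed ≈ 100%) and spuriously in the null metric at ≈ α.

Replicate counts were chosen so each study resolves its question (binomial
SEs well inside the tolerance being checked) while the whole battery runs
in a few minutes on one CPU; the analysis drivers use smaller quick-look
versions of the same routines.

## Known limitations

- The mixed ANOVA requires balanced between-group cells; unbalanced
  cohorts are rejected rather than approximated (no Type-III/REML path).
- No Huynh–Feldt correction, no mixed-effects models, no effect sizes
  beyond mean differences.
- `licks_per_cluster` aggregates per animal-phase as total/clusters (the
  mean cluster size); group summaries average these per-animal values.
- The number of paired sessions is configurable (default 8); the analyzers
  infer it from the data and the Bonferroni family follows it.
- Raw MED-PC acquisition files are not parsed; the tidy CSV dialect is the
  adapter surface.
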