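# Methods

This note documents the models, conventions and numerical choices behind
the package, in the order data flows through it: coordinate frame and
endpoint definitions, the synthetic generative model, the kinematic
extraction chain, the psychometric estimators, and known limitations.

## Coordinate frame and units

One fixed lab frame throughout: **X = anterior (+), Y = vertical up (+),
Z = subject's left (+)**. Lengths in cm, angles in degrees, time in
seconds, rates in Hz. Frames are 0-based; analysis windows are half-open
`[start, end)`. "To the left" always means increasing Z; the
%-left-leg scale used by P-WB and SB-%BW maps the medio-lateral position
linearly with 50% at the inter-malleolar midpoint and 100% at the left
malleolus, extrapolating (never clamping) beyond — a value outside
[0, 100] records a CoP beyond the ankle span and is preserved as such.

## The 18 endpoints

Posture offsets are time means over the whole filtered quiet-stance
trial (a sub-window option was considered and rejected: with an 8 s
trial and 7 Hz filtering the mean is already stable, and a whole-trial
mean needs no extra convention). The neck angle P-NA is the signed
sagittal angle between the spine line (mid-hip → mid-shoulder) and the
neck line (mid-shoulder → head top), positive when the head end leans
anterior. Two deliberately exposed conventions:

* **P-HF reference** — the head frontal offset is measured from the
  shoulder midpoint by default, with a `frontal_reference="feet"`
  switch; both are defensible definitions of "frontal deviation" and
  instruments disagree on which they use.
* **P-HS (height loss)** — estimated standing height is the mean
  vertical head-top marker position plus a configurable `head_top_offset`
  (default 0, i.e. the marker is taken to sit at the vertex), minus the
  self-reported height. Self-report error therefore flows into this
  endpoint by design; it measures the discrepancy, not true stature.

Sway area is the area of the convex hull of the 2-D CoP point cloud,
computed by Andrew's monotone chain followed by the shoelace formula;
collinear or otherwise degenerate clouds have area 0 rather than raising.
Sway "maximal" velocity is the 95th percentile (linear-interpolation
quantile between order statistics — the definition matters at small n
and is therefore fixed and documented) of per-axis speeds
v_i = |s_{i+1} − s_i|·f. The percentile is applied to both devices by
default with `percentile=100` available for a raw maximum, since the
outlier-robust maximum is only documented for force-plate pipelines and
consumer systems may use the raw extreme. Axes are differenced
separately; no resultant-path speed is computed.

A perfectly constant CoP trace is treated as a legitimate record of
perfect stillness (all three sway endpoints 0), not as an error: a
subject can in principle be still at sensor resolution, and the
degenerate-input path must not masquerade as missing data.

## Filtering, windows, trial selection

Butterworth low-pass, cut-off 7 Hz, order 4, zero-phase
(forward–backward with reflective padding) — order and phase are
conventions of the package (standard biomechanics practice), exposed in
`FilterSpec`, since only the cut-off is dictated by the protocol.
Single-pass order-4 magnitude at the cut-off is 1/√2; the zero-phase
double pass squares this to 1/2 — both are pinned by tests. The
single-leg analysis window starts at the frame where the swinging
ankle's anterior displacement peaks (earliest frame on exact ties — the
deterministic tie-break), lasts `round(hold·f)` frames for a hold of
3–5 s, and a trial with under 3 s of data after the peak is a
missing-trial outcome, not a crash. Panel assembly prefers trial 3, then
2, then 1 per task (later trials exclude learning effects); a task with
no usable trial leaves its endpoints explicitly missing with the reason
recorded.

## Synthetic generative model

The generator's defaults *are* the study conditions: a test-retest arm
of n = 37, a device-agreement arm of n = 30, and a clinical arm of 20
patients vs 17 controls, at 30 Hz (consumer device) and 100 Hz
(laboratory reference).

**Endpoint level.** Each endpoint y for subject i, occasion o is

    y_io = μ + b_i + w_io,   b_i ~ N(0, σ²_b),  w_io ~ N(0, σ²_w),

with independent within-occasion noise on *both* occasions, so the true
test-retest ICC is exactly σ²_b/(σ²_b+σ²_w). Per-endpoint defaults (μ,
σ_b, σ_w) encode a healthy working-age cohort measured with a consumer
system: means at typical cohort medians, total SD = IQR/1.349 (the
normal-equivalent), split by the reliability such systems exhibit —
high for side-bend depth (≈0.9), low (≈0.05–0.23) for the 3–5 s balance
endpoints, whose short sampling duration leaves most variance within
subject. Nominally negative reliabilities are floored at 0.05, since a
variance ratio cannot be negative. A Student-t option
(`heavy_tailed_df`, variance-matched) acknowledges that real screening
endpoints are visibly non-Gaussian; the Gaussian default is a modelling
choice, not an inference.

The low-fidelity device adds a per-endpoint bias and N(0, σ²_device)
noise; the reference device reads `ref_scale·latent + ref_offset`
(defaults: ×5 on maximal sway velocities — force plates at high sampling
rates register several-fold higher CoP speeds than a 30 Hz contour-based
system — and +6 %height on side-bend depth). In the agreement design
both devices observe the *same* occasion draw, so only the measurement
models differ. Default device noise is zero so that the reliability
arm's variance bookkeeping stays exact; validity configurations set it
explicitly.

**Trace level.** Marker positions come from a static pose built from
standard anthropometric proportions of standing height, with the planted
posture traits inserted exactly (the shoulder anterior offset is solved
so a planted neck angle coexists with a planted head offset — these two
endpoints share geometry). CoP sway is a per-axis stationary
Ornstein-Uhlenbeck process (exact discretisation), the simplest
stationary process with separately tunable amplitude (stationary SD:
0.30/0.20 cm AP/ML in double stance, 0.80/0.70 cm in single-leg stance)
and temporal structure (time constant 1 s) — magnitudes typical of quiet
posturography. Single-leg trials raise the swinging ankle to a unique
anterior maximum at t* = 2 s (smoothstep rise, slight settle-back, then
hold), planting the window start by construction; side-bend trials dip
each fingertip to exactly the subject's capacity × height. Marker noise
is isotropic Gaussian per frame, uncorrelated — sufficient to exercise
filters and metrics, with no soft-tissue-artifact structure. In the
trace-level agreement design the consumer recording is literally the
reference recording subsampled to 30 Hz plus noise and the additively
expressible biases.

Determinism: every draw keys on `(master_seed, subject, occasion,
device, task, trial)`, so any dataset is a pure function of its config.

## Estimators

* **ICC(3,1)** — two-way mixed-effects, single-measure, consistency:
  (MS_subjects − MS_error)/(MS_subjects + MS_error), occasion treated as
  fixed; negative estimates preserved. CI by the F-method
  (F = MS_subjects/MS_error, df (n−1), (n−1)); the CI method is a package
  choice where reports leave it unstated. Cross-checked in tests against
  an independent variance-components route and against pingouin's
  ICC(C,1) to 1e-10.
* **SEM** — SD·√(1−ICC) with SD the root mean of the two occasion
  variances. This pooling is chosen because it makes SEM a consistent
  estimator of the within-subject SD (verified by simulation); pooling
  with √MS_error instead would double-count the reliability correction.
  The alternative `2·SD·ICC` form that some reports print is available
  behind `formula="footnote"` for comparison; it is not standard and is
  not the default.
* **MDC** — 1.96·√2·SEM, the 95% threshold for a real individual change
  under test-retest error on both measurements. The ratio MDC/SEM ≡
  2.772 is pinned by tests, and the worked (SEM, MDC) pairs in the
  acceptance suite reproduce published 3-decimal values to ±0.002.
* **Rank tests** — Wilcoxon signed-rank (zero differences dropped; exact
  null for n ≤ 25 without tied absolute differences, tie-corrected
  normal approximation with continuity correction otherwise) and
  Mann-Whitney U (exact when min(n) ≤ 8 without cross-group ties).
  Both are checked against exhaustive-enumeration oracles at small n.
* **Spearman** — average ranks on ties, t-approximation p-value.
* **Bland-Altman** — bias = mean(A−B), limits bias ± 1.96·sample SD,
  proportional bias as the OLS slope of differences on pair means.
* **Bands** — ICC: ≤0.20 poor, ≤0.40 fair, ≤0.60 moderate, ≤0.80 good,
  ≤1 very good; |ρ|: ≤0.3 negligible, ≤0.5 low, ≤0.7 moderate, ≤0.9
  high, ≤1 very high. Intervals are upper-closed and the conventional
  printed gaps (e.g. 0.20–0.21) are assigned to the higher band;
  negative ICCs are poor.
* **Normality report** — Lilliefors-corrected Kolmogorov-Smirnov (the
  estimated-parameters variant that statistics packages label "KS") plus
  Shapiro-Wilk; advisory only, the pipeline is nonparametric throughout.
* **Missing data** — pairwise deletion per endpoint with exclusion
  counts in every report. No multiplicity correction across the 18
  endpoints; the comparison count is reported instead so a reader can
  apply their own.

## Monte-Carlo problem sizes

Recovery tests use sizes chosen so the sampling SD of the estimate is
small against the assertion band: ICC recovery at n = 200 with 20
replicates (SE of the mean estimate ≤ ~0.02 at all true values, asserted
within 0.03); the qualitative band-pattern run at n = 500 (SD of a
single ICC estimate ~0.06 at true 0.1, so "poor" vs "very good" labels
are stable); planted-bias recovery over 50 seeded runs of the n = 30
agreement design with device noise 0.3 %height (SE of the bias ≈ 0.055,
asserted within 0.2). The analysis drivers run the designs at their
default cohort sizes (37 / 30 / 20+17).

## What passing tests do and do not show

The synthetic cohorts have Gaussian (optionally t) components, no
learning or fatigue effects across trials beyond the trial-selection
rule's premise, isotropic marker noise, stationary sway, and exact
anthropometric rigidity. Passing the suite demonstrates that the
*computations* are correct and that the *statistical battery recovers
planted truth* under the stated designs — not that any physical device
has these psychometric properties, and not that real sway is OU or real
endpoints Gaussian. C3D input is out of scope; the long-format CSV
schema (with a marker-alias table for foreign label sets) is the
interchange format. Inverse dynamics, segment-inertia body centre-of-mass
estimation, and squat movement-control metrics are out of scope.
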