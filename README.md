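# posturometry

Quantitative screening of standing posture, balance and side-bending —
and, more importantly, a complete psychometric evaluation pipeline for
such screening instruments — exercised end-to-end on synthetic motion
data with known ground truth.

Consumer depth-camera systems promise cheap, objective alternatives to
visual clinical examination: from a short protocol (quiet double-leg
stance, 3–5 s single-leg stances, maximal side-bends) they report scalar
endpoints such as head and pelvic alignment, centre-of-pressure (CoP)
sway, and side-bending depth. Whether those endpoints are *usable*
clinically is a psychometric question: are they repeatable across
occasions (test-retest reliability), do they agree with a laboratory
motion-capture/force-plate reference (construct validity), and can they
separate patients from controls (discriminative validity)? This package
implements both halves of that question for a panel of 18 endpoints: the
kinematic computation of the endpoints from marker trajectories and CoP
traces, and the statistical battery applied to them.

It is written for biomechanists and clinical-measurement researchers who
want a tested, reproducible reference implementation of this pipeline —
either to analyse their own marker/CoP recordings (long-format CSV) or
to study the statistical behaviour of the battery on simulated cohorts.

## What is computed

**Endpoints** (per subject-session; cm, deg, cm², cm/s, % units):

* *Posture* — head lateral/frontal offsets (P-HL, P-HF), cervicothoracic
  neck angle (P-NA), pelvic offset (P-PP), height loss (P-HS), weight
  distribution in % left leg (P-WB);
* *Balance* — for double stance and single-leg stance left/right: sway
  area SA as the convex-hull area of the CoP point cloud (monotone-chain
  hull + shoelace formula), and maximal sway velocity per axis as the
  95th percentile of |Δs|·f (outlier-robust maximum);
* *Side-bending* — minimal fingertip height as % body height per side
  (SB-LF, SB-RF; lower = deeper bend), and the maximal leftward weight
  shift SB-%BW.

Signals are low-pass filtered (Butterworth, 7 Hz cut-off, order 4,
zero-phase by default); the single-leg analysis window starts at the
anterior-posterior maximum of the swinging ankle and lasts 3–5 s (90–150
frames at 30 Hz); per task the third trial is used, falling back to the
second, then the first.

**Statistics** (per endpoint):

* reliability — Wilcoxon signed-rank for systematic occasion differences;
  ICC(3,1) = (MS_subjects − MS_error) / (MS_subjects + MS_error) from the
  two-way mixed-effects model, with an F-based 95% CI;
  SEM = SD·√(1 − ICC); MDC = 1.96·√2·SEM ≈ 2.772·SEM;
* agreement — Spearman ρ, ICC, Bland-Altman fixed bias mean(A−B) with
  1.96·SD limits and proportional bias (OLS slope of difference on mean);
* discrimination — Mann-Whitney U with group medians and IQRs;
* conventional qualitative bands for ICC (poor … very_good) and ρ
  (negligible … very_high), and an advisory normality report.

The synthetic-data module generates all three study designs at two
granularities: direct endpoint-level draws from a variance-components
model (exact control of the true ICC = σ²_between/(σ²_between+σ²_within))
and full trace-level recordings (15 named markers + CoP, Ornstein-
Uhlenbeck sway, planted window starts and bend depths) that exercise the
whole kinematic chain.

## Worked example

Run the three study designs (thin drivers under `analysis/`, tables
under `results/`):

```bash
python analysis/01_simulate_cohort.py     # trace-level cohort -> scratch/raw/
python analysis/02_extract_panels.py      # raw recordings -> results/panels.csv
python analysis/03_reliability_study.py   # test-retest study, n = 37
python analysis/04_validity_study.py      # device agreement, n = 30
python analysis/05_clinical_study.py      # patients 20 vs controls 17
```

`03_reliability_study.py` prints (abridged):

```
variable  n  p_systematic    icc   icc_band   sem    mdc
    P-HL 37         0.216 -0.056       poor 1.716  4.756
   DS-SA 37         0.845  0.024       poor 0.066  0.183
SSL-SVAP 37         0.928 -0.182       poor 0.606  1.680
   SB-LF 37         0.373  0.912  very_good 0.706  1.956
  SB-%BW 37         0.083  0.702       good 6.344 17.585

side-bend left: very_good; balance endpoints poor/fair: 7/9
```

Reading the rows: left side-bend depth is highly repeatable (ICC 0.91,
"very good") with a minimal detectable change of ~2 % body height — an
individual's change smaller than that is indistinguishable from
measurement error. The short-trial balance endpoints have ICCs near
zero: almost all their variance is within-subject, so they cannot
monitor individuals. The validity driver shows the planted device
contrast (reference ≈ 6 %height deeper side-bends, ~4–6× higher maximal
sway velocities, rank order preserved), and the clinical driver
separates the groups on side-bending only.

The same workflows are available as a CLI
(`posturometry simulate|extract|reliability|validity|clinical`, see
`posturometry --help`); every report echoes its config and seed and is
written as CSV + JSON against a shipped JSON schema.

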