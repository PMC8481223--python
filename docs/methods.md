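# Methods

This note documents the statistical content of `ctdemog`: the models and
estimators, the parameters that matter, the choices made where several
defensible designs exist, and what the synthetic-data tests do and do not
demonstrate.

## Detection events and relative indices

Photo records are segmented per camera by a rolling independence gap:
a record opens a new event iff it falls **at least** `gap` (default
60 min) after the *previous record*, not after the event's first record.
The rolling rule matches the field convention of measuring independence
from the last image sequence; it makes event counts monotone
non-increasing in the gap, a property the tests assert.

Per-event composition is a *minimum group size*: for each age-sex
category, the larger of (a) the maximum simultaneous count of the
category on a single image and (b) the number of distinct identified
individuals of the category across the event.  No correction for animals
outside the camera's field of view is applied; all downstream group-size
statistics inherit this undercount.

Trapping rate is 100 × events / operational camera-days, with camera-days
counted only over calendar days on which at least a configurable fraction
(default 0.75) of deployed cameras were working.  Naive occupancy is the
share of camera sites with ≥ 1 detection; no detectability correction is
attempted (a deliberate non-goal — single-season occupancy modelling would
need more detections than such surveys yield).

Timestamps are naive local time with midnight day boundaries, and
deployment intervals are half-open `[start, end)` dates.  Coordinates are
planar projected metres; no geodesy.

## Circular statistics

Clock times map to angles by 2π·(seconds since midnight)/86400.  The
summary is the standard first-order one: mean direction μ = atan2(𝑠̄, 𝑐̄),
resultant length R, circular SD √(−2 ln R) (undefined at R = 0, signalled
explicitly rather than fudged), and the circular median restricted to
sample points with ties broken toward the smallest angle.

The Rayleigh test uses Z = nR² with the series approximation

p ≈ e^(−Z) [1 + (2Z − Z²)/(4n) − (24Z − 132Z² + 76Z³ − 9Z⁴)/(288n²)],

clamped to (0, 1].  The series is accurate for moderate Z but can go
negative for extreme Z at small n, hence the clamp; an exact Monte-Carlo
p-value is available (`exact=True`) and the tests verify agreement within
Monte-Carlo error.  Type-I error at n = 49 is calibrated to 5 % ± 2 % over
2000 simulated uniform samples.

Rao's spacing test uses U = ½ Σ|Tᵢ − 360/n| over sorted arc spacings
(wrap-around included).  Significance comes from a packaged critical-value
table at levels 0.10/0.05/0.01/0.001, computed by large Monte Carlo
(8 × 10⁵ replicates per n ≤ 60) under the uniform null with
`scripts/generate_rao_table.py` — the same construction as the published
tables, which this table reproduces to ~0.1°.  The n grid is dense from 4
to 60 (where camera-trap samples live) and sparse beyond; lookups use the
nearest tabulated n with ties toward the smaller (conservative) n, and
report a bracketing (p_low, p_high) rather than a point p.  Note that at
n = 49 the 10 % critical value is ≈ 147.2, so a statistic of exactly 147
classifies as P > 0.10 — a statistic printed rounded to three figures can
therefore straddle the bracket boundary.

Event *start* times enter the circular sample (the choice is immaterial
for bursts a few seconds long, but it is fixed and documented).

## Vital rates from cross-sectional tallies

With eleven categories (ADM, ADF, ADU, 2YM/F/U, 1YM/F/U, JUV, UNK), the
estimators assume a stationary age distribution and equal detectability of
all classes:

* juvenile mortality M_anJUV = (N_JUV − N_1Y)/N_JUV, where N_1Y pools
  sexed **and** unsexed yearlings (the pooled definition is required for
  internal consistency of the juvenile cohort, which is itself unsexed);
  clamped at 0 with a warning when sampling noise yields more yearlings
  than juveniles;
* adult mortality M_anADF = N_SUBF (1 − M_anJUV)/N_ADF and the male
  analogue, where N_SUBF/N_SUBM are **sexed** sub-adults only, because the
  equations condition on sex.  Published adult-survival percentages that
  relied on an unstated allocation of unsexed sub-adults are consequently
  not reproducible from the tallies, and the package asserts the exact
  equation output instead;
* breeding rate = N_JUV / ADF_adj, with
  ADF_adj = N_ADF + N_ADU·N_ADF/(N_ADM + N_ADF) allocating unsexed adults
  by the sexed adult ratio.

Rounding (half-up, at the printed precision) happens only in reporting;
internals keep full precision.  Herd typing uses sexed non-juvenile
members (MIX / UNI-M / UNI-F), with single animals SOLITARY and sexless
multi-animal herds UNSEXED.  Group-size statistics accept an explicit
exclusion list because the published n = 48 selection of events is not
otherwise derivable.

## Scenario life tables

The class ladder is JUV (0–1), 1Y, 2Y, AD (absorbing, constant annual
survival).  Scenario 'JUV+1Y' anchors observed JUV and 1Y and models
2Y = n_1Y(1 − q_1Y); 'JUV+2Y' anchors JUV and 2Y and interpolates
1Y = n_JUV(1 − q_JUV).  Annual recruits into adulthood are
n_2Y(1 − q_2Y).  The closure is a stationary balance
N_AD = recruits/(1 − s): with the reference adult survival it yields the
expected adult stock; inverted against the observed adult count it yields
implied adult survival s = 1 − recruits/N_AD (clamped to [0, 1)).  The
closure is this package's interpretation — the original supplementary
algebra is not published — and is validated against individual-based
stationary simulations (within 1 % at large cohort sizes).

Unsexed animals are split between the sex-specific tables proportionally
to sexed counts (default), evenly, or excluded; juveniles, never sexed in
the field, are always split evenly.  The packaged reference schedule is
**illustrative and synthetic** (plausible values for an unpredated large
antelope: q_JUV 0.35, sub-adult 0.05–0.12, adult 0.08–0.12); real
reference schedules load from CSV (`age_class,sex,qx`).

## SECR

Null-model (constant g0, σ) spatially explicit capture-recapture for
binary proximity detectors.  Home-range centres follow a 2-D Poisson
process; detection of an individual centred at X by detector k on an
occasion is Bernoulli with probability g(‖X − x_k‖) for half-normal,
exponential or hazard-rate g (hazard-rate shape constrained z > 1 via a
log(z − 1) link so g stays finite at 0).  The likelihood is conditional on
the n observed individuals, integrating centres over a discrete habitat
mask; density is the derived estimator D̂ = n/a(θ̂) with effective sampling
area a(θ) = Σ_X p·(X) w.  Variance combines Poisson variation in n with
parameter uncertainty by the delta method,
Var(D̂)/D̂² = 1/n + (∇a/a)ᵀ V (∇a/a), and intervals are lognormal.
Abundance is N̂ = D̂ × mask area ("volume under the density surface" for a
flat surface).

Numerics: optimisation on link scales (logit g0, log σ, log(z − 1)) with
Nelder-Mead polishing into BFGS; covariance from the inverse numerical
Hessian (singular Hessians reported as missing SEs, not guessed);
likelihood evaluated in log space with per-detector detection counts, so
cost is O(n·K + K·M) per evaluation rather than O(n·S·K·M).  Masks are
square grids clipped to a buffer around the detectors; the default buffer
is 4σ̂ from a pilot half-normal fit (capped at 1.5× the array span so a
weakly identified pilot σ̂ cannot blow the mask up) and default spacing
buffer/32.  The tests assert D̂ changes by < 2 % between 4σ̂ and 8σ̂
buffers, exact agreement (1e−10) with brute-force enumeration of the
likelihood on small instances, and translation/rotation invariance of D̂.

AICc uses the number of individuals as the sample size (the convention of
the standard SECR software); model weights are Akaike weights over fits to
identical data.  Occasions a detector was down contribute through the
usage matrix only.  Repeat same-day detections at one detector collapse to
a single binary cell; same-day detections at *different* detectors are
retained (proximity detectors permit them) with a log note, since the
motivating dataset happened to contain none.

## Synthetic data

The generator has two layers sharing one seeded configuration.

The **individual layer** draws centres Poisson(D × area) uniform over a
rectangular region (defaults: 40 × 40 km, D = 0.138/km², a 7 × 7 detector
grid at 2315 m spacing, 50 daily occasions, half-normal g0 = 0.08,
σ = 2000 m) and Bernoulli detections — exactly the process the SECR
likelihood assumes.  By default an individual detected at several
detectors on one occasion keeps only the detection nearest its centre,
mirroring the one-per-occasion structure of the observed data; the
estimator-calibration tests disable this collapse so the fitted model is
exactly the generating model, while the end-to-end test keeps it and
checks interval coverage is robust to it.

The **event layer** places events at detector-days (Poisson rate
0.02/detector-day), draws herd sizes from a zero-truncated negative
binomial with mean 7.58 and SD 8.90 (overdispersion rules out Poisson;
k = μ²/(σ² − μ) ≈ 0.80), compositions multinomial with the normalised
2018 survey proportions, clock times from a three-component von Mises
mixture (peaks 09:30/16:30/23:30, κ = 2/3/1.5, weights 0.30/0.45/0.25,
echoing the observed trimodal activity), three images per trigger, and
category-dependent identification success (adults ≈ 0.40 down to
juveniles 0.05).  Identities are drawn from spatially local pools (blocks
≈ 2σ across) so recaptures concentrate at the same or adjacent cameras.
Juvenile annotations are suppressed during the Nov–Dec birth-pulse window
itself, concentrating calf records in the following dry season.

What passing recovery tests show: the pipeline arithmetic is faithful to
its own definitions, the SECR estimator is calibrated under its model, and
the descriptive statistics recover the generator's parameters at survey
scale.  What they do not show: robustness to the things real surveys add —
non-independent herd movement (group detections are spatially clustered in
ways the individual-layer Bernoulli model ignores), misidentification,
heterogeneous g0 across animals or cameras, and transient (non-closed)
populations.

## Problem sizes

Test and acceptance simulations run at survey scale (≈ 50–250 animals,
49 detectors, 40–160 occasions, masks of ≈ 800–6000 points; 20 seeded
replicates for calibration claims), which keeps the full suite to a few
minutes on one CPU while leaving the per-replicate sampling error well
below the tolerances asserted.
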