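# Methods

`servechain` implements a complete, testable analysis chain for IMU-based
tennis-serve kinematics: a synthetic-cohort generator with known ground
truth, a gyroscope signal pipeline, zone-based accuracy scoring, and the
clustered statistics used to relate kinematics to serve performance. This
note records the models, the defaults and why they were chosen, and the
limits of what the simulations demonstrate.

## The measurement model

A serve window is a 1.5 s, 1,000 Hz recording of triaxial angular velocity
(deg/s) from three body-worn gyroscopes: pelvis, trunk and dominant upper
arm, in proximal-to-distal order. The analysis quantities are:

* **Peak angular velocity** ω per segment: the maximum of the Euclidean
  norm of the low-pass-filtered triaxial signal.
* **Intersegmental timing**: the signed interval between peak times of
  adjacent segments, distal minus proximal —
  `dt_pelvis_trunk = t_trunk − t_pelvis`, `dt_trunk_upper_arm = t_arm − t_trunk`.
  Positive values mean the distal segment peaks later, as a
  proximal-to-distal kinetic chain predicts.

Filtering uses a second-order Butterworth low-pass, 12 Hz for pelvis and
trunk and 50 Hz for the faster upper arm, applied **zero-phase**
(forward-backward). Whether published analyses of this kind filter causally
or zero-phase is usually unstated; we default to zero-phase because a causal
pass delays peaks by several milliseconds and would bias every timing
estimate, while zero-phase filtering moves the peak of a symmetric pulse by
at most one sample (verified numerically). A causal mode remains available
(`zero_phase=False` / `--causal`) for sensitivity checks. Edge transients
are controlled by odd-reflection padding of `3·fs/cutoff` samples. Peaks are
global maxima over the window with ties resolved to the earliest sample; no
prominence criterion is applied because the window is a single serve.

## The synthetic generator

The generator emulates an eight-player professional cohort, 24 first + 24
second serves each, hit in first/second pairs at called targets (T, body,
wide) alternating deuce/ad sides, with the same call sequence for every
player. All defaults are calibrated to published group statistics for
professional players (`servechain.calibration`).

**Variance partition.** Published tables report between-player SDs only. We
treat each printed SD as the total scale and split its square by
`rho_between` (default 0.5): player-level offsets carry
`rho_between · SD²`, serve-to-serve scatter the rest. Player offsets are
shared standard-normal deviates scaled per serve type, so a player fast on
first serves is fast on second serves too. This partition induces the
exchangeable within-player correlation the GEE assumes; the 0.5 default is
an assumption, not a published value, and is a configuration knob.

**Kinematic truth.** Peaks and the two timings are drawn from normal laws
centred on population mean + player offset. The trunk peak is anchored at
700 ms; pelvis and arm peak times follow by inverting the timing
definitions, so both intervals are controlled independently. Times are
snapped to the 1 ms grid (zero-mean rounding, ≤ 0.5 ms) so the timing
identities hold exactly on-grid. Non-positive peak draws are redrawn and
logged; at the calibrated scale (means ~10 SDs above zero) this never
triggers in practice.

**Traces.** Each segment's norm profile is a Gaussian pulse: amplitude =
true peak, centre = true peak time, width σ = 50 ms (pelvis, trunk) or
20 ms (arm — distal events are faster, consistent with the higher filter
cutoff). The pulse is phenomenological: real serves have multi-phase
profiles, but a smooth symmetric unimodal pulse is what peak-location
estimators are entitled to assume, and it makes filter-induced bias
analysable. The pulse is projected onto the three axes by a fixed per-serve
unit direction with one dominant axis (perpendicular components ~25% of the
dominant one on average), reflecting that segmental rotation in a serve is
concentrated about one anatomical axis. White Gaussian noise (default SD
5 deg/s per axis, a conservative figure for MEMS gyros at this bandwidth)
is added per axis; samples beyond the sensor range (±4,000 deg/s proximal,
±20,000 deg/s arm) are clamped and flagged, and a segment with > 5% flagged
samples is marked saturated downstream.

Zero-phase filtering attenuates a σ = 50 ms Gaussian pulse at 12 Hz by
about 1.5% (the arm's σ = 20 ms pulse at 50 Hz by < 0.2%), so
pipeline-extracted pelvis/trunk peak means sit ~1–1.5% below the configured
truth. We do not compensate: the published peaks are themselves post-filter
quantities.

**Outcomes.** Ball speed (kph) and accuracy (points) follow
single-predictor linear models `b0 + b1·x + u_player + ε`, with the trunk
peak as the default predictor for both, per the published trunk-row
coefficients. Speed noise defaults (player SD 6.0, residual SD 6.0 kph)
were chosen once so that slope-carried variance plus noise reproduces the
published speed spread under `rho_between = 0.5`. Accuracy keeps the
published slopes (±0.002 points per deg/s) but re-centres the intercept so
the simulated mean accuracy matches the published group means (2.8 first /
4.4 second); the published accuracy intercepts describe fits to a real
predictor distribution that differs from the simulator's. Continuous
accuracy is snapped to the nearest admissible score {0, 1, 3, 6, 9}, and a
bounce coordinate is then rejection-sampled from a zone with exactly that
value, so scoring round-trips exactly. A configurable fraction of serves
(default 11%, matching the reference protocol's camera dropout) has ball
speed marked missing.

**What the generator does not emulate.** Segment peaks are drawn
independently across segments, so only the configured predictor shows an
association with outcomes in full-cohort fits — there is no cross-segment
kinetic-chain correlation, no ball-flight or racket model, no lets, no
skill drift within a session, and pulses are single-peaked. Passing
round-trip tests therefore demonstrates correctness of the *pipeline and
estimators* under known truth, not biomechanical realism.

## Accuracy scoring

Bounces live in a side-local frame: origin at the "T" of the correct
service box, x toward the net along the centre service line, y toward the
singles sideline (box 6.40 m × 4.115 m). A bounce outside the box scores 0;
inside, it takes the value of the containing region, or 1 where no region
is configured (coach-defined schemes tile the box; the lowest positive
score is the natural default for unspecified area). Lines count as in, and
shared boundaries belong to the higher-valued region so ties are
deterministic. The shipped geometry (`data/default_zones.json`) is
**synthetic**: rectangular 9/6/3 regions near each aiming target, with
second-serve regions shifted 0.5 m toward the net. Real target-area
definitions vary by coaching staff and should be supplied as a config; all
validation (closed point scale, regions inside the box, pairwise
non-overlap) applies to user geometry too.

## Statistics

**Paired t-tests.** Each player's serves are averaged per serve type; the
per-player mean pairs give `t = mean(d)/(SD(d)/√n)`, df = n−1, two-sided p.
Group descriptives report the mean and the SD of per-player means
(between-player SD), plus each player's serve-in percentage.

**Exchangeable GEE.** Outcomes are regressed on one predictor at a time,
separately per serve type, with identity link, Gaussian variance, and an
exchangeable working correlation over serves within a player. The solver
alternates (i) the weighted-least-squares coefficient update under
R(α) with (ii) moment estimation of the scale φ (Pearson residuals, N−p
denominator) and of α (within-cluster residual cross-products over
Σ nᵢ(nᵢ−1)/2 − p), until coefficients change by < 1e-8 (≤ 500 iterations;
small datasets converge linearly and can need a few hundred). These
conventions exactly match the widely used reference implementation, and an
equivalence test holds to ≤ 1e-6 relative error. With singleton clusters or
α = 0 the estimator reduces to OLS. The exchangeable inverse is applied in
closed form (Sherman–Morrison), so no per-cluster matrix is ever inverted.

Inference uses the robust sandwich covariance `B⁻¹MB⁻¹`; the 95% CI is
`b1 ± z₀.₉₇₅·SE` and the p-value a 1-df Wald chi-square. The plain sandwich
is anticonservative with few clusters: at 8 players our simulations measure
87–93% coverage of a nominal 95% CI. A Mancl–DeRouen bias-corrected mode
(per-cluster residuals inflated by `(I − Hᵢ)⁻¹`) is available behind
`bias_corrected=True` / `--bias-corrected` and restores coverage to 91–96%
in the same simulations; reported coefficient tables default to the plain
sandwich, while the simulation-calibration tests (CI coverage, type-I
error) use the corrected mode. Accuracy is treated as a continuous outcome
in these models despite its discrete support, matching how such coefficient
tables are conventionally produced; residual checks are left to diagnostic
inspection rather than automated gating.

## Numerical and degenerate-input choices

* Units are fixed internally: deg/s, ms, Hz, kph, metres; conversions occur
  only at I/O boundaries.
* Cutoff ≥ Nyquist, traces shorter than the filter padding, empty peak
  windows, missing segments, zero-variance predictors, < 2 clusters, and
  zero-variance paired differences all raise immediate, specific errors.
* All-zero traces summarise to zero peaks at the window start and zero
  timings.
* Non-convergent GEE raises an error carrying the last iterate rather than
  returning silently.
* Every stochastic routine takes a seed or `numpy` Generator; dataset
  generation derives per-serve substreams from a `SeedSequence`, making
  written datasets byte-identical across runs with the same seed.

## Problem sizes used in the shipped studies

The simulation studies run at the cohort scale they emulate — 8 players ×
24 serves per type. Parameter-recovery studies use 200 replicate cohorts
per coefficient row; pipeline round-trip means are averaged over 20 cohort
replicates (3,840 first serves); variance-partition and ICC checks use
1,500–2,000 simulated players. These sizes give Monte-Carlo standard errors
comfortably below the effect scales being checked.
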