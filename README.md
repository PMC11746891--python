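# servechain

Analysis pipeline for IMU-measured tennis-serve kinematics: from raw
triaxial gyroscope traces to peak segmental angular velocities,
intersegmental timing, bounce-accuracy scores, and the clustered statistics
that relate them to serve performance. Because raw recordings of
professional cohorts are rarely shareable, the package ships a calibrated
synthetic-cohort generator with known ground truth, so every stage is
testable end to end.

Intended users: sports-biomechanics researchers and data scientists working
with wearable-sensor serve (or other overhead-stroke) data, and
methodologists studying clustered regression at small cluster counts.

## The quantities and models

For each serve window (1.5 s at 1,000 Hz) and each segment s ∈ {pelvis,
trunk, upper arm}, the triaxial gyroscope signal is low-pass filtered
(second-order Butterworth, zero-phase; 12 Hz proximal, 50 Hz arm) and
reduced to its Euclidean norm. The segment's **peak angular velocity** is

    omega_s = max_t ||g_s(t)||,   t_s = argmax_t ||g_s(t)||,

and the **intersegmental timing** between adjacent segments is the signed
difference of peak times, distal minus proximal:

    dt_{proximal,distal} = t_distal − t_proximal,

positive when the distal segment peaks later (proximal-to-distal
sequencing). Bounce accuracy maps the 2D bounce coordinate to points in
{9, 6, 3, 1} via configurable target zones inside the service box, and 0
outside it.

First-vs-second-serve differences use two-tailed paired t-tests on
per-player means. Kinematics-performance associations use generalized
estimating equations with identity link, exchangeable working correlation
over serves within a player, robust (sandwich) covariance, and 1-df Wald
chi-square inference:

    outcome_ij = b0 + b1 · predictor_ij + e_ij,   corr(e_ij, e_ik) = alpha,

fit separately per serve type and per predictor. The GEE solver is
implemented in this package and verified to 1e-6 against an independent
reference implementation; a Mancl–DeRouen small-sample sandwich correction
is available for few-cluster settings.

## Worked example

Simulate the default cohort (8 players × 24 first + 24 second serves at the
published professional calibration), extract kinematics, and fit the
statistics:

```sh
servechain simulate --seed 7 --out demo
servechain process  --dataset demo
servechain fit      --dataset demo
servechain report   --dataset demo
```

which prints

```
wrote 384 serves (46 with unregistered speed) for 8 players to demo
summarised 384/384 serves (0 saturation flags) -> demo/summary.csv
wrote descriptives, paired t-tests and 20 GEE fits to demo/fits
```

`demo/fits/paired_t.csv` then contains (excerpt):

```
          quantity         t  df            p  mean_diff
    ball_speed_kph 24.650463   7 4.608100e-08  30.866715
       peak_pelvis 11.821187   7 7.031905e-06  45.455495
   dt_pelvis_trunk  0.630276   7 5.485284e-01   1.796875
```

First serves are ~31 kph faster and have higher segment peaks than second
serves (p < 0.001 at 7 degrees of freedom), while the pelvis-trunk timing
does not differ — the same qualitative pattern the generator was calibrated
to. `demo/fits/gee_fits.csv` holds the coefficient table; the first-serve
trunk row

```
       outcome  predictor serve_type   n         b0        b1    ci_low  ci_high            p
ball_speed_kph peak_trunk      first 172 125.051661  0.052820  0.047094 0.058545 4.408900e-73
```

recovers the configured slope of 0.055 kph per deg/s within sampling error:
each 0.053 kph of speed per deg/s of trunk angular velocity means a player
serving 10 kph faster shows ≈ 190 deg/s more trunk rotation speed. (Only
the trunk — the generative predictor — carries an association in simulated
cohorts; segment peaks are drawn independently.) `demo/report/report.md`
collects the tables with per-predictor scatter plots and fitted lines.

The library API mirrors the CLI: `synth.simulate_serves`,
`kinematics.summarize_serve`, `scoring.score_bounce`, `stats.fit_gee`, etc.

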