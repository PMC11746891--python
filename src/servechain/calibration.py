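"""Default population calibration for professional-level serve simulation.

The constants below are group-level descriptive statistics and simple-GEE
regression coefficients published for professional players (an eight-player
indoor protocol of 24 first + 24 second serves each, IMU gyroscopes at
1,000 Hz). They parameterise the synthetic generator so that simulated
cohorts reproduce the magnitudes, timing structure and kinematics-outcome
associations of elite serving:

* peak angular velocities (deg/s): pelvis < trunk < upper arm, first serve
  faster than second;
* intersegmental timing (ms): pelvis-trunk negative on average (the pelvis
  peaks *after* the trunk — no strict proximal-to-distal order proximally),
  trunk-arm strongly positive;
* ball speed (kph) and bounce-accuracy points linked linearly to the trunk
  peak within players.

The published SDs are between-player SDs of per-player means; how total
variance splits between and within players is not published, so the split is
governed by ``rho_between`` (see :mod:`servechain.synth`).
"""

from __future__ import annotations

#: Peak angular velocity of the Euclidean gyroscope norm, deg/s: (mean, SD).
PEAKS_DPS = {
    "first": {"pelvis": (586.8, 58.4), "trunk": (897.2, 152.9), "upper_arm": (3206.6, 807.8)},
    "second": {"pelvis": (541.8, 49.4), "trunk": (846.2, 146.3), "upper_arm": (2719.8, 715.1)},
}

#: Intersegmental timing, ms (distal peak time minus proximal): (mean, SD).
TIMINGS_MS = {
    "first": {"pelvis_trunk": (-28.3, 33.5), "trunk_upper_arm": (124.5, 14.3)},
    "second": {"pelvis_trunk": (-28.9, 27.0), "trunk_upper_arm": (127.3, 13.4)},
}

#: Ball speed, kph: (mean, SD).
BALL_SPEED_KPH = {"first": (175.1, 12.3), "second": (145.7, 12.9)}

#: Mean bounce-accuracy points on the 0/1/3/6/9 scale: (mean, SD).
ACCURACY_POINTS = {"first": (2.8, 0.6), "second": (4.4, 1.1)}

#: Simple-GEE coefficients, ball speed (kph) = b0 + b1 * predictor.
#: Keys: (serve_type, predictor); predictor units deg/s for peaks, ms for timings.
SPEED_GEE = {
    ("first", "peak_pelvis"): (156.2, 0.032),
    ("second", "peak_pelvis"): (136.6, 0.017),
    ("first", "peak_trunk"): (125.4, 0.055),
    ("second", "peak_trunk"): (106.6, 0.046),
    ("first", "peak_upper_arm"): (143.0, 0.010),
    ("second", "peak_upper_arm"): (121.5, 0.009),
    ("first", "dt_pelvis_trunk"): (174.3, -0.028),
    ("second", "dt_pelvis_trunk"): (146.5, 0.030),
    ("first", "dt_trunk_upper_arm"): (157.1, 0.143),
    ("second", "dt_trunk_upper_arm"): (159.5, -0.109),
}

#: Simple-GEE coefficients, accuracy (points) = b0 + b1 * predictor.
ACCURACY_GEE = {
    ("first", "peak_pelvis"): (3.31, 0.003),
    ("second", "peak_pelvis"): (4.43, 0.002),
    ("first", "peak_trunk"): (3.30, 0.002),
    ("second", "peak_trunk"): (7.07, -0.002),
    ("first", "peak_upper_arm"): (6.24, 0.000),
    ("second", "peak_upper_arm"): (6.55, 0.000),
    ("first", "dt_pelvis_trunk"): (5.50, 0.014),
    ("second", "dt_pelvis_trunk"): (5.31, -0.009),
    ("first", "dt_trunk_upper_arm"): (4.12, 0.007),
    ("second", "dt_trunk_upper_arm"): (7.53, -0.015),
}

#: Gyroscope full-scale range, deg/s (proximal sensors vs the fast arm sensor).
SENSOR_RANGE_DPS = {"pelvis": 4000.0, "trunk": 4000.0, "upper_arm": 20000.0}

#: Study shape: players and serves per type per player.
N_PLAYERS = 8
SERVES_PER_TYPE = 24

#: Fraction of serves whose ball speed went unregistered by the court-camera
#: system in the reference protocol (43 of 390).
UNREGISTERED_RATE = 0.11


def predictor_increment(slope: float, delta_outcome: float) -> float:
    """Predictor change associated with a ``delta_outcome`` change.

    Inverts a simple linear coefficient: e.g. with a trunk-peak slope of
    0.055 kph per deg/s, a 10 kph speed gain corresponds to
    ``10 / 0.055 ≈ 181.8`` deg/s of extra trunk angular velocity.
    """
    if slope == 0:
        raise ZeroDivisionError("slope is zero; the increment is undefined")
    return delta_outcome / slope
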