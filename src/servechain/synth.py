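"""Synthetic serve datasets with the statistical structure the analysis assumes.

One simulated cohort mimics the reference protocol: ``n_players`` athletes
each hit serves in first/second pairs at called targets (T, body, wide,
alternating deuce/ad sides). Per serve the generator draws

* ground-truth kinematics — peak angular velocity per segment and the two
  intersegmental timings — from normal laws whose means are shifted by
  player-level offsets (fraction ``rho_between`` of the total variance is
  between players, which induces the exchangeable within-player correlation
  the downstream GEE assumes);
* three triaxial gyroscope traces whose Euclidean norm is a smooth Gaussian
  pulse with exactly the true peak amplitude and peak time, spread over the
  three axes by a fixed per-serve rotation-axis direction, plus white
  measurement noise and sensor-range clipping;
* outcomes (ball speed, accuracy points) from single-predictor linear models
  with a player-level intercept, so kinematics-outcome associations and the
  within-player correlation are both controlled;
* a bounce location consistent with the accuracy score under the active
  zone configuration.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import calibration
from .kinematics import SEGMENTS, GyroTrace, write_trace_csv
from .scoring import ZoneConfig, default_zone_config, load_zone_config, sample_bounce_for_score

__all__ = [
    "SERVE_TYPES",
    "ACCURACY_SCALE",
    "ServeTypeLaws",
    "PopulationParams",
    "PlayerProfile",
    "KinematicTruth",
    "OutcomeModel",
    "GenerationConfig",
    "SimulatedDataset",
    "default_population_params",
    "default_outcome_models",
    "sample_players",
    "draw_serve_truth",
    "synthesize_traces",
    "generate_outcomes",
    "discretize_accuracy",
    "simulate_serves",
    "simulate_regression_dataset",
    "generate_dataset",
    "load_generation_config",
]

logger = logging.getLogger(__name__)

SERVE_TYPES = ("first", "second")
TIMING_KEYS = ("pelvis_trunk", "trunk_upper_arm")
ACCURACY_SCALE = (0, 1, 3, 6, 9)

_MAX_REDRAWS = 1000


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Population parameters


@dataclass(frozen=True)
class ServeTypeLaws:
    """Normal laws for one serve type: ``{quantity: (mean, sd)}``."""

    peaks_dps: Mapping[str, tuple[float, float]]
    timings_ms: Mapping[str, tuple[float, float]]
    ball_speed_kph: tuple[float, float]
    accuracy_points: tuple[float, float]

    def __post_init__(self) -> None:
        for seg in SEGMENTS:
            if seg not in self.peaks_dps:
                raise ValueError(f"peak law missing for segment {seg!r}")
        for key in TIMING_KEYS:
            if key not in self.timings_ms:
                raise ValueError(f"timing law missing for {key!r}")
        for name, (_, sd) in {**dict(self.peaks_dps), **dict(self.timings_ms),
                              "ball_speed": self.ball_speed_kph,
                              "accuracy": self.accuracy_points}.items():
            if sd <= 0:
                raise ValueError(f"SD for {name!r} must be > 0, got {sd}")


@dataclass(frozen=True)
class PopulationParams:
    """Full generator calibration.

    ``rho_between`` splits each quantity's total variance into a
    between-player share (player offsets) and a within-player share
    (serve-to-serve scatter); published SDs are treated as the total scale.
    """

    first: ServeTypeLaws
    second: ServeTypeLaws
    rho_between: float = 0.5
    pulse_sigma_ms: Mapping[str, float] = field(
        default_factory=lambda: {"pelvis": 50.0, "trunk": 50.0, "upper_arm": 20.0})
    noise_sd_dps: float = 5.0
    sensor_range_dps: Mapping[str, float] = field(
        default_factory=lambda: dict(calibration.SENSOR_RANGE_DPS))
    fs_hz: float = 1000.0
    window_ms: float = 1500.0
    trunk_anchor_ms: float = 700.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho_between < 1.0:
            raise ValueError(f"rho_between must lie in [0, 1), got {self.rho_between}")
        if self.noise_sd_dps < 0:
            raise ValueError("noise SD must be non-negative")
        for seg in SEGMENTS:
            if self.pulse_sigma_ms.get(seg, 0) <= 0:
                raise ValueError(f"pulse width for {seg!r} must be positive")
            if self.sensor_range_dps.get(seg, 0) <= 0:
                raise ValueError(f"sensor range for {seg!r} must be positive")
        if self.window_ms < 1500.0:
            raise ValueError("serve window must be at least 1,500 ms")
        if not 0 < self.trunk_anchor_ms < self.window_ms:
            raise ValueError("trunk anchor must lie inside the serve window")

    def laws(self, serve_type: str) -> ServeTypeLaws:
        if serve_type not in SERVE_TYPES:
            raise ValueError(f"unknown serve type {serve_type!r}")
        return self.first if serve_type == "first" else self.second

    def between_sd(self, sd_total: float) -> float:
        return sd_total * np.sqrt(self.rho_between)

    def within_sd(self, sd_total: float) -> float:
        return sd_total * np.sqrt(1.0 - self.rho_between)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for st in SERVE_TYPES:
            laws = d[st]
            laws["peaks_dps"] = {k: list(v) for k, v in laws["peaks_dps"].items()}
            laws["timings_ms"] = {k: list(v) for k, v in laws["timings_ms"].items()}
            laws["ball_speed_kph"] = list(laws["ball_speed_kph"])
            laws["accuracy_points"] = list(laws["accuracy_points"])
        d["pulse_sigma_ms"] = dict(self.pulse_sigma_ms)
        d["sensor_range_dps"] = dict(self.sensor_range_dps)
        return d


def _laws_from_calibration(serve_type: str) -> ServeTypeLaws:
    return ServeTypeLaws(
        peaks_dps=dict(calibration.PEAKS_DPS[serve_type]),
        timings_ms=dict(calibration.TIMINGS_MS[serve_type]),
        ball_speed_kph=calibration.BALL_SPEED_KPH[serve_type],
        accuracy_points=calibration.ACCURACY_POINTS[serve_type],
    )


def default_population_params(**overrides) -> PopulationParams:
    """Population calibrated to published elite-player statistics."""
    return PopulationParams(first=_laws_from_calibration("first"),
                            second=_laws_from_calibration("second"), **overrides)


# ---------------------------------------------------------------------------
# Players


@dataclass(frozen=True)
class PlayerProfile:
    """Player-level standard-normal deviates, shared across serve types.

    A player who is fast on the first serve is fast on the second: the same
    deviate scales by each serve type's between-player SD. ``offset(...)``
    returns the deviation of that player's mean from the population mean.
    """

    player_id: int
    z_peak: Mapping[str, float]
    z_timing: Mapping[str, float]
    z_outcome: Mapping[str, float]  # keys: "ball_speed_kph", "accuracy_points"

    def peak_offset(self, segment: str, serve_type: str, params: PopulationParams) -> float:
        sd = params.laws(serve_type).peaks_dps[segment][1]
        return self.z_peak[segment] * params.between_sd(sd)

    def timing_offset(self, key: str, serve_type: str, params: PopulationParams) -> float:
        sd = params.laws(serve_type).timings_ms[key][1]
        return self.z_timing[key] * params.between_sd(sd)


def sample_players(n_players: int, params: PopulationParams,
                   seed: int | np.random.Generator) -> list[PlayerProfile]:
    """Draw reproducible player profiles with the configured between-player variance."""
    if n_players < 1:
        raise ValueError(f"n_players must be >= 1, got {n_players}")
    rng = _rng(seed)
    players = []
    for pid in range(1, n_players + 1):
        z_peak = {seg: float(rng.standard_normal()) for seg in SEGMENTS}
        z_timing = {key: float(rng.standard_normal()) for key in TIMING_KEYS}
        z_outcome = {"ball_speed_kph": float(rng.standard_normal()),
                     "accuracy_points": float(rng.standard_normal())}
        if params.rho_between == 0.0:
            z_peak = {s: 0.0 for s in z_peak}
            z_timing = {k: 0.0 for k in z_timing}
        players.append(PlayerProfile(pid, z_peak, z_timing, z_outcome))
    return players


# ---------------------------------------------------------------------------
# Per-serve kinematic truth


@dataclass(frozen=True)
class KinematicTruth:
    """Ground truth for one serve; peak times sit exactly on the sample grid."""

    peak_dps: Mapping[str, float]
    peak_time_ms: Mapping[str, float]

    @property
    def timing_pelvis_trunk_ms(self) -> float:
        return self.peak_time_ms["trunk"] - self.peak_time_ms["pelvis"]

    @property
    def timing_trunk_upper_arm_ms(self) -> float:
        return self.peak_time_ms["upper_arm"] - self.peak_time_ms["trunk"]

    def predictor(self, name: str) -> float:
        """Value of a named predictor: ``peak_<segment>`` or ``dt_<interval>``."""
        if name.startswith("peak_"):
            seg = name[len("peak_"):]
            if seg in self.peak_dps:
                return float(self.peak_dps[seg])
        elif name == "dt_pelvis_trunk":
            return float(self.timing_pelvis_trunk_ms)
        elif name == "dt_trunk_upper_arm":
            return float(self.timing_trunk_upper_arm_ms)
        raise ValueError(f"unknown predictor {name!r}")


def draw_serve_truth(profile: PlayerProfile, serve_type: str,
                     params: PopulationParams,
                     seed: int | np.random.Generator) -> KinematicTruth:
    """Draw true peaks and peak times for one serve.

    The trunk peak is anchored at a fixed nominal time inside the window;
    pelvis and arm peak times follow from the drawn intersegmental timings
    (distal minus proximal, inverted). Times are snapped to the 1-sample
    grid so the derived timings are exact on-grid quantities. Non-positive
    peak draws (non-physical) are redrawn and logged.
    """
    rng = _rng(seed)
    laws = params.laws(serve_type)
    dt_sample = 1000.0 / params.fs_hz

    peaks: dict[str, float] = {}
    for seg in SEGMENTS:
        mean, sd = laws.peaks_dps[seg]
        centre = mean + profile.peak_offset(seg, serve_type, params)
        for attempt in range(_MAX_REDRAWS):
            value = rng.normal(centre, params.within_sd(sd))
            if value > 0:
                break
            logger.info("redraw: non-positive %s peak (%.1f deg/s) for player %d",
                        seg, value, profile.player_id)
        else:
            raise RuntimeError(f"could not draw a positive {seg} peak near {centre:.1f} deg/s")
        peaks[seg] = float(value)

    t_trunk = params.trunk_anchor_ms
    for attempt in range(_MAX_REDRAWS):
        dts = {}
        for key in TIMING_KEYS:
            mean, sd = laws.timings_ms[key]
            centre = mean + profile.timing_offset(key, serve_type, params)
            dts[key] = rng.normal(centre, params.within_sd(sd))
        times = {
            "pelvis": t_trunk - dts["pelvis_trunk"],
            "trunk": t_trunk,
            "upper_arm": t_trunk + dts["trunk_upper_arm"],
        }
        times = {seg: round(t / dt_sample) * dt_sample for seg, t in times.items()}
        if all(0.0 < t < params.window_ms - dt_sample for t in times.values()):
            break
        logger.info("redraw: peak time outside window for player %d", profile.player_id)
    else:
        raise RuntimeError("could not place peak times inside the serve window")
    return KinematicTruth(peaks, times)


# ---------------------------------------------------------------------------
# Trace synthesis


def _unit_vector(rng: np.random.Generator, concentration: float = 0.25) -> np.ndarray:
    """Random rotation-axis direction with one dominant gyroscope axis.

    Segmental rotation during a serve is concentrated about one anatomical
    axis (e.g. upper-arm internal rotation), so the dominant axis carries
    most of the signal and perpendicular components are a fraction
    ``concentration`` of it on average.
    """
    axis = rng.integers(3)
    v = concentration * rng.standard_normal(3)
    v[axis] = rng.choice([-1.0, 1.0])
    return v / np.linalg.norm(v)


def synthesize_traces(truth: KinematicTruth, params: PopulationParams,
                      seed: int | np.random.Generator) -> dict[str, GyroTrace]:
    """Render one serve's truth into three noisy triaxial gyroscope traces.

    Per segment the norm profile is a Gaussian pulse (amplitude = true peak,
    centre = true peak time, width ``pulse_sigma_ms``) distributed over the
    axes by a fixed per-serve unit direction; i.i.d. Gaussian noise is added
    per axis and samples beyond the sensor range are clamped and flagged.
    """
    rng = _rng(seed)
    n = int(round(params.window_ms * params.fs_hz / 1000.0))
    t_ms = np.arange(n) * (1000.0 / params.fs_hz)
    traces: dict[str, GyroTrace] = {}
    for seg in SEGMENTS:
        t0 = truth.peak_time_ms[seg]
        if not 0.0 <= t0 <= params.window_ms:
            raise ValueError(f"{seg} pulse centre {t0} ms lies outside the "
                             f"[0, {params.window_ms}] ms window")
        sigma = params.pulse_sigma_ms[seg]
        pulse = truth.peak_dps[seg] * np.exp(-0.5 * ((t_ms - t0) / sigma) ** 2)
        u = _unit_vector(rng)
        w = pulse[:, None] * u[None, :]
        if params.noise_sd_dps > 0:
            w = w + rng.normal(0.0, params.noise_sd_dps, size=(n, 3))
        rng_dps = params.sensor_range_dps[seg]
        clipped = np.abs(w) > rng_dps
        w = np.clip(w, -rng_dps, rng_dps)
        traces[seg] = GyroTrace(seg, params.fs_hz, t_ms, w, clipped.any(axis=1))
    return traces


# ---------------------------------------------------------------------------
# Outcomes


@dataclass(frozen=True)
class OutcomeModel:
    """Single-predictor linear outcome with a player-level random intercept.

    ``outcome = b0 + b1 * predictor + z_player * player_sd + N(0, resid_sd)``;
    in ``"points"`` output mode the continuous accuracy value is snapped to
    the nearest admissible score (0/1/3/6/9).
    """

    outcome: str  # "ball_speed_kph" or "accuracy_points"
    predictor: str  # e.g. "peak_trunk", "dt_pelvis_trunk"
    b0: float
    b1: float
    resid_sd: float
    player_sd: float
    output: str = "continuous"  # or "points"

    def __post_init__(self) -> None:
        if self.resid_sd <= 0:
            raise ValueError("residual SD must be > 0")
        if self.player_sd < 0:
            raise ValueError("player-intercept SD must be >= 0")
        if self.output not in ("continuous", "points"):
            raise ValueError(f"unknown output mode {self.output!r}")


def discretize_accuracy(value: float) -> int:
    """Nearest admissible accuracy score on the 0/1/3/6/9 scale."""
    scale = np.asarray(ACCURACY_SCALE, dtype=float)
    return int(ACCURACY_SCALE[int(np.argmin(np.abs(scale - value)))])


def generate_outcomes(truth: KinematicTruth, profile: PlayerProfile,
                      model: OutcomeModel,
                      seed: int | np.random.Generator) -> float | int:
    """Draw one outcome linked to the serve's true kinematics."""
    rng = _rng(seed)
    x = truth.predictor(model.predictor)  # raises on unknown selector
    z = profile.z_outcome.get(model.outcome, 0.0)
    y = model.b0 + model.b1 * x + z * model.player_sd + rng.normal(0.0, model.resid_sd)
    if model.output == "points":
        return discretize_accuracy(y)
    return float(y)


def default_outcome_models() -> dict[str, dict[str, OutcomeModel]]:
    """Trunk-linked speed and accuracy models per serve type.

    Speed uses the published trunk-row coefficients directly; accuracy keeps
    the published trunk slope but re-centres the intercept so the population
    mean accuracy matches the published group mean (published accuracy
    intercepts describe real-data fits whose predictor distribution differs
    from the simulator's). Noise split: 6.0 kph player / 6.0 kph residual for
    speed, 1.2 / 1.2 points for accuracy.
    """
    models: dict[str, dict[str, OutcomeModel]] = {"ball_speed_kph": {}, "accuracy_points": {}}
    for st in SERVE_TYPES:
        b0, b1 = calibration.SPEED_GEE[(st, "peak_trunk")]
        models["ball_speed_kph"][st] = OutcomeModel(
            "ball_speed_kph", "peak_trunk", b0, b1, resid_sd=6.0, player_sd=6.0)
        slope = calibration.ACCURACY_GEE[(st, "peak_trunk")][1]
        trunk_mean = calibration.PEAKS_DPS[st]["trunk"][0]
        acc_mean = calibration.ACCURACY_POINTS[st][0]
        models["accuracy_points"][st] = OutcomeModel(
            "accuracy_points", "peak_trunk", acc_mean - slope * trunk_mean, slope,
            resid_sd=1.2, player_sd=1.2, output="points")
    return models


# ---------------------------------------------------------------------------
# Whole-dataset generation


@dataclass
class GenerationConfig:
    n_players: int = calibration.N_PLAYERS
    serves_per_type: int = calibration.SERVES_PER_TYPE
    drop_rate: float = calibration.UNREGISTERED_RATE
    population: PopulationParams = field(default_factory=default_population_params)
    outcome_models: dict[str, dict[str, OutcomeModel]] = field(
        default_factory=default_outcome_models)
    zone_config_path: str | None = None  # None -> packaged default

    def __post_init__(self) -> None:
        if self.n_players < 1:
            raise ValueError("n_players must be >= 1")
        if self.serves_per_type < 1:
            raise ValueError("serves_per_type must be >= 1")
        if not 0.0 <= self.drop_rate < 1.0:
            raise ValueError("drop_rate must lie in [0, 1)")

    def zone_config(self) -> ZoneConfig:
        if self.zone_config_path is None:
            return default_zone_config()
        return load_zone_config(self.zone_config_path)

    def to_dict(self) -> dict:
        return {
            "n_players": self.n_players,
            "serves_per_type": self.serves_per_type,
            "drop_rate": self.drop_rate,
            "population": self.population.to_dict(),
            "outcome_models": {
                outcome: {st: dataclasses.asdict(m) for st, m in per_type.items()}
                for outcome, per_type in self.outcome_models.items()},
            "zone_config_path": self.zone_config_path,
        }


_CONFIG_KEYS = {"n_players", "serves_per_type", "drop_rate", "population",
                "outcome_models", "zone_config_path"}
_POP_KEYS = {"rho_between", "pulse_sigma_ms", "noise_sd_dps", "sensor_range_dps",
             "fs_hz", "window_ms", "trunk_anchor_ms", "first", "second"}
_LAW_KEYS = {"peaks_dps", "timings_ms", "ball_speed_kph", "accuracy_points"}


def _laws_from_dict(base: ServeTypeLaws, d: Mapping) -> ServeTypeLaws:
    unknown = set(d) - _LAW_KEYS
    if unknown:
        raise ValueError(f"unknown serve-type law key(s): {sorted(unknown)}")
    peaks = dict(base.peaks_dps)
    peaks.update({k: tuple(v) for k, v in d.get("peaks_dps", {}).items()})
    timings = dict(base.timings_ms)
    timings.update({k: tuple(v) for k, v in d.get("timings_ms", {}).items()})
    return ServeTypeLaws(peaks, timings,
                         tuple(d.get("ball_speed_kph", base.ball_speed_kph)),
                         tuple(d.get("accuracy_points", base.accuracy_points)))


def _population_from_dict(d: Mapping) -> PopulationParams:
    unknown = set(d) - _POP_KEYS
    if unknown:
        raise ValueError(f"unknown population key(s): {sorted(unknown)}")
    base = default_population_params()
    kwargs: dict = {}
    for key in ("rho_between", "noise_sd_dps", "fs_hz", "window_ms", "trunk_anchor_ms"):
        if key in d:
            kwargs[key] = float(d[key])
    for key in ("pulse_sigma_ms", "sensor_range_dps"):
        if key in d:
            merged = dict(getattr(base, key))
            merged.update({k: float(v) for k, v in d[key].items()})
            kwargs[key] = merged
    return PopulationParams(first=_laws_from_dict(base.first, d.get("first", {})),
                            second=_laws_from_dict(base.second, d.get("second", {})),
                            **kwargs)


def load_generation_config(document: Mapping | str | Path) -> GenerationConfig:
    """Build a :class:`GenerationConfig` from a JSON/YAML file or a dict.

    Omitted keys fall back to the published-calibration defaults; unknown
    keys are rejected so typos cannot silently revert to defaults.
    """
    if isinstance(document, (str, Path)):
        text = Path(document).read_text()
        document = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(document, Mapping):
        raise ValueError("generation config must be a mapping")
    unknown = set(document) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown generation-config key(s): {sorted(unknown)}")
    kwargs: dict = {k: document[k] for k in
                    ("n_players", "serves_per_type", "drop_rate", "zone_config_path")
                    if k in document}
    if "population" in document:
        kwargs["population"] = _population_from_dict(document["population"])
    if "outcome_models" in document:
        models = default_outcome_models()
        for outcome, per_type in document["outcome_models"].items():
            if outcome not in models:
                raise ValueError(f"unknown outcome {outcome!r}")
            for st, fields in per_type.items():
                base = dataclasses.asdict(models[outcome][st])
                base.update(fields)
                models[outcome][st] = OutcomeModel(**base)
        kwargs["outcome_models"] = models
    return GenerationConfig(**kwargs)


@dataclass
class SimulatedDataset:
    """In-memory cohort: manifest, ground truth and (optionally) raw traces."""

    manifest: pd.DataFrame
    truth: pd.DataFrame
    traces: dict[tuple[int, int], dict[str, GyroTrace]]
    config: GenerationConfig
    seed: int


def _protocol_sequence(serves_per_type: int, rng: np.random.Generator):
    """Common call sequence for all players: one (side, target, target) per pair.

    Sides alternate deuce/ad; targets cycle through shuffled T/body/wide
    blocks, independently for first and second serves, as in a randomized
    but fixed serving protocol.
    """
    targets = np.array(["T", "body", "wide"])

    def cycle():
        seq: list[str] = []
        while len(seq) < serves_per_type:
            seq.extend(rng.permutation(targets).tolist())
        return seq[:serves_per_type]

    first_targets, second_targets = cycle(), cycle()
    return [("deuce" if i % 2 == 0 else "ad", first_targets[i], second_targets[i])
            for i in range(serves_per_type)]


def simulate_serves(config: GenerationConfig, seed: int,
                    with_traces: bool = True) -> SimulatedDataset:
    """Simulate a full cohort; deterministic given ``seed``."""
    ss = np.random.SeedSequence(seed)
    ss_players, ss_protocol, ss_serves = ss.spawn(3)
    players = sample_players(config.n_players, config.population,
                             np.random.default_rng(ss_players))
    protocol = _protocol_sequence(config.serves_per_type,
                                  np.random.default_rng(ss_protocol))
    zones = config.zone_config()
    serve_streams = iter(ss_serves.spawn(config.n_players * config.serves_per_type * 2))

    manifest_rows, truth_rows = [], []
    traces: dict[tuple[int, int], dict[str, GyroTrace]] = {}
    for profile in players:
        serve_idx = 0
        for pair_i, (side, tgt_first, tgt_second) in enumerate(protocol):
            for serve_type, target in (("first", tgt_first), ("second", tgt_second)):
                serve_idx += 1
                rng = np.random.default_rng(next(serve_streams))
                truth = draw_serve_truth(profile, serve_type, config.population, rng)
                if with_traces:
                    traces[(profile.player_id, serve_idx)] = synthesize_traces(
                        truth, config.population, rng)
                speed = generate_outcomes(
                    truth, profile, config.outcome_models["ball_speed_kph"][serve_type], rng)
                points = generate_outcomes(
                    truth, profile, config.outcome_models["accuracy_points"][serve_type], rng)
                bounce = sample_bounce_for_score(int(points), serve_type, target,
                                                 zones, rng, side=side)
                unregistered = rng.random() < config.drop_rate
                stem = f"p{profile.player_id:02d}_s{serve_idx:03d}"
                manifest_rows.append({
                    "player_id": profile.player_id, "serve_idx": serve_idx,
                    "serve_type": serve_type, "side": side, "target": target,
                    "ball_speed_kph": np.nan if unregistered else round(speed, 3),
                    "bounce_x_m": round(bounce.x_m, 4), "bounce_y_m": round(bounce.y_m, 4),
                    "accuracy_points": int(points),
                    **{f"trace_{seg}": f"{stem}_{seg}" for seg in SEGMENTS},
                })
                row = {"player_id": profile.player_id, "serve_idx": serve_idx,
                       "serve_type": serve_type}
                row.update({f"true_peak_{seg}": truth.peak_dps[seg] for seg in SEGMENTS})
                row.update({f"true_t_{seg}": truth.peak_time_ms[seg] for seg in SEGMENTS})
                row["true_dt_pelvis_trunk"] = truth.timing_pelvis_trunk_ms
                row["true_dt_trunk_upper_arm"] = truth.timing_trunk_upper_arm_ms
                truth_rows.append(row)
    manifest = pd.DataFrame(manifest_rows)
    truth_df = pd.DataFrame(truth_rows)
    n_dropped = int(manifest["ball_speed_kph"].isna().sum())
    logger.info("simulated %d serves for %d players (%d with unregistered speed)",
                len(manifest), config.n_players, n_dropped)
    return SimulatedDataset(manifest, truth_df, traces, config, seed)


def simulate_regression_dataset(model: OutcomeModel, serve_type: str,
                                params: PopulationParams, n_players: int,
                                serves_per_player: int, seed: int
                                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single-predictor clustered dataset ``(y, x, player_id)`` for recovery studies."""
    ss = np.random.SeedSequence(seed)
    ss_players, ss_serves = ss.spawn(2)
    players = sample_players(n_players, params, np.random.default_rng(ss_players))
    rng = np.random.default_rng(ss_serves)
    y, x, cluster = [], [], []
    for profile in players:
        for _ in range(serves_per_player):
            truth = draw_serve_truth(profile, serve_type, params, rng)
            y.append(generate_outcomes(truth, profile, model, rng))
            x.append(truth.predictor(model.predictor))
            cluster.append(profile.player_id)
    return np.asarray(y, float), np.asarray(x, float), np.asarray(cluster)


def generate_dataset(config: GenerationConfig, seed: int, out_dir: str | Path,
                     force: bool = False) -> SimulatedDataset:
    """Simulate a cohort and write it to disk.

    Layout: ``manifest.csv``, ``truth.csv``, ``traces/<stem>_<segment>.csv``
    and a ``config.json`` provenance copy (config + seed).
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"output directory {out_dir} is not empty (use force)")
    (out_dir / "traces").mkdir(parents=True, exist_ok=True)

    ds = simulate_serves(config, seed, with_traces=True)
    try:
        ds.manifest.to_csv(out_dir / "manifest.csv", index=False)
        ds.truth.to_csv(out_dir / "truth.csv", index=False)
        for row in ds.manifest.itertuples():
            for seg in SEGMENTS:
                stem = getattr(row, f"trace_{seg}")
                write_trace_csv(ds.traces[(row.player_id, row.serve_idx)][seg],
                                out_dir / "traces" / f"{stem}.csv")
        with open(out_dir / "config.json", "w") as fh:
            json.dump({"seed": seed, **config.to_dict()}, fh, indent=1)
    except OSError as exc:
        raise OSError(f"failed writing dataset under {out_dir}: {exc}") from exc
    return ds
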