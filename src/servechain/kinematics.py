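"""Per-serve gyroscope kinematics: filtering, norm, peaks, intersegmental timing.

A serve window is analysed in three steps that mirror standard wearable-sensor
practice for overhead strokes:

1. each triaxial angular-velocity channel is low-pass filtered with a
   second-order Butterworth response applied zero-phase (forward-backward),
   12 Hz for the slow proximal segments (pelvis, trunk) and 50 Hz for the
   much faster upper arm;
2. the Euclidean norm of the three filtered channels gives a rotation-axis-
   independent angular speed per sample;
3. the peak of that norm is the segment's peak angular velocity omega
   (deg/s), and signed differences between peak times of adjacent segments
   give the intersegmental timing (distal minus proximal, ms) — positive
   means the distal segment peaks later, as in a proximal-to-distal
   kinetic chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, lfilter, sosfiltfilt

__all__ = [
    "SEGMENTS",
    "DEFAULT_CUTOFFS_HZ",
    "GyroTrace",
    "KinematicSummary",
    "lowpass_filter",
    "euclidean_norm",
    "find_peak",
    "intersegmental_timing",
    "summarize_serve",
    "read_trace_csv",
    "write_trace_csv",
    "summarize_traces",
    "summarize_dataset",
]

logger = logging.getLogger(__name__)

#: Segments in proximal-to-distal order.
SEGMENTS: tuple[str, ...] = ("pelvis", "trunk", "upper_arm")

#: Default low-pass cutoffs (Hz) per segment.
DEFAULT_CUTOFFS_HZ: Mapping[str, float] = {"pelvis": 12.0, "trunk": 12.0, "upper_arm": 50.0}

#: Fraction of clipped samples above which a segment is flagged saturated.
SATURATION_WARN_FRACTION = 0.05

_MIN_SAMPLES = 100


@dataclass
class GyroTrace:
    """One segment's triaxial angular velocity over one serve window.

    Parameters
    ----------
    segment : str
        One of :data:`SEGMENTS`.
    fs_hz : float
        Sampling rate, Hz (1,000 Hz for the reference hardware).
    t_ms : ndarray, shape (n,)
        Sample times in ms, uniform and strictly increasing.
    w : ndarray, shape (n, 3)
        Angular velocity channels (gx, gy, gz), deg/s.
    clipped : ndarray of bool, shape (n,)
        True where any channel hit the sensor range before clamping.
    """

    segment: str
    fs_hz: float
    t_ms: np.ndarray
    w: np.ndarray
    clipped: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.segment not in SEGMENTS:
            raise ValueError(f"unknown segment {self.segment!r}; expected one of {SEGMENTS}")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.clipped is None:
            self.clipped = np.zeros(self.t_ms.shape, dtype=bool)
        self.clipped = np.asarray(self.clipped, dtype=bool)
        n = self.t_ms.shape[0]
        if n < _MIN_SAMPLES:
            raise ValueError(f"trace too short: {n} samples < {_MIN_SAMPLES}")
        if self.w.shape != (n, 3):
            raise ValueError(f"channel array shape {self.w.shape} does not match {n} samples x 3 axes")
        if self.clipped.shape != (n,):
            raise ValueError("clipped flags must match the time vector length")
        if not np.all(np.isfinite(self.t_ms)) or not np.all(np.isfinite(self.w)):
            raise ValueError("trace contains non-finite values")
        dt = np.diff(self.t_ms)
        if dt.size and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=0, atol=1e-9)):
            raise ValueError("time vector must be uniform and strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.t_ms.shape[0]

    @property
    def clipped_fraction(self) -> float:
        return float(self.clipped.mean())


@dataclass(frozen=True)
class KinematicSummary:
    """Peak angular velocities and intersegmental timing for one serve.

    ``timing_pelvis_trunk`` and ``timing_trunk_upper_arm`` follow the
    distal-minus-proximal sign convention: positive values mean the distal
    segment peaked later than its proximal neighbour.
    """

    peak_dps: Mapping[str, float]
    peak_time_ms: Mapping[str, float]
    timing_pelvis_trunk_ms: float
    timing_trunk_upper_arm_ms: float
    saturated: Mapping[str, bool]

    def as_row(self) -> dict[str, float]:
        """Flatten to a summary-CSV row fragment."""
        row: dict[str, float] = {}
        for seg in SEGMENTS:
            row[f"peak_{seg}"] = self.peak_dps[seg]
            row[f"t_{seg}"] = self.peak_time_ms[seg]
        row["dt_pelvis_trunk"] = self.timing_pelvis_trunk_ms
        row["dt_trunk_upper_arm"] = self.timing_trunk_upper_arm_ms
        for seg in SEGMENTS:
            row[f"saturated_{seg}"] = int(self.saturated[seg])
        return row


def _padlen(fs_hz: float, cutoff_hz: float) -> int:
    # odd-reflection padding spanning ~3x the filter's impulse-response scale
    return int(round(3.0 * fs_hz / cutoff_hz))


def lowpass_filter(trace: GyroTrace, cutoff_hz: float, order: int = 2,
                   zero_phase: bool = True) -> GyroTrace:
    """Low-pass filter all three channels of a trace.

    Butterworth response of the given order; by default applied
    forward-backward (zero phase), which preserves peak times of symmetric
    events — a causal single pass (``zero_phase=False``) is available for
    sensitivity checks but delays peaks.
    """
    nyquist = trace.fs_hz / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist}) Hz")
    if order < 1:
        raise ValueError("filter order must be >= 1")
    sos = butter(order, cutoff_hz, btype="low", fs=trace.fs_hz, output="sos")
    if zero_phase:
        padlen = _padlen(trace.fs_hz, cutoff_hz)
        if trace.n_samples <= padlen:
            raise ValueError(
                f"trace of {trace.n_samples} samples is shorter than the edge padding "
                f"({padlen} samples) required for a {cutoff_hz} Hz zero-phase filter")
        filtered = sosfiltfilt(sos, trace.w, axis=0, padtype="odd", padlen=padlen)
    else:
        b, a = butter(order, cutoff_hz, btype="low", fs=trace.fs_hz)
        filtered = lfilter(b, a, trace.w, axis=0)
    return GyroTrace(trace.segment, trace.fs_hz, trace.t_ms.copy(), filtered,
                     trace.clipped.copy())


def euclidean_norm(trace: GyroTrace) -> np.ndarray:
    """Per-sample Euclidean norm sqrt(gx^2 + gy^2 + gz^2), deg/s."""
    return np.linalg.norm(trace.w, axis=1)


def find_peak(values: Sequence[float], t_ms: Sequence[float],
              window_ms: tuple[float, float] | None = None) -> tuple[float, float]:
    """Global maximum of a scalar series; ties resolve to the earliest sample.

    Returns ``(value, time_ms)``. ``window_ms`` restricts the search to a
    closed time interval.
    """
    values = np.asarray(values, dtype=float)
    t_ms = np.asarray(t_ms, dtype=float)
    if values.shape != t_ms.shape:
        raise ValueError("series and time vector must have equal length")
    if window_ms is not None:
        lo, hi = window_ms
        mask = (t_ms >= lo) & (t_ms <= hi)
        if not mask.any():
            raise ValueError(f"search window [{lo}, {hi}] ms contains no samples")
        values, t_ms = values[mask], t_ms[mask]
    i = int(np.argmax(values))  # argmax returns the first maximal index
    return float(values[i]), float(t_ms[i])


def intersegmental_timing(peak_time_ms: Mapping[str, float]) -> tuple[float, float]:
    """Signed peak-time intervals (distal minus proximal).

    Returns ``(t_trunk - t_pelvis, t_upper_arm - t_trunk)`` in ms.
    """
    missing = [s for s in SEGMENTS if s not in peak_time_ms]
    if missing:
        raise ValueError(f"missing peak time for segment(s): {missing}")
    return (float(peak_time_ms["trunk"] - peak_time_ms["pelvis"]),
            float(peak_time_ms["upper_arm"] - peak_time_ms["trunk"]))


def summarize_serve(traces: Mapping[str, GyroTrace],
                    cutoffs_hz: Mapping[str, float] | None = None,
                    zero_phase: bool = True,
                    window_ms: tuple[float, float] | None = None) -> KinematicSummary:
    """Full per-serve pipeline: filter, norm, peak, timing.

    ``traces`` must contain all three segments at a common sampling rate.
    A segment with more than 5% clipped samples is flagged saturated in the
    summary (the serve is still summarised).
    """
    cutoffs = dict(DEFAULT_CUTOFFS_HZ)
    if cutoffs_hz:
        cutoffs.update(cutoffs_hz)
    missing = [s for s in SEGMENTS if s not in traces]
    if missing:
        raise ValueError(f"missing trace for segment(s): {missing}")
    rates = {traces[s].fs_hz for s in SEGMENTS}
    if len(rates) != 1:
        raise ValueError(f"segments sampled at different rates: {sorted(rates)}")

    peaks: dict[str, float] = {}
    times: dict[str, float] = {}
    saturated: dict[str, bool] = {}
    for seg in SEGMENTS:
        tr = traces[seg]
        if tr.segment != seg:
            raise ValueError(f"trace under key {seg!r} is labelled {tr.segment!r}")
        filt = lowpass_filter(tr, cutoffs[seg], order=2, zero_phase=zero_phase)
        norm = euclidean_norm(filt)
        peaks[seg], times[seg] = find_peak(norm, filt.t_ms, window_ms)
        saturated[seg] = tr.clipped_fraction > SATURATION_WARN_FRACTION
        if saturated[seg]:
            logger.warning("segment %s: %.1f%% clipped samples — peak may be underestimated",
                           seg, 100 * tr.clipped_fraction)
    dt_pt, dt_ta = intersegmental_timing(times)
    return KinematicSummary(peaks, times, dt_pt, dt_ta, saturated)


# ---------------------------------------------------------------------------
# Trace CSV dialect (shared with the synthetic generator)

_TRACE_COLUMNS = ["t_ms", "gx_dps", "gy_dps", "gz_dps", "clipped"]


def write_trace_csv(trace: GyroTrace, path: str | Path) -> None:
    df = pd.DataFrame({
        "t_ms": trace.t_ms,
        "gx_dps": trace.w[:, 0],
        "gy_dps": trace.w[:, 1],
        "gz_dps": trace.w[:, 2],
        "clipped": trace.clipped.astype(int),
    })
    df.to_csv(path, index=False)


def read_trace_csv(path: str | Path, segment: str, fs_hz: float = 1000.0) -> GyroTrace:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # surface the offending file
        raise ValueError(f"malformed trace CSV {path}: {exc}") from exc
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV {path} lacks column(s) {missing}")
    w = df[["gx_dps", "gy_dps", "gz_dps"]].to_numpy(dtype=float)
    return GyroTrace(segment, fs_hz, df["t_ms"].to_numpy(dtype=float), w,
                     df["clipped"].to_numpy(dtype=bool))


def summarize_traces(manifest: pd.DataFrame,
                     traces: Mapping[tuple[int, int], Mapping[str, GyroTrace]],
                     cutoffs_hz: Mapping[str, float] | None = None,
                     zero_phase: bool = True,
                     serve_type: str | None = None) -> pd.DataFrame:
    """Summarise in-memory serves keyed by ``(player_id, serve_idx)``.

    Same output layout as :func:`summarize_dataset`, without the file
    round-trip. ``serve_type`` optionally restricts the work to one type.
    """
    rows: list[dict] = []
    for m in manifest.itertuples():
        if serve_type is not None and m.serve_type != serve_type:
            continue
        summary = summarize_serve(traces[(m.player_id, m.serve_idx)],
                                  cutoffs_hz=cutoffs_hz, zero_phase=zero_phase)
        row = {"player_id": m.player_id, "serve_idx": m.serve_idx,
               "serve_type": m.serve_type}
        row.update(summary.as_row())
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_dataset(manifest: pd.DataFrame, trace_dir: str | Path,
                      cutoffs_hz: Mapping[str, float] | None = None,
                      fs_hz: float = 1000.0,
                      zero_phase: bool = True) -> pd.DataFrame:
    """Summarise every serve listed in a manifest.

    The manifest must carry ``player_id``, ``serve_idx``, ``serve_type`` and a
    ``trace_<segment>`` file-stem column per segment. Serves with a missing
    trace file are logged and skipped. Returns one row per summarised serve.
    """
    trace_dir = Path(trace_dir)
    rows: list[dict] = []
    for _, m in manifest.iterrows():
        traces: dict[str, GyroTrace] = {}
        ok = True
        for seg in SEGMENTS:
            p = trace_dir / f"{m[f'trace_{seg}']}.csv"
            if not p.exists():
                logger.warning("serve %s/%s: missing trace %s — skipped",
                               m["player_id"], m["serve_idx"], p)
                ok = False
                break
            traces[seg] = read_trace_csv(p, seg, fs_hz=fs_hz)
        if not ok:
            continue
        summary = summarize_serve(traces, cutoffs_hz=cutoffs_hz, zero_phase=zero_phase)
        row = {"player_id": m["player_id"], "serve_idx": m["serve_idx"],
               "serve_type": m["serve_type"]}
        row.update(summary.as_row())
        rows.append(row)
    columns = (["player_id", "serve_idx", "serve_type"]
               + [f"peak_{s}" for s in SEGMENTS] + [f"t_{s}" for s in SEGMENTS]
               + ["dt_pelvis_trunk", "dt_trunk_upper_arm"]
               + [f"saturated_{s}" for s in SEGMENTS])
    return pd.DataFrame(rows, columns=columns)
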