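"""Kinematic measurement pipeline shared by simulated and recorded trials.

Implements the standard processing applied to planar reaching recordings:
zero-phase Butterworth smoothing (5th order, 12.5 Hz cutoff), movement
segmentation with a 1 cm/s hand-speed threshold, and per-condition summaries
(duration, peak velocity in cm/s, log endpoint variance in log(mm^2),
time-normalized mean speed profile).  The same code path measures model
rollouts and experimental data, so model-vs-data comparisons (RMSD, R^2) are
free of pipeline mismatch.  A synthetic minimum-jerk trial generator with
known ground truth stands in for tablet recordings in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .simulate import endpoint_statistics, EndpointStats

__all__ = [
    "RawTrial",
    "KinematicSummary",
    "smooth",
    "speed_profile",
    "segment",
    "summarize",
    "compare",
    "generate_synthetic_trials",
    "min_jerk_position",
    "min_jerk_speed",
    "read_trials_xls",
]

SAMPLE_RATE = 125.0  # Hz, tablet recording rate


@dataclass
class RawTrial:
    """One recorded or simulated planar trajectory."""

    t: np.ndarray                     # (n,) sample times, uniform
    pos: np.ndarray                   # (n, 2) planar positions (m)
    condition: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (len(self.t), 2):
            raise ValueError("pos must have shape (len(t), 2)")
        dt = np.diff(self.t)
        if len(dt) and (np.any(dt <= 0)
                        or np.max(np.abs(dt - dt[0])) > 1e-6 + 1e-3 * dt[0]):
            raise ValueError("sample times must be uniform and increasing")

    @property
    def rate(self) -> float:
        return 1.0 / (self.t[1] - self.t[0])


@dataclass
class KinematicSummary:
    duration: float                   # s (mean over trials)
    peak_velocity: float              # cm/s (mean over trials)
    log_endpoint_variance: float      # log(mm^2)
    ellipse: EndpointStats | None
    n_trials: int
    mean_speed_profile: np.ndarray    # (n_norm,) time-normalized (m/s)
    condition: dict = field(default_factory=dict)


def smooth(trial: RawTrial, order: int = 5, cutoff: float = 12.5) -> RawTrial:
    """Zero-phase low-pass filtering of the positions (forward–backward).

    The forward–backward pass removes the filter's phase delay ("without
    delay"), at the price of doubling the effective order.
    """
    rate = trial.rate
    if rate <= 2 * cutoff:
        raise ValueError("sample rate must exceed twice the cutoff frequency")
    if len(trial.t) < 3 * (order + 1):
        raise ValueError("trial too short to filter")
    sos = signal.butter(order, cutoff, fs=rate, output="sos")
    pos = signal.sosfiltfilt(sos, trial.pos, axis=0)
    return RawTrial(t=trial.t.copy(), pos=pos, condition=dict(trial.condition))


def speed_profile(trial: RawTrial) -> np.ndarray:
    """Hand speed (m/s) by numerical differentiation of the positions."""
    vel = np.gradient(trial.pos, trial.t, axis=0)
    return np.linalg.norm(vel, axis=-1)


def segment(speed: np.ndarray, t: np.ndarray,
            threshold: float = 0.01) -> tuple[int, int, float]:
    """Movement boundaries from a speed threshold.

    Start is the first sample above threshold, end the last sample above it;
    the duration is ``t[end] - t[start]``.  Raises if the speed never
    exceeds the threshold.
    """
    speed = np.asarray(speed, dtype=float)
    above = speed > threshold
    if not above.any():
        raise ValueError("no movement: speed never exceeds the threshold")
    i0 = int(np.argmax(above))
    i1 = int(len(speed) - 1 - np.argmax(above[::-1]))
    return i0, i1, float(t[i1] - t[i0])


def _normalize_profile(speed: np.ndarray, i0: int, i1: int,
                       n_norm: int) -> np.ndarray:
    s = np.linspace(0.0, 1.0, n_norm)
    src = np.linspace(0.0, 1.0, i1 - i0 + 1)
    return np.interp(s, src, speed[i0:i1 + 1])


def summarize(trials: Sequence[RawTrial], threshold: float = 0.01,
              presmooth: bool = False, n_norm: int = 101) -> KinematicSummary:
    """Per-condition kinematic summary over a set of trials.

    Each trial is segmented with the speed threshold; the endpoint is the
    position at the segmentation end sample.  ``presmooth=True`` applies the
    Butterworth filter first (use for raw recordings; simulated trajectories
    are already band-limited by the plant dynamics).
    """
    if len(trials) < 2:
        raise ValueError("need >= 2 trials to estimate endpoint variance")
    durations, peaks, endpoints, profiles = [], [], [], []
    for tr in trials:
        if presmooth:
            tr = smooth(tr)
        sp = speed_profile(tr)
        i0, i1, dur = segment(sp, tr.t, threshold)
        durations.append(dur)
        peaks.append(sp.max())
        endpoints.append(tr.pos[i1])
        profiles.append(_normalize_profile(sp, i0, i1, n_norm))
    ep = None
    if len(trials) >= 3:
        try:
            ep = endpoint_statistics(np.asarray(endpoints))
        except ValueError:
            ep = None  # degenerate spread: no ellipse, log-variance is -inf
    cov = np.cov(np.asarray(endpoints).T)
    with np.errstate(divide="ignore"):
        logvar = float(np.log(np.trace(cov) * 1e6))
    return KinematicSummary(
        duration=float(np.mean(durations)),
        peak_velocity=float(np.mean(peaks) * 100.0),
        log_endpoint_variance=logvar,
        ellipse=ep,
        n_trials=len(trials),
        mean_speed_profile=np.mean(profiles, axis=0),
        condition=dict(trials[0].condition),
    )


def compare(model: pd.DataFrame, data: pd.DataFrame,
            metrics: Sequence[str] = ("duration", "peak_velocity",
                                      "log_endpoint_variance"),
            keys: Sequence[str] = ("direction", "distance", "vision"),
            ) -> pd.DataFrame:
    """RMSD and correlation between matched model and data summaries.

    Both frames must contain the key columns and the metric columns; rows are
    matched on the keys (all conditions must be present in both).  Returns
    one row per metric with RMSD, RMSD as a percentage of the data mean,
    Pearson r and R^2.
    """
    keys = list(keys)
    merged = model.merge(data, on=keys, suffixes=("_model", "_data"),
                         validate="one_to_one")
    if len(merged) != len(model) or len(merged) != len(data):
        raise ValueError("condition keys of model and data do not match")
    rows = []
    for m in metrics:
        a = merged[f"{m}_model"].to_numpy(dtype=float)
        b = merged[f"{m}_data"].to_numpy(dtype=float)
        rmsd = float(np.sqrt(np.mean((a - b) ** 2)))
        if len(a) > 1 and np.std(a) > 0 and np.std(b) > 0:
            r = float(np.corrcoef(a, b)[0, 1])
        else:
            r = np.nan
        rows.append({"metric": m, "rmsd": rmsd,
                     "rmsd_pct_of_mean": 100.0 * rmsd / abs(b.mean()),
                     "pearson_r": r, "r_squared": r ** 2})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# synthetic fixture generator
# --------------------------------------------------------------------------

def min_jerk_position(t: np.ndarray, T: float, p0: np.ndarray,
                      p1: np.ndarray) -> np.ndarray:
    """Minimum-jerk point-to-point path sampled at times t (clipped to [0,T])."""
    s = np.clip(np.asarray(t, dtype=float) / T, 0.0, 1.0)
    blend = 10 * s ** 3 - 15 * s ** 4 + 6 * s ** 5
    return np.asarray(p0) + blend[:, None] * (np.asarray(p1) - np.asarray(p0))


def min_jerk_speed(t: np.ndarray, T: float, dist: float) -> np.ndarray:
    """Closed-form speed of the minimum-jerk path (peak 1.875*dist/T)."""
    s = np.clip(np.asarray(t, dtype=float) / T, 0.0, 1.0)
    return dist / T * 30.0 * s ** 2 * (1.0 - s) ** 2


def generate_synthetic_trials(conditions: Sequence[dict] | None = None,
                              n_trials: int = 5,
                              rate: float = SAMPLE_RATE,
                              endpoint_sd: float = 0.003,
                              timing_sd: float = 0.05,
                              measurement_sd: float = 5e-5,
                              rest_pad: float = 0.3,
                              seed: int = 0) -> list[RawTrial]:
    """Minimum-jerk trials with known ground truth, as a stand-in fixture.

    Each condition dict needs ``direction`` (deg), ``distance`` (m) and
    ``duration`` (s); optional ``start`` (2,) and ``vision`` label.  Trials
    get i.i.d. endpoint offsets (per-axis sd ``endpoint_sd``), lognormal-free
    multiplicative timing jitter (sd fraction ``timing_sd``), additive
    measurement noise and rest padding before and after the movement — the
    statistical structure the measurement pipeline assumes.  Synthetic data;
    no experimental recordings are involved.
    """
    if conditions is None:
        conditions = [{"direction": 45.0, "distance": 0.12, "duration": 0.8}]
    rng = np.random.default_rng(seed)
    trials = []
    dt = 1.0 / rate
    for cond in conditions:
        ang = np.deg2rad(cond["direction"])
        start = np.asarray(cond.get("start", (0.0, 0.0)), dtype=float)
        disp = cond["distance"] * np.array([np.cos(ang), np.sin(ang)])
        for _ in range(n_trials):
            T = cond["duration"] * (1.0 + timing_sd * rng.standard_normal())
            T = max(T, 0.2)
            endpoint = start + disp + endpoint_sd * rng.standard_normal(2)
            n_move = int(np.ceil(T * rate))
            n_pad = int(round(rest_pad * rate))
            t = np.arange(n_move + 2 * n_pad + 1) * dt
            t_move = t - n_pad * dt
            pos = min_jerk_position(t_move, T, start, endpoint)
            pos = pos + measurement_sd * rng.standard_normal(pos.shape)
            labels = {k: v for k, v in cond.items() if k != "start"}
            trials.append(RawTrial(t=t, pos=pos, condition=labels))
    return trials


def read_trials_xls(path: str | Path) -> pd.DataFrame:
    """Defensive reader for a per-condition summary spreadsheet.

    Accepts .xls/.xlsx/.csv files whose first sheet (or the sheet named
    like 'data') contains columns recognizable as direction, distance,
    vision and at least one of duration / peak velocity / endpoint variance;
    column names are matched case-insensitively on substrings.  Returns a
    normalized DataFrame with canonical column names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".csv", ".tsv"):
        df = pd.read_csv(path, sep=None, engine="python")
    else:
        book = pd.read_excel(path, sheet_name=None)
        name = next((k for k in book if "data" in k.lower()), None)
        df = book[name] if name else next(iter(book.values()))
    aliases = {
        "direction": ("direction", "dir"),
        "distance": ("distance", "amplitude", "dist"),
        "vision": ("vision", "condition", "visual"),
        "duration": ("duration", "movement time", "mt"),
        "peak_velocity": ("peak velocity", "peak_vel", "pv"),
        "log_endpoint_variance": ("endpoint variance", "variance",
                                  "log_var", "logvar"),
    }
    out = {}
    lowered = {c.lower().strip(): c for c in df.columns}
    for canon, keys in aliases.items():
        for low, orig in lowered.items():
            if any(k in low for k in keys):
                out[canon] = df[orig]
                break
    if not {"direction", "distance"} <= set(out):
        raise ValueError(
            f"could not recognize condition columns in {path.name}; "
            f"found columns {list(df.columns)}")
    res = pd.DataFrame(out)
    if "distance" in res and res["distance"].max() > 1.0:
        res["distance"] = res["distance"] / 100.0  # cm -> m
    return res
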