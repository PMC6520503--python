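"""Trace preprocessing: filtering, differentiation, baseline subtraction,
direction pooling, and windowed response-gain extraction.

Raw inputs are per-trial lateral force (N, channel trials) or lateral hand
velocity/acceleration (cm/s, cm/s^2, standard trials) sampled at 1 kHz and
aligned to the cursor-jump event (t = 0 ms).  The response gain of a trial
ensemble is the mean baseline-subtracted, sign-pooled trace value over the
170-220 ms post-jump window; its sign convention is positive = correction
toward the center target.

Every operation here is linear in the trace values, so preprocessing
commutes with trial averaging (a property the tests exercise).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "Timeseries",
    "GainObservation",
    "DEFAULT_WINDOW",
    "lowpass",
    "differentiate",
    "subtract_baseline",
    "pool_directions",
    "response_gain",
    "latency_correct",
    "extract_gains",
]

#: analysis window for the rapid visuomotor response, ms after the cursor jump
DEFAULT_WINDOW: tuple[int, int] = (170, 220)

SAMPLING_RATE_HZ = 1000.0


@dataclass(frozen=True)
class Timeseries:
    """A 1 kHz trace aligned to the cursor jump.

    Parameters
    ----------
    t : array of int
        Time in ms relative to the (displayed) cursor jump; strictly uniform
        1 ms steps.
    values : array of float
        Lateral force (N), velocity (cm/s) or acceleration (cm/s^2).
    channel : {"force", "velocity", "acceleration"}
    """

    t: np.ndarray
    values: np.ndarray
    channel: str = "force"

    def __post_init__(self):
        t = np.asarray(self.t)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("t and values must be 1-D arrays of equal length")
        if len(t) > 1 and not np.all(np.diff(t) == 1):
            raise ValueError("Timeseries requires strictly uniform 1 ms sampling")
        object.__setattr__(self, "t", t.astype(int))
        object.__setattr__(self, "values", v)

    def window_mask(self, lo: int, hi: int) -> np.ndarray:
        return (self.t >= lo) & (self.t <= hi)


@dataclass(frozen=True)
class GainObservation:
    """Windowed response gain of one subject x condition x direction cell.

    ``gain`` is the mean baseline-subtracted trace value over ``window``
    (inclusive endpoints), sign-pooled so that positive = correction toward
    the center target.
    """

    subject_id: str
    condition_id: str
    jump_direction: str  # "left", "right" or "pooled"
    gain: float
    n_trials: int = 1
    channel: str = "force"
    window: tuple[int, int] = DEFAULT_WINDOW

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def lowpass(ts: Timeseries, cutoff: float = 50.0, order: int = 4) -> Timeseries:
    """Zero-phase low-pass filter (Butterworth, forward-backward).

    The cutoff (default 50 Hz) is the binding parameter; the 4th-order
    zero-phase realization is the package's choice of a standard
    human-movement filter.  Raises for cutoffs at or above Nyquist (500 Hz).
    """
    nyquist = SAMPLING_RATE_HZ / 2.0
    if cutoff >= nyquist:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({nyquist} Hz)")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sos = signal.butter(order, cutoff, btype="low", fs=SAMPLING_RATE_HZ, output="sos")
    filtered = signal.sosfiltfilt(sos, ts.values)
    return replace(ts, values=filtered)


def differentiate(velocity_ts: Timeseries) -> Timeseries:
    """Differentiate a velocity trace (cm/s) to acceleration (cm/s^2).

    Central differences with endpoint replication: the series is padded by
    repeating its first and last samples, so the end samples carry a
    first-order one-sided estimate at half weight.  Length is preserved.
    """
    if velocity_ts.channel != "velocity":
        raise ValueError(f"expected a velocity trace, got channel={velocity_ts.channel!r}")
    v = velocity_ts.values
    dt = 1.0 / SAMPLING_RATE_HZ  # seconds per sample
    padded = np.concatenate([[v[0]], v, [v[-1]]])
    accel = (padded[2:] - padded[:-2]) / (2.0 * dt)
    return Timeseries(velocity_ts.t, accel, channel="acceleration")


def subtract_baseline(trace: Timeseries, baseline: Timeseries) -> Timeseries:
    """Pointwise subtraction of a per-subject unperturbed-trial baseline.

    The baseline must be the mean trace of the matching trial type (channel
    baselines for channel trials, unperturbed-standard baselines for
    standard trials) on an identical time grid.
    """
    if not np.array_equal(trace.t, baseline.t):
        raise ValueError("trace and baseline time grids differ")
    if trace.channel != baseline.channel:
        raise ValueError("trace and baseline channels differ")
    return replace(trace, values=trace.values - baseline.values)


def pool_directions(
    traces: Sequence[Timeseries], directions: Sequence[str]
) -> list[Timeseries]:
    """Merge left- and right-jump traces into a common sign convention.

    Right-jump traces are negated so that, in the pooled ensemble, positive
    values mean a correction toward the center target.  Unperturbed trials
    (direction "none") have no jump to pool over and are rejected.
    """
    if len(traces) != len(directions):
        raise ValueError("traces and directions length mismatch")
    pooled = []
    for trace, direction in zip(traces, directions):
        if direction == "left":
            pooled.append(trace)
        elif direction == "right":
            pooled.append(replace(trace, values=-trace.values))
        else:
            raise ValueError(f"cannot pool jump_direction={direction!r}")
    return pooled


def response_gain(
    trace: Timeseries,
    window: tuple[int, int] = DEFAULT_WINDOW,
    *,
    subject_id: str = "",
    condition_id: str = "",
    jump_direction: str = "pooled",
    n_trials: int = 1,
) -> GainObservation:
    """Mean of a (baseline-subtracted, sign-pooled) trace over the window.

    Both window endpoints are inclusive: the default [170, 220] ms window
    averages 51 samples.
    """
    lo, hi = window
    mask = trace.window_mask(lo, hi)
    if trace.t[0] > lo or trace.t[-1] < hi:
        raise ValueError(f"window [{lo}, {hi}] ms exceeds trace support "
                         f"[{trace.t[0]}, {trace.t[-1]}] ms")
    gain = float(np.mean(trace.values[mask]))
    return GainObservation(
        subject_id=subject_id,
        condition_id=condition_id,
        jump_direction=jump_direction,
        gain=gain,
        n_trials=n_trials,
        channel=trace.channel,
        window=(lo, hi),
    )


def latency_correct(ts: Timeseries, display_latency: int = 24) -> Timeseries:
    """Shift the time axis so t = 0 is the *displayed* cursor jump.

    The display pipeline lags the commanded jump by ``display_latency`` ms
    (default 24 ms, the photodiode-measured value), so an event at raw time
    t appears at corrected time t - display_latency.
    """
    return replace(ts, t=ts.t - int(display_latency))


# ---------------------------------------------------------------------------
# Table-level pipeline


def extract_gains(
    trials: pd.DataFrame,
    traces: pd.DataFrame,
    *,
    channel: str = "force",
    window: tuple[int, int] = DEFAULT_WINDOW,
    cutoff: float | None = None,
    pool: bool = True,
) -> pd.DataFrame:
    """Run the full gain-extraction pipeline on long-format trace tables.

    For each subject, the mean unperturbed trace of the matching trial type
    (channel trials for force, standard trials for acceleration) is
    subtracted from every cursor-jump trace of that type; right-jump traces
    are sign-flipped; and the mean windowed value per subject x condition
    (x direction if ``pool`` is False) is returned as one row per
    GainObservation.

    Parameters
    ----------
    trials : DataFrame with TrialRecord columns (see design_sim).
    traces : long DataFrame with columns trial_id, t_ms and a value column
        ``force_N`` or ``accel_cm_s2``.
    channel : "force" (channel trials) or "acceleration" (standard trials).
    cutoff : optional low-pass cutoff in Hz applied to each trace first.
    """
    value_col = {"force": "force_N", "acceleration": "accel_cm_s2"}[channel]
    trial_type = {"force": "channel", "acceleration": "standard"}[channel]

    merged = traces.merge(
        trials[["trial_id", "subject_id", "condition_id", "trial_type",
                "jump_direction", "phase"]],
        on="trial_id",
    )
    merged = merged[(merged["trial_type"] == trial_type) & (merged["phase"] == "main")]

    rows = []
    for subject, sub in merged.groupby("subject_id"):
        wide = sub.pivot_table(index="trial_id", columns="t_ms", values=value_col)
        t = wide.columns.to_numpy()
        meta = sub.drop_duplicates("trial_id").set_index("trial_id")
        mat = wide.to_numpy()
        if cutoff is not None:
            sos = signal.butter(4, cutoff, btype="low", fs=SAMPLING_RATE_HZ, output="sos")
            mat = signal.sosfiltfilt(sos, mat, axis=1)

        directions = meta.loc[wide.index, "jump_direction"].to_numpy()
        conditions = meta.loc[wide.index, "condition_id"].to_numpy()
        is_unperturbed = directions == "none"
        if not is_unperturbed.any():
            raise ValueError(f"subject {subject}: no unperturbed {trial_type} trials "
                             "to form a baseline")
        baseline = mat[is_unperturbed].mean(axis=0)

        jump = ~is_unperturbed
        sub_mat = mat[jump] - baseline
        sub_dir = directions[jump]
        sub_cond = conditions[jump]
        signed = np.where(sub_dir[:, None] == "right", -sub_mat, sub_mat)

        lo, hi = window
        win_mask = (t >= lo) & (t <= hi)
        win_means = signed[:, win_mask].mean(axis=1)

        if pool:
            keys = pd.DataFrame({"condition_id": sub_cond})
        else:
            keys = pd.DataFrame({"condition_id": sub_cond, "jump_direction": sub_dir})
        keys["gain"] = win_means
        grouped = keys.groupby(list(keys.columns[:-1]), as_index=False).agg(
            gain=("gain", "mean"), n_trials=("gain", "size"))
        for _, rec in grouped.iterrows():
            rows.append({
                "subject_id": subject,
                "condition_id": rec["condition_id"],
                "jump_direction": rec.get("jump_direction", "pooled"),
                "gain": rec["gain"],
                "n_trials": int(rec["n_trials"]),
                "channel": channel,
                "window_lo": lo,
                "window_hi": hi,
            })
    return pd.DataFrame(rows)
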