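"""Response-onset detection by time-resolved ROC analysis.

Given two ensembles of response traces (e.g., blocks where the outer vs the
center target was more valuable, or jump vs unperturbed trials), the area
under the ROC curve (aROC) is computed independently at every 1 ms sample.
An aROC of 0.5 means the ensembles are indistinguishable at that sample.

To estimate the time the ensembles first diverge, the aROC series is
truncated after the first run of three consecutive samples above 0.62
(saturation of the effect is uninformative about its onset), a "dog-leg"
— a flat line fixed at 0.5 followed by a linear rise — is least-squares
fitted with the breakpoint scanned exhaustively over sample times, and the
onset is the later of (a) the end of the flat portion and (b) the last
local minimum of the truncated series.  Taking the later time is a
conservative choice appropriate to the low 0.62 criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ArocSeries",
    "OnsetEstimate",
    "DoglegFit",
    "aroc_at_sample",
    "aroc_series",
    "truncate_aroc",
    "fit_dogleg",
    "last_local_minimum",
    "detect_onset",
]


@dataclass(frozen=True)
class ArocSeries:
    """aROC values on a 1 ms grid, with an optional truncation time."""

    t: np.ndarray
    aroc: np.ndarray
    truncation_time: float | None = None

    def __post_init__(self):
        t = np.asarray(self.t)
        a = np.asarray(self.aroc, dtype=float)
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError("t and aroc must be 1-D arrays of equal length")
        if len(t) > 1 and not np.all(np.diff(t) == 1):
            raise ValueError("aROC series requires a 1 ms grid")
        if np.any((a < 0) | (a > 1)):
            raise ValueError("aROC values must lie in [0, 1]")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "aroc", a)


@dataclass(frozen=True)
class DoglegFit:
    flat_end: float
    slope: float
    sse: float
    degenerate: bool = False


@dataclass(frozen=True)
class OnsetEstimate:
    onset: float
    flat_end: float
    last_local_min: float
    dogleg_slope: float
    reflected: bool = False
    degenerate: bool = False

    @property
    def valid(self) -> bool:
        """Whether the estimate is a usable response onset.

        Degenerate fits and onsets at or before the perturbation (t <= 0,
        physically impossible for a response to it) mark detection
        failures — typically a spurious early truncation of a noisy aROC
        series — and should be excluded from group summaries.
        """
        return not self.degenerate and self.onset > 0


def aroc_at_sample(values_a, values_b) -> float:
    """Area under the ROC curve separating two samples at one time point.

    Equals P(b > a) + 0.5 P(b = a) over all pairs — the Mann-Whitney U
    statistic normalized by n_a * n_b, with ties counted as half.
    Computed from midranks; tests verify it against a brute-force all-pairs
    count.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = rankdata(np.concatenate([a, b]))
    rank_sum_b = ranks[a.size:].sum()
    u_b = rank_sum_b - b.size * (b.size + 1) / 2.0
    return float(u_b / (a.size * b.size))


def _as_matrix(group) -> tuple[np.ndarray, np.ndarray | None]:
    """Accept a 2-D array (trials x time) or a list of Timeseries."""
    if hasattr(group, "ndim"):
        return np.asarray(group, dtype=float), None
    first = group[0]
    if hasattr(first, "t") and hasattr(first, "values"):
        t = first.t
        for ts in group:
            if not np.array_equal(ts.t, t):
                raise ValueError("traces must share a common time grid")
        return np.vstack([ts.values for ts in group]), np.asarray(t)
    return np.asarray(group, dtype=float), None


def aroc_series(group_a, group_b, t=None) -> ArocSeries:
    """aROC at every sample of two trace ensembles on a common grid.

    Groups may be 2-D arrays (trials x time) or lists of Timeseries.
    """
    mat_a, t_a = _as_matrix(group_a)
    mat_b, t_b = _as_matrix(group_b)
    if mat_a.ndim == 1:
        mat_a = mat_a[None, :]
    if mat_b.ndim == 1:
        mat_b = mat_b[None, :]
    if mat_a.shape[1] != mat_b.shape[1]:
        raise ValueError("ensembles are on different time grids")
    if t_a is not None and t_b is not None and not np.array_equal(t_a, t_b):
        raise ValueError("ensembles are on different time grids")
    if t is None:
        t = t_a if t_a is not None else np.arange(mat_a.shape[1])
    t = np.asarray(t)

    n_a, n_b = mat_a.shape[0], mat_b.shape[0]
    both = np.vstack([mat_a, mat_b])
    # column-wise midranks in one pass
    ranks = rankdata(both, axis=0)
    u_b = ranks[n_a:].sum(axis=0) - n_b * (n_b + 1) / 2.0
    return ArocSeries(t, u_b / (n_a * n_b))


def truncate_aroc(series: ArocSeries, criterion: float = 0.62, run: int = 3) -> ArocSeries:
    """Cut the series at the first run of ``run`` consecutive samples whose
    aROC is strictly greater than ``criterion``.

    Samples from the first sample of that run onward are excluded (the kept
    series ends at the last pre-run sample) and the run's first sample time
    is recorded as ``truncation_time``; the series is returned unchanged if
    no such run exists.
    """
    above = series.aroc > criterion
    count = 0
    start = None
    for i, flag in enumerate(above):
        count = count + 1 if flag else 0
        if count == run:
            start = i - run + 1
            break
    if start is None:
        return series
    return ArocSeries(series.t[:start], series.aroc[:start],
                      truncation_time=float(series.t[start]))


def fit_dogleg(series: ArocSeries) -> DoglegFit:
    """Least-squares dog-leg fit: flat at 0.5 up to the breakpoint, then a
    line continuous at 0.5.

    For each candidate breakpoint t_b on the sample grid, the best slope
    has the closed form  s = sum((y-0.5)(t-t_b)) / sum((t-t_b)^2)  over
    t > t_b; the breakpoint minimizing total SSE is returned (earliest on
    ties).  A series with no variation is flagged degenerate.
    """
    t = series.t.astype(float)
    y = series.aroc
    if len(t) < 3:
        raise ValueError("need at least 3 samples to fit a dog-leg")
    resid = y - 0.5
    if np.allclose(y, y[0]):
        return DoglegFit(flat_end=float(t[0]), slope=0.0,
                         sse=float(np.sum(resid**2)), degenerate=True)

    best = None
    # breakpoint candidates: every sample except the last two (the linear
    # part needs at least two samples beyond the breakpoint to be identified)
    for k in range(len(t) - 2):
        dt = t[k + 1:] - t[k]
        num = float(np.dot(resid[k + 1:], dt))
        den = float(np.dot(dt, dt))
        s = num / den
        sse = float(np.sum(resid[:k + 1] ** 2)
                    + np.sum((resid[k + 1:] - s * dt) ** 2))
        if best is None or sse < best[0] - 1e-15:
            best = (sse, float(t[k]), s)
    sse, flat_end, slope = best
    return DoglegFit(flat_end=flat_end, slope=slope, sse=sse)


def last_local_minimum(series: ArocSeries) -> float:
    """Time of the last local minimum of the series.

    A sample strictly lower than both neighbors is a local minimum; for a
    plateau flanked by higher values on both sides, the plateau's last
    sample counts.  Returns the series start time if no interior minimum
    exists.
    """
    y = series.aroc
    t = series.t
    if len(y) < 3:
        raise ValueError("need at least 3 samples")
    last = None
    i = 1
    while i < len(y) - 1:
        if y[i] < y[i - 1]:
            j = i
            while j + 1 < len(y) and y[j + 1] == y[i]:
                j += 1
            if j < len(y) - 1 and y[j + 1] > y[i]:
                last = j
            i = j + 1
        else:
            i += 1
    return float(t[last]) if last is not None else float(t[0])


def detect_onset(
    group_a,
    group_b,
    t=None,
    *,
    criterion: float = 0.62,
    run: int = 3,
    reflect: bool | str = "auto",
) -> OnsetEstimate:
    """Full onset pipeline: aROC series -> truncation -> dog-leg and last
    local minimum -> onset = the later of the two.

    ``reflect`` controls the divergence direction convention: the dog-leg
    assumes an upward departure from 0.5, so a series running below 0.5 is
    reflected (1 - aROC) first.  "auto" reflects when the largest downward
    excursion exceeds the largest upward one.
    """
    series = aroc_series(group_a, group_b, t)
    if reflect == "auto":
        dev = series.aroc - 0.5
        reflected = bool(-dev.min() > dev.max())
    else:
        reflected = bool(reflect)
    if reflected:
        series = ArocSeries(series.t, 1.0 - series.aroc)

    truncated = truncate_aroc(series, criterion=criterion, run=run)
    if len(truncated.t) < 3:
        # criterion exceeded from (nearly) the first sample: no flat
        # baseline exists, so no onset can be localized
        start = float(series.t[0])
        return OnsetEstimate(onset=start, flat_end=start, last_local_min=start,
                             dogleg_slope=0.0, reflected=reflected,
                             degenerate=True)
    fit = fit_dogleg(truncated)
    llm = last_local_minimum(truncated)
    return OnsetEstimate(
        onset=max(fit.flat_end, llm),
        flat_end=fit.flat_end,
        last_local_min=llm,
        dogleg_slope=fit.slope,
        reflected=reflected,
        degenerate=fit.degenerate,
    )
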