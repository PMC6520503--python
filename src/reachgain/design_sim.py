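"""Synthetic designs and data for the three cursor-jump experiments.

The three experiments share a center-out reaching task in which the visual
cursor can jump 3 cm left or right mid-reach, before one of three targets
(left / center / right) is cued.  Blocks manipulate the relative reward
(R_O/R_C) and/or cueing probability (P_O/P_C) of the outer versus center
target:

* Experiment 1 (reward): 20-fold reward asymmetry, equal probabilities,
  blocks of 102 trials.
* Experiment 2 (probability): equal rewards, 2-fold probability asymmetry,
  blocks of 112 (center more probable) or 122 (outer more probable) trials.
* Experiment 3 (value): reward and probability ratios crossed over
  {0.5, 1, 2} x {0.5, 1, 2} minus the (1, 1) cell — eight blocks of 136
  trials spanning five distinct relative values r*p in {1/4, 1/2, 1, 2, 4}.

The generator draws subject-level regression parameters (intercept, slope,
risk weight) from group distributions, produces windowed response gains
that are linear in a risk-weighted log value ratio with Gaussian noise,
synthesizes force/acceleration traces with a ~125 ms onset whose analysis-
window mean equals the generating gain, and draws trial hits from a
logistic link on the corrective gain toward the cued target (calibrated to
a ~74% pooled hit rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit

from .preprocess import DEFAULT_WINDOW, GainObservation, Timeseries

__all__ = [
    "ConditionDesign",
    "TrialRecord",
    "SubjectParams",
    "GroupParams",
    "DEFAULT_GROUP_PARAMS",
    "experiment_conditions",
    "build_block_schedule",
    "sample_subject_params",
    "expected_gain",
    "simulate_gain_table",
    "synthesize_trace",
    "simulate_hits",
    "hit_probability",
    "calibrate_hit_intercept",
    "default_hit_params",
    "simulate_trial_hits",
    "simulate_cohort",
    "gain_table_to_frame",
]


@dataclass(frozen=True)
class ConditionDesign:
    """Reward / probability structure of one block.

    ``p_outer_given_jump`` / ``p_center_given_jump`` are the probabilities
    that the outer (jump-side) or center target is cued on a cursor-jump
    trial; only those two targets can be cued after a jump.
    ``unperturbed_target_probs`` is the (left, center, right) cueing
    distribution on unperturbed trials.
    """

    condition_id: str
    experiment: int
    reward_outer: float
    reward_center: float
    p_outer_given_jump: float
    p_center_given_jump: float
    unperturbed_target_probs: tuple[float, float, float]

    def __post_init__(self):
        if self.experiment not in (1, 2, 3):
            raise ValueError(f"unknown experiment {self.experiment}")
        if self.reward_outer <= 0 or self.reward_center <= 0:
            raise ValueError("rewards must be positive")
        for p in (self.p_outer_given_jump, self.p_center_given_jump,
                  *self.unperturbed_target_probs):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not math.isclose(self.p_outer_given_jump + self.p_center_given_jump, 1.0):
            raise ValueError("p_outer_given_jump + p_center_given_jump must be 1")
        if not math.isclose(sum(self.unperturbed_target_probs), 1.0):
            raise ValueError("unperturbed target probabilities must sum to 1")

    @property
    def reward_ratio(self) -> float:
        return self.reward_outer / self.reward_center

    @property
    def prob_ratio(self) -> float:
        return self.p_outer_given_jump / self.p_center_given_jump

    @property
    def relative_value(self) -> float:
        """Product of reward and probability ratios (outer vs center)."""
        return self.reward_ratio * self.prob_ratio


@dataclass(frozen=True)
class TrialRecord:
    subject_id: str
    block_id: str
    trial_index: int
    phase: str                  # "context" | "main"
    trial_type: str             # "standard" | "channel"
    jump_direction: str         # "left" | "right" | "none"
    cued_target: str            # "left" | "center" | "right"
    condition_id: str
    cue_distance: float = 15.5  # cm from start at which the target appears
    hit: bool | None = None

    def __post_init__(self):
        if self.jump_direction == "left" and self.cued_target == "right":
            raise ValueError("left jump can only cue the left or center target")
        if self.jump_direction == "right" and self.cued_target == "left":
            raise ValueError("right jump can only cue the right or center target")


@dataclass(frozen=True)
class SubjectParams:
    """Generating parameters of one synthetic subject."""

    subject_id: str
    intercept: float            # gain units (N or cm/s^2)
    slope: float                # gain units per unit log-ratio predictor
    risk_weight: float          # in [0, 1]; 0.5 = risk neutral
    noise_sd: float             # per-trial gain noise SD

    def __post_init__(self):
        if not 0.0 <= self.risk_weight <= 1.0:
            raise ValueError("risk_weight must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative (0 = noise-free "
                             "degenerate limit)")


@dataclass(frozen=True)
class GroupParams:
    """Group-level generating distribution for subject parameters.

    Defaults: intercept near the single-target-like force gain (1.0 N),
    a negative slope (corrections toward center shrink as the outer
    target's relative value rises), risk weight 0.68 (mild risk aversion),
    and 0.5 N per-trial gain noise.
    """

    intercept_mean: float = 1.0
    intercept_sd: float = 0.3
    slope_mean: float = -0.4
    slope_sd: float = 0.15
    risk_weight_mean: float = 0.68
    risk_weight_sd: float = 0.1
    noise_sd: float = 0.5


DEFAULT_GROUP_PARAMS = GroupParams()


# ---------------------------------------------------------------------------
# Condition grids


def experiment_conditions(experiment: int) -> list[ConditionDesign]:
    """The block-condition grid of one experiment."""
    if experiment == 1:
        third = (1 / 3, 1 / 3, 1 / 3)
        return [
            ConditionDesign("e1_center_rewarded", 1, 0.5, 10.0, 0.5, 0.5, third),
            ConditionDesign("e1_outer_rewarded", 1, 10.0, 0.5, 0.5, 0.5, third),
        ]
    if experiment == 2:
        return [
            ConditionDesign("e2_center_probable", 2, 1.0, 1.0, 1 / 3, 2 / 3,
                            (0.25, 0.50, 0.25)),
            ConditionDesign("e2_outer_probable", 2, 1.0, 1.0, 2 / 3, 1 / 3,
                            (0.4, 0.2, 0.4)),
        ]
    if experiment == 3:
        reward = {0.5: (5.0, 10.0), 1.0: (10.0, 10.0), 2.0: (10.0, 5.0)}
        conditions = []
        for r in (0.5, 1.0, 2.0):
            for p in (0.5, 1.0, 2.0):
                if r == 1.0 and p == 1.0:
                    continue
                r_o, r_c = reward[r]
                conditions.append(ConditionDesign(
                    f"e3_r{r:g}_p{p:g}", 3, r_o, r_c,
                    p / (1 + p), 1 / (1 + p), (0.0, 1.0, 0.0)))
        return conditions
    raise ValueError(f"unknown experiment {experiment}")


# ---------------------------------------------------------------------------
# Block schedules


def _trials(n, **kw) -> list[dict]:
    return [dict(kw) for _ in range(n)]


def _exp1_main(condition: ConditionDesign) -> list[dict]:
    spec = []
    # 36 unperturbed: 12 per target, 6 of the center trials in a channel
    for target, n_channel in (("left", 0), ("center", 6), ("right", 0)):
        spec += _trials(n_channel, trial_type="channel", jump_direction="none",
                        cued_target=target)
        spec += _trials(12 - n_channel, trial_type="standard",
                        jump_direction="none", cued_target=target)
    # 48 cursor-jump: per direction 12 outer-cued standard + 12 center-cued
    # (6 channel + 6 standard)
    for direction, outer in (("left", "left"), ("right", "right")):
        spec += _trials(12, trial_type="standard", jump_direction=direction,
                        cued_target=outer)
        spec += _trials(6, trial_type="channel", jump_direction=direction,
                        cued_target="center")
        spec += _trials(6, trial_type="standard", jump_direction=direction,
                        cued_target="center")
    return spec


def _exp2_main(condition: ConditionDesign) -> list[dict]:
    center_probable = condition.p_center_given_jump > condition.p_outer_given_jump
    if center_probable:
        unpert = {"left": 10, "center": 20, "right": 10}
        jump_counts = {"outer": 10, "center": 20}
    else:
        unpert = {"left": 20, "center": 10, "right": 20}
        jump_counts = {"outer": 20, "center": 10}
    spec = []
    for target, n in unpert.items():
        n_channel = n // 2 if target == "center" else 0
        spec += _trials(n_channel, trial_type="channel", jump_direction="none",
                        cued_target=target)
        spec += _trials(n - n_channel, trial_type="standard",
                        jump_direction="none", cued_target=target)
    for direction, outer in (("left", "left"), ("right", "right")):
        spec += _trials(jump_counts["outer"], trial_type="standard",
                        jump_direction=direction, cued_target=outer)
        n_center = jump_counts["center"]
        spec += _trials(n_center // 2, trial_type="channel",
                        jump_direction=direction, cued_target="center")
        spec += _trials(n_center - n_center // 2, trial_type="standard",
                        jump_direction=direction, cued_target="center")
    return spec


def _exp3_main(condition: ConditionDesign) -> list[dict]:
    # 10 unperturbed center-cued (5 channel + 5 standard) + 108 jump trials
    # (54 per direction: 36 channel and 72 standard overall, cue counts set
    # by the probability ratio).
    spec = []
    spec += _trials(5, trial_type="channel", jump_direction="none",
                    cued_target="center")
    spec += _trials(5, trial_type="standard", jump_direction="none",
                    cued_target="center")
    p = condition.prob_ratio
    per_dir_outer = {0.5: 18, 1.0: 27, 2.0: 36}[round(p, 6)]
    chan_outer = {0.5: 6, 1.0: 9, 2.0: 12}[round(p, 6)]
    per_dir_center = 54 - per_dir_outer
    chan_center = 18 - chan_outer
    for direction, outer in (("left", "left"), ("right", "right")):
        spec += _trials(chan_outer, trial_type="channel",
                        jump_direction=direction, cued_target=outer)
        spec += _trials(per_dir_outer - chan_outer, trial_type="standard",
                        jump_direction=direction, cued_target=outer)
        spec += _trials(chan_center, trial_type="channel",
                        jump_direction=direction, cued_target="center")
        spec += _trials(per_dir_center - chan_center, trial_type="standard",
                        jump_direction=direction, cued_target="center")
    return spec


_CONTEXT_BUILDERS = {
    # Exp 1: 18 standard unperturbed reaches, 6 per target, to show rewards.
    1: lambda c: [t for target in ("left", "center", "right")
                  for t in _trials(6, trial_type="standard",
                                   jump_direction="none", cued_target=target)],
    # Exp 2: 12 unperturbed reaches to the more probable location(s).
    2: lambda c: (
        _trials(12, trial_type="standard", jump_direction="none",
                cued_target="center")
        if c.p_center_given_jump > c.p_outer_given_jump else
        _trials(6, trial_type="standard", jump_direction="none", cued_target="left")
        + _trials(6, trial_type="standard", jump_direction="none",
                  cued_target="right")),
    # Exp 3: 18 standard unperturbed center reaches (composition unspecified
    # in the design; context trials are never analyzed).
    3: lambda c: _trials(18, trial_type="standard", jump_direction="none",
                         cued_target="center"),
}

_MAIN_BUILDERS = {1: _exp1_main, 2: _exp2_main, 3: _exp3_main}


def build_block_schedule(
    experiment: int,
    condition: ConditionDesign,
    seed: int,
    *,
    subject_id: str = "s01",
    block_id: str | None = None,
    n_context: int | None = None,
) -> list[TrialRecord]:
    """Build one block's ordered trial list for the given condition.

    Context trials come first in fixed order; the remaining (main) trials
    are shuffled with the given seed.  Trial counts per category match the
    published designs exactly: 102 trials in Experiment 1, 112/122 in
    Experiment 2 (center/outer more probable), 136 in Experiment 3.
    """
    if experiment not in _MAIN_BUILDERS:
        raise ValueError(f"unknown experiment {experiment}")
    if condition.experiment != experiment:
        raise ValueError(
            f"condition {condition.condition_id!r} belongs to experiment "
            f"{condition.experiment}, not {experiment}")
    grid_ids = {c.condition_id for c in experiment_conditions(experiment)}
    if condition.condition_id not in grid_ids:
        raise ValueError(f"condition {condition.condition_id!r} is not in the "
                         f"experiment-{experiment} design grid")

    context = _CONTEXT_BUILDERS[experiment](condition)
    if n_context is not None:
        if n_context > len(context):
            raise ValueError("n_context exceeds the design's context-trial count")
        context = context[:n_context]
    main = _MAIN_BUILDERS[experiment](condition)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(main))
    main = [main[i] for i in order]

    block = block_id or condition.condition_id
    records = []
    for i, spec in enumerate(context + main):
        records.append(TrialRecord(
            subject_id=subject_id, block_id=block, trial_index=i,
            phase="context" if i < len(context) else "main",
            condition_id=condition.condition_id, **spec))
    return records


def schedule_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in records])
    df.insert(0, "trial_id", df["subject_id"] + "_" + df["block_id"] + "_"
              + df["trial_index"].astype(str))
    return df


# ---------------------------------------------------------------------------
# Subject parameters and gains


def sample_subject_params(
    group_means: GroupParams | Mapping[str, float] = DEFAULT_GROUP_PARAMS,
    group_sds: Mapping[str, float] | None = None,
    n_subjects: int = 12,
    seed: int = 0,
) -> list[SubjectParams]:
    """Draw subject-level parameters from the group distribution.

    Intercepts and slopes are Gaussian; the risk weight is Gaussian
    truncated to [0, 1].  SDs of exactly zero are allowed as the degenerate
    limit (every subject equals the group mean); negative SDs raise.
    """
    fields_ = set(GroupParams.__dataclass_fields__)

    def _canon(mapping, suffix):
        out = {}
        for k, v in dict(mapping).items():
            key = k if k in fields_ else f"{k}{suffix}"
            if key not in fields_:
                raise ValueError(f"unknown group parameter {k!r}")
            out[key] = v
        return out

    if isinstance(group_means, GroupParams):
        gp = group_means
    else:
        gp = GroupParams(**{**asdict(DEFAULT_GROUP_PARAMS),
                            **_canon(group_means, "_mean")})
    if group_sds is not None:
        gp = GroupParams(**{**asdict(gp), **_canon(group_sds, "_sd")})
    for sd in (gp.intercept_sd, gp.slope_sd, gp.risk_weight_sd):
        if sd < 0:
            raise ValueError("group SDs must be non-negative")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")

    rng = np.random.default_rng(seed)
    intercepts = gp.intercept_mean + gp.intercept_sd * rng.standard_normal(n_subjects)
    slopes = gp.slope_mean + gp.slope_sd * rng.standard_normal(n_subjects)
    if gp.risk_weight_sd == 0:
        weights = np.full(n_subjects, min(max(gp.risk_weight_mean, 0.0), 1.0))
    else:
        a = (0.0 - gp.risk_weight_mean) / gp.risk_weight_sd
        b = (1.0 - gp.risk_weight_mean) / gp.risk_weight_sd
        weights = stats.truncnorm.rvs(
            a, b, loc=gp.risk_weight_mean, scale=gp.risk_weight_sd,
            size=n_subjects, random_state=rng)
    return [
        SubjectParams(f"s{i + 1:02d}", float(intercepts[i]), float(slopes[i]),
                      float(weights[i]), gp.noise_sd)
        for i in range(n_subjects)
    ]


def expected_gain(
    params: SubjectParams, condition: ConditionDesign, model: str = "value_risk"
) -> float:
    """Noise-free response gain of one subject in one condition.

    ``alpha_s + beta_s * x`` where x is the model's log-ratio predictor
    (risk weight ``w_s`` enters only the risk-sensitive predictor).
    """
    from .models import predictor  # local import to avoid a module cycle

    w = params.risk_weight if model == "value_risk" else None
    return params.intercept + params.slope * predictor(condition, model, w=w)


def simulate_gain_table(
    conditions: Sequence[ConditionDesign],
    subjects: Sequence[SubjectParams],
    trials_per_cell: int = 18,
    seed: int = 0,
    *,
    model: str = "value_risk",
    directions: Sequence[str] = ("left", "right"),
    channel: str = "force",
) -> list[GainObservation]:
    """Simulate windowed response gains for every subject x condition x
    jump-direction cell.

    Each observation is the expected gain plus Gaussian noise with SD
    ``noise_sd / sqrt(trials_per_cell)`` (the cell mean of
    ``trials_per_cell`` noisy trials); the sign convention is already
    direction-pooled (positive = toward center).
    """
    if not conditions:
        raise ValueError("empty condition set")
    if trials_per_cell < 1:
        raise ValueError("trials_per_cell must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for subject in subjects:
        cell_sd = subject.noise_sd / math.sqrt(trials_per_cell)
        for condition in conditions:
            mu = expected_gain(subject, condition, model)
            for direction in directions:
                out.append(GainObservation(
                    subject_id=subject.subject_id,
                    condition_id=condition.condition_id,
                    jump_direction=direction,
                    gain=float(mu + cell_sd * rng.standard_normal()),
                    n_trials=trials_per_cell,
                    channel=channel,
                ))
    return out


def gain_table_to_frame(gains: Sequence[GainObservation]) -> pd.DataFrame:
    rows = []
    for g in gains:
        d = asdict(g)
        lo, hi = d.pop("window")
        d["window_lo"], d["window_hi"] = lo, hi
        rows.append(d)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Traces


def synthesize_trace(
    gain: float,
    onset: float = 125.0,
    rise_time: float = 60.0,
    duration: float = 500.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    *,
    t_start: float = -100.0,
    channel: str = "force",
) -> Timeseries:
    """Synthesize a 1 kHz response trace with a smooth post-onset ramp.

    The deterministic part is zero before ``onset`` and follows a logistic
    ramp afterwards (midpoint at onset + rise_time/2, scale rise_time/8),
    rescaled so its mean over the 170-220 ms analysis window equals
    ``gain`` exactly; Gaussian noise is added on top.  The logistic shape
    is a modeling choice — only the onset latency and window mean are
    constrained by the analysis.
    """
    if not 0 < onset < duration:
        raise ValueError("onset must lie strictly inside (0, duration)")
    if rise_time <= 0:
        raise ValueError("rise_time must be positive")
    t = np.arange(int(t_start), int(duration) + 1)
    mid = onset + rise_time / 2.0
    scale = rise_time / 8.0
    ramp = expit((t - mid) / scale)
    ramp = np.where(t <= onset, 0.0, ramp - expit((onset - mid) / scale))
    ramp = np.clip(ramp, 0.0, None)
    lo, hi = DEFAULT_WINDOW
    window_mean = ramp[(t >= lo) & (t <= hi)].mean()
    if window_mean <= 0:
        raise ValueError("onset/rise_time leave the analysis window flat; "
                         "cannot scale the ramp to the requested gain")
    values = ramp * (gain / window_mean)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + noise_sd * rng.standard_normal(len(t))
    return Timeseries(t, values, channel=channel)


# ---------------------------------------------------------------------------
# Hits


def hit_probability(corrective_gain, params: tuple[float, float]):
    """P(hit) = logistic(a + b * gain-toward-cued-target)."""
    a, b = params
    return expit(a + b * np.asarray(corrective_gain, dtype=float))


def simulate_hits(
    corrective_gain,
    logistic_params: tuple[float, float] | None = None,
    seed: int | None = None,
):
    """Bernoulli hit draws given the corrective gain toward the cued target.

    ``corrective_gain`` may be a scalar or array; with default parameters
    the pooled hit rate under the default generator is ~= 0.74.
    """
    params = default_hit_params() if logistic_params is None else logistic_params
    p = hit_probability(corrective_gain, params)
    rng = np.random.default_rng(seed)
    draw = rng.random(np.shape(p)) < p if np.ndim(p) else rng.random() < p
    return draw


def calibrate_hit_intercept(
    signed_gains: np.ndarray,
    target_rate: float = 0.738,
    slope: float = 1.2,
    weights: np.ndarray | None = None,
) -> tuple[float, float]:
    """Solve for the logistic intercept giving the target pooled hit rate.

    ``signed_gains`` is a representative sample of corrective gains toward
    the cued target; the intercept a solves
    weighted-mean(logistic(a + b g)) = target_rate by bisection.
    """
    g = np.asarray(signed_gains, dtype=float)
    w = None if weights is None else np.asarray(weights, dtype=float)

    def pooled(a):
        return float(np.average(expit(a + slope * g), weights=w)) - target_rate

    a = brentq(pooled, -20.0, 20.0)
    return (float(a), slope)


_DEFAULT_HIT_PARAMS: tuple[float, float] | None = None


def default_hit_params() -> tuple[float, float]:
    """Default logistic hit parameters, calibrated once against the default
    generator so the pooled standard-trial hit rate is ~73.8%."""
    global _DEFAULT_HIT_PARAMS
    if _DEFAULT_HIT_PARAMS is None:
        subjects = sample_subject_params(n_subjects=60, seed=20190515)
        rng = np.random.default_rng(20190515)
        cohort_sizes = {1: 12, 2: 12, 3: 10}  # study cohort sizes
        signed, weights = [], []
        for experiment in (1, 2, 3):
            conditions = experiment_conditions(experiment)
            cue_counts = {}
            for c in conditions:
                # cue mix of the standard cursor-jump trials in one block
                recs = build_block_schedule(experiment, c, seed=0)
                cues = [r.cued_target for r in recs
                        if r.phase == "main" and r.trial_type == "standard"
                        and r.jump_direction != "none"]
                cue_counts[c.condition_id] = (
                    len(cues), sum(cue != "center" for cue in cues) / len(cues))
            total = sum(n for n, _ in cue_counts.values())
            for c in conditions:
                n_cell, frac_outer = cue_counts[c.condition_id]
                # each subject contributes equally to the pooled rate, so a
                # cell's weight is its share of the subject's standard jump
                # trials times the experiment's cohort size
                w_cell = cohort_sizes[experiment] * n_cell / total
                for s in subjects:
                    mu = expected_gain(s, c, "value_risk")
                    g = mu + s.noise_sd * rng.standard_normal(4)
                    # outer-cued trials count the gain *away* from center
                    # as corrective
                    cue_outer = rng.random(4) < frac_outer
                    signed.append(np.where(cue_outer, -g, g))
                    weights.append(np.full(4, w_cell))
        _DEFAULT_HIT_PARAMS = calibrate_hit_intercept(
            np.concatenate(signed), weights=np.concatenate(weights))
    return _DEFAULT_HIT_PARAMS


def simulate_trial_hits(
    trials: pd.DataFrame,
    subjects: Sequence[SubjectParams],
    conditions: Sequence[ConditionDesign],
    *,
    model: str = "value_risk",
    logistic_params: tuple[float, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fill the ``hit`` column of a trial table for standard jump trials.

    Each standard cursor-jump trial gets a per-trial corrective gain (the
    subject's expected gain plus trial noise, signed toward the cued
    target) and a Bernoulli hit draw through the logistic link.  Channel
    and unperturbed trials keep hit = NA.
    """
    params = default_hit_params() if logistic_params is None else logistic_params
    by_subject = {s.subject_id: s for s in subjects}
    by_condition = {c.condition_id: c for c in conditions}
    rng = np.random.default_rng(seed)

    trials = trials.copy()
    hits = np.full(len(trials), np.nan)
    mask = ((trials["trial_type"] == "standard")
            & (trials["jump_direction"] != "none")
            & (trials["phase"] == "main"))
    idx = np.flatnonzero(mask.to_numpy())
    for i in idx:
        row = trials.iloc[i]
        s = by_subject[row["subject_id"]]
        c = by_condition[row["condition_id"]]
        g = expected_gain(s, c, model) + s.noise_sd * rng.standard_normal()
        toward_cued = -g if row["cued_target"] != "center" else g
        hits[i] = rng.random() < hit_probability(toward_cued, params)
    trials["hit"] = pd.array(
        [bool(h) if not np.isnan(h) else pd.NA for h in hits], dtype="boolean")
    return trials


# ---------------------------------------------------------------------------
# Cohort driver


def simulate_cohort(
    experiment: int,
    n_subjects: int = 10,
    seed: int = 0,
    *,
    group_params: GroupParams = DEFAULT_GROUP_PARAMS,
    model: str = "value_risk",
    traces: bool = False,
    trace_noise_sd: float = 0.15,
) -> dict:
    """Simulate a full cohort: schedules, hits, and (optionally) traces.

    Returns a dict with ``conditions``, ``subjects`` (true generating
    parameters), ``trials`` and, when ``traces`` is set, a long-format
    ``traces`` table for main-phase channel trials (force) restricted to
    channel trials to keep tables tractable.
    """
    root = np.random.SeedSequence(seed)
    seeds = root.generate_state(4)
    conditions = experiment_conditions(experiment)
    subjects = sample_subject_params(group_params, n_subjects=n_subjects,
                                     seed=int(seeds[0]))

    all_trials = []
    for si, subject in enumerate(subjects):
        for ci, condition in enumerate(conditions):
            block_seed = int((seeds[1] + 997 * si + 31 * ci) % (2**31 - 1))
            recs = build_block_schedule(
                experiment, condition, block_seed,
                subject_id=subject.subject_id,
                block_id=f"b{ci + 1:02d}_{condition.condition_id}")
            all_trials.append(schedule_to_frame(recs))
    trials = pd.concat(all_trials, ignore_index=True)
    trials = simulate_trial_hits(trials, subjects, conditions, model=model,
                                 seed=int(seeds[2]))

    out = {
        "conditions": pd.DataFrame([asdict(c) for c in conditions]),
        "subjects": pd.DataFrame([asdict(s) for s in subjects]),
        "trials": trials,
    }
    if traces:
        out["traces"] = _simulate_channel_traces(
            trials, subjects, conditions, model=model,
            noise_sd=trace_noise_sd, seed=int(seeds[3]))
    return out


def _simulate_channel_traces(trials, subjects, conditions, *, model,
                             noise_sd, seed) -> pd.DataFrame:
    by_subject = {s.subject_id: s for s in subjects}
    by_condition = {c.condition_id: c for c in conditions}
    rng = np.random.default_rng(seed)
    sel = trials[(trials["trial_type"] == "channel") & (trials["phase"] == "main")]
    frames = []
    for _, row in sel.iterrows():
        s = by_subject[row["subject_id"]]
        c = by_condition[row["condition_id"]]
        direction = row["jump_direction"]
        if direction == "none":
            gain = 0.0
        else:
            g = expected_gain(s, c, model) + s.noise_sd * rng.standard_normal()
            gain = -g if direction == "right" else g  # raw sign convention
        ts = synthesize_trace(gain, noise_sd=noise_sd,
                              seed=int(rng.integers(2**31 - 1)))
        frames.append(pd.DataFrame({
            "trial_id": row["trial_id"], "t_ms": ts.t, "force_N": ts.values,
            "accel_cm_s2": np.nan,
        }))
    return pd.concat(frames, ignore_index=True)
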