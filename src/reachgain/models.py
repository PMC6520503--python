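"""Gain predictors and the hierarchical Bayesian model of response gains.

Four models of how the windowed response gain G of subject s in condition c
depends on the block's reward ratio r = R_O/R_C and cueing-probability
ratio p = P_O/P_C (outer vs center target):

    probability    x = ln p
    reward         x = ln r
    value_neutral  x = ln(r p)                       (risk-neutral value)
    value_risk     x = 2 [(1 - w) ln r + w ln p],    w in [0, 1]

with G_{s,c} ~ Normal(alpha_s + beta_s x_c, sigma).  The risk weight w
mixes the reward and probability ratios: w = 0.5 reproduces the
risk-neutral value predictor exactly (the factor 2 makes the reduction
exact rather than absorbed into the slope), w > 0.5 is risk-averse
(probability-dominated) and w < 0.5 risk-seeking (reward-dominated).

Subject parameters are partially pooled: alpha_s and beta_s are Gaussian
around group means, w_s is a Gaussian truncated to [0, 1], with weak
priors — Normal(0, 10000) on group means, half-Cauchy(5) on group SDs and
on the shared observation noise sigma.

The posterior is sampled with an affine-invariant ensemble sampler (emcee)
over a non-centered parameterization, with scale parameters sampled on the
log scale and w through a logit transform (Jacobians included).  Walkers
are grouped into pseudo-chains for the split-R-hat diagnostic, a MAP
estimate is refined from the best draw, and pointwise log-likelihood draws
are retained for WAIC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import emcee
import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, log_ndtr

from .preprocess import GainObservation

__all__ = [
    "MODEL_NAMES",
    "ModelSpec",
    "SamplerConfig",
    "HierarchicalPosterior",
    "predictor",
    "fit_hierarchical",
    "compute_rhat",
    "posterior_predict",
    "variance_explained",
]

MODEL_NAMES = ("probability", "reward", "value_neutral", "value_risk")

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ModelSpec:
    predictor: str = "value_risk"
    gain_channel: str = "force"

    def __post_init__(self):
        if self.predictor not in MODEL_NAMES:
            raise ValueError(f"unknown predictor {self.predictor!r}; "
                             f"expected one of {MODEL_NAMES}")


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC schedule, in sampler steps (matching a single-chain reading of
    tune 1000 / 30000 draws / first 5000 discarded).

    ``reduced()`` gives the fast profile used for tests and simulation
    studies (tune 500, draws 2000, burn 500).
    """

    tune_draws: int = 1000
    draws: int = 30000
    burn_discard: int = 5000
    seed: int = 0
    chains: int = 4          # pseudo-chains (walker groups) for R-hat
    nwalkers: int | None = None
    max_stored_steps: int = 4000
    waic_draws: int = 4000   # posterior draws retained for pointwise loglik

    def __post_init__(self):
        if self.burn_discard >= self.draws:
            raise ValueError("burn_discard must be smaller than draws")

    @classmethod
    def reduced(cls, seed: int = 0, **kw) -> "SamplerConfig":
        return cls(tune_draws=500, draws=2000, burn_discard=500, seed=seed, **kw)


def predictor(condition, spec: ModelSpec | str, w: float | None = None) -> float:
    """The model's scalar predictor x for one condition.

    ``condition`` needs ``reward_ratio`` and ``prob_ratio`` attributes (or
    ``reward_outer``/``reward_center`` etc.); ``w`` must be supplied exactly
    for the risk-sensitive model.
    """
    name = spec.predictor if isinstance(spec, ModelSpec) else spec
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown predictor {name!r}")
    r = getattr(condition, "reward_ratio", None)
    p = getattr(condition, "prob_ratio", None)
    if r is None:
        r = condition.reward_outer / condition.reward_center
    if p is None:
        p = condition.p_outer_given_jump / condition.p_center_given_jump
    if r <= 0 or p <= 0:
        raise ValueError("reward and probability ratios must be positive")
    if name == "value_risk":
        if w is None:
            raise ValueError("the risk-sensitive predictor requires w")
        return 2.0 * ((1.0 - w) * math.log(r) + w * math.log(p))
    if w is not None:
        raise ValueError(f"w is only meaningful for value_risk, not {name}")
    if name == "probability":
        return math.log(p)
    if name == "reward":
        return math.log(r)
    return math.log(r * p)  # value_neutral


# ---------------------------------------------------------------------------
# Log-posterior


def _half_cauchy_logpdf(x, scale=5.0):
    return math.log(2.0 / (math.pi * scale)) - np.log1p((x / scale) ** 2)


def _norm_logpdf(z):
    return -0.5 * (z**2 + _LOG_2PI)


def _truncnorm01_log_z(mu, sd):
    """log normalizing constant of Normal(mu, sd) truncated to [0, 1]."""
    la = log_ndtr((0.0 - mu) / sd)
    lb = log_ndtr((1.0 - mu) / sd)
    return lb + np.log1p(-np.exp(np.minimum(la - lb, -1e-12)))


class _HierarchicalLogProb:
    """Vectorized log-posterior over walker coordinate matrices.

    Layout (S subjects): [mu_a, log_sd_a, mu_b, log_sd_b, log_sigma,
    (mu_w, log_sd_w,) z_a[0..S), z_b[0..S) (, z_w[0..S))].  All subject
    effects are non-centered — alpha_s = mu_a + sd_a z_a and likewise
    w_s = mu_w + sd_w z_w — which removes the funnel when a group SD
    shrinks toward zero; proposals taking any w_s outside [0, 1] are
    rejected, which together with the standard-normal density on z_w and
    the truncation normalizer realizes the [0, 1]-truncated Gaussian on w.
    """

    PRIOR_MEAN_SD = 10000.0

    def __init__(self, y, subject_idx, log_r, log_p, model: str):
        self.y = np.asarray(y, dtype=float)
        self.s = np.asarray(subject_idx, dtype=int)
        self.lr = np.asarray(log_r, dtype=float)
        self.lp = np.asarray(log_p, dtype=float)
        self.model = model
        self.n_subjects = int(self.s.max()) + 1
        self.n_obs = len(self.y)
        self.risk = model == "value_risk"
        S = self.n_subjects
        self.ndim = (3 * S + 7) if self.risk else (2 * S + 5)
        if not self.risk:
            self.x_fixed = {
                "probability": self.lp,
                "reward": self.lr,
                "value_neutral": self.lr + self.lp,
            }[model]

    def unpack(self, theta):
        theta = np.atleast_2d(theta)
        S = self.n_subjects
        mu_a, log_sd_a = theta[:, 0], theta[:, 1]
        mu_b, log_sd_b = theta[:, 2], theta[:, 3]
        log_sigma = theta[:, 4]
        k = 5
        out = {"mu_a": mu_a, "sd_a": np.exp(log_sd_a),
               "mu_b": mu_b, "sd_b": np.exp(log_sd_b),
               "sigma": np.exp(log_sigma)}
        if self.risk:
            out["mu_w"] = theta[:, 5]
            out["sd_w"] = np.exp(theta[:, 6])
            k = 7
        out["z_a"] = theta[:, k:k + S]
        out["z_b"] = theta[:, k + S:k + 2 * S]
        if self.risk:
            out["z_w"] = theta[:, k + 2 * S:k + 3 * S]
            out["w"] = out["mu_w"][:, None] + out["sd_w"][:, None] * out["z_w"]
        out["alpha"] = out["mu_a"][:, None] + out["sd_a"][:, None] * out["z_a"]
        out["beta"] = out["mu_b"][:, None] + out["sd_b"][:, None] * out["z_b"]
        return out

    def pointwise_loglik(self, theta):
        p = self.unpack(theta)
        alpha = p["alpha"][:, self.s]
        beta = p["beta"][:, self.s]
        if self.risk:
            w = p["w"][:, self.s]
            x = 2.0 * ((1.0 - w) * self.lr + w * self.lp)
        else:
            x = self.x_fixed
        resid = self.y - (alpha + beta * x)
        sigma = p["sigma"][:, None]
        return -0.5 * (resid / sigma) ** 2 - np.log(sigma) - 0.5 * _LOG_2PI

    def __call__(self, theta):
        theta = np.atleast_2d(theta)
        p = self.unpack(theta)
        lp = np.zeros(theta.shape[0])
        # group means: Normal(0, 10000)
        lp += _norm_logpdf(p["mu_a"] / self.PRIOR_MEAN_SD) - math.log(self.PRIOR_MEAN_SD)
        lp += _norm_logpdf(p["mu_b"] / self.PRIOR_MEAN_SD) - math.log(self.PRIOR_MEAN_SD)
        # group SDs and sigma: half-Cauchy(5), sampled on the log scale
        for key, col in (("sd_a", 1), ("sd_b", 3), ("sigma", 4)):
            lp += _half_cauchy_logpdf(p[key]) + theta[:, col]  # + log|d sd/d log sd|
        # non-centered subject effects
        lp += _norm_logpdf(p["z_a"]).sum(axis=1)
        lp += _norm_logpdf(p["z_b"]).sum(axis=1)
        if self.risk:
            lp += _norm_logpdf(p["mu_w"] / self.PRIOR_MEAN_SD) - math.log(self.PRIOR_MEAN_SD)
            lp += _half_cauchy_logpdf(p["sd_w"]) + theta[:, 6]
            w = p["w"]
            ok = np.all((w >= 0.0) & (w <= 1.0), axis=1)
            lp += _norm_logpdf(p["z_w"]).sum(axis=1)
            lp -= w.shape[1] * _truncnorm01_log_z(p["mu_w"], p["sd_w"])
            lp = np.where(ok, lp, -np.inf)
        lp += self.pointwise_loglik(theta).sum(axis=1)
        return np.where(np.isfinite(lp), lp, -np.inf)


@dataclass
class HierarchicalPosterior:
    """Posterior draws and summaries of the hierarchical gain model."""

    spec: ModelSpec
    config: SamplerConfig
    param_names: list[str]
    draws: dict                      # name -> (chains, draws[, subjects]) arrays
    rhat: dict                       # name -> float (max over subjects)
    map_estimate: dict               # name -> float / per-subject array
    log_likelihood: np.ndarray       # (waic_draws, n_obs)
    data: pd.DataFrame               # observations used in the fit
    logprob: object = field(repr=False, default=None)

    def flat(self, name: str) -> np.ndarray:
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    def summary(self, hdi_prob: float = 0.95) -> pd.DataFrame:
        lo_q, hi_q = (1 - hdi_prob) / 2, 1 - (1 - hdi_prob) / 2
        rows = []
        for name in self.param_names:
            flat = self.flat(name)
            if flat.ndim == 1:
                flat = flat[:, None]
            for j in range(flat.shape[1]):
                label = name if flat.shape[1] == 1 else f"{name}[{j}]"
                col = flat[:, j]
                rows.append({
                    "parameter": label,
                    "mean": col.mean(),
                    "sd": col.std(ddof=1),
                    f"hdi_{100 * lo_q:g}": np.quantile(col, lo_q),
                    f"hdi_{100 * hi_q:g}": np.quantile(col, hi_q),
                    "rhat": self.rhat[name],
                })
        return pd.DataFrame(rows)

    def max_rhat(self) -> float:
        return max(self.rhat.values())


def _as_frame(gains, conditions) -> pd.DataFrame:
    if isinstance(gains, pd.DataFrame):
        df = gains.copy()
    else:
        df = pd.DataFrame([{
            "subject_id": g.subject_id, "condition_id": g.condition_id,
            "gain": g.gain, "jump_direction": g.jump_direction,
        } for g in gains])
    if conditions is None:
        raise ValueError("conditions (ConditionDesign sequence or mapping) required")
    if isinstance(conditions, Mapping):
        lookup = dict(conditions)
    else:
        lookup = {c.condition_id: c for c in conditions}
    df["log_r"] = [math.log(lookup[c].reward_ratio) for c in df["condition_id"]]
    df["log_p"] = [math.log(lookup[c].prob_ratio) for c in df["condition_id"]]
    return df


def fit_hierarchical(
    gains,
    spec: ModelSpec,
    config: SamplerConfig | None = None,
    conditions=None,
    *,
    rhat_threshold: float = 1.05,
) -> HierarchicalPosterior:
    """Fit the hierarchical gain model by ensemble MCMC.

    Parameters
    ----------
    gains : sequence of GainObservation or DataFrame with subject_id,
        condition_id and gain columns.
    spec : which predictor to fit.
    config : sampler schedule; defaults to the full schedule
        (tune 1000, draws 30000, burn 5000).
    conditions : ConditionDesign sequence or id->design mapping, used to
        compute the log reward/probability ratios per observation.

    A warning is issued (never an exception) when the largest split-R-hat
    exceeds ``rhat_threshold``.
    """
    config = config or SamplerConfig()
    df = _as_frame(gains, conditions)
    subjects = sorted(df["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    if df["condition_id"].nunique() < 2:
        raise ValueError("need at least 2 conditions (single-condition input "
                         "cannot identify a slope)")
    s_idx = df["subject_id"].map({s: i for i, s in enumerate(subjects)}).to_numpy()
    y = df["gain"].to_numpy(dtype=float)

    lp = _HierarchicalLogProb(y, s_idx, df["log_r"].to_numpy(),
                              df["log_p"].to_numpy(), spec.predictor)
    ndim = lp.ndim
    nwalkers = config.nwalkers or max(2 * ndim + 2, 64)
    nwalkers += nwalkers % 2

    rng = np.random.default_rng(config.seed)
    p0 = _initial_walkers(lp, df, subjects, nwalkers, rng)

    total_steps = config.tune_draws + config.draws
    thin = max(1, math.ceil(total_steps / config.max_stored_steps))
    nsteps = math.ceil(total_steps / thin)
    burn_stored = math.ceil((config.tune_draws + config.burn_discard) / thin)

    # differential-evolution moves mix far better than the default stretch
    # move on this correlated hierarchical posterior
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(nwalkers, ndim, lp, vectorize=True,
                                    moves=moves)
    state = emcee.State(
        p0, random_state=np.random.RandomState(config.seed % (2**32)).get_state())
    sampler.run_mcmc(state, nsteps, thin_by=thin, progress=False)
    chain = sampler.get_chain()[burn_stored:]          # (steps, walkers, ndim)

    draws, rhat, names = _collect_draws(lp, chain, config.chains, subjects)
    if max(rhat.values()) > rhat_threshold:
        warnings.warn(
            f"split-R-hat up to {max(rhat.values()):.3f} exceeds "
            f"{rhat_threshold}; chains may not have converged", RuntimeWarning)

    flat = chain.reshape(-1, ndim)
    keep = min(config.waic_draws, flat.shape[0])
    sel = np.linspace(0, flat.shape[0] - 1, keep).astype(int)
    log_likelihood = lp.pointwise_loglik(flat[sel])

    map_estimate = _map_estimate(lp, flat, subjects)

    return HierarchicalPosterior(
        spec=spec, config=config, param_names=names, draws=draws, rhat=rhat,
        map_estimate=map_estimate, log_likelihood=log_likelihood, data=df,
        logprob=lp)


def _initial_walkers(lp, df, subjects, nwalkers, rng):
    """Data-informed, mildly overdispersed starting ensemble."""
    x0 = df["log_r"].to_numpy() + df["log_p"].to_numpy()  # neutral-value axis
    alpha0, beta0 = [], []
    for s in subjects:
        sub = df[df["subject_id"] == s]
        xs = sub["log_r"].to_numpy() + sub["log_p"].to_numpy()
        ys = sub["gain"].to_numpy()
        if np.ptp(xs) > 0:
            b, a = np.polyfit(xs, ys, 1)
        else:
            a, b = ys.mean(), 0.0
        alpha0.append(a)
        beta0.append(b)
    alpha0, beta0 = np.array(alpha0), np.array(beta0)
    mu_a0, mu_b0 = alpha0.mean(), beta0.mean()
    sd_a0 = max(alpha0.std(), 0.05)
    sd_b0 = max(beta0.std(), 0.05)
    resid_sd = max(np.std(df["gain"]), 0.05)

    S = len(subjects)
    base = [mu_a0, math.log(sd_a0), mu_b0, math.log(sd_b0), math.log(resid_sd)]
    if lp.risk:
        base += [0.5, math.log(0.15)]
    base += list((alpha0 - mu_a0) / sd_a0)
    base += list((beta0 - mu_b0) / sd_b0)
    if lp.risk:
        base += [0.0] * S  # u_w = 0 -> w = 0.5
    base = np.array(base)
    p0 = base + 0.05 * rng.standard_normal((nwalkers, lp.ndim))
    return p0


def _collect_draws(lp, chain, n_chains, subjects):
    """Reshape (steps, walkers, ndim) into per-parameter (chains, draws)
    arrays on the natural scale."""
    steps, walkers, ndim = chain.shape
    per = walkers // n_chains
    grouped = chain[:, :per * n_chains].reshape(steps, n_chains, per, ndim)
    # (chains, steps*per, ndim)
    grouped = grouped.transpose(1, 0, 2, 3).reshape(n_chains, steps * per, ndim)

    p = lp.unpack(grouped.reshape(-1, ndim))
    n_total = n_chains * steps * per

    def shape(name):
        arr = p[name]
        return arr.reshape(n_chains, steps * per, *arr.shape[1:])

    draws = {
        "alpha_mu": shape("mu_a"), "alpha_sd": shape("sd_a"),
        "beta_mu": shape("mu_b"), "beta_sd": shape("sd_b"),
        "sigma": shape("sigma"),
        "alpha": shape("alpha"), "beta": shape("beta"),
    }
    names = ["alpha_mu", "beta_mu", "alpha_sd", "beta_sd", "sigma"]
    if lp.risk:
        draws["w_mu"] = shape("mu_w")
        draws["w_sd"] = shape("sd_w")
        draws["w"] = shape("w")
        # mean of the group-level truncated-Gaussian w distribution: the
        # group-level risk weight on the observable [0, 1] scale
        mu_w, sd_w = draws["w_mu"], draws["w_sd"]
        a = (0.0 - mu_w) / sd_w
        b = (1.0 - mu_w) / sd_w
        draws["w_group_mean"] = stats.truncnorm.mean(a, b, loc=mu_w, scale=sd_w)
        names = ["alpha_mu", "beta_mu", "w_mu", "w_group_mean", "alpha_sd",
                 "beta_sd", "w_sd", "sigma"]
    names += ["alpha", "beta"] + (["w"] if lp.risk else [])

    rhat = {}
    for name, arr in draws.items():
        if arr.ndim == 2:
            rhat[name] = compute_rhat(arr)
        else:
            rhat[name] = max(compute_rhat(arr[:, :, j])
                             for j in range(arr.shape[2]))
    return draws, rhat, names


def _map_estimate(lp, flat, subjects):
    """Refine the best posterior draw into a MAP point with L-BFGS."""
    logp = lp(flat[np.linspace(0, len(flat) - 1, min(2000, len(flat))).astype(int)])
    start_pool = flat[np.linspace(0, len(flat) - 1, min(2000, len(flat))).astype(int)]
    best = start_pool[np.argmax(logp)]
    res = optimize.minimize(lambda th: -float(lp(th[None, :])[0]), best,
                            method="L-BFGS-B",
                            options={"maxiter": 500})
    p = lp.unpack(res.x[None, :])
    out = {
        "alpha_mu": float(p["mu_a"][0]), "alpha_sd": float(p["sd_a"][0]),
        "beta_mu": float(p["mu_b"][0]), "beta_sd": float(p["sd_b"][0]),
        "sigma": float(p["sigma"][0]),
        "alpha": p["alpha"][0].copy(), "beta": p["beta"][0].copy(),
        "subjects": list(subjects),
    }
    if lp.risk:
        out["w_mu"] = float(p["mu_w"][0])
        out["w_sd"] = float(p["sd_w"][0])
        out["w"] = p["w"][0].copy()
    return out


def compute_rhat(chains) -> float:
    """Gelman-Rubin split-R-hat of one scalar parameter.

    ``chains`` is (n_chains, n_draws); each chain is split in half, and
    R-hat = sqrt(((n-1)/n W + B/n) / W) over the split chains.
    """
    arr = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = arr.shape
    if n < 4:
        raise ValueError("chains too short to split (need >= 4 draws)")
    half = n // 2
    split = np.vstack([arr[:, :half], arr[:, half:2 * half]])
    n = half
    means = split.mean(axis=1)
    variances = split.var(axis=1, ddof=1)
    w = variances.mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else np.inf
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def posterior_predict(
    posterior: HierarchicalPosterior,
    conditions=None,
    x=None,
    *,
    kind: str = "mean",
    seed: int = 0,
) -> pd.DataFrame:
    """Posterior-predictive gain bands over the predictor axis.

    ``kind="mean"`` gives the group-level regression line
    mu_alpha + mu_beta x per posterior draw; ``kind="new_subject"`` draws a
    new subject's parameters and observation noise on top.  Returns one row
    per condition/x with the predictive mean and central 50% and 95%
    credible intervals.  For the risk-sensitive model, conditions are
    placed on the x axis at the posterior-mean group risk weight.
    """
    if x is None:
        if conditions is None:
            raise ValueError("provide conditions or an x grid")
        w_hat = (float(posterior.flat("w_mu").mean())
                 if posterior.spec.predictor == "value_risk" else None)
        x = np.array([predictor(c, posterior.spec.predictor, w=w_hat)
                      for c in conditions])
        ids = [c.condition_id for c in conditions]
    else:
        x = np.asarray(x, dtype=float)
        ids = [f"x={v:g}" for v in x]

    mu_a = posterior.flat("alpha_mu")
    mu_b = posterior.flat("beta_mu")
    pred = mu_a[:, None] + mu_b[:, None] * x[None, :]
    if kind == "new_subject":
        rng = np.random.default_rng(seed)
        sd_a = posterior.flat("alpha_sd")
        sd_b = posterior.flat("beta_sd")
        sigma = posterior.flat("sigma")
        pred = pred + (sd_a[:, None] * rng.standard_normal(pred.shape)
                       + (sd_b[:, None] * rng.standard_normal(pred.shape)) * x[None, :]
                       + sigma[:, None] * rng.standard_normal(pred.shape))
    elif kind != "mean":
        raise ValueError("kind must be 'mean' or 'new_subject'")

    q = np.quantile(pred, [0.025, 0.25, 0.75, 0.975], axis=0)
    return pd.DataFrame({
        "condition_id": ids, "x": x, "mean": pred.mean(axis=0),
        "lo95": q[0], "lo50": q[1], "hi50": q[2], "hi95": q[3],
    })


def variance_explained(posterior: HierarchicalPosterior, gains=None,
                       conditions=None) -> float:
    """R^2 of condition-mean gains against posterior-mean predictions.

    Fitted values use each subject's posterior-mean parameters; observed
    and fitted values are averaged within condition before computing
    1 - SS_resid / SS_total.  By default the observations used in the fit
    are scored.
    """
    df = posterior.data if gains is None else _as_frame(gains, conditions)
    alpha = posterior.flat("alpha").mean(axis=0)
    beta = posterior.flat("beta").mean(axis=0)
    subjects = sorted(df["subject_id"].unique())
    s_idx = df["subject_id"].map({s: i for i, s in enumerate(subjects)}).to_numpy()
    if posterior.spec.predictor == "value_risk":
        w = posterior.flat("w").mean(axis=0)[s_idx]
        x = 2.0 * ((1 - w) * df["log_r"].to_numpy() + w * df["log_p"].to_numpy())
    else:
        x = {
            "probability": df["log_p"],
            "reward": df["log_r"],
            "value_neutral": df["log_r"] + df["log_p"],
        }[posterior.spec.predictor].to_numpy()
    fitted = alpha[s_idx] + beta[s_idx] * x

    tmp = pd.DataFrame({"condition_id": df["condition_id"],
                        "obs": df["gain"].to_numpy(), "fit": fitted})
    means = tmp.groupby("condition_id").mean()
    obs = means["obs"].to_numpy()
    fit = means["fit"].to_numpy()
    ss_total = float(np.sum((obs - obs.mean()) ** 2))
    if ss_total == 0:
        raise ValueError("zero-variance condition means")
    return 1.0 - float(np.sum((obs - fit) ** 2)) / ss_total
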