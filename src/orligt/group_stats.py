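"""Preregistered 2x2 group-level inference.

Three Bayesian linear models, each with dummy-coded main effects for
alcohol and mood and their product interaction:

1. winning-deck draws in the final 60 trials, judged against a region of
   practical equivalence (ROPE) of +/-3 draws;
2. the reward learning rate (subjects' posterior-mean estimates), judged
   by whether the 95% credible interval excludes 0;
3. the punishment learning rate, same rule.

Sampling uses an adaptive random-walk Metropolis kernel on
(coefficients, log sigma); the posterior is low-dimensional and close to
Gaussian, where this kernel mixes well. Priors (the "weakly_informative"
preset) follow standard conventions: Normal(0, 2.5*SD(y)) on the effect
coefficients, Student-t(3, median(y), 2.5*MAD(y)) on the intercept, and
half-Student-t(3, 0, 2.5*SD(y)) on the residual scale. The "flat" preset
replaces the effect-coefficient priors with improper flat ones, mirroring
regression-software defaults, for the prior sensitivity analysis.

Also here: the design power analysis for the 2x2 interaction via the
noncentral F distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats

from .behavior_metrics import behavior_table, mood_responder_filter
from .inference import FitResult
from .synthetic_study import StudyDataset

COEF_NAMES = ("intercept", "alcohol", "mood", "interaction")


@dataclass(frozen=True)
class RopeSpec:
    """Region of practical equivalence in outcome units."""

    lower: float = -3.0
    upper: float = 3.0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("ROPE lower bound must be below the upper bound")


@dataclass
class PosteriorSummary:
    """One coefficient's posterior: mean, 95% equal-tailed CI, ROPE share."""

    name: str
    mean: float
    ci_low: float
    ci_high: float
    rhat: float
    ess: float
    rope_fraction: float | None = None
    decision: str | None = None

    @property
    def ci_excludes_zero(self) -> bool:
        return self.ci_low > 0 or self.ci_high < 0


@dataclass
class LinearSamplerConfig:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1500
    seed: int = 0


@dataclass
class LinearModelResult:
    """Posterior draws and summaries for one 2x2 linear model."""

    draws: dict[str, np.ndarray]  # name -> (chains, draws)
    summaries: dict[str, PosteriorSummary]
    diagnostics: dict

    def coefficient_draws(self, name: str) -> np.ndarray:
        return self.draws[name].ravel()


def _mad(y: np.ndarray) -> float:
    return float(np.median(np.abs(y - np.median(y))) * 1.4826)


def fit_2x2_linear(
    outcome: np.ndarray,
    alcohol: np.ndarray,
    mood: np.ndarray,
    priors: str = "weakly_informative",
    sampler: LinearSamplerConfig | None = None,
) -> LinearModelResult:
    """Bayesian linear regression of ``outcome`` on the 2x2 design.

    ``alcohol`` and ``mood`` are 0/1 indicators; the design matrix is
    [1, alcohol, mood, alcohol*mood]. Returns draws, equal-tailed 95%
    summaries, and split-Rhat/ESS diagnostics.
    """
    y = np.asarray(outcome, dtype=float)
    a = np.asarray(alcohol, dtype=int)
    m = np.asarray(mood, dtype=int)
    if not (len(y) == len(a) == len(m)):
        raise ValueError("outcome, alcohol and mood must have equal length")
    if not np.all(np.isfinite(y)):
        raise ValueError("outcome must be finite")
    for aa in (0, 1):
        for mm in (0, 1):
            if np.sum((a == aa) & (m == mm)) < 2:
                raise ValueError(f"design cell ({aa}, {mm}) has fewer than 2 subjects")
    if priors not in ("weakly_informative", "flat"):
        raise ValueError(f"unknown prior preset {priors!r}")
    cfg = sampler or LinearSamplerConfig()

    X = np.column_stack([np.ones_like(y), a, m, a * m]).astype(float)
    sd_y = max(float(np.std(y)), 1e-6)
    coef_scale = 2.5 * sd_y
    int_loc = float(np.median(y))
    int_scale = max(2.5 * _mad(y), 1e-6)

    def log_post(w: np.ndarray) -> float:
        beta, log_sigma = w[:4], w[4]
        sigma = np.exp(log_sigma)
        resid = y - X @ beta
        ll = -len(y) * (log_sigma + 0.5 * np.log(2 * np.pi)) - 0.5 * np.sum(resid**2) / sigma**2
        lp = stats.t.logpdf(beta[0], df=3, loc=int_loc, scale=int_scale)
        if priors == "weakly_informative":
            lp += -0.5 * np.sum((beta[1:] / coef_scale) ** 2)
        lp += stats.t.logpdf(sigma, df=3, scale=coef_scale)  # half-t (constant factor dropped)
        lp += log_sigma  # Jacobian of the log-sigma parameterization
        return float(ll + lp)

    # start chains near the least-squares solution
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    sigma_ols = max(float(np.std(y - X @ beta_ols)), 1e-3)
    w0 = np.concatenate([beta_ols, [np.log(sigma_ols)]])

    master = np.random.default_rng(cfg.seed)
    all_draws = np.empty((cfg.chains, cfg.draws, 5))
    for c in range(cfg.chains):
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        w = w0 + 0.1 * rng.standard_normal(5) * np.maximum(np.abs(w0), 1.0)
        step = np.full(5, 0.1) * np.maximum(np.abs(w0), 1.0)
        lp = log_post(w)
        for it in range(cfg.warmup + cfg.draws):
            in_warmup = it < cfg.warmup
            for j in range(5):
                w_prop = w.copy()
                w_prop[j] += step[j] * rng.standard_normal()
                lp_prop = log_post(w_prop)
                acc = np.log(rng.uniform()) < lp_prop - lp
                if acc:
                    w, lp = w_prop, lp_prop
                if in_warmup:
                    step[j] *= np.exp(0.05 * (float(acc) - 0.44))
            if not in_warmup:
                all_draws[c, it - cfg.warmup] = w

    names = list(COEF_NAMES) + ["sigma"]
    draws = {n: all_draws[:, :, j].copy() for j, n in enumerate(names)}
    draws["sigma"] = np.exp(draws["sigma"])

    idata = az.from_dict(posterior=draws)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    summaries = {}
    for n in names:
        flat = draws[n].ravel()
        lo, hi = np.percentile(flat, [2.5, 97.5])
        summaries[n] = PosteriorSummary(
            name=n, mean=float(flat.mean()), ci_low=float(lo), ci_high=float(hi),
            rhat=float(rhat[n].values), ess=float(ess[n].values),
        )
    max_rhat = max(s.rhat for s in summaries.values())
    diagnostics = {
        "max_rhat": max_rhat,
        "min_ess": min(s.ess for s in summaries.values()),
        "priors": priors,
        "warnings": [] if max_rhat <= 1.05 else [f"max split-Rhat {max_rhat:.3f} > 1.05"],
    }
    return LinearModelResult(draws=draws, summaries=summaries, diagnostics=diagnostics)


def rope_summary(draws: np.ndarray, rope: RopeSpec) -> tuple[float, str]:
    """Fraction of draws inside the ROPE plus a decision label.

    "effect" when the 95% equal-tailed CI falls entirely outside the ROPE,
    "practically null" when entirely inside, otherwise "inconclusive".
    """
    flat = np.asarray(draws, dtype=float).ravel()
    if len(flat) < 100:
        raise ValueError("need at least 100 posterior draws")
    fraction = float(np.mean((flat >= rope.lower) & (flat <= rope.upper)))
    lo, hi = np.percentile(flat, [2.5, 97.5])
    if hi < rope.lower or lo > rope.upper:
        decision = "effect"
    elif lo >= rope.lower and hi <= rope.upper:
        decision = "practically null"
    else:
        decision = "inconclusive"
    return fraction, decision


def power_2x2_interaction(n_per_cell: int, eta_sq: float, alpha: float = 0.05) -> float:
    """Power to detect a 2x2 interaction of partial eta-squared ``eta_sq``.

    Effect size f^2 = eta^2 / (1 - eta^2); noncentrality lambda = f^2 * N
    with N = 4 * n_per_cell; power = P(F'(1, N-4, lambda) > F_crit(alpha)).
    """
    if n_per_cell < 2:
        raise ValueError("n_per_cell must be >= 2")
    if not 0 < eta_sq < 1:
        raise ValueError("eta_sq must be in (0, 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    N = 4 * n_per_cell
    f2 = eta_sq / (1 - eta_sq)
    lam = f2 * N
    crit = stats.f.isf(alpha, 1, N - 4)
    return float(stats.ncf.sf(crit, 1, N - 4, lam))


@dataclass
class SuiteReport:
    """The three preregistered models plus per-coefficient summaries."""

    models: dict[str, LinearModelResult]
    rope: RopeSpec
    n_subjects: int

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for model_name, res in self.models.items():
            for coef in ("alcohol", "mood", "interaction"):
                s = res.summaries[coef]
                rows.append(
                    {
                        "model": model_name,
                        "coefficient": coef,
                        "estimate": s.mean,
                        "ci_low": s.ci_low,
                        "ci_high": s.ci_high,
                        "ci_excludes_zero": s.ci_excludes_zero,
                        "rope_fraction": s.rope_fraction,
                        "decision": s.decision,
                    }
                )
        return pd.DataFrame(rows)

    def to_markdown(self) -> str:
        lines = [f"# 2x2 group analyses (n = {self.n_subjects})", ""]
        for model_name, res in self.models.items():
            lines.append(f"## {model_name}")
            for coef in ("alcohol", "mood", "interaction"):
                s = res.summaries[coef]
                line = (
                    f"- {coef}: estimate = {s.mean:.3f}, "
                    f"95% CI = [{s.ci_low:.3f}, {s.ci_high:.3f}]"
                )
                if s.rope_fraction is not None:
                    line += f", ROPE fraction = {s.rope_fraction:.3f} ({s.decision})"
                else:
                    line += f" ({'CI excludes 0' if s.ci_excludes_zero else 'CI includes 0'})"
                lines.append(line)
            lines.append("")
        return "\n".join(lines)


MODEL_NAMES = ("winning_final60", "a_rew", "a_pun")


def run_preregistered_suite(
    study: StudyDataset,
    fit: FitResult,
    rope: RopeSpec = RopeSpec(),
    priors: str = "weakly_informative",
    sampler: LinearSamplerConfig | None = None,
) -> SuiteReport:
    """Fit the three preregistered 2x2 models.

    Model 1 predicts the winning-deck score (ROPE inference); models 2 and
    3 predict the reward and punishment learning-rate estimates
    (CI-excludes-0 inference). Learning-rate outcomes are the per-subject
    posterior means from ``fit`` (two-stage analysis).
    """
    meta = study.metadata().set_index("subject")
    est = fit.estimates
    missing = set(meta.index) - set(est.index)
    if missing:
        raise ValueError(f"fit is missing estimates for subjects {sorted(missing)[:5]} ...")
    est = est.loc[meta.index]
    behav = behavior_table(study)["winning_final60"].loc[meta.index].to_numpy(dtype=float)
    alcohol = meta["alcohol"].to_numpy()
    mood = meta["mood"].to_numpy()

    base_cfg = sampler or LinearSamplerConfig()
    models: dict[str, LinearModelResult] = {}
    outcomes = {
        "winning_final60": behav,
        "a_rew": est["a_rew"].to_numpy(dtype=float),
        "a_pun": est["a_pun"].to_numpy(dtype=float),
    }
    for i, (name, y) in enumerate(outcomes.items()):
        cfg = LinearSamplerConfig(
            chains=base_cfg.chains, warmup=base_cfg.warmup,
            draws=base_cfg.draws, seed=base_cfg.seed + i,
        )
        res = fit_2x2_linear(y, alcohol, mood, priors=priors, sampler=cfg)
        if name == "winning_final60":
            for coef in ("alcohol", "mood", "interaction"):
                frac, decision = rope_summary(res.draws[coef], rope)
                res.summaries[coef].rope_fraction = frac
                res.summaries[coef].decision = decision
        models[name] = res
    return SuiteReport(models=models, rope=rope, n_subjects=len(meta))


def sensitivity_suite(
    study: StudyDataset,
    fit: FitResult,
    rope: RopeSpec = RopeSpec(),
    sampler: LinearSamplerConfig | None = None,
) -> dict[str, SuiteReport]:
    """The two preregistered sensitivity analyses.

    (a) "responder_filtered": rerun the suite on mood responders only (the
    per-subject ORL estimates are reused; only the group models are refit).
    (b) "flat_priors": rerun on all subjects with the flat prior preset.
    """
    filtered = mood_responder_filter(study)
    for alcohol in (0, 1):
        for mood in (0, 1):
            n = sum(1 for s in filtered.kept.subjects if s.alcohol == alcohol and s.mood == mood)
            if n < 2:
                raise ValueError(
                    f"responder filter left design cell ({alcohol}, {mood}) with {n} "
                    f"subject(s); cannot rerun the 2x2 models"
                )
    kept_fit = FitResult(
        estimates=fit.estimates.loc[[s.subject for s in filtered.kept.subjects]],
        pointwise=fit.pointwise,
        diagnostics=fit.diagnostics,
        method=fit.method,
    )
    return {
        "responder_filtered": run_preregistered_suite(
            filtered.kept, kept_fit, rope=rope, sampler=sampler
        ),
        "flat_priors": run_preregistered_suite(
            study, fit, rope=rope, priors="flat", sampler=sampler
        ),
    }
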