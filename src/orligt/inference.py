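"""Parameter estimation for the ORL model.

Two estimators share one likelihood code path
(:func:`orligt.orl_core.pointwise_loglik_matrix`):

* :func:`fit_subject_map` — fast per-subject maximum a posteriori, used for
  quick looks and degenerate cases;
* :func:`fit_hierarchical` — the main estimator: a non-centered hierarchy
  in which each subject's unconstrained parameter vector is Normal(group
  mean, group SD), with Normal(0, 1) priors on group means and
  half-Normal(0, 1) priors on group SDs, sampled by an adaptive
  Metropolis-within-Gibbs scheme. Subject-level proposals for all subjects
  are evaluated in one vectorized likelihood call and accepted or rejected
  independently (valid because subject likelihoods are independent given
  the group parameters); group means are updated by their conjugate normal
  conditional and group SDs by a random-walk step on the log scale.

Parameters are sampled on an unconstrained scale: logit for the two
learning rates (support (0, 1)), scaled logit for K' (support (0, 5)),
identity for beta_F and beta_P. Convergence is summarized with split-Rhat
and effective sample sizes (via arviz).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy import optimize, special

from .orl_core import (
    OUTCOME_DIVISOR,
    ORLParams,
    PARAM_NAMES,
    SubjectTrials,
    pointwise_loglik_matrix,
)

K_PRIME_UPPER = 5.0  # K' support bound; keeps 3**K' numerically tame

_BOUNDED = (True, True, True, False, False)  # which params use a logit transform


# ---------------------------------------------------------------------------
# transforms between the constrained and unconstrained parameterizations
# ---------------------------------------------------------------------------

def unconstrain(theta: np.ndarray) -> np.ndarray:
    """Map (..., 5) constrained parameters to the unconstrained scale."""
    theta = np.asarray(theta, dtype=float)
    z = theta.copy()
    z[..., 0] = special.logit(theta[..., 0])
    z[..., 1] = special.logit(theta[..., 1])
    z[..., 2] = special.logit(theta[..., 2] / K_PRIME_UPPER)
    return z


def constrain(z: np.ndarray) -> np.ndarray:
    """Inverse of :func:`unconstrain`."""
    z = np.asarray(z, dtype=float)
    theta = z.copy()
    theta[..., 0] = special.expit(z[..., 0])
    theta[..., 1] = special.expit(z[..., 1])
    theta[..., 2] = K_PRIME_UPPER * special.expit(z[..., 2])
    return theta


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SamplerConfig:
    """MCMC settings for the hierarchical fit."""

    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    thin: int = 2
    seed: int = 0
    loo_draws: int = 400  # pointwise log-lik draws retained for LOO

    @classmethod
    def preset(cls, name: str, seed: int = 0) -> "SamplerConfig":
        if name == "full":
            return cls(chains=4, warmup=1000, draws=1000, thin=2, seed=seed)
        if name == "test":
            return cls(chains=2, warmup=350, draws=350, thin=1, seed=seed)
        raise ValueError(f"unknown sampler preset {name!r}")


@dataclass
class PriorConfig:
    """Independent normal priors on the unconstrained scale (MAP estimator)."""

    loc: np.ndarray = field(default_factory=lambda: np.zeros(5))
    scale: np.ndarray = field(default_factory=lambda: np.array([1.0, 1.0, 1.0, 2.0, 2.0]))


@dataclass
class FitResult:
    """Estimates plus (for the hierarchical mode) posterior draws.

    ``estimates``: per-subject posterior means (or MAP), subjects x 5.
    ``draws``: dict with "theta" (chain, draw, subject, 5), "mu", "tau".
    ``pointwise``: posterior-mean per-trial log-likelihood, subjects x T.
    ``pointwise_draws``: (n_loo_draws, subjects, T) for PSIS-LOO.
    """

    estimates: pd.DataFrame
    pointwise: np.ndarray
    diagnostics: dict
    method: str
    draws: dict[str, np.ndarray] | None = None
    pointwise_draws: np.ndarray | None = None

    @property
    def subjects(self) -> list[str]:
        return list(self.estimates.index)


def _as_trials_list(study) -> list[SubjectTrials]:
    if hasattr(study, "all_trials"):
        return study.all_trials()
    return list(study)


def _stack(trials: Sequence[SubjectTrials]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    lengths = {t.n_trials for t in trials}
    if len(lengths) != 1:
        raise ValueError("all subjects must have the same number of trials")
    choices = np.array([t.choices for t in trials])
    nets = np.array([t.net for t in trials])
    return choices, nets, [t.subject for t in trials]


# ---------------------------------------------------------------------------
# per-subject MAP
# ---------------------------------------------------------------------------

def fit_subject_map(
    trials: SubjectTrials,
    prior: PriorConfig | None = None,
    n_starts: int = 10,
    seed: int = 0,
    outcome_divisor: float = OUTCOME_DIVISOR,
) -> FitResult:
    """Maximum a posteriori estimate for one subject (multi-start L-BFGS).

    The log posterior is the sequence log-likelihood plus the normal prior
    on the unconstrained scale. All-start failure is flagged in
    ``diagnostics['converged']`` rather than raised.
    """
    if trials.n_trials == 0:
        raise ValueError("cannot fit an empty trial sequence")
    if trials.n_trials < 20:
        warnings.warn(f"only {trials.n_trials} trials; MAP estimate will be unstable")
    prior = prior or PriorConfig()
    choices = trials.choices[None, :]
    nets = trials.net[None, :]

    def neg_log_post(z: np.ndarray) -> float:
        theta = constrain(z[None, :])[0]
        ll = pointwise_loglik_matrix(
            choices, nets, theta[0:1], theta[1:2], theta[2:3], theta[3:4], theta[4:5],
            outcome_divisor=outcome_divisor,
        ).sum()
        lp = -0.5 * np.sum(((z - prior.loc) / prior.scale) ** 2)
        return -(ll + lp)

    rng = np.random.default_rng(seed)
    best, best_val, any_ok = None, np.inf, False
    for k in range(n_starts):
        z0 = prior.loc if k == 0 else rng.normal(prior.loc, prior.scale)
        res = optimize.minimize(neg_log_post, z0, method="L-BFGS-B")
        any_ok = any_ok or bool(res.success)
        if res.fun < best_val:
            best, best_val = res.x, float(res.fun)
    theta = constrain(best[None, :])[0]
    pointwise = pointwise_loglik_matrix(
        choices, nets, theta[0:1], theta[1:2], theta[2:3], theta[3:4], theta[4:5],
        outcome_divisor=outcome_divisor,
    )
    estimates = pd.DataFrame([theta], columns=PARAM_NAMES, index=[trials.subject])
    estimates.index.name = "subject"
    return FitResult(
        estimates=estimates,
        pointwise=pointwise,
        diagnostics={"converged": any_ok, "neg_log_posterior": best_val, "n_starts": n_starts},
        method="map",
    )


def fit_study_map(study, prior: PriorConfig | None = None, n_starts: int = 10, seed: int = 0) -> FitResult:
    """Independent MAP fits for every subject in a study."""
    trials = _as_trials_list(study)
    fits = [fit_subject_map(t, prior=prior, n_starts=n_starts, seed=seed + i) for i, t in enumerate(trials)]
    estimates = pd.concat([f.estimates for f in fits])
    pointwise = np.vstack([f.pointwise for f in fits])
    return FitResult(
        estimates=estimates,
        pointwise=pointwise,
        diagnostics={"converged": all(f.diagnostics["converged"] for f in fits)},
        method="map",
    )


# ---------------------------------------------------------------------------
# hierarchical Metropolis-within-Gibbs
# ---------------------------------------------------------------------------

def _halfnormal_logpdf(x: float, scale: float = 1.0) -> float:
    return -0.5 * (x / scale) ** 2 if x > 0 else -np.inf


def _run_chain(
    choices: np.ndarray,
    nets: np.ndarray,
    cfg: SamplerConfig,
    chain_seed: int,
    outcome_divisor: float,
) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(chain_seed)
    S = choices.shape[0]
    P = 5

    def loglik(z: np.ndarray) -> np.ndarray:
        theta = constrain(z)
        return pointwise_loglik_matrix(
            choices, nets, theta[:, 0], theta[:, 1], theta[:, 2], theta[:, 3], theta[:, 4],
            outcome_divisor=outcome_divisor,
        ).sum(axis=1)

    z = rng.normal(0.0, 0.5, size=(S, P))
    mu = np.zeros(P)
    tau = np.full(P, 0.5)
    step = np.full((S, P), 0.4)
    tau_step = np.full(P, 0.2)
    shift_step = np.full(P, 0.2)
    scale_step = np.full(P, 0.1)
    rho = np.full(P, 0.9)  # pCN autoregression; adapted toward 60% acceptance
    ll = loglik(z)

    n_keep = cfg.draws // cfg.thin
    theta_out = np.empty((n_keep, S, P))
    mu_out = np.empty((n_keep, P))
    tau_out = np.empty((n_keep, P))
    kept = 0

    total = cfg.warmup + cfg.draws
    for it in range(total):
        in_warmup = it < cfg.warmup
        gain = 0.05 if in_warmup else 0.0
        for p in range(P):
            prop_col = z[:, p] + step[:, p] * rng.standard_normal(S)
            z_prop = z.copy()
            z_prop[:, p] = prop_col
            ll_prop = loglik(z_prop)
            log_prior_new = -0.5 * ((prop_col - mu[p]) / tau[p]) ** 2
            log_prior_old = -0.5 * ((z[:, p] - mu[p]) / tau[p]) ** 2
            log_r = (ll_prop - ll) + (log_prior_new - log_prior_old)
            acc = np.log(rng.uniform(size=S)) < log_r
            z[acc, p] = prop_col[acc]
            ll[acc] = ll_prop[acc]
            if in_warmup:
                step[:, p] *= np.exp(gain * (acc.astype(float) - 0.44))
            # prior-preserving autoregressive (pCN) refresh: resamples each
            # subject's value partly from its group prior, which keeps the
            # spread of subject values (and hence tau) mixing even under
            # strong shrinkage. Acceptance ratio is the likelihood alone.
            for _ in range(2):
                prop_col = mu[p] + rho[p] * (z[:, p] - mu[p]) + np.sqrt(
                    1.0 - rho[p] ** 2
                ) * tau[p] * rng.standard_normal(S)
                z_prop = z.copy()
                z_prop[:, p] = prop_col
                ll_prop = loglik(z_prop)
                acc = np.log(rng.uniform(size=S)) < (ll_prop - ll)
                z[acc, p] = prop_col[acc]
                ll[acc] = ll_prop[acc]
                if in_warmup:
                    rho[p] = 1.0 - np.clip(
                        (1.0 - rho[p]) * np.exp(gain * (acc.mean() - 0.50)), 1e-3, 0.99
                    )
        # group means: conjugate normal conditional (prior N(0, 1))
        for p in range(P):
            prec = 1.0 + S / tau[p] ** 2
            mean = (z[:, p].sum() / tau[p] ** 2) / prec
            mu[p] = mean + rng.standard_normal() / np.sqrt(prec)
        # group SDs: random walk on log(tau), half-Normal(0, 1) prior
        for p in range(P):
            lt_prop = np.log(tau[p]) + tau_step[p] * rng.standard_normal()
            t_prop = np.exp(lt_prop)
            dev = z[:, p] - mu[p]

            def tau_logpost(t: float) -> float:
                return (
                    -S * np.log(t)
                    - 0.5 * np.sum(dev**2) / t**2
                    + _halfnormal_logpdf(t)
                    + np.log(t)  # Jacobian of the log transform
                )

            if np.log(rng.uniform()) < tau_logpost(t_prop) - tau_logpost(tau[p]):
                tau[p] = t_prop
                acc_t = 1.0
            else:
                acc_t = 0.0
            if in_warmup:
                tau_step[p] *= np.exp(gain * (acc_t - 0.44))
        # group translation / scale moves: shift or rescale mu_p together
        # with every subject's z[:, p]. These traverse the hierarchy's slow
        # directions that the one-at-a-time updates cannot.
        for p in range(P):
            delta = shift_step[p] * rng.standard_normal()
            z_prop = z.copy()
            z_prop[:, p] += delta
            ll_prop = loglik(z_prop)
            mu_new = mu[p] + delta
            log_r = (ll_prop - ll).sum() - 0.5 * (mu_new**2 - mu[p] ** 2)
            acc_s = np.log(rng.uniform()) < log_r
            if acc_s:
                z, ll, mu[p] = z_prop, ll_prop, mu_new
            if in_warmup:
                shift_step[p] *= np.exp(gain * (float(acc_s) - 0.30))

            c = np.exp(scale_step[p] * rng.standard_normal())
            z_prop = z.copy()
            z_prop[:, p] = mu[p] + c * (z[:, p] - mu[p])
            ll_prop = loglik(z_prop)
            tau_new = c * tau[p]
            # prior(z | mu, tau) is invariant under the joint rescaling up to
            # a factor c^-S, cancelled by the Jacobian c^(S+1); the leftover
            # factor c and the tau prior ratio appear below.
            log_r = (
                (ll_prop - ll).sum()
                + _halfnormal_logpdf(tau_new)
                - _halfnormal_logpdf(tau[p])
                + np.log(c)
            )
            acc_c = np.log(rng.uniform()) < log_r
            if acc_c:
                z, ll, tau[p] = z_prop, ll_prop, tau_new
            if in_warmup:
                scale_step[p] *= np.exp(gain * (float(acc_c) - 0.30))
        if not in_warmup:
            k = it - cfg.warmup
            if k % cfg.thin == 0 and kept < n_keep:
                theta_out[kept] = constrain(z)
                mu_out[kept] = mu
                tau_out[kept] = tau
                kept += 1
    return {"theta": theta_out[:kept], "mu": mu_out[:kept], "tau": tau_out[:kept]}


def fit_hierarchical(
    study,
    sampler: SamplerConfig | str | None = None,
    seed: int | None = None,
    outcome_divisor: float = OUTCOME_DIVISOR,
) -> FitResult:
    """Hierarchical Bayesian fit of the ORL model across subjects.

    ``sampler`` may be a :class:`SamplerConfig` or a preset name ("full",
    "test"). Divergence-free by construction (random-walk kernel); poor
    mixing shows up as split-Rhat > 1.05, which is recorded as a warning in
    the diagnostics rather than raised.
    """
    trials = _as_trials_list(study)
    if len(trials) < 2:
        raise ValueError("hierarchical fit requires at least 2 subjects")
    if isinstance(sampler, str):
        sampler = SamplerConfig.preset(sampler, seed=seed or 0)
    cfg = sampler or SamplerConfig()
    if seed is not None:
        cfg = SamplerConfig(**{**cfg.__dict__, "seed": seed})
    choices, nets, subjects = _stack(trials)

    master = np.random.default_rng(cfg.seed)
    chain_seeds = master.integers(0, 2**31 - 1, size=cfg.chains)
    chains = [_run_chain(choices, nets, cfg, int(s), outcome_divisor) for s in chain_seeds]
    theta = np.stack([c["theta"] for c in chains])  # (C, D, S, 5)
    mu = np.stack([c["mu"] for c in chains])
    tau = np.stack([c["tau"] for c in chains])

    # diagnostics on the group-level parameters (the slow-mixing directions)
    idata = az.from_dict(posterior={"mu": mu, "tau": tau})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    max_rhat = float(max(rhat["mu"].values.max(), rhat["tau"].values.max()))
    min_ess = float(min(ess["mu"].values.min(), ess["tau"].values.min()))
    diagnostics = {
        "max_rhat": max_rhat,
        "min_ess": min_ess,
        "chains": cfg.chains,
        "warmup": cfg.warmup,
        "draws": cfg.draws,
        "warnings": [] if max_rhat <= 1.05 else [f"max split-Rhat {max_rhat:.3f} > 1.05"],
    }

    est = theta.reshape(-1, len(subjects), 5).mean(axis=0)
    estimates = pd.DataFrame(est, columns=PARAM_NAMES, index=subjects)
    estimates.index.name = "subject"

    # pointwise log-likelihood draws for LOO, evenly thinned across chains
    flat = theta.reshape(-1, len(subjects), 5)
    n_take = min(cfg.loo_draws, flat.shape[0])
    idx = np.linspace(0, flat.shape[0] - 1, n_take).astype(int)
    pw = np.empty((n_take, len(subjects), choices.shape[1]))
    for d, i in enumerate(idx):
        th = flat[i]
        pw[d] = pointwise_loglik_matrix(
            choices, nets, th[:, 0], th[:, 1], th[:, 2], th[:, 3], th[:, 4],
            outcome_divisor=outcome_divisor,
        )
    return FitResult(
        estimates=estimates,
        pointwise=pw.mean(axis=0),
        diagnostics=diagnostics,
        method="hierarchical",
        draws={"theta": theta, "mu": mu, "tau": tau},
        pointwise_draws=pw,
    )


# ---------------------------------------------------------------------------
# recovery reporting and fit serialization
# ---------------------------------------------------------------------------

def recovery_report(fit: FitResult, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter recovery table: Pearson r, mean bias, RMSE.

    ``truth`` is a truth manifest (one row per subject with the five
    parameter columns); it must cover exactly the fitted subjects.
    """
    truth = truth.set_index("subject") if "subject" in truth.columns else truth
    missing = set(fit.subjects) - set(truth.index)
    if missing:
        raise ValueError(f"truth manifest missing subjects: {sorted(missing)[:5]} ...")
    truth = truth.loc[fit.subjects]
    rows = []
    for p in PARAM_NAMES:
        t = truth[p].to_numpy(dtype=float)
        e = fit.estimates[p].to_numpy(dtype=float)
        r = float(np.corrcoef(t, e)[0, 1]) if np.std(t) > 0 and np.std(e) > 0 else np.nan
        rows.append(
            {
                "parameter": p,
                "correlation": r,
                "bias": float(np.mean(e - t)),
                "rmse": float(np.sqrt(np.mean((e - t) ** 2))),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def save_fit(fit: FitResult, outdir: str | Path) -> dict[str, Path]:
    """Serialize a fit: estimates.csv, pointwise_loglik.csv, diagnostics.json,
    and (hierarchical mode) posterior draws as a compressed columnar .npz."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "estimates": outdir / "estimates.csv",
        "pointwise": outdir / "pointwise_loglik.csv",
        "diagnostics": outdir / "diagnostics.json",
    }
    fit.estimates.to_csv(paths["estimates"])
    pd.DataFrame(fit.pointwise, index=fit.subjects).to_csv(paths["pointwise"])
    paths["diagnostics"].write_text(json.dumps({**fit.diagnostics, "method": fit.method}, indent=2))
    if fit.draws is not None:
        paths["draws"] = outdir / "draws.npz"
        np.savez_compressed(paths["draws"], **fit.draws)
    return paths
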