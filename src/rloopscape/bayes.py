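"""Bayesian regression machinery shared by the feature-level and
mutation-rate models: ensemble-MCMC GLM sampling, Bayes factors against a
region of practical equivalence (ROPE), and PSIS-LOO model comparison.

Evidence for a coefficient is summarised by two Bayes factors:

``K``
    posterior odds of a *substantial* effect (|beta| > delta, with the
    dominant posterior sign) versus the ROPE (|beta| <= delta), divided by
    the same odds under the prior.
``K0``
    the reciprocal construction for the hypothesis that the effect is
    *near zero* (inside the ROPE) versus its complement.

Categories follow the conventional evidence bins: K in [3, 20) positive,
[20, 150) strong, >= 150 very strong.  Finite draw counts cannot estimate
unbounded odds, so empty posterior cells are clamped to ``1/n_draws`` and
flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import norm

import emcee


class ConvergenceError(RuntimeError):
    """Sampling did not converge (R-hat above threshold)."""


@dataclass
class GLMFit:
    """Posterior sample of a GLM with stored pointwise log-likelihoods."""

    coef_names: list
    draws: np.ndarray  # (n_draws, n_params); Gaussian fits append log_sigma
    loglik: np.ndarray  # (n_draws, n_obs)
    rhat: np.ndarray
    family: str
    prior_sd: float
    acceptance: float
    n_obs: int
    metadata: dict = field(default_factory=dict)

    def coef_draws(self, name: str) -> np.ndarray:
        return self.draws[:, self.coef_names.index(name)]

    def summary(self) -> pd.DataFrame:
        q = np.quantile(self.draws, [0.05, 0.5, 0.95], axis=0)
        return pd.DataFrame(
            {
                "coef": self.coef_names,
                "mean": self.draws.mean(axis=0),
                "sd": self.draws.std(axis=0),
                "q05": q[0],
                "median": q[1],
                "q95": q[2],
                "rhat": self.rhat,
            }
        )

    def to_inference_data(self, n_chains: int = 4):
        import arviz as az

        nd = (self.draws.shape[0] // n_chains) * n_chains
        post = {
            name: self.draws[:nd, j].reshape(n_chains, -1)
            for j, name in enumerate(self.coef_names)
        }
        ll = self.loglik[:nd].reshape(n_chains, -1, self.n_obs)
        return az.from_dict(posterior=post, log_likelihood={"y": ll})


def _make_logpost(X, y, family, offset, prior_sd, sigma_prior_scale):
    n, p = X.shape
    if family == "poisson":
        lgy = gammaln(y + 1.0)

        def pointwise(theta):
            eta = offset + X @ theta[:p]
            eta = np.clip(eta, -300, 30)
            return y * eta - np.exp(eta) - lgy

        def logpost(theta):
            lp = pointwise(theta).sum()
            return lp - 0.5 * np.sum((theta[:p] / prior_sd) ** 2)

        ndim = p
    elif family == "gaussian":

        def pointwise(theta):
            sigma = np.exp(theta[p])
            resid = y - X @ theta[:p]
            return -0.5 * (resid / sigma) ** 2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)

        def logpost(theta):
            sigma = np.exp(theta[p])
            lp = pointwise(theta).sum()
            lp -= 0.5 * np.sum((theta[:p] / prior_sd) ** 2)
            # half-Normal(0, scale^2) on sigma, with log-Jacobian for log sigma
            lp += -0.5 * (sigma / sigma_prior_scale) ** 2 + theta[p]
            return lp

        ndim = p + 1
    else:
        raise ValueError(f"unknown family {family!r}")
    return logpost, pointwise, ndim


def sample_glm(
    X: np.ndarray,
    y: np.ndarray,
    coef_names: list,
    family: str = "poisson",
    offset: np.ndarray | None = None,
    prior_sd: float = 2.0,
    sigma_prior_scale: float = 2.0,
    draws: int = 4000,
    seed: int = 0,
    burn: int | None = None,
    rhat_threshold: float = 1.05,
) -> GLMFit:
    """Sample a Poisson (log link, optional exposure offset) or Gaussian
    linear model with Normal(0, prior_sd^2) coefficient priors using an
    affine-invariant ensemble sampler.

    Raises :class:`ConvergenceError` when max R-hat exceeds the threshold
    and ValueError on a rank-deficient design (naming collinear columns).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if len(coef_names) != p:
        raise ValueError("coef_names length must match design columns")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify a minimal set of dependent columns via QR pivoting
        _, r = np.linalg.qr(X)
        bad = [coef_names[j] for j in range(p) if abs(r[min(j, r.shape[0] - 1), j]) < 1e-8]
        raise ValueError(f"rank-deficient design (rank {rank} < {p}); "
                         f"collinear columns include {bad or coef_names}")
    offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    logpost, pointwise, ndim = _make_logpost(
        X, y, family, offset, prior_sd, sigma_prior_scale
    )

    theta0 = np.zeros(ndim)
    res = minimize(lambda t: -logpost(t), theta0, method="L-BFGS-B")
    start = res.x

    nwalkers = max(4 * ndim, 32)
    rng = np.random.RandomState(seed)
    p0 = start[None, :] + 1e-3 * rng.randn(nwalkers, ndim)

    def logpost_vec(thetas):
        return np.array([logpost(t) for t in thetas])

    sampler = emcee.EnsembleSampler(nwalkers, ndim, logpost_vec, vectorize=True)
    sampler.random_state = np.random.RandomState(seed + 1).get_state()
    # ensemble autocorrelation times for these GLM posteriors run ~10x ndim
    # steps; budget ~50 autocorrelation lengths of post-burn sampling
    tau_guess = 12 * ndim
    if burn is None:
        burn = max(1000, 15 * tau_guess)
    per_walker = int(np.ceil(draws / nwalkers))
    post_steps = max(per_walker, 50 * tau_guess)
    sampler.run_mcmc(p0, burn + post_steps, progress=False)
    thin = max(1, post_steps // per_walker)
    chain = sampler.get_chain(discard=burn, thin=thin)  # (per_walker', nwalkers, ndim)

    import arviz as az

    # diagnose on a moderately thinned post-burn chain (the chain kept for
    # inference can be too short for a stable R-hat)
    diag = sampler.get_chain(discard=burn, thin=max(1, tau_guess // 4))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat_da = az.rhat(
            az.from_dict(posterior={"theta": np.moveaxis(diag, 0, 1)})
        )["theta"].values
    if np.nanmax(rhat_da) > rhat_threshold:
        raise ConvergenceError(
            f"max R-hat {np.nanmax(rhat_da):.3f} > {rhat_threshold}; "
            f"per-parameter: {np.round(rhat_da, 3)}"
        )

    flat = chain.reshape(-1, ndim)[:draws]
    loglik = np.empty((len(flat), n))
    for i, t in enumerate(flat):
        loglik[i] = pointwise(t)
    names = list(coef_names) + (["log_sigma"] if family == "gaussian" else [])
    return GLMFit(
        coef_names=names,
        draws=flat,
        loglik=loglik,
        rhat=np.asarray(rhat_da, dtype=float),
        family=family,
        prior_sd=prior_sd,
        acceptance=float(np.mean(sampler.acceptance_fraction)),
        n_obs=n,
        metadata={"seed": seed, "burn": burn, "thin": thin,
                  "nwalkers": nwalkers, "post_steps": post_steps},
    )


# ---------------------------------------------------------------------------
# Bayes factors with a ROPE
# ---------------------------------------------------------------------------


EVIDENCE_BINS = ((150.0, "very strong"), (20.0, "strong"), (3.0, "positive"))


def evidence_category(k: float) -> str:
    for lo, label in EVIDENCE_BINS:
        if k >= lo:
            return label
    return "weak"


@dataclass
class EffectPosterior:
    name: str
    draws: np.ndarray
    rope_halfwidth: float
    K: float
    K0: float
    K_category: str
    K0_category: str
    clamped: bool

    @property
    def mean(self) -> float:
        return float(self.draws.mean())


def bayes_factors(
    draws: np.ndarray,
    prior_sd: float,
    rope_halfwidth: float = 0.05,
    name: str = "effect",
) -> EffectPosterior:
    """K (substantial effect vs ROPE) and K0 (ROPE vs complement).

    Posterior cell probabilities come from the draws; prior probabilities
    are the analytic Normal(0, prior_sd^2) masses.  Empty cells are clamped
    to 1/n_draws with a warning flag.
    """
    if rope_halfwidth <= 0:
        raise ValueError("rope_halfwidth must be positive")
    draws = np.asarray(draws, dtype=float)
    m = len(draws)
    sign = 1.0 if np.median(draws) >= 0 else -1.0

    post_eff = np.mean(sign * draws > rope_halfwidth)
    post_rope = np.mean(np.abs(draws) <= rope_halfwidth)
    clamped = False
    eps = 1.0 / m
    vals = []
    for v in (post_eff, post_rope, 1.0 - post_rope):
        if v <= 0.0:
            v, clamped = eps, True
        elif v >= 1.0:
            v, clamped = 1.0 - eps, True
        vals.append(v)
    post_eff, post_rope, post_out = vals

    prior_rope = norm.cdf(rope_halfwidth / prior_sd) - norm.cdf(-rope_halfwidth / prior_sd)
    prior_eff = norm.sf(rope_halfwidth / prior_sd)  # one-signed tail
    K = (post_eff / post_rope) / (prior_eff / prior_rope)
    K0 = (post_rope / post_out) / (prior_rope / (1.0 - prior_rope))
    if clamped:
        warnings.warn(
            f"{name}: posterior cell empty at {m} draws; Bayes factor clamped"
        )
    return EffectPosterior(
        name=name,
        draws=draws,
        rope_halfwidth=rope_halfwidth,
        K=float(K),
        K0=float(K0),
        K_category=evidence_category(K),
        K0_category=evidence_category(K0),
        clamped=clamped,
    )


# ---------------------------------------------------------------------------
# LOO-CV comparison
# ---------------------------------------------------------------------------


#: ELPD differences below this are negligible regardless of their SE; the
#: paired SE estimate is known to be unreliable for small differences
#: between nested models.
ELPD_NEGLIGIBLE = 4.0


@dataclass
class LooComparison:
    elpd_full: float
    elpd_reduced: float
    diff: float  # elpd_full - elpd_reduced
    se: float  # SE of the pointwise difference
    bad_k_full: int
    bad_k_reduced: int

    @property
    def indistinguishable(self) -> bool:
        """True when the models are predictively equivalent: the ELPD
        difference is within 2 SE or below the negligibility threshold."""
        return abs(self.diff) < max(2.0 * self.se, ELPD_NEGLIGIBLE)


def loo_compare(fit_full: GLMFit, fit_reduced: GLMFit) -> LooComparison:
    """PSIS-LOO expected log predictive density difference with its SE.

    Both fits must be on identical observations.  Observations with Pareto
    k > 0.7 are counted and reported.
    """
    if fit_full.n_obs != fit_reduced.n_obs:
        raise ValueError("fits are on different numbers of observations")
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        loo_f = az.loo(fit_full.to_inference_data(), pointwise=True)
        loo_r = az.loo(fit_reduced.to_inference_data(), pointwise=True)
    pw_f = np.asarray(loo_f.loo_i)
    pw_r = np.asarray(loo_r.loo_i)
    diff_i = pw_f - pw_r
    diff = float(diff_i.sum())
    se = float(np.sqrt(len(diff_i) * np.var(diff_i, ddof=1)))
    bad_f = int(np.sum(np.asarray(loo_f.pareto_k) > 0.7))
    bad_r = int(np.sum(np.asarray(loo_r.pareto_k) > 0.7))
    if bad_f or bad_r:
        warnings.warn(
            f"PSIS-LOO: {bad_f} (full) / {bad_r} (reduced) observations with Pareto k > 0.7"
        )
    return LooComparison(
        elpd_full=float(loo_f.elpd_loo),
        elpd_reduced=float(loo_r.elpd_loo),
        diff=diff,
        se=se,
        bad_k_full=bad_f,
        bad_k_reduced=bad_r,
    )
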