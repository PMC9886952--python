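"""Shared Bayesian machinery.

Posterior sampling uses Hamiltonian Monte Carlo with leapfrog integration,
dual-averaging step-size adaptation and a diagonal mass matrix estimated
during warm-up; four chains run vectorized.  Models supply the joint
log-density and its gradient in closed form.  Split-R-hat is computed per
parameter with ArviZ and a run counts as converged iff max R-hat < 1.01;
non-convergence and divergent transitions are flagged, never silent.

HPD intervals (shortest interval at a given mass), kernel-density posterior
modes and PSIS-LOO model comparison are the summary vocabulary used by both
hierarchical models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SamplerConfig",
    "PosteriorSamples",
    "PosteriorSummary",
    "ModelComparisonResult",
    "sample_posterior",
    "hpd",
    "posterior_mode",
    "summarize",
    "psis_loo",
    "compare_models",
]

logger = logging.getLogger(__name__)

RHAT_THRESHOLD = 1.01


@dataclass(frozen=True)
class SamplerConfig:
    """HMC settings.

    Defaults mirror a 20,000-draw, 4-chain run thinned by 4 (5,000 stored
    draws); recovery fits configure the draws down.  ``thin`` is a storage
    option only.
    """

    chains: int = 4
    n_steps: int = 1250          # stored draws per chain
    n_burn: int = 700            # warm-up iterations (adaptation)
    thin: int = 1
    max_leapfrog: int = 24
    target_accept: float = 0.8
    seed: int = 0


@dataclass
class PosteriorSamples:
    """Draws for all parameters of one fitted model.

    ``chain`` has shape (draw, chain, ndim); ``names`` labels the last axis.
    """

    chain: np.ndarray
    names: list[str]
    rhat: np.ndarray
    acceptance_rate: float
    n_divergent: int = 0

    @property
    def converged(self) -> bool:
        return bool(np.nanmax(self.rhat) < RHAT_THRESHOLD)

    @property
    def n_samples(self) -> int:
        return self.chain.shape[0] * self.chain.shape[1]

    def flat(self) -> np.ndarray:
        return self.chain.reshape(-1, self.chain.shape[-1])

    def get(self, name: str) -> np.ndarray:
        return self.flat()[:, self.names.index(name)]

    def max_rhat(self) -> float:
        return float(np.nanmax(self.rhat))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.flat(), columns=self.names)

    def save(self, path) -> None:
        """Persist draws in a columnar layout (parameter name -> draws)."""
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def load(path) -> "PosteriorSamples":
        df = pd.read_csv(path)
        chain = df.to_numpy()[:, None, :]
        return PosteriorSamples(
            chain=chain,
            names=list(df.columns),
            rhat=np.full(chain.shape[-1], np.nan),
            acceptance_rate=np.nan,
        )


@dataclass(frozen=True)
class PosteriorSummary:
    """Mode and 95% HPD bounds of one scalar estimand, plus its draws."""

    mode: float
    hpd_low: float
    hpd_high: float
    n_samples: int
    rhat: float = np.nan
    samples_ref: np.ndarray | None = field(default=None, repr=False)

    def __str__(self) -> str:
        return f"{self.mode:.3g} [{self.hpd_low:.3g}, {self.hpd_high:.3g}]"


def _finite_logp(lp: np.ndarray) -> np.ndarray:
    return np.where(np.isfinite(lp), lp, -np.inf)


def sample_posterior(
    logp_grad: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]],
    init: np.ndarray,
    init_scale: np.ndarray | float,
    names: Sequence[str] | None = None,
    config: SamplerConfig | None = None,
) -> PosteriorSamples:
    """Draw from a posterior with Hamiltonian Monte Carlo.

    ``logp_grad`` maps a (chains, ndim) position array to the tuple
    (log-density (chains,), gradient (chains, ndim)); -inf marks points
    outside the support.  Chains start from ``init`` jittered by
    ``init_scale``, which also seeds the diagonal mass matrix.  Identical
    (logp_grad, init, config) including the seed reproduce draws exactly.
    """
    config = config or SamplerConfig()
    rng = np.random.default_rng(config.seed)
    init = np.asarray(init, float)
    ndim = init.size
    C = config.chains
    names = list(names) if names is not None else [f"p{i}" for i in range(ndim)]
    scale = np.broadcast_to(np.asarray(init_scale, float), (ndim,)).copy()
    scale = np.where(scale > 0, scale, 1e-3)

    q = init[None, :] + 0.3 * scale[None, :] * rng.standard_normal((C, ndim))
    lp, grad = logp_grad(q)
    lp = _finite_logp(lp)
    shrink = 1.0
    for _ in range(60):
        bad = ~np.isfinite(lp)
        if not bad.any():
            break
        shrink *= 0.7
        q[bad] = init[None, :] + shrink * scale[None, :] * rng.standard_normal(
            (int(bad.sum()), ndim))
        lp, grad = logp_grad(q)
        lp = _finite_logp(lp)
    if not np.isfinite(lp).all():
        raise RuntimeError("could not initialize chains in the support")

    # Metric: position covariance estimate Sigma (dense when feasible).
    # Momenta ~ N(0, Sigma^-1); q-update uses Sigma @ p.
    dense = 2 <= ndim <= 600
    sigma_diag = scale ** 2
    chol_sigma = None  # dense factor, set after warm-up window

    def draw_momentum(z):
        if chol_sigma is None:
            return z / np.sqrt(sigma_diag)[None, :]
        from scipy.linalg import solve_triangular
        return solve_triangular(chol_sigma, z.T, lower=True, trans="T").T

    def kinetic(p):
        with np.errstate(over="ignore", invalid="ignore"):
            if chol_sigma is None:
                return 0.5 * np.sum(p ** 2 * sigma_diag[None, :], axis=1)
            v = p @ chol_sigma
            return 0.5 * np.sum(v ** 2, axis=1)

    def sigma_dot(p):
        with np.errstate(over="ignore", invalid="ignore"):
            if chol_sigma is None:
                return p * sigma_diag[None, :]
            return (p @ chol_sigma) @ chol_sigma.T

    eps = np.full(C, 0.05)
    # dual averaging state (per chain)
    mu_da = np.log(10 * eps)
    log_eps_bar = np.log(eps)
    h_bar = np.zeros(C)
    gamma, t0, kappa = 0.05, 10.0, 0.75

    n_keep = config.n_steps
    draws = np.empty((n_keep, C, ndim))
    window: list[np.ndarray] = []
    accept_hist = []
    n_divergent = 0

    total = config.n_burn + n_keep * config.thin
    mass_update_at = int(config.n_burn * 0.7)
    da_count = 0

    old_err = np.seterr(over="ignore", invalid="ignore")
    for it in range(total):
        warm = it < config.n_burn
        p = draw_momentum(rng.standard_normal((C, ndim)))
        kin0 = kinetic(p)
        L = int(rng.integers(max(2, config.max_leapfrog // 3),
                             config.max_leapfrog + 1))
        q_new, p_new = q.copy(), p.copy()
        lp_new, grad_new = lp.copy(), grad.copy()
        ok = np.isfinite(lp_new)
        p_new += 0.5 * eps[:, None] * grad_new
        for step in range(L):
            q_new += eps[:, None] * sigma_dot(p_new)
            lp_new, grad_new = logp_grad(q_new)
            lp_new = _finite_logp(lp_new)
            ok &= np.isfinite(lp_new) & np.all(np.isfinite(grad_new), axis=1)
            grad_new = np.where(np.isfinite(grad_new), grad_new, 0.0)
            p_new += (eps[:, None] if step < L - 1
                      else 0.5 * eps[:, None]) * grad_new
        kin1 = kinetic(p_new)
        log_alpha = np.where(ok, (lp_new - kin1) - (lp - kin0), -np.inf)
        alpha = np.exp(np.minimum(0.0, log_alpha))
        accept = np.log(rng.random(C)) < log_alpha
        n_divergent += int((~ok).sum()) if not warm else 0
        q[accept] = q_new[accept]
        lp[accept] = lp_new[accept]
        grad[accept] = grad_new[accept]
        accept_hist.append(alpha.mean())

        if warm:
            da_count += 1
            eta = 1.0 / (da_count + t0)
            h_bar = (1 - eta) * h_bar + eta * (config.target_accept - alpha)
            log_eps = mu_da - np.sqrt(da_count) / gamma * h_bar
            w = da_count ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = np.exp(log_eps)
            if it >= mass_update_at // 3 and it < mass_update_at:
                window.append(q.copy())
            if it == mass_update_at and window:
                pool = np.concatenate(window, axis=0)
                n_w = pool.shape[0]
                var = pool.var(axis=0)
                w_n = n_w / (n_w + 5.0)
                sigma_diag = np.maximum(
                    w_n * var + (1 - w_n) * scale ** 2, 1e-10)
                if dense and n_w > ndim // 2:
                    cov = np.cov(pool.T)
                    cov = w_n * cov + (1 - w_n) * np.diag(np.diag(cov))
                    cov[np.diag_indices_from(cov)] = sigma_diag
                    try:
                        chol_sigma = np.linalg.cholesky(
                            cov + 1e-10 * np.eye(ndim))
                    except np.linalg.LinAlgError:  # pragma: no cover
                        chol_sigma = None
                window.clear()
                # restart step-size adaptation for the new metric
                eps = np.full(C, 0.1)
                mu_da = np.log(10 * eps)
                log_eps_bar = np.log(eps)
                h_bar = np.zeros(C)
                da_count = 0
            if it == config.n_burn - 1:
                eps = np.exp(log_eps_bar)
        else:
            j = it - config.n_burn
            if j % config.thin == 0:
                draws[j // config.thin] = q

    np.seterr(**old_err)
    rhat_da = az.rhat(
        az.convert_to_dataset(np.moveaxis(draws, 1, 0), group="posterior")
    )["x"]
    rhat = np.asarray(rhat_da)
    samples = PosteriorSamples(
        chain=draws,
        names=names,
        rhat=rhat,
        acceptance_rate=float(np.mean(accept_hist[config.n_burn:])),
        n_divergent=n_divergent,
    )
    if not samples.converged:
        logger.warning(
            "sampler not converged: max R-hat %.4f (threshold %.2f)",
            samples.max_rhat(), RHAT_THRESHOLD,
        )
    if n_divergent:
        logger.warning("%d divergent/out-of-support trajectories", n_divergent)
    return samples


def hpd(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``ceil(mass * n)`` sorted draws."""
    x = np.sort(np.asarray(samples, float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("no draws")
    if not (0.0 < mass <= 1.0):
        raise ValueError("mass must be in (0, 1]")
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


def posterior_mode(samples: np.ndarray, grid_size: int = 512) -> float:
    """Mode of a Gaussian-KDE (Silverman bandwidth) over the draws,
    evaluated on a grid spanning the sample range."""
    x = np.asarray(samples, float).ravel()
    if x.size == 0:
        raise ValueError("no draws")
    lo, hi = x.min(), x.max()
    if lo == hi:
        return float(lo)
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(lo, hi, grid_size)
    return float(grid[np.argmax(kde(grid))])


def summarize(samples: np.ndarray, mass: float = 0.95,
              rhat: float = np.nan) -> PosteriorSummary:
    x = np.asarray(samples, float).ravel()
    low, high = hpd(x, mass)
    return PosteriorSummary(
        mode=posterior_mode(x),
        hpd_low=low,
        hpd_high=high,
        n_samples=x.size,
        rhat=rhat,
        samples_ref=x,
    )


# ---------------------------------------------------------------------------
# PSIS-LOO


@dataclass(frozen=True)
class LooResult:
    elpd: float
    se: float
    p_loo: float
    pareto_k: np.ndarray

    @property
    def pareto_k_warnings(self) -> int:
        return int(np.sum(self.pareto_k > 0.7))


@dataclass(frozen=True)
class ModelComparisonResult:
    """PSIS-LOO ranking over model variants (rank 0 = best)."""

    table: pd.DataFrame

    @property
    def best(self) -> str:
        return str(self.table.index[0])

    def rank(self, name: str) -> int:
        return int(self.table.loc[name, "rank"])

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:.2f}")


def _loglik_to_idata(loglik: np.ndarray, n_chains: int = 4) -> az.InferenceData:
    loglik = np.asarray(loglik, float)
    if loglik.ndim != 2:
        raise ValueError("expected a (draws, observations) matrix")
    if not np.all(np.isfinite(loglik)):
        raise ValueError("non-finite pointwise log-likelihoods")
    n, m = loglik.shape
    n_chains = min(n_chains, n)
    n_keep = (n // n_chains) * n_chains
    arr = loglik[:n_keep].reshape(n_chains, n_keep // n_chains, m)
    dummy = arr.sum(axis=-1)
    return az.from_dict(posterior={"lp": dummy}, log_likelihood={"obs": arr})


def psis_loo(loglik: np.ndarray) -> LooResult:
    """PSIS-LOO expected log predictive density from a pointwise
    log-likelihood matrix (draws x observations)."""
    res = az.loo(_loglik_to_idata(loglik), pointwise=True)
    return LooResult(
        elpd=float(res.elpd_loo),
        se=float(res.se),
        p_loo=float(res.p_loo),
        pareto_k=np.asarray(res.pareto_k),
    )


def compare_models(logliks: Mapping[str, np.ndarray]) -> ModelComparisonResult:
    """Rank model variants by PSIS-LOO elpd."""
    comp = az.compare(
        {name: _loglik_to_idata(ll) for name, ll in logliks.items()},
        ic="loo",
    )
    table = pd.DataFrame(
        {
            "rank": comp["rank"].astype(int),
            "elpd": comp["elpd_loo"],
            "elpd_diff": comp["elpd_diff"],
            "diff_se": comp["dse"],
        }
    )
    warnings = {
        name: psis_loo(ll).pareto_k_warnings for name, ll in logliks.items()
    }
    table["pareto_k_warnings"] = pd.Series(warnings)
    table = table.sort_values("rank")
    return ModelComparisonResult(table=table)
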