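"""Shared MCMC infrastructure: configuration, posterior container, diagnostics.

Samplers in this package are conjugate Gibbs (regression coefficients and
variances) with Metropolis steps only where a conditional is non-standard
(latent states of the state-space model). Convergence is summarized with
the rank-normalized split-chain potential scale reduction factor (R-hat)
computed by arviz; fits with any R-hat at or above the threshold are
flagged, never silently accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

RHAT_THRESHOLD = 1.1


@dataclass
class MCMCConfig:
    """Chains/iterations follow the analysis defaults; reduce for testing.

    `coef_prior_sd` is the SD of the diffuse Normal(0, sd²) prior on every
    regression coefficient; `sd_prior_upper` bounds the Uniform(0, upper)
    prior on residual/process/observation SDs.
    """

    chains: int = 3
    iterations: int = 50_000
    burn_in: int = 10_000
    thin: int = 5
    seed: int | None = None
    coef_prior_sd: float = 100.0
    sd_prior_upper: float = 100.0

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class PosteriorFit:
    """Retained draws plus summaries for one fitted model.

    `draws` maps parameter name to a (chains, n_retained) array. `summary`
    has one row per parameter: mean, sd, q2.5, q97.5, rhat, influential
    (95% credible interval excludes zero; NaN for scale parameters).
    """

    draws: dict[str, np.ndarray]
    summary: pd.DataFrame
    bayes_p: float | None = None
    converged: bool = True
    warnings: list[str] = field(default_factory=list)

    def stacked(self, name: str) -> np.ndarray:
        """All chains' retained draws of one parameter, concatenated."""
        return self.draws[name].reshape(-1)

    def mean(self, name: str) -> float:
        return float(self.summary.loc[name, "mean"])

    def credible_interval(self, name: str) -> tuple[float, float]:
        row = self.summary.loc[name]
        return float(row["q2.5"]), float(row["q97.5"])


def sample_sigma2_trunc(
    shape: float, scale: float, upper_sd: float, rng: np.random.Generator
) -> float:
    """Draw σ² from InvGamma(shape, scale) truncated to σ < upper_sd.

    This is the full conditional of the variance under a flat Uniform(0,
    upper) prior on the SD: p(σ²) ∝ (σ²)^(−shape−1) exp(−scale/σ²) on
    (0, upper²).
    """
    upper_var = upper_sd**2
    # σ² = scale / Gamma(shape, 1); truncation σ² < upper² ⟺ g > scale/upper².
    # The bound is rarely active for a diffuse prior, so rejection is cheap.
    lo = scale / upper_var
    for _ in range(16):
        g = rng.gamma(shape)
        if g > lo:
            return float(scale / g)
    cdf_hi = stats.invgamma.cdf(upper_var, shape, scale=scale)
    if cdf_hi <= 0.0:
        # numerically all mass above the bound; return the bound
        log.warning("variance conditional truncated at prior upper bound")
        return upper_var
    u = rng.uniform(0.0, cdf_hi)
    return float(stats.invgamma.ppf(u, shape, scale=scale))


def summarize_draws(
    draws: dict[str, np.ndarray],
    scale_params: tuple[str, ...] = (),
    rhat_threshold: float = RHAT_THRESHOLD,
) -> tuple[pd.DataFrame, bool]:
    """Posterior summary table and a converged flag.

    R-hat is the rank-normalized split-chain estimator (arviz). The
    `influential` column flags coefficients whose 95% credible interval
    excludes zero; scale parameters listed in `scale_params` are exempt.
    """
    ds = az.convert_to_dataset({k: v for k, v in draws.items()})
    rhat = az.rhat(ds)
    rows = {}
    for name, arr in draws.items():
        flat = arr.reshape(-1)
        lo, hi = np.quantile(flat, [0.025, 0.975])
        r = float(rhat[name].values)
        rows[name] = {
            "mean": float(flat.mean()),
            "sd": float(flat.std(ddof=1)),
            "q2.5": float(lo),
            "q97.5": float(hi),
            "rhat": r,
            "influential": (np.nan if name in scale_params
                            else bool(lo > 0 or hi < 0)),
        }
    summary = pd.DataFrame.from_dict(rows, orient="index")
    converged = bool((summary["rhat"] < rhat_threshold).all())
    if not converged:
        log.warning("non-convergence: max rhat = %.3f", summary["rhat"].max())
    return summary, converged


def chain_seeds(config: MCMCConfig, salt: int = 0) -> list[np.random.Generator]:
    """One independent Generator per chain, derived from the config seed."""
    if config.seed is None:
        ss = np.random.SeedSequence()
    else:
        ss = np.random.SeedSequence([config.seed, salt])
    return [np.random.default_rng(s) for s in ss.spawn(config.chains)]
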