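"""Posterior summaries: Pagel's lambda, effect tables, prediction curves."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import gaussian_kde

from .design import Model
from .sampler import Posterior

__all__ = [
    "LambdaSummary",
    "pagel_lambda",
    "summarize_effects",
    "predict_curve",
]

#: latent logistic-link variance added to the lambda denominator for
#: binary/binomial responses
LOGIT_LINK_VARIANCE = math.pi**2 / 3.0

LAMBDA_DENOMINATORS = ("latent", "no_link", "species")


@dataclass
class LambdaSummary:
    samples: np.ndarray
    mean: float
    ci_lower: float
    ci_upper: float
    denominator: str


def pagel_lambda(posterior: Posterior, denominator: str = "latent") -> LambdaSummary:
    """Per-sample phylogenetic signal and its posterior summary.

    denominator:
      ``latent`` (default)
          V_phylo / (V_phylo + sum of other variance components + residual
          overdispersion variance + pi^2/3), the latent-scale convention for
          binomial responses;
      ``no_link``
          as above without the pi^2/3 link variance (sensitivity option);
      ``species``
          V_phylo / (V_phylo + V_species_identity): the branch-length-
          transformation mixing weight, commensurate with a generator that
          mixes the phylogenetic correlation with the identity.
    """
    if denominator not in LAMBDA_DENOMINATORS:
        raise ValueError(f"denominator must be one of {LAMBDA_DENOMINATORS}")
    if "phylogeny" not in posterior.variance_names:
        raise ValueError("model has no phylogeny random term")
    v_phylo = posterior.variance_column("phylogeny")
    if denominator == "species":
        if "species_identity" not in posterior.variance_names:
            raise ValueError("'species' denominator needs a species_identity term")
        denom = v_phylo + posterior.variance_column("species_identity")
    else:
        others = sum(
            posterior.variance_column(name)
            for name in posterior.variance_names
            if name != "phylogeny"
        )
        denom = v_phylo + others + posterior.residual_variance
        if denominator == "latent":
            denom = denom + LOGIT_LINK_VARIANCE
    samples = v_phylo / denom
    lo, hi = np.quantile(samples, [0.025, 0.975])
    return LambdaSummary(
        samples=samples,
        mean=float(samples.mean()),
        ci_lower=float(lo),
        ci_upper=float(hi),
        denominator=denominator,
    )


def _posterior_mode(samples: np.ndarray) -> float:
    """Highest-density point of a kernel density estimate."""
    if np.allclose(samples, samples[0]):
        return float(samples[0])
    kde = gaussian_kde(samples)
    grid = np.linspace(samples.min(), samples.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def summarize_effects(posterior: Posterior, ci: float = 0.95) -> pd.DataFrame:
    """Per fixed term: posterior mean, mode, equal-tailed CI, and the
    CI-excludes-zero significance flag; rows follow the design order."""
    if posterior.n_retained == 0:
        raise ValueError("empty posterior")
    a = (1.0 - ci) / 2.0
    rows = []
    for name in posterior.beta_names:
        x = posterior.beta_column(name)
        lo, hi = np.quantile(x, [a, 1.0 - a])
        mean = float(x.mean())
        if not (lo <= mean <= hi):  # heavy-tailed draws only
            warnings.warn(f"{name}: posterior mean outside the {ci:.0%} CI")
        rows.append(
            {
                "term": name,
                "posterior_mean": mean,
                "posterior_mode": _posterior_mode(x),
                "ci_lower": float(lo),
                "ci_upper": float(hi),
                "significant": bool(lo > 0.0 or hi < 0.0),
            }
        )
    return pd.DataFrame(rows)


def predict_curve(
    posterior: Posterior,
    model: Model,
    times: np.ndarray | None = None,
    levels: list | None = None,
) -> pd.DataFrame:
    """Population-level decline curves with 95% credible bands.

    For each predictor level and time, the fixed-effect linear predictor is
    inverse-logit transformed per retained sample (random effects
    marginalized at zero) and scaled to percent; the point estimate is the
    posterior mean and the band the 2.5/97.5 percentiles.  Categorical
    predictors get one curve per level; the continuous seed-mass predictor
    is evaluated at its centering value unless explicit values are given.
    """
    times = np.linspace(0.0, 10.0, 101) if times is None else np.asarray(times, float)
    if times.min() < 0.0 or times.max() > 10.0:
        warnings.warn(
            "prediction times outside [0, 10] years extrapolate beyond the "
            "modeled window"
        )
    if levels is None:
        if model.predictor_levels is not None:
            levels = list(model.predictor_levels)
        elif model.spec.predictor == "none":
            levels = ["all"]
        else:
            levels = [model.predictor_reference or 0.0]

    rows = []
    for level in levels:
        design = np.stack(
            [
                model.fixed_row(t, level if model.spec.predictor != "none" else None)
                for t in times
            ]
        )
        eta = posterior.beta @ design.T  # (samples, times)
        pct = 100.0 * expit(eta)
        fit = pct.mean(axis=0)
        lo, hi = np.percentile(pct, [2.5, 97.5], axis=0)
        for j, t in enumerate(times):
            rows.append(
                {
                    "group": str(level),
                    "time": float(t),
                    "fit_pct": float(fit[j]),
                    "lo_pct": float(lo[j]),
                    "hi_pct": float(hi[j]),
                }
            )
    return pd.DataFrame(rows)
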