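"""Probit-linear seed-survival fits and the time to 50% viability (P50).

The survival model is nu = K_i - p / sigma: viability (as a normal
equivalent deviate on the default probit scale, or as a raw percentage on
the percent scale) declines linearly with burial time p.  sigma is the
standard deviation, in years, of the distribution of seed deaths in time.
P50 follows in closed form: the time at which the fitted line crosses
viability 50% (probit 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "probit",
    "ViabilityFit",
    "fit_viability",
    "p50",
    "GroupP50Summary",
    "group_p50",
    "fit_all_species",
]

K_I_MODES = ("fixed_full", "fixed_measured", "free")
SCALES = ("probit", "percent")


def probit(v_pct: float, n: int = 100) -> float:
    """Normal equivalent deviate of a viability percentage.

    Exact 0% / 100% observations carry no probit; they are clamped to the
    half-count bounds 0.5/n and 1 - 0.5/n of the bag size first.
    """
    if not 0.0 <= v_pct <= 100.0:
        raise ValueError(f"viability percentage out of range: {v_pct}")
    lo, hi = 0.5 / n, 1.0 - 0.5 / n
    p = min(max(v_pct / 100.0, lo), hi)
    return float(stats.norm.ppf(p))


@dataclass(frozen=True)
class ViabilityFit:
    """Least-squares fit of the survival line for one species.

    On the probit scale ``p50 = sigma * k_i``; on the percent scale
    ``p50 = sigma * (k_i - 50)``.  ``censored`` marks fits with no decline
    signal (non-negative slope), for which p50 is +inf.
    """

    species_id: str
    scale: str
    k_i: float
    sigma: float
    p50: float
    rss: float
    censored: bool = False
    n_bags: int = 0


def _transform(v_pct: np.ndarray, scale: str, n_seeds: int) -> np.ndarray:
    if scale == "probit":
        return np.array([probit(v, n=n_seeds) for v in v_pct])
    return np.asarray(v_pct, dtype=float)


def fit_viability(
    times: np.ndarray,
    viability_pct: np.ndarray,
    *,
    species_id: str = "",
    k_i_mode: str = "fixed_full",
    scale: str = "probit",
    pre_burial_pct: float | None = None,
    n_seeds: int = 100,
) -> ViabilityFit:
    """Fit nu = K_i - p/sigma to per-bag viability observations.

    k_i_mode:
      ``fixed_full`` (default) pins the intercept at full initial viability
      (clamped 100%), ``fixed_measured`` pins it at the measured pre-burial
      viability, ``free`` estimates it.
    """
    if k_i_mode not in K_I_MODES:
        raise ValueError(f"k_i_mode must be one of {K_I_MODES}")
    if scale not in SCALES:
        raise ValueError(f"scale must be one of {SCALES}")
    times = np.asarray(times, dtype=float)
    viability_pct = np.asarray(viability_pct, dtype=float)
    if times.shape != viability_pct.shape:
        raise ValueError("times and viability_pct must have equal length")
    if times.size < 3 or np.unique(times).size < 2:
        raise ValueError(
            f"{species_id or 'fit'}: need >= 3 bags across >= 2 distinct times"
        )

    y = _transform(viability_pct, scale, n_seeds)

    if k_i_mode == "free":
        slope, intercept = np.polyfit(times, y, 1)
        k_i = float(intercept)
    else:
        if k_i_mode == "fixed_full":
            full = 100.0
            k_i = probit(full, n=n_seeds) if scale == "probit" else full
        else:
            if pre_burial_pct is None:
                raise ValueError("fixed_measured requires pre_burial_pct")
            k_i = (
                probit(pre_burial_pct, n=n_seeds)
                if scale == "probit"
                else float(pre_burial_pct)
            )
        # regression through the pinned intercept: y - k_i = slope * p
        slope = float(np.sum(times * (y - k_i)) / np.sum(times**2))

    resid = y - (k_i + slope * times)
    rss = float(np.sum(resid**2))

    if slope >= -1e-12:  # no decline signal (tolerates float noise on flat data)
        return ViabilityFit(
            species_id=species_id,
            scale=scale,
            k_i=float(k_i),
            sigma=math.inf,
            p50=math.inf,
            rss=rss,
            censored=True,
            n_bags=times.size,
        )

    sigma = -1.0 / float(slope)
    return ViabilityFit(
        species_id=species_id,
        scale=scale,
        k_i=float(k_i),
        sigma=sigma,
        p50=_p50_closed_form(scale, float(k_i), sigma),
        rss=rss,
        censored=False,
        n_bags=times.size,
    )


def _p50_closed_form(scale: str, k_i: float, sigma: float) -> float:
    if scale == "probit":
        return sigma * k_i
    return sigma * (k_i - 50.0)


def p50(fit: ViabilityFit) -> float:
    """Time for fitted viability to fall to 50%; +inf for censored fits."""
    if fit.censored or not math.isfinite(fit.sigma):
        return math.inf
    return _p50_closed_form(fit.scale, fit.k_i, fit.sigma)


@dataclass(frozen=True)
class GroupP50Summary:
    """Group-level P50 spread is reported two ways — the across-species
    min-max range and the 2.5/97.5 percentile spread — since either could
    be meant by a printed "(range)"."""

    group: str
    central: float  # NaN when the group has no finite fit
    range_low: float
    range_high: float
    q2_5: float
    q97_5: float
    n_finite: int
    n_censored: int
    central_statistic: str = "median"


def group_p50(
    fits: list[ViabilityFit],
    status_by_species: dict[str, str],
    central: str = "median",
) -> list[GroupP50Summary]:
    """Summarize per-species P50 within invasion-status groups.

    Central tendency is the median (configurable to mean) of finite P50
    values; the range is their min-max.  Censored (+inf) fits are counted
    but excluded from the summary statistics.
    """
    if central not in ("median", "mean"):
        raise ValueError("central must be 'median' or 'mean'")
    groups: dict[str, list[float]] = {}
    censored: dict[str, int] = {}
    for fit in fits:
        g = status_by_species[fit.species_id]
        groups.setdefault(g, [])
        censored.setdefault(g, 0)
        if fit.censored or not math.isfinite(fit.p50):
            censored[g] += 1
        else:
            groups[g].append(fit.p50)
    out = []
    for g in sorted(groups):
        vals = groups[g]
        if vals:
            stat = float(np.median(vals)) if central == "median" else float(np.mean(vals))
            lo, hi = float(min(vals)), float(max(vals))
            q_lo, q_hi = (float(q) for q in np.percentile(vals, [2.5, 97.5]))
        else:
            stat = lo = hi = q_lo = q_hi = float("nan")
        out.append(
            GroupP50Summary(
                group=g,
                central=stat,
                range_low=lo,
                range_high=hi,
                q2_5=q_lo,
                q97_5=q_hi,
                n_finite=len(vals),
                n_censored=censored[g],
                central_statistic=central,
            )
        )
    return out


def fit_all_species(
    fate_table: pd.DataFrame,
    *,
    k_i_mode: str = "fixed_full",
    scale: str = "probit",
    pre_burial_by_species: dict[str, float] | None = None,
    n_seeds: int = 100,
) -> list[ViabilityFit]:
    """Fit the survival line per species on a tidy FateSummary table,
    pooling all replicate bags."""
    fits = []
    for sp, sub in fate_table.groupby("species_id", sort=True):
        pre = (pre_burial_by_species or {}).get(sp)
        fits.append(
            fit_viability(
                sub["years_since_burial"].to_numpy(),
                sub["viability_pct"].to_numpy(),
                species_id=str(sp),
                k_i_mode=k_i_mode,
                scale=scale,
                pre_burial_pct=pre,
                n_seeds=n_seeds,
            )
        )
    return fits
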