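"""Model assembly: response counts, fixed design, random-effect structure."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..core import BagRecord, SpeciesTraits
from ..phylo import PhyloCorrelation, PSD_JITTER

__all__ = [
    "ChainConfig",
    "PriorConfig",
    "ModelSpec",
    "RandomTerm",
    "Model",
    "SeparationWarning",
    "build_model",
    "RESPONSES",
    "PREDICTORS",
    "RANDOM_TERMS",
]

RESPONSES = ("viability", "germinability")
PREDICTORS = ("status", "log_seed_mass", "life_form", "glossbank_type", "none")
RANDOM_TERMS = ("phylogeny", "species_identity", "triplet", "row_sequence", "row_number")


class SeparationWarning(UserWarning):
    """Response column is all-success or all-failure (quasi-separation)."""


@dataclass(frozen=True)
class ChainConfig:
    """MCMC bookkeeping; retained samples = floor((n_iter - burn_in)/thin)."""

    n_iter: int = 20_000
    burn_in: int = 2_000
    thin: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass(frozen=True)
class PriorConfig:
    """Weakly informative defaults: fixed effects N(0, fixed_sd^2);
    random-effect SDs half-Cauchy(variance_scale); the per-observation
    overdispersion variance is fixed (0 disables the term)."""

    fixed_sd: float = 10.0
    variance_scale: float = 1.0
    residual_variance: float = 1.0

    def __post_init__(self) -> None:
        if self.fixed_sd <= 0 or self.variance_scale <= 0:
            raise ValueError("prior scales must be > 0")
        if self.residual_variance < 0:
            raise ValueError("residual_variance must be >= 0")


@dataclass(frozen=True)
class ModelSpec:
    """One model: a response, a species-level predictor crossed with time,
    and an ordered set of random terms."""

    response: str = "viability"
    predictor: str = "status"
    random_terms: tuple[str, ...] = RANDOM_TERMS
    priors: PriorConfig = field(default_factory=PriorConfig)
    chains: ChainConfig = field(default_factory=ChainConfig)

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(f"response must be one of {RESPONSES}")
        if self.predictor not in PREDICTORS:
            raise ValueError(f"predictor must be one of {PREDICTORS}")
        bad = [t for t in self.random_terms if t not in RANDOM_TERMS]
        if bad:
            raise ValueError(f"unknown random terms {bad}")


@dataclass
class RandomTerm:
    """One random-effect grouping: level index per row plus, for the
    phylogenetic term, the Cholesky factor of the correlation."""

    name: str
    levels: list
    index: np.ndarray  # row -> level position
    chol: np.ndarray | None = None  # None => identity structure

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass
class Model:
    """Assembled data for the sampler, plus metadata for prediction."""

    spec: ModelSpec
    y: np.ndarray  # successes per bag
    n: np.ndarray  # trials per bag
    X: np.ndarray
    x_names: list[str]
    terms: list[RandomTerm]
    times: np.ndarray
    meta: pd.DataFrame
    predictor_levels: list | None  # categorical levels, or None for continuous
    predictor_reference: float | None  # centering value for continuous predictor

    @property
    def n_obs(self) -> int:
        return self.y.size

    def fixed_row(self, time: float, level) -> np.ndarray:
        """Design row for prediction at a time and predictor level."""
        row = {name: 0.0 for name in self.x_names}
        row["intercept"] = 1.0
        row["time"] = time
        pred = self.spec.predictor
        if pred == "none":
            pass
        elif self.predictor_levels is not None:
            if level != self.predictor_levels[0]:
                row[f"{pred}[{level}]"] = 1.0
                row[f"{pred}[{level}]:time"] = time
        else:
            centered = float(level) - (self.predictor_reference or 0.0)
            row[pred] = centered
            row[f"{pred}:time"] = centered * time
        return np.array([row[name] for name in self.x_names])


def _trait_value(tr: SpeciesTraits, predictor: str):
    if predictor == "status":
        return tr.invasion_status.value
    if predictor == "life_form":
        return tr.life_form.value
    if predictor == "glossbank_type":
        return tr.glossbank_type.value
    if predictor == "log_seed_mass":
        return math.log(tr.seed_mass)
    return None


def build_model(
    records: list[BagRecord],
    traits: list[SpeciesTraits],
    correlation: PhyloCorrelation | None,
    spec: ModelSpec,
) -> Model:
    """Assemble per-bag binomial responses and design matrices.

    Viability counts (viable, buried) use every bag; germinability counts
    (germinated, viable) drop bags with no viable seed.  The time covariate
    enters raw in years, so slopes are logits/year with the intercept at
    burial.  Species with a missing external seed-bank label are dropped
    from glossbank models.
    """
    if not records:
        raise ValueError("no records")
    trait_by_sp = {t.species_id: t for t in traits}
    missing = sorted({r.species_id for r in records} - set(trait_by_sp))
    if missing:
        raise ValueError(f"species missing from trait table: {missing}")

    rows = []
    for r in records:
        if spec.response == "viability":
            succ, tot = r.n_viable, r.n_buried
        else:
            if r.n_viable == 0:
                continue  # germinability undefined
            succ, tot = r.n_germinated, r.n_viable
        tr = trait_by_sp[r.species_id]
        if spec.predictor == "glossbank_type" and tr.glossbank_type.value == "missing":
            continue
        rows.append(
            {
                "species_id": r.species_id,
                "replicate_id": r.replicate_id,
                "years_since_burial": r.years_since_burial,
                "row_number": r.row_number,
                "row_sequence": r.row_sequence,
                "success": succ,
                "trials": tot,
                "pred": _trait_value(tr, spec.predictor),
            }
        )
    if not rows:
        raise ValueError("no usable rows for this response/predictor")
    meta = pd.DataFrame(rows)

    y = meta["success"].to_numpy(dtype=float)
    n = meta["trials"].to_numpy(dtype=float)
    if np.all(y == 0) or np.all(y == n):
        warnings.warn(
            f"{spec.response}: response is all-{'zero' if np.all(y == 0) else 'one'}; "
            "quasi-separation likely",
            SeparationWarning,
        )

    t = meta["years_since_burial"].to_numpy(dtype=float)
    cols = {"intercept": np.ones_like(t), "time": t}
    pred_levels: list | None = None
    pred_ref: float | None = None
    if spec.predictor in ("status", "life_form", "glossbank_type"):
        levels = sorted(meta["pred"].unique())
        pred_levels = levels
        for lev in levels[1:]:
            ind = (meta["pred"] == lev).to_numpy(dtype=float)
            cols[f"{spec.predictor}[{lev}]"] = ind
            cols[f"{spec.predictor}[{lev}]:time"] = ind * t
    elif spec.predictor == "log_seed_mass":
        vals = meta["pred"].to_numpy(dtype=float)
        pred_ref = float(vals.mean())
        centered = vals - pred_ref
        cols["log_seed_mass"] = centered
        cols["log_seed_mass:time"] = centered * t
    X = np.column_stack(list(cols.values()))
    x_names = list(cols)

    terms: list[RandomTerm] = []
    species_levels = sorted(meta["species_id"].unique())
    for name in spec.random_terms:
        if name == "phylogeny":
            if correlation is None:
                raise ValueError("phylogeny term requires a correlation matrix")
            absent = sorted(set(species_levels) - set(correlation.species))
            if absent:
                raise ValueError(f"species missing from correlation: {absent}")
            if len(species_levels) < 2:
                raise ValueError(
                    "phylogeny term is degenerate with a single species"
                )
            sub = correlation.subset(species_levels)
            idx = meta["species_id"].map(
                {s: i for i, s in enumerate(species_levels)}
            ).to_numpy()
            terms.append(
                RandomTerm("phylogeny", species_levels, idx, chol=sub.cholesky(PSD_JITTER))
            )
        elif name == "species_identity":
            idx = meta["species_id"].map(
                {s: i for i, s in enumerate(species_levels)}
            ).to_numpy()
            terms.append(RandomTerm("species_identity", species_levels, idx))
        elif name == "triplet":
            keys = list(zip(meta["species_id"], meta["years_since_burial"]))
            levels = sorted(set(keys))
            lut = {k: i for i, k in enumerate(levels)}
            terms.append(
                RandomTerm("triplet", levels, np.array([lut[k] for k in keys]))
            )
        elif name in ("row_sequence", "row_number"):
            vals = meta[name].tolist()
            levels = sorted(set(vals))
            lut = {k: i for i, k in enumerate(levels)}
            terms.append(
                RandomTerm(name, levels, np.array([lut[v] for v in vals]))
            )

    return Model(
        spec=spec,
        y=y,
        n=n,
        X=X,
        x_names=x_names,
        terms=terms,
        times=t,
        meta=meta,
        predictor_levels=pred_levels,
        predictor_reference=pred_ref,
    )
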