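"""Synthetic burial experiments with known ground truth.

Generates a pure-birth phylogeny, phylogenetically correlated per-species
decline curves, a spatial layout of bags in rows of six, and bag-level
binomial seed-fate counts — emitting the same delimited tables and Newick
tree the real pipeline consumes, plus a truth table sufficient to score
parameter recovery downstream.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from scipy.stats import norm

from .core import BagRecord, SpeciesTraits, InvasionStatus, LifeForm, SeedBankType
from .phylo import Phylogeny, PhyloCorrelation, phylo_correlation, PSD_JITTER

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "simulate_species_params",
    "simulate_experiment",
    "simulate_dataset",
    "write_dataset",
]


@dataclass
class SimulationConfig:
    """Design and generating-model parameters; defaults mirror the target
    experiment: 59 species (21 invasive / 38 naturalized), 3 replicate bags
    per exhumation year, 7 yearly exhumations of 100-seed bags."""

    n_invasive: int = 21
    n_naturalized: int = 38
    n_replicates: int = 3
    exhumation_years: tuple[float, ...] = (1.5, 2.5, 3.5, 4.5, 5.5, 6.5, 7.5)
    seeds_per_bag: int = 100
    lambda_true: float = 0.8
    intercept_invasive: float = 2.5
    intercept_naturalized: float = 2.5
    slope_invasive: float = -0.80
    slope_naturalized: float = -0.55
    sd_phylo: float = 1.0
    sd_species: float = 0.0
    sd_slope: float = 0.0
    sd_bag: float = 0.5
    germ_intercept: float = 1.5
    germ_slope: float = -0.10
    spont_fraction: float = 0.8
    birth_rate: float = 1.0
    status_clustering: float = 0.0
    probit_generator: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_invasive + self.n_naturalized < 2:
            raise ValueError("need at least 2 species")
        for name in ("sd_phylo", "sd_species", "sd_slope", "sd_bag"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        yrs = tuple(self.exhumation_years)
        if any(y <= 0 for y in yrs) or any(
            b <= a for a, b in zip(yrs, yrs[1:])
        ):
            raise ValueError("exhumation_years must be positive and strictly increasing")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must lie in [0, 1]")
        if not 0.0 <= self.spont_fraction <= 1.0:
            raise ValueError("spont_fraction must lie in [0, 1]")

    @property
    def n_species(self) -> int:
        return self.n_invasive + self.n_naturalized

    @property
    def bags_per_species(self) -> int:
        return self.n_replicates * len(self.exhumation_years)

    def species_ids(self) -> list[str]:
        width = len(str(self.n_species))
        return [f"sp{idx + 1:0{width}d}" for idx in range(self.n_species)]

    def to_yaml(self) -> str:
        d = asdict(self)
        d["exhumation_years"] = list(d["exhumation_years"])
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        d = yaml.safe_load(text)
        if "exhumation_years" in d:
            d["exhumation_years"] = tuple(d["exhumation_years"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Tree


def _yule_tree(n_tips: int, rate: float, rng: np.random.Generator) -> dendropy.Tree:
    """Forward pure-birth simulation; returns an ultrametric dendropy tree."""
    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    root = tree.seed_node
    root.birth_time = 0.0
    # single stem lineage below the origin, so even the first split leaves a
    # shared root-to-MRCA path (off-diagonal correlations strictly positive)
    stem = dendropy.Node()
    stem.birth_time = 0.0
    root.add_child(stem)
    active = [stem]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (rate * len(active)))
        parent = active.pop(rng.integers(len(active)))
        parent.split_time = t
        for _ in range(2):
            child = dendropy.Node()
            child.birth_time = t
            parent.add_child(child)
            active.append(child)
    # extend the present beyond the last split so no pendant edge is zero
    t += rng.exponential(1.0 / (rate * len(active)))
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = 0.0
            continue
        end = t if node.is_leaf() else node.split_time
        node.edge.length = end - node.birth_time
    return tree


def _assign_status(
    tip_order: list[str], config: SimulationConfig, rng: np.random.Generator
) -> dict[str, str]:
    """Interleave invasive/naturalized labels over tips.

    ``status_clustering`` = 0 gives a uniformly random assignment; values
    toward 1 increasingly place the invasive labels as contiguous runs in
    the tree's tip order (phylogenetically clumped), while both statuses
    still span multiple clades for intermediate settings.
    """
    n = len(tip_order)
    n_inv = config.n_invasive
    if config.status_clustering <= 0:
        inv_idx = set(rng.choice(n, size=n_inv, replace=False).tolist())
    else:
        n_runs = max(1, round(n_inv * (1.0 - config.status_clustering)))
        starts = sorted(rng.choice(n, size=n_runs, replace=False).tolist())
        inv_idx = set()
        cursor = 0
        per_run = math.ceil(n_inv / n_runs)
        for s in starts:
            for k in range(per_run):
                if len(inv_idx) >= n_inv:
                    break
                inv_idx.add((s + k) % n)
            cursor += 1
        # fill any shortfall caused by run overlap
        pool = [i for i in range(n) if i not in inv_idx]
        while len(inv_idx) < n_inv:
            inv_idx.add(pool.pop(int(rng.integers(len(pool)))))
    return {
        tip: ("invasive" if i in inv_idx else "naturalized")
        for i, tip in enumerate(tip_order)
    }


def simulate_tree(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[Phylogeny, dict[str, str]]:
    """Pure-birth ultrametric tree, depth normalized to 1, with invasion
    status assigned across its tips; returns (tree, status-by-species)."""
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    tree = _yule_tree(config.n_species, config.birth_rate, rng)
    ids = config.species_ids()
    leaves = list(tree.leaf_node_iter())
    for leaf, sp in zip(leaves, ids):
        leaf.taxon = tree.taxon_namespace.new_taxon(label=sp)
    # normalize depth to 1
    node, depth = leaves[0], 0.0
    while node.parent_node is not None:
        depth += node.edge.length or 0.0
        node = node.parent_node
    for edge in tree.preorder_edge_iter():
        if edge.length:
            edge.length = edge.length / depth
    phylo = Phylogeny(tree)
    assert phylo.is_ultrametric(rel_tol=1e-9)
    status = _assign_status(phylo.tip_labels, config, rng)
    return phylo, status


# ---------------------------------------------------------------------------
# Species parameters


def composite_covariance(
    corr: np.ndarray, lambda_true: float, sd_phylo: float, sd_species: float
) -> np.ndarray:
    """sd_phylo^2 * [lambda*C + (1-lambda)*I] + sd_species^2 * I."""
    n = corr.shape[0]
    eye = np.eye(n)
    cov = sd_phylo**2 * (lambda_true * corr + (1.0 - lambda_true) * eye)
    cov += sd_species**2 * eye
    return cov


def simulate_species_params(
    phylo: Phylogeny,
    status: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    corr: PhyloCorrelation | None = None,
) -> pd.DataFrame:
    """Draw per-species intercepts and slopes around their group means.

    Intercept deviations carry the phylogenetic structure
    ``sd_phylo^2 [lambda C + (1-lambda) I] + sd_species^2 I``; slope
    deviations are independent N(0, sd_slope^2).  The returned frame is
    itself the truth record (one row per species).
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    corr = corr if corr is not None else phylo_correlation(phylo)
    species = corr.species
    if set(species) != set(status):
        raise ValueError("tree tips and status labels disagree")
    cov = composite_covariance(
        corr.matrix, config.lambda_true, config.sd_phylo, config.sd_species
    )
    n = len(species)
    if not cov.any():
        intercept_dev = np.zeros(n)
    else:
        try:
            chol = np.linalg.cholesky(cov + PSD_JITTER * np.eye(n))
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"composite covariance not positive definite: {exc}"
            ) from exc
        intercept_dev = chol @ rng.standard_normal(n)
    slope_dev = config.sd_slope * rng.standard_normal(n)

    rows = []
    for i, sp in enumerate(species):
        st = status[sp]
        base_int = (
            config.intercept_invasive if st == "invasive" else config.intercept_naturalized
        )
        base_slope = (
            config.slope_invasive if st == "invasive" else config.slope_naturalized
        )
        intercept = base_int + intercept_dev[i]
        slope = base_slope + slope_dev[i]
        true_p50 = (-intercept / slope) if slope < 0 else math.inf
        rows.append(
            {
                "species_id": sp,
                "invasion_status": st,
                "intercept": intercept,
                "slope": slope,
                "intercept_dev": intercept_dev[i],
                "slope_dev": slope_dev[i],
                "true_p50": true_p50,
            }
        )
    return pd.DataFrame(rows)


def simulate_traits(
    params: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> list[SpeciesTraits]:
    """Trait table for the generated species; masses lognormal, life form
    and external seed-bank label random (the latter occasionally missing)."""
    traits = []
    for _, row in params.iterrows():
        gb = rng.choice(["transient", "persistent", "missing"], p=[0.35, 0.45, 0.2])
        traits.append(
            SpeciesTraits(
                species_id=row["species_id"],
                invasion_status=InvasionStatus(row["invasion_status"]),
                life_form=LifeForm(rng.choice(["annual", "perennial"])),
                seed_mass=float(np.exp(rng.normal(-1.0, 1.5))),
                glossbank_type=SeedBankType(gb),
                pre_burial_viability=float(np.round(rng.uniform(75.0, 99.5), 1)),
            )
        )
    return traits


# ---------------------------------------------------------------------------
# Experiment


def _layout_rows(
    n_species: int, n_years: int, n_replicates: int, rng: np.random.Generator
) -> dict[tuple[int, int, int], tuple[int, int]]:
    """Assign each (species, year, replicate) bag a (row_number, row_sequence).

    Bags are laid out in rows of six.  Replicates are placed in disjoint
    row blocks, so no two members of a triplet ever share a row — the
    'replicates not nearby' design constraint — and positions within each
    block are shuffled.
    """
    per_rep = n_species * n_years
    rows_per_block = math.ceil(per_rep / 6)
    layout: dict[tuple[int, int, int], tuple[int, int]] = {}
    for rep in range(n_replicates):
        positions = rng.permutation(per_rep)
        base_row = rep * rows_per_block
        k = 0
        for sp in range(n_species):
            for yr in range(n_years):
                pos = int(positions[k])
                layout[(sp, yr, rep)] = (base_row + pos // 6 + 1, pos % 6 + 1)
                k += 1
    return layout


def simulate_experiment(
    params: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[BagRecord], pd.DataFrame]:
    """Generate bag-level counts for every species x replicate x year.

    True bag viability is inverse-logit(intercept + slope*t + bag noise)
    (or the normal CDF of the same linear predictor with
    ``probit_generator``); the viable count is binomial in the bag size,
    germinated seeds binomial in the viable count, and the spontaneous /
    GA-stimulated split binomial with a fixed fraction.

    Returns the records and a per-bag truth table of latent probabilities.
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    species = params["species_id"].tolist()
    years = list(config.exhumation_years)
    layout = _layout_rows(len(species), len(years), config.n_replicates, rng)
    link = norm.cdf if config.probit_generator else expit

    records: list[BagRecord] = []
    truth_rows = []
    for si, (_, prow) in enumerate(params.iterrows()):
        for yi, t in enumerate(years):
            for rep in range(config.n_replicates):
                noise = rng.normal(0.0, config.sd_bag) if config.sd_bag > 0 else 0.0
                eta_v = prow["intercept"] + prow["slope"] * t + noise
                pi_v = float(link(eta_v))
                pi_g = float(expit(config.germ_intercept + config.germ_slope * t))
                n = config.seeds_per_bag
                viable = int(rng.binomial(n, pi_v))
                germ = int(rng.binomial(viable, pi_g)) if viable else 0
                spont = int(rng.binomial(germ, config.spont_fraction)) if germ else 0
                row_no, row_seq = layout[(si, yi, rep)]
                records.append(
                    BagRecord(
                        species_id=prow["species_id"],
                        replicate_id=rep + 1,
                        years_since_burial=t,
                        row_number=row_no,
                        row_sequence=row_seq,
                        n_buried=n,
                        n_germ_spont=spont,
                        n_germ_ga=germ - spont,
                        n_viable_stained=viable - germ,
                        n_dead=n - viable,
                    )
                )
                truth_rows.append(
                    {
                        "species_id": prow["species_id"],
                        "replicate_id": rep + 1,
                        "years_since_burial": t,
                        "true_viability": pi_v,
                        "true_germinability": pi_g,
                        "bag_noise": noise,
                    }
                )
    return records, pd.DataFrame(truth_rows)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    phylo: Phylogeny
    traits: list[SpeciesTraits]
    species_truth: pd.DataFrame
    records: list[BagRecord]
    bag_truth: pd.DataFrame


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run the whole generator from a single seed."""
    rng = np.random.default_rng(config.rng_seed)
    phylo, status = simulate_tree(config, rng)
    params = simulate_species_params(phylo, status, config, rng)
    traits = simulate_traits(params, config, rng)
    records, bag_truth = simulate_experiment(params, config, rng)
    return SyntheticDataset(
        config=config,
        phylo=phylo,
        traits=traits,
        species_truth=params,
        records=records,
        bag_truth=bag_truth,
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write records.csv, traits.csv, tree.nwk, truth tables, and config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": out / "records.csv",
        "traits": out / "traits.csv",
        "tree": out / "tree.nwk",
        "species_truth": out / "species_truth.csv",
        "bag_truth": out / "bag_truth.csv",
        "config": out / "sim_config.yaml",
    }
    from .core import records_to_frame

    records_to_frame(dataset.records).to_csv(paths["records"], index=False)
    pd.DataFrame(
        [
            {
                "species_id": tr.species_id,
                "invasion_status": tr.invasion_status.value,
                "life_form": tr.life_form.value,
                "seed_mass": tr.seed_mass,
                "glossbank_type": tr.glossbank_type.value,
                "pre_burial_viability": tr.pre_burial_viability,
            }
            for tr in dataset.traits
        ]
    ).to_csv(paths["traits"], index=False)
    dataset.phylo.write_newick(paths["tree"])
    dataset.species_truth.to_csv(paths["species_truth"], index=False)
    dataset.bag_truth.to_csv(paths["bag_truth"], index=False)
    paths["config"].write_text(dataset.config.to_yaml())
    return paths
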