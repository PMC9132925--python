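import math

import numpy as np
import pytest

from seedburial.core import records_to_frame
from seedburial.phylo import phylo_correlation
from seedburial.pglmm import (
    ChainConfig,
    ModelSpec,
    PriorConfig,
    build_model,
    pagel_lambda,
    predict_curve,
    sample_posterior,
    summarize_effects,
)
from seedburial.pglmm.design import SeparationWarning
from seedburial.pglmm.sampler import Posterior
from seedburial.simulate import SimulationConfig, simulate_dataset

from conftest import make_bag

FAST_CHAIN = ChainConfig(n_iter=1_500, burn_in=300, thin=10, rng_seed=1)


def make_posterior(beta, beta_names, variances=None, variance_names=(), resid=1.0):
    beta = np.asarray(beta, dtype=float)
    if variances is None:
        variances = np.empty((beta.shape[0], 0))
    return Posterior(
        beta=beta,
        beta_names=list(beta_names),
        variances=np.asarray(variances, dtype=float),
        variance_names=list(variance_names),
        residual_variance=resid,
        chain=ChainConfig(n_iter=100, burn_in=0, thin=1),
        accept_hmc=1.0,
        accept_var={},
        log_lik=np.zeros(beta.shape[0]),
    )


class TestChainConfig:
    def test_full_scale_retained_count(self):
        # the 10^6 / 10^4 / 100 configuration retains 9,900 samples
        assert ChainConfig(1_000_000, 10_000, 100).n_retained == 9_900

    def test_desk_scale_retained_count(self):
        assert ChainConfig(20_000, 2_000, 20).n_retained == 900

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            ChainConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            ChainConfig(thin=0)

    @pytest.mark.parametrize(
        "n_iter,burn_in,thin", [(1000, 100, 7), (5000, 499, 13), (333, 1, 3)]
    )
    def test_retained_bookkeeping_exact(self, n_iter, burn_in, thin):
        assert ChainConfig(n_iter, burn_in, thin).n_retained == (
            (n_iter - burn_in) // thin
        )


class TestBuildModel:
    def test_full_design_row_count(self):
        dataset = simulate_dataset(SimulationConfig(rng_seed=0))
        corr = phylo_correlation(dataset.phylo)
        spec = ModelSpec(response="viability", predictor="status")
        model = build_model(dataset.records, dataset.traits, corr, spec)
        assert model.n_obs == 1239  # 59 species x 21 bags
        assert model.x_names == [
            "intercept",
            "time",
            "status[naturalized]",
            "status[naturalized]:time",
        ]
        assert [t.name for t in model.terms] == [
            "phylogeny",
            "species_identity",
            "triplet",
            "row_sequence",
            "row_number",
        ]
        assert model.terms[2].n_levels == 59 * 7  # triplets

    def test_germinability_drops_zero_viable_bags(self, small_dataset):
        corr = phylo_correlation(small_dataset.phylo)
        n_zero = sum(1 for r in small_dataset.records if r.n_viable == 0)
        assert n_zero > 0  # the fixture must exercise the rule
        spec = ModelSpec(response="germinability", predictor="status")
        model = build_model(small_dataset.records, small_dataset.traits, corr, spec)
        assert model.n_obs == len(small_dataset.records) - n_zero

    def test_single_species_phylogeny_degenerate(self):
        records = [make_bag(years=t) for t in (1.5, 2.5, 3.5)]
        from seedburial.core import InvasionStatus, LifeForm, SpeciesTraits

        traits = [SpeciesTraits("spA", InvasionStatus.invasive, LifeForm.annual, 1.0)]
        from seedburial.phylo import PhyloCorrelation

        corr = PhyloCorrelation(["spA"], np.eye(1))
        spec = ModelSpec(predictor="none")
        with pytest.raises(ValueError, match="single species"):
            build_model(records, traits, corr, spec)

    def test_missing_trait_species_rejected(self, small_dataset):
        corr = phylo_correlation(small_dataset.phylo)
        spec = ModelSpec(predictor="status")
        with pytest.raises(ValueError, match="missing from the trait|missing from trait"):
            build_model(small_dataset.records, small_dataset.traits[:-1], corr, spec)

    def test_all_dead_flags_separation(self):
        records = [
            make_bag(replicate=rep, years=t, spont=0, ga=0, stained=0)
            for rep in (1, 2, 3)
            for t in (1.5, 2.5, 3.5)
        ]
        from seedburial.core import InvasionStatus, LifeForm, SpeciesTraits

        traits = [SpeciesTraits("spA", InvasionStatus.invasive, LifeForm.annual, 1.0)]
        spec = ModelSpec(predictor="none", random_terms=())
        with pytest.warns(SeparationWarning):
            build_model(records, traits, None, spec)

    def test_glossbank_missing_species_dropped(self, small_dataset):
        corr = phylo_correlation(small_dataset.phylo)
        missing = {
            t.species_id
            for t in small_dataset.traits
            if t.glossbank_type.value == "missing"
        }
        spec = ModelSpec(predictor="glossbank_type")
        model = build_model(small_dataset.records, small_dataset.traits, corr, spec)
        assert set(model.meta["species_id"]) & missing == set()


class TestSampler:
    def test_same_seed_identical_samples(self, small_dataset):
        corr = phylo_correlation(small_dataset.phylo)
        spec = ModelSpec(
            predictor="status",
            random_terms=("phylogeny", "species_identity"),
            chains=FAST_CHAIN,
        )
        model = build_model(small_dataset.records, small_dataset.traits, corr, spec)
        p1 = sample_posterior(model)
        p2 = sample_posterior(model)
        np.testing.assert_array_equal(p1.beta, p2.beta)
        np.testing.assert_array_equal(p1.variances, p2.variances)

    def test_retained_count_matches_config(self, small_dataset):
        corr = phylo_correlation(small_dataset.phylo)
        spec = ModelSpec(
            predictor="none",
            random_terms=("species_identity",),
            chains=ChainConfig(n_iter=777, burn_in=77, thin=7, rng_seed=2),
        )
        model = build_model(small_dataset.records, small_dataset.traits, corr, spec)
        posterior = sample_posterior(model)
        assert posterior.n_retained == 100
        assert (posterior.variances > 0).all()

    def test_degeneracy_matches_ml_logistic(self):
        """No random effects, no overdispersion: posterior mean within 2
        posterior SDs of maximum-likelihood logistic regression."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        records = []
        for rep in (1, 2, 3):
            for t in (1.5, 2.5, 3.5, 4.5, 5.5, 6.5, 7.5):
                p_v = 1.0 / (1.0 + math.exp(-(2.0 - 0.5 * t)))
                v = int(rng.binomial(100, p_v))
                records.append(
                    make_bag(replicate=rep, years=t, spont=0, ga=0, stained=v)
                )
        from seedburial.core import InvasionStatus, LifeForm, SpeciesTraits

        traits = [SpeciesTraits("spA", InvasionStatus.invasive, LifeForm.annual, 1.0)]
        spec = ModelSpec(
            predictor="none",
            random_terms=(),
            priors=PriorConfig(residual_variance=0.0),
            chains=ChainConfig(n_iter=6_000, burn_in=1_000, thin=5, rng_seed=3),
        )
        model = build_model(records, traits, None, spec)
        posterior = sample_posterior(model)
        ml = sm.GLM(
            np.column_stack([model.y, model.n - model.y]),
            model.X,
            family=sm.families.Binomial(),
        ).fit()
        for j in range(model.X.shape[1]):
            post_mean = posterior.beta[:, j].mean()
            post_sd = posterior.beta[:, j].std()
            assert abs(post_mean - ml.params[j]) < 2.0 * post_sd

    def test_unrecoverable_init_raises_after_retries(self, small_dataset, monkeypatch):
        import seedburial.pglmm.sampler as sampler_mod

        monkeypatch.setattr(sampler_mod, "_log_lik", lambda model, eta: math.nan)
        corr = phylo_correlation(small_dataset.phylo)
        spec = ModelSpec(
            predictor="none", random_terms=("species_identity",), chains=FAST_CHAIN
        )
        model = build_model(small_dataset.records, small_dataset.traits, corr, spec)
        with pytest.raises(RuntimeError, match="finite initial state"):
            sample_posterior(model)

    def test_diagnostics_frame(self, small_dataset):
        corr = phylo_correlation(small_dataset.phylo)
        spec = ModelSpec(
            predictor="none",
            random_terms=("species_identity",),
            chains=FAST_CHAIN,
        )
        model = build_model(small_dataset.records, small_dataset.traits, corr, spec)
        diag = sample_posterior(model).diagnostics()
        assert set(diag.columns) == {"parameter", "rhat", "ess_bulk"}
        assert (diag["ess_bulk"] > 0).all()


class TestPagelLambda:
    def test_zero_phylo_variance(self):
        post = make_posterior(
            np.zeros((50, 1)),
            ["intercept"],
            variances=np.column_stack([np.zeros(50), np.ones(50)]),
            variance_names=["phylogeny", "species_identity"],
        )
        assert pagel_lambda(post).mean == 0.0

    def test_dominant_phylo_variance_approaches_one(self):
        post = make_posterior(
            np.zeros((50, 1)),
            ["intercept"],
            variances=np.column_stack([np.full(50, 1e9), np.ones(50)]),
            variance_names=["phylogeny", "species_identity"],
        )
        assert pagel_lambda(post).mean == pytest.approx(1.0, abs=1e-6)

    def test_plug_in_value(self):
        # V_phylo=2, V_species=1, V_e=1, link pi^2/3
        post = make_posterior(
            np.zeros((10, 1)),
            ["intercept"],
            variances=np.column_stack([np.full(10, 2.0), np.ones(10)]),
            variance_names=["phylogeny", "species_identity"],
            resid=1.0,
        )
        expected = 2.0 / (2.0 + 1.0 + 1.0 + math.pi**2 / 3.0)
        assert pagel_lambda(post).mean == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.274, abs=0.001)

    def test_no_link_and_species_denominators(self):
        post = make_posterior(
            np.zeros((10, 1)),
            ["intercept"],
            variances=np.column_stack([np.full(10, 2.0), np.ones(10)]),
            variance_names=["phylogeny", "species_identity"],
            resid=1.0,
        )
        assert pagel_lambda(post, "no_link").mean == pytest.approx(2.0 / 4.0)
        assert pagel_lambda(post, "species").mean == pytest.approx(2.0 / 3.0)

    def test_requires_phylogeny_term(self):
        post = make_posterior(
            np.zeros((10, 1)),
            ["intercept"],
            variances=np.ones((10, 1)),
            variance_names=["species_identity"],
        )
        with pytest.raises(ValueError, match="phylogeny"):
            pagel_lambda(post)


class TestEffectSummaries:
    def test_all_positive_significant(self):
        post = make_posterior(np.linspace(0.5, 1.5, 100)[:, None], ["time"])
        row = summarize_effects(post).iloc[0]
        assert row["significant"]

    def test_symmetric_about_zero_not_significant(self):
        post = make_posterior(np.linspace(-1, 1, 101)[:, None], ["time"])
        row = summarize_effects(post).iloc[0]
        assert not row["significant"]

    def test_normal_samples_ci(self):
        rng = np.random.default_rng(0)
        samples = rng.normal(1.0, 0.5, size=1000)
        post = make_posterior(samples[:, None], ["time"])
        row = summarize_effects(post).iloc[0]
        assert row["ci_lower"] == pytest.approx(0.02, abs=0.1)
        assert row["ci_upper"] == pytest.approx(1.98, abs=0.1)
        assert row["significant"]
        assert row["posterior_mean"] == pytest.approx(1.0, abs=0.06)
        assert row["posterior_mode"] == pytest.approx(1.0, abs=0.2)


class TestPredictCurve:
    @pytest.fixture
    def status_model(self, small_dataset):
        corr = phylo_correlation(small_dataset.phylo)
        spec = ModelSpec(predictor="status", chains=FAST_CHAIN)
        return build_model(small_dataset.records, small_dataset.traits, corr, spec)

    def test_flat_when_no_time_effect(self, status_model):
        post = make_posterior(
            np.tile([0.5, 0.0, 0.0, 0.0], (20, 1)), status_model.x_names
        )
        curves = predict_curve(post, status_model)
        for _, group in curves.groupby("group"):
            assert group["fit_pct"].nunique() == 1

    def test_negative_slope_strictly_decreasing(self, status_model):
        post = make_posterior(
            np.tile([2.0, -0.5, 0.3, -0.2], (20, 1)), status_model.x_names
        )
        curves = predict_curve(post, status_model)
        for _, group in curves.groupby("group"):
            assert group.sort_values("time")["fit_pct"].is_monotonic_decreasing

    def test_logit_zero_gives_fifty_percent(self, status_model):
        post = make_posterior(
            np.tile([0.0, -1.0, 0.0, 0.0], (20, 1)), status_model.x_names
        )
        curves = predict_curve(post, status_model, times=np.array([0.0]))
        assert curves["fit_pct"].unique() == pytest.approx(50.0)

    def test_band_contains_fit_and_range(self, status_model):
        rng = np.random.default_rng(1)
        beta = rng.normal([2.0, -0.5, 0.3, -0.2], 0.1, size=(200, 4))
        post = make_posterior(beta, status_model.x_names)
        curves = predict_curve(post, status_model)
        assert ((curves["lo_pct"] <= curves["fit_pct"]) &
                (curves["fit_pct"] <= curves["hi_pct"])).all()
        assert curves[["fit_pct", "lo_pct", "hi_pct"]].min().min() >= 0.0
        assert curves[["fit_pct", "lo_pct", "hi_pct"]].max().max() <= 100.0

    def test_extrapolation_warns(self, status_model):
        post = make_posterior(np.zeros((10, 4)), status_model.x_names)
        with pytest.warns(UserWarning, match="extrapolate"):
            predict_curve(post, status_model, times=np.array([12.0]))

    def test_band_shrinks_with_chain_length(self):
        """Monte-Carlo error in the band shrinks as the chain grows."""
        config = SimulationConfig(
            n_invasive=3, n_naturalized=5, sd_phylo=0.5, rng_seed=10
        )
        dataset = simulate_dataset(config)
        corr = phylo_correlation(dataset.phylo)

        def width_at_t5(n_iter, burn_in):
            spec = ModelSpec(
                predictor="none",
                random_terms=("phylogeny", "species_identity"),
                chains=ChainConfig(n_iter=n_iter, burn_in=burn_in, thin=10, rng_seed=4),
            )
            model = build_model(dataset.records, dataset.traits, corr, spec)
            posterior = sample_posterior(model)
            curves = predict_curve(posterior, model, times=np.array([5.0]))
            return float((curves["hi_pct"] - curves["lo_pct"]).iloc[0])

        assert width_at_t5(20_000, 2_000) < width_at_t5(2_000, 200)
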