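"""Hamiltonian Monte Carlo for the binomial-logistic mixed model.

The latent state is non-centered: each random-effect vector is a standard
normal ``z`` scaled by its standard deviation ``s_g`` (and, for the
phylogenetic term, rotated by the Cholesky factor of the species
correlation), which keeps the geometry well conditioned when variance
components collapse toward zero.  Fixed effects and all ``z`` blocks move
jointly by HMC with dual-averaging step-size adaptation during burn-in.
Each log standard deviation moves by an adaptive random-walk Metropolis
step against its half-Cauchy prior, followed by two likelihood-invariant
moves that are essential for mixing of the variance components: an exact
Gibbs redistribution of the phylogenetic vs. species-identity split of the
summed species effect, and an interweaved centered-parameterization update
of each standard deviation.  The per-observation overdispersion term has a
fixed variance and belongs to the HMC block.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import ChainConfig, Model

__all__ = ["Posterior", "sample_posterior"]

logger = logging.getLogger(__name__)

_HMC_TARGET_ACCEPT = 0.8
_RW_TARGET_ACCEPT = 0.44
_N_LEAPFROG = 10
_MAX_INIT_ATTEMPTS = 10


@dataclass
class Posterior:
    """Retained MCMC samples of fixed effects and variance components."""

    beta: np.ndarray  # (n_retained, p)
    beta_names: list[str]
    variances: np.ndarray  # (n_retained, n_terms), variance scale
    variance_names: list[str]
    residual_variance: float
    chain: ChainConfig
    accept_hmc: float
    accept_var: dict[str, float]
    log_lik: np.ndarray

    @property
    def n_retained(self) -> int:
        return self.beta.shape[0]

    def beta_column(self, name: str) -> np.ndarray:
        return self.beta[:, self.beta_names.index(name)]

    def variance_column(self, name: str) -> np.ndarray:
        return self.variances[:, self.variance_names.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.beta, columns=self.beta_names)
        for i, name in enumerate(self.variance_names):
            df[f"V[{name}]"] = self.variances[:, i]
        df["log_lik"] = self.log_lik
        return df

    def diagnostics(self) -> pd.DataFrame:
        """Split-Rhat and bulk effective sample size per retained quantity."""
        import arviz as az

        def _stats(name: str, x: np.ndarray) -> dict:
            half = x[: 2 * (x.size // 2)].reshape(2, -1)  # split one chain in two
            return {
                "parameter": name,
                "rhat": float(az.rhat(half)),
                "ess_bulk": float(az.ess(half)),
            }

        rows = [_stats(n, self.beta_column(n)) for n in self.beta_names]
        rows += [
            _stats(f"log V[{n}]", np.log(self.variance_column(n)))
            for n in self.variance_names
        ]
        return pd.DataFrame(rows)


class _Layout:
    """Flat-vector layout: [beta | z_term_0 | ... | z_e]."""

    def __init__(self, model: Model):
        self.p = model.X.shape[1]
        self.has_e = model.spec.priors.residual_variance > 0
        sizes = [self.p] + [t.n_levels for t in model.terms]
        if self.has_e:
            sizes.append(model.n_obs)
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        self.beta_sl = slice(0, self.p)
        self.z_sl = [
            slice(int(bounds[1 + g]), int(bounds[2 + g]))
            for g in range(len(model.terms))
        ]
        self.e_sl = slice(int(bounds[-2]), int(bounds[-1])) if self.has_e else None
        self.dim = int(bounds[-1])


class _State:
    """Mutable sampler state: flat latent vector plus log SDs."""

    def __init__(self, model: Model, layout: _Layout, rng, from_prior: bool):
        self.model = model
        self.layout = layout
        self.sigma_e = math.sqrt(model.spec.priors.residual_variance)
        self.theta = np.zeros(layout.dim)
        if from_prior:
            self.theta[layout.beta_sl] = rng.normal(0.0, 1.0, size=layout.p)
            self.log_s = np.log(np.abs(rng.standard_cauchy(len(model.terms))) + 1e-3)
        else:
            self.log_s = np.full(len(model.terms), math.log(0.3))

    @property
    def beta(self) -> np.ndarray:
        return self.theta[self.layout.beta_sl]

    def z(self, g: int) -> np.ndarray:
        return self.theta[self.layout.z_sl[g]]

    @property
    def z_e(self) -> np.ndarray | None:
        return self.theta[self.layout.e_sl] if self.layout.e_sl else None

    def term_contrib(self, g: int) -> np.ndarray:
        """(W_g z_g)[idx] without the s_g scale."""
        term = self.model.terms[g]
        zg = self.z(g)
        u = term.chol @ zg if term.chol is not None else zg
        return u[term.index]

    def eta(self, theta: np.ndarray | None = None) -> np.ndarray:
        theta = self.theta if theta is None else theta
        model, layout = self.model, self.layout
        out = model.X @ theta[layout.beta_sl]
        for g, term in enumerate(model.terms):
            zg = theta[layout.z_sl[g]]
            u = term.chol @ zg if term.chol is not None else zg
            out += math.exp(self.log_s[g]) * u[term.index]
        if layout.e_sl:
            out += self.sigma_e * theta[layout.e_sl]
        return out


def _log_lik(model: Model, eta: np.ndarray) -> float:
    return float(np.sum(model.y * eta - model.n * np.logaddexp(0.0, eta)))


def _log_prior_latent(model: Model, layout: _Layout, theta: np.ndarray) -> float:
    fixed_var = model.spec.priors.fixed_sd ** 2
    beta = theta[layout.beta_sl]
    rest = theta[layout.p :]
    return -0.5 * float(beta @ beta) / fixed_var - 0.5 * float(rest @ rest)


def _log_prior_sd(log_s: float, scale: float) -> float:
    """Half-Cauchy(scale) on s, with the log-parameterization Jacobian."""
    s = math.exp(log_s)
    return -math.log1p((s / scale) ** 2) + log_s


def _grad(
    state: _State, theta: np.ndarray, eta: np.ndarray, out: np.ndarray
) -> np.ndarray:
    """Gradient of the log posterior w.r.t. the flat latent vector."""
    model, layout = state.model, state.layout
    r = model.y - model.n * expit(eta)
    out[layout.beta_sl] = model.X.T @ r
    out[layout.beta_sl] -= theta[layout.beta_sl] / model.spec.priors.fixed_sd ** 2
    for g, term in enumerate(model.terms):
        a = np.bincount(term.index, weights=r, minlength=term.n_levels)
        s = math.exp(state.log_s[g])
        sl = layout.z_sl[g]
        if term.chol is not None:
            out[sl] = s * (term.chol.T @ a)
        else:
            out[sl] = s * a
        out[sl] -= theta[sl]
    if layout.e_sl:
        out[layout.e_sl] = state.sigma_e * r - theta[layout.e_sl]
    return out


def _hmc_step(state: _State, eps: float, rng) -> tuple[bool, float]:
    """One leapfrog trajectory; returns (accepted, acceptance probability)."""
    model, layout = state.model, state.layout
    theta0 = state.theta
    eta0 = state.eta()
    logp0 = _log_lik(model, eta0) + _log_prior_latent(model, layout, theta0)

    p = rng.standard_normal(layout.dim)
    ke0 = 0.5 * float(p @ p)

    theta = theta0.copy()
    grad = np.empty(layout.dim)
    _grad(state, theta, eta0, grad)
    for _ in range(_N_LEAPFROG):
        p += (0.5 * eps) * grad
        theta += eps * p
        eta = state.eta(theta)
        _grad(state, theta, eta, grad)
        p += (0.5 * eps) * grad

    logp1 = _log_lik(model, eta) + _log_prior_latent(model, layout, theta)
    ke1 = 0.5 * float(p @ p)
    log_alpha = (logp1 - ke1) - (logp0 - ke0)
    if not math.isfinite(log_alpha):
        return False, 0.0
    alpha = math.exp(min(0.0, log_alpha))
    if rng.random() < alpha:
        state.theta = theta
        return True, alpha
    return False, alpha


def _variance_sweep(
    state: _State,
    eta: np.ndarray,
    ll: float,
    rw_steps: np.ndarray,
    rng,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Random-walk Metropolis on each log SD given the current latents."""
    model = state.model
    scale = model.spec.priors.variance_scale
    accepted = np.zeros(len(model.terms))
    for g in range(len(model.terms)):
        w = state.term_contrib(g)
        log_s_new = state.log_s[g] + rw_steps[g] * rng.standard_normal()
        s_old, s_new = math.exp(state.log_s[g]), math.exp(log_s_new)
        eta_new = eta + (s_new - s_old) * w
        ll_new = _log_lik(model, eta_new)
        log_alpha = (
            ll_new
            - ll
            + _log_prior_sd(log_s_new, scale)
            - _log_prior_sd(state.log_s[g], scale)
        )
        if math.log(rng.random()) < log_alpha:
            state.log_s[g] = log_s_new
            eta, ll = eta_new, ll_new
            accepted[g] = 1.0
    return eta, ll, accepted


def _slice_sample_1d(log_f, x0: float, rng, width: float = 1.0, max_steps: int = 50):
    """Univariate slice sampler with stepping-out and shrinkage."""
    log_y = log_f(x0) + math.log(rng.random())
    lo = x0 - width * rng.random()
    hi = lo + width
    for _ in range(max_steps):
        if log_f(lo) < log_y:
            break
        lo -= width
    for _ in range(max_steps):
        if log_f(hi) < log_y:
            break
        hi += width
    x = x0
    for _ in range(max_steps):
        x = lo + (hi - lo) * rng.random()
        if log_f(x) >= log_y:
            return x
        if x < x0:
            lo = x
        else:
            hi = x
    return x0


def _interweave_sweep(state: _State, rng) -> None:
    """Centered-parameterization update of each SD, likelihood-invariant.

    With the realized effect u_g = s_g W_g z_g held fixed, the centered
    conditional of s_g is  s^-m exp(-Q / (2 s^2)) x half-Cauchy(s)  with
    Q = s_old^2 ||z_g||^2; after drawing s_new via slice sampling, z_g is
    rescaled by s_old/s_new so eta does not change.
    """
    scale = state.model.spec.priors.variance_scale
    for g in range(len(state.model.terms)):
        zg = state.z(g)
        znorm2 = float(zg @ zg)
        if znorm2 == 0.0:
            continue
        m = zg.size
        s_old = math.exp(state.log_s[g])
        q = s_old**2 * znorm2

        def log_f(log_s: float) -> float:
            s2 = math.exp(2.0 * log_s)
            return (
                -m * log_s
                - 0.5 * q / s2
                - math.log1p(s2 / scale**2)
                + log_s  # Jacobian of the log parameterization
            )

        log_s_new = _slice_sample_1d(log_f, state.log_s[g], rng)
        zg *= s_old / math.exp(log_s_new)
        state.log_s[g] = log_s_new


class _RecenterDirection:
    """A likelihood-flat direction pairing fixed column j with one random
    term: adding delta to beta_j while subtracting delta * d from the
    term's effects leaves eta unchanged whenever column j is constant
    (value d_l) within every level l of the term."""

    __slots__ = ("col", "term", "d", "gvec")

    def __init__(self, col: int, term: int | None, d: np.ndarray, gvec: np.ndarray | None):
        self.col = col
        self.term = term  # None => overdispersion block
        self.d = d  # level-space (or row-space for overdispersion) column values
        self.gvec = gvec  # L^-1 d for the phylogenetic term


def _recenter_directions(model: Model, layout: _Layout) -> list[_RecenterDirection]:
    dirs: list[_RecenterDirection] = []
    X = model.X
    for j in range(X.shape[1]):
        x = X[:, j]
        for g, term in enumerate(model.terms):
            mins = np.full(term.n_levels, np.inf)
            maxs = np.full(term.n_levels, -np.inf)
            np.minimum.at(mins, term.index, x)
            np.maximum.at(maxs, term.index, x)
            if not np.allclose(mins, maxs, atol=1e-12):
                continue  # column varies within levels; eta would change
            d = mins
            if not np.any(d):
                continue
            gvec = (
                np.linalg.solve(term.chol, d) if term.chol is not None else None
            )
            dirs.append(_RecenterDirection(j, g, d, gvec))
        if layout.e_sl is not None:
            dirs.append(_RecenterDirection(j, None, x.copy(), None))
    return dirs


def _recenter_sweep(
    state: _State, dirs: list[_RecenterDirection], rng
) -> None:
    """Gibbs moves along each flat direction (exact Gaussian conditionals).

    Fixed effects and the random terms that can absorb them (intercept vs.
    species effects, a species-level covariate vs. the same effects, any
    column vs. the per-row overdispersion block) form long posterior ridges
    that plain HMC traverses slowly; these moves jump along them directly.
    """
    layout = state.layout
    fixed_var = state.model.spec.priors.fixed_sd ** 2
    for dr in dirs:
        beta_j = state.theta[dr.col]
        if dr.term is None:
            sl = layout.e_sl
            z = state.theta[sl]
            s = state.sigma_e
            dd = float(dr.d @ dr.d)
            du = float(dr.d @ z) * s
            dvec = dr.d
        else:
            s = math.exp(state.log_s[dr.term])
            if s < 1e-10:
                continue
            sl = layout.z_sl[dr.term]
            z = state.theta[sl]
            if dr.gvec is not None:
                dd = float(dr.gvec @ dr.gvec)
                du = float(dr.gvec @ z) * s
                dvec = dr.gvec
            else:
                dd = float(dr.d @ dr.d)
                du = float(dr.d @ z) * s
                dvec = dr.d
        prec = 1.0 / fixed_var + dd / s**2
        mean = (-beta_j / fixed_var + du / s**2) / prec
        delta = mean + rng.standard_normal() / math.sqrt(prec)
        state.theta[dr.col] = beta_j + delta
        z -= (delta / s) * dvec


def _species_pair(model: Model) -> tuple[int, int] | None:
    """Indices of the (phylogeny, species_identity) term pair, if both are
    present and share the same grouping."""
    names = [t.name for t in model.terms]
    if "phylogeny" not in names or "species_identity" not in names:
        return None
    gp, gs = names.index("phylogeny"), names.index("species_identity")
    if not np.array_equal(model.terms[gp].index, model.terms[gs].index):
        return None
    return gp, gs


def _redistribute_species_effects(
    state: _State, pair: tuple[int, int], corr: np.ndarray, rng
) -> None:
    """Gibbs move on the phylogenetic vs. i.i.d. split of the species effect.

    The likelihood depends only on the sum w = u_phylo + u_species, so with
    w held fixed the conditional of u_phylo under the Gaussian priors is
    N(S_p (S_p + S_s)^-1 w, S_p - S_p (S_p + S_s)^-1 S_p), with S_p = V_p C
    and S_s = V_s I.  Resampling the split exactly is what lets the two
    variance components exchange mass; without it the likelihood-flat
    direction mixes only diffusively.
    """
    gp, gs = pair
    s_p = math.exp(state.log_s[gp])
    s_s = math.exp(state.log_s[gs])
    if s_p < 1e-8 or s_s < 1e-8:
        return
    chol_c = state.model.terms[gp].chol
    m = corr.shape[0]
    u_p = s_p * (chol_c @ state.z(gp))
    w = u_p + s_s * state.z(gs)
    sig_p = s_p**2 * corr
    total = sig_p + s_s**2 * np.eye(m)
    gain = np.linalg.solve(total, sig_p).T  # S_p S^-1
    mean = gain @ w
    cov = sig_p - gain @ sig_p
    cov = 0.5 * (cov + cov.T) + 1e-10 * np.eye(m)
    u_p_new = mean + np.linalg.cholesky(cov) @ rng.standard_normal(m)
    state.theta[state.layout.z_sl[gp]] = (
        np.linalg.solve(chol_c, u_p_new) / s_p
    )
    state.theta[state.layout.z_sl[gs]] = (w - u_p_new) / s_s


def sample_posterior(model: Model, chains: ChainConfig | None = None) -> Posterior:
    """Run the sampler and return retained draws.

    Reproducible given ``chains.rng_seed``.  If the initial log posterior is
    non-finite the state is re-initialized from the prior, up to 10 attempts.
    """
    chains = chains if chains is not None else model.spec.chains
    rng = np.random.default_rng(chains.rng_seed)
    layout = _Layout(model)

    state = _State(model, layout, rng, from_prior=False)
    for attempt in range(_MAX_INIT_ATTEMPTS):
        lp = _log_lik(model, state.eta()) + _log_prior_latent(
            model, layout, state.theta
        )
        if math.isfinite(lp):
            break
        logger.warning("non-finite log posterior at init; re-drawing (%d)", attempt + 1)
        state = _State(model, layout, rng, from_prior=True)
    else:
        raise RuntimeError("could not find a finite initial state")

    n_terms = len(model.terms)
    pair = _species_pair(model)
    corr = None
    if pair is not None:
        chol_c = model.terms[pair[0]].chol
        corr = chol_c @ chol_c.T
    recenter_dirs = _recenter_directions(model, layout)

    eps = 0.1 / max(1.0, model.X.shape[0]) ** 0.25
    # dual averaging (step-size adaptation during burn-in)
    mu = math.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    rw_steps = np.full(n_terms, 0.5)
    rw_acc_sum = np.zeros(n_terms)
    hmc_acc_sum = 0.0
    n_after = 0

    n_ret = chains.n_retained
    beta_out = np.empty((n_ret, layout.p))
    var_out = np.empty((n_ret, n_terms))
    ll_out = np.empty(n_ret)
    k_out = 0

    for it in range(1, chains.n_iter + 1):
        eps_it = eps * math.exp(0.2 * rng.uniform(-1.0, 1.0))  # jittered step size
        _, alpha = _hmc_step(state, eps_it, rng)

        if it <= chains.burn_in:
            frac = 1.0 / (it + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (_HMC_TARGET_ACCEPT - alpha)
            log_eps = mu - math.sqrt(it) / gamma * h_bar
            w = it ** (-kappa)
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = math.exp(log_eps)
            if it == chains.burn_in:
                eps = math.exp(log_eps_bar)
        else:
            hmc_acc_sum += alpha
            n_after += 1

        if n_terms:
            eta = state.eta()
            ll = _log_lik(model, eta)
            eta, ll, acc = _variance_sweep(state, eta, ll, rw_steps, rng)
            if it <= chains.burn_in:
                rw_steps *= np.exp((acc - _RW_TARGET_ACCEPT) / math.sqrt(it))
                rw_steps = np.clip(rw_steps, 1e-3, 5.0)
            else:
                rw_acc_sum += acc
            if pair is not None:
                _redistribute_species_effects(state, pair, corr, rng)
            _interweave_sweep(state, rng)
        if recenter_dirs:
            _recenter_sweep(state, recenter_dirs, rng)

        if it > chains.burn_in and (it - chains.burn_in) % chains.thin == 0:
            beta_out[k_out] = state.beta
            var_out[k_out] = np.exp(2.0 * state.log_s)
            ll_out[k_out] = _log_lik(model, state.eta())
            k_out += 1

    assert k_out == n_ret, f"retained {k_out}, expected {n_ret}"

    posterior = Posterior(
        beta=beta_out,
        beta_names=list(model.x_names),
        variances=var_out,
        variance_names=[t.name for t in model.terms],
        residual_variance=model.spec.priors.residual_variance,
        chain=chains,
        accept_hmc=hmc_acc_sum / max(1, n_after),
        accept_var={
            t.name: float(rw_acc_sum[g]) / max(1, n_after)
            for g, t in enumerate(model.terms)
        },
        log_lik=ll_out,
    )
    logger.info(
        "sampler done: %d retained, HMC accept %.2f", n_ret, posterior.accept_hmc
    )
    return posterior
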