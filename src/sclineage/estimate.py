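"""Metropolis-Hastings estimation of the dropout and amplification-error rates.

The likelihood of the reads at a site, as a function of ``(p_ado, p_ae)``,
marginalizes the mutation type, all cells' mutation statuses (Beta-Bernoulli
with the count-weight subset-sum DP) and each cell's amplification nuisance
variables.  The per-site fragment-configuration sums do not depend on the
parameters, so they are precomputed once (:class:`sclineage.model.PreparedSite`)
and each likelihood evaluation only reweights them — a parameter sweep costs
milliseconds per iteration.

Sampling uses a Gaussian random-walk proposal with independent per-parameter
steps (default sd 0.01) and uniform priors on [0, 1]; the proposal is
symmetric, so the acceptance probability is exactly the likelihood ratio,
and proposals outside the unit interval are rejected outright (prior density
zero).  Default settings: 5000 iterations, 3 chains with independent
uniform starts (``p_ado`` from U[0, 1], ``p_ae`` from U[0, 0.1] since
amplification-error rates are known to be small), 20% burn-in, point
estimates are the post-burn-in sample means pooled across chains, and 20
randomly chosen sites are used.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from sclineage.model import (
    ModelParameters,
    PreparedSite,
    _count_weights,
    _status_sum_tables,
    likelihood_matrix,
    mutation_type_prior,
    prepare_site,
)
from sclineage.sites import SiteObservation


@dataclass
class MHConfig:
    """Sampler settings (defaults follow the reference analysis protocol)."""

    n_iter: int = 5000
    n_chains: int = 3
    proposal_sd: float = 0.01
    burn_in_fraction: float = 0.2
    n_sites: int = 20
    p_ado_init: tuple[float, float] = (0.0, 1.0)
    p_ae_init: tuple[float, float] = (0.0, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.burn_in_fraction < 1.0:
            raise ValueError("burn-in fraction must be in (0, 1)")
        if self.proposal_sd <= 0:
            raise ValueError("proposal standard deviation must be positive")


@dataclass
class MHResult:
    """Chains of ``(p_ado, p_ae)`` samples and pooled point estimates."""

    chains: np.ndarray  # (n_chains, n_iter, 2)
    acceptance_rates: np.ndarray
    burn_in: int
    p_ado: float
    p_ae: float
    site_indices: np.ndarray

    def trace_to_tsv(self, path: str | Path) -> None:
        lines = ["chain\titeration\tp_ado\tp_ae"]
        for chain in range(self.chains.shape[0]):
            for it in range(self.chains.shape[1]):
                ado, ae = self.chains[chain, it]
                lines.append(f"{chain}\t{it}\t{ado:.8g}\t{ae:.8g}")
        Path(path).write_text("\n".join(lines) + "\n")


def _as_prepared(sites) -> list[PreparedSite]:
    return [
        site if isinstance(site, PreparedSite) else prepare_site(site)
        for site in sites
    ]


def data_log_likelihood(
    sites: list[SiteObservation] | list[PreparedSite],
    p_ado: float,
    p_ae: float,
    params: ModelParameters | None = None,
) -> float:
    """Joint log-likelihood of the reads at all sites given the parameters.

    Hyperparameters (``alpha``, ``a``, ``b``) are taken from ``params``;
    the site product makes the value invariant to site ordering.
    """
    hyper = params or ModelParameters()
    total = 0.0
    for ps in _as_prepared(sites):
        C = ps.n_cells
        lik, logscale = likelihood_matrix(ps, p_ado, p_ae)
        peak = lik.max(axis=0)
        if np.any(peak <= 0.0):
            return -np.inf
        lik_s = lik / peak
        T = _status_sum_tables(lik_s, list(range(C)))
        W = _count_weights(C, hyper.a, hyper.b)
        prior_z = mutation_type_prior(hyper.alpha, ps.K)
        site_sum = float(np.sum(prior_z * (T @ W)))
        if site_sum <= 0.0:
            return -np.inf
        total += logscale.sum() + np.log(peak).sum() + np.log(site_sum)
    return float(total)


def mh_sample(
    sites: list[SiteObservation] | list[PreparedSite],
    config: MHConfig = MHConfig(),
    params: ModelParameters | None = None,
) -> MHResult:
    """Random-walk Metropolis-Hastings over ``(p_ado, p_ae)``.

    Runs ``n_chains`` independent chains from uniform random starting points
    on a random subset of ``n_sites`` sites; returns all chains and the
    pooled post-burn-in means.
    """
    if not sites:
        raise ValueError("parameter estimation needs at least one site")
    prepared = _as_prepared(sites)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains + 1)
    picker = np.random.default_rng(seeds[0])
    if len(prepared) > config.n_sites:
        site_indices = np.sort(
            picker.choice(len(prepared), size=config.n_sites, replace=False)
        )
    else:
        site_indices = np.arange(len(prepared))
    subset = [prepared[i] for i in site_indices]

    chains = np.empty((config.n_chains, config.n_iter, 2))
    acc = np.zeros(config.n_chains)
    for chain in range(config.n_chains):
        rng = np.random.default_rng(seeds[chain + 1])
        state = np.array(
            [rng.uniform(*config.p_ado_init), rng.uniform(*config.p_ae_init)]
        )
        state_ll = data_log_likelihood(subset, state[0], state[1], params)
        accepted = 0
        for it in range(config.n_iter):
            proposal = state + rng.normal(0.0, config.proposal_sd, size=2)
            if np.all((proposal >= 0.0) & (proposal <= 1.0)):
                prop_ll = data_log_likelihood(subset, proposal[0], proposal[1], params)
                if np.log(rng.random()) < prop_ll - state_ll:
                    state, state_ll = proposal, prop_ll
                    accepted += 1
            chains[chain, it] = state
        acc[chain] = accepted / config.n_iter
    burn_in = int(config.burn_in_fraction * config.n_iter)
    pooled = chains[:, burn_in:, :].reshape(-1, 2)
    return MHResult(
        chains=chains,
        acceptance_rates=acc,
        burn_in=burn_in,
        p_ado=float(pooled[:, 0].mean()),
        p_ae=float(pooled[:, 1].mean()),
        site_indices=site_indices,
    )
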