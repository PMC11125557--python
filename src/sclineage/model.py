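"""Lineage model: mutation-type marginalization, pairwise genotype posteriors, distances.

Under the infinite-sites assumption a candidate site is mutated at most once
in the lineage tree, so all mutated cells share one mutation type ``Z`` that
differs from the bulk genotype ``B`` by a single nucleotide (3 types at a
singleton site, 6 at a paired site; Dirichlet-Categorical prior with
concentration ``alpha``).  Cell mutation statuses are i.i.d. Bernoulli with a
Beta(a, b)-distributed mutation probability that is integrated out
analytically, giving each status vector with ``m`` mutated cells the weight
``Beta(m + a, C - m + b) / Beta(a, b)``.

For a pair of cells ``(c, c')`` the posterior over their joint mutation
status ``(G_c, G_c')`` marginalizes the mutation type, the statuses of all
other cells (a subset-sum dynamic program over cells), and — inside each
cell's likelihood — dropout states, amplification-error counts and fragment
configurations.  The per-site distance between two cells is the posterior
probability that exactly one of them is mutated; the distance to the
unmutated bulk is the marginal posterior mutation probability.  Per-site
distances are averaged over sites where both cells have coverage.

All heavy arithmetic is done on per-read max-rescaled likelihoods with the
log scale tracked separately, which keeps the computation stable without
per-operation log-sum-exp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import betaln

from sclineage.amplification import (
    NUCLEOTIDES,
    ado_prior,
    error_config_arrays,
    error_variants,
)
from sclineage.readlike import (
    GAP,
    assignment_table_three,
    assignment_table_two,
)
from sclineage.sites import SiteObservation

#: dropout states with nonzero likelihood for a covered cell, in storage order
DSTATES = ((0, 0), (0, 1), (1, 0))


@dataclass
class ModelParameters:
    """Parameters and hyperparameters of the per-site probabilistic model.

    ``p_ado``
        allelic-dropout probability per allele (default 0.1).
    ``p_ae``
        amplification-error probability per amplification-tree edge
        (default 1e-3).
    ``alpha``
        concentration vector of the Dirichlet-Categorical mutation-type
        prior; ``None`` means all ones (uniform over types).
    ``a``, ``b``
        Beta hyperparameters of the mutation probability, integrated out
        analytically; (1, 1) is the uniform prior.
    """

    p_ado: float = 0.1
    p_ae: float = 1e-3
    alpha: Sequence[float] | None = None
    a: float = 1.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_ado <= 1.0 or not 0.0 <= self.p_ae <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")
        if self.alpha is not None and min(self.alpha) <= 0:
            raise ValueError("alpha must be strictly positive")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Beta hyperparameters must be positive")


def enumerate_mutation_types(
    bulk: tuple[str, str], candidate_index: int = 0
) -> list[tuple[str, str]]:
    """All mutation genotypes differing from ``bulk`` by one nucleotide.

    Substitutes the candidate-position nucleotide of either haplotype with
    each of its three alternatives; for a homozygous (singleton) bulk the two
    haplotype choices coincide, leaving 3 types; a paired-site bulk is
    heterozygous at the gSNV and yields 6.  Genotypes are unordered allele
    pairs, returned in sorted canonical form.
    """
    seen: list[tuple[str, str]] = []
    for hap_index in (0, 1):
        hap = bulk[hap_index]
        base = hap[candidate_index]
        for alt in NUCLEOTIDES:
            if alt == base:
                continue
            mutated = hap[:candidate_index] + alt + hap[candidate_index + 1 :]
            other = bulk[1 - hap_index]
            z = tuple(sorted((mutated, other)))
            if z not in seen:
                seen.append(z)
    return seen


def mutation_type_prior(
    alpha: Sequence[float] | None, K: int
) -> np.ndarray:
    """Dirichlet-Categorical prior over the ``K`` mutation types.

    ``P(Z = z) = Beta(sum_k alpha_k, 1) / Beta(alpha_z, 1)``; with an
    all-ones concentration this is uniform, ``1 / K``.
    """
    if alpha is None:
        a = np.ones(K)
    else:
        a = np.asarray(alpha, dtype=float)
        if a.shape != (K,):
            raise ValueError(f"alpha must have length {K}")
    return np.exp(betaln(a.sum(), 1.0) - betaln(a, 1.0))


def mutation_count_weight(m: int, C: int, a: float = 1.0, b: float = 1.0) -> float:
    """Probability of one specific status vector with ``m`` of ``C`` cells mutated."""
    if not 0 <= m <= C:
        raise ValueError("need 0 <= m <= C")
    return float(np.exp(betaln(m + a, C - m + b) - betaln(a, b)))


def _count_weights(C: int, a: float, b: float) -> np.ndarray:
    m = np.arange(C + 1)
    return np.exp(betaln(m + a, C - m + b) - betaln(a, b))


# ---------------------------------------------------------------------------
# Per-site preparation: parameter-independent branch sums


class PreparedSite:
    """Parameter-independent per-site quantities.

    For every cell, genotype (bulk + mutation types) and dropout/error branch
    the fragment-configuration-marginalized read likelihood is precomputed on
    a per-read rescaled scale (``logscale`` holds the per-cell log of the
    scaling factor).  Model parameters only reweight these sums, so parameter
    estimation can sweep ``(p_ado, p_ae)`` cheaply.

    ``max_coverage`` optionally caps the number of reads used per cell (the
    first ``max_coverage`` reads are kept), bounding the cubic per-cell cost
    on unusually deep sites; off by default.
    """

    def __init__(self, obs: SiteObservation, max_coverage: int | None = None):
        self.kind = obs.kind
        self.bulk = obs.bulk
        self.genotypes: list[tuple[str, str]] = [tuple(obs.bulk)]
        self.genotypes += enumerate_mutation_types(obs.bulk, obs.candidate_index)
        self.K = len(self.genotypes) - 1
        C = obs.n_cells
        self.n_cells = C
        cell_reads = [
            reads if max_coverage is None else reads[:max_coverage]
            for reads in obs.cell_reads
        ]
        self.L = np.array([len(reads) for reads in cell_reads], dtype=np.intp)
        self.logscale = np.zeros(C)
        self.S = np.zeros((self.K + 1, C, len(DSTATES), 2))
        for c, reads in enumerate(cell_reads):
            if reads:
                self._prepare_cell(c, reads)

    def _prepare_cell(self, c: int, reads) -> None:
        L = len(reads)
        bases = [r.bases for r in reads]
        eps = [r.error_probs for r in reads]
        # Per-read scaling by the best attainable likelihood (all matches).
        scales = np.array(
            [
                np.prod([1.0 - q for b, q in zip(rb, re) if b != GAP])
                for rb, re in zip(bases, eps)
            ]
        )
        self.logscale[c] = float(np.sum(np.log(scales)))

        frag_probs: dict[str, np.ndarray] = {}

        def probs(fragment: str) -> np.ndarray:
            if fragment not in frag_probs:
                vec = np.empty(L)
                for l, (rb, re) in enumerate(zip(bases, eps)):
                    p = 1.0
                    for b, q, f in zip(rb, re, fragment):
                        if b == GAP:
                            continue
                        p *= (1.0 - q) if b == f else q / 3.0
                    vec[l] = p / scales[l]
                frag_probs[fragment] = vec
            return frag_probs[fragment]

        table2_cache: dict[tuple[str, str], np.ndarray] = {}
        table3_cache: dict[tuple[str, str, str], np.ndarray] = {}

        for g, (f1, f2) in enumerate(self.genotypes):
            key2 = (f1, f2)
            if key2 not in table2_cache:
                table2_cache[key2] = assignment_table_two(
                    np.column_stack([probs(f1), probs(f2)])
                )
            table2 = table2_cache[key2]
            # no-error branch, by dropout state
            if L >= 2:
                self.S[g, c, 0, 0] = table2[1:L].sum() / (L - 1)
            self.S[g, c, 1, 0] = table2[L]  # allele 2 dropped: all reads from f1
            self.S[g, c, 2, 0] = table2[0]  # allele 1 dropped: all reads from f2
            # single-error branch
            variants = (error_variants(f1), error_variants(f2))
            for didx, (d1, d2) in enumerate(DSTATES):
                n1s, n3s, trees, var_idx, prob = error_config_arrays(
                    self.kind, d1, d2, L
                )
                if len(prob) == 0:
                    continue
                values = np.empty(len(prob))
                for tree in (1, 2):
                    for v in range(len(variants[0])):
                        sel = (trees == tree) & (var_idx == v)
                        if not sel.any():
                            continue
                        f3 = variants[tree - 1][v]
                        key3 = (f1, f2, f3)
                        if key3 not in table3_cache:
                            table3_cache[key3] = assignment_table_three(
                                np.column_stack([probs(f1), probs(f2), probs(f3)])
                            )
                        values[sel] = table3_cache[key3][n1s[sel], n3s[sel]]
                self.S[g, c, didx, 1] = float(values @ prob)


def prepare_site(obs: SiteObservation, max_coverage: int | None = None) -> PreparedSite:
    """Precompute the parameter-independent branch sums for one site."""
    return PreparedSite(obs, max_coverage=max_coverage)


def _branch_weights(ps: PreparedSite, p_ado: float, p_ae: float) -> np.ndarray:
    """Weights ``w[dstate, A, cell] = P(dstate) P(A | E(dstate, L_c))``."""
    C = ps.n_cells
    w = np.zeros((len(DSTATES), 2, C))
    L = ps.L
    covered = L > 0
    for didx, (d1, d2) in enumerate(DSTATES):
        prior = ado_prior(d1, d2, p_ado)
        E = 2 * L - 2 if (d1, d2) == (0, 0) else 2 * L - 1
        E = np.where(covered, E, 0)
        with np.errstate(invalid="ignore"):
            w[didx, 0] = prior * np.power(1.0 - p_ae, E)
            w[didx, 1] = np.where(
                E > 0, prior * E * p_ae * np.power(1.0 - p_ae, np.maximum(E - 1, 0)), 0.0
            )
    w[:, :, ~covered] = 0.0
    return w


def likelihood_matrix(
    ps: PreparedSite, p_ado: float, p_ae: float
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled per-cell likelihoods under every genotype.

    Returns ``(lik, logscale)`` where ``lik[g, c] * exp(logscale[c])`` is
    ``P(R_c | X_c = genotype g, ...)``; cells without coverage have
    likelihood 1 under every genotype.
    """
    w = _branch_weights(ps, p_ado, p_ae)
    lik = np.einsum("gcda,dac->gc", ps.S, w)
    lik[:, ps.L == 0] = 1.0
    return lik, ps.logscale.copy()


def _rescaled_likelihoods(
    ps: PreparedSite, params: ModelParameters
) -> np.ndarray:
    """Per-cell likelihoods rescaled by their max over genotypes.

    Cell-wise constant factors cancel in every posterior computed from these,
    so only the ratios matter.
    """
    lik, _ = likelihood_matrix(ps, params.p_ado, params.p_ae)
    peak = lik.max(axis=0)
    peak[peak == 0.0] = 1.0
    return lik / peak


def _status_sum_tables(lik: np.ndarray, cells: list[int]) -> np.ndarray:
    """Subset-sum DP over ``cells``: ``T[z - 1, k]`` sums, over all subsets of
    ``cells`` of size ``k``, the product of ``lik[z, i]`` for subset members
    and ``lik[0, i]`` for the rest."""
    K = lik.shape[0] - 1
    T = np.zeros((K, len(cells) + 1))
    T[:, 0] = 1.0
    for j, i in enumerate(cells):
        b = lik[0, i]
        z = lik[1:, i]
        upper = j + 2
        Tn = T[:, :upper].copy() * b
        Tn[:, 1:] += T[:, : upper - 1] * z[:, None]
        T[:, :upper] = Tn
    return T


def _pair_posterior_from_lik(
    lik: np.ndarray,
    c: int,
    c_prime: int,
    W: np.ndarray,
    prior_z: np.ndarray,
) -> np.ndarray:
    C = lik.shape[1]
    others = [i for i in range(C) if i not in (c, c_prime)]
    T = _status_sum_tables(lik, others)
    k = np.arange(len(others) + 1)
    # S[z - 1, j] = sum_k T[z - 1, k] * W[k + j]
    S = np.stack([T @ W[k + j] for j in range(3)], axis=1)
    joint = np.empty((2, 2))
    for g in (0, 1):
        lc = lik[0, c] if g == 0 else lik[1:, c]
        for gp in (0, 1):
            lcp = lik[0, c_prime] if gp == 0 else lik[1:, c_prime]
            joint[g, gp] = float(np.sum(prior_z * lc * lcp * S[:, g + gp]))
    total = joint.sum()
    if total <= 0.0:
        raise FloatingPointError("pair posterior vanished; check inputs")
    return joint / total


def pair_posterior(
    obs: SiteObservation | PreparedSite,
    c: int,
    c_prime: int,
    params: ModelParameters,
) -> np.ndarray:
    """Posterior 2x2 table over ``(G_c, G_c')`` at one site.

    Marginalizes the mutation type, the statuses of all other cells and each
    cell's amplification/sequencing nuisance variables; normalized to sum
    to 1.
    """
    if c == c_prime:
        raise ValueError("pair posterior requires two distinct cells")
    ps = obs if isinstance(obs, PreparedSite) else prepare_site(obs)
    lik = _rescaled_likelihoods(ps, params)
    W = _count_weights(ps.n_cells, params.a, params.b)
    prior_z = mutation_type_prior(params.alpha, ps.K)
    return _pair_posterior_from_lik(lik, c, c_prime, W, prior_z)


def site_distance(posterior: np.ndarray) -> float:
    """Distance contribution of one site: P(exactly one of the pair is mutated)."""
    return float(posterior[0, 1] + posterior[1, 0])


def _bulk_distance_from_lik(
    lik: np.ndarray, c: int, W: np.ndarray, prior_z: np.ndarray
) -> float:
    C = lik.shape[1]
    others = [i for i in range(C) if i != c]
    T = _status_sum_tables(lik, others)
    k = np.arange(C)
    post = np.empty(2)
    for g in (0, 1):
        lc = lik[0, c] if g == 0 else lik[1:, c]
        post[g] = float(np.sum(prior_z * lc * (T @ W[k + g])))
    return float(post[1] / post.sum())


def site_bulk_distance(
    obs: SiteObservation | PreparedSite, c: int, params: ModelParameters
) -> float:
    """Distance between cell ``c`` and the unmutated bulk at one site.

    The bulk carries the unmutated state by definition, so this is the
    marginal posterior mutation probability ``P(G_c = 1)``.
    """
    ps = obs if isinstance(obs, PreparedSite) else prepare_site(obs)
    lik = _rescaled_likelihoods(ps, params)
    W = _count_weights(ps.n_cells, params.a, params.b)
    prior_z = mutation_type_prior(params.alpha, ps.K)
    return _bulk_distance_from_lik(lik, c, W, prior_z)


def site_distance_matrix(
    obs: SiteObservation | PreparedSite,
    params: ModelParameters,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site distance matrix over cells + bulk (bulk last) with coverage mask.

    Entries for pairs where either cell lacks coverage at this site are 0 and
    masked out; they do not enter the aggregated distance.
    """
    ps = obs if isinstance(obs, PreparedSite) else prepare_site(obs)
    C = ps.n_cells
    lik = _rescaled_likelihoods(ps, params)
    W = _count_weights(C, params.a, params.b)
    prior_z = mutation_type_prior(params.alpha, ps.K)
    D = np.zeros((C + 1, C + 1))
    mask = np.zeros((C + 1, C + 1), dtype=bool)
    np.fill_diagonal(mask, True)
    covered = ps.L > 0
    for c in range(C):
        if not covered[c]:
            continue
        for cp in range(c + 1, C):
            if not covered[cp]:
                continue
            d = site_distance(_pair_posterior_from_lik(lik, c, cp, W, prior_z))
            D[c, cp] = D[cp, c] = d
            mask[c, cp] = mask[cp, c] = True
        d = _bulk_distance_from_lik(lik, c, W, prior_z)
        D[c, C] = D[C, c] = d
        mask[c, C] = mask[C, c] = True
    return D, mask


# ---------------------------------------------------------------------------
# Aggregation


@dataclass
class DistanceMatrix:
    """Aggregated distance matrix over cells + bulk, with per-site components."""

    labels: list[str]
    values: np.ndarray
    site_values: np.ndarray | None = None  # (n_sites, n, n)
    site_masks: np.ndarray | None = None

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", float_format="%.17g"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        import pandas as pd

        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=[str(c) for c in frame.columns], values=frame.to_numpy())


def combine_site_matrices(
    site_values: np.ndarray, site_masks: np.ndarray, warn: bool = True
) -> np.ndarray:
    """Average per-site distances over the sites where each pair is co-covered.

    Pairs never co-covered get an imputed distance (the mean of the defined
    distances involving either member of the pair) so neighbor joining can
    run on a complete matrix; a warning is emitted.
    """
    num = (site_values * site_masks).sum(axis=0)
    den = site_masks.sum(axis=0)
    n = num.shape[0]
    values = np.zeros((n, n))
    defined = den > 0
    values[defined] = num[defined] / den[defined]
    np.fill_diagonal(values, 0.0)
    np.fill_diagonal(defined, True)
    if not defined.all():
        offdiag = ~np.eye(n, dtype=bool)
        for i, j in zip(*np.where(~defined)):
            related = (defined[i] | defined[j]) & offdiag[i]
            related[j] = False
            pool = np.concatenate(
                [values[i, defined[i] & offdiag[i]], values[j, defined[j] & offdiag[j]]]
            )
            values[i, j] = float(pool.mean()) if pool.size else 0.5
        if warn:
            warnings.warn(
                "some pairs share no co-covered site; their distances were imputed",
                stacklevel=2,
            )
    return values


def aggregate_distances(
    site_values: np.ndarray | list[np.ndarray],
    site_masks: np.ndarray | list[np.ndarray],
    labels: list[str] | None = None,
    warn: bool = True,
) -> DistanceMatrix:
    """Combine per-site matrices and coverage masks into a :class:`DistanceMatrix`."""
    site_values = np.asarray(site_values, dtype=float)
    site_masks = np.asarray(site_masks, dtype=bool)
    if site_values.shape != site_masks.shape or site_values.ndim != 3:
        raise ValueError("site matrices and masks must be stacked (n_sites, n, n)")
    n = site_values.shape[1]
    if labels is None:
        labels = [f"cell{i}" for i in range(n - 1)] + ["bulk"]
    values = combine_site_matrices(site_values, site_masks, warn=warn)
    return DistanceMatrix(labels, values, site_values, site_masks)
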