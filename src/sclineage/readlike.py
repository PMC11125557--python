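"""Sequencing-error read likelihoods and the fragment-assignment dynamic program.

A cell's reads at a site are an unordered multiset; which amplified fragment
each read was sequenced from is latent.  ``P(R | F, N, Q)`` is defined as the
uniform mixture over all assignments of reads to fragment types with the
given counts: the sum over ordered type-assignments of per-read likelihoods,
divided by the multinomial coefficient.  This makes the read likelihood a
proper distribution over read multisets (it normalizes over the outcome
space, which the test suite verifies by exhaustive enumeration).

The dynamic program introduces reads one at a time and tracks how many of
them were assigned to the first and third fragment types, yielding all count
configurations in a single ``O(L^3)`` pass.

Per-read base-call likelihoods follow the Phred model: a sequenced base
matches its fragment with probability ``1 - q`` and is any specific other
nucleotide with probability ``q / 3``; at a paired site the two covered
positions contribute independent factors.  Reads covering only one position
of a paired site are scored on the covered position alone.
"""

from __future__ import annotations

from math import exp, lgamma

import numpy as np

from sclineage.amplification import (
    AdoState,
    FragmentConfiguration,
    ado_prior,
    ae_count_prob,
    edge_count,
    enumerate_configs,
)

GAP = "."


def phred_to_error(rho: float) -> float:
    """Base-calling error probability from a Phred quality score."""
    return 10.0 ** (-0.1 * rho)


def single_read_likelihood(
    bases: str, error_probs: "np.ndarray | tuple[float, ...]", fragment: str
) -> float:
    """Likelihood of one read given its originating fragment.

    ``bases`` is aligned to the site position(s); ``GAP`` marks positions the
    read does not cover, which contribute no factor.
    """
    if len(bases) != len(fragment):
        raise ValueError("read and fragment must span the same site positions")
    p = 1.0
    for base, q, ref in zip(bases, error_probs, fragment):
        if base == GAP:
            continue
        p *= (1.0 - q) if base == ref else q / 3.0
    return p


def _log_multinomial(L: int, counts: tuple[int, ...]) -> float:
    return lgamma(L + 1) - sum(lgamma(n + 1) for n in counts)


def read_probs(
    reads: list[str], error_probs: list, fragments: tuple[str, ...]
) -> np.ndarray:
    """Matrix ``P[l, j] = P(read l | fragment j)`` for all reads and fragments."""
    out = np.empty((len(reads), len(fragments)))
    for l, (bases, eps) in enumerate(zip(reads, error_probs)):
        for j, frag in enumerate(fragments):
            out[l, j] = single_read_likelihood(bases, eps, frag)
    return out


def assignment_table_two(p: np.ndarray) -> np.ndarray:
    """DP over reads for two fragment types.

    ``p`` has shape ``(L, 2)``.  Returns ``T[n1]`` = likelihood of the read
    multiset when ``n1`` reads come from the first fragment type and
    ``L - n1`` from the second (already divided by ``binom(L, n1)``).
    """
    L = p.shape[0]
    D = np.zeros(L + 1)
    D[0] = 1.0
    for l in range(L):
        a, b = p[l, 0], p[l, 1]
        Dn = D * b
        Dn[1:] += D[:-1] * a
        D = Dn
    n1 = np.arange(L + 1)
    with np.errstate(divide="ignore"):
        logbinom = np.array([_log_multinomial(L, (k, L - k)) for k in n1])
    return D * np.exp(-logbinom)


def assignment_table_three(p: np.ndarray) -> np.ndarray:
    """DP over reads for three fragment types.

    ``p`` has shape ``(L, 3)``.  Returns ``T[n1, n3]`` = likelihood of the
    read multiset for the count configuration ``(n1, L - n1 - n3, n3)``,
    divided by the corresponding multinomial coefficient; entries with
    ``n1 + n3 > L`` are zero.
    """
    L = p.shape[0]
    D = np.zeros((L + 1, L + 1))
    D[0, 0] = 1.0
    for l in range(L):
        a, b, c = p[l]
        Dn = D * b
        Dn[1:, :] += D[:-1, :] * a
        Dn[:, 1:] += D[:, :-1] * c
        D = Dn
    norm = np.zeros((L + 1, L + 1))
    for n1 in range(L + 1):
        for n3 in range(L + 1 - n1):
            norm[n1, n3] = exp(-_log_multinomial(L, (n1, L - n1 - n3, n3)))
    return D * norm


def reads_likelihood_dp(
    reads: list[str],
    error_probs: list,
    config: FragmentConfiguration,
) -> float:
    """Likelihood ``P(R | F, N, Q)`` of a cell's read multiset given a configuration."""
    L = len(reads)
    if config.total != L:
        raise ValueError(
            f"fragment counts sum to {config.total}, but {L} reads were given"
        )
    if L == 0:
        return 1.0
    if config.f3 is None:
        table = assignment_table_two(
            read_probs(reads, error_probs, (config.f1, config.f2))
        )
        return float(table[config.n1])
    table = assignment_table_three(
        read_probs(reads, error_probs, (config.f1, config.f2, config.f3))
    )
    return float(table[config.n1, config.n3])


def cell_genotype_likelihood(
    reads: list[str],
    error_probs: list,
    X: tuple[str, str],
    kind: str,
    p_ado: float,
    p_ae: float,
) -> float:
    """Marginal likelihood ``P(R_c | X_c, Q_c, L_c, p_ado, p_ae)`` for one cell.

    Marginalizes dropout states, the (truncated) amplification-error count and
    all fragment configurations.  A cell without coverage is uninformative and
    has likelihood 1 under every genotype.

    This is the reference implementation; :mod:`sclineage.model` uses a
    vectorized equivalent for whole-site computations (the two are checked
    against each other in the test suite).
    """
    L = len(reads)
    if L == 0:
        return 1.0
    total = 0.0
    for d1, d2 in ((0, 0), (0, 1), (1, 0)):
        prior = ado_prior(d1, d2, p_ado)
        if prior == 0.0:
            continue
        E = edge_count(d1, d2, L)
        for A in (0, 1):
            w = prior * ae_count_prob(A, E, p_ae)
            if w == 0.0:
                continue
            branch = 0.0
            for config, p in enumerate_configs(X, AdoState(d1, d2), A, L, kind):
                branch += p * reads_likelihood_dp(reads, error_probs, config)
            total += w * branch
    return total
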