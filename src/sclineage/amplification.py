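"""Generalized Polya-urn model of whole-genome amplification.

Whole-genome amplification of the (at most two) allele molecules of a cell at
a genomic site is modelled as an urn process: the urn starts with one ball per
non-dropped allele; repeatedly a ball is drawn, copied, and both are returned,
until the urn holds as many fragments as the observed read coverage ``L``.
The genealogy of the fragments descending from one original molecule is an
*amplification tree*: a rooted binary tree whose leaves are the final
fragments, whose internal nodes are the copy events, and which carries an
extra incoming edge above the root accounting for subsampling during
sequencing.  An amplification error on an edge substitutes one nucleotide in
every fragment below that edge.

This module provides

* the allelic-dropout prior over the urn's initial state,
* the edge count of the amplification forest given dropout state and coverage,
* the (truncated) Binomial probability of the amplification-error count,
* exact combinatorics of amplification-tree topologies (``tree_count``,
  ``subtree_edge_count``), and
* enumeration of fragment-type/count configurations with their marginal
  probabilities given dropout state, error count, genotype and coverage.

The inference model truncates the number of amplification errors per site and
cell to at most one; the truncated Binomial is used without renormalization,
so the per-cell likelihood is a slight (order ``p_ae**2``) underestimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np

NUCLEOTIDES = "ACGT"

SINGLETON = "singleton"
PAIRED = "paired"


class ModelTruncationError(ValueError):
    """Raised when more than one amplification error is requested from the model."""


@dataclass(frozen=True)
class AdoState:
    """Dropout indicators for the two alleles; ``1`` marks a dropped allele."""

    d1: int
    d2: int

    def __post_init__(self) -> None:
        if self.d1 not in (0, 1) or self.d2 not in (0, 1):
            raise ValueError("dropout indicators must be 0 or 1")


@dataclass(frozen=True)
class FragmentConfiguration:
    """Amplified fragment types ``(f1, f2, f3)`` and counts ``(n1, n2, n3)``.

    ``f1`` and ``f2`` are the cell genotype's allele fragments, ``f3`` the
    erroneous fragment created by a single amplification error (``None`` when
    no error occurred).  The counts sum to the read coverage.
    """

    f1: str
    f2: str
    f3: str | None
    n1: int
    n2: int
    n3: int

    def __post_init__(self) -> None:
        if min(self.n1, self.n2, self.n3) < 0:
            raise ValueError("fragment counts must be nonnegative")
        if (self.f3 is None) != (self.n3 == 0):
            raise ValueError("f3 must be empty iff n3 == 0")

    @property
    def total(self) -> int:
        return self.n1 + self.n2 + self.n3


def error_variants(fragment: str) -> list[str]:
    """All fragments at Hamming distance 1 from ``fragment``, in a fixed order.

    There are ``3 * len(fragment)`` of them: 3 for a singleton-site fragment,
    6 for a paired-site fragment.
    """
    out = []
    for i, base in enumerate(fragment):
        for alt in NUCLEOTIDES:
            if alt != base:
                out.append(fragment[:i] + alt + fragment[i + 1 :])
    return out


def ado_prior(d1: int, d2: int, p_ado: float) -> float:
    """Prior probability of the dropout state: two i.i.d. Bernoulli events."""
    if d1 not in (0, 1) or d2 not in (0, 1):
        raise ValueError("dropout indicators must be 0 or 1")
    if not 0.0 <= p_ado <= 1.0:
        raise ValueError("p_ado must be in [0, 1]")
    k = d1 + d2
    return p_ado**k * (1.0 - p_ado) ** (2 - k)


def edge_count(d1: int, d2: int, L: int) -> int:
    """Total number of edges of the amplification forest, root edges included.

    With both alleles present the forest has two trees with ``L`` leaves in
    total, hence ``2L - 2`` edges; with one dropout a single tree with ``L``
    leaves and ``2L - 1`` edges; with both alleles dropped there are no
    fragments and no edges.
    """
    if d1 == 1 and d2 == 1:
        return 0
    if L < 1:
        raise ValueError("coverage must be >= 1 unless both alleles dropped")
    if d1 == 0 and d2 == 0:
        return 2 * L - 2
    return 2 * L - 1


def ae_count_prob(A: int, E: int, p_ae: float) -> float:
    """Binomial(E, p_ae) probability of ``A`` amplification errors.

    The model truncates to ``A`` in {0, 1} without renormalizing, i.e. the
    probability deficit ``P(A >= 2)`` is simply neglected.
    """
    if A not in (0, 1):
        raise ModelTruncationError(
            "the amplification model is truncated to at most one error (A <= 1)"
        )
    if E < 0:
        raise ValueError("edge count must be nonnegative")
    if A > E:
        return 0.0
    if A == 0:
        return (1.0 - p_ae) ** E
    return E * p_ae * (1.0 - p_ae) ** (E - 1)


def enumerate_amplification_trees(n: int) -> set:
    """Distinct order-labelled topologies by exhaustive history enumeration.

    Grows the urn from one fragment to ``n`` by trying every possible
    draw-copy history; each resulting tree is canonicalized (internal nodes
    keyed by event order, children unordered).  Exponential in ``n``; used to
    validate the closed-form :func:`tree_count` and the
    :func:`subtree_edge_count` recurrence, and practical up to ``n`` around 8.
    """
    if n < 1:
        raise ValueError("an amplification tree has at least one fragment")
    trees: set = set()

    def encode(node: int, children: dict) -> object:
        if node not in children:
            return 0  # leaf fragment
        # children are ordered: the continuing original first, the copy second
        event, a, b = children[node]
        return (event, (encode(a, children), encode(b, children)))

    def grow(leaves: list[int], children: dict, next_id: int, event: int) -> None:
        if len(leaves) == n:
            trees.add(encode(0, children))
            return
        for i, x in enumerate(leaves):
            extended = dict(children)
            extended[x] = (event, next_id, next_id + 1)
            grow(
                leaves[:i] + [next_id, next_id + 1] + leaves[i + 1 :],
                extended,
                next_id + 2,
                event + 1,
            )

    grow([0], {}, 1, 1)
    return trees


def tree_count(n: int) -> int:
    """Number of distinct order-labelled amplification-tree topologies with ``n`` leaves.

    Growing an urn from one ball to ``n`` balls picks, at the step with ``t``
    balls, one of ``t`` fragments to copy, so there are ``(n-1)!`` ordered
    histories; distinct histories yield distinct order-labelled topologies
    (verified by exhaustive enumeration in the test suite), hence
    ``tree_count(n) == (n-1)!``.
    """
    if n < 1:
        raise ValueError("an amplification tree has at least one fragment")
    return math.factorial(n - 1)


@lru_cache(maxsize=None)
def _subtree_edge_table(n: int) -> tuple[int, ...]:
    # T[k] = total number of edges whose below-edge subtree holds exactly k
    # fragments, across all (n-1)! order-labelled n-leaf topologies (root edge
    # included).  Growth recurrence: extending an (n-1)-leaf history by
    # splitting one of its n-1 leaves keeps a k-edge a k-edge unless the split
    # leaf lies below it (k of the n-1 choices), and every extension creates
    # two fresh 1-edges.
    if n == 1:
        return (0, 1)
    prev = _subtree_edge_table(n - 1)
    table = [0] * (n + 1)
    for k in range(1, n + 1):
        total = 0
        if k <= n - 1:
            total += (n - 1 - k) * prev[k]
        if k >= 2:
            total += (k - 1) * prev[k - 1]
        if k == 1:
            total += 2 * math.factorial(n - 1)
        table[k] = total
    return tuple(table)


def subtree_edge_count(n: int, k: int) -> int:
    """Total number of ``k``-edges across all ``tree_count(n)`` topologies.

    A ``k``-edge is an edge (the dashed root edge included) whose below-edge
    subtree contains exactly ``k`` of the ``n`` fragments.
    """
    if not 1 <= k <= n:
        raise ValueError("need 1 <= k <= n")
    return _subtree_edge_table(n)[k]


@lru_cache(maxsize=None)
def error_config_arrays(
    kind: str, d1: int, d2: int, L: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Genotype-independent configuration table for the single-error branch.

    Returns arrays ``(n1, n3, tree, variant, prob)`` over all fragment-count
    configurations compatible with one amplification error, where ``tree`` in
    {1, 2} is the allele whose amplification tree carries the error and
    ``variant`` indexes :func:`error_variants` of that allele's fragment.
    ``prob`` is the full configuration probability: partition factor x
    topology factor x error-type factor (1/3 singleton, 1/6 paired).
    """
    if kind not in (SINGLETON, PAIRED):
        raise ValueError(f"unknown site kind: {kind!r}")
    if (d1, d2) == (1, 1):
        raise ValueError("no fragments exist when both alleles dropped")
    n_var = 3 if kind == SINGLETON else 6
    E = edge_count(d1, d2, L)
    rows: list[tuple[int, int, int, int, float]] = []

    def add_tree(tree: int, size: int, n_other: int, partition: Fraction) -> None:
        denom = tree_count(size) * E * n_var
        for n3 in range(1, size + 1):
            topo = Fraction(subtree_edge_count(size, n3), denom)
            prob = float(partition * topo)
            n1 = size - n3 if tree == 1 else n_other
            for var in range(n_var):
                rows.append((n1, n3, tree, var, prob))

    if d1 == 0 and d2 == 0:
        if L >= 2:
            part = Fraction(1, L - 1)
            for s in range(1, L):
                add_tree(1, s, L - s, part)
                add_tree(2, L - s, s, part)
    elif d1 == 1:
        add_tree(2, L, 0, Fraction(1))
    else:
        add_tree(1, L, 0, Fraction(1))

    n1 = np.array([r[0] for r in rows], dtype=np.intp)
    n3 = np.array([r[1] for r in rows], dtype=np.intp)
    tree = np.array([r[2] for r in rows], dtype=np.intp)
    var = np.array([r[3] for r in rows], dtype=np.intp)
    prob = np.array([r[4] for r in rows], dtype=np.float64)
    return n1, n3, tree, var, prob


def enumerate_configs(
    X: tuple[str, str],
    ado: AdoState,
    A: int,
    L: int,
    kind: str,
) -> list[tuple[FragmentConfiguration, float]]:
    """Enumerate fragment configurations and probabilities for one cell and site.

    Configurations with identical ``(F, N)`` (possible for homozygous
    genotypes) are merged.  Probabilities sum to 1 over the returned list for
    every branch the model assigns positive mass to; the no-dropout branch
    with ``L == 1`` and the single-error branch with ``E == 0`` are
    zero-probability branches and yield an empty list.
    """
    if A not in (0, 1):
        raise ModelTruncationError(
            "the amplification model is truncated to at most one error (A <= 1)"
        )
    f1, f2 = X
    if ado.d1 == 1 and ado.d2 == 1:
        if L > 0:
            return []
        return [(FragmentConfiguration(f1, f2, None, 0, 0, 0), 1.0)]
    if L < 1:
        raise ValueError("coverage must be >= 1 unless both alleles dropped")

    merged: dict[tuple[str, str, str | None, int, int, int], float] = {}

    def add(f3: str | None, n1: int, n2: int, n3: int, p: float) -> None:
        key = (f1, f2, f3, n1, n2, n3)
        merged[key] = merged.get(key, 0.0) + p

    if A == 0:
        if ado.d1 == 0 and ado.d2 == 0:
            if L >= 2:
                for s in range(1, L):
                    add(None, s, L - s, 0, 1.0 / (L - 1))
        elif ado.d1 == 1:
            add(None, 0, L, 0, 1.0)
        else:
            add(None, L, 0, 0, 1.0)
    else:
        n1s, n3s, trees, variants, probs = error_config_arrays(kind, ado.d1, ado.d2, L)
        var1 = error_variants(f1)
        var2 = error_variants(f2)
        for n1, n3, tree, var, p in zip(n1s, n3s, trees, variants, probs):
            f3 = var1[var] if tree == 1 else var2[var]
            n2 = L - n1 - n3
            add(f3, int(n1), int(n2), int(n3), float(p))

    return [
        (FragmentConfiguration(*key), p)
        for key, p in sorted(merged.items(), key=lambda kv: kv[0][2:])
    ]
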