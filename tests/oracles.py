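"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written without reusing the package's
production code paths: urn histories are enumerated explicitly, read
assignments are enumerated as permutations, posteriors sum over all 2^C
status vectors, and transfer distances try leaf-removal subsets directly.
"""

from __future__ import annotations

import itertools
from collections import Counter
from fractions import Fraction

import numpy as np

NUCS = "ACGT"


# ---------------------------------------------------------------------------
# Urn histories


def enumerate_histories(start_leaves: int, n: int):
    """All ordered draw-copy histories growing ``start_leaves`` -> ``n`` fragments.

    Yields ``(parents, leaves, roots)`` where ``parents`` maps node -> parent
    (roots map to None).  Every history has equal probability.
    """
    roots = list(range(start_leaves))
    init_parents = {r: None for r in roots}

    def rec(parents, leaves, next_id):
        if len(leaves) == n:
            yield dict(parents), list(leaves), roots
            return
        for i, x in enumerate(leaves):
            p2 = dict(parents)
            a, b = next_id, next_id + 1
            p2[a] = x
            p2[b] = x
            yield from rec(p2, leaves[:i] + [a, b] + leaves[i + 1 :], next_id + 2)

    yield from rec(init_parents, roots, start_leaves)


def history_tree_shapes(n: int) -> set:
    """Distinct order-labelled topologies of single-root histories (oracle for C(n))."""

    shapes = set()
    for parents, leaves, roots in enumerate_histories(1, n):
        children = {}
        for node in sorted(parents):
            p = parents[node]
            if p is not None:
                children.setdefault(p, []).append(node)
        # the split creating ids (2e-1, 2e) was event e (single-root histories)
        order = {node: (kids[0] - 1) // 2 + 1 for node, kids in children.items()}

        def enc(node):
            if node not in children:
                return 0
            a, b = children[node]  # insertion order: original first, copy second
            return (order[node], (enc(a), enc(b)))

        shapes.add(enc(roots[0]))
    return shapes


def history_k_edge_total(n: int, k: int) -> int:
    """Total k-edges (root edge included) across distinct n-leaf topologies."""
    totals = {}
    for parents, leaves, roots in enumerate_histories(1, n):
        children = {}
        for node in sorted(parents):
            p = parents[node]
            if p is not None:
                children.setdefault(p, []).append(node)
        order = {node: (kids[0] - 1) // 2 + 1 for node, kids in children.items()}

        def enc(node):
            if node not in children:
                return 0
            a, b = children[node]  # insertion order: original first, copy second
            return (order[node], (enc(a), enc(b)))

        def leaves_below(node):
            if node not in children:
                return 1
            return sum(leaves_below(c) for c in children[node])

        # one edge above every node; the root's is the dashed subsampling edge
        count = sum(1 for node in parents if leaves_below(node) == k)
        totals[enc(roots[0])] = count
    return sum(totals.values())


def config_distribution(f1: str, f2: str, d1: int, d2: int, A: int, L: int, kind: str):
    """Exact distribution over (F, N) by exhaustive urn-history enumeration.

    Enumerates every equally likely history of the (possibly two-tree) urn,
    then — for a single amplification error — every equally likely error
    edge (root edges included) and every equally likely substituted
    nucleotide.  Returns ``{(f1, f2, f3, n1, n2, n3): Fraction}``.
    """
    assert (d1, d2) != (1, 1)
    n_var = 3 * len(f1)
    start = 2 if (d1, d2) == (0, 0) else 1
    histories = list(enumerate_histories(start, L))
    out: dict = Counter()
    h_prob = Fraction(1, len(histories))
    for parents, leaves, roots in histories:
        def root_of(node):
            while parents[node] is not None:
                node = parents[node]
            return node

        if (d1, d2) == (0, 0):
            tree_of_leaf = {l: (1 if root_of(l) == roots[0] else 2) for l in leaves}
        elif d1 == 1:  # only allele 2 survives
            tree_of_leaf = {l: 2 for l in leaves}
        else:
            tree_of_leaf = {l: 1 for l in leaves}
        sizes = Counter(tree_of_leaf.values())
        if A == 0:
            key = (f1, f2, None, sizes.get(1, 0), sizes.get(2, 0), 0)
            out[key] += h_prob
            continue
        # error edge: uniform over all edges incl. each tree's root edge
        edges = list(parents)  # one edge above every node
        e_prob = h_prob * Fraction(1, len(edges)) * Fraction(1, n_var)
        for e in edges:
            def below(leaf):
                x = leaf
                while x is not None:
                    if x == e:
                        return True
                    x = parents[x]
                return False

            hit = [l for l in leaves if below(l)]
            tree = tree_of_leaf[hit[0]]
            origin = f1 if tree == 1 else f2
            n3 = len(hit)
            n1 = sizes.get(1, 0) - (n3 if tree == 1 else 0)
            n2 = sizes.get(2, 0) - (n3 if tree == 2 else 0)
            for i in range(len(origin)):
                for alt in NUCS:
                    if alt == origin[i]:
                        continue
                    f3 = origin[:i] + alt + origin[i + 1 :]
                    out[(f1, f2, f3, n1, n2, n3)] += e_prob
    return dict(out)


# ---------------------------------------------------------------------------
# Read likelihood


def single_read_prob(bases: str, eps, fragment: str) -> float:
    p = 1.0
    for b, q, f in zip(bases, eps, fragment):
        if b == ".":
            continue
        p *= (1.0 - q) if b == f else q / 3.0
    return p


def brute_reads_likelihood(reads, eps, fragments, counts) -> float:
    """Average over all distinct ordered type-assignments with the given counts."""
    types = []
    for t, n in enumerate(counts):
        types += [t] * n
    assignments = set(itertools.permutations(types))
    total = 0.0
    for assign in assignments:
        p = 1.0
        for t, rb, re in zip(assign, reads, eps):
            p *= single_read_prob(rb, re, fragments[t])
        total += p
    return total / len(assignments)


# ---------------------------------------------------------------------------
# Pairwise posterior by 2^C enumeration


def brute_pair_posterior(obs, c, c_prime, params):
    from sclineage.model import (
        enumerate_mutation_types,
        mutation_count_weight,
        mutation_type_prior,
    )
    from sclineage.readlike import cell_genotype_likelihood

    C = obs.n_cells
    genotypes = [tuple(obs.bulk)] + enumerate_mutation_types(
        obs.bulk, obs.candidate_index
    )
    K = len(genotypes) - 1
    lik = {}
    for i in range(C):
        bases = [r.bases for r in obs.cell_reads[i]]
        eps = [r.error_probs for r in obs.cell_reads[i]]
        for g, X in enumerate(genotypes):
            lik[i, g] = cell_genotype_likelihood(
                bases, eps, X, obs.kind, params.p_ado, params.p_ae
            )
    prior = mutation_type_prior(params.alpha, K)
    joint = np.zeros((2, 2))
    for z in range(1, K + 1):
        for status in itertools.product((0, 1), repeat=C):
            p = prior[z - 1] * mutation_count_weight(
                sum(status), C, params.a, params.b
            )
            for i in range(C):
                p *= lik[i, z if status[i] else 0]
            joint[status[c], status[c_prime]] += p
    return joint / joint.sum()


# ---------------------------------------------------------------------------
# Transfer distance by leaf removal


def brute_transfer_distance(side: frozenset, leaves: list, boot_masks) -> int:
    """Minimum leaf removals making ``side|rest`` match some edge of the tree.

    ``boot_masks`` are boolean side-masks over ``leaves`` for every edge of
    the bootstrap tree (trivial edges included).  A bipartition that becomes
    trivial after removals matches a pendant edge by definition.
    """
    n = len(leaves)
    index = {l: i for i, l in enumerate(leaves)}
    b = np.zeros(n, dtype=bool)
    for l in side:
        b[index[l]] = True
    for removals in range(n):
        for removed in itertools.combinations(range(n), removals):
            keep = np.ones(n, dtype=bool)
            keep[list(removed)] = False
            rb = b[keep]
            size = rb.sum()
            if size <= 1 or size >= keep.sum() - 1:
                return removals
            for mask in boot_masks:
                rm = mask[keep]
                if np.array_equal(rb, rm) or np.array_equal(rb, ~rm):
                    return removals
    raise AssertionError("unreachable")
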