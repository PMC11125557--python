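"""Neighbor-joining tree reconstruction, bulk rerooting and site bootstrapping.

The standard Saitou-Nei neighbor-joining algorithm is applied to the
aggregated (cells + bulk) distance matrix.  Tie-breaking on the Q-criterion
is deterministic (the lowest-index pair wins), so reconstruction is
reproducible and independent of parallelism.  The inferred tree is re-rooted
so that the bulk sample — which represents the unmutated state — becomes the
root's attachment.  Bootstrap trees are obtained by resampling sites with
replacement and re-aggregating the per-site distance matrices (coverage
masks travel with the sites, so the per-pair denominators are recomputed for
every resample).

Branch lengths are carried along but are not validated by the method;
negative neighbor-joining branch lengths are clamped to zero at
serialization time only.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np

from sclineage.model import combine_site_matrices


def neighbor_joining(matrix: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Saitou-Nei neighbor joining on a complete symmetric distance matrix.

    Raises ``ValueError`` naming the offending taxon pair when the matrix has
    a missing (NaN) entry.
    """
    D0 = np.asarray(matrix, dtype=float)
    n = len(labels)
    if D0.shape != (n, n):
        raise ValueError("distance matrix shape does not match the label count")
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    bad = np.argwhere(np.isnan(D0))
    if len(bad):
        i, j = bad[0]
        raise ValueError(f"distance missing for pair ({labels[i]}, {labels[j]})")
    if not np.allclose(D0, D0.T):
        raise ValueError("distance matrix must be symmetric")

    size = 2 * n - 2
    D = np.zeros((size, size))
    D[:n, :n] = D0
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes: dict[int, dendropy.Node] = {}
    for i, label in enumerate(labels):
        nodes[i] = dendropy.Node(taxon=tns.get_taxon(label))
    active = list(range(n))
    next_id = n

    while len(active) > 2:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best_pair = None
        best_q = np.inf
        ordered = sorted(active)
        for a, i in enumerate(ordered):
            for j in ordered[a + 1 :]:
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if q < best_q:  # strict: ties keep the lowest-index pair
                    best_q = q
                    best_pair = (i, j)
        i, j = best_pair
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        nodes[next_id] = parent
        for k in active:
            if k in (i, j):
                continue
            D[next_id, k] = D[k, next_id] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    x, y = active
    if not nodes[x].is_leaf():
        seed, child = x, y
    else:
        seed, child = y, x
    tree.seed_node = nodes[seed]
    nodes[seed].add_child(nodes[child])
    nodes[child].edge.length = D[x, y]
    tree.is_rooted = False
    return tree


def reroot_at_bulk(tree: dendropy.Tree, bulk_label: str = "bulk") -> dendropy.Tree:
    """Root the tree on the bulk sample's pendant edge.

    The bulk represents the unmutated state and becomes the root's
    attachment; cell-leaf bipartitions are unchanged.  Idempotent.
    """
    rooted = tree.clone(depth=1)
    leaf = None
    for nd in rooted.leaf_node_iter():
        if nd.taxon is not None and nd.taxon.label == bulk_label:
            leaf = nd
            break
    if leaf is None:
        raise ValueError(f"no leaf labelled {bulk_label!r} in the tree")
    if rooted.is_rooted and leaf.parent_node is rooted.seed_node and len(
        rooted.seed_node.child_nodes()
    ) == 2:
        return rooted
    rooted.is_rooted = True
    length = leaf.edge.length
    half = None if length is None else length / 2.0
    rooted.reroot_at_edge(leaf.edge, length1=half, length2=half)
    return rooted


def bootstrap_trees(
    site_values: np.ndarray,
    site_masks: np.ndarray,
    labels: list[str],
    n_boot: int,
    seed: int,
    bulk_label: str = "bulk",
) -> list[dendropy.Tree]:
    """Site-bootstrap trees: resample sites with replacement, aggregate, NJ, reroot."""
    site_values = np.asarray(site_values, dtype=float)
    site_masks = np.asarray(site_masks, dtype=bool)
    n_sites = site_values.shape[0]
    if n_sites == 0:
        raise ValueError("cannot bootstrap an empty site list")
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(n_boot):
        idx = rng.integers(0, n_sites, size=n_sites)
        values = combine_site_matrices(site_values[idx], site_masks[idx], warn=False)
        tree = neighbor_joining(values, labels)
        if bulk_label in labels:
            tree = reroot_at_bulk(tree, bulk_label)
        trees.append(tree)
    return trees


def write_newick(
    trees: dendropy.Tree | list[dendropy.Tree],
    path: str | Path,
    clamp_negative: bool = True,
) -> None:
    """Serialize one or several trees as Newick (negative lengths clamped to 0)."""
    if isinstance(trees, dendropy.Tree):
        trees = [trees]
    lines = []
    for tree in trees:
        out = tree.clone(depth=1)
        if clamp_negative:
            for edge in out.preorder_edge_iter():
                if edge.length is not None and edge.length < 0:
                    edge.length = 0.0
        lines.append(
            out.as_string(schema="newick", suppress_rooting=False).strip()
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_newick(path: str | Path) -> list[dendropy.Tree]:
    """Read one tree per line from a Newick file (shared taxon namespace)."""
    tns = dendropy.TaxonNamespace()
    trees = dendropy.TreeList.get(
        path=str(path), schema="newick", taxon_namespace=tns
    )
    return list(trees)
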