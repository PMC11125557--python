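"""Tree-accuracy metrics: normalized Robinson-Foulds similarity and TBE supports.

The similarity between two topologies is ``1 - RF / I_B`` where ``RF`` is
the number of nontrivial bipartitions present in exactly one tree and
``I_B`` the total number of nontrivial (internal) edges of both trees;
identical topologies score 1, trees sharing no nontrivial bipartition
score 0.

The transfer bootstrap expectation (TBE) of a reference edge ``b`` with
lighter side of size ``p`` is ``1 - mean_T [ delta(b, T) / (p - 1) ]`` over
bootstrap trees ``T``, where the transfer index ``delta`` is the minimum
number of leaf removals needed to make ``b`` match some edge of ``T`` —
equivalently the minimum, over edges ``e`` of ``T``, of the Hamming distance
between the bipartitions (taking the smaller of the two orientations).
Compared with Felsenstein's bootstrap proportion, TBE penalizes small
topological discrepancies less.

All bipartitions are computed on the cell leaf set after removing the bulk
leaf, so trees with and without the bulk outgroup compare consistently.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np

BULK_LABEL = "bulk"

Bipartition = frozenset


def _cell_leaves(tree: dendropy.Tree, exclude: str) -> list[str]:
    labels = [
        leaf.taxon.label
        for leaf in tree.leaf_node_iter()
        if leaf.taxon is not None and leaf.taxon.label != exclude
    ]
    return sorted(labels)


def _edge_masks(
    tree: dendropy.Tree, index: dict[str, int], include_trivial: bool
) -> list[np.ndarray]:
    """Bipartition membership masks (one side) for the tree's edges.

    Masks are canonicalized so that the leaf with index 0 is always outside
    the masked side; duplicates (which arise when the bulk leaf is removed)
    are dropped.
    """
    n = len(index)
    masks = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = np.zeros(n, dtype=bool)
        for leaf in node.leaf_iter():
            if leaf.taxon is not None and leaf.taxon.label in index:
                below[index[leaf.taxon.label]] = True
        size = int(below.sum())
        if size == 0 or size == n:
            continue
        if not include_trivial and (size == 1 or size == n - 1):
            continue
        if below[0]:
            below = ~below
        masks[below.tobytes()] = below
    return list(masks.values())


def _bipartition_sets(
    tree: dendropy.Tree, leaves: list[str], include_trivial: bool = False
) -> set[Bipartition]:
    index = {label: i for i, label in enumerate(leaves)}
    out = set()
    for mask in _edge_masks(tree, index, include_trivial):
        out.add(frozenset(label for label, i in index.items() if mask[i]))
    return out


def rf_similarity(
    tree1: dendropy.Tree, tree2: dendropy.Tree, exclude_label: str = BULK_LABEL
) -> float:
    """Similarity ``1 - RF / I_B`` between two topologies on the same cell leaf set."""
    leaves1 = _cell_leaves(tree1, exclude_label)
    leaves2 = _cell_leaves(tree2, exclude_label)
    if leaves1 != leaves2:
        raise ValueError("trees must share the same (cell) leaf set")
    s1 = _bipartition_sets(tree1, leaves1)
    s2 = _bipartition_sets(tree2, leaves2)
    total = len(s1) + len(s2)
    if total == 0:
        return 1.0
    return 1.0 - len(s1 ^ s2) / total


def tbe_supports(
    reference: dendropy.Tree,
    bootstrap: list[dendropy.Tree],
    exclude_label: str = BULK_LABEL,
) -> dict[Bipartition, float]:
    """Transfer bootstrap expectation support of every internal reference edge.

    Returns a map from the reference edge's bipartition (as the canonical
    frozenset of cell labels on the side not containing the first cell) to
    its support in [0, 1].
    """
    if not bootstrap:
        raise ValueError("the bootstrap tree set is empty")
    leaves = _cell_leaves(reference, exclude_label)
    index = {label: i for i, label in enumerate(leaves)}
    n = len(leaves)
    ref_masks = _edge_masks(reference, index, include_trivial=False)
    if not ref_masks:
        return {}
    ref = np.array(ref_masks)  # (n_edges, n)
    p = np.minimum(ref.sum(axis=1), n - ref.sum(axis=1))
    deltas = np.zeros((len(bootstrap), len(ref_masks)))
    for t, tree in enumerate(bootstrap):
        boot = np.array(_edge_masks(tree, index, include_trivial=True))
        # Hamming distance between bipartitions, in the better orientation.
        ham = (ref[:, None, :] != boot[None, :, :]).sum(axis=2)
        ham = np.minimum(ham, n - ham)
        deltas[t] = ham.min(axis=1)
    support = 1.0 - deltas.mean(axis=0) / (p - 1)
    labels = np.array(leaves)
    return {
        frozenset(labels[mask]): float(s) for mask, s in zip(ref_masks, support)
    }


def project_supports(
    reference: dendropy.Tree,
    supports: dict[Bipartition, float],
    exclude_label: str = BULK_LABEL,
) -> dendropy.Tree:
    """Annotate the reference topology with supports as internal-node labels."""
    annotated = reference.clone(depth=1)
    leaves = _cell_leaves(annotated, exclude_label)
    index = {label: i for i, label in enumerate(leaves)}
    n = len(leaves)
    for node in annotated.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = np.zeros(n, dtype=bool)
        for leaf in node.leaf_iter():
            if leaf.taxon is not None and leaf.taxon.label in index:
                below[index[leaf.taxon.label]] = True
        size = int(below.sum())
        if size < 2 or size > n - 2:
            continue
        if below[0]:
            below = ~below
        key = frozenset(label for label, i in index.items() if below[i])
        if key in supports:
            node.label = f"{supports[key]:.4f}"
    return annotated


def write_supports_table(
    supports: dict[Bipartition, float], path: str | Path
) -> None:
    """Write a TSV of bipartition -> TBE support."""
    lines = ["clade\tsupport"]
    for key in sorted(supports, key=lambda k: (len(k), sorted(k))):
        lines.append(",".join(sorted(key)) + f"\t{supports[key]:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
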