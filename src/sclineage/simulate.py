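"""Synthetic single-cell DNA sequencing datasets with known ground truth.

The generator emulates the full experimental protocol the inference model
targets:

1. a random binary cell lineage tree with ``C`` leaves;
2. ``2 (C - 1) mu`` somatic mutations assigned to tree edges (every edge
   carries at least one); mutation loci sit at odd genome positions, all
   leaves below an edge inherit its mutations;
3. a diploid bulk genome (default 1 Mbp), homozygous except at
   ``round(rho * genome_length / 2)`` heterozygous germline-SNV loci at even
   positions — for ``rho = 1`` every second position is a gSNV, so every
   site-pair read carries a phasing anchor;
4. allelic dropout: per cell, per site-pair (consecutive even/odd position
   pair) and per allele, independent Bernoulli(``p_ado``) masking;
5. Polya-urn amplification of the surviving alleles at each sequenced
   site-pair up to a Poisson(``lambda``) coverage, each copy event
   independently corrupting one position of the copy with probability
   ``p_ae`` (multiple errors per site can accumulate, although inference
   truncates at one);
6. read sequencing with Phred scores drawn uniformly from ``[30, 42]`` and
   base-calling errors at rate ``10**(-0.1 * phred)``;
7. error-free bulk reads: 15 unamplified copies of each haplotype.

Only site-pairs that carry a mutation (plus an optional number of background
pairs) are sequenced; other pairs would never pass candidate selection and
would only cost time.  All randomness flows from the single config seed, so
identical configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pysam

from sclineage.readlike import phred_to_error
from sclineage.sites import ReadRecord

BASES = "ACGT"


@dataclass
class SimulationConfig:
    """Study conditions of a synthetic dataset (defaults follow the protocol above)."""

    n_cells: int = 10
    genome_length: int = 1_000_000
    mutations_per_edge: int = 10
    phasing_frequency: float = 1.0
    p_ado: float = 0.1
    p_ae: float = 1e-3
    coverage_rate: float = 10.0
    phred_range: tuple[int, int] = (30, 42)
    bulk_copies: int = 15
    read_length: int = 2
    background_pairs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 3:
            raise ValueError("need at least 3 cells for a meaningful lineage tree")
        if self.genome_length < 2 or self.genome_length % 2 != 0:
            raise ValueError("genome length must be a positive even number")
        if self.mutations_per_edge < 1:
            raise ValueError("need at least one mutation per edge")
        for p in (self.phasing_frequency, self.p_ado, self.p_ae):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.coverage_rate < 0:
            raise ValueError("coverage rate must be nonnegative")
        lo, hi = self.phred_range
        if lo > hi or lo < 1:
            raise ValueError("invalid Phred range")
        if self.read_length < 2 or self.read_length % 2 != 0:
            raise ValueError("read length must be an even number >= 2")

    @property
    def n_pairs(self) -> int:
        return self.genome_length // 2

    @property
    def n_gsnvs(self) -> int:
        return int(round(self.phasing_frequency * self.genome_length / 2))


@dataclass
class GroundTruth:
    """Everything the simulator knows and the inference must recover."""

    tree: dendropy.Tree
    mutation_map: dict[int, int]  # mutation locus -> edge index
    mutation_details: dict[int, tuple[int, int, int]]  # locus -> (edge, hap, alt code)
    gsnv_loci: np.ndarray
    bulk_genome: np.ndarray  # (2, G) uint8 base codes
    cell_genomes: np.ndarray  # (C, 2, G)
    ado_mask: np.ndarray  # (C, n_pairs, 2) bool


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    truth: GroundTruth
    sequenced_pairs: list[int]
    cell_reads: list[list[ReadRecord]]
    bulk_reads: list[ReadRecord]

    def mutation_loci(self) -> list[int]:
        return sorted(self.truth.mutation_map)


# ---------------------------------------------------------------------------
# Lineage tree and mutations


def _random_binary_tree(C: int, rng: np.random.Generator) -> dendropy.Tree:
    labels = [f"cell{i}" for i in range(C)]
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    leaves = [tree.seed_node]
    while len(leaves) < C:
        node = leaves.pop(int(rng.integers(len(leaves))))
        left, right = dendropy.Node(), dendropy.Node()
        node.add_child(left)
        node.add_child(right)
        left.edge.length = right.edge.length = 1.0
        leaves.extend([left, right])
    order = rng.permutation(C)
    for leaf, k in zip(leaves, order):
        leaf.taxon = tns.get_taxon(labels[k])
    return tree


def generate_lineage_tree(C: int, seed: int) -> dendropy.Tree:
    """Random rooted binary lineage tree with ``C`` labelled leaves.

    The tree has ``2 (C - 1)`` edges (both child edges of every internal
    node); reproducible for a fixed seed.
    """
    if C < 3:
        raise ValueError("need at least 3 cells for a meaningful lineage tree")
    return _random_binary_tree(C, np.random.default_rng(seed))


def tree_edges(tree: dendropy.Tree) -> list[dendropy.Node]:
    """Edges of the rooted tree, as their child nodes, in preorder; fixed ids."""
    return [nd for nd in tree.preorder_node_iter() if nd.parent_node is not None]


def assign_mutations(
    tree: dendropy.Tree,
    mutations_per_edge: int,
    genome_length: int,
    rng: np.random.Generator,
) -> dict[int, int]:
    """Map ``2 (C - 1) mu`` odd-position loci to tree edges, at least one per edge."""
    edges = tree_edges(tree)
    n_edges = len(edges)
    n_mut = n_edges * mutations_per_edge
    n_odd = genome_length // 2
    if n_mut > n_odd:
        raise ValueError(
            f"genome holds only {n_odd} odd-position loci; {n_mut} mutations requested"
        )
    loci = np.sort(rng.choice(n_odd, size=n_mut, replace=False)) * 2 + 1
    assignment = np.concatenate(
        [np.arange(n_edges), rng.integers(0, n_edges, size=n_mut - n_edges)]
    )
    rng.shuffle(assignment)
    return {int(locus): int(edge) for locus, edge in zip(loci, assignment)}


# ---------------------------------------------------------------------------
# Genomes


def generate_genomes(
    config: SimulationConfig,
    tree: dendropy.Tree,
    mutation_map: dict[int, int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[int, tuple[int, int, int]]]:
    """Bulk and per-cell diploid genomes (uint8 base codes).

    The bulk is homozygous except at the gSNV loci; every cell inherits the
    bulk plus the mutations on its root path.  Returns ``(bulk_genome,
    gsnv_loci, cell_genomes, mutation_details)``.
    """
    G = config.genome_length
    hap1 = rng.integers(0, 4, size=G, dtype=np.uint8)
    hap2 = hap1.copy()
    gsnv_loci = np.sort(rng.choice(G // 2, size=config.n_gsnvs, replace=False)) * 2
    shift = rng.integers(1, 4, size=len(gsnv_loci)).astype(np.uint8)
    hap2[gsnv_loci] = (hap1[gsnv_loci] + shift) % 4
    bulk = np.stack([hap1, hap2])

    edges = tree_edges(tree)
    leaf_index = {f"cell{i}": i for i in range(config.n_cells)}
    cells_below = []
    for node in edges:
        cells_below.append(
            [leaf_index[leaf.taxon.label] for leaf in node.leaf_iter()]
        )

    cell_genomes = np.broadcast_to(bulk, (config.n_cells,) + bulk.shape).copy()
    details: dict[int, tuple[int, int, int]] = {}
    for locus in sorted(mutation_map):
        edge = mutation_map[locus]
        hap = int(rng.integers(2))
        alt = int((bulk[hap, locus] + rng.integers(1, 4)) % 4)
        details[locus] = (edge, hap, alt)
        for cell in cells_below[edge]:
            cell_genomes[cell, hap, locus] = alt
    return bulk, gsnv_loci, cell_genomes, details


def apply_ado_mask(
    n_cells: int, n_pairs: int, p_ado: float, rng: np.random.Generator
) -> np.ndarray:
    """Independent Bernoulli(``p_ado``) dropout flags per cell, site-pair and allele."""
    if not 0.0 <= p_ado <= 1.0:
        raise ValueError("p_ado must be in [0, 1]")
    return rng.random((n_cells, n_pairs, 2)) < p_ado


# ---------------------------------------------------------------------------
# Amplification and sequencing


def amplify_site(
    alleles: list[tuple[int, np.ndarray]],
    coverage: int,
    p_ae: float,
    rng: np.random.Generator,
) -> list[tuple[int, np.ndarray]]:
    """Forward Polya-urn amplification of the surviving alleles at one site-pair.

    ``alleles`` holds ``(haplotype_index, bases)`` for each non-dropped
    allele (the urn's initial balls).  The urn grows by draw-copy-return
    steps until it holds ``coverage`` fragments; each copy independently
    corrupts one of its positions with probability ``p_ae``.  If the
    requested coverage is below the initial ball count the fragments are
    subsampled (the model's extra root edge accounts for this).  Both
    alleles dropped, or zero coverage, yields no fragments.
    """
    if not alleles or coverage == 0:
        return []
    balls = [(hap, bases.copy()) for hap, bases in alleles]
    while len(balls) < coverage:
        hap, bases = balls[int(rng.integers(len(balls)))]
        copy = bases.copy()
        if rng.random() < p_ae:
            pos = int(rng.integers(len(copy)))
            copy[pos] = (copy[pos] + rng.integers(1, 4)) % 4
        balls.append((hap, copy))
    if len(balls) > coverage:
        keep = rng.choice(len(balls), size=coverage, replace=False)
        balls = [balls[int(k)] for k in sorted(keep)]
    return balls


def sequence_reads(
    fragments: list[np.ndarray],
    phred_range: tuple[int, int],
    rng: np.random.Generator,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Sequence each fragment into one read: Phred scores and base-call errors.

    Per covered position the Phred score is DiscreteUniform over the
    inclusive range and the base is replaced by a uniformly chosen different
    nucleotide with probability ``10**(-0.1 * phred)``.
    """
    lo, hi = phred_range
    reads = []
    for bases in fragments:
        phred = rng.integers(lo, hi + 1, size=len(bases))
        q = 10.0 ** (-0.1 * phred)
        err = rng.random(len(bases)) < q
        out = bases.copy()
        out[err] = (out[err] + rng.integers(1, 4, size=int(err.sum())).astype(np.uint8)) % 4
        reads.append((out, phred))
    return reads


def make_bulk_reads(
    bulk_genome: np.ndarray,
    bulk_copies: int,
    pairs: list[int] | None = None,
    read_length: int = 2,
    phred: int = 42,
) -> list[ReadRecord]:
    """Error-free bulk reads: ``bulk_copies`` unamplified copies of each haplotype.

    Emits one read per haplotype copy per site-pair (every bulk position is
    covered by ``2 * bulk_copies`` reads when all pairs are requested).
    """
    G = bulk_genome.shape[1]
    if pairs is None:
        pairs = list(range(G // 2))
    eps = phred_to_error(phred)
    reads = []
    for pair in pairs:
        start = 2 * pair
        stop = min(start + read_length, G)
        for hap in (0, 1):
            bases = "".join(BASES[b] for b in bulk_genome[hap, start:stop])
            record = ReadRecord(None, start, bases, (eps,) * (stop - start))
            reads.extend([record] * bulk_copies)
    return reads


# ---------------------------------------------------------------------------
# Whole-dataset generation


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete synthetic dataset from a single seed."""
    rng = np.random.default_rng(config.seed)
    C, G = config.n_cells, config.genome_length
    tree = _random_binary_tree(C, rng)
    mutation_map = assign_mutations(tree, config.mutations_per_edge, G, rng)
    bulk, gsnv_loci, cell_genomes, details = generate_genomes(
        config, tree, mutation_map, rng
    )
    ado_mask = apply_ado_mask(C, config.n_pairs, config.p_ado, rng)

    mutation_pairs = sorted({locus // 2 for locus in mutation_map})
    pairs = set(mutation_pairs)
    if config.background_pairs:
        free = np.setdiff1d(np.arange(config.n_pairs), np.array(mutation_pairs))
        extra = rng.choice(free, size=min(config.background_pairs, len(free)), replace=False)
        pairs.update(int(p) for p in extra)
    sequenced = sorted(pairs)

    cell_reads: list[list[ReadRecord]] = [[] for _ in range(C)]
    half = config.read_length
    for pair in sequenced:
        start = 2 * pair
        stop = min(start + half, G)
        for cell in range(C):
            surviving = [
                (hap, cell_genomes[cell, hap, start : start + 2].copy())
                for hap in (0, 1)
                if not ado_mask[cell, pair, hap]
            ]
            coverage = int(rng.poisson(config.coverage_rate))
            fragments = amplify_site(surviving, coverage, config.p_ae, rng)
            # extend fragments with flanking context from the source haplotype
            extended = [
                np.concatenate([bases, cell_genomes[cell, hap, start + 2 : stop]])
                for hap, bases in fragments
            ]
            for bases, phred in sequence_reads(extended, config.phred_range, rng):
                cell_reads[cell].append(
                    ReadRecord(
                        cell,
                        start,
                        "".join(BASES[b] for b in bases),
                        tuple(phred_to_error(p) for p in phred),
                    )
                )

    bulk_reads = make_bulk_reads(
        bulk, config.bulk_copies, sequenced, config.read_length, config.phred_range[1]
    )
    truth = GroundTruth(
        tree=tree,
        mutation_map=mutation_map,
        mutation_details=details,
        gsnv_loci=gsnv_loci,
        bulk_genome=bulk,
        cell_genomes=cell_genomes,
        ado_mask=ado_mask,
    )
    return SyntheticDataset(config, truth, sequenced, cell_reads, bulk_reads)


# ---------------------------------------------------------------------------
# On-disk dataset


def _sam_header(genome_length: int) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": "ref", "LN": genome_length}],
    }


def _write_sam(
    path: Path, reads: list[ReadRecord], genome_length: int, prefix: str
) -> None:
    header = _sam_header(genome_length)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, read in enumerate(sorted(reads, key=lambda r: (r.start, r.bases))):
            aln = pysam.AlignedSegment(out.header)
            aln.query_name = f"{prefix}.{i}"
            aln.query_sequence = read.bases
            aln.reference_id = 0
            aln.reference_start = read.start
            aln.mapping_quality = 60
            aln.cigarstring = f"{len(read.bases)}M"
            aln.query_qualities = pysam.qualitystring_to_array(
                "".join(
                    chr(int(round(-10 * np.log10(e))) + 33) for e in read.error_probs
                )
            )
            out.write(aln)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write the dataset as plain-text artifacts.

    Layout: ``reference.fasta`` (two haplotype records), ``bulk.sam``,
    ``cells/cell_<i>.sam``, ``truth.nwk``, ``mutations.tsv`` (locus, edge,
    haplotype, alternative base), ``gsnv_loci.txt``, ``config.json``.
    """
    out = Path(out_dir)
    (out / "cells").mkdir(parents=True, exist_ok=True)
    G = dataset.config.genome_length
    with open(out / "reference.fasta", "w") as fasta:
        for hap in (0, 1):
            fasta.write(f">ref_hap{hap + 1}\n")
            seq = "".join(BASES[b] for b in dataset.truth.bulk_genome[hap])
            for i in range(0, len(seq), 80):
                fasta.write(seq[i : i + 80] + "\n")
    _write_sam(out / "bulk.sam", dataset.bulk_reads, G, "bulk")
    for cell, reads in enumerate(dataset.cell_reads):
        _write_sam(out / "cells" / f"cell_{cell}.sam", reads, G, f"cell{cell}")
    (out / "truth.nwk").write_text(
        dataset.truth.tree.as_string(schema="newick").strip() + "\n"
    )
    with open(out / "mutations.tsv", "w") as tsv:
        tsv.write("locus\tedge\thaplotype\talt\n")
        for locus in sorted(dataset.truth.mutation_details):
            edge, hap, alt = dataset.truth.mutation_details[locus]
            tsv.write(f"{locus}\t{edge}\t{hap}\t{BASES[alt]}\n")
    (out / "gsnv_loci.txt").write_text(
        "\n".join(str(int(x)) for x in dataset.truth.gsnv_loci) + "\n"
    )
    (out / "config.json").write_text(
        json.dumps(dataclasses.asdict(dataset.config), indent=2) + "\n"
    )
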