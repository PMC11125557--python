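# sclineage

Distance-based cell lineage tree reconstruction from whole-genome-amplified
single-cell DNA sequencing (scDNA-seq) data of healthy, diploid tissue, with
a matched unamplified bulk sample as the unmutated outgroup.

## Who this is for

Somatic mutations accumulated over cell divisions are the only usable lineage
signal in healthy tissue, and they are scarce (~1e-9 per site per division).
scDNA-seq reveals them, but whole-genome amplification (MDA, MALBAC)
introduces allelic dropout (ADO) and amplification errors (AE) that mimic or
hide mutations, on top of ordinary sequencing error.  `sclineage` is for
anyone who wants to turn per-cell read pileups at candidate mutation sites
into a lineage tree with calibrated uncertainty, without calling hard
genotypes first.

## The model

At each candidate site π the bulk genotype *B* is observed and, under the
infinite-sites assumption, all mutated cells share one mutation type *Z*
that differs from *B* by a single nucleotide (Dirichlet-Categorical prior,
uniform by default).  Cell mutation statuses *G*<sub>c</sub> ∈ {0, 1} are
i.i.d. Bernoulli(*p*<sub>m</sub>) with *p*<sub>m</sub> ~ Beta(*a*, *b*)
integrated out analytically, so a status vector with *m* mutated cells has
weight B(*m* + *a*, *C* − *m* + *b*)/B(*a*, *b*).

The per-cell read likelihood marginalizes the amplification process:

* two Bernoulli(*p*<sub>ado</sub>) dropout indicators set the initial state
  of a generalized Pólya urn whose draw-copy-return steps grow the surviving
  allele molecules to the observed coverage *L*<sub>c</sub>;
* the fragment genealogy is an *amplification tree* (leaves = fragments,
  internal nodes = copy events, plus a root edge accounting for
  subsampling); the AE count is Binomial(*E*, *p*<sub>ae</sub>) over its
  *E* edges (2*L* − 2 without dropout, 2*L* − 1 with one), truncated to at
  most one error;
* fragment-type/count configurations get exact probabilities from urn
  combinatorics — the uniform 1/(*L* − 1) tree-size partition, the
  *C*(*n*, *k*)/(*C*(*n*)·*E*) topology factor counting *k*-edges among the
  *C*(*n*) = (*n* − 1)! order-labelled *n*-fragment topologies, and the 1/3
  (singleton) or 1/6 (paired) erroneous-genotype factor;
* reads are tied to fragments by a dynamic program over all assignments,
  with Phred-derived base-call error probabilities
  *Q* = 10<sup>−0.1ρ</sup> (match 1 − *q*, specific mismatch *q*/3).

When a candidate site has a nearby heterozygous germline SNV co-covered by
the same reads (*paired site*), reads are phased to haplotypes, which
separates mutations from errors far more effectively than singleton-site
analysis.

The per-site pairwise distance is the posterior probability that exactly one
cell of the pair is mutated, M<sup>π</sup><sub>c,c′</sub> =
P(*G*<sub>c</sub>=0, *G*<sub>c′</sub>=1 | …) + P(*G*<sub>c</sub>=1,
*G*<sub>c′</sub>=0 | …); the distance to bulk is the marginal
P(*G*<sub>c</sub>=1).  Distances are averaged over sites where both members
of the pair have coverage, and the (C+1)×(C+1) matrix goes through standard
Saitou–Nei neighbor joining, re-rooted at the bulk.  Site bootstrap plus
transfer bootstrap expectation (TBE) gives branch supports, and
random-walk Metropolis–Hastings can estimate (*p*<sub>ado</sub>,
*p*<sub>ae</sub>) from the data.

## Worked example

Simulate a 10-cell dataset (diploid genome, full phasing, 10% ADO, AE rate
1e-3, mean coverage 10), select sites, and fit:

```python
from sclineage import (
    SimulationConfig, simulate_dataset, select_sites,
    CellLineageModel, ModelParameters, rf_similarity,
)

config = SimulationConfig(
    n_cells=10, genome_length=10_000, mutations_per_edge=10,
    phasing_frequency=1.0, p_ado=0.1, p_ae=1e-3, coverage_rate=10.0, seed=1,
)
dataset = simulate_dataset(config)
observations = select_sites(dataset.bulk_reads, dataset.cell_reads, mode="hybrid")
model = CellLineageModel(observations, params=ModelParameters(p_ado=0.1, p_ae=1e-3))
result = model.fit(n_boot=100, seed=1)
print(result.summary())
print("similarity to truth:", round(rf_similarity(result.tree, dataset.truth.tree), 3))
```

prints

```
Cell lineage reconstruction
===========================
cells:               10 (+ bulk)
sites:               67 paired, 2 singleton
p_ado:               0.1
p_ae:                0.001
mean pair distance:  0.4456
bootstrap trees:     100
TBE supports:        min 0.97, median 0.99, max 1.00
tree: [&R] (bulk:0.0109,((cell3:0.0290,cell4:0.0300):0.0425,(cell1:0.0393,...
similarity to truth: 1.0
```

69 of the 180 simulated mutation loci pass the selection thresholds (the
rest sit on pendant edges, where a single mutated cell carries no topology
information, or fall below the per-cell read-fraction cutoffs); almost all
are paired with an adjacent gSNV because the simulation uses full phasing.
Every TBE support is near 1 and the reconstructed topology matches the
ground truth exactly (similarity 1.0 means identical bipartition sets; 0
means none shared).

The same workflow is available from the shell:

```
sclineage simulate --out data --cells 10 --seed 1
sclineage run --data data --out results --mode hybrid --jobs 4 --n-boot 100
sclineage evaluate --truth data/truth.nwk --inferred results/tree.nwk
```

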