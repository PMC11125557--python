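# Methods

## Model overview

`sclineage` reconstructs a cell lineage tree from bulk and single-cell DNA
reads in four steps: (1) candidate-site selection from read pileups, (2) an
independent per-site probabilistic computation of pairwise
genotype-difference posteriors, (3) aggregation into a (C+1)×(C+1) distance
matrix over cells plus bulk, and (4) neighbor joining with bulk re-rooting,
optionally followed by site bootstrapping with transfer-bootstrap-expectation
(TBE) supports.  Step (2) is embarrassingly parallel over sites and the
reduction is order-invariant, so results are bit-identical for any worker
count.

### Assumptions

* Healthy, diploid genomes: no copy-number variation; the bulk sample is
  unmutated and deep enough to call reference nucleotides and germline SNVs.
* Infinite-sites: a site mutates at most once in the tree, so all mutated
  cells share one mutation type that differs from the bulk genotype by one
  nucleotide (3 candidate types at a singleton site, 6 at a paired site).
* At most one amplification error per cell and site is modelled in
  inference.  The Binomial AE-count law is truncated to {0, 1} *without*
  renormalization, so each cell likelihood is underestimated by the
  neglected mass P(A ≥ 2) = O((E·p_ae)²); with realistic p_ae ≤ 1e-3 and
  coverage ≤ 50 this is below 1e-2 relative and cancels almost entirely in
  the normalized posteriors.  The simulator deliberately allows multiple
  errors, so tests exercise this model misspecification.
* Reads are short, ungapped, and independent given their source fragment;
  base-calling errors follow the Phred model Q = 10^(−0.1ρ), uniform over
  the three alternative nucleotides.

### Amplification combinatorics

The fragment genealogy of one allele is an order-labelled rooted binary tree
with an extra incoming root edge accounting for subsampling: `tree_count(n)`
= (n−1)! distinct topologies, in bijection with the urn's draw-copy
histories (validated by exhaustive enumeration in the tests, and exposed as
`enumerate_amplification_trees`).  `subtree_edge_count(n, k)` — the number
of edges across all topologies whose below-edge subtree holds exactly k
fragments — is computed by the exact integer recurrence

    T(1, 1) = 1
    T(n, k) = (n−1−k)·T(n−1, k) + (k−1)·T(n−1, k−1) + 2(n−1)!·[k = 1]

derived from the growth process (splitting a leaf below a k-edge grows it;
every extension creates two fresh 1-edges) and validated against the same
enumeration.  Configuration probabilities combine the uniform 1/(L−1)
two-tree size partition (the Pólya-urn Beta-Binomial with unit pseudo-counts
is uniform), the topology factor C(n,k)/(C(n)·E), and the 1/3 or 1/6
erroneous-genotype factor; within every dropout/error branch they sum to 1
by construction (root-edge errors, which turn an entire tree erroneous, are
included — the history-enumeration oracle confirms both the inclusion and
the factors).  Two degenerate branches carry zero mass: both alleles dropped
with reads present, and no dropout with L = 1 (two surviving alleles cannot
yield a single fragment, because the partition excludes empty trees).

### Read-likelihood dynamic program

P(R | F, N, Q) is the *uniform mixture over assignments* of reads to
fragment types with the given counts: the DP introduces reads one at a time
over states (reads seen, used of type 1, used of type 3) in O(L³) and the
result is divided by the multinomial coefficient.  This normalization makes
the likelihood a proper distribution over ordered read outcomes (verified
exhaustively over the 4^L outcome space), which the marginalization chain
requires; the assignment-enumeration oracle checks the DP exactly for
L ≤ 6.  Reads covering only one position of a paired site contribute a
single-position factor — an interpretation choice for a case the
marginalization leaves open.

### Numerical strategy

All per-cell tables are computed on a per-read rescaled scale (each read's
probabilities divided by its all-match likelihood, the log of the scale
tracked separately) instead of per-operation log-sum-exp; posteriors
normalize the scale away and the joint log-likelihood adds it back.  Branch
sums are cached per site in a parameter-independent form (`PreparedSite`),
so Metropolis–Hastings sweeps of (p_ado, p_ae) only reweight precomputed
quantities — one likelihood evaluation over 20 sites and 10 cells costs
about 4 ms.  Read coverages above ~60 with heavily discordant reads can
underflow double precision; coverage at that depth is far outside the
intended regime and can be downsampled upstream if needed.

## Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| `p_ado` | per-allele dropout probability | 0.1 | mid-range of amplification chemistries; estimable by MCMC |
| `p_ae` | per-edge amplification-error probability | 1e-3 | reported rates span ~1e-6–3e-4; 1e-3 is a conservative default, estimable by MCMC |
| `alpha` | mutation-type concentration | all ones | uniform over the 3 or 6 types |
| `a`, `b` | Beta prior on the mutation probability | 1, 1 | uniform; raising `a` biases toward mutations |

Site selection (all thresholds non-strict): bulk reference needs depth ≥ 10
and ≥ 80% agreement; a gSNV needs bulk depth ≥ 10, alternative frequency
≥ 20%, and ≥ 2 cells displaying both alleles at ≥ 20% of their reads; a
candidate needs 2 … C−1 cells supporting the same alternative at ≥ 20% of
each cell's reads.  A per-cell minimum depth of 2 reads (configurable)
gates the 20% fraction rules — the fraction of a single read is
meaningless.  Candidates pair with the closest co-covered validated gSNV;
the gSNV criterion is re-checked on the phaseable (co-covering) reads only,
and failure drops the pair (hybrid mode falls back to a singleton site)
rather than trying farther gSNVs, which by construction are co-covered by
fewer reads.  "Agree on an alternative" means the *same* alternative
nucleotide; ties are broken by supporting-cell count, pooled read count,
then alphabetically.

Metropolis–Hastings: 5000 iterations × 3 chains, Gaussian random-walk
proposals with sd 0.01 perturbing both parameters jointly, uniform [0, 1]
priors, 20% burn-in, estimates pooled across chains, 20 randomly chosen
sites.  The proposal is symmetric, so the acceptance ratio is exactly the
likelihood ratio; out-of-bounds proposals are rejected (prior density zero)
rather than reflected.  Whether "the means of the samples" pools chains or
not was an open choice; pooling is used.

## Synthetic-data generator

The simulator emulates the full protocol the model targets: a random binary
lineage tree over C cells; 2(C−1)μ mutations on odd genome positions with
at least one per edge (all leaves below an edge inherit them); a diploid
bulk genome with round(ρ·G/2) heterozygous gSNVs at even positions (ρ = 1
makes every site-pair phaseable); independent Bernoulli(p_ado) allele
dropout per cell and site-pair; Pólya-urn amplification to a Poisson(λ)
coverage with an error corrupting each copy independently with probability
p_ae (so multiple errors can accumulate, unlike in inference); Phred scores
uniform on [30, 42] with matching base-call errors; and 15 error-free
unamplified copies of each bulk haplotype.  The Phred bounds are
configurable; [30, 42] is the modern-instrument range the defaults assume.

Choices the protocol leaves open, fixed here: bulk reads carry no
sequencing errors (the bulk is unamplified and deep, so threshold calls are
insensitive to this); the two original allele molecules count toward the
Poisson coverage rather than in addition to it (when the drawn coverage is
below the initial ball count, fragments are subsampled — the model's root
edge exists precisely to absorb subsampling); reads default to the 2 bp
site-pair span, with longer reads available that extend fragments with
haplotype flanking context.

Only site-pairs containing a mutation (plus an optional number of
background pairs) are sequenced: unmutated pairs cannot pass candidate
selection and would only cost time.  What passing tests on this generator
do *not* show: robustness to alignment artifacts, chimeric MDA fragments,
coverage waves, indels, or copy-number events — none of which the generator
emulates.

## Tree reconstruction and evaluation

Neighbor joining is the standard Saitou–Nei algorithm with a deterministic
tie-break (lowest-index pair on equal Q-criterion); an incomplete matrix
raises an error naming the missing pair.  Pairs with no co-covered site are
imputed with the mean of the defined distances involving either member (a
complete matrix is required; a warning is emitted).  Negative NJ branch
lengths are clamped to zero at serialization only; branch *lengths* are
carried but not validated — only the topology is the estimand.  Bootstrap
trees resample sites with replacement and re-aggregate with the resampled
coverage masks, so per-pair denominators are recomputed per replicate.

Similarity between topologies is 1 − RF/I_B with RF the symmetric
bipartition difference and I_B the total nontrivial edges of both trees;
TBE support of a reference edge with lighter side p is 1 − mean over
bootstrap trees of the transfer index divided by (p − 1), the transfer
index being the minimum Hamming distance (better orientation) between the
edge's bipartition and any branch of the bootstrap tree — equivalent to the
minimum number of leaf removals, which a brute-force oracle verifies on
small trees.  All bipartitions are computed on the cell leaf set with the
bulk removed, so trees with and without the outgroup compare consistently.

One definitional ambiguity resolved as a design choice: the cell-to-bulk
distance sums the pair posterior over the partner cell's states, which is
the marginal posterior mutation probability P(G_c = 1); it is implemented
as that marginal.

## Problem sizes used in the shipped checks

Unit and property tests run oracles at enumeration scale (L ≤ 6, C ≤ 8).
The end-to-end checks use 10-cell datasets on a 10 kb genome with 10
mutations per edge — the genome length only bounds where loci can sit, so
shrinking it from 1 Mb leaves the statistical conditions (C, μ, λ, ρ, error
rates) unchanged while keeping a fit under a minute; parameter recovery
uses mean coverage 10 and the full 5000 × 3 MCMC protocol; topology
recovery uses coverage 20 with no dropout and AE 1e-5 over five seeds.

## Known limitations

* Branch lengths are not calibrated; downstream use should treat the
  output as a topology with supports.
* The likelihood truncates at one amplification error per cell-site;
  datasets with pervasive early-cycle errors will inflate distances.
* Site selection assumes a reasonably uniform bulk; systematic allelic
  imbalance in bulk would miscall gSNVs.
* The O(C³ + C·L³) per-site cost makes very deep sites (L ≳ 60)
  disproportionately expensive; downsampling such sites is advisable.
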