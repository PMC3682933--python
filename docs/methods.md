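# Methods

`snpanel` turns an aligned set of mitochondrial COI barcode sequences into
(a) operational taxonomic units (OTUs) delimited by a data-driven distance
threshold and (b) near-minimal diagnostic SNP panels that separate every
OTU pair by at least *k* positions, together with the evaluation machinery
(NJ/patristic distances, Mantel concordance, minimum spanning haplotype
networks) used to judge how much information such a panel retains.

## Distances

Pairwise distances use the Kimura 2-parameter model,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q),

with P and Q the transition and transversion proportions over comparable
sites.  Site filtering is pairwise deletion: a site contributes to a pair
only when both characters are unambiguous bases; `deletion="complete"`
drops ambiguous columns globally instead.  When the logarithm argument is
non-positive the pair is *saturated*; this is a flagged state (or an
exception), never a silent NaN, and threshold inference refuses flagged
matrices.  Thresholds and reported distances use the percent scale (1.70
means 1.70%); internal computation is on substitutions/site.

## Taxon delimitation

The delimitation threshold is the first interior local minimum of a
Gaussian kernel density over all lower-triangle pairwise distances
(Silverman's rule-of-thumb bandwidth, 1024 grid points spanning
`[0, max]`).  The first depression is taken because it marks the
transition from the within-taxon to the between-taxon mode of the
distribution (the barcode gap); further minima are reported for
inspection.  A unimodal density raises a "no barcode gap" error with a
pointer to the `--manual-threshold` override.  Because described species
represented by one sequence contribute only between-taxon distances and
can drag the depression towards zero, the inference can be rerun with
singletons excluded.

Clustering at the threshold is single linkage with an inclusive boundary
(d <= t joins): OTUs are the connected components of the threshold graph.
Component ids are canonicalized by lexicographically smallest member id,
so partitions are invariant under input permutation.  Partition summaries
flag composite OTUs (>= 2 described species), split species (spanning
>= 2 OTUs) and singleton OTUs, and report the percentage of OTUs that
contain exactly one described species.

## Consensus and silent/non-silent classification

Each OTU is summarised by a strict union consensus: the base set at a
position is the union of member base sets (input ambiguity codes expand),
written as the IUPAC code.  Union rather than majority semantics is what
makes the panel guarantee meaningful — the consensus covers every observed
member state, so a panel that separates consensi separates any sampled
haplotypes.  Gaps are ignored unless unanimous, in which case the position
is flagged uninformative and carries the full base set {A,C,G,T}.

The reading frame is chosen per dataset as the offset (1..3) minimising
codons whose every disambiguation is a stop, summed over all consensi
under the invertebrate mitochondrial code (NCBI table 5, configurable);
ties break to the smallest offset.  A position is *non-silent* when two
OTUs have disjoint amino-acid sets for the codon containing it, over all
disambiguations.  Disjointness (not mere difference) keeps the call
conservative under ambiguity codes.  Positions outside any complete codon
are classified silent with a warning flag.

## Candidate extraction and panel search

Two states are *incompatible* when their base sets are disjoint; gaps and
N never count as differences.  This is deliberately conservative: an assay
built on the panel distinguishes the taxa regardless of which underlying
haplotype is sampled.

Per OTU, every polymorphic position at which that OTU is incompatible with
at least one other OTU is ranked by (non-silent first, then degeneracy —
the number of distinct states across OTUs — descending, then position
ascending) and the top 25 per OTU are pooled.  The cap and the preference
for non-silent, high-degeneracy positions follow the published selection
scheme; whether non-silent status outranks degeneracy was an open choice
and is exposed via `prefer_nonsilent`.

The search screens subsets of the pool at increasing sizes n (starting at
n = k, since no smaller panel can separate any pair by k), up to a fixed
number of trials per size (default 10^6).  A returned panel's minimum
pairwise incompatibility count is >= k by construction and is re-checked
by `validate_panel`'s independent recount.  Two numerical choices matter:

- **Enumeration below the trial budget.**  When C(pool, n) <= trials the
  subsets are enumerated in lexicographic order rather than sampled.
  Random draws are with replacement across trials, so even a budget equal
  to the space size would miss a unique minimal subset with probability
  about 1/e; enumeration makes small instances exact and lets the search
  provably match the exhaustive oracle there.  At survey scale the space
  dwarfs the budget and the behaviour is the randomized screening.
- **Feasibility first.**  Before any screening, every OTU pair must have
  >= k incompatible positions in the pool; otherwise the limiting pair and
  its available count are reported.  This turns a hopeless search into an
  immediate, interpretable error.

Per-position pair incompatibility is precomputed as a (positions x pairs)
matrix so a batch of trials reduces to integer row sums; a full growth
search with 10^6 trials per size over a 50-OTU, 120-position pool runs in
about a minute on one CPU.  The RNG is a seeded PCG64; the seed, sizes
attempted, trials used and enumeration/sampling mode per size are recorded
in the panel metadata.

`exhaustive_min_panel` (guarded to pools <= 20) enumerates sizes ascending
and returns the lexicographically smallest minimal panel; it is the oracle
the randomized search is tested against.

## Evaluation

- **NJ trees** use the Saitou–Nei agglomeration, implemented in-package so
  that negative branch lengths are clamped to zero with the deficit
  shifted to the sister branch (both-negative limbs, which arise only on
  non-additive inputs, clamp to zero).  Patristic matrices reproduce
  additive inputs exactly.
- **Mantel test** correlates the off-diagonal entries of two labelled
  distance matrices by Spearman rank; the null permutes rows and columns
  of one matrix simultaneously, and the two-tailed p-value is
  `(count(|r_perm| >= |r_obs|) + 1) / (n_permutations + 1)` (default
  10,000 permutations).  Because a simultaneous permutation only permutes
  the off-diagonal multiset, ranks are computed once and permuted, making
  the test O(n^2) per permutation.
- **Minimum spanning network**: identical sequences collapse into
  haplotype nodes; an edge (u, v, w) over haplotype Hamming distances is
  in the MSN iff u and v lie in different components once all edges of
  weight < w are present (Kruskal equal-weight closure) — exactly the
  union of all minimum spanning trees.  Nodes whose members span two or
  more described species are reported as shared haplotypes, the signature
  of mitochondrial introgression.  Concatenated-panel distances in the
  Mantel comparison use Hamming counts rather than K2P because few-dozen
  base concatenations routinely saturate the K2P correction.

## Synthetic data

The generator emulates a curated barcode survey on a star phylogeny: a
random ancestral coding sequence without internal stops (table 5), one
founder per OTU at Poisson(L x divergence) substitutions, members at
Poisson(L x within_diversity) substitutions from their founder.
Substitutions have transition bias kappa/(kappa+2) and land on codon
positions with weights (0.10, 0.05, 0.85), mimicking the third-position
bias of coding mitochondrial DNA.  Defaults: 699 bp (the barcode fragment
length), 10 OTUs x 5 members, divergence 0.08, within-OTU diversity 0.003,
kappa 4 — a wide, unambiguous barcode gap typical of well-separated
congeners.  Introgression pairs copy a realized member haplotype of the
donor OTU into the recipient's sample under the recipient's species label,
so the shared haplotype is guaranteed to be present in both species.
Ground truth (partition, species labels, shared haplotypes, per-sequence
mutation logs) is emitted alongside.

What the generator does not emulate: indels (the pipeline strips gap
columns anyway), rate heterogeneity beyond codon-position weights,
non-star topologies, sequencing error and the heavy-tailed sampling depth
of real repositories.  Passing tests therefore demonstrate correctness of
the algorithms under planted structure, not field performance on real
surveys.

`simulate_candidate_pool` generates candidate pools directly (states per
OTU per position, with a skewed majority state).  It exists because the
25-per-OTU extraction cap with a global ranking key makes alignment-derived
pools cluster near 25-30 positions at any OTU count, while the panel
search itself must also be exercised at survey scale (many OTUs, pools of
100+ positions).

## Scales used in the shipped checks

The test suite and `scripts/acceptance.py` run everything from scratch at
sizes chosen to finish in minutes on one CPU: 200 small instances for the
search-vs-oracle equivalence, 50 seeded searches for the recount
postcondition, 20 seeds for barcode-gap recovery, the full 4^5-sequence
exhaustive K2P check, 200 Mantel null replicates, and one full-growth
10^6-trial search over a 50-OTU, 120-position pool.  The acceptance script
simulates a 12-OTU survey (two singleton species, one introgression pair,
divergence 0.12) and reports threshold, partition recovery, panel sizes at
k = 3 and 4, Mantel concordance and shared-haplotype detection; the
divergence is set where candidate pools under the 25-per-OTU cap remain
k = 4-feasible across seeds.

## Known limitations

- The candidate ranking key (non-silent, degeneracy, position) is shared
  across OTUs, so per-OTU top-25 lists overlap heavily and pools stay
  small; on real data with patchy ambiguity structure the lists diverge
  more.
- Panels are only as robust as the sample behind the consensi: new
  haplotypes can erase a diagnostic position.  With zero within-OTU
  diversity the shipped robustness check shows designed panels stay valid
  on fresh samples; with diversity they may not, and `validate_panel`
  reports the violation.
- The published survey's own panels (e.g. 52 SNPs over 182 OTUs) depend on
  a ~1,000-sequence GenBank/BOLD compilation and are not regenerated here;
  the shipped numbers come from the package's own synthetic surveys and
  from the published tables' arithmetic.
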