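# snpanel

Diagnostic SNP panel design within the limits of COI-based species
delimitation.

DNA barcoding identifies specimens — including larvae and fragments that
defeat morphological keys — from a ~650–700 bp fragment of the
mitochondrial cytochrome oxidase I (COI) gene.  In recently radiated
groups such as tephritid fruit flies, some described species cannot be
told apart by COI at all, so the practical unit of identification is the
*operational taxonomic unit* (OTU): a cluster of sequences separated from
all other clusters by a data-driven distance threshold.  `snpanel`
implements the full workflow from an aligned barcode FASTA to:

1. **OTU delimitation.**  Kimura 2-parameter distances
   (`d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)`, P/Q transition/transversion
   proportions), a threshold read off the first depression (the "barcode
   gap") in the kernel density of all pairwise distances — with or without
   singleton species — and single-linkage clustering at that threshold,
   with composite/split-OTU bookkeeping against the described species
   labels.
2. **Near-minimal diagnostic SNP panels.**  One IUPAC union consensus per
   OTU, a candidate pool of up to 25 preference-ranked SNPs per OTU
   (non-silent first, under the invertebrate mitochondrial code, then
   higher degeneracy), and a randomized screening that grows panel size
   until some set of positions separates *every* OTU pair by at least `k`
   SNPs (k = 3 or 4 gives headroom for assay attrition).  Positions count
   as separating a pair only when the consensus base sets are disjoint, so
   the guarantee holds for any sampled member haplotype.  Small instances
   are solved exactly; an exhaustive oracle (`exhaustive_min_panel`)
   certifies minimality where enumeration is feasible.
3. **Evaluation.**  Independent recounts of a panel's pairwise difference
   matrix, neighbour-joining trees and patristic distances, a Spearman
   Mantel test measuring how much of the full barcode's distance structure
   a concatenated panel retains, and minimum spanning haplotype networks
   that expose haplotypes shared between described species (mitochondrial
   introgression).
4. **Synthetic surveys.**  A seeded generator planting OTU structure, a
   barcode gap, singleton species, codon structure and optional
   introgression, with full ground truth — every stage is testable without
   downloads.

## Worked example

Simulate a 10-OTU survey and run the whole pipeline at k = 3:

```sh
snpanel simulate --seed 4 --out sim.fa --truth truth.json
snpanel pipeline --fasta sim.fa --k 3 --trials 1000000 --seed 1 --outdir run
```

which prints (abridged):

```json
{
    "threshold": 6.319255688781017,
    "partition_summary": {
        "n_otus": 10,
        "n_composite_otus": 0,
        "percent_single_species_otus": 100.0
    },
    "panel_size": 8,
    "achieved_min": 3,
    "validation": {
        "achieved_min": 3,
        "passes": true,
        "n_pairwise_comparisons": 45,
        "mean_diff": 4.155555555555556
    },
    "reading_frame": 1
}
```

Reading: the density of all pairwise K2P distances dips first at 6.32%,
single-linkage clustering there recovers 10 OTUs each containing exactly
one described species (100% single-species OTUs), and a panel of 8
alignment positions separates all 45 OTU pairs by at least 3 SNPs
(4.16 on average).  `run/` holds `partition.tsv`, the consensus FASTA
`cons.fa`, `panel.tsv` (one row per panel position with per-OTU states,
degeneracy and silent status) and `report.json` with the seed and all
effective parameters.  The same command with the same seed reproduces
`panel.tsv` byte for byte.

The stages are also available separately (`simulate`, `distances`,
`delimit`, `consensus`, `design`, `validate`, `mantel`, `network`) and as
library functions (`snpanel.run_pipeline`, `snpanel.search_panel`, ...).

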