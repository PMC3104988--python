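# clonepop

Inference of reproductive mode — obligate parthenogenesis, cyclic
parthenogenesis, or a mixed/uncertain system — for diploid populations,
from multilocus codominant genotypes (microsatellites) and mtDNA
haplotype sets.

The package bundles, as one tested pipeline:

* **`genotypes_io`** — a diploid multilocus genotype data model with
  GenePop and CSV readers/writers, whole-call missingness, and
  complete-case filtering.
* **`clonal`** — multilocus genotype (MLMG) partitioning and clonality
  statistics: probability of identity (P_ID, P_ID_sib), the number of
  loci needed to resolve individuals, round-robin allele frequency
  estimation on unique MLMGs, P_gen / P_sex (with an optional Fis
  correction), genotypic richness R = (G−1)/(N−1), and the genotypic
  diversity ratio (observed / expected distinct genotypes under
  Hardy–Weinberg and independent loci, Monte Carlo or analytic).
* **`hwe_ld`** — observed/unbiased expected heterozygosity,
  Weir–Cockerham Fis (per locus and multilocus), a Fis permutation test,
  exact Hardy–Weinberg score (U) tests against heterozygote excess or
  deficiency (complete enumeration, a Guo–Thompson-style switch Markov
  chain with batch standard errors, or fast i.i.d. conditional
  sampling), a calibrated global multilocus score test, and the
  standardized index of association r̄_d with a permutation null and
  clone correction.
* **`ordination`** — binary allele presence/absence matrix, Dice/Nei
  distance (shared absences ignored), principal coordinate analysis,
  cascaded K-means with the Calinski–Harabasz criterion, hybrid-centroid
  intermediacy, Cavalli-Sforza/Edwards chord distances, and rarefied
  allelic richness.
* **`mtdna`** — haplotype collapsing, haplotype and nucleotide diversity
  (h ± SD, π ± SD, S), p-distance summaries within/between regions, and
  in-silico ApoI (R^AATTY) digestion with a two-group species call.
* **`simulate`** — seeded generators for cyclic (panmictic, optional
  inbreeding), obligate (clonal copies of founder genotypes, optionally
  of F1-hybrid origin with fixed heterozygosity), and mixed populations,
  missing-data injection, and haplotype sets with optional planted
  restriction sites.  Every generator emits a truth record.
* **`pipeline`** — per-population orchestration and the decision rules:
  GD ratio < 0.75 with Hardy–Weinberg rejected (Bonferroni-adjusted)
  → obligate; GD ratio > 0.75 with Hardy–Weinberg not rejected
  → cyclic; anything else → mixed-or-uncertain.

## CLI

The console script `clonepop` exposes each stage:

```sh
# generate synthetic populations from a JSON list of specs
clonepop simulate --spec specs.json --out data.gen --truth-out truth.json

# per-population clonality table (G, N, R, GD ratio, P_sex rows)
clonepop clonal-stats --input data.gen --out clonal.tsv --seed 1

# Ho/He/Fis and score-test p-values per population x locus
clonepop hwe --input data.gen --out hwe.tsv --method sampling

# multilocus linkage disequilibrium, raw and clone-corrected
clonepop ld --input data.gen --out ld.tsv --permutations 1000

# PCoA + cascade K-means (optional scatter plot)
clonepop ordinate --input data.gen --out ord.tsv --plot ord.png

# mtDNA diversity summary and ApoI digestion
clonepop mtdna --fasta nd5.fasta --regions regions.tsv --out div.tsv
clonepop digest --fasta nd5.fasta --out digest.tsv

# everything at once, with verdicts
clonepop classify --input data.gen --outdir results/
clonepop run-all --config config.json --outdir results/
```

`run-all` accepts a JSON config naming either an input file
(`{"input": {"format": "genepop", "path": ...}}`) or a simulation
(`{"simulate": [<population spec>, ...]}`), plus seeds, chain /
permutation / replicate sizes and thresholds; reruns with the same
config are byte-identical.

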