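# introscan

SNP-based analysis of hybridisation and introgression between two
closely related species — built for systems like the Darwin's tree
finches, where a critically endangered species (*Camarhynchus pauper*)
hybridises with a stable congener (*C. parvulus*) and forms a
backcrossing hybrid swarm. Given a VCF of biallelic SNPs (with RAD-locus
metadata) and a population map of prior group labels and sampling years,
the pipeline:

1. **filters** SNPs (overall MAF ≥ 0.03, call rate ≥ 0.75 per
   population, optional one-SNP-per-RAD-locus thinning), screens
   relatedness with the KING-robust kinship estimator;
2. **re-classifies** individuals from ancestry coefficients estimated by
   a sparse nonnegative matrix factorisation (parental when
   max q ≥ 0.80, hybrid otherwise; K chosen by masked binomial
   cross-entropy), then re-filters under the new labels;
3. **quantifies divergence**: multi-locus Weir–Cockerham θ
   (F_ST = Σa/Σ(a+b+c)) with locus-bootstrap CIs, per-SNP θ, AMOVA Φ_ST
   over RAD-locus haplotypes, Ho/He/F_is per group;
4. **tracks private alleles** — alleles observed in one parental species
   and absent in the other — through the hybrid swarm: frequency per
   sampling year, the ≥ 0.30 high-frequency rule, cross-year shifts, and
   a hybrid-subsampling sensitivity analysis;
5. **scans for selection** with a PC-regression Mahalanobis test
   (genomic-inflation rescaled χ²_K p-values, Bonferroni) and a trimmed
   chi-square F_ST null fit (BH at FDR 5%), plus a local-PCA scan
   (windowed eigen summaries → window dissimilarity → MDS → three
   extreme corners);
6. **combines evidence** into a tiered candidate table (high-frequency
   private allele + scan outlier + corner window) and reports
   reclassification percentages.

A synthetic-data module simulates the whole design with known truth
(Balding–Nichols parental divergence at a target F_ST, F1s and
backcrosses with recorded ancestry, RAD-locus linkage, two sampling
years with Wright–Fisher drift, uniform missingness), so every stage is
testable without the original data. See `docs/methods.md` for the
models and all defaults.

## Worked example

```python
from introscan.simdata import SimConfig, YearCohort, simulate_dataset, write_dataset
from introscan.pipeline import PipelineConfig, run_pipeline

cfg = SimConfig(
    n_loci=1000, n_chromosomes=6, snps_per_radlocus=2, target_fst=0.08,
    years=[YearCohort("2005", n_parvulus=12, n_pauper=10, n_f1=4, n_backcross=6),
           YearCohort("2013", n_parvulus=10, n_pauper=8, n_f1=2, n_backcross=2)],
    missing_rate=0.05, planted_outliers=3, seed=31,
)
G, loci, popmap, truth = simulate_dataset(cfg)
paths = write_dataset(G, loci, popmap, "example")

res = run_pipeline(PipelineConfig(
    vcf=str(paths["vcf"]), popmap=str(paths["popmap"]), outdir="example/out",
    seed=1, k_range=(1, 2), snmf_repeats=3, bootstrap=50,
    subsample_n=4, subsample_year="2005",
))
print(res["fst"][["group_1", "group_2", "theta"]])
print(res["evidence"][["chrom", "pos", "origin", "tier"]].head())
```

prints

```
    group_1 group_2     theta
0  parvulus  pauper  0.080142
1  parvulus  hybrid  0.011307
2    pauper  hybrid  0.027537
  chrom   pos    origin  tier
0  chr2  1000  parvulus     3
1  chr2  1010  parvulus     3
2  chr1  1000  parvulus     3
3  chr1  1010  parvulus     3
4  chr3  1000  parvulus     3
```

The parental pair's θ recovers the simulated divergence (0.08), the
hybrid group sits closer to both parents than they are to each other
(the signature of an admixed swarm), and the evidence table lists
high-frequency private alleles ranked by how many independent lines of
evidence agree. The top hits here are the three planted fixed-difference
loci (two SNPs each, at the start of chromosomes 1–3): their parvulus
alleles are private, at high frequency in hybrids, flagged by the
outlier scan, and inside a local-PCA corner window — tier 3.

The same stages are available as a CLI:

```sh
introscan simulate --config sim.yaml --out data/
introscan filter --vcf data/genotypes.vcf --popmap data/popmap.tsv \
    --maf 0.03 --call-rate 0.75 --single-snp --out filtered/
introscan ancestry --vcf ... --popmap ... --k-range 1:10 --q-threshold 0.80 --out anc/
introscan private-alleles --vcf ... --popmap ... --threshold 0.30 --subsample 4x3 --out pa/
introscan run-all --config pipeline.yaml
```

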