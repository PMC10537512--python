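# heterokit

Analysis pipeline for classifying maize inbred lines into heterotic groups
from line × tester testcross trials, and confronting those groups with
SNP-marker-based diversity and clustering.

Components:

- **io** — phenotype CSV / genotype (VCF or matrix-CSV) readers and writers,
  newick dendrogram export, grain-yield moisture adjustment (15% basis).
- **simulate** — seeded generators for multi-environment line × tester trials
  (additive GCA/SCA + G×E + error, optional planted two-group SCA structure)
  and structured genotype panels (Balding–Nichols subpopulations, Dirichlet
  admixture, residual heterozygosity, missingness) with full ground truth.
- **combining** — cross means, GCA/SCA/HSGCA effects (`HSGCA = GCA + SCA`),
  combined RCBD ANOVA across environments with variance components,
  entry-mean repeatability, CV and LSD.
- **grouping** — SCA-based (sign opposition + magnitude threshold + check-mean
  condition) and HSGCA-based (sign rule + tie-break) heterotic assignment,
  plus Spearman/agreement concordance between methods.
- **markers** — SNP QC (missing > 10%, major-allele frequency > 95%,
  heterozygosity > 20%; strict thresholds) and per-marker MAF, gene
  diversity, Botstein PIC, observed heterozygosity.
- **structure** — pairwise IBS distances, Ward minimum-variance clustering,
  dosage-matrix PCA, an EM admixture estimator with the ≥ 60% membership
  rule, and Evanno ΔK model selection over replicate log-likelihoods.
- **report** — heterotic-group × marker-cluster cross-tabulations,
  per-cluster testcross trait means, and the end-to-end pipeline driver.

## CLI

```sh
heterokit simulate --seed 7 --grouped --out-dir sim/       # trial + panel + truth
heterokit effects sim/phenotypes.csv --trait pva --out eff.csv
heterokit anova sim/phenotypes.csv --trait pva --out anova.csv
heterokit group sim/phenotypes.csv --trait pva --out groups.csv
heterokit markers-qc sim/genotypes.csv --out-dir qc/
heterokit structure qc/genotypes_filtered.csv --k 3 --out-dir struct/
heterokit run sim/phenotypes.csv sim/genotypes.csv --out-dir out/   # everything
```

All outputs are plain CSV/JSON/newick text; every run records its seed and
conventions in `run_log.txt`.

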