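# balscan

Scanning candidate gene regions for the footprints of **balancing
selection**, and placing a disease cohort into that picture.  The
package is aimed at population geneticists who want the classic
site-frequency-spectrum / differentiation / haplotype-structure
workflow as tested, scriptable Python instead of a chain of GUI tools.

A balanced polymorphism — two deeply diverged haplotype clades held at
intermediate frequency — leaves coordinated signatures that this
package computes and calibrates:

* **SFS neutrality tests.**  Per locus and population: S, per-site π,
  θ_W, Tajima's *D*, Fu & Li's *D′* and *F* (outgroup or starred
  variants).  Significance by one-tailed empirical p-values,
  p = (1+k)/(R+1), against neutral Kingman-coalescent replicates
  conditioned on the observed S; multiplicity by the adaptive
  Benjamini–Hochberg procedure (lowest-slope m₀ estimate).
* **Per-SNP F_st outlier scan** between population clusters
  (G_ST/Hudson/Weir–Cockerham estimators) against an empirical genome
  background at a nearest-rank percentile threshold, with derived
  allele frequencies per cluster.
* **LD structure**: genotypic and haplotypic r², sliding-window
  pruning (50 SNPs / step 10 / r² > 0.1), and extraction of the
  mutually high-LD SNP set (r² > 0.95) around candidate variants.
* **DAPC** (discriminant analysis of principal components) with
  α-score-based choice of retained PCs, group posteriors, and
  projection of held-out cohorts as supplementary individuals —
  a scikit-learn estimator (`fit` / `transform` / `predict_proba`).
* **EM haplotype inference** (Excoffier–Slatkin under HWE, restarts,
  partial enumeration for tight-LD blocks) for unphased cohorts.
* **Median-joining haplotype network** (ε-relaxed MSN + median
  vectors), outgroup rooting, and **rho-statistic TMRCA** with a
  divergence-calibrated per-locus mutation rate
  (rate = fixed_differences / (2 × divergence_time)).
* **Synthetic-data generators** for all of the above with known ground
  truth: neutral nulls, n-island and Balding–Nichols structured
  cohorts, a planted two-clade balanced locus, a disease subsample
  with clade enrichment, and a genome-background F_st distribution.

## Worked example

Run the full scan on the built-in synthetic scenario (a three-cluster
reference panel of 492/758/572 chromosomes carrying a 4-kb locus with
two haplotype clades at frequencies 0.21/0.50/0.06, plus an 18-person
disease cohort resampled from the European cluster at clade frequency
0.53):

```python
from balscan.pipeline import run_full_scan

bundle = run_full_scan({"seed": 7, "neutrality": {"reps": 3000},
                        "scenario": {"background": {"n_snps": 8000}}},
                       output_dir="scan_out")
cols = ["group", "N", "S", "pi_per_site", "tajima_d", "p_tajima_d", "significant"]
print(bundle["neutrality_table"][cols])
ft = bundle["fst_table"]
print("diagnostic SNPs flagged EUR-EAS:",
      ft[(ft.pair == "EUR-EAS") & ft.snp.str.startswith("split")].outlier.mean())
print("rho = %.2f  ->  TMRCA = %.2f My"
      % (bundle["tmrca"].rho, bundle["tmrca"].tmrca_years / 1e6))
```

prints (seed 7):

```
  group    N   S  pi_per_site  tajima_d  p_tajima_d  significant
0   AFR  492  42     0.002767  2.140767    0.019993        False
1   EUR  758  44     0.004172  4.612139    0.000333         True
2   EAS  572  41     0.000821 -1.198884    0.087637        False
3  NCWS   36  36     0.003985  2.966554    0.000666         True
diagnostic SNPs flagged EUR-EAS: 1.0
rho = 9.23  ->  TMRCA = 0.92 My
```

Reading it: the European cluster — and the disease cohort drawn from
it — shows the balanced-locus signature (large positive Tajima's *D*,
significant after adaptive-BH correction at α = 0.01), the African and
East-Asian clusters do not; all 30 planted clade-diagnostic SNPs
exceed the 99th percentile of the genome-wide F_st background in the
EUR–EAS comparison; and the rooted median-joining network dates the
mean mutational depth of the sample (rho ≈ 9 mutations at 10⁻⁵ per
locus per year) to ~0.9 My.  Each stage also lands in `scan_out/` as
TSV/GML plus a `manifest.yaml` that makes the run bit-reproducible.

The same stages are available as subcommands of the `balscan` CLI
(`simulate`, `neutrality`, `fst-scan`, `ld-prune`, `ld-set`, `dapc`,
`phase`, `hapfreq`, `network`, `tmrca`, `full-scan`, `validate`) for
file-based use on VCF + panel + BED inputs.

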