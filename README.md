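# imfnet

Integrative miRNA–mRNA co-expression network analysis for two-group
transcriptome studies of intramuscular fat (IMF) in cattle muscle — and, more
generally, for any paired small-RNA/mRNA count dataset split into high/low
phenotype groups.

The package is aimed at quantitative-genetics and systems-biology
practitioners who have feature × sample count tables for both expression
layers, a per-animal phenotype table (IMF %, genomic estimated breeding
values, H/L group, covariates), and optionally 3'UTR sequences and a GO
annotation. It implements the full analysis arc of a muscle miRNA–mRNA
integration study on top of numpy/scipy/pandas/statsmodels:

* **Normalization & differential expression** — median-of-ratios size
  factors; per-feature negative-binomial regression (log link, size-factor
  offset, group + optional covariates), method-of-moments dispersion and a
  Wald test on the group coefficient; Benjamini–Hochberg FDR at 10%.
* **PCIT networks & differential hubbing (DH)** — per-group Pearson
  correlation networks filtered by partial correlation with an
  information-theory tolerance: for every trio (x, y, z),
  ε = ⅓(r_xy·z/r_xy + r_xz·y/r_xz + r_yz·x/r_yz), and the pair (x, y) is
  discarded if some z gives |r_xy| < |ε·r_xz| and |r_xy| < |ε·r_yz|.
  A connection requires retention plus |r| > 0.9; DH is the per-feature
  connection-count difference between the High and Low groups.
* **PIF / RIF regulator ranking** — with per-group mean log2 expression
  μ_H, μ_L, average abundance a and difference d: PIF_j = a_j·d_j;
  RIF1_i = mean_j PIF_j (r_Hij − r_Lij)² (differential wiring to DE
  features); RIF2_i = mean_j [(μ_Hj r_Hij)² − (μ_Lj r_Lij)²].
* **Signed co-expression modules** — signed similarity (1 + r)/2 raised to a
  soft power β (lowest with scale-free fit R² > 0.90, or a fixed override),
  topological overlap, average-linkage clustering with a static cut,
  minimum module sizes 30 (mRNA) / 5 (miRNA), eigengenes as first principal
  components, merging at eigengene dissimilarity 0.25, module membership and
  hub calling.
* **Integration** — miRNA-module × mRNA-module eigengene correlation
  (retained at r ≤ −0.4, p < 0.05), module–trait correlation (p < 0.1), and
  bipartite hub-miRNA ↔ GO-term network assembly.
* **Targets & enrichment** — canonical seed-match site scanning
  (8mer / 7mer-m8 / 7mer-A1) of miRNA seeds against 3'UTR FASTA, and
  upper-tail hypergeometric gene-set enrichment with BH control.
* **Synthetic data with planted truth** — a negative-binomial generator that
  emulates the 15 + 15 animal design: block-correlated modules from latent
  factors, planted DE miRNAs, a differentially wired regulator that is also
  a Low-group network hub, an anti-correlated cross-layer module pair, and a
  trait driven by one module's factor. Every planted element is recorded so
  recovery tests can score the pipeline end to end.

## Worked example

The phenotype records of the 30 Nelore steers (15 high, 15 low IMF GEBV) ship
with the package:

```python
>>> from imfnet import load_study_phenotypes, summarize_phenotypes, compare_groups
>>> pheno = load_study_phenotypes()
>>> summarize_phenotypes(pheno, "imf_percent")[["mean", "sd", "n"]]
           mean        sd   n
group
H      4.306667  0.560761  15
L      1.508000  0.354747  15
>>> compare_groups(pheno, "gebv")
(18.130814344215626, 5.636500599132483e-17)
```

The groups differ in IMF % by ~2.8 percentage points, and the Welch t-test
confirms the breeding-value separation between groups (t ≈ 18.1,
p ≈ 5.6e-17).

A full synthetic end-to-end run from the shell:

```bash
imfnet run --seed 1 --outdir demo_run
imfnet report demo_run
```

This simulates the default dataset (2,000 genes, 150 miRNAs, 15 + 15
samples), runs normalization, DE, PCIT/DH (top 500 features by variance),
PIF/RIF, per-group module detection, cross-layer and trait integration, and
writes one TSV per stage plus `report.md`. On seed 1 the DE stage flags the
ten planted miRNAs (log2 fold changes −1.7…−1.3, all lower in the Low
group) plus one borderline false positive — expected at a 10% FDR; the
planted regulator attains the most negative DH score (−59: ~60 connections
in the Low group, none in the High group) and ranks first among miRNAs by
|RIF1 z-score|. The whole run takes under half a minute.

Key library entry points: `generate_dataset`, `size_factors` / `de_test`,
`correlation_network` / `pcit` / `dh_scores`, `rif_scores`,
`pick_soft_threshold` / `tom` / `detect_modules`,
`module_module_correlation` / `module_trait_correlation`,
`predict_targets` / `enrich`.

## Testing

```bash
python -m pytest tests/
```

The suite contains per-module unit and property tests plus an end-to-end
block (`tests/test_acceptance.py`) that reproduces the published phenotype
summaries, checks the vectorized PCIT filter against its triple-loop
definition on 100 random instances, scores planted-truth recovery over 20
synthetic datasets, and verifies the DE stage's type-I and false-discovery
calibration. The full run takes a few minutes; everything outside
`test_acceptance.py` finishes in seconds.

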