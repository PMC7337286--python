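# protmr — proteome-by-phenome Mendelian randomization

`protmr` implements a three-step screen that asks, for a panel of plasma
proteins, which of them *causally* influence disease risk or quantitative
traits — the evidence pattern used to prioritize drug targets:

1. **pQTL discovery and replication.** Plasma protein abundances measured in
   two genotyped cohorts are rank-inverse-normal transformed, residualized on
   covariates, corrected for relatedness (single-GRM REML / BLUP environmental
   residuals), and scanned SNP-by-SNP. Discovery leads (p < 5×10⁻⁸ after LD
   clumping at ±5 Mb, r² > 0.2) must replicate in the second cohort
   (Bonferroni over the number of discovery leads, consistent effect
   direction). The instrument for each protein is the replicated lead within
   ±150 kb of its encoding gene with the lowest discovery p, subject to
   MAF > 1% and imputation info > 0.95 in both cohorts.
2. **Summary-statistic MR.** For instrument Z, protein X and outcome Y, the
   causal effect is estimated by the delta-method Wald ratio

   β̂_YX = (β̂_YZ / β̂_XZ) · (1 + se²_XZ / β̂²_XZ)
   se_YX = √( se²_YZ / β²_XZ + β²_YZ · se²_XZ / β⁴_XZ )
   p_YX  = 2Φ(−|β̂_YX| / se_YX)

   with exposure estimates taken from the *replication* cohort to avoid
   winner's curse, alleles harmonized between exposure and outcome records,
   and Benjamini–Hochberg FDR (< 0.05) run separately per outcome source.
3. **Heterogeneity and colocalization.** Each significant pair is screened
   with a HEIDI-type test (are the Wald ratios of the lead's LD partners
   consistent with a single shared causal variant?) and with an
   eCAVIAR-style colocalization posterior (CLPP = product of the exposure
   and outcome posterior inclusion probabilities at the instrument, by
   exhaustive enumeration of causal configurations; CLPP > 1% is taken as
   colocalization).

Real cohort data are not required: `protmr.simulate` generates two matched
cohorts with block-LD genotypes (Gaussian-copula haplotypes with calibrated
dosage correlation), proteins driven by local pQTLs plus covariates, a
polygenic/kinship component and noise, and outcome GWAS summary statistics
under protein-causal, linkage (two causal variants in LD) and null
architectures, with a ground-truth table for recovery testing.

## Worked example

The numbered drivers under `analysis/` run the whole design on the default
synthetic world (30 proteins over 630 variants, cohorts of 909 and 998,
10 protein-causal / 10 linkage / 10 null outcome traits of n = 100,000):

```bash
python analysis/01_simulate_world.py --seed 1
python analysis/02_pqtl_scan.py
python analysis/03_select_instruments.py
python analysis/04_mr_screen.py
python analysis/05_heidi_clpp.py
python analysis/06_report.py
```

prints, step by step:

```
discovery: 18900 SNP-protein tests, 511 at p < 5e-8
73 discovery lead SNPs across 30 proteins
73 replicated at p < 0.05/73 with sign consistency
30 proteins with a replicated local (+/-150 kb) instrument; 37 secondary sensitivity instruments
screened 900 protein-trait pairs: 21 significant at FDR < 0.05; 0 exclusions
21 significant pairs tested: 11 survive HEIDI (p > 0.05), 17 have CLPP > 1%
```

and the final report scores the two step-3 filters against the simulator's
ground truth: all 10 protein-causal pairs survive both HEIDI (p > 0.05) and
the CLPP threshold, while all 10 linkage pairs — genuine genetic
associations that are *not* causal for the protein — are rejected by HEIDI
and 60% also fall below the CLPP threshold. The intersection of the two
survivor sets (11 pairs) is the screen's high-confidence causal call set.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete pipeline (simulation → pQTL scan → instruments → MR →
HEIDI/CLPP → report) from scratch at the given seed, prints the screen
summary, and writes its JSON output to `--out`.
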