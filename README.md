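# lipidstrat

A tested, reusable pipeline for comparing genetically-based atherogenic
hyperlipidemias: genotype-derived polygenic risk scores and APOE haplotypes,
rule-based patient classification (familial dysbetalipoproteinemia, familial
hypercholesterolemia, polygenic / severe hypercholesterolemia, control),
lipid harmonization, carotid and femoral atherosclerosis quantification, and
the accompanying nonparametric group-comparison statistics — exercised
end-to-end on a seeded synthetic cohort generator, so no patient data are
required to run or test anything.

## Modules

| Module | What it does |
| --- | --- |
| `lipidstrat.prs` | Weighted polygenic scores, APOE haplotype calling (rs7412/rs429358), percentile stratification (HIGH > 80th, LOW < 50th percentile), rare-variant filter |
| `lipidstrat.classify` | Friedewald LDL-C, statin-equivalence and pretreatment back-correction, statin-use predicate, Lp(a) banding, DLCN score, group-assignment cascade |
| `lipidstrat.ultrasound` | Plaque predicate, area-based ECST stenosis, per-territory aggregates (plaque number, max/total stenosis, max height, plaque score) |
| `lipidstrat.stats` | Exact Mann-Whitney / Fisher (2×2 and r×c) / Kruskal-Wallis, Holm-Bonferroni, covariate-adjusted median-discretized logistic contrasts with fallback, noncentral-t detectable-difference power analysis |
| `lipidstrat.simulate` | Seeded reference populations (Hardy-Weinberg genotypes) and study cohorts calibrated to the published group summaries |
| `lipidstrat.io` | VCF v4.2 + CSV fixture writers/readers (pysam-backed reading) |
| `lipidstrat.cli` | End-to-end orchestration and the `lipidstrat` command line |

The shipped PRS coefficient tables (`src/lipidstrat/data/*.csv`) are
**synthetic placeholders** with plausible frequency/weight ranges — the
original per-variant effect estimates are not public. Replace them with your
own CSVs (`rsid,effect_allele,effect_allele_freq,beta`) for real analyses.
The statin equivalence / LDL-reduction tables and the DLCN criteria table
are editable CSVs in the same directory.

## Command line

```sh
# generate a seeded synthetic fixture set (VCF, phenotype CSV,
# ultrasound CSV, reference scores)
lipidstrat simulate --seed 1 --out fixtures/

# full pipeline: score -> harmonize -> classify -> aggregate -> compare
lipidstrat report \
    --phenotypes fixtures/phenotypes.csv \
    --vcf fixtures/cohort.vcf \
    --ultrasound fixtures/ultrasound.csv \
    --reference-scores fixtures/reference_scores.csv \
    --out out/

# classification only
lipidstrat classify --phenotypes fixtures/phenotypes.csv --out labels.json

# ultrasound aggregation only
lipidstrat ultrasound --ultrasound fixtures/ultrasound.csv --out metrics.csv

# minimal detectable differences (noncentral t, 80% power, two-sided 0.05)
lipidstrat power --n1 29 --n2 41 --sd 15 --name max_stenosis
```

`report` writes `participants.csv` (one row per subject with group label,
harmonized lipids and plaque metrics), `report.json` (group summaries,
comparison battery, provenance) and `comparisons.csv` (one row per contrast
with method tag, raw and Holm-adjusted p).

## Conventions (fixed and documented)

- Percentile of a score in a reference sample: fraction strictly below,
  midpoint at ties; HIGH strictly above the 80th percentile, LOW strictly
  below the 50th.
- Friedewald (mmol/L): LDL-C = TC − HDL-C − TG/2.2, invalid above TG
  4.5 mmol/L.
- Mann-Whitney: exact enumeration for combined n ≤ 20 (midrank ties),
  tie-corrected normal approximation otherwise.
- Fisher two-sided p: point-probability rule; r×c tables enumerate fully up
  to 10⁶ tables, then seeded Monte-Carlo with reported standard error.
- Quantiles: linear interpolation (numpy default / R type 7).
- Only LDL-C is back-corrected for statin use; HDL-C and TG never are.
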