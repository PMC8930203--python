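# sexkaryo

Genetic-sex and sex-chromosome-karyotype inference from massively parallel
sequencing data — targeted gene panels, exomes, and genomes.

Recorded sex is missing or wrong surprisingly often in clinical sequencing
cohorts (sample swaps, data-entry errors), and sex-chromosome aneuploidies
(XYY, XXY/Klinefelter, XXX, X monosomy/Turner) confound any tool that
assumes two clean sexes. `sexkaryo` addresses both as a QC step: it infers
each sample's genetic sex without training data, and screens the cohort
for aneuploid samples. It is aimed at people running cohort QC on BAM +
VCF inputs, including targeted panels whose limited X/Y content defeats
threshold-based checks such as PLINK's F-coefficient.

## Method

Five sex-associated features are extracted per sample:

| feature   | definition |
|-----------|------------|
| `XH`      | X heterozygosity: fraction of non-missing diploid genotype calls on X (outside the pseudoautosomal regions) with two different allele indices |
| `Xmap`    | fraction of high-quality reads (mapq > 30, primary alignments) mapped to X, over all such reads genome-wide |
| `Ymap`    | same fraction for Y |
| `XYratio` | `Xmap / Ymap` |
| `SRY_dep` | mean read depth over the *SRY* locus on Y |

Panels without Y content can select any informative subset (e.g. `XH` +
`Xmap` only). Selected features are z-scored and clustered with a
two-component full-covariance Gaussian mixture fitted by EM (seeded
restarts, ridge-regularised covariances). Clusters are named male/female
from their unscaled feature means (higher `Ymap` → male, falling back to
`SRY_dep`, `XYratio`, `XH`, `Xmap` for Y-free panels). Each sample's
uncertainty is 1 − max posterior; samples above 0.1 are flagged as
outliers. A single sample is classified by appending it to a reference
cohort and refitting.

Karyotypes are then screened with interval gates on raw (`Xmap`, `Ymap`):
per-sex normal bands `mean ± 3·sd` computed from the inferred males and
females, and fold-change thresholds for aneuploidies (e.g. XYY when
`Ymap > 2·mean_ymap_m` with `Xmap` inside the male band). Samples matching
no gate are reported `UNCLASSIFIED` rather than forced into a karyotype.

## Worked example

```sh
python examples/karyotype_screen.py
```

simulates 80 males, 80 females and three XYY samples, infers sex, and
screens the gates. It prints:

```
male stats:   Xmap 0.0177 ± 0.0011, Ymap 6.94e-04 ± 2.20e-04 (n=83)
female stats: Xmap 0.0347 ± 0.0020, Ymap 3.59e-05 ± 2.27e-05 (n=80)
karyotype counts: {'XX': 80, 'XY': 80, 'XYY': 3}
  abnormal: KXYY_0001  XYY  Xmap=0.0168  Ymap=1.65e-03
  abnormal: KXYY_0002  XYY  Xmap=0.0183  Ymap=1.58e-03
  abnormal: KXYY_0003  XYY  Xmap=0.0174  Ymap=1.51e-03
```

All 160 normal samples are called XX/XY, and exactly the three injected
XYY samples — whose Y read fraction is more than double the male cohort
mean — are flagged. The other scripts in `examples/` show feature
extraction from hand-countable BAM/VCF fixtures, plain cohort inference,
and single-sample mode against the packaged synthetic reference.

The same pipeline is available as a CLI for shell use:

```sh
sexkaryo features --bam-list bams.txt --vcf cohort.vcf --out features.tsv
sexkaryo infer --features-table features.tsv --seed 1 --out sex.tsv
sexkaryo karyotype --features-table features.tsv --sex-calls sex.tsv \
    --out-prefix cohort
sexkaryo simulate --n-male 100 --n-female 100 --aneuploidy XYY=3 \
    --seed 1 --out-prefix sim
```

## Layout

- `src/sexkaryo/` — `features` (BAM/VCF extraction), `model` (scaling,
  EM, sex calls), `karyotype` (cohort stats and gates), `simulate`
  (synthetic cohorts and fixtures), `plots`, `cli`.
- `docs/methods.md` — model assumptions, parameter defaults, simulator
  scope, numerical choices, limitations.
- `examples/` — one narrative script per capability.
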