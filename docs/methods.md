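# Methods

## Problem and model

Sequencing cohorts routinely contain samples whose recorded sex is wrong
and, at a rate of roughly 1 in 400–1,000 births, samples with
sex-chromosome aneuploidies. `sexkaryo` treats sex inference as
unsupervised clustering: per-sample features that separate XX from XY
samples are extracted from alignments and genotypes, and a two-component
Gaussian mixture is fitted to the standardized feature matrix. Because the
clustering is refit per cohort, the method adapts to the covariance
structure of each panel design instead of relying on fixed thresholds or a
classifier trained on one assay.

### Features

* **XH** — among diploid genotype calls on X, outside the pseudoautosomal
  regions (PARs), the fraction with two different allele indices. Males
  carry one X, so their called X genotypes are (near-)homozygous; XH ≈ 0
  for males and ≈ 0.2–0.3 for females in typical panels. PAR sites are
  excluded because they are diploid in males and would inflate male XH
  (GRCh37 PAR1 X:60,001–2,699,520 and PAR2 X:154,931,044–155,260,560 by
  default; configurable, including off). A genotype is heterozygous iff
  its two allele indices differ, whatever the alleles; haploid and
  higher-ploidy calls are skipped.
* **Xmap, Ymap** — reads with mapping quality strictly greater than 30
  (primary alignments only; unmapped, secondary and supplementary records
  excluded) mapped to X or Y, divided by all such reads genome-wide.
  Diploid X gives females about twice the male Xmap; Y reads in females
  are residual mismapping, orders of magnitude below male Ymap.
* **XYratio** — Xmap/Ymap. When Ymap is exactly 0 (routine for female
  panel data) the denominator is replaced by the smallest observable
  fraction, one read out of the sample's high-quality total, and the value
  is flagged censored; this keeps the feature finite and order-preserving.
  Both fractions zero is an error.
* **SRY_dep** — mean per-base depth over the *SRY* locus (GRCh37
  Y:2,654,896–2,655,740 by default), same mapping-quality filter. A
  near-binary male indicator when the panel covers *SRY*.

Feature selection is explicit: a feature may be selected for modeling only
when present for every sample, so X-only panels run on `XH` + `Xmap`.

### Variant filtering

X-heterozygosity is meaningful only on reasonably clean genotypes. The
`filter_variants` operation applies standard cohort QC: genotypes with
depth < 5 are set missing first; then sites are dropped when missing in
more than 50% of samples, when the minor allele count (over called
alleles, after the depth mask) is below 3, or when QUAL < 30. Minor allele
count at multi-allelic sites is the number of called alleles not belonging
to the major allele. The operation is idempotent.

### Mixture model

Selected features are z-scored per column (sample sd, ddof = 1; a column
with zero variance is rejected as degenerate). The mixture has two
full-covariance Gaussian components; EM runs with a diagonal ridge
(1e-6) added to every covariance on every M-step. The ridge matters: in
real cohorts most males have XH exactly 0, so the male component's XH
variance collapses and an unregularised fit fails. Initialization places
component means at two random samples with the pooled data covariance; 10
seeded restarts keep the best final log-likelihood. Convergence is a
relative log-likelihood change below 1e-8 (max 500 iterations). A single
top-level seed fans out to restart seeds via `numpy.random.SeedSequence`,
making every fit bit-reproducible.

Clusters are mapped to sexes on their responsibility-weighted **unscaled**
feature means, using the first applicable rule in decreasing biological
decisiveness: higher Ymap → male; else higher SRY_dep → male; else higher
XYratio → female; else lower XH → male; else lower Xmap → male. Any
feature present for all samples participates, selected or not. If no
feature separates the cluster means, labeling fails loudly.

Per sample, uncertainty = 1 − max posterior (∈ [0, 0.5] for two
components); samples with uncertainty strictly above 0.1 are flagged as
outliers. Outliers are excluded from downstream cohort statistics by
default (configurable) so ambiguous samples cannot inflate per-sex
spreads.

Single-sample mode appends the query to a reference feature table sharing
the same selected features, rescales, refits with the same seed, and
returns the query's call — by construction identical to running the cohort
path on reference + query. A 200-sample synthetic reference (seed
20220101, 100 per sex) ships with the package; it is generated by this
package's own simulator and labelled synthetic, suitable for smoke tests
and for cohorts drawn from comparable assays only. For production use,
build a reference from your own assay.

### Karyotype gates

Per-sex Xmap/Ymap are close to Gaussian in large cohorts, so mean ± 3 sd
bands contain ~99.7% of karyotypically normal samples — consistent with
the ~0.02% population rate of sex-chromosome abnormalities. With the
per-sex statistics (suffix m/f) from the inferred sexes, the six gates
are, all inequalities strict, evaluated on raw fractions:

* **XY**: x ∈ mean_xmap_m ± 3 sd_xmap_m and y ∈ mean_ymap_m ± 3 sd_ymap_m
* **XYY**: x ∈ male X band and y > 2·mean_ymap_m
* **XX**: x ∈ mean_xmap_f ± 3 sd_xmap_f and y ∈ mean_ymap_f ± 3 sd_ymap_f
* **XXY**: x > 2·mean_xmap_f and y ∈ male Y band
* **XXX**: x > 3·mean_xmap_f and y ∈ female Y band
* **X**: x < 0.5·mean_xmap_f and y ∈ female Y band

The reported karyotype is the first matching gate in the fixed precedence
XX, XY, XYY, XXY, XXX, X (normal calls first, then the aneuploidies in
listing order); all matches are recorded. A sample matching no gate is
`UNCLASSIFIED` — laboratory karyotyping is the appropriate follow-up, and
forcing a call would hide exactly the samples the screen exists to
surface.

Note a deliberate fidelity choice: the XXY and XXX thresholds are
multiples of the **female** Xmap mean, as published, although copy-number
arithmetic says an XXY sample has female-like X coverage (≈ 1·mean_xmap_f,
not > 2·mean_xmap_f). These thresholds are kept exactly as published and
exposed in `GateConfig` for users who prefer copy-number-consistent
values; the implementation does not silently "fix" them.

## Synthetic data

The simulator draws per-sex features from truncated Gaussians
(fractions clipped to [0, 1], depths to [0, ∞)). Xmap/Ymap defaults
reproduce the per-sex statistics of a real ~1,000-sample targeted-panel
cohort: male 0.018 ± 0.0011 / 0.00067 ± 0.00014, female 0.035 ± 0.0020 /
1.61e-05 ± 3.36e-05. XH and SRY_dep magnitudes are plumbing choices that
preserve the qualitative contrast (male XH half-normal around 0, sd 0.002;
female XH 0.25 ± 0.05; male SRY_dep 30 ± 5; female half-normal sd 0.1);
they are configurable and only their separation matters to the tests.
XYratio is derived from the drawn fractions. A configuration whose
truncation would discard more than half the probability mass is rejected.

Two caveats on the female Ymap distribution: its published sd exceeds its
mean, which no nonnegative (zero-truncated) Gaussian can realise, so the
realised simulated mean (~3.3e-05) sits above the 1.61e-05 location
parameter. The cohort statistics the pipeline *measures* on simulated data
reflect the truncated distributions, not the raw parameters; tests compare
against analytic truncated-normal moments.

Aneuploid samples are injected two ways:

* **copy-number placement** (default): Xmap/Ymap means scaled by
  chromosome dose — XYY (1×, 2×) and XXY (2×, 1×) of the male means, XXX
  (1.5×) and X monosomy (0.5×) of the female means. XH and SRY_dep follow
  the biologically matching sex profile (e.g. XXY: female-like XH,
  male-like SRY).
* **gate-aligned placement** (`match_gate_thresholds`): draws constrained
  (by truncation bounds) to satisfy the published gate inequalities, e.g.
  XYY Ymap centered at 2.5× the male mean with a 2.25× floor and Xmap held
  inside the male band. This exists because a copy-number XYY sits with
  its Ymap mean *exactly on* the XYY gate threshold (y > 2·mean_ymap_m),
  making strict-inequality recovery of such samples a coin flip per draw
  — the observed Ymap of real detected XYY samples runs 2.2–2.7× the male
  mean. End-to-end recovery tests use gate-aligned placement; the gates
  themselves are additionally tested against fixed reference statistics
  with both placements' geometry.

The simulator also writes miniature sorted/indexed BAMs and multi-sample
VCFs from explicit read-block and genotype specs, so feature extraction is
tested as exact integer-ratio round-trips. What the simulator does **not**
emulate: read-level sequence content, mapping error structure,
batch/coverage heterogeneity, mosaicism, and panel-specific target maps.
Passing tests therefore demonstrate correctness of the statistical
machinery on well-specified inputs, not robustness to every real-data
pathology.

## Numerical and interface choices

* Mapping-quality cutoff is strict (> 30); the mapq = 30 boundary is
  excluded and covered by tests.
* Chromosome naming dialects ("X" vs "chrX") are resolved against each
  file's header in both directions.
* Config intervals are 1-based closed, converted internally to 0-based
  half-open. An SRY window extending past a (test-sized) contig is clamped
  for the query while the mean keeps the configured window length.
* Feature tables are TSVs with full floating precision (`repr`
  round-trip); missing values are `NA`.
* Extraction parallelises per sample across processes; results are
  re-ordered to input order, so worker count never changes output bytes.
* Cohorts below 10 samples refuse unsupervised mode and require a
  reference table; two well-separated blobs need a handful of points per
  component before the mixture is meaningful.
* Acceptance-scale problem sizes: twenty seeds of 200–2,000-sample
  cohorts for recovery; a 2,000-sample cohort for measured per-sex
  statistics; a 50-sample cohort for single-sample consistency. These
  sizes give sampling error well inside the margins the checks assert.

## Known limitations

* The gates assume the per-sex cohorts are large enough that a few
  aneuploid samples barely perturb the male/female statistics; in small
  cohorts an included XYY inflates the male Ymap sd and can hide itself.
* Mosaic and chimeric samples produce intermediate feature values that may
  land between gates (`UNCLASSIFIED`) or inside a normal band.
* No CRAM input; no model selection over covariance structure or number
  of components; no semi-supervised mode.
* Uncertainty calibration is the mixture's own posterior; it is not a
  frequentist error rate.
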