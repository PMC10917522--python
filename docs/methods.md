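# Methods

This note records the models, parameter choices and numerical conventions
behind `brewtrack`, and what the synthetic-data validation does and does not
demonstrate about real data.

## Quantification

**Digestion.** Trypsin cleaves C-terminal to K or R unless the next residue
is P. Peptides with up to `missed_cleavages` internal sites are enumerated
and filtered to `min_len`–`max_len` residues (defaults 7–40, the usual
detectable window for Orbitrap shotgun data). The *theoretical* peptide set
used for quantification always uses 0 missed cleavages so that it
partitions the sequence — otherwise overlapping peptides would be counted
twice in the correction factor — while observed evidence peptides may carry
up to 2 missed cleavages, matching common search-engine settings.
Isoleucine and leucine are distinct residues and peptide identity is exact
string match; no mass-based ambiguity is modelled.

**ppm from PSM counts.** Per protein and sample,
`signal = Σ_peptides (PSM × peptide length) × CF`, with
`CF = 1 / Σ(lengths of the protein's in-range theoretical peptides)`;
`ppm = signal × 10⁶ / Σ_proteins signal`. The operator order (lengths
weighted before the correction factor) makes the signal a length-normalized
fraction of the protein's detectable sequence; a different association of
the same factors changes every protein by a constant and cancels in the
ppm normalization only partially, so the chosen reading is documented here
rather than asserted as canonical. Proteins with no in-range theoretical
peptide cannot be normalized and are excluded with a warning. ppm columns
sum to 10⁶ by construction; this is asserted, not assumed, in the tests.

**iBAQ** divides the summed peptide intensity by the in-range theoretical
peptide count. The same 7–40 residue window is used as for ppm (one
digestion parameterization across metrics); the window is configurable for
users who prefer the classic 6–30.

**Between-sample normalization** is a median-ratio scaling against a
geometric-mean pseudo-reference built from proteins detected in every
sample, with factors rescaled so the median factor is 1 (a typical sample
is left untouched; a sample with doubled loading gets factor ≈ 0.5). It is
a deliberately simple, transparent stand-in for delayed-normalization LFQ
schemes and is labelled as such; it corrects global loading differences
only, not peptide-level run effects.

**Replicate merging** sums intensities across replicates (maximizing
detections) and separately records a detection flag per time point:
`strict=True` (the default used before differential testing) requires
presence in *all* replicates of the time point. Missing values are stored
as absent (`NaN`), never zero, until after the log transform.

## Differential expression

Intensities are log₂ transformed (they are log-normal to good
approximation) and median-centred per sample to equalize variances. Each
pair of time points is tested per protein with a two-sample t-test; Welch's
unequal-variance form is the default because with 2–4 replicates per group
a pooled-variance assumption buys little and can mislead (the pooled test
is available via `equal_var=True`). p-values are BH-adjusted *within each
contrast* over the proteins actually tested in it — matching per-comparison
reporting — and a call requires both adjusted p < 0.05 and |log₂FC| ≥ 1,
applied symmetrically. With only two replicates per group p-values are
unstable; the package warns, and the simulation-based validation uses four
replicates per group. Proteins with zero variance in both groups and zero
difference receive p = 1 (identical data are no evidence of change).

## Clustering and enrichment

Profiles are row-mean-centred on the log₂ scale and rows whose maximal
deviation from their mean is below log₂(2) = 1 are removed. Distance is
1 − Pearson correlation across time points (shape, not amplitude, drives
cluster identity; Euclidean is available); linkage is average. Rows with
residual missing cells are imputed with the row mean (counted and
reported); constant rows have undefined correlation and receive distance 1
to everything, with a warning.

Clusters are extracted by **node depth**: the root is depth 0 and the cut
at depth *d* collects the leaf sets of all nodes exactly *d* merges below
the root (leaves reached earlier become singletons), so at most 2^d
clusters result. Clusters exceeding 500 proteins are re-cut at depth 5
within their own subtree. Depth counting from the root reproduces the
familiar "8 clusters at depth 3" arithmetic of dendrogram viewers.

Enrichment is the one-sided hypergeometric upper tail per term over a
universe of *detected* proteins (detection-biased omics should not be
tested against the whole proteome; the universe is a parameter), BH-adjusted
across terms with non-zero overlap, significance at adjusted p < 0.05.

## Systems correlation

Correlations are computed on replicate-summed log₂ abundances. Protein
eligibility requires detection in ≥ 2 time points; pair summaries
additionally require ≥ 3 shared time points because a two-point correlation
is ±1 by construction (such pairs are flagged, not summarized). Complex
variants from the same curation are treated as discrete groups, and
multi-localized proteins are duplicated into each compartment so no
information is lost. The interacting vs non-interacting comparison uses a
one-sided Mann–Whitney U test and reports the difference of medians as the
location shift; no parametric claim is made about either distribution.

## Pathway perturbation

DRPS of a reaction = max over its enzymes of (max − min across samples) of
row-mean-normalized log₂ abundance; enzymes without data are skipped, and a
reaction with no measured enzyme scores 0 but is flagged. DPPS =
`sqrt(Σ DRPS² / n_reactions)` where the divisor is the pathway's *total*
reaction count by default (a literal reading of "total number of
reactions"; `measured_only=True` divides by reactions with data instead).
Multi-enzyme reactions take the max over isozymes. DPPS is therefore
monotone in any enzyme's range, scale-equivariant, and strictly decreased
by appending a zero-score reaction.

## Genome profiles

Windows are non-overlapping 1,000-bp tiles (a step parameter allows true
sliding). Copy = `ploidy × depth / baseline`, with the baseline taken as
the **median of per-chromosome median depths**: a whole-chromosome gain can
occupy a quarter of all windows and would bias a plain genome-wide median,
dragging every euploid window's estimate low. Integer copy calls round a
per-chromosome rolling-median (window 5) smoothed estimate — Poisson
counting noise at ~30× misrounds isolated windows near half-copy
boundaries, and a short median filter removes those flips while leaving
block edges in place. Deletions are called on the *unsmoothed* estimate
(zero depth is unambiguous evidence on its own) as runs of ≥ 3 copy-0
windows, which keeps two deletions separated by a single normal window
distinct.

Variant tracks apply minimum coverage 10, minimum alternate count 2 and
minimum frequency 0, exclude the mitochondrial contig, and place variants
on a concatenated coordinate from the supplied chromosome order. Windows
are 0-based half-open; variant positions 1-based (VCF convention). LOH
candidates are runs of ≥ 10 consecutive variants with allele frequency
outside the heterozygous band [0.1, 0.9]; up to one in-band variant is
tolerated inside a run (at 30× coverage a fixed site occasionally
mis-estimates onto the band edge), but runs must start and end on
out-of-band variants so the tolerance never extends a segment's
boundaries. This run-length formalization is a conservative surrogate for
model-based callers and is intended for tetraploid-style data where
heterozygous sites sit near 0.25/0.5/0.75.

## Synthetic-data generator

The generator's defaults describe the study design being emulated: 2
batches × 7 time points (0–120 h, including a post-crash-like final point)
× 2 independent replicates; 600 proteins of 100–1,000 residues drawn
uniformly over the 20 standard residues (K+R ≈ 10% combined, so tryptic
digestion is productive); natural-log abundance mean 13, sd 2 (≈ 4 decades
of dynamic range); six planted trajectory archetypes over a 25% flat
background; twenty 5-member complexes with target within-complex
correlation 0.7.

* **Trajectories.** The six default archetypes are built from orthonormal
  polynomial contrasts arranged as three correlated pairs — two pairs share
  orthogonal family signals, the third opposes both — so that profile
  correlation separates families before it separates archetypes within a
  family, and a depth-3 cut recovers the planted labels. Peak log₂
  amplitude is 1.5 (≈ 8-fold swing), typical of strongly responding
  fermentation proteins. Four archetypes receive 2.5× the membership of the
  other two; real cluster size spectra are far from uniform.
* **Noise.** Biological (between-time-point) noise and technical
  (replicate) noise are separate log-normal components (`temporal_cv`,
  default 0.10; `replicate_cv`, default 0.20) because the two variance
  components are not identifiable from the emulated design and should stay
  free parameters. Complex members mix a shared latent temporal signal with
  weight √ρ so the expected within-complex log-abundance correlation equals
  the target ρ.
* **Detection.** Missingness is logistic in log abundance, centred at
  `detection_limit` (default 6 × 10⁴, ≈ 1 sd below the median abundance)
  with scale 0.5 — low-abundance proteins drop out first, as observed for
  proteins below ~1,000 copies per cell in real shotgun data. PSM counts
  are Poisson with mean `psm_rate × ln(peptide intensity / psm_floor)`,
  clamped to ≥ 1; the log link keeps counts in the realistic single-digit
  range across 4 decades of intensity. Consequence: ppm (a spectral-count
  metric) tracks true abundance with high but not perfect rank fidelity,
  while the intensity route is rank-exact under zero noise — mirroring why
  intensity-based LFQ is preferred in practice. In the exact zero-noise
  limit (`replicate_cv = 0`) all per-replicate draws are shared so
  replicates are byte-identical.
* **Genome.** Four chromosomes × 500 windows × 1 kb at ploidy 4 and 30×
  coverage (read length 150 → ~200 reads per window). Planted events: one
  whole-chromosome gain (copy 5), one 40-window loss (copy 3), one 8-window
  deletion, one 150-window LOH block near allele frequency 1 and one near
  0. Window read counts are Poisson in `copy/ploidy`; heterozygous variants
  draw from the tetraploid fractions {0.25, 0.5, 0.75}; "fixed" LOH sites
  use a 0.5% error floor, so near-0 LOH variants are mostly removed by the
  minimum-alternate-count filter — exactly as reference-homozygous
  positions vanish from real variant calls.

**What the synthetic validation shows — and does not.** Passing tests
demonstrate that each stage recovers structure it was designed to detect
under the stated noise model: correct arithmetic (exact oracles for
digestion, BH, the hypergeometric tail, DPPS closed forms), FDR control and
power at the simulated effect sizes, ARI ≥ 0.9 archetype recovery, a
detectable complex co-regulation shift, and window-exact CNV/LOH recovery
at 30×. The generator does not model peptide-level run effects, shared
peptides between proteins, post-translational modification, batch effects
beyond the trajectory design, read mappability or GC bias; conclusions
about real data therefore require the usual caution, and the simple
median-ratio normalization in particular does not substitute for
peptide-level LFQ on real runs.

## Problem sizes

The bundled validation uses desk-scale sizes chosen to exercise every code
path with comfortable statistical margins: 20 seeds × 3-time-point studies
for ppm conservation; 1,000 random sequences / p-vectors for the digestion
and BH oracles; 50 Monte-Carlo replicates of 1,000 proteins × 4 replicates
for null FDR and planted-change power; 600 proteins × 14 time points for
cluster recovery; 20 replicate studies of 500 proteins for the
co-regulation shift; the full 2,000-window genome for CNV/LOH recovery; and
the exhaustive ~41,000 hypergeometric instances with population ≤ 30.
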