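# Methods

## Inference model

A bulk female tissue sample is treated as a mosaic of cells in which a
fraction *p* keep haplotype A active and 1 − *p* keep haplotype B
active.  A gene with Xi/Xa escape ratio *e* ∈ [0, 1) contributes one
unit of expression from the active haplotype and *e* from the inactive
one in every cell, so the haplotype expression masses are
m_A = p + (1 − p)e and m_B = (1 − p) + pe, and the noise-free allelic
fold change is min(m_A, m_B)/max(m_A, m_B).  Two limiting cases define
the method's operating regime: at p = 0.5 the aFC is 1 for every gene
(random XCI hides escape entirely), and at p = 1 the aFC equals *e*
(a completely skewed sample reads the escape ratio off directly).
XIST is expressed from the inactive X only, so its expected
haplotype-A fraction is 1 − p; the degree of skewing DS = |0.5 −
XIST_ASE| estimates |p − 0.5| without needing phasing of the rest of
the chromosome to be consistent with XIST's phase, because only the
magnitude is used.

Because real samples are only partially skewed, aFC retains a
systematic dependence on DS — a fully silenced gene still shows
aFC ≈ (1 − p)/p.  The package removes this by a single pooled OLS
regression of aFC on DS over every retained observation of every
skewed sample (all tissues, whole blood included: the fit only needs
the aFC–DS relationship, and more DS span stabilises it).  Residuals
are min-max rescaled over the fitting set to give EscScore′ ∈ [0, 1].
Residual orthogonality makes EscScore′ exactly uncorrelated with DS on
the fitting set; a positive affine rescale preserves this, and the
test suite asserts it to 1e-10.

Assumptions worth stating explicitly: escape is additive across cells
(bulk aFC averages over the mosaic); the lower-count haplotype is the
inactive one (valid only in skewed samples, which is why random-XCI
samples are excluded); one global aFC–DS line is adequate for all
genes and tissues (the line models the skew artefact, not gene
biology; per-tissue fitting is available behind `per_tissue_fit` for
sensitivity analysis).

## Quality control

Observations need total allelic depth ≥ 8 reads (`depth_threshold`)
and evidence that both haplotypes are expressed at least once — a
heterozygosity guard.  The both-haplotypes rule is applied per gene
per *individual*, pooling all of that individual's samples: a
monoallelic observation in one sample is a genuine full-silencing
signal (EscScore ≈ 0) and must not be discarded when another sample of
the same individual shows the second allele.  A strict per-sample mode
(`both_haps_scope = sample`) is provided; it is more conservative and
biases scores upward by censoring exact zeros.  Zero-depth records are
dropped with a logged count rather than raising.  Attrition is logged
at every filter so record counts always reconcile.

## Thresholds (all configuration keys)

| key | default | meaning |
|---|---|---|
| `depth_threshold` | 8 reads | minimum allelic depth per observation |
| `skew_threshold` | 0.3 | DS at or above which a sample is skewed (= XIST_ASE ≤ 0.2 or ≥ 0.8) |
| `escape_cutoff` | 0.36 | median EscScore′ at or above which a gene-tissue is an escapee |
| `min_samples_per_call` | 3 | skewed samples behind a gene-tissue call |
| `min_individuals_consistency` | 10 | individuals needed for a consistency label |
| `consistency_band_fraction` | 0.8 | fraction of individuals within ±1 SD for "consistent" |
| `min_shared_genes_twins` | 5 | shared genes for a valid pair correlation |
| `min_skewed_samples` | 10 | skewed samples below which the model fit aborts |

All boundaries are inclusive (DS = 0.3 is skewed, median = 0.36 is an
escapee, depth = 8 passes).  The escape cutoff can be re-derived for
any dataset with `benchmark_thresholds`, which sweeps cutoffs and
tabulates concordance against a reference annotation, excluding genes
whose prior status ("variable", "discordant_unknown") has no binary
expectation.

## Downstream statistics

*Gene-tissue calls* use the median across skewed samples; multiple
samples of one individual and both co-twins all count, matching the
sample-level unit of the calling rule.  *Intra-donor profiles* are
restricted to donors with a scored skewed sample in every analysed
tissue and to genes scored in all of them, binning genes by the number
of tissues in which they reach the cutoff (a 0 bin is reported so the
bins partition the gene set).  *Consistency* uses one score per
individual (median over their samples), the population SD by default
(`sample_sd_consistency` switches to n−1), and the 80% band; SD = 0
puts every individual in the band.  *Between-group comparisons* use
Kruskal-Wallis with mid-ranks and the standard tie correction.
*Overlap* with a reference escapee list uses the upper-tail
hypergeometric probability within the universe of genes called in the
dataset and present in the annotation.  *Twin statistics* use Spearman
correlation by default — the analysis is rank-based throughout and
robust to the min-max scale — with Pearson behind a flag, and compare
zygosity groups with Welch's t-test on per-pair coefficients (a
Fisher-z option exists; with ρ mostly in [0.3, 0.8] the transform
changes little).

## The synthetic cohort

The generator inverts the inference model.  Defaults (one choice,
fixed): 200 genes plus XIST; 60% silenced (baseline *e* ~ Beta(1, 19),
mean 0.05), 25% constitutive escapees (*e* ~ 0.3 + 0.5·Beta(2, 2) —
escape ratios observed in tissues stay below ~0.8), 15% variable
(broad mid-range).  74 individuals (17 MZ pairs, 10 DZ pairs, 20
singletons) across LCL, adipose, skin and whole blood with
availabilities 1.0/0.85/0.85/0.35, giving ≈ 214 samples.  The
active-A fraction *p* ~ Beta(1.5, 1.5) per sample makes ≈ 28% of
samples skewed, inside the 14–32% per-tissue range typical of adult
cohorts; `skew_distribution = "skewed_cohort"` instead draws
|p − 0.5| ~ U(0.32, 0.45) to emulate a cohort pre-selected for skew,
which is what twin-concordance analyses condition on.  Depth is
negative-binomial (mean 50, dispersion 5) per gene-sample — no public
empirical distribution of gene-level allelic depth exists, so this is
the package's own choice, config-exposed.  Haplotype-A counts are
binomial (beta-binomial when `allelic_overdispersion` > 0).

Escape propensity varies on the logit scale, which keeps *e* in (0, 1)
without truncation artefacts: logit e(g, t, i) = logit e_g + tissue
effect (SD 0.5, shared across individuals) + individual effect.  The
individual effect is `environment_sd` · (√w·G + √(1−w)·E) with w =
`heritability_weight` (default 0.6); G is shared exactly by MZ
co-twins and correlated 0.5 between DZ co-twins (√½·shared + √½·own),
E is independent.  Thus w = 1 with `environment_sd` > 0 makes MZ
co-twin escape vectors identical while DZ vectors differ, and w = 0
removes any co-twin sharing.  `environment_sd` defaults to 1.5,
calibrated by pilot runs against the generator's own ground truth so
that the simulated cohort reproduces realistic twin concordance
(mean per-pair Spearman ≈ 0.63 for MZ and ≈ 0.55 for DZ at w = 0.6,
near reported values of 0.6/0.46) and substantial inter-individual
variability, consistent with observations that roughly half of
escaping genes vary across females.  Skew is drawn per sample by
default (`correlate_skew_within_individual` shares one *p* across an
individual's tissues); XIST depth follows the same depth model as
other genes, since no association between skew and XIST expression
level is modelled.

What the generator does *not* emulate: mapping bias and phasing switch
errors (upstream concerns), genotype missingness (every gene is
heterozygous in every individual, so real data are sparser),
positional structure along the chromosome (the PAR flag in the
emitted annotation is always False), cell-type composition differences
between tissues, and any coupling between expression level and escape.
Passing recovery tests therefore demonstrates that the estimator
inverts its own generative assumptions at realistic depth, skew and
sample sizes — not that those assumptions hold in any particular real
dataset.

## Numerical and degenerate-case choices

Min-max rescaling is exactly the affine map of the fitting set's
residual extremes — sensitive to outliers by design fidelity; a
0.5%/99.5% quantile variant sits behind `quantile_rescale`.  Samples
scored against a persisted model (e.g. purified immune cells scored
with the cohort-fitted model, the default for out-of-cohort data) clip
to [0, 1] with a `clamped` flag.  A fitting set with a single DS value
raises a degenerate-design error; residual spread below 1e-10
(relative) raises a degenerate-rescale error — the tolerance absorbs
floating-point rounding when the fitting set is exactly linear.  Ties
in aFC need no tie-break (min/max handles ac = bc); tied ranks are
mid-ranked.  aFC = 1 exactly when counts are equal, 0 exactly when one
count is 0.

## Problem sizes

The default simulated cohort (200 genes, ≈ 214 samples, ≈ 69 skewed)
runs the full pipeline in a few seconds; the twin-replicate analyses
use 100 cohorts of 27 pairs × 120 genes per heritability setting,
about 15 s per batch.  These sizes give Monte-Carlo error comfortably
below the margins asserted in the test suite while keeping the whole
suite under a minute of CPU.

## Known limitations

EscScore′ is a *relative* score: its scale is set by the fitting set's
residual extremes, so scores are comparable within one fitted cohort
but not directly across independently fitted cohorts (persist the
model and use `score_new_samples` to stay on one scale).  The linear
aFC–DS adjustment is a first-order correction; the true relationship
is mildly nonlinear in p, which the residual ranking tolerates but a
mechanistic estimate of *e* would not.  Twin analyses report
correlation contrasts only — no variance-component (ACE) heritability
model is fitted.  The inter-individual "variable vs consistent" split
depends on the ±1 SD band and is reported per tissue; aggregate ratios
across tissues are left to the user, as the denominator is
analysis-specific.
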