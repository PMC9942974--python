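# xciescape

Quantify escape from X-chromosome inactivation (XCI) in bulk RNA-seq
cohorts, starting from gene-level haplotype expression counts.

## The problem

XCI silences one X chromosome in each female somatic cell, but a subset
of X-linked genes *escape* silencing and are expressed from both
parental alleles. In a bulk tissue sample with random XCI — a 50:50
mosaic of cells with either parental X active — both alleles of every
gene are expressed at the tissue level, so escape is invisible.  In a
*skewed* sample, where most cells inactivated the same X, a silenced
gene looks monoallelic and an escaping gene biallelic, so the allelic
ratio of each gene becomes a direct readout of escape.  This package
implements that strategy: it identifies skewed samples from the XIST
allelic ratio, adjusts each gene's allelic imbalance for the residual
skew, and turns the result into a comparable escape score across
genes, tissues, individuals and twin pairs.

It is intended for analysts working with phased bulk (or purified cell
type) RNA-seq from female cohorts, downstream of read-backed phasing
tools that emit per-gene haplotype counts (e.g. phASER's gene-level
haplotypic expression table).

## The model

For gene *g* in sample *s* with haplotype read counts AC, BC
(TC = AC + BC):

```
ASE_gs = AC_gs / TC_gs
aFC_gs = min(AC_gs, BC_gs) / max(AC_gs, BC_gs)
```

aFC ∈ [0, 1] is the allelic fold change: 0 = monoallelic (fully
silenced), 1 = balanced biallelic expression.  In a skewed sample it is
read as the Xi/Xa expression ratio (the inactive X carries the
lower-count haplotype).  Per sample, XIST — expressed exclusively from
the inactive X — gives the degree of skewing

```
DS_s = |0.5 − XIST_ASE_s|          (skewed iff DS ≥ 0.3)
```

aFC still depends on DS (at partial skew even a silenced gene shows
residual minor-haplotype signal), so a single OLS regression of aFC on
DS is fitted across all retained observations of all skewed samples,
and the residuals are min-max rescaled to [0, 1]:

```
EscScore′ = (EscScore − min EscScore) / (max EscScore − min EscScore)
```

EscScore′ is uncorrelated with DS by construction.  A gene is called
an **escapee** in a tissue when its median EscScore′ across ≥ 3 skewed
samples is ≥ 0.36 (a cutoff benchmarked against reference XCI-status
annotation; a sweep utility is included).  On top of the calls the
package quantifies intra-donor tissue sharing, inter-individual
consistency (80% of individuals within ±1 SD, ≥ 10 individuals),
immune-cell-type summaries, and twin concordance (per-pair Spearman
correlation over ≥ 5 shared genes, MZ vs DZ Welch t-test, discordance
rates).

A fully tested synthetic-data generator produces allelic counts with
the generative structure the method assumes — mosaic samples with
active-haplotype fraction *p*, per-gene Xi/Xa escape ratio *e* (so the
expected haplotype-A read fraction is `(p + (1−p)e) / (1+e)`), XIST
counts drawn from `1 − p`, negative-binomial depth, and a twin-shared
genetic component of escape — plus the ground truth for recovery
testing.

## Worked example

```python
from scipy import stats
from xciescape import (simulate_dataset, apply_qc, call_sample_skew,
                       fit_escape_model, call_gene_tissue)

counts, sheet, truth, annotation = simulate_dataset(seed=1)
obs = apply_qc(counts, sheet)                    # ASE/aFC + QC filters
skew = call_sample_skew(obs, sheet)              # XIST-based DS per sample
model, scores = fit_escape_model(obs, skew)      # pooled aFC ~ DS + rescale
calls = call_gene_tissue(scores, sheet)          # per gene x tissue status
```

On the default cohort (200 X-linked genes + XIST, 74 individuals
including 17 MZ and 10 DZ twin pairs, four tissues, seed 1) this
prints:

```
>>> len(sheet), int(obs.retained.sum())
(214, 42877)
>>> skew.status.value_counts().to_dict()
{'random': 144, 'skewed': 69, 'unavailable': 1}
>>> round(model.slope, 3), round(model.intercept, 3), model.n_obs
(-1.183, 0.845, 13829)
>>> round(stats.pearsonr(scores.escscore, scores.ds).statistic, 12)
0.0
```

69 of 214 samples are skewed (DS ≥ 0.3) and enter the model; the
fitted slope is negative — raw aFC falls as skew rises, which is
exactly the bias the residual construction removes, leaving EscScore
uncorrelated with DS (Pearson r ≈ 2e-16).  Escape incidence among
called genes is 39.8% in LCL, 41.8% in adipose and 37.8% in skin,
reflecting the simulated 40% of genes with escaping or variable
escape ratios.

The same stages are available as a CLI:

```
xciescape --outdir sim simulate --seed 1
xciescape --outdir res run --counts sim/counts.tsv \
    --sheet sim/sample_sheet.tsv --annotation sim/annotation.tsv
```

which writes every result table (observations, skew calls, escape
scores, gene-tissue calls, threshold benchmark, donor profiles,
consistency calls, twin-pair statistics) as TSV.

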