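# Methods

This note documents the statistical model behind each stage, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions a maintainer
should know before changing anything.

## Preprocessing

**Site collapse.** DIA search engines report several precursors per
phosphosite (charge states, missed cleavages, co-fragmenting forms).
Records are collapsed to one per (sample, site) taking the maximum
intensity and the maximum localization probability over contributing
precursors. Max-intensity collapse is the common convention; it is
order-independent and idempotent, which matters for byte-identical
reruns.

**Class I filter.** Only sites with localization probability *strictly*
greater than 0.75 are retained. The boundary is deliberately strict —
many tools use ≥, so the convention is stated here once and fixed
repo-wide. Site keys are `PROTEIN_<residue><1-based position>`
(e.g. `STAT1_Y701`) everywhere.

**Replicate-presence filter.** A feature is kept iff at least one
condition (genotype × treatment × dose × timepoint × cell type) has ≥ k
observed replicates; the rule is an integer pair (k, n), a bare k, or a
fraction. Default (3, 4); (2, 3) fits triplicate designs. Filtering is
idempotent and only ever removes rows.

**Normalization.** log2 transform, then per-sample median centering over
observed values. Centering on log2 input skips the transform, making
`normalize` idempotent. All-missing columns pass through with a warning
rather than failing a whole run.

**QC.** Enrichment purity is precursor-count-based (phospho precursors /
all precursors), matching an identification-count reading of enrichment
performance; an intensity-weighted variant would track ion current
instead and is deliberately not the default. CVs are computed on
linear-scale values (CV of log values is not scale-free); replicate
correlations on log2 values over mutually observed features; input
linearity as per-feature Pearson r of linear intensity against cell
input, requiring ≥ 3 input levels.

## Missingness model and imputation

Gaps are classified by the partially-observed vs missing-entire-condition
convention: a gap in a condition block with ≥ 1 observed replicate is
MAR; a block entirely missing (feature quantified elsewhere) is MNAR.
The dichotomy is standard in proteomics imputation practice and — by
construction — exactly recoverable on the generator's output, which
makes the classifier testable.

- **kNN (global, MAR).** Neighbours are the k = 10 features nearest by
  nan-Euclidean distance (squared differences over mutually observed
  samples, rescaled by `n_samples / n_shared`), requiring ≥ 3 shared
  samples; the imputed value is the mean of the neighbours' observed
  values in the gap's sample. Fewer than k candidates → use all, warn;
  none → leave missing, warn.
- **SLSA (phospho, MAR).** Imputed value = mean of the feature's
  observed replicates in the gap's condition + a sample offset, where
  the offset is the median over fully observed features of (value in
  the gap's sample − mean of that feature's other replicates). This is
  a deterministic least-squares-flavoured reconstruction of a replicate
  structure plus sample effect; the published method name covers several
  variants and this definition is the package's fixed, documented
  interpretation.
- **Downshift (MNAR).** Per sample column with observed mean μ and sd
  σ, MNAR gaps are drawn from N(μ − 1.8σ, (0.3σ)²). Shift 1.8 and width
  0.3 are the widely used defaults for values below the detection
  limit. Per-sample (not global) moments are used so columns with
  different dynamic ranges stay comparable; columns with < 2 observed
  values fall back to global moments with a warning.

Observed entries are never altered by any imputer — tests assert
bit-identity. Known limitation: downshift imputes at a fixed depth below
the column centre, so features whose true abundance lies far below the
detection limit get compressed fold changes; this is inherent to the
method, visible in the generator as reduced recall for the
lowest-baseline induced features, and is one reason the signature
recovery is characterized on complete data (see below).

## Differential statistics

Donor centering subtracts each donor's per-feature mean, removing
additive donor offsets exactly while preserving every within-donor
treated-minus-control contrast (asserted to machine precision). Fold
changes are computed against the time-matched vehicle in the same
genotype: log2FC = mean(log2 treated) − mean(log2 vehicle).

Two engines:

- **Student:** two-sided pooled-variance t with n_T + n_C − 2 df.
  Pooled (not Welch) is the stated convention. Zero pooled variance with
  equal means → (t = 0, p = 1); with unequal means → signed infinite t,
  p = 0, flagged in the log.
- **Moderated:** the hierarchical model s²_g | σ²_g ~ σ²_g χ²_d/d with a
  scaled inverse-chi-square prior on σ²_g. The prior (d₀, s₀²) is fitted
  by method of moments on log s²_g using the exact digamma/trigamma
  moment identities, with the trigamma inverse solved by Newton
  iteration. When the spread of log variances does not exceed its
  sampling expectation, d₀ = ∞ and every feature uses s₀² (the
  documented degenerate branch). d₀ = 0 reproduces Student's t exactly.
  The fit and the resulting t and p values match limma's `eBayes` to
  ~1e-8 relative on a shared fixture (tested via Rscript).

BH adjustment is applied per comparison (per volcano), not pooled across
comparisons, and p-values outside (0, 1] are rejected as input errors.
Per-timepoint contrasts are fitted independently; a single joint model
across timepoints would share variance information but couple
comparisons, and per-timepoint matches how per-panel volcano thresholds
are applied downstream.

Significance convention for "upregulated": adj p < 0.05 AND
log2FC > 0.75, both strict.

## KSEA

z = (mean FC over the m quantified substrates − mean FC over all sites)
· √m / sd(FC over all sites), two-sided normal p, BH across kinases per
comparison. The background *includes* substrate sites; excluding them
moves z by < 5% when substrates are < 1% of sites (asserted in tests),
and the inclusive background is simpler and matches the mean-based KSEA
convention. Kinases with fewer than 3 quantified substrates are omitted
as not reliably quantifiable. Substrate matching is exact on site key;
isoform and position-offset tolerance is out of scope.

## Signatures

The signature is the intersection of (adj p < alpha, log2FC > fc_min)
sets over *every* independent stimulated-control comparison — an
intersection, not a vote, so one failing arm excludes a feature.
Derivation is monotone in the thresholds. Perturbation scoring counts
members still significant in the knockout and reports member vs
non-member mean fold changes (the density-shift readout). Member
classification uses two invented, exposed thresholds: abolished = not
significant and FC below 0.25× the control's; retained = significant
and FC at least 0.75× the control's; attenuated otherwise. The 0.25 /
0.75 ratios are package defaults chosen to split a bimodal
ablated-vs-retained pattern cleanly; they are configuration, not
doctrine. Cross-perturbation comparison reports Pearson r, OLS slope
and intercept (with intercept, A on x), and the Jaccard index of the
two significant member sets at the same thresholds.

## Synthetic-data generator

The generator is first-class, tested code that defines the study
conditions. Log2 intensities follow

    x[f, s] = b_f + treated(s)·effect(f, s)·ablation[genotype(s)]
              + donor[d(s), f] + ε[f, s]

with b_f ~ N(20, 2) (typical DIA dynamic range), donor offsets
N(0, donor_sigma = 0.5) constant within a donor, ε ~ N(0, noise_sigma =
0.5), and reported linear intensities 2^x. Two effect routes mirror the
fast/slow biology of interferon signaling: kinase effects (default 1.5
log2 units) act on annotated substrate sites at *every* treated
timepoint (phosphorylation responds within minutes), while induced-set
effects (default 2.0 log2 units, 30 proteins) act only at timepoints ≥
240 min (protein-level induction takes hours). Genotype ablation scales
both routes by a multiplier in [0, 1].

Localization probabilities are Beta(9, 1) for confidently localized
sites and Beta(2, 2) for an ambiguous fraction (default 0.2); only the
behaviour around the 0.75 cut matters downstream.

**Dropout.** MNAR emulates a detection limit and is intensity-dependent
*entire-condition* absence: per feature × condition block, dropout fires
with probability expit(slope · (midpoint − mean block log2 intensity))
and removes the whole block. Defaults midpoint 17.0 (1.5 sd below the
baseline mean) and slope 8.0 per log2 unit — a steep curve, i.e. nearly
a hard threshold, the regime in which MAR and MNAR are well separated.
MAR dropout is uniform at rate 0.05 on surviving entries. These rates
are plausible for deep DIA data but uncalibrated against any specific
instrument; they are exposed on `GroundTruth`.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: peptide-level interference and
ratio compression, correlated (pathway-structured) noise, non-normal
heavy-tailed error, retention-time or acquisition artefacts, shared
peptides between proteins, and site-localization errors that swap
neighbouring residues. Recovery rates measured here are upper bounds
for instrument data.

## Problem sizes and determinism

Tests and the acceptance script use screens of 300–1000 features,
4 replicates, 1–2 timepoints and up to ~30 samples, with 5–20
simulation seeds per check — sizes chosen so the full suite
characterizes calibration (type-I error, FDR, recovery rates) while
staying interactive to run. Signature recovery is characterized on
complete data (no dropout) to isolate the derivation machinery from
detection-limit fold-change compression, which is characterized
separately by the imputation checks; with default dropout applied the
same recovery loses roughly 5 points of recall to compression of the
lowest-baseline induced features — a real phenomenon, not an artefact.

Every stochastic step takes an explicit seed (`numpy.random.default_rng`);
pipeline outputs embed the config hash and seed, and reruns with
identical config are byte-identical. Stable orderings (feature id, then
sample id) are used in all writers.
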