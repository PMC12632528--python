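# phospipe

Analysis pipeline for perturbation phosphoproteomics screens: from
long-format DIA search reports through QC, mechanism-aware missing-value
imputation, moderated differential statistics, kinase-activity inference
(KSEA), and empirical stimulation-signature scoring across genetic
perturbations (CRISPR knockouts, base edits).

## Who this is for

Groups running arrayed perturbation screens read out by quantitative
(phospho)proteomics — e.g. interferon-pathway knockouts in primary T
cells profiled by DIA mass spectrometry — who need a reproducible,
scriptable path from a Spectronaut-style precursor report and a sample
manifest to volcano-ready differential tables, kinase activity z-scores,
and per-knockout signature readouts. A synthetic-data generator with
known ground truth makes every stage testable without instrument data.

## The analysis in brief

Given precursor intensities `I` per (sample, modified peptide):

1. **Site collapse & Class I filter.** Phosphosite records are collapsed
   per (sample, site) by maximum intensity and maximum localization
   probability; only Class I sites (localization probability > 0.75,
   strict) are kept.
2. **Presence filter & normalization.** A feature is kept if it is
   quantified in ≥ k of n replicates of at least one condition (default
   3 of 4). Intensities are log2-transformed and median-centered per
   sample.
3. **Mechanism-aware imputation.** Gaps within a partially observed
   condition block are treated as missing at random (MAR) and imputed by
   feature-space kNN (global runs) or SLSA — replicate mean plus a
   sample-level offset (phospho runs). Blocks missing entirely are
   treated as intensity-dependent dropout (MNAR) and imputed by
   downshift sampling from N(μ − 1.8σ, (0.3σ)²) per sample column.
4. **Differential statistics.** After per-donor centering, each treated
   condition is compared to its time-matched vehicle:
   log2FC = mean(treated) − mean(vehicle), with either a pooled
   Student's t or an empirical-Bayes moderated t,

   t̃_g = log2FC_g / (s̃_g √(1/n_T + 1/n_C)),
   s̃²_g = (d₀s₀² + d_g s²_g) / (d₀ + d_g),

   where the variance prior (d₀, s₀²) is fitted by method of moments on
   log s²_g (verified against limma's `eBayes` to machine precision).
   Benjamini–Hochberg adjustment is applied within each comparison.
5. **KSEA.** For kinase K with m quantified substrates,
   z = (mean FC_substrates − mean FC_all) · √m / sd(FC_all),
   with BH across kinases; kinases with < 3 substrates are not
   quantifiable.
6. **Signatures.** The stimulation signature is the set of features with
   adj p < 0.05 and log2FC > 0.75 in *every* independent stimulated
   control arm. Perturbations are scored by how many members stay
   significant, by member fold-change shifts, by per-member
   classification (abolished / attenuated / retained), and by
   member-wise regression between perturbations.

## Worked example

Simulate a small knockout screen (1 receptor knockout with full pathway
ablation + 3 scrambled controls, quadruplicate, 24 h stimulation with
time-matched vehicles), then run the analysis:

```python
from phospipe import synthetic_data as sd, io_formats, preprocess, \
    impute, differential, signatures

truth = sd.default_truth(seed=11, n_induced=30, n_active_kinases=5,
                         ablation_map={"KO01": 0.0})
design = sd.generate_design(1, 3, 4, [1440.0], include_vehicle=True,
                            assay="global")
print("samples:", len(design))
report, _ = sd.simulate_dataset(design, truth, 400)
matrix = io_formats.pivot_to_matrix(report, design, level="protein")
gapped, _ = sd.apply_missingness(matrix, truth, design)
gapped = preprocess.normalize(
    preprocess.filter_by_replicates(gapped, design, (3, 4)))
print("features after filtering:", len(gapped.features))
imputed, labels = impute.impute_mixed(gapped, design, mode="global", seed=11)
print("gaps imputed:", int((labels != "observed").to_numpy().sum()))
centered = differential.center_by_donor(imputed, design)
diff = differential.differential_table(centered, design, engine="moderated")
per = dict(tuple(diff.groupby("genotype")))
sig = signatures.derive_signature(
    [per[g] for g in ("scramble1", "scramble2", "scramble3")])
print("signature members:", len(sig.members))
for g in ("scramble1", "KO01"):
    s = signatures.score_perturbation(per[g], sig, genotype=g)
    print(f"{g}: {s.n_significant_members}/{s.n_quantified} significant "
          f"members, mean member FC {s.mean_member_fc:.2f}, "
          f"non-member FC {s.mean_nonmember_fc:.2f}")
```

This prints:

```
samples: 32
features after filtering: 384
gaps imputed: 988
signature members: 27
scramble1: 27/27 significant members, mean member FC 1.82, non-member FC -0.15
KO01: 0/27 significant members, mean member FC 0.00, non-member FC -0.03
```

Of the 30 truly induced proteins, 27 survive detection and make the
signature in all three control arms; the scrambled control re-scores all
of them as significant with a mean induction of ~1.8 log2 units (truth:
2.0, attenuated slightly by imputation at the detection limit), while
the fully ablated knockout retains none and its member fold changes
collapse to zero.

The same workflow is available from the shell:

```
phospipe make-design --knockouts 11 --controls 3 --replicates 4 \
    --timepoints 5,30 --assay phospho --out design.csv
phospipe simulate --design design.csv --truth truth.json --ks-map ks.tsv \
    --n-features 1000 --seed 1 --out report.tsv
phospipe run --config config.json --seed 1
```

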