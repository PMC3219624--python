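# Methods

This note documents the statistical model behind `poolfit`, the choices made
where the method leaves room, and what the synthetic benchmark does and does
not demonstrate.

## The measurement model

A pooled fitness experiment measures the abundance of every tagged mutant
strain before ("start") and after growth in a condition. The package works
from tag-level log₂ intensities with replicate probes; the strain fitness in
an experiment is

    f = (mean log₂ intensity of the tag in the condition hybridization)
      − (mean log₂ intensity in the start hybridization),

followed by two median-centering passes (below). One hybridization reads
both pools: uptags report the upPool sample and downtags the dnPool sample,
so a strain archived in both pools contributes two independent measurements
per experiment. Control experiments are independent recoveries of the start
pools with no treatment; their fitness values carry every noise source but
no biology, which is what makes them usable as an empirical null.

Each fitness experiment — condition or control — is paired with its own
start hybridization (linked by the `group` column of `experiments.tsv`).
This matters statistically: if all experiments shared one start array, its
noise would correlate Z scores across experiments and inflate the
chi-squared combination. When an experiment has no start of its own, the
average of all start arrays substitutes, mirroring laboratory practice.

## Detection and filtering

* **Detection**: a strain is kept if its linear-scale level in the average
  start array is at least `detect_multiplier` (default 5) times background,
  where background is the median linear level of unused tags. The threshold
  is inclusive.
* **Low-start filter**: the `low_start_fraction` (default 2%) of detected
  strains with the lowest average start levels are removed, separately per
  pool since each pool is an independently constructed population. Exactly
  ⌊fraction·N⌋ strains are removed; ties break by lexicographic strain_id so
  the rule is deterministic.

## Normalization

Per experiment, the median fitness is set to zero within each
(pool × replicon) group — the megaplasmid is centered independently of the
main chromosome, absorbing copy-number-like shifts — and then within each
96-well plate group, absorbing batch effects from pool construction. These
groupings cross-cut, so a single pass of each cannot zero both sets of
medians; the two passes are repeated in the stated order until every group
median is below 1e−9 (typically 2–4 iterations). This makes the operation
idempotent and both invariants exact; when the groups happen to nest it
reduces to the single pass of each. Strains mapping to no gene are assigned
to the chromosome for the replicon pass (the dominant replicon; the strain
table does not carry a replicon column).

## Gene fitness and the moderated statistic

Gene fitness is the mean over the gene's insertion measurements, restricted
to "good" insertions — gene_fraction within [0.05, 0.80] on the transcribed
strand, boundaries inclusive — whenever at least one exists. Edge-only
genes fall back to all insertions, which keeps them scorable at the cost of
a possible attenuation bias.

Reliability is summarized by

    T = μ √n / (Ψ + s),

with s = 0 for singletons and Ψ the median, over all (gene, experiment)
cells with n ≥ 2, of the per-gene sample SD. One Ψ is computed per
compendium, over all experiments including controls, so control and
condition statistics live on the same scale. This form is one of several
"t-like" statistics built from μ, n, s and Ψ; adding Ψ to the denominator
shrinks unreliable small-n variance estimates and keeps T finite at n = 1.
Because T is calibrated against its own empirical null (next section), the
downstream Z scores are insensitive to the exact algebraic form — an
alternative such as μ/((Ψ+s)/√n) differs only by a within-stratum monotone
rescaling, which the quantile map absorbs.

## Empirical-null Z calibration

Control-experiment T values are pooled by measurement count into strata
n ∈ {1, 2, 3, ≥4}, since the null spread of T depends on n. Within a
stratum, Z(T) = Φ⁻¹(p) where p is the mid-rank ECDF position
((i − ½)/N, linearly interpolated) of T among the sorted control values.
Outside the observed control range the map continues linearly with slope
1/scale, where scale = 1.4826 × MAD of the stratum — a robust normal fit —
so extreme statistics receive finite, monotone Z scores instead of ±∞. A
stratum with fewer than 50 control values is merged into the next one (with
a warning); with fewer than two control experiments calibration refuses to
run.

The phenotype test combines Z over condition experiments only (controls are
the calibration set): X² = ΣZ², df = number of non-missing Z, P from the
upper chi-squared tail, significance at `phenotype_alpha` = 0.001. Strong
patterns are the union of the top third of X² among all tested genes
(boundary ties included) and genes whose minimum Z falls below the
one-sided Bonferroni threshold Φ⁻¹(0.01/N_experiments). The "top third
among all tested genes" reading was chosen over "among significant genes"
because the cutoff is explicitly arbitrary and the union with the
single-condition branch makes the distinction minor.

## Compendium analytics

Correlations use pairwise-complete experiments with a minimum overlap
(default 10) and omit constant profiles. Cofitness P-values use the exact
t transform t = r√(n−2)/√(1−r²). Polarity is counted per
(operon pair, experiment) event — upstream-only-sick means upstream fitness
< −2 while the downstream gene stays > −1 — and tested with a two-sided
binomial against equal rates; two-sided is the conservative choice where
sidedness is not specified. Operon metrics use adjacent co-operonic pairs
ordered by transcription direction. Quality metrics r(Same)/r(Operon) need
at least 3 pairs, otherwise they are reported missing with a warning.

## Function prediction

Features are per-experiment mean-centered profiles with missing values
imputed as zero after centering (the column mean). Subrole labels lacking a
subrole or containing "unknown"/"other" are excluded as non-specific. Where
a gene could carry several assignments, one label per gene is kept.
Cross-validation folds are assigned to whole operons: operons are shuffled
and greedily placed in the currently smallest fold, balancing gene counts
within the largest operon size while guaranteeing zero leakage (asserted in
tests on every run). The classifier is a random forest with
`n_trees` = 500 and library defaults otherwise; confidence is the vote
fraction of the winning class. Unlabeled genes are predicted by a final
forest trained on all labeled genes. The regulon null shuffles target
assignments uniformly across pairs and re-excludes autoregulatory draws;
the shuffle design is seed-controlled since no canonical scheme exists.

## The synthetic generator

The generator emulates the statistical structure of a real tag-array
compendium: two pools of tagged strains with ~2% truly undetectable
members, five replicate probes per tag, per-(plate, experiment) batch
effects, a separately shifting megaplasmid, sparse condition-specific
effects shared within operons, and control recoveries. Defaults:

| parameter | default | rationale |
|---|---|---|
| start level | N(10, 1) log₂ | bright, well-detected tags; no distribution is published, so this is a configurable stand-in |
| low start tail | 3% near background + 2.8 | exercises both the 5× detection and the 2% filter |
| probe_sd | 0.25 log₂ | moderate array noise; benchmarks also use 0.05 (clean) and 0.5 (hard) |
| plate_sd, replicon_shift | 0.25 log₂ | visible but removable batch structure |
| sparsity | 0.05 per condition | most genes unaffected in any one condition |
| effect_scale | 2.0 log₂ | defects of −1 to −3, occasional positives (15%) |
| operon_share | 0.75 | strong within-operon effect correlation |
| edge_attenuation | 0.5 | insertions outside the central window retain partial function |
| pools | ~40% of strains in both | two measurements for a sizable strain fraction |
| n_controls | 14 | matches the empirical-null design |

What the generator does **not** model: sequence-dependent insertion-site
bias, hybridization chemistry and cross-hybridization, spatial array
artifacts, condition-specific population takeovers, or any coupling between
a gene's subrole label and its fitness profile (classifier benchmarks that
need such coupling construct it explicitly). Passing tests therefore
demonstrate correctness of the statistical machinery under a plausible
noise model, not performance on any real compendium.

## Problem sizes

The default end-to-end configuration uses 400 genes, 800 insertions,
40 conditions and 14 controls and runs in well under a minute on one CPU;
the null-calibration benchmark uses 1,250 genes so that ≥1,000 genes are
scored, and the type-I-error benchmark 2,600 genes so that ≥2,000 are
tested. These sizes give the empirical checks enough resolution (binomial
intervals, KS tests) while keeping the whole suite fast.

## Known limitations

* Strains without a mapped gene are excluded from gene-level scoring and
  are assigned to the chromosome during normalization.
* Genes represented only by edge insertions are scored from attenuated
  measurements; their fitness is biased toward zero by construction.
* The empirical-null tails beyond the observed control range rely on the
  robust-normal extension; extreme |Z| values are ordinal rather than
  exact tail probabilities.
* The significant-gene fraction in synthetic runs depends strongly on the
  truth sparsity and the number of conditions; it is a property of the
  simulated conditions, not a calibration target.
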