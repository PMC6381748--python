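# Methods

## The experimental design being modeled

The package targets paired stimulation time courses: for each time point
(defaults 5, 30, 60 min) the same replicate index exists under a resting
("low", 2.5 mM glucose) and a stimulated ("high", 16.7 mM) condition, five
replicates per condition, with per-p-site log2 quantitative values from a
TMT-style multiplexed experiment. Replicate *i* of low pairs with replicate
*i* of high at the same time point; the pairing is the basis of the paired
*t*-test and is configurable through the table layout. The unit of
quantification is the p-site: a protein accession plus one or more
phosphorylated S/T/Y positions quantified together (canonical string form
`ACCESSION_S123`, multi-site `ACCESSION_S519/S523`).

## Ingest filters

Rows are dropped when the best-estimate localization probability is below
0.95, when any (condition, time) cell has fewer than 2 of the replicates
quantified, or when the row is absent from a condition entirely; a
replicate value whose partner in the other condition is missing is removed
pairwise (a paired test cannot use it). The filter is idempotent and the
count removed by each rule is reported. Missing values are NA throughout —
never zero-imputed, since 0 is a legal log2 value.

## Differential statistics

Per p-site and time: log2FC = mean(high_i − low_i); p from a two-sided
paired *t*-test on the differences; *regulated* ⇔ p ≤ α AND |log2FC| > θ
(defaults α = 0.05, θ = 0.3 log2 ≈ 23% change; both gates must pass —
a significant 19% change is not called). The test is two-sided because
both gains and losses of phosphorylation are of interest. No
multiple-testing correction enters the calls; a Benjamini–Hochberg column
is emitted alongside for users who want it. Degenerate variance is handled
explicitly: all-zero differences give p = 1 (no change); identical
non-zero differences make the *t* statistic unbounded, so p is reported as
the smallest positive float and the row flagged `degenerate_variance`
rather than NaN-poisoning downstream stages. An unpaired mode exists
(`paired=False`) because table layouts in the wild sometimes lack reliable
pairing; paired is the default.

Protein-level runs reuse the same machinery on a non-enriched-fraction
table; the reconciliation report counts, per time, the proteins carrying
regulated p-sites that are also regulated at the total-protein level (the
"10/76" ratio form) and flags those p-sites as protein-confounded.

## Trajectory clustering

Trajectories are the per-time log2FC values prepended with 0 at t = 0: the
stimulus-relative change is zero before stimulation, and with only three
measured times the extra point keeps second-difference measures
non-degenerate. This baseline augmentation is a deliberate design choice —
clustering raw FC triplets is possible by passing `baseline=False`, but the
augmented series is the default and what the tests exercise.

Nineteen descriptive measures summarize each trajectory (range, mean, SD,
CV, total change, change per unit time, change relative to first/mean
value, least-squares slope and its R², max/SD/mean-absolute/max-absolute
first differences, mean/mean-absolute/max-absolute second differences, and
two ratio measures). Ratios with a zero denominator are flagged missing
and the measure is dropped from factoring rather than imputed; with the
baseline at 0 the change-relative-to-first measure is always in this
category. The *mean of the second differences* is computed but excluded
from clustering by default; exclusion is specified by name, not by index,
since measure numbering varies across implementations of this framework.

Selection: candidate measures (complete, non-constant) are standardized;
principal factors of their correlation matrix with eigenvalue > 1 are
retained (Kaiser criterion), varimax-rotated, and the measure with the
highest absolute loading per factor is selected. Clustering: k-medoids
under the Manhattan (1-norm) distance on the selected standardized
measures — k-means would tie the procedure to the 2-norm — with 50 random
restarts keeping the lowest total within-cluster cost, fixed seed
(default 1), deterministic tie-breaks. Archetype labels come from each
cluster's mean trajectory: *early* when the largest |step| is the first
interval — further split into *transient* when the final value has
returned within 50% of the peak excursion, else *sustained* —
*intermediate*/*late* by the interval of the largest |step|; the sign
follows the peak excursion. The "most markedly changed" sub-selection
(`top_n`) ranks by max |log2FC| across times with ties broken by key; the
selection rule is a documented default, not a claim about how any
particular published subset was chosen.

Heatmap ordering uses complete-linkage hierarchical clustering on the
Gower dissimilarity, which for all-quantitative data is the per-variable
range-scaled Manhattan distance averaged over variables (as R's
`cluster::daisy` computes it). Zero-range variables are dropped, so the
ordering is invariant to constant columns; rows are canonicalized by id
before linkage so the ordering depends only on the (id, row) pairs.

## KSEA

Substrate groups are built by joining the quantified p-sites to
kinase–substrate relationship records on uppercase gene symbol plus
residue/position (default; an exact-accession mode exists). Gene-symbol
joining is the default because the public kinase–substrate databases are
largely human-centric while the data may come from another species; a
symbol+site join is the pragmatic cross-species bridge. Optional motif
groups match a regular expression against each p-site's ±7-residue window,
requiring the match to cover the central phospho-residue. A multi-site
feature joins any group whose site list intersects its sites, once per
group.

The score is the mean-based variant: z = (s̄ − p̄)·√m/δ with background
p̄, δ taken over *all* quantified p-sites in that replicate/time (not only
regulated ones), per-replicate fold changes high_i − low_i. Two-sided
normal p; BH across enzymes within each (time, replicate). z is exactly 0
for the full background as a group and is invariant to adding a constant
to, or positively rescaling, all fold changes. A permutation p over random
same-size subsets of the background is provided as an independent check of
the normal approximation; on dataset-sized backgrounds (thousands of
sites) the without-replacement correction √((n−m)/(n−1)) is negligible for
the m ≤ tens regime and the two agree within Monte-Carlo error. Minimum
group size defaults to m ≥ 1 — real matching is sparse, and excluding
singletons would silence most enzymes — but significance is reported only
for m ≥ 2, and low-m groups are listed. Replicate-mean matrices carry a
complete-linkage row ordering, top/bottom extraction by overall mean
score, and the |z| > 2 highlight convention.

Temporal classification prepends 0 to the mean score series; the
largest-magnitude change between consecutive points gives the direction
(positive/negative) and its interval the timing class (early /
intermediate / late); flat profiles are *unchanged*. For kinases a
positive direction reads *activated*; for phosphatases the reading is
inverted, since an active phosphatase removes phosphate from its
substrates.

## Gene-set enrichment

Upper-tail hypergeometric p (P(X ≥ k)) per set, sets intersected with the
universe before testing, BH across the collection. The universe defaults
to the quantified proteins in the input table rather than a whole-genome
background: testing against genes that could never have appeared inflates
enrichment. Gene mapping uses the gene symbol when present, else the
accession. The cross-group differential ranking computes, per set, the SD
of −log10 p across the per-time queries, sorting in decreasing order; a
set untested in a group enters as p = 1 and is flagged. Display truncation
defaults to the top 30.

## Respirometry

Basal rate = mean OCR over the pre-stimulus cycles (default window:
everything before the annotated injection). Response = signed trapezoidal
integral of (OCR − basal) from the stimulus time to the trace end on the
actual timestamps — robust to skipped cycles; below-basal excursions count
negatively (no clipping), preserving inhibition information. The AUC
window ends at trace end by default and is configurable. Treatments are
compared to mock wells as fold change of mean AUC with a two-sided Welch
*t*-test across wells (wells are independent, so unpaired; Welch because
equal variances are not guaranteed). A treatment whose mean basal differs
from mock basal by more than 15% is flagged `basal_perturbed`: its
stimulus response cannot be read independently of the resting-respiration
effect.

## Synthetic data generator

The generator emulates the study design: paired log2 tables at 5/30/60 min
with five replicates. Defaults: 3000 p-sites on 1500 proteins (desk-scale
mirror of a ~3000-site phosphoproteome), baseline log2 intensities
N(20, 2), additive homoscedastic Gaussian noise SD 0.2 log2 (typical
TMT reporter variability at this scale), planted effects of 0.8 log2 from
12 enzymes (9 kinases, 3 phosphatases) with 10 substrates each plus
unattached regulated sites up to 234 planted sites total, protein-level
co-regulation for 15% of the proteins carrying planted sites. Effect-time
profiles are piecewise constant over the sampled times in one of four
archetypes (early-sustained / early-transient / intermediate / late,
transient = effect at the first time only), signed up or down. High values
are the paired low values plus the archetype effect plus noise, so a null
site's paired difference is pure noise and the type-I rate of the
differential stage is directly checkable. Missingness is
missing-completely-at-random only (default off). The ground truth —
site→archetype/direction, enzyme memberships and effects, protein
co-regulation — is serialized as JSON next to the data, and generation is
bit-reproducible per seed.

What the generator does *not* emulate: intensity-dependent variance (an
optional term exists but homoscedastic is default), batch/channel effects,
non-random missingness, correlated substrate noise within a kinase group,
and imperfect kinase–substrate annotation (the synthetic relationship
table is exactly the planted truth). Passing recovery tests therefore
shows the statistical chain is correct under its own assumptions, not that
real data meet those assumptions.

The respirometry generator produces 6-min-cycle plates: a flat basal
segment (default 100 pmol O₂/min, 5 cycles ≈ the 30-min pre-incubation), a
post-injection linear rise over one cycle to a plateau (default +50
pmol/min), per-treatment multiplicative effects on amplitude and basal,
Gaussian noise (SD 3 pmol/min), and the noise-free expected AUC as truth.

## Problem sizes and numerical choices

The test-suite and acceptance-script simulations run at desk scale chosen
to keep the statistical claims sharp: ≥ 2000 null sites for type-I
calibration (3·binomial-SE band), 20 seeds × 12 enzymes for KSEA sign
recovery (effect 0.8, noise 0.2, m = 10, 5 replicates), 20 seeds at noise
SD 0.08 = 0.1 × effect for trajectory recovery (adjusted Rand index), 10⁵
permutation draws for the normal-approximation check, and exact
enumeration oracles for the hypergeometric tail (N ≤ 30) and
complete-linkage agglomeration (≤ 8 rows). Volcano exports cap −log10 p at
320 when p underflows. TSV writers use 17-significant-digit formatting and
readers round-trip floats exactly, which is what makes pipeline reruns
byte-identical.

## Known limitations

- The paired test with n = 5 pairs has limited power for effects near the
  fold-change gate; no variance moderation (empirical Bayes) is applied,
  by design fidelity to the raw-p workflow.
- Table legends in the wild sometimes describe such data as unpaired while
  the design is paired; both modes are provided, paired is the default,
  and results differ — check the experimental design.
- KSEA significance for tiny groups (m < 2) is suppressed rather than
  reported; single-substrate "activities" are just that substrate's fold
  change.
- The factor-analysis selection uses principal components with the Kaiser
  rule; other extraction/rotation choices can select different (correlated)
  representatives and shift cluster boundaries for borderline
  trajectories.
- Enrichment p-values depend strongly on the universe; the
  quantified-protein default is the defensible choice for proteomics but
  is not comparable to whole-genome-background numbers.
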