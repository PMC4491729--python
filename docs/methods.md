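# Methods

## Problem setting

Exon–junction transcriptome arrays measure, for every gene, two kinds of
probesets: *exon* probesets covering each exon body and *junction*
probesets straddling each exon–exon junction. Comparing two conditions,
an alternatively spliced (e.g. skipped) exon changes relative to its
gene, its *inclusion* junctions (those ending at the exon) change with
it, and its *exclusion* junctions (those skipping over it) change the
opposite way. The pipeline exploits this redundancy in three steps:
robust gene expression from data-selected constitutive exons, candidate
calling that requires junction corroboration, and recovery of candidates
whose junction probesets are unreliable.

All computation is on log2 expression indices. "Fold change" always
means a difference of log2 means between the two conditions, second
condition minus first in lexicographic order unless the design overrides
it. Runs compare exactly two conditions; multi-group studies are run
pairwise.

## Preprocessing

Probe-level matrices are median-scale normalized (each sample column
shifted so its median equals a common target; `auto` = mean of the
original column medians) and summarized per probeset by Tukey median
polish. The per-sample expression index is the polish's overall effect
plus the column effect; probe (row) effects absorb probe-affinity
differences, and the median makes the index robust to a minority of
aberrant probes. Convergence: row sweep first, stop when the largest
median removed in a sweep is below 1e-6 or after 30 sweeps; even-length
medians are the mean of the two central values (fixed for
bit-reproducibility). Normalization happens at probe level before
summarization; the algorithm is insensitive to this ordering at the
median, and doing it first keeps summarized indices directly
comparable across samples.

Detectability uses detection-above-background (DABG) p-values supplied
per probeset and sample. The group-level call per condition is the
geometric mean of the condition's sample p-values; a probeset is
*present* where that group p-value is at or below the presence threshold
(default 0.01). Input p-values are clamped to [1e-16, 1] so the log-mean
is always defined.

## Step 1 — putatively constitutive exons and the gene index

For each gene, exons undetected in either condition are set aside as
absent. Over the remaining exons' fold changes the trimming loop
computes the mean `m` and sample standard deviation `s` (ddof=1; `s = 0`
for a single exon) and flags exons strictly outside `[m − d·s, m + d·s]`
(`d = 2` by default). `m` and `s` are recomputed over the survivors and
the loop repeats until no exon is flagged. Numerical conventions:

- the interval boundary is inclusive, so an all-equal gene (`s = 0`)
  keeps every exon;
- removal is monotone — a flagged exon is never re-admitted — which
  guarantees termination within one pass per exon (re-admission can
  cycle);
- with `d ≥ 1` a pass can never flag every retained exon (the sum of
  squared deviations equals `(n−1)s²`, so not all deviations can exceed
  `d·s`); a guard also stops the loop if floating-point underflow of `s`
  would ever flag the whole set;
- `m` and `s` are computed on log2 fold changes (the procedure is
  scale-equivariant, so the choice is a convention).

The gene expression index is a median polish over the constitutive
exons' signal — pooled probes when probe-level data is available,
otherwise the exon index rows. Genes with no constitutive exon fall back
to all present exons and are flagged (`min_constitutive = 1`); a large
fraction of real genes have no annotated constitutive exon, and the
pipeline must still score them. Genes with no present exon at all are
excluded from testing.

## Step 2 — junction-supported calls

The splicing index (SI) of a probeset is its fold change minus its
gene's fold change; its sign is the direction of the event. Significance
is a one-way ANOVA across conditions on the gene-normalized per-sample
values (the MIDAS construction); the test function is pluggable so a
rank-based alternative can be substituted. Degenerate inputs are
resolved explicitly: zero within-group variance gives p = 1 when the
group means agree and p = 0 otherwise; fewer than two replicates in a
group makes the probeset untestable.

Junction probesets carry fewer and less optimized probes than exon
probesets, so the two p-value populations differ systematically. The
exon threshold `p` (default 0.01) is mapped onto the junction scale
through empirical quantiles: with `f` the fraction of exon p-values at
or below `p` and `k = ceil(f·N_junc)`, the adjusted threshold `p′` is
the k-th smallest junction p-value (0 when `k = 0`), computed in exact
integer arithmetic so the junction pass-fraction is exactly `k/N_junc`
up to ties. A significant exon becomes *junction-supported* when at
least one of its junctions passes `p′` and moves with it: an inclusion
junction in the same direction, or an exclusion junction in the opposite
direction. Probesets with SI exactly 0 have no direction and neither
give nor receive support. Support through an exclusion junction alone
counts, and the support type is reported so downstream users can
distinguish it.

Exons absent in one condition but present and significant in the other
are kept as ordinary significant exons and flagged (`presence_flag`);
exons absent in both conditions are not called.

## Step 3 — unreliable junctions

A significant exon without support may simply have failing junction
probesets. For every significant exon the *best junction* is the one
with the largest |SI| among those sharing the exon's direction; with
none, the junction change is truncated to 0. The fold-change difference
`|SI_exon| − |SI_best|` is computed on the log scale (negative when the
junction outruns the exon). The junction-supported exons of step 2
provide an empirical null of this difference — how exon and best
junction co-behave when junctions work. The decision boundary is the
top-`q` quantile of the null (`q = 0.05`): the k-th smallest of the `N`
null differences with `k = ceil((1−q)·N)`. Unsupported significant exons
strictly above the boundary are called `unreliable_junction_candidate`;
ties fall inside the null. Step 3 requires at least 20 null differences
(a quantile from fewer points is meaningless); below that it is disabled
with a warning and only step-2 calls are emitted.

Every exon ends in exactly one category: `junction_supported`,
`unreliable_junction_candidate`, `exon_only_not_called`,
`not_significant`, or `absent`.

## Synthetic data

The simulator generates the four pipeline inputs plus ground truth.
Genes are linear chains of exons with an adjacent junction between every
consecutive pair; each planted skipping event on an internal exon also
gets the skip junction joining its neighbours. Probe-level log2
intensities are

    gene abundance(condition) + splicing shift + probe affinity + noise

with gene abundance uniform on [8, 11] in the first condition and a
N(0, 0.5²) log2 shift in the second. Defaults mirror a three-replicate
two-tissue array study: 200 genes × 10 exons, 8 probes per exon probeset
(noise sd 0.25), 4 per junction probeset (noise sd 0.5 — junction probes
cover ~30 bp against ~120 bp for exons and behave worse), probe
affinities N(0, 0.3²), splicing effect 2.0 log2 units on 5% of internal
exons with random direction (inclusion junctions move with the exon, the
exclusion junction against it). Failure modes with truth labels: absent
exons (background in both conditions, default 5%), uniformly failed
junction probesets (flat background; default 0), and — for the step-3
recovery scenario — a fraction of planted events whose junctions are all
forced to fail. DABG p-values are a logistic function of signal above
background (background 3.0, slope 3.0 per log2 unit, seeded N(0, 0.5²)
jitter), putting expressed probesets far below the 0.01 presence
threshold and background-level ones near 0.5. Everything is reproducible
from a single seed.

What the simulator does not emulate: cross-hybridization, sequence-
dependent probe affinity, partial isoform mixtures (events are all-or-
none shifts), alternative 5′/3′ splice sites, retained introns,
multi-exon skips, and array-level spatial artifacts. Passing tests
demonstrate the algorithm's behaviour under its own model assumptions,
not performance on real hybridizations.

`evaluate_calls` scores called exons (`junction_supported` ∪
`unreliable_junction_candidate`) against planted events: precision,
recall, F1, per-category precision and direction agreement. Precision
with zero calls is reported as missing, not zero.

## Evaluation choices

The gene-index robustness check compares the constitutive-exon index
against the non-robust all-exon estimate (mean of exon indices, the
construction common in splicing-index pipelines) on the abundance scale,
per condition, with normalization disabled for both routes — the
simulator already emits probes on a common scale, and median scaling
would only inject a global offset when planted event directions are
imbalanced. A median-polish all-exon index is itself robust to a single
outlier exon row, so the contrast against it is not informative about
contamination.

The threshold-adjustment calibration note: `p′ < p` is observed when the
junction p-value population has a denser low tail than the exon
population, which is what skipping events produce (each event touches
about three junctions but one exon). It is not implied by junction
p-values being stochastically larger — matched quantiles would then move
`p′` the other way.

## Default problem sizes

Tests and the acceptance script run the pipeline at the default
simulation scale (200 genes × 10 exons, 3+3 samples, ~23,500 probes),
which completes in a few seconds per run; the null-calibration and
precision-ordering checks repeat it across seeds. Monte-Carlo checks use
10,000 draws (type-I rate, trimming termination) or 1,000 ten-exon genes
(retention rate).

## Known limitations

- The empirical-null cutoff is estimated from the same run's supported
  exons; with few true events the null is small and step 3 disables
  itself rather than extrapolate.
- The junction threshold adjustment assumes exon and junction p-value
  populations are comparable across the whole array; gene-specific
  junction quality is not modelled.
- Presence-based events (absent in exactly one condition) are flagged
  but share the ordinary significance path; no dedicated presence test
  is applied.
- With probeset-level input the gene index polishes exon index rows
  rather than probes, which weights exons equally regardless of probe
  count.
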