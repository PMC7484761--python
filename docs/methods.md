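# Methods

This note documents the models, conventions and design choices behind
`proteoconnect`, and what the synthetic validation does and does not show.

## Study design and preprocessing

The pipeline targets a label-free LC-MS/MS protein quantification table from
a four-arm design — WT, DKD, DKD+R, WT+R with 8 biological replicates each —
where each sample is acquired in a single injection, so one sample column is
one analytical run.

Preprocessing order follows the standard narrative for such tables:
contaminant and < 2-peptide removal first, then median normalization, then a
per-comparison quantification filter, then imputation of the retained
proteins only.

* **Median normalization** operates on the log2 scale: each sample column is
  shifted so that every per-sample median over observed values equals the
  grand median of the pre-normalization column medians. Any common target is
  equivalent up to a global shift (two-sample t-tests are shift-invariant);
  the grand median keeps the output on the input's intensity scale. The
  operation is idempotent to float precision.
* **Quantification filter**: a protein enters a pairwise comparison iff it
  has ≥ 4 observed intensities in at least one of the two groups
  (disjunctive reading: 4/8 in one group and 0/8 in the other is retained).
  The filter depends only on the missingness pattern.
* **Imputation**: missingness in deep label-free data is left-censored
  (low-abundance measurements drop out preferentially), so remaining missing
  cells are replaced by a constant per-run noise floor — the 1st percentile
  of the run's observed protein population, computed with numpy's linear
  interpolation between order statistics. The percentile and its
  interpolation convention are exposed as configuration because "1st
  percentile" alone does not pin down an order-statistic convention.
  Imputation happens inside each comparison, after the quantification
  filter: proteins failing the filter are excluded from that comparison
  anyway, so imputing them would only distort the floor.

## Differential abundance and selection

Tests run on log2 intensities (effects are additive and symmetric on that
scale, the norm for label-free MS). The default is Welch's two-sided
unequal-variance t-test; Student's equal-variance variant is selectable
because published protein counts from such studies rarely state the variant.
Benjamini–Hochberg q-values are computed over each comparison's retained set
and reported as annotation; *selection* uses raw p < 0.05 by default (the
convention of the flowchart this pipeline reproduces), with q-based
selection available as a switch.

The signature flowchart:

* disease signature = Set1-significant proteins, split by fold-change sign;
* **drug-insensitive (RI)**: disease proteins not significant in Set2
  (candidates), minus candidates significant in Set3 — an apparent
  insensitivity in diabetic animals paired with a response in healthy ones
  is treated as unspecific;
* **drug-sensitive (RS)**: disease proteins significant in Set2 with the
  sign opposite to Set1 (counter-regulation), minus candidates whose Set3
  behaviour reproduces the drug response seen in Set2.

The RS removal rule (Filter 2) is genuinely ambiguous in prose descriptions
of such flowcharts: "a drug response not specific to disease" is read here
as *Set3-significant with the same sign as the Set2 change* (the drug does
the same thing in healthy animals). The literal opposite-sign reading and a
sign-blind reading are provided as `filter2_policy="opposite" | "any"`.
Proteins absent from a comparison (they failed that pair's quantification
filter) count as not significant there, with a logged count. The RI share of
the disease signature is reported truncated to a whole percent, the
convention used when such figures are quoted (e.g. 350/666 → 52%).

## Connectivity mapping

The classic (build-02 style) construction: for each compound instance, a
complete ranking of N genes; for each query tail of n genes at sorted
positions V(j), the two-sided KS enrichment

    a = max_j [ j/n − V(j)/N ],   b = max_j [ V(j)/N − (j−1)/n ],
    KS = a if a > b, else −b.

The instance's raw score is `KS_up − KS_down` when the two tails disagree in
sign and 0 otherwise; raw scores are scaled into [−1, 1] by dividing
positives by the maximum positive and negatives by |minimum negative|.
Compound-level enrichment is the same KS statistic applied to the compound's
instance positions within all instances ordered by scaled score (descending;
ties broken by compound and instance id for determinism — synthetic
rankings are strict permutations, and real data would need a documented
tie-break such as stable order by gene name).

Numerical caveats, verified by the test suite:

* the statistic is *not* exactly antisymmetric under list reversal — the
  discrete a-vs-b decision can flip at the sign boundary (e.g.
  KS({1}, 4) = 0.75 but KS({4}, 4) = −1.0), so raw scores negate exactly
  under database reversal only where the same-sign zeroing rule does not
  engage;
* the permutation p-value, `p = (r+1)/(n_perm+1)` with r counting random
  same-sign instance subsets at least as extreme, is one-tailed within the
  observed sign class: under a null query the *doubled* p is approximately
  Uniform(0, 1). The +1/+1 correction avoids zero p-values.

Specificity is the fraction of random null queries (same up/down sizes,
drawn from the database universe) for which the compound scores an
enrichment of the same sign at least as extreme — a generated-null stand-in
for the historical query compendium a production connectivity service would
use; this is a documented divergence. The simplified modern score aggregates
each compound's instances into a consensus ranking by mean rank, computes
`wtcs = (ES_up − ES_down)/2` (0 when the tails agree in sign), normalises by
the mean |wtcs| of same-sign compounds (ncs), and standardises against
reference null queries into [−100, 100] (the tau idea): the score is
`sign(ncs) × 100 ×` the fraction of reference queries with strictly smaller
|ncs| for that compound.

## Ortholog mapping and overlap enrichment

Mouse-to-human conversion is table-driven (which ortholog resource to use is
the user's choice). Unmapped ids are dropped and counted; 1-to-many ids are
dropped by default (expandable by policy); a human symbol reached from both
tails is removed from both (a gene cannot be up and down at once); ids that
are already all-uppercase human-style symbols pass through unchanged, making
the conversion idempotent. Overlap enrichment is the hypergeometric upper
tail P(X ≥ x) over a universe defaulting to the union of the loaded GMT
collection (the "compute overlaps" convention), BH-corrected across sets.

## Synthetic data: what it emulates and what it does not

`generate_study` draws per-protein baselines b_i ~ N(25, 2) on the log2
scale, adds a signed disease effect e_i (|e_i| ~ U(0.5, 2.5) by default) to
both diabetic arms for 600 of 2,400 proteins, subtracts f·e_i
(f ~ U(0.8, 1.2), so counter-regulation without exact cancellation) in
DKD+R for the drug-reversed 15%, applies the same response in WT+R too for
the non-specific 5%, plants 50 drug-only proteins, and adds N(0, 0.5)
replicate noise. Cells go missing via a logistic MNAR model,
P(missing) = 1/(1 + exp((x − 19.3)/1.0)): the midpoint was calibrated once
so the default study shows ~2.1% mean missingness, the level typical of a
deep single-shot glomerular run. Contaminants (2%) receive ordinary
intensities — removing them is the filter's job — and peptide counts are
Poisson(5) clipped to ≥ 1, leaving a small single-peptide tail for the
filter to exercise. Effects are planted only on rows that survive the hard
filters so that truth sets are recoverable in principle. Intensities are
stored on the raw scale (2^x), as MaxQuant-style tables are.

The generator deliberately omits several features of real data: per-protein
variance heterogeneity (a single replicate noise SD; the field's moderated
tests exist precisely because real variances vary), correlated proteins
(complexes, shared peptides), batch structure across runs, and the
correlation structure of a real compound compendium (decoy compounds are
uniform permutations, which makes the planted reverser easier to find than a
real hit would be). Passing the planted-recovery tests therefore
demonstrates the *correctness of the selection and scoring logic*, not the
expected sensitivity on real data.

The compound database plants one reverser (query's down genes ranked top, up
genes bottom; each signature gene relocated to a random position with
probability `reverser_noise`) and one mimic (the opposite) among 20 uniform
decoys, 4 instances each over 500 genes.

## Problem sizes and determinism

Default analyses use 2,400 proteins × 32 samples; calibration checks use a
2,000-protein null study; recovery checks use 1,200 proteins with 300
planted effects at |e| ≥ 1.5, where the two-sample power at n = 8/group
makes misses rare. Permutation p-values use 1,000 permutations, specificity
50–100 null queries. Every stochastic step takes an explicit integer seed;
reruns with identical configuration are byte-identical, including all
written artifacts.

## Known limitations

* The flowchart's published-count replication on the deposited study table
  requires that external table; the package validates the count *relations*
  and the full logic on synthetic data instead.
* Connectivity scores are comparable only within one database scoring run
  (the scaling step is database-relative).
* The permutation p and specificity are estimators; their resolution is
  bounded by `n_perm` and the null-query count.
* Exact zero log2 fold changes (possible only with degenerate ties) are
  excluded from both signature directions with a warning.
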