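# proteoconnect

Drug repurposing from label-free proteomics of the diabetic kidney.

In diabetic kidney disease (DKD), standard-of-care RAAS blockade (an ACE
inhibitor such as ramipril) controls albuminuria but leaves much of the
disease-associated glomerular proteome untouched. `proteoconnect` implements
the full computational chain that turns a four-arm mouse glomerular
proteomics study — wild-type (WT), diabetic (DKD), and both arms treated with
ramipril (DKD+R, WT+R), 8 biological replicates each — into a ranked list of
compounds predicted to *reverse* the drug-insensitive part of the disease
signature:

1. **Preprocessing** of the protein quantification table: removal of
   contaminants and proteins identified by < 2 peptides, median
   normalization across conditions, a per-comparison quantification filter
   (≥ 4 observed replicates in at least one group), and imputation of the
   left-censored missing values by a per-run noise floor (the 1st percentile
   of the run's observed intensities).
2. **Differential abundance** per pairwise comparison on log2 intensities —
   Set1 = DKD vs WT, Set2 = DKD+R vs DKD, Set3 = WT+R vs WT — with Welch's
   unequal-variance t-test (two-sided) and Benjamini–Hochberg FDR
   annotation; significance at p < 0.05.
3. **Flowchart selection** of the ramipril-insensitive (RI) signature
   (Set1-significant, Set2-non-significant, minus Set3-significant
   candidates) and the ramipril-sensitive (RS) signature (Set1-significant,
   counter-regulated in Set2, minus candidates whose drug response is
   reproduced in healthy animals).
4. **Ortholog mapping** of the mouse protein signature to disjoint up/down
   human gene-symbol sets (`.grp` query files).
5. **Connectivity mapping**: the classic two-tail Kolmogorov–Smirnov
   enrichment of the query in each compound instance's full gene ranking,

       a = max_j [ j/n − V(j)/N ],  b = max_j [ V(j)/N − (j−1)/n ],
       KS = a if a > b else −b,     raw_s = KS_up − KS_down (0 if same sign),

   with per-compound enrichment, permutation p, specificity against null
   queries and percent non-null — plus a simplified modern (wtcs/ncs/tau
   style) score in [−100, 100]. Negative enrichment = predicted reverser.
6. **Gene-set overlap enrichment** (hypergeometric upper tail, BH FDR)
   against GMT collections.

Because the real compound compendium and the deposited study table are
external resources, the package ships a first-class **synthetic data
generator** that plants known disease effects, drug-reversed and
non-disease-specific subsets, missing-not-at-random dropout, and a known
"reverser" compound — so every stage is validated against planted ground
truth.

## Worked example

Run the whole pipeline on a simulated study (2,400 proteins, 4 × 8 samples,
600 planted disease effects of which 15% are drug-reversed and 5%
drug-responsive in healthy animals too):

```bash
proteoconnect run-all --seed 1 --outdir run1
```

which prints

```
flowchart: |DKD|=615 |RI|=448 |RS|=89; top reversing compound: reverser (enrichment -0.966)
```

and writes, among other artifacts, the flowchart trace `run1/trace.tsv`:

```
quantity              count
n_set1_sig            615     # disease-associated proteins (Set1 p < 0.05)
n_filter3_candidates  486     # of those, not significant under the drug (Set2)
n_filter4_removed     38      # removed: drug-responsive in healthy mice (Set3)
n_ri_final            448     # final ramipril-insensitive signature
n_filter1_candidates  123     # counter-regulated in Set2
n_filter2_removed     34      # removed: response reproduced in Set3
n_rs_final            89      # final ramipril-sensitive signature
ri_fraction_pct       72      # share of the disease signature the drug misses
```

and the connectivity table `run1/connectivity_cmap1.tsv`, whose first row is
the planted reverser:

```
cmap_name  mean    n  enrichment  p        specificity  percent_non_null
reverser   -0.995  4  -0.966      0.000999 0.0          100
```

Reading the row: all 4 of the compound's instances score negatively against
the query (mean −0.995, percent non-null 100), the compound's instances
cluster at the reversing end of the database (enrichment −0.966), no random
permutation of instance positions was as extreme (p = 1/1001), and no random
query of the same size matched as strongly (specificity 0). The same
compound tops the modern-score table at −100.

The library mirrors the CLI one-to-one:

```python
import proteoconnect as pc

cfg = pc.PipelineConfig(seed=1)
result = pc.run_pipeline(cfg, outdir="run1")
result.signatures.trace          # flowchart counts
result.connectivity[0].name      # 'reverser'
```

Individual stages (`simulate`, `preprocess`, `diff`, `select`, `map`,
`connect`, `enrich`) are available as subcommands and as plain functions
(`generate_study`, `median_normalize`, `run_comparison`,
`select_signatures`, `map_to_human`, `summarize`, `enrich_collection`, ...)
operating on TSV/GMT/.grp files and pandas objects.

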