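# rarebench

Simulation benchmark of sequencing-depth normalization strategies for
microbiome diversity analysis.

## The problem

Amplicon (16S rRNA gene) sequencing yields OTU count tables whose library
sizes routinely vary more than ten-fold between samples. Before comparing
communities — by ecological distances (beta diversity) or by richness and
Shannon diversity (alpha diversity) — that unevenness has to be controlled.
Practitioners disagree about how: convert to proportions, rescale with
model-based size factors borrowed from gene-expression analysis
(variance-stabilizing transforms, upper-quartile scaling), take a single
random subsample of every library down to a common size *N*<sub>*L*,*m*</sub>
("rarefying"), or perform **rarefaction** proper — subsample many times,
compute the metric each time, and average the metric.

`rarebench` measures the consequences of that choice by simulation. Two
parent relative-abundance distributions **p**<sub>A</sub>, **p**<sub>B</sub>
over a shared set of OTUs are mixed at an effect size *f* ≥ 1,

  mix<sub>A</sub> ∝ *f* **p**<sub>A</sub> + **p**<sub>B</sub>,  mix<sub>B</sub> ∝ **p**<sub>A</sub> + *f* **p**<sub>B</sub>,

so *f* = 1 is an exact null. Eighty samples (40 per group) are drawn
multinomially at library sizes taken from either an empirical 26-depth pool
(resampled with replacement) or an 80-depth log-scaled ladder, rescaled to a
target median depth, and assigned to groups either at random or fully
confounded with treatment (all shallow libraries in one group). Each
simulated table is then pushed through six normalizations (raw counts,
proportions, VST, upper-quartile log-CPM, single subsampling, rarefaction),
seven distance menus (Bray-Curtis, Euclidean, Poisson deviance,
unweighted/weighted UniFrac, top mean-squared difference), three clustering
algorithms (PAM, K-means, complete-linkage hierarchical) scored by
best-matched accuracy, and hypothesis tests (PERMANOVA on distance matrices,
Wilcoxon rank-sum on alpha metrics). Rejection fractions at *f* = 1.00 give
empirical type-I error; at *f* > 1 they give power.

## Worked example

```python
import rarebench as rb

parents = rb.make_synthetic_parents(n_otus=200, seed=11)
base = rb.make_log_scaled_depths(80, 5869, 235718)
model = rb.DepthModel(kind="log_scaled", base_depths=base,
                      target_median=1000, assignment="confounded")
assign = rb.assign_depths(model, seed=7)
mix_a, mix_b = rb.mix_parents(parents.p_a, parents.p_b, effect_size=1.00)
table = rb.draw_samples(mix_a, mix_b, assign, parents.otu_ids, seed=13)

# proportions: depth leaks into the distances when it tracks the groups
dm = rb.distance_matrix(rb.normalize_relabund(table), "bray")
print(rb.permanova(dm, table.groups, n_perm=999, seed=1).p_value)
# 0.001

# rarefaction to the minimum library size: the null survives
params = rb.pick_threshold(table.depths, 0, n_iterations=25, seed=3)
from rarebench.grid import ConditionGrid, evaluate_cell
import numpy as np
dm_r, groups, _ = evaluate_cell(table, params, "rarefy", 0, "bray",
                                parents.tree, ConditionGrid(), np.arange(8))
print(rb.permanova(dm_r, groups, n_perm=999, seed=1).p_value)
# 0.408
```

Both groups were drawn from the *same* community (effect size 1.00), but the
shallow libraries all sit in group A. On proportions, PERMANOVA rejects at
its permutation floor (p = 0.001) — a pure depth artifact. After
rarefaction to a common depth the test correctly retains the null
(p = 0.408). The scripts under `analysis/` repeat this over replicated
grids: with confounded depths the raw, proportion, VST and upper-quartile
pipelines reject the true null in 100% of replicates while rarefaction
stays at 2% (see `results/type1_error.tsv`), and rarefied clustering
accuracies are at least as high, and less variable, than single-subsample
accuracies in every condition tried (`results/rarefaction_vs_subsampling.tsv`).

## Command line

`rarebench simulate | normalize | distance | cluster | test | run-grid |
summarize` wrap the same library calls; `rarebench run-grid --preset desk
--out records.tsv` runs a laptop-scale condition grid into one tidy TSV
(resumable, checksummed rows, one row per processing cell with NA cells
preserved).

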