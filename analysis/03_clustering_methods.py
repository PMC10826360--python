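#!/usr/bin/env python
"""Compare PAM, K-means and hierarchical clustering at a small effect size.

At effect size 1.15 the groups barely separate, which is where the choice of
clustering algorithm matters most.  For each normalization x distance cell,
the per-replicate accuracies of the three algorithms are compared and each
method's win rate (fraction of cells where it is at least as good as every
rival; ties count for all) is reported.  Writes
results/clustering_win_rates.tsv.
"""

from pathlib import Path

import rarebench as rb
from rarebench.clustering import method_win_rates

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    grid = rb.ConditionGrid(
        effect_sizes=(1.15,), depth_models=("empirical_resample",),
        target_medians=(1000, 10000), assignments=("randomized",),
        filters=(False,), n_replicates=10, n_otus=200, depth_scale=10.0,
        normalizations=("raw", "relabund", "rarefy"),
        threshold_quantiles=(0,), rarefaction_iterations=10, n_perm=99,
        run_alpha=False, run_permanova=False, master_seed=20259)
    records = rb.run_grid(grid)
    acc = records.dropna(subset=["accuracy"])[
        ["normalization", "metric", "replicate", "cluster_method", "accuracy"]]
    rates = method_win_rates(acc).rename("win_rate").reset_index()

    OUT.mkdir(exist_ok=True)
    rates.to_csv(OUT / "clustering_win_rates.tsv", sep="\t", index=False)
    print(rates.to_string(index=False))
    best = rates.loc[rates.win_rate.idxmax(), "cluster_method"]
    print(f"\n{best} clustering is at least as good as its rivals most "
          f"often at this effect size; accuracy differences concentrate "
          f"where the groups barely separate.")


if __name__ == "__main__":
    main()
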