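"""Headline benchmark experiments, packaged as reusable functions.

These drive the package end to end at a desk scale (200-OTU parents,
tens of replicates) to measure the quantities the benchmark is about:
empirical type-I error of PERMANOVA under each normalization, with
sequencing depth either randomized across treatment groups or fully
confounded with them, and the accuracy/stability comparison of rarefaction
against a single subsampling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import normalize as norm_mod
from .clustering import accuracy, cluster
from .diversity import permanova
from .grid import ConditionGrid, _stage_seeds, evaluate_cell, simulate_condition
from .parents import ParentPair, make_synthetic_parents

#: the normalization -> distance pairing used when each method is put to the
#: PERMANOVA test (the pairing each normalization is reported with)
TYPE1_PAIRINGS = {
    "rarefy": "bray",
    "raw": "bray",
    "relabund": "bray",
    "vst": "euclidean",
    "uq_logfc": "top_msd",
}


def _desk_grid(n_otus: int, rarefaction_iterations: int, n_perm: int,
               master_seed: int) -> ConditionGrid:
    return ConditionGrid(n_otus=n_otus, depth_scale=10.0,
                         rarefaction_iterations=rarefaction_iterations,
                         n_perm=n_perm, master_seed=master_seed)


def _distance_for(table, normalization: str, metric: str, tree,
                  grid: ConditionGrid, seeds: np.ndarray, quantile: int = 0):
    if normalization in ("subsample", "rarefy"):
        obj = norm_mod.pick_threshold(
            table.depths, quantile,
            n_iterations=(grid.rarefaction_iterations
                          if normalization == "rarefy" else 1),
            seed=int(seeds[3]))
    else:
        obj = {"raw": norm_mod.normalize_raw,
               "relabund": norm_mod.normalize_relabund,
               "vst": norm_mod.normalize_vst,
               "uq_logfc": norm_mod.normalize_uq}[normalization](table)
    return evaluate_cell(table, obj, normalization, quantile, metric, tree,
                         grid, seeds)


def type1_error_by_method(methods: dict[str, str] | None = None,
                          assignment: str = "randomized",
                          effect_size: float = 1.00,
                          depth_model: str = "empirical_resample",
                          target_median: int = 1000,
                          n_otus: int = 200,
                          n_replicates: int = 100,
                          rarefaction_iterations: int = 25,
                          n_perm: int = 999,
                          seed: int = 0,
                          alpha: float = 0.05,
                          parents: ParentPair | None = None) -> dict[str, float]:
    """Fraction of replicates with PERMANOVA p <= alpha, per normalization.

    At ``effect_size=1.00`` the two groups share one sampling distribution,
    so the returned fractions are empirical type-I error rates; at larger
    effect sizes they are power.  All normalizations are evaluated on the
    same simulated tables.
    """
    if methods is None:
        methods = dict(TYPE1_PAIRINGS)
    grid = _desk_grid(n_otus, rarefaction_iterations, n_perm, seed)
    if parents is None:
        parents = make_synthetic_parents(n_otus=n_otus, seed=seed)
    hits = {m: 0 for m in methods}
    for rep in range(n_replicates):
        seeds = _stage_seeds(seed, 0, rep)
        table, _ = simulate_condition(parents, depth_model, target_median,
                                      assignment, effect_size, False, seeds,
                                      depth_scale=grid.depth_scale)
        for method, metric in methods.items():
            cell = _distance_for(table, method, metric, parents.tree, grid,
                                 seeds)
            dm, groups, _ = cell
            res = permanova(dm, groups, n_perm=n_perm, seed=int(seeds[5]))
            hits[method] += res.p_value <= alpha
    return {m: h / n_replicates for m, h in hits.items()}


def rarefy_vs_subsample(effect_sizes=(1.15, 1.25, 1.50),
                        target_medians=(1000, 2000),
                        depth_model: str = "empirical_resample",
                        metric: str = "bray",
                        quantile: int = 15,
                        cluster_method: str = "kmeans",
                        n_otus: int = 200,
                        n_replicates: int = 25,
                        rarefaction_iterations: int = 25,
                        seed: int = 0,
                        parents: ParentPair | None = None) -> pd.DataFrame:
    """Clustering-accuracy medians and IQRs: rarefaction vs one subsampling.

    Both strategies discard the shallowest ``quantile`` percent of samples,
    then cluster the (averaged or single-draw) distance matrix; one row per
    (effect size, median depth) condition.
    """
    grid = _desk_grid(n_otus, rarefaction_iterations, n_perm=99, master_seed=seed)
    if parents is None:
        parents = make_synthetic_parents(n_otus=n_otus, seed=seed)
    rows = []
    for ci, (es, tm) in enumerate(
            [(e, t) for e in effect_sizes for t in target_medians]):
        acc = {"rarefy": [], "subsample": []}
        for rep in range(n_replicates):
            seeds = _stage_seeds(seed, ci, rep)
            table, _ = simulate_condition(parents, depth_model, tm,
                                          "randomized", es, False, seeds,
                                          depth_scale=grid.depth_scale)
            for method in ("rarefy", "subsample"):
                dm, groups, n_removed = _distance_for(
                    table, method, metric, parents.tree, grid, seeds,
                    quantile=quantile)
                labels = cluster(dm, cluster_method, seed=int(seeds[4]))
                acc[method].append(accuracy(labels, groups, n_removed))
        row = {"effect_size": es, "target_median": tm}
        for method, values in acc.items():
            q1, med, q3 = np.percentile(values, [25, 50, 75])
            row[f"{method}_median"] = med
            row[f"{method}_iqr"] = q3 - q1
        rows.append(row)
    return pd.DataFrame(rows)
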