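"""Condition-grid enumeration and the end-to-end simulation driver.

A condition is one combination of (effect size, depth model, target median
depth, depth-group assignment, rare-OTU filtering).  For every condition and
replicate, one count table is simulated and then shared across every
normalization x threshold x distance x clustering cell, mirroring how the
benchmark normalizes the same simulated data many ways.  Results stream into
one long-format table with per-row checksums so interrupted runs can resume.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from . import depths as depths_mod
from . import normalize as norm_mod
from .clustering import CLUSTER_METHODS, accuracy, cluster
from .distances import ADMISSIBLE_PAIRS, DISTANCE_METHODS, DistanceMatrix, \
    distance_matrix
from .diversity import permanova, richness, shannon, wilcoxon_two_sample
from .parents import ParentPair, make_synthetic_parents
from .simulate import EFFECT_SIZES, draw_samples, filter_rare_otus, mix_parents

logger = logging.getLogger(__name__)

#: the full normalization menu counted in the processing grid; the two
#: gene-expression scaling variants (TMM, RLE) are enumerated but not
#: evaluated here.
COUNTED_ONLY_NORMALIZATIONS = ("tmm", "rle")

RECORD_COLUMNS = [
    "depth_model", "target_median", "assignment", "effect_size", "filtered",
    "replicate", "normalization", "threshold_quantile", "metric",
    "cluster_method", "status", "accuracy", "p_value", "n_removed",
    "vst_negative_fraction", "seed", "checksum",
]


@dataclass
class ConditionGrid:
    """The factors that define one batch of simulations."""

    effect_sizes: tuple = EFFECT_SIZES
    depth_models: tuple = ("empirical_resample", "log_scaled")
    target_medians: tuple = depths_mod.TARGET_MEDIANS
    assignments: tuple = ("randomized", "confounded")
    filters: tuple = (True, False)
    n_replicates: int = 100
    master_seed: int = 0
    # scale of the simulated communities / processing
    n_otus: int = 2000
    n_samples: int = 80
    normalizations: tuple = ("raw", "relabund", "vst", "uq_logfc",
                             "subsample", "rarefy")
    threshold_quantiles: tuple = norm_mod.THRESHOLD_QUANTILES
    rarefaction_iterations: int = 100
    n_perm: int = 999
    depth_scale: float = 1.0   # divide base depth range by this (desk runs)
    run_alpha: bool = True
    run_clustering: bool = True
    run_permanova: bool = True

    def conditions(self) -> list[tuple]:
        return list(product(self.depth_models, self.target_medians,
                            self.assignments, self.effect_sizes, self.filters))

    def n_conditions(self) -> int:
        return len(self.conditions())


def preset(name: str, master_seed: int = 0) -> ConditionGrid:
    """Named grids: ``wnwn`` (the original 160-dataset layout), ``full``
    (the expanded study), and ``desk`` (a 200-OTU, 25-replicate scale that
    runs on a laptop)."""
    if name == "wnwn":
        return ConditionGrid(target_medians=(1000, 2000, 5000, 10000),
                             depth_models=("empirical_resample",),
                             assignments=("randomized",),
                             filters=(True,), n_replicates=5,
                             master_seed=master_seed)
    if name == "full":
        return ConditionGrid(master_seed=master_seed)
    if name == "desk":
        return ConditionGrid(
            effect_sizes=(1.00, 1.15, 1.25, 1.50),
            depth_models=("empirical_resample", "log_scaled"),
            target_medians=(1000, 10000),
            assignments=("randomized", "confounded"),
            filters=(False,),
            n_replicates=25, n_otus=200, rarefaction_iterations=25,
            threshold_quantiles=(0, 15), depth_scale=10.0,
            master_seed=master_seed)
    raise ValueError(f"unknown preset {name!r}")


def enumerate_wnwn_grid() -> int:
    """Number of simulated data sets in the original benchmark layout."""
    g = preset("wnwn")
    return g.n_conditions() * g.n_replicates


def count_processing_combinations(
        threshold_quantiles: tuple = norm_mod.THRESHOLD_QUANTILES,
        n_distances: int = len(DISTANCE_METHODS) + 1) -> int:
    """Processing combinations per simulated data set.

    2 filter settings x (4 whole-table scalings + 2 counted-only scalings +
    subsampling and rarefaction at each threshold quantile) x the distance
    menu (the seven published calculations, including the one never
    discussed).
    """
    n_norm = 4 + len(COUNTED_ONLY_NORMALIZATIONS) + 2 * len(threshold_quantiles)
    return 2 * n_norm * n_distances


def _stage_seeds(master_seed: int, cond_idx: int, replicate: int,
                 n: int = 8) -> np.ndarray:
    """Collision-free per-stage seeds via a counter-based seed sequence."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(cond_idx, replicate))
    return np.random.default_rng(ss).integers(2 ** 31, size=n)


def _base_depths(kind: str, seed: int, depth_scale: float) -> np.ndarray:
    lo = max(int(depths_mod.DEPTH_MIN_DEFAULT / depth_scale), 2)
    hi = int(depths_mod.DEPTH_MAX_DEFAULT / depth_scale)
    if kind == "empirical_resample":
        return depths_mod.make_empirical_depths(
            26, mean=depths_mod.EMPIRICAL_MEAN_DEFAULT / depth_scale,
            sd=depths_mod.EMPIRICAL_SD_DEFAULT / depth_scale,
            min_depth=lo, max_depth=hi, seed=seed)
    return depths_mod.make_log_scaled_depths(80, lo, hi)


def simulate_condition(parents: ParentPair, depth_model: str, target_median: int,
                       assignment: str, effect_size: float, filtered: bool,
                       seeds: np.ndarray, depth_scale: float = 1.0,
                       n_samples: int = 80):
    """One replicate's count table (and its depth assignment) for a condition."""
    base = _base_depths(depth_model, int(seeds[0]), depth_scale)
    model = depths_mod.DepthModel(kind=depth_model, base_depths=base,
                                  target_median=target_median,
                                  assignment=assignment)
    assign = depths_mod.assign_depths(model, int(seeds[1]), n_samples=n_samples)
    mix_a, mix_b = mix_parents(parents.p_a, parents.p_b, effect_size)
    table = draw_samples(mix_a, mix_b, assign, parents.otu_ids,
                         seed=int(seeds[2]), effect_size=effect_size)
    if filtered:
        table = filter_rare_otus(table)
    return table, assign


def _normalized_tables(table, grid: ConditionGrid, seeds: np.ndarray):
    """Yield (normalization, threshold_quantile, NormalizedTable-or-spec)."""
    for method in grid.normalizations:
        if method == "raw":
            yield method, 0, norm_mod.normalize_raw(table)
        elif method == "relabund":
            yield method, 0, norm_mod.normalize_relabund(table)
        elif method == "vst":
            yield method, 0, norm_mod.normalize_vst(table)
        elif method == "uq_logfc":
            yield method, 0, norm_mod.normalize_uq(table)
        elif method in ("subsample", "rarefy"):
            for q in grid.threshold_quantiles:
                params = norm_mod.pick_threshold(
                    table.depths, q,
                    n_iterations=(grid.rarefaction_iterations
                                  if method == "rarefy" else 1),
                    seed=int(seeds[3]) + q)
                yield method, q, params


def evaluate_cell(table, norm_or_params, normalization: str, quantile: int,
                  metric: str, tree, grid: ConditionGrid, seeds: np.ndarray):
    """Distance matrix (possibly rarefaction-averaged) for one processing cell.

    Returns ``(dm, retained_groups, n_removed)`` or ``None`` for an
    inadmissible pairing.
    """
    if normalization == "rarefy":
        params = norm_or_params
        if metric not in ADMISSIBLE_PAIRS["rarefy"]:
            return None
        probe = norm_mod.subsample_once(table, params, quantile)

        def metric_fn(draw):
            nt = norm_mod.NormalizedTable(
                values=draw.astype(float), sample_ids=probe.sample_ids,
                otu_ids=list(table.otu_ids), groups=probe.groups,
                method="subsample", threshold_quantile=quantile)
            return distance_matrix(nt, metric, tree=tree).values

        avg, retained_ids, removed = norm_mod.rarefy_metric(
            table, params, metric_fn, quantile)
        dm = DistanceMatrix(values=avg, sample_ids=retained_ids, method=metric,
                            provenance={"normalization": "rarefy",
                                        "threshold_quantile": quantile,
                                        "n_iterations": params.n_iterations})
        return dm, probe.groups, len(removed)
    if normalization == "subsample":
        norm = norm_mod.subsample_once(table, norm_or_params, quantile)
    else:
        norm = norm_or_params
    dm = distance_matrix(norm, metric, tree=tree)
    if dm is None:
        return None
    return dm, norm.groups, len(norm.removed_samples)


def _alpha_values(table, normalization: str, norm_or_params, quantile: int):
    """Per-sample richness and Shannon values for one normalization, or None.

    The variance-stabilized output is excluded (negative values); the
    upper-quartile log output is excluded from richness (every cell nonzero).
    """
    if normalization == "vst":
        return None
    if normalization == "rarefy":
        params = norm_or_params

        def metric_fn(draw):
            return np.column_stack([[richness(r) for r in draw],
                                    [shannon(r) for r in draw]])

        avg, retained_ids, removed = norm_mod.rarefy_metric(
            table, params, metric_fn, quantile)
        groups = table.groups[[table.sample_ids.index(s) for s in retained_ids]]
        return {"richness": avg[:, 0], "shannon": avg[:, 1]}, groups
    if normalization == "subsample":
        norm = norm_mod.subsample_once(table, norm_or_params, quantile)
    else:
        norm = norm_or_params
    out = {"shannon": np.array([shannon(r) for r in norm.values])}
    if normalization != "uq_logfc":
        out["richness"] = np.array([richness(r) for r in norm.values])
    return out, norm.groups


def _row_checksum(values: list) -> str:
    # floats canonicalized to 12 significant digits so the checksum is
    # stable across the TSV round-trip
    parts = [f"{v:.12g}" if isinstance(v, (float, np.floating)) else str(v)
             for v in values]
    return hashlib.md5("\t".join(parts).encode()).hexdigest()[:8]


def run_grid(grid: ConditionGrid, out_path: str | Path | None = None,
             parents: ParentPair | None = None,
             resume: bool = True) -> pd.DataFrame:
    """Run every (condition, replicate, processing cell) and return tidy records.

    Each simulated table is shared across all normalization/distance/
    clustering cells.  Inadmissible pairings are recorded with status ``na``
    rather than dropped.  If ``out_path`` exists and ``resume`` is set,
    completed (condition, replicate) blocks with intact checksums are reused.
    """
    if parents is None:
        parents = make_synthetic_parents(n_otus=grid.n_otus,
                                         seed=grid.master_seed)
    out_path = Path(out_path) if out_path is not None else None
    done_keys: set[tuple] = set()
    old_rows = None
    key_cols = ["depth_model", "target_median", "assignment", "effect_size",
                "filtered", "replicate"]
    if out_path is not None and out_path.exists() and resume:
        old_rows = pd.read_csv(out_path, sep="\t")
        ok = old_rows.apply(
            lambda r: _row_checksum(list(r[RECORD_COLUMNS[:-1]])) == r["checksum"],
            axis=1)
        n_bad = int((~ok).sum())
        if n_bad:
            logger.warning("discarding %d corrupt records; their replicate "
                           "blocks will be recomputed", n_bad)
            bad_keys = set(map(tuple,
                               old_rows.loc[~ok, key_cols].itertuples(index=False)))
            ok &= ~old_rows[key_cols].apply(tuple, axis=1).isin(bad_keys)
        old_rows = old_rows[ok]
        done_keys = set(map(tuple, old_rows[key_cols].itertuples(index=False)))

    rows: list[list] = []
    for cond_idx, cond in enumerate(grid.conditions()):
        depth_model, target_median, assignment, effect_size, filtered = cond
        for rep in range(grid.n_replicates):
            key = (depth_model, target_median, assignment, effect_size,
                   filtered, rep)
            if key in done_keys:
                continue
            seeds = _stage_seeds(grid.master_seed, cond_idx, rep)
            table, _ = simulate_condition(parents, *cond, seeds=seeds,
                                          depth_scale=grid.depth_scale,
                                          n_samples=grid.n_samples)
            rows.extend(_replicate_rows(table, parents, grid, cond, rep, seeds))
            logger.info("condition %d/%d replicate %d done",
                        cond_idx + 1, grid.n_conditions(), rep)

    new = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    records = (pd.concat([old_rows, new], ignore_index=True)
               if old_rows is not None and len(old_rows) else new)
    records = records.sort_values(key_cols + ["normalization",
                                              "threshold_quantile", "metric",
                                              "cluster_method"],
                                  kind="stable").reset_index(drop=True)
    if out_path is not None:
        out_path.parent.mkdir(parents=True, exist_ok=True)
        records.to_csv(out_path, sep="\t", index=False)
    return records


def _replicate_rows(table, parents, grid, cond, rep, seeds) -> list[list]:
    depth_model, target_median, assignment, effect_size, filtered = cond
    base = [depth_model, target_median, assignment, effect_size, filtered, rep]
    seed_val = int(seeds[0])
    rows: list[list] = []

    def add(normalization, quantile, metric, cluster_method, status,
            acc, p, n_removed, neg_frac):
        # floats throughout so checksums survive the TSV round-trip
        vals = base + [normalization, quantile, metric, cluster_method,
                       status, float(acc), float(p), float(n_removed),
                       float(neg_frac), seed_val]
        rows.append(vals + [_row_checksum(vals)])

    for normalization, quantile, obj in _normalized_tables(table, grid, seeds):
        neg_frac = np.nan
        if normalization == "vst":
            neg_frac = norm_mod.detect_negative_fraction(obj)[0]
        # beta diversity: distances -> clustering + permanova
        for metric in (DISTANCE_METHODS
                       if grid.run_clustering or grid.run_permanova else ()):
            cell = evaluate_cell(table, obj, normalization, quantile, metric,
                                 parents.tree, grid, seeds)
            if cell is None:
                add(normalization, quantile, metric, "-", "na",
                    np.nan, np.nan, np.nan, neg_frac)
                continue
            dm, groups, n_removed = cell
            if grid.run_clustering:
                for cm in CLUSTER_METHODS:
                    labels = cluster(dm, cm, seed=int(seeds[4]))
                    acc = accuracy(labels, groups, n_removed)
                    add(normalization, quantile, metric, cm, "ok",
                        acc, np.nan, n_removed, neg_frac)
            if grid.run_permanova:
                res = permanova(dm, groups, n_perm=grid.n_perm,
                                seed=int(seeds[5]))
                add(normalization, quantile, metric, "permanova", "ok",
                    np.nan, res.p_value, n_removed, neg_frac)
        # alpha diversity: wilcoxon on richness / shannon
        if grid.run_alpha:
            alpha = _alpha_values(table, normalization, obj, quantile)
            if alpha is None:
                for m in ("richness", "shannon"):
                    add(normalization, quantile, m, "wilcoxon", "na",
                        np.nan, np.nan, np.nan, neg_frac)
            else:
                values, groups = alpha
                for m in ("richness", "shannon"):
                    if m not in values:
                        add(normalization, quantile, m, "wilcoxon", "na",
                            np.nan, np.nan, np.nan, neg_frac)
                        continue
                    res = wilcoxon_two_sample(values[m][groups == "A"],
                                              values[m][groups == "B"],
                                              metric=m)
                    add(normalization, quantile, m, "wilcoxon", "ok",
                        np.nan, res.p_value, np.nan, neg_frac)
    return rows


def summarize(records: pd.DataFrame,
              value_col: str = "accuracy") -> pd.DataFrame:
    """Median, empirical 95% interval and IQR of a value per condition."""
    sub = records.dropna(subset=[value_col])
    key_cols = [c for c in ["depth_model", "target_median", "assignment",
                            "effect_size", "filtered", "normalization",
                            "threshold_quantile", "metric", "cluster_method"]
                if c in sub.columns]
    if len(sub) < 2:
        raise ValueError("need at least two replicates to summarize")

    def agg(g: pd.Series) -> pd.Series:
        q = np.percentile(g, [2.5, 25, 50, 75, 97.5])
        return pd.Series({"median": q[2], "ci_lo": q[0], "ci_hi": q[4],
                          "iqr": q[3] - q[1], "n": len(g)})

    return (sub.groupby(key_cols, dropna=False)[value_col]
            .apply(agg).unstack().reset_index())
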