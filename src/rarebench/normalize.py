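"""Depth-normalization strategies for OTU count tables.

Six strategies are benchmarked:

- ``raw``       : untouched counts;
- ``relabund``  : per-sample proportions;
- ``vst``       : variance-stabilizing transform under a fitted negative-
                  binomial mean-dispersion curve (may produce negatives);
- ``uq_logfc``  : upper-quartile-scaled log2 counts-per-million;
- ``subsample`` : one draw without replacement to the minimum library size;
- ``rarefy``    : many such draws, with the *metric* (not the counts)
                  averaged across draws.

``subsample``/``rarefy`` first pick a minimum library size N_L_m from a
quantile of the depth distribution; samples below it are discarded and count
against downstream accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .simulate import CountTable

logger = logging.getLogger(__name__)

THRESHOLD_QUANTILES = (0, 5, 10, 15, 20, 25, 40)
NORMALIZATION_METHODS = ("raw", "relabund", "vst", "uq_logfc", "subsample", "rarefy")


@dataclass
class RarefactionParams:
    """Minimum library size plus subsampling controls."""

    n_l_m: int                # minimum library size (reads)
    n_iterations: int = 100
    seed: int = 0
    removed_samples: list[str] = field(default_factory=list)
    removed_mask: np.ndarray | None = None  # positional removal mask, if known

    def __post_init__(self) -> None:
        if self.n_l_m < 1:
            raise ValueError("minimum library size must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class NormalizedTable:
    """Real-valued normalized matrix over the retained samples."""

    values: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    groups: np.ndarray
    method: str
    threshold_quantile: int = 0
    removed_samples: list[str] = field(default_factory=list)
    n_iterations: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.method not in NORMALIZATION_METHODS:
            raise ValueError(f"unknown normalization {self.method!r}")
        if set(self.removed_samples) & set(self.sample_ids):
            raise ValueError("removed samples overlap retained samples")


def pick_threshold(depths: np.ndarray, quantile: int,
                   n_iterations: int = 100, seed: int = 0) -> RarefactionParams:
    """Minimum library size at a percentile of the depth distribution.

    Uses the linear-interpolation empirical quantile, so with distinct depths
    a quantile of q% marks exactly q% of the samples for removal; N_L_m is
    the smallest retained depth.  Quantile 0 keeps every sample.
    """
    if quantile not in THRESHOLD_QUANTILES:
        raise ValueError(f"quantile must be one of {THRESHOLD_QUANTILES}")
    depths = np.asarray(depths)
    cutoff = np.quantile(depths, quantile / 100)
    removed_mask = depths < cutoff
    n_l_m = int(depths[~removed_mask].min())
    return RarefactionParams(n_l_m=n_l_m, n_iterations=n_iterations, seed=seed,
                             removed_mask=removed_mask)


def _retained(table: CountTable, params: RarefactionParams | None):
    if params is None:
        mask = np.ones(table.n_samples, dtype=bool)
    elif params.removed_mask is not None:
        mask = ~params.removed_mask
    else:
        mask = table.depths >= params.n_l_m
    removed = [s for s, m in zip(table.sample_ids, mask) if not m]
    retained_ids = [s for s, m in zip(table.sample_ids, mask) if m]
    return mask, retained_ids, removed


def normalize_raw(table: CountTable) -> NormalizedTable:
    return NormalizedTable(values=table.counts.astype(float),
                           sample_ids=list(table.sample_ids),
                           otu_ids=list(table.otu_ids),
                           groups=table.groups, method="raw")


def normalize_relabund(table: CountTable) -> NormalizedTable:
    """Per-sample relative abundances (rows sum to one)."""
    depths = table.depths
    if (depths == 0).any():
        raise ValueError("cannot compute proportions for zero-depth samples")
    return NormalizedTable(values=table.counts / depths[:, None],
                           sample_ids=list(table.sample_ids),
                           otu_ids=list(table.otu_ids),
                           groups=table.groups, method="relabund")


def subsample_counts(counts_row: np.ndarray, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` reads without replacement (multivariate hypergeometric)."""
    total = int(counts_row.sum())
    if n > total:
        raise ValueError(f"cannot draw {n} reads from a depth-{total} sample")
    if n == total:
        return counts_row.copy()
    return rng.multivariate_hypergeometric(counts_row.astype(np.int64), n)


def subsample_once(table: CountTable, params: RarefactionParams,
                   quantile: int = 0) -> NormalizedTable:
    """Single subsampling of each retained sample to N_L_m reads."""
    mask, retained_ids, removed = _retained(table, params)
    sub = table.counts[mask]
    if (sub.sum(axis=1) < params.n_l_m).any():
        raise ValueError("a retained sample is shallower than N_L_m")
    rng = np.random.default_rng(params.seed)
    out = np.vstack([subsample_counts(row, params.n_l_m, rng) for row in sub])
    return NormalizedTable(values=out.astype(float), sample_ids=retained_ids,
                           otu_ids=list(table.otu_ids), groups=table.groups[mask],
                           method="subsample", threshold_quantile=quantile,
                           removed_samples=removed + list(params.removed_samples))


def rarefy_metric(table: CountTable, params: RarefactionParams, metric,
                  quantile: int = 0):
    """Rarefaction: average a metric over repeated subsamplings.

    ``metric`` maps an integer (retained-samples x OTUs) count matrix to an
    array (per-sample alpha values, or a square distance matrix); the
    elementwise mean over ``params.n_iterations`` independent subsamplings is
    returned together with the retained sample ids and removed ids.  Only the
    metric is averaged — counts from different draws are never pooled.
    """
    mask, retained_ids, removed = _retained(table, params)
    sub = table.counts[mask]
    if (sub.sum(axis=1) < params.n_l_m).any():
        raise ValueError("a retained sample is shallower than N_L_m")
    rng = np.random.default_rng(params.seed)
    acc = None
    for _ in range(params.n_iterations):
        draw = np.vstack([subsample_counts(row, params.n_l_m, rng) for row in sub])
        value = np.asarray(metric(draw), dtype=float)
        acc = value if acc is None else acc + value
    return acc / params.n_iterations, retained_ids, removed


def fit_dispersion_curve(counts: np.ndarray, size_factors: np.ndarray
                         ) -> tuple[float, float]:
    """Method-of-moments fit of the dispersion curve alpha(mu) = a0/mu + a1.

    Per-OTU dispersions are estimated from the normalized counts as
    ``(var - xim * mu) / mu**2`` with ``xim = mean(1 / size_factor)`` (the
    Poisson part of the variance under scaling), then regressed on 1/mu.
    """
    q = counts / size_factors[:, None]
    mu = q.mean(axis=0)
    var = q.var(axis=0, ddof=1)
    xim = float(np.mean(1.0 / size_factors))
    ok = mu > 0
    mu, var = mu[ok], var[ok]
    alpha = (var - xim * mu) / mu**2
    use = alpha > 0
    if use.sum() < 2:
        logger.warning("too few overdispersed OTUs; using near-Poisson curve")
        return 1e-8, 1e-8
    x = np.column_stack([1.0 / mu[use], np.ones(use.sum())])
    (a0, a1), *_ = np.linalg.lstsq(x, alpha[use], rcond=None)
    if a1 <= 0:
        logger.warning("asymptotic dispersion estimate %.3g <= 0; "
                       "falling back to 1e-8", a1)
        a1 = 1e-8
    if a0 <= 0:
        a0 = 1e-8
    return float(a0), float(a1)


def vst_transform(q: np.ndarray, a0: float, a1: float) -> np.ndarray:
    """Closed-form VST for the curve alpha(mu) = a0/mu + a1.

    Monotone in ``q`` and asymptotically ``log2(q)`` as ``q`` grows; small
    normalized counts can map below zero.
    """
    return np.log2((1 + a0 + 2 * a1 * q
                    + 2 * np.sqrt(a1 * q * (1 + a0 + a1 * q))) / (4 * a1))


def median_of_ratios_size_factors(counts: np.ndarray,
                                  pseudocount: float = 1.0) -> np.ndarray:
    """Size factors: per-sample median ratio to the geometric-mean reference."""
    y = counts + pseudocount
    log_ref = np.log(y).mean(axis=0)
    ratios = np.log(y) - log_ref
    return np.exp(np.median(ratios, axis=1))


def normalize_vst(table: CountTable, pseudocount: float = 1.0) -> NormalizedTable:
    """Variance-stabilizing transform of pseudocounted, size-factor-scaled counts."""
    if table.n_samples < 2:
        raise ValueError("VST needs at least two samples")
    y = table.counts + pseudocount
    sf = median_of_ratios_size_factors(table.counts, pseudocount)
    a0, a1 = fit_dispersion_curve(y, sf)
    values = vst_transform(y / sf[:, None], a0, a1)
    return NormalizedTable(values=values, sample_ids=list(table.sample_ids),
                           otu_ids=list(table.otu_ids), groups=table.groups,
                           method="vst")


def detect_negative_fraction(norm: NormalizedTable) -> tuple[float, bool]:
    """Fraction of strictly negative cells, and whether any exist."""
    if norm.method != "vst":
        raise ValueError("negative-value diagnostics apply to VST output")
    frac = float((norm.values < 0).mean())
    return frac, bool(frac > 0)


def normalize_uq(table: CountTable, pseudocount: float = 1.0) -> NormalizedTable:
    """Upper-quartile log2 counts-per-million.

    Per-sample scaling factors are the 75th percentile of that sample's
    nonzero counts divided by its library size, rescaled to geometric mean
    one.  Output is log2 CPM against the effective library size
    (depth x factor), with the pseudocount added on the CPM scale so that
    doubling every count in a sample leaves its row unchanged.
    """
    if table.n_samples < 2:
        raise ValueError("UQ normalization needs at least two samples")
    counts = table.counts
    depths = table.depths.astype(float)
    if (depths == 0).any():
        raise ValueError("a sample has no counts; cannot UQ-normalize")
    factors = np.array([np.quantile(row[row > 0], 0.75) for row in counts])
    factors = factors / depths
    factors = factors / np.exp(np.mean(np.log(factors)))
    eff_lib = depths * factors
    values = np.log2(counts / eff_lib[:, None] * 1e6 + pseudocount)
    return NormalizedTable(values=values, sample_ids=list(table.sample_ids),
                           otu_ids=list(table.otu_ids), groups=table.groups,
                           method="uq_logfc")
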