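"""Pairwise dissimilarities between community samples.

Implements the distance menu used in the benchmark — Bray-Curtis, Euclidean,
a Poisson model-based dissimilarity, unweighted/weighted UniFrac and the
top-k mean-squared-difference on log-scale data — together with the pairing
rules that say which normalization each distance may be computed from.
UniFrac is delegated to scikit-bio; the others are computed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio.diversity import beta_diversity

DISTANCE_METHODS = ("bray", "euclidean", "poisson", "unifrac_u", "unifrac_w",
                    "top_msd")

#: which (normalization -> distances) pairs are admissible.  Raw counts feed
#: the count-based distances; proportions feed the composition-based ones;
#: subsampled/rarefied counts feed everything; the variance-stabilized output
#: (which can be negative) only feeds Euclidean; upper-quartile log output
#: only feeds top-MSD.
ADMISSIBLE_PAIRS: dict[str, tuple[str, ...]] = {
    "raw": ("bray", "euclidean", "poisson", "unifrac_w"),
    "relabund": ("bray", "unifrac_u", "unifrac_w"),
    "subsample": DISTANCE_METHODS,
    "rarefy": DISTANCE_METHODS,
    "vst": ("euclidean",),
    "uq_logfc": ("top_msd",),
}

#: extra pairings only available in "reproduce-pathology" mode: distances
#: whose formulas sum abundances and become meaningless on negative input.
PATHOLOGY_PAIRS: dict[str, tuple[str, ...]] = {
    "vst": ("bray", "unifrac_w"),
}


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal dissimilarity matrix with provenance."""

    values: np.ndarray
    sample_ids: list[str]
    method: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match sample_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0, atol=1e-10):
            raise ValueError("diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """sum|x - y| / sum(x + y); on nonnegative input this lies in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero samples")
    return float(np.abs(x - y).sum() / denom)


def euclidean(x: np.ndarray, y: np.ndarray) -> float:
    """Root sum of squared differences; sign-safe, so negatives are fine."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    return float(np.sqrt((d * d).sum()))


def _bray_matrix(values: np.ndarray) -> np.ndarray:
    row_sums = values.sum(axis=1)
    if (row_sums == 0).any():
        raise ValueError("Bray-Curtis undefined for all-zero samples")
    num = squareform(pdist(values, metric="cityblock"), checks=False)
    denom = row_sums[:, None] + row_sums[None, :]
    out = num / denom
    np.fill_diagonal(out, 0.0)
    return out


def poisson_gof_alpha(counts: np.ndarray,
                      grid: np.ndarray | None = None) -> float:
    """Power-transform exponent chosen by a chi-square goodness-of-fit rule.

    Searches a grid of exponents and picks the one whose transformed table's
    Pearson chi-square statistic (against the independence expectation) is
    closest to its degrees of freedom — the transformation rule published
    with the Poisson dissimilarity.
    """
    if grid is None:
        grid = np.linspace(0.01, 1.0, 50)
    n, g = counts.shape
    dof = (n - 1) * (g - 1)

    def gof(alpha: float) -> float:
        x = counts.astype(float) ** alpha
        e = np.outer(x.sum(axis=1), x.sum(axis=0)) / x.sum()
        ok = e > 0
        return float((((x - e) ** 2 / np.where(ok, e, 1.0))[ok]).sum())

    stats = np.array([gof(a) for a in grid])
    return float(grid[int(np.argmin(np.abs(stats - dof)))])


def poisson_distance(counts: np.ndarray, sample_ids: list[str],
                     transform: bool = True) -> DistanceMatrix:
    """Poisson log-likelihood-ratio dissimilarity between count samples.

    For each pair the counts are pooled per OTU and split by the two samples'
    total-count ratio to give null expected rates; the dissimilarity is the
    summed Poisson deviance of the observed counts from those shared rates.
    Counts are first power-transformed (``x**alpha``) to damp overdispersion.
    """
    counts = np.asarray(counts)
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("Poisson distance requires integer counts")
    x = counts.astype(float)
    alpha = poisson_gof_alpha(counts) if transform else 1.0
    x = x ** alpha
    totals = x.sum(axis=1)
    n = x.shape[0]
    out = np.zeros((n, n))
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(n):
            for j in range(i + 1, n):
                pooled = x[i] + x[j]
                si = totals[i] / (totals[i] + totals[j])
                mu_i = pooled * si
                mu_j = pooled * (1 - si)
                ti = np.where(x[i] > 0, x[i] * np.log(x[i] / mu_i), 0.0)
                tj = np.where(x[j] > 0, x[j] * np.log(x[j] / mu_j), 0.0)
                out[i, j] = out[j, i] = ti.sum() + tj.sum()
    return DistanceMatrix(values=out, sample_ids=list(sample_ids),
                          method="poisson",
                          provenance={"power_alpha": alpha})


def unifrac(values: np.ndarray, sample_ids: list[str], otu_ids: list[str],
            tree, weighted: bool, normalized_w: bool = True) -> DistanceMatrix:
    """Unweighted or weighted UniFrac via scikit-bio.

    Unweighted compares branch memberships only (presence/absence of the
    OTUs descending from each branch); weighted accumulates branch-length-
    scaled differences in the fraction of each sample's reads below the
    branch, divided by the maximum attainable value when ``normalized_w``.
    """
    values = np.asarray(values)
    if (values < 0).any():
        raise ValueError("UniFrac requires nonnegative abundances")
    tree_tips = {t.name for t in tree.tips()}
    missing = [o for o in otu_ids if o not in tree_tips]
    if missing:
        raise ValueError(f"OTUs missing from tree: {missing[:5]}")
    if weighted:
        dm = beta_diversity("weighted_unifrac", values, ids=sample_ids,
                            taxa=otu_ids, tree=tree, normalized=normalized_w,
                            validate=False)
        method = "unifrac_w"
    else:
        dm = beta_diversity("unweighted_unifrac", (values > 0).astype(int),
                            ids=sample_ids, taxa=otu_ids, tree=tree,
                            validate=False)
        method = "unifrac_u"
    return DistanceMatrix(values=dm.data, sample_ids=list(sample_ids),
                          method=method,
                          provenance={"normalized_w": normalized_w})


def top_msd(values: np.ndarray, sample_ids: list[str],
            n_top: int = 500) -> DistanceMatrix:
    """Root of the mean of the ``n_top`` largest squared per-OTU differences.

    Intended for log-scale input (upper-quartile log-CPM); with ``n_top``
    equal to the OTU count it collapses to the root-mean-square difference.
    """
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    if n_top > g:
        warnings.warn(f"n_top={n_top} exceeds {g} OTUs; clamping")
        n_top = g
    out = np.zeros((n, n))
    for i in range(n):
        sq = (values[i + 1:] - values[i]) ** 2
        if n_top < g:
            part = np.partition(sq, g - n_top, axis=1)[:, g - n_top:]
        else:
            part = sq
        d = np.sqrt(part.mean(axis=1))
        out[i, i + 1:] = d
        out[i + 1:, i] = d
    return DistanceMatrix(values=out, sample_ids=list(sample_ids),
                          method="top_msd", provenance={"n_top": n_top})


def is_admissible(normalization: str, method: str, pathology: bool = False) -> bool:
    if method in ADMISSIBLE_PAIRS.get(normalization, ()):
        return True
    return pathology and method in PATHOLOGY_PAIRS.get(normalization, ())


def distance_matrix(norm, method: str, tree=None, n_top: int = 500,
                    pathology: bool = False) -> DistanceMatrix | None:
    """Dispatch a normalized table to one distance method.

    Returns ``None`` (an NA record) for inadmissible normalization/distance
    pairs instead of raising, so grid runs can log them; the pathology flag
    additionally allows the negative-value-sensitive pairs.
    """
    if method not in DISTANCE_METHODS:
        raise ValueError(f"unknown distance method {method!r}")
    if not is_admissible(norm.method, method, pathology):
        return None
    v = norm.values
    ids = list(norm.sample_ids)
    if method == "bray":
        out = DistanceMatrix(values=_bray_matrix(v), sample_ids=ids,
                             method="bray")
    elif method == "euclidean":
        out = DistanceMatrix(values=squareform(pdist(v, metric="euclidean"),
                                               checks=False),
                             sample_ids=ids, method="euclidean")
    elif method == "poisson":
        out = poisson_distance(v, ids)
    elif method in ("unifrac_u", "unifrac_w"):
        out = unifrac(v, ids, list(norm.otu_ids), tree,
                      weighted=(method == "unifrac_w"))
    else:
        out = top_msd(v, ids, n_top=n_top)
    out.provenance.update(normalization=norm.method,
                          threshold_quantile=norm.threshold_quantile)
    return out
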