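"""Parent community distributions for the two simulated treatment groups.

Each simulated data set is built by mixing two "parent" relative-abundance
vectors defined over a shared OTU set.  Parents can be generated synthetically
(lognormal species-abundance distributions with a controllable support
overlap, plus a random bifurcating phylogeny for UniFrac) or derived from a
real count table by pooling two groups of samples.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode


@dataclass
class ParentPair:
    """Two relative-abundance vectors over a shared, ordered OTU set.

    ``p_a`` and ``p_b`` are nonnegative, sum to one, and are indexed
    identically by ``otu_ids``.  ``tree`` is a rooted phylogeny with branch
    lengths whose leaf names are exactly ``otu_ids``.
    """

    otu_ids: list[str]
    p_a: np.ndarray
    p_b: np.ndarray
    tree: TreeNode | None = None

    def __post_init__(self) -> None:
        self.p_a = np.asarray(self.p_a, dtype=float)
        self.p_b = np.asarray(self.p_b, dtype=float)
        if self.p_a.shape != self.p_b.shape or len(self.p_a) != len(self.otu_ids):
            raise ValueError("p_a, p_b and otu_ids must have identical length")
        for name, p in (("p_a", self.p_a), ("p_b", self.p_b)):
            if (p < 0).any():
                raise ValueError(f"{name} has negative entries")
            if abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} does not sum to 1 (got {p.sum()!r})")
        if self.tree is not None:
            leaves = {t.name for t in self.tree.tips()}
            if leaves != set(self.otu_ids):
                raise ValueError("tree leaves do not match otu_ids")

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)


def random_bifurcating_tree(otu_ids: list[str], rng: np.random.Generator,
                            branch_scale: float = 1.0) -> TreeNode:
    """Random bifurcating topology with exponential branch lengths.

    Built by repeatedly joining two randomly chosen subtrees until one root
    remains (a random coalescent-style topology).  Branch lengths are iid
    Exponential(``branch_scale``).
    """
    if len(otu_ids) < 2:
        raise ValueError("need at least two OTUs for a tree")
    nodes = [f"{name}:{rng.exponential(branch_scale):.6f}" for name in otu_ids]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        right = nodes.pop(j)
        left = nodes.pop(i)
        if len(nodes) == 0:
            nodes.append(f"({left},{right});")
        else:
            bl = rng.exponential(branch_scale)
            nodes.append(f"({left},{right}):{bl:.6f}")
    return TreeNode.read(io.StringIO(nodes[0]))


def _lognormal_sad(n: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    x = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    return x / x.sum()


def make_synthetic_parents(n_otus: int = 2000, overlap_fraction: float = 0.6,
                           sad_sigma: float = 2.0, seed: int = 0) -> ParentPair:
    """Generate two overlapping lognormal parent communities plus a phylogeny.

    Exactly ``ceil(overlap_fraction * n_otus)`` OTUs carry nonzero abundance
    in both parents; the remaining OTUs are split evenly into group-exclusive
    sets.  Each parent's abundances over its own support are iid lognormal
    with shape ``sad_sigma`` and are normalized to sum to one.

    Parameters
    ----------
    n_otus : total number of OTUs shared by the two parents (columns).
    overlap_fraction : fraction of OTUs present in both parents, in [0, 1].
    sad_sigma : lognormal sigma of the species-abundance distribution.
    seed : master seed; fixed seed gives a bit-identical pair.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    if n_otus < 10:
        raise ValueError("n_otus must be at least 10")
    rng = np.random.default_rng(seed)
    otu_ids = [f"otu{i:05d}" for i in range(n_otus)]

    n_shared = int(np.ceil(overlap_fraction * n_otus))
    n_rest = n_otus - n_shared
    n_a_only = n_rest // 2
    # support layout: [shared | a-only | b-only]
    support_a = np.zeros(n_otus, dtype=bool)
    support_b = np.zeros(n_otus, dtype=bool)
    support_a[:n_shared + n_a_only] = True
    support_b[:n_shared] = True
    support_b[n_shared + n_a_only:] = True

    p_a = np.zeros(n_otus)
    p_b = np.zeros(n_otus)
    p_a[support_a] = _lognormal_sad(int(support_a.sum()), sad_sigma, rng)
    p_b[support_b] = _lognormal_sad(int(support_b.sum()), sad_sigma, rng)

    tree = random_bifurcating_tree(otu_ids, rng)
    return ParentPair(otu_ids=otu_ids, p_a=p_a, p_b=p_b, tree=tree)


def build_parents_from_counts(counts: np.ndarray, otu_ids: list[str],
                              sample_ids: list[str],
                              group_a_samples: list[str],
                              group_b_samples: list[str],
                              n_top: int,
                              tree: TreeNode | None = None) -> ParentPair:
    """Derive a parent pair from a real sample-by-OTU count table.

    Pools the named samples from the two groups.  An OTU qualifies if it is
    observed (count > 0) in more than one of the pooled samples.  Qualifying
    OTUs are sorted by prevalence (number of pooled samples observed in,
    descending) then by total abundance across the pooled samples
    (descending); the first ``n_top`` are kept.  Counts are then pooled within
    each group and normalized to proportions.
    """
    counts = np.asarray(counts)
    idx = {s: i for i, s in enumerate(sample_ids)}
    missing = [s for s in group_a_samples + group_b_samples if s not in idx]
    if missing:
        raise KeyError(f"samples not in table: {missing}")
    rows_a = [idx[s] for s in group_a_samples]
    rows_b = [idx[s] for s in group_b_samples]
    pooled_rows = rows_a + rows_b

    sub = counts[pooled_rows, :]
    prevalence = (sub > 0).sum(axis=0)
    totals = sub.sum(axis=0)
    qualifying = np.flatnonzero(prevalence > 1)
    if len(qualifying) < n_top:
        raise ValueError(
            f"only {len(qualifying)} OTUs observed in >1 pooled sample; "
            f"{n_top} requested ({n_top - len(qualifying)} short)")
    # two-key descending sort: prevalence first, then total abundance
    order = qualifying[np.lexsort((-totals[qualifying], -prevalence[qualifying]))]
    keep = order[:n_top]

    pool_a = counts[rows_a, :][:, keep].sum(axis=0).astype(float)
    pool_b = counts[rows_b, :][:, keep].sum(axis=0).astype(float)
    kept_ids = [otu_ids[j] for j in keep]
    if tree is not None:
        tree = tree.shear(kept_ids)
        tree.prune()
    return ParentPair(otu_ids=kept_ids, p_a=pool_a / pool_a.sum(),
                      p_b=pool_b / pool_b.sum(), tree=tree)
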