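"""Simulate 80-sample OTU count tables from a parent pair at a chosen effect size.

The two treatment groups' sampling distributions are built by mixing the two
parent communities: group A samples from ``effect_size * p_a + p_b``
(renormalized) and group B from ``p_a + effect_size * p_b``.  An effect size
of 1.00 makes the two mixtures identical — an exact null.  Each sample is a
multinomial draw of its assigned library size from its group's mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .depths import DepthAssignment

EFFECT_SIZES = (1.00, 1.15, 1.25, 1.50, 1.75, 2.00, 2.50, 3.50)


@dataclass
class CountTable:
    """Integer sample-by-OTU matrix with depths, group labels and provenance."""

    counts: np.ndarray          # (n_samples, n_otus) nonnegative ints
    groups: np.ndarray          # per-sample labels in {"A", "B"}
    otu_ids: list[str]
    sample_ids: list[str]
    effect_size: float = 1.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.groups = np.asarray(self.groups)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (samples x OTUs)")
        n, g = self.counts.shape
        if len(self.groups) != n or len(self.sample_ids) != n:
            raise ValueError("groups/sample_ids must match row count")
        if len(self.otu_ids) != g:
            raise ValueError("otu_ids must match column count")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def depths(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]


def mix_parents(p_a: np.ndarray, p_b: np.ndarray,
                effect_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Mixture distributions for the two groups at a given effect size.

    ``mix_a`` is proportional to ``effect_size * p_a + p_b`` and ``mix_b`` to
    ``p_a + effect_size * p_b``; both are renormalized to sum to one.  The
    multiplier is applied to a group's *own* parent, so the construction is
    symmetric, exactly null at 1.00, and increasingly separated as the effect
    size grows.
    """
    if effect_size < 1.0:
        raise ValueError("effect_size must be >= 1.00")
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    mix_a = effect_size * p_a + p_b
    mix_b = p_a + effect_size * p_b
    return mix_a / mix_a.sum(), mix_b / mix_b.sum()


def draw_samples(mix_a: np.ndarray, mix_b: np.ndarray,
                 assignment: DepthAssignment, otu_ids: list[str],
                 seed: int, effect_size: float = 1.0) -> CountTable:
    """Multinomial count table: one draw of each sample's depth from its mixture."""
    for name, v in (("mix_a", mix_a), ("mix_b", mix_b)):
        if abs(np.sum(v) - 1.0) > 1e-9:
            raise ValueError(f"{name} must sum to 1")
    rng = np.random.default_rng(seed)
    n = len(assignment.depths)
    counts = np.empty((n, len(otu_ids)), dtype=np.int64)
    for i in range(n):
        mix = mix_a if assignment.groups[i] == "A" else mix_b
        counts[i] = rng.multinomial(int(assignment.depths[i]), mix)
    sample_ids = [f"s{i:03d}{assignment.groups[i]}" for i in range(n)]
    return CountTable(counts=counts, groups=assignment.groups.copy(),
                      otu_ids=list(otu_ids), sample_ids=sample_ids,
                      effect_size=effect_size)


def filter_rare_otus(table: CountTable) -> CountTable:
    """Two-step rare/low-prevalence OTU filter.

    Step 1 removes an OTU only if its total across all samples is below 3
    *and* it appears (count > 0) in fewer than 3 samples.  Step 2 removes an
    OTU only if it has counts above 1 in no more than 5% of the samples *and*
    its total is no more than half the per-group sample count (20 for 40/40).
    Each step's two clauses are a conjunction: failing either one alone is
    not enough for removal.  Surviving columns keep their order and values;
    samples are never removed.
    """
    counts = table.counts
    n = table.n_samples
    totals = counts.sum(axis=0)
    prevalence = (counts > 0).sum(axis=0)
    keep1 = ~((totals < 3) & (prevalence < 3))

    n_above_one = (counts > 1).sum(axis=0)
    half_group = (n // 2) / 2  # half the per-group sample count
    keep2 = ~((n_above_one <= 0.05 * n) & (totals <= half_group))

    keep = keep1 & keep2
    if not keep.any():
        raise ValueError("rare-OTU filter removed every OTU")
    return replace(table, counts=counts[:, keep],
                   otu_ids=[o for o, k in zip(table.otu_ids, keep) if k])
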