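"""Sequencing-depth models and per-sample depth/group assignment.

Two depth models are supported:

``empirical_resample``
    Emulates a small real sequencing run: a base pool of 26 depths drawn from
    a truncated normal over the observed range; simulated samples resample
    from the pool *with replacement*, so each base depth is reused an average
    of 80/26 ~ 3.08 times.

``log_scaled``
    80 depths spaced evenly on the log scale across the same range, each used
    exactly once (*without* replacement) — no duplicate depths, the pattern
    seen in real sequence collections.

Either way the 80 depths are rescaled so their median hits a target median
library size, and group labels are attached either at random (depth
independent of treatment) or fully confounded (one group gets every
below-median depth, the other every above-median depth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TARGET_MEDIANS = (1000, 2000, 5000, 10000, 50000)
DEPTH_MIN_DEFAULT = 58_688
DEPTH_MAX_DEFAULT = 2_357_181
#: mean/sd used to emulate the 26-depth empirical pool (approximately normal
#: over the default range)
EMPIRICAL_MEAN_DEFAULT = 1_085_256.8
EMPIRICAL_SD_DEFAULT = 600_000.0


@dataclass
class DepthModel:
    """How the 80 per-sample library sizes are generated and labelled."""

    kind: str                      # "empirical_resample" | "log_scaled"
    base_depths: np.ndarray        # pool of library sizes (reads)
    target_median: int             # median library size after scaling
    assignment: str = "randomized" # "randomized" | "confounded"

    def __post_init__(self) -> None:
        if self.kind not in ("empirical_resample", "log_scaled"):
            raise ValueError(f"unknown depth model kind {self.kind!r}")
        if self.assignment not in ("randomized", "confounded"):
            raise ValueError(f"unknown assignment {self.assignment!r}")
        self.base_depths = np.asarray(self.base_depths)
        if (self.base_depths < 1).any():
            raise ValueError("all base depths must be >= 1")
        expected = {"empirical_resample": 26, "log_scaled": 80}[self.kind]
        if len(self.base_depths) != expected:
            raise ValueError(
                f"{self.kind} expects {expected} base depths, "
                f"got {len(self.base_depths)}")
        if self.target_median not in TARGET_MEDIANS:
            raise ValueError(
                f"target_median must be one of {TARGET_MEDIANS}")


@dataclass
class DepthAssignment:
    """80 library sizes with their treatment labels (40 'A', 40 'B')."""

    depths: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        self.groups = np.asarray(self.groups)
        if len(self.depths) != len(self.groups):
            raise ValueError("depths and groups must align")
        counts = dict(zip(*np.unique(self.groups, return_counts=True)))
        if set(counts) != {"A", "B"} or len(set(counts.values())) != 1:
            raise ValueError("groups must be balanced 'A'/'B'")


def make_empirical_depths(n: int = 26,
                          mean: float = EMPIRICAL_MEAN_DEFAULT,
                          sd: float = EMPIRICAL_SD_DEFAULT,
                          min_depth: int = DEPTH_MIN_DEFAULT,
                          max_depth: int = DEPTH_MAX_DEFAULT,
                          seed: int = 0) -> np.ndarray:
    """Draw ``n`` integer depths from a normal clipped to [min, max]."""
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    if n < 2:
        raise ValueError("need at least two depths")
    if min_depth >= max_depth:
        raise ValueError("min_depth must be below max_depth")
    rng = np.random.default_rng(seed)
    draws = rng.normal(mean, sd, size=n) if sd > 0 else np.full(n, float(mean))
    return np.round(np.clip(draws, min_depth, max_depth)).astype(np.int64)


def make_log_scaled_depths(n: int = 80,
                           min_depth: int = DEPTH_MIN_DEFAULT,
                           max_depth: int = DEPTH_MAX_DEFAULT) -> np.ndarray:
    """``n`` depths evenly spaced on the log scale, endpoints inclusive."""
    if min_depth < 1 or min_depth >= max_depth:
        raise ValueError("require 1 <= min_depth < max_depth")
    if n < 2:
        raise ValueError("need at least two depths")
    return np.round(np.geomspace(min_depth, max_depth, n)).astype(np.int64)


def scale_to_median(depths: np.ndarray, target_median: float) -> np.ndarray:
    """Rescale depths so the median equals ``target_median`` (round, floor 1)."""
    depths = np.asarray(depths, dtype=float)
    scaled = np.round(depths * (target_median / np.median(depths)))
    return np.maximum(scaled, 1).astype(np.int64)


def assign_depths(model: DepthModel, seed: int, n_samples: int = 80) -> DepthAssignment:
    """Draw, scale and label the per-sample library sizes for one replicate.

    ``empirical_resample`` draws ``n_samples`` depths with replacement from
    the base pool; ``log_scaled`` uses each base depth exactly once.  Depths
    are then scaled to the model's target median.  ``randomized`` assignment
    shuffles balanced group labels independently of depth; ``confounded``
    sorts the depths and hands the lower half to group A and the upper half
    to group B.
    """
    if n_samples % 2:
        raise ValueError("n_samples must be even")
    rng = np.random.default_rng(seed)
    if model.kind == "empirical_resample":
        depths = rng.choice(model.base_depths, size=n_samples, replace=True)
    else:
        if len(model.base_depths) != n_samples:
            raise ValueError("log_scaled pool size must equal n_samples")
        depths = model.base_depths.copy()
    depths = scale_to_median(depths, model.target_median)

    half = n_samples // 2
    if model.assignment == "confounded":
        order = np.argsort(depths, kind="stable")
        groups = np.empty(n_samples, dtype="<U1")
        groups[order[:half]] = "A"
        groups[order[half:]] = "B"
    else:
        groups = np.array(["A"] * half + ["B"] * half)
        rng.shuffle(groups)
    return DepthAssignment(depths=depths, groups=groups)
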