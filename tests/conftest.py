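import numpy as np
import pytest

import rarebench as rb


@pytest.fixture(scope="session")
def parents200():
    return rb.make_synthetic_parents(n_otus=200, overlap_fraction=0.6, seed=11)


@pytest.fixture(scope="session")
def assignment1000():
    base = rb.make_log_scaled_depths(80, 5869, 235718)
    model = rb.DepthModel(kind="log_scaled", base_depths=base,
                          target_median=1000, assignment="randomized")
    return rb.assign_depths(model, seed=7)


@pytest.fixture(scope="session")
def null_table(parents200, assignment1000):
    """An 80-sample table at effect size 1.00 (exact null)."""
    mix_a, mix_b = rb.mix_parents(parents200.p_a, parents200.p_b, 1.0)
    return rb.draw_samples(mix_a, mix_b, assignment1000, parents200.otu_ids,
                           seed=13)


@pytest.fixture(scope="session")
def effect_table(parents200, assignment1000):
    """An 80-sample table at a large effect size (well separated groups)."""
    mix_a, mix_b = rb.mix_parents(parents200.p_a, parents200.p_b, 3.5)
    return rb.draw_samples(mix_a, mix_b, assignment1000, parents200.otu_ids,
                           seed=17, effect_size=3.5)


@pytest.fixture
def toy_table():
    counts = np.array([[5, 0, 3, 2],
                       [4, 1, 0, 5],
                       [6, 0, 2, 2],
                       [3, 2, 1, 4]])
    return rb.CountTable(counts=counts, groups=np.array(["A", "A", "B", "B"]),
                         otu_ids=["o1", "o2", "o3", "o4"],
                         sample_ids=["s1", "s2", "s3", "s4"])
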