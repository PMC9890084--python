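import numpy as np
import pytest

from aifnet.prep import pair_from_curves
from aifnet.saturation_net import scaled_recipe, train
from aifnet.synthetic import CohortConfig, gen_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-parameter cohort shared by read-only tests."""
    cfg = CohortConfig(n_subjects=12, seed=99, fractions=(0.5, 0.25, 0.25))
    return cfg, gen_cohort(cfg)


@pytest.fixture(scope="session")
def trained_setup():
    """The scaled-down training run shared by the learning and end-to-end tests.

    200 training pairs, 20 validation pairs, 2 000 optimizer iterations
    (the quick recipe), plus 100 held-out pairs and a separate 20-subject
    evaluation cohort.
    """
    cfg = CohortConfig(n_subjects=225, seed=7, fractions=(8 / 9, 4 / 45, 1 / 45))
    cohort = gen_cohort(cfg)
    pairs = {
        split: [pair_from_curves(s.sat_aif, s.ref_aif) for s in subjects]
        for split, subjects in cohort.items()
    }
    assert len(pairs["train"]) == 200 and len(pairs["val"]) == 20

    net_cfg, train_cfg = scaled_recipe(seed=0)
    model, history = train(pairs["train"], pairs["val"], net_cfg, train_cfg)

    held_cfg = CohortConfig(n_subjects=100, seed=11, fractions=(0.0, 0.0, 1.0))
    held_pairs = [
        pair_from_curves(s.sat_aif, s.ref_aif) for s in gen_cohort(held_cfg)["test"]
    ]

    eval_cfg = CohortConfig(n_subjects=20, seed=13, fractions=(0.0, 0.0, 1.0))
    eval_subjects = gen_cohort(eval_cfg)["test"]

    return {
        "model": model,
        "history": history,
        "held_pairs": held_pairs,
        "eval_subjects": eval_subjects,
    }
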