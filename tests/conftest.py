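"""Shared fixtures: tiny hand-written lexical resources and worked examples."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fluencylab as fl

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cmu_prons():
    """Hand-copied ARPAbet pronunciations for the letter-F predicate examples."""
    return {
        "freight": [("F", "R", "EY1", "T")],
        "fate": [("F", "EY1", "T")],
        "for": [("F", "AO1", "R")],
        "four": [("F", "AO1", "R")],
        "fit": [("F", "IH1", "T")],
        "fat": [("F", "AE1", "T")],
        "first": [("F", "ER1", "S", "T")],
        "fidget": [("F", "IH1", "JH", "AH0", "T")],
        "fox": [("F", "AA1", "K", "S")],
        "fiddle": [("F", "IH1", "D", "AH0", "L")],
        "france": [("F", "R", "AE1", "N", "S")],
        "phone": [("F", "OW1", "N")],
        "fun": [("F", "AH1", "N")],
    }


@pytest.fixture(scope="session")
def animal_subcats():
    return {
        "lion": {"feline", "african"},
        "tiger": {"feline"},
        "beaver": {"rodent", "water_creature", "fur"},
        "muskrat": {"rodent", "water_creature"},
        "dog": {"canine", "pet"},
        "cat": {"feline", "pet"},
        "zebra": {"african"},
        "salmon": {"fish"},
    }


# The worked example: seven chains of animal words whose derived scores are
# a switching score of 6 and a mean chain size of 1.43.
CAPTION_CHAINS = [
    ["dog", "cat", "elephant", "kangaroo", "chicken"],
    ["fox"],
    ["hippopotamus"],
    ["duck"],
    ["hog", "horse", "cow", "mule", "donkey"],
    ["sheep", "goat"],
    ["ox", "zebra"],
]


@pytest.fixture(scope="session")
def caption_chains():
    return [list(run) for run in CAPTION_CHAINS]


@pytest.fixture(scope="session")
def synthetic_fixtures():
    cfg = fl.SyntheticConfig(seed=7)
    subcats, prons, emb, planted = fl.make_fixtures(cfg)
    return cfg, subcats, prons, emb, planted


def random_relation(rng: np.random.Generator, words: list[str], p: float) -> fl.LinkageRelation:
    """A random symmetric relation over ``words`` with edge probability ``p``."""
    rel = fl.LinkageRelation(method="troyer", vocabulary=set(words))
    uniq = sorted(set(words))
    for i, a in enumerate(uniq):
        for b in uniq[i + 1:]:
            if rng.random() < p:
                rel.add(a, b)
    return rel
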