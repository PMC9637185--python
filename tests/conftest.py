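"""Shared fixtures: published ERBB2/ESR1 model parameterizations and helpers.

The printed per-class weights are rounded to two digits and do not always
sum exactly to one (e.g. the 8-class set sums to 0.95), so models are
built with renormalized weights; density-equality cutoffs are invariant
to this and posterior ratios are preserved.
"""

import numpy as np
import pytest

from g3mix import Component, MixtureModel

ERBB2_4 = [
    # (label, mean, sd, weight, frozen)
    (0, 40.4, 13.6, 0.46, True),
    (1, 88.7, 48.9, 0.38, False),
    (2, 403.0, 189.0, 0.14, False),
    (3, 879.0, 29.1, 0.02, False),
]

ERBB2_5 = [
    (0, 40.4, 13.6, 0.43, True),
    (1, 74.8, 37.9, 0.36, False),
    (2, 287.0, 155.0, 0.17, False),
    (3, 661.0, 38.7, 0.03, False),
    (4, 878.0, 28.6, 0.02, False),
]

ERBB2_8 = [
    (-1, 27.0, 10.1, 0.21, False),
    (0, 40.4, 13.6, 0.20, True),
    (1, 77.2, 21.8, 0.28, False),
    (2, 168.0, 57.6, 0.14, False),
    (3, 381.0, 36.0, 0.04, False),
    (4, 506.0, 18.6, 0.03, False),
    (5, 659.0, 38.1, 0.03, False),
    (6, 878.0, 28.6, 0.02, False),
]

ESR1_5 = [
    (-1, 0.49, 0.57, 0.25, False),
    (0, 3.34, 3.18, 0.27, True),
    (1, 17.4, 9.22, 0.25, False),
    (2, 63.4, 29.2, 0.19, False),
    (3, 99.5, 105.0, 0.05, False),
]


def build_model(rows, n_train=142) -> MixtureModel:
    total = sum(r[3] for r in rows)
    comps = [
        Component(label=lb, mean=m, sd=s, weight=w / total, frozen=fr)
        for lb, m, s, w, fr in rows
    ]
    return MixtureModel(comps, n_train=n_train)


@pytest.fixture
def erbb2_4class() -> MixtureModel:
    return build_model(ERBB2_4)


@pytest.fixture
def erbb2_5class() -> MixtureModel:
    return build_model(ERBB2_5)


@pytest.fixture
def erbb2_8class() -> MixtureModel:
    return build_model(ERBB2_8)


@pytest.fixture
def esr1_5class() -> MixtureModel:
    return build_model(ESR1_5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220922)
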