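"""Shared fixtures: one default synthetic campaign and fitted soft sensors.

The heavy artifacts (10,000-record default dataset, preprocessing
blocks, trained models) are session-scoped so the suite builds them
exactly once.
"""

import numpy as np
import pandas as pd
import pytest

from adentropy.models import ANNSpec, RFSpec, SVMSpec, fit_model
from adentropy.preprocess import minmax_apply, minmax_fit, remove_outliers, split
from adentropy.synth import INPUT_VARIABLES, OUTPUT_VARIABLES, PlantDataGenerator

FEATURES = list(INPUT_VARIABLES)
TARGETS = list(OUTPUT_VARIABLES)


@pytest.fixture(scope="session")
def generator():
    return PlantDataGenerator()


@pytest.fixture(scope="session")
def table10k(generator):
    """Default-configuration campaign: 10,000 records, seed 1."""
    return generator.generate(10_000, seed=1)


@pytest.fixture(scope="session")
def prepared(table10k):
    """Cleaned, chronologically split and min-max scaled blocks."""
    clean, removed = remove_outliers(table10k)
    train, val, test = split(clean)
    params = minmax_fit(train, FEATURES + TARGETS)
    return {
        "clean": clean,
        "removed": removed,
        "train": train,
        "val": val,
        "test": test,
        "params": params,
        "train_s": minmax_apply(train, params),
        "val_s": minmax_apply(val, params),
        "test_s": minmax_apply(test, params),
    }


@pytest.fixture(scope="session")
def ann_model(prepared):
    return fit_model(
        ANNSpec(),
        prepared["train_s"][FEATURES],
        prepared["train_s"][TARGETS],
        validation=(prepared["val_s"][FEATURES], prepared["val_s"][TARGETS]),
        normalization=prepared["params"],
    )


@pytest.fixture(scope="session")
def rf_model(prepared):
    return fit_model(
        RFSpec(), prepared["train_s"][FEATURES], prepared["train_s"]["biogas_yield"]
    )


@pytest.fixture(scope="session")
def svm_model(prepared):
    return fit_model(
        SVMSpec(), prepared["train_s"][FEATURES], prepared["train_s"]["biogas_yield"]
    )
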