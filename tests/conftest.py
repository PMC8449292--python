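import logging

import numpy as np
import pandas as pd
import pytest

from rdocpheno import CANONICAL_DOMAINS, CohortTable, GeneratorSpec, make_lexicon
from rdocpheno.simulate import LosModel

# model-fit and repeat-admission warnings are expected noise in simulations
logging.getLogger("rdocpheno").setLevel(logging.ERROR)
logging.getLogger("rdocpheno.stats").setLevel(logging.ERROR)
logging.getLogger("rdocpheno.cohort").setLevel(logging.ERROR)


@pytest.fixture
def tiny_lexicon():
    return make_lexicon(
        {
            "negval": {"hopeless", "worthless", "suicidal ideation"},
            "arousal": {"insomnia"},
        }
    )


@pytest.fixture
def small_spec():
    """Scaled-down generator spec for fast unit tests (same structure as the default)."""
    return GeneratorSpec(
        seed=7,
        group_sizes={"depression": 90, "schizophrenia": 30, "bipolar_disorder": 20},
        patients_per_group={"depression": 70, "schizophrenia": 25, "bipolar_disorder": 15},
        terms_per_domain=20,
        filler_vocab_size=100,
        note_filler_mean=30.0,
    )


def make_cohort_df(n, rng=None, diagnosis="depression", los=None, age=None, sex=None,
                   cci=None, scores=None):
    """Hand-rolled admission table for targeted statistical tests."""
    rng = rng or np.random.default_rng(0)
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "admission_id": [f"A{i:06d}" for i in range(n)],
            "diagnosis": diagnosis if isinstance(diagnosis, (list, np.ndarray, pd.Series)) else [diagnosis] * n,
            "age": age if age is not None else rng.integers(18, 80, n),
            "sex": sex if sex is not None else np.where(rng.random(n) < 0.6, "female", "male"),
            "los_days": los if los is not None else rng.uniform(0.5, 30, n),
            "cci": cci if cci is not None else rng.poisson(0.3, n),
            "htn": 0, "dm": 0, "stroke": 0, "renal": 0, "pneumonia": 0,
        }
    )
    if scores is not None:
        for name, col in scores.items():
            df[name] = col
    return df


@pytest.fixture
def cohort_factory():
    return make_cohort_df


def null_spec(seed, n_dep=150, n_scz=50, n_bip=30, p=0.12, terms=20):
    """All groups identical, outcome independent of everything: a pure null study."""
    probs = {d: p for d in CANONICAL_DOMAINS}
    return GeneratorSpec(
        seed=seed,
        group_sizes={"depression": n_dep, "schizophrenia": n_scz, "bipolar_disorder": n_bip},
        patients_per_group={"depression": n_dep, "schizophrenia": n_scz, "bipolar_disorder": n_bip},
        term_probs={g: dict(probs) for g in ("depression", "schizophrenia", "bipolar_disorder")},
        terms_per_domain=terms,
        filler_vocab_size=50,
        note_filler_mean=20.0,
        los_model=LosModel(intercept=0.0, domain_coefs={}),
    )
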