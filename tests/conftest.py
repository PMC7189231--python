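import numpy as np
import pytest

from behrt.corpus import PatientRecord, Visit, build_vocab
from behrt.model import ModelConfig
from behrt.synthetic import SimConfig, generate_corpus


@pytest.fixture(scope="session")
def small_sim():
    """A 120-patient corpus with planted structure, plus its ground truth."""
    return generate_corpus(SimConfig(n_patients=120, seed=7))


@pytest.fixture(scope="session")
def small_corpus(small_sim):
    return small_sim[0]


@pytest.fixture(scope="session")
def ground_truth(small_sim):
    return small_sim[1]


@pytest.fixture(scope="session")
def vocab(small_corpus):
    return build_vocab(small_corpus)


@pytest.fixture
def tiny_config():
    """Smallest non-degenerate architecture, dropout off."""
    return ModelConfig(vocab_size=8, n_layers=1, n_heads=1, hidden_size=4,
                       intermediate_size=8, max_position=8, dropout=0.0)


def record(pid, ages, code_lists, obs_end=None, attributes=None, months=None):
    """Hand-build a PatientRecord from parallel age/code lists."""
    if months is None:
        months = [None] * len(ages)
    visits = tuple(Visit(age_years=a, codes=tuple(c), age_months=m)
                   for a, c, m in zip(ages, code_lists, months))
    if obs_end is None:
        obs_end = visits[-1].month_age if visits else 0
    return PatientRecord(patient_id=pid, visits=visits,
                         observation_end_age_months=obs_end,
                         attributes=attributes or {})
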