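"""Shared fixtures: published primer sets and small planted databases."""

import pytest

from barisa import DbSpec, generate_reference_db, published_primer_sets


@pytest.fixture(scope="session")
def primer_sets():
    return published_primer_sets()


@pytest.fixture(scope="session")
def its_set(primer_sets):
    return primer_sets["ITSF/ITSReub"]


@pytest.fixture(scope="session")
def borneman_set(primer_sets):
    return primer_sets["1406f/23Sr"]


@pytest.fixture(scope="session")
def small_db(primer_sets):
    """60-species database planted for ITSF/ITSReub: 40% exact sites,
    20% one-mismatch, 10% two-mismatch, remainder absent."""
    spec = DbSpec(
        n_species=60,
        site_plans={"ITSF/ITSReub": {0: 0.4, 1: 0.2, 2: 0.1}},
        seed=11,
    )
    records, taxonomy, truth = generate_reference_db(spec, primer_sets)
    return spec, records, taxonomy, truth
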