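import numpy as np
import pytest

from clonodiverge.data_io import (
    CharacterSpec,
    Observation,
    ObservationTable,
    ThresholdRule,
)


@pytest.fixture
def binomial_spec():
    return CharacterSpec(character_id="01", body_part="head", family="binomial")


@pytest.fixture
def poisson_spec():
    return CharacterSpec(character_id="12", body_part="abdomen", family="poisson",
                         bilateral=True)


@pytest.fixture
def count_binomial_spec():
    # a near-two-valued count character grouped at values <=3 vs >=4
    return CharacterSpec(
        character_id="06", body_part="thorax", family="binomial",
        binarize_rule=ThresholdRule("06", cut=3),
    )


@pytest.fixture
def specs(binomial_spec, poisson_spec, count_binomial_spec):
    return {s.character_id: s for s in (binomial_spec, poisson_spec, count_binomial_spec)}


def make_table(values_by_strain, spec, extra_specs=()):
    """Observation table with one character from {strain: iterable of states}."""
    obs = []
    for strain, values in values_by_strain.items():
        for i, v in enumerate(values):
            obs.append(Observation(
                strain_id=strain, individual_id=f"{strain}{i}",
                character_id=spec.character_id,
                side="left" if spec.bilateral else "none",
                value=int(v),
            ))
    all_specs = {spec.character_id: spec, **{s.character_id: s for s in extra_specs}}
    return ObservationTable.from_observations(obs, all_specs)


@pytest.fixture
def rng():
    return np.random.default_rng(90210)
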