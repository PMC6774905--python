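import dataclasses

import numpy as np
import pytest

import entolidar as el
from entolidar.features import assemble_dataset


@pytest.fixture(scope="session")
def beam() -> el.BeamModel:
    return el.BeamModel()


@pytest.fixture(scope="session")
def quiet_beam() -> el.BeamModel:
    """Noiseless instrument for exactness checks."""
    return el.BeamModel(noise_sd=0.0)


@pytest.fixture(scope="session")
def gravid_spec() -> el.InsectClassSpec:
    return el.culex_female_gravid_spec()


@pytest.fixture(scope="session")
def nongravid_spec() -> el.InsectClassSpec:
    return el.culex_female_nongravid_spec()


def frozen(spec: el.InsectClassSpec, **overrides) -> el.InsectClassSpec:
    """Spec with all dispersions zeroed (every draw equals its mean)."""
    zeros = dict(
        wbf_sd=0.0,
        delta_body_sd=0.0,
        delta_wing_sd=0.0,
        sigma_rel_sd=0.0,
        body_swir_nir_ratio_sd=0.0,
        wing_swir_nir_ratio_sd=0.0,
        transit_speed_sd=0.0,
    )
    zeros.update(overrides)
    return dataclasses.replace(spec, **zeros)


def featurize(events, **kwargs):
    """Decompose + extract cross sections + assemble features for a batch."""
    pairs = []
    for ev in events:
        dec = el.separate_body_wing(ev)
        el.extract_cross_sections(dec)
        pairs.append((dec, ev.label))
    return assemble_dataset(pairs, **kwargs)


@pytest.fixture(scope="session")
def small_two_class_dataset(beam):
    """Modest gravid/non-gravid feature set shared by classifier tests."""
    events = el.simulate_dataset(el.two_class_specs(), 60, beam, seed=424)
    dataset, drops = featurize(events)
    assert len(drops) == 0
    return dataset
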