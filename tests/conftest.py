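from __future__ import annotations

import numpy as np
import pytest

from micromine.config import PipelineConfig
from micromine.homology.pairwise import default_params
from micromine.homology.phmm import build_phmm
from micromine.synthetic import make_family

FAMILY_SEED = 101


@pytest.fixture(scope="session")
def family():
    return make_family(FAMILY_SEED)


@pytest.fixture(scope="session")
def bundle(family):
    return family.to_training_bundle()


@pytest.fixture(scope="session")
def config(family) -> PipelineConfig:
    return family.pipeline_config()


@pytest.fixture(scope="session")
def microcin_model(family):
    return build_phmm(family.microcins, source_msa_id="microcin")


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_protein(rng: np.random.Generator, length: int) -> str:
    from micromine.homology.phmm import AA_ORDER, BACKGROUND

    return "".join(AA_ORDER[i] for i in rng.choice(20, size=length, p=BACKGROUND))
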