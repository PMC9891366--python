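import numpy as np
import pytest

from crystalmotifs import (
    DescriptorConfig,
    SyntheticSpec,
    generate,
    make_worked_micro_examples,
)

# Frozen study conditions for the synthetic model-recovery experiments:
# feature dimension (108) deliberately below the training-set sizes so the
# planted linear model is identifiable, at desk-scale descriptor cost.
EXPERIMENT_CFG = DescriptorConfig(
    r_cut=4.0, n_max=2, l_max=2, sigma_atom=0.4,
    species_list=("C", "H", "N", "O"), normalize=True, n_quad=40,
)


@pytest.fixture(scope="session")
def micro():
    return make_worked_micro_examples()


@pytest.fixture(scope="session")
def small_cfg():
    return DescriptorConfig(
        r_cut=3.0, n_max=3, l_max=2, sigma_atom=0.4,
        species_list=("C", "H", "N", "O"), normalize=False, n_quad=40,
    )


@pytest.fixture(scope="session")
def synth_small():
    """25 noise-free toy crystals shared across attribution/map tests."""
    return generate(
        SyntheticSpec(seed=11, n_crystals=25, descriptor_config=EXPERIMENT_CFG)
    )


@pytest.fixture(scope="session")
def synth_matrices(synth_small):
    from crystalmotifs import collection_matrices

    return collection_matrices(
        synth_small.records, synth_small.ds_solid,
        synth_small.ds_gas, synth_small.ds_remnant,
    )
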