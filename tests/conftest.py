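import numpy as np
import pytest

from repave import alignment as aln
from repave import landscape as lsc
from repave import synthetic as syn


@pytest.fixture(scope="session")
def hinge_model():
    return syn.build_hinge_template(syn.HingeTopology(20, 10, 4), seed=1)


@pytest.fixture(scope="session")
def hinge_regions(hinge_model):
    return lsc.RegionSpec.from_hinge_model(hinge_model)


@pytest.fixture(scope="session")
def template(hinge_model):
    return hinge_model.template


@pytest.fixture(scope="session")
def random_tensor():
    return aln.SaupeTensor.from_components(3e-4, -1e-4, 2e-4, -1.5e-4, 5e-5)


@pytest.fixture(scope="session")
def small_ensemble(hinge_model):
    spec = syn.AngleDistributionSpec(110.0, 8.0)
    return syn.sample_hinge_ensemble(hinge_model, spec, 200, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
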