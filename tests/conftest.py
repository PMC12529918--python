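import numpy as np
import pytest

from framonc.potentials import FFParameters, ForceFieldBackend
from framonc.system import Box, Configuration, MoleculeInstance, MoleculeTemplate, SiteSpec
from framonc.toys import ToySystemSpec, generate_toy_system


@pytest.fixture(scope="session")
def water_box_30():
    """A 30-molecule water-like box at 1 g/cm3 (session-cached)."""
    config, templates = generate_toy_system(
        ToySystemSpec("toy_water", n_molecules=30, seed=11)
    )
    return config, templates


@pytest.fixture(scope="session")
def methanol_box_20():
    config, templates = generate_toy_system(
        ToySystemSpec("toy_methanol", n_molecules=20, seed=5)
    )
    return config, templates


@pytest.fixture()
def lj_templates():
    """A neutral single-site LJ particle (sigma=3.0, epsilon=1.0)."""
    tmpl = MoleculeTemplate(
        "lj", [SiteSpec("Ar", "Ar", 0.0, 3.0, 1.0, (0.0, 0.0, 0.0))]
    )
    return {"lj": tmpl}


@pytest.fixture()
def ideal_templates():
    """A non-interacting point particle (zero charge and epsilon)."""
    tmpl = MoleculeTemplate(
        "ideal", [SiteSpec("Ar", "Ar", 0.0, 0.0, 0.0, (0.0, 0.0, 0.0))]
    )
    return {"ideal": tmpl}


def make_lj_dimer(r, templates, edge=50.0):
    """Two single-site LJ particles at separation r in a large box."""
    q = np.array([1.0, 0.0, 0.0, 0.0])
    name = next(iter(templates))
    config = Configuration(
        Box(np.full(3, edge)),
        [
            MoleculeInstance(name, np.array([1.0, 1.0, 1.0]), q.copy()),
            MoleculeInstance(name, np.array([1.0 + r, 1.0, 1.0]), q.copy()),
        ],
    )
    return config


@pytest.fixture()
def ff_backends():
    params = FFParameters(r_cut=4.5)
    return ForceFieldBackend(params), ForceFieldBackend(params, epsilon_scale=1.2)
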