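import numpy as np
import pytest

from demrisk import SimConfig, SpeciesParams, build_leslie
from demrisk.synthetic_data import GeneratorSpec, generate_species_table


@pytest.fixture(scope="session")
def toy_params():
    """Small, fast species: 4 age classes, modest carrying capacity."""
    return SpeciesParams(
        name="toy",
        status="extant",
        group="carnivore",
        mass_kg=10.0,
        alpha=1,
        omega=3,
        survival=[0.6, 0.8, 0.85, 0.8],
        fertility=[0.0, 0.8, 1.1, 1.1],
        density=0.008,  # K = 2,000 females over the default study area
    )


@pytest.fixture(scope="session")
def toy2_params():
    """Second toy species, later maturity, no terminal self-loop."""
    return SpeciesParams(
        name="toy2",
        status="extinct",
        group="macropodiform",
        mass_kg=25.0,
        alpha=2,
        omega=5,
        survival=[0.55, 0.75, 0.85, 0.85, 0.85, 0.8],
        fertility=[0.0, 0.0, 0.9, 0.9, 0.9, 0.9],
        density=0.006,
        terminal_self_loop=False,
    )


@pytest.fixture(scope="session")
def toy_model(toy_params):
    return build_leslie(toy_params)


@pytest.fixture(scope="session")
def fast_config():
    """Cheap stochastic config for unit tests."""
    return SimConfig(iterations=200, seed=11, horizon_generations=10)


@pytest.fixture(scope="session")
def species_table():
    """The default 21-species synthetic assemblage."""
    return generate_species_table(GeneratorSpec(seed=7))


@pytest.fixture(scope="session")
def species_models(species_table):
    return {sp.name: build_leslie(sp) for sp in species_table}


@pytest.fixture(scope="session")
def mini_table():
    """Five-species assemblage (one per group) for end-to-end smoke runs."""
    from demrisk.synthetic_data import DEFAULT_GROUPS, GroupProfile

    groups = {}
    for name, prof in DEFAULT_GROUPS.items():
        gm = float(np.sqrt(prof.mass_range_kg[0] * prof.mass_range_kg[1]))
        groups[name] = GroupProfile(
            n_species=1,
            n_extinct=1 if name in ("vombatiform", "bird", "macropodiform") else 0,
            mass_range_kg=(gm, gm),
            g_coef=prof.g_coef,
            fertility_base=prof.fertility_base,
        )
    return generate_species_table(GeneratorSpec(groups=groups, seed=3, noise_sd=0.05))
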