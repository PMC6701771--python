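"""Shared fixtures: a compact optical configuration, the default synthetic
scene, and precomputed binocular quality tables.

The session-wide optical configuration uses a 4-degree field so the retinal
simulations stay light; pupil, wavelength and sampling match the standard
device settings (5 mm, 555 nm).
"""

import pytest

from presbysim import build_catalog, default_cohort, generate_scene, run_experiment
from presbysim.observer import compute_quality_table
from presbysim.optics import OpticalConfig

SCENE_SEED = 1


@pytest.fixture(scope="session")
def optical_config() -> OpticalConfig:
    return OpticalConfig(field_of_view=4.0)


@pytest.fixture(scope="session")
def scene(optical_config):
    return generate_scene(optical_config, seed=SCENE_SEED)


@pytest.fixture(scope="session")
def catalog():
    return build_catalog()


@pytest.fixture(scope="session")
def quality_table(scene, catalog, optical_config):
    """Binocular (better-eye) contrast quality per correction x distance."""
    return compute_quality_table(scene, catalog, optical_config)


@pytest.fixture(scope="session")
def study_tables(catalog, quality_table):
    """Score and choice tables from the shipped default 8-subject cohort."""
    cohort = default_cohort()
    return run_experiment(cohort, catalog, None, None, quality=quality_table)
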