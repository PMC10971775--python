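import numpy as np
import pandas as pd
import pytest

from urbanshift.synthetic_world import generate_climate, generate_species


@pytest.fixture(scope="session")
def world():
    """A small synthetic climate world shared by read-only tests."""
    return generate_climate(seed=7, shape=(48, 48), n_vars=5, collinear_pairs=1)


@pytest.fixture(scope="session")
def historic(world):
    return world["historic"]


@pytest.fixture(scope="session")
def species_list(historic):
    return generate_species(seed=11, n_species=4, stack=historic,
                            niche_vars=["MAT", "MAP"], n_niche_vars=1)


@pytest.fixture(scope="session")
def demo_world(tmp_path_factory):
    """A full demo study (climate + occurrences + cities + truth) on disk."""
    from urbanshift.pipeline import make_demo

    root = tmp_path_factory.mktemp("demo")
    return make_demo(seed=3, out_dir=root, n_species=12, shape=(60, 60), n_cities=3)


@pytest.fixture(scope="session")
def demo_run(demo_world):
    """The demo pipeline executed once; several tests inspect its outputs."""
    from urbanshift.pipeline import run_pipeline

    return run_pipeline(demo_world.config)
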