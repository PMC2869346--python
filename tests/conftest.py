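import pytest

from hextaxis import LigandSchedule, SimulationConfig, build_receptor_mask, initialize


@pytest.fixture(scope="session")
def default_mask():
    """The full 100x60 / 1083-receptor mask (built once per session)."""
    return build_receptor_mask(100, 60, 60, 1083)


@pytest.fixture(scope="session")
def small_mask():
    """Fully tiled 12x9 mask (36 receptors) for exhaustive checks."""
    return build_receptor_mask(12, 9, 12, 36)


def small_pathway_config(seed=0, **kw):
    """A 24x18 lattice with 72 receptors and the full soluble pathway —
    large enough for bridges to assemble, small enough for fast tests."""
    defaults = dict(columns=24, rows=18, receptor_region_columns=12,
                    n_receptors=72, include_pathway=True,
                    schedule=LigandSchedule([(0, "MeAsp", 0.0)]),
                    record_interval=100, seed=seed)
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture
def small_pathway_world():
    return initialize(small_pathway_config(seed=3))
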