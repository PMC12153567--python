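import numpy as np
import pytest

from flygroup import arena, synth, trackio


@pytest.fixture(scope="session")
def reference_table():
    return synth.make_reference_fixture()


@pytest.fixture(scope="session")
def default_spec():
    return arena.ArenaSpec()


@pytest.fixture(scope="session")
def plain_map(default_spec):
    """Arena map with only the geometric labels: food circle + everything
    else intermediate (no data-driven clusters)."""
    n = default_spec.n_cells
    labels = np.full((n, n), arena.AREA_LABELS.index(arena.INTERMEDIATE), dtype=np.int8)
    c = (np.arange(n) + 0.5) * default_spec.grid_cell
    cx, cy = np.meshgrid(c, c, indexing="ij")
    fx, fy = default_spec.center
    food = (cx - fx) ** 2 + (cy - fy) ** 2 <= (default_spec.food_diameter / 2) ** 2
    labels[food] = arena.AREA_LABELS.index(arena.FOOD)
    return arena.MicroAreaMap(default_spec, labels)


@pytest.fixture(scope="session")
def schedule():
    return trackio.PhaseSchedule()


@pytest.fixture(scope="session")
def short_sim():
    """One 10-individual trial of 1200 s, the study geometry otherwise."""
    cfg = synth.SimulationConfig(duration=1200, seed=11)
    return synth.simulate_group(cfg)
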