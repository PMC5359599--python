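import dataclasses

import pytest

from lipidscreen import RunConfig, SimulationConfig, run_screen
from lipidscreen.io import ScreenDesign


def summary_screen(
    seed,
    n_compounds=320,
    controls_per_role=16,
    n_replicates=2,
    planted_hits=(),
    death_by_compound=None,
    hit_effect=0.5,
    cells_per_well=300,
):
    """Run one summary-mode screen with the given design and return its result."""
    cfg = RunConfig(
        mode="summary",
        seed=seed,
        screen=ScreenDesign(n_compounds=n_compounds, controls_per_role=controls_per_role,
                            n_replicates=n_replicates),
        simulation=SimulationConfig(
            planted_hits=tuple(planted_hits),
            death_by_compound=dict(death_by_compound or {}),
            hit_effect=hit_effect,
            cells_per_well=cells_per_well,
        ),
    )
    return run_screen(cfg)


@pytest.fixture(scope="session")
def quiet_config():
    """Noise-free simulation config for exactness checks."""
    return SimulationConfig(seed=11, noise_sd=0.0)


@pytest.fixture
def small_layout():
    from lipidscreen import generate_plate_layout

    return generate_plate_layout(20, 4, plate_id="T1", replicate_id=1, seed=5,
                                 n_rows=8, n_cols=12)


def make_config(**overrides):
    base = dict(seed=11, noise_sd=0.0)
    base.update(overrides)
    return SimulationConfig(**base)
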