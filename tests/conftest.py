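import pytest

from bsamap import (
    default_cross_config,
    run_pipeline,
    simulate_experiment,
    suppressor_screen_model,
)
from bsamap.cross import ChromosomeSpec, GenomeLayout
from bsamap.segregation import FunctionalLocus

#: seed of the shared default-experiment fixtures
DEFAULT_SEED = 11


@pytest.fixture(scope="session")
def model():
    return suppressor_screen_model()


@pytest.fixture(scope="session")
def default_config():
    return default_cross_config(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_result(default_config):
    """One full simulated experiment at the design point (80+98 pools, 44x)."""
    return simulate_experiment(default_config)


@pytest.fixture(scope="session")
def default_pipeline(default_config):
    """The default experiment analysed end to end."""
    return run_pipeline(default_config)


def mini_layout(n_chromosomes=2, length_bp=2_000_000, length_cm=100.0, spacing=20_000.0):
    chroms = tuple(
        ChromosomeSpec(f"Chr{i:02d}", length_bp, length_cm)
        for i in range(1, n_chromosomes + 1)
    )
    return GenomeLayout(chromosomes=chroms, marker_spacing_bp=spacing)


def mini_model(layout, selection_viability=1.0):
    """Two-locus screen model on the first two chromosomes of a small layout."""
    sel_bp = layout.chromosomes[0].length_bp // 2
    sup_bp = layout.chromosomes[1].length_bp // 2
    sel = FunctionalLocus(
        "NOG1", layout.chromosomes[0].name, sel_bp,
        layout.bp_to_cm(layout.chromosomes[0].name, sel_bp), 1, "selection",
    )
    sup = FunctionalLocus(
        "SNOG1A", layout.chromosomes[1].name, sup_bp,
        layout.bp_to_cm(layout.chromosomes[1].name, sup_bp), 1, "suppressor",
    )
    return suppressor_screen_model(sel, sup, selection_viability)
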