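import numpy as np
import pytest

from sigpolytope import PipelineConfig, SimulationSpec, simulate_atlas
from sigpolytope.pipeline import embed_table
from sigpolytope.records import SideAnnotation, SurvivalAnnotation


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_atlas():
    """40-circuitry synthetic atlas with all four mixture components."""
    table, truth = simulate_atlas(
        SimulationSpec(n_circuitries=40, n_strata=4, seed=101)
    )
    return table, truth


@pytest.fixture(scope="session")
def small_model(small_atlas, config):
    table, _ = small_atlas
    tensor, model = embed_table(table, config)
    return tensor, model


def make_survival(direction="ns", p=0.5, chi2=1.0, significant=False):
    return SurvivalAnnotation(direction=direction, p=p, chi2=chi2, significant=significant)


def make_side(
    rho=0.3,
    rho_adj_p=0.01,
    tn_direction="up",
    tn_wilcoxon_p=0.001,
    survival=None,
    micro_score=0.5,
    immune_class="hot",
):
    if survival is None:
        survival = {e: make_survival() for e in ("os", "dss", "dfi", "pfi")}
    return SideAnnotation(
        rho=rho,
        rho_adj_p=rho_adj_p,
        tn_direction=tn_direction,
        tn_wilcoxon_p=tn_wilcoxon_p,
        survival=survival,
        micro_score=micro_score,
        immune_class=immune_class,
    )


@pytest.fixture
def neutral_side():
    """A completely neutral annotation encoding to the zero vector."""
    return make_side(
        rho=0.0,
        rho_adj_p=1.0,
        tn_direction="ns",
        tn_wilcoxon_p=1.0,
        micro_score=0.0,
        immune_class="intermediate",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
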