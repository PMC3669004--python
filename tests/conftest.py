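import numpy as np
import pytest

from eelgrass_allometry import (
    AllometricParams,
    Campaign,
    LeafObservation,
    ShootSample,
    SimulationConfig,
    simulate_campaigns,
)

PAPER_PARAMS = AllometricParams(alpha=2e-5, beta=1.3)


@pytest.fixture(scope="session")
def params():
    return PAPER_PARAMS


@pytest.fixture(scope="session")
def default_sims():
    """The default simulated season (35 biweekly campaigns, seed 0)."""
    return simulate_campaigns(SimulationConfig())


@pytest.fixture(scope="session")
def exact_sims():
    """A season in the exact-allometry regime: dry weights are exact
    transforms of lengths, so all identities hold at machine precision."""
    return simulate_campaigns(SimulationConfig().exact_allometry())


def make_leaf(rank, length_start, length_end, weight_end=None, above=None,
              weight_start=None, params=PAPER_PARAMS):
    if weight_end is None:
        weight_end = params.alpha * length_end ** params.beta
    return LeafObservation(
        rank=rank,
        length_start=length_start,
        length_end=length_end,
        dry_weight_end=weight_end,
        increment_above_mark=above,
        dry_weight_start=weight_start,
    )


@pytest.fixture
def simple_shoot(params):
    """Three leaves with exact allometric weights at both endpoints."""
    leaves = []
    for rank, (l0, l1) in enumerate([(0.0, 90.0), (150.0, 210.0), (300.0, 330.0)], start=1):
        leaves.append(
            LeafObservation(
                rank=rank,
                length_start=l0,
                length_end=l1,
                dry_weight_end=params.alpha * l1 ** params.beta,
                dry_weight_start=params.alpha * l0 ** params.beta,
            )
        )
    return ShootSample(shoot_id="s1", leaves=tuple(leaves))


@pytest.fixture
def simple_campaign(simple_shoot):
    return Campaign(
        date="1999-03-15",
        delta_t=14.0,
        shoots=(simple_shoot,),
        n_marked=2,
        new_leaves=1,
        p=14.0,
    )
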