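import pytest

from ptcdelay import (aggregate_decompositions, decompose_delays,
                      default_config, demo_cohort, demo_pathway,
                      simulate_cohort)
from ptcdelay.simulate import CohortConfig


@pytest.fixture
def demo():
    return demo_pathway()


@pytest.fixture
def demo_coh():
    return demo_cohort()


@pytest.fixture(scope="session")
def small_cohort():
    """A seeded 40-participant synthetic cohort shared across tests."""
    return simulate_cohort(default_config(seed=424, n_participants=40))


@pytest.fixture(scope="session")
def small_table(small_cohort):
    ds = [decompose_delays(p) for p in small_cohort.pathways.values()]
    return aggregate_decompositions(ds, small_cohort.covariates)


def deterministic_chain_config(**overrides) -> CohortConfig:
    """Config whose walks are the fixed chain Family -> ED -> STEP with all
    delays exactly 1 day (sigma 0, no covariate effects, no frailty)."""
    from ptcdelay.nodes import NODE_TYPES, STEP

    one_hot = {t: 0.0 for t in NODE_TYPES}
    demand = {}
    supply = {}
    for t in NODE_TYPES:
        row = dict(one_hot, **{STEP: 0.0})
        if t == "Family":
            row["ED"] = 1.0
        else:
            row[STEP] = 1.0
        demand[t] = dict(row)
        supply[t] = dict(row)
    kw = dict(
        n_participants=25,
        seed=5,
        onset_delay_median=1.0,
        onset_delay_sigma=0.0,
        initial_node_probs=dict(one_hot, Family=1.0),
        demand_matrix=demand,
        supply_matrix=supply,
        delay_median_demand={t: 1.0 for t in NODE_TYPES},
        delay_median_supply={t: 1.0 for t in NODE_TYPES},
        delay_sigma={t: 0.0 for t in NODE_TYPES},
        prescribing_prob=1.0,
        covariate_effects={},
        participant_frailty_sd=0.0,
    )
    kw.update(overrides)
    return CohortConfig(**kw)
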