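import numpy as np
import pytest

from umbrellapick import (
    OverlapMatrix,
    RunConfig,
    SpeciesRecord,
    ThreatMatrix,
    make_figure1_fixture,
    unit_weights,
)
from umbrellapick.synthgen import SyntheticConfig, generate_assemblage


@pytest.fixture
def fig1():
    """Koala / bilby / orchid worked example (koala index 0)."""
    return make_figure1_fixture()


@pytest.fixture
def base_config():
    return RunConfig(budget=1000.0)


@pytest.fixture
def six_species():
    """Hand-built 6-species instance used for step-by-step greedy checks.

    Areas and intersections (km^2): a=100, b=100, c=400, d=25, e=225,
    f=64; a&b=50, b&c=100, d&e=25, all other pairs disjoint.  With q=1,
    z=0.5 the action costs are a=10, b=10, c=20, d=5, e=15, f=8.
    """
    records = [
        SpeciesRecord("a", "A", 100.0, frozenset({"t1"})),
        SpeciesRecord("b", "B", 100.0, frozenset({"t1", "t2"})),
        SpeciesRecord("c", "C", 400.0, frozenset({"t2"})),
        SpeciesRecord("d", "D", 25.0, frozenset({"t3"})),
        SpeciesRecord("e", "E", 225.0, frozenset({"t1", "t3"})),
        SpeciesRecord("f", "F", 64.0, frozenset({"t4"})),
    ]
    ids = tuple(r.species_id for r in records)
    O = np.eye(6)
    O[0, 1] = 50 / 100   # a covers half of b
    O[1, 0] = 50 / 100
    O[1, 2] = 100 / 400  # b covers a quarter of c
    O[2, 1] = 100 / 100  # c covers all of b
    O[3, 4] = 25 / 225   # d covers 1/9 of e
    O[4, 3] = 25 / 25    # e covers all of d
    overlap = OverlapMatrix(values=O, species_ids=ids)
    overlap.validate(areas=[r.range_area for r in records])
    T = ThreatMatrix.from_records(records, vocabulary=["t1", "t2", "t3", "t4"])
    return records, overlap, T


def small_random_instance(seed, n_species=8, denominator="recipient",
                          budget_fraction=0.5):
    """A small synthetic instance plus a matching RunConfig.

    The budget is a fixed fraction of the full portfolio cost so that
    the knapsack constraint binds on most draws.
    """
    from umbrellapick.cost import CostModel, portfolio_cost

    cfg = SyntheticConfig(
        n_species=n_species,
        n_threats=4,
        grid=(30, 30),
        range_area_bounds=(4, 100),
        clustering=0.4,
        threat_prevalence=(0.4, 0.4, 0.3, 0.3),
        seed=seed,
    )
    records, O, T = generate_assemblage(cfg)
    model = CostModel(q=1.0, z=0.3)
    total = portfolio_cost([r.species_id for r in records], records, model)
    run = RunConfig(
        budget=budget_fraction * total,
        benefit_denominator=denominator,
        cost_q=1.0,
        cost_z=0.3,
        seed=seed,
    )
    return records, O, T, unit_weights(len(records)), run
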