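"""Power-law management costs with diminishing returns.

The annual cost of managing all threats to a species across its full
range R (km^2) is C = q * R^z with 0 < z <= 1, so the marginal cost per
km^2 falls as the managed area grows.  q converts area to currency and
is supplied by the user (typical z values reported for management-cost
scaling are 0.15-0.40); all currency is unit-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .datamodel import ConfigError, RunConfig, SpeciesRecord, UnknownSpeciesError


@dataclass(frozen=True)
class CostModel:
    """Parameters of the power-law cost C = q * R^z."""

    q: float
    z: float

    def __post_init__(self) -> None:
        if not (self.q > 0):
            raise ConfigError(f"cost q must be positive, got {self.q!r}")
        if not (0 < self.z <= 1):
            raise ConfigError(f"cost z must be in (0, 1], got {self.z!r}")

    @classmethod
    def from_config(cls, config: RunConfig) -> "CostModel":
        return cls(q=config.cost_q, z=config.cost_z)


def action_cost(range_area: float, model: CostModel) -> float:
    """Annual cost of managing all threats over ``range_area`` km^2.

    q * R^z; zero for zero area.  Negative areas are a domain error.
    """
    if range_area < 0:
        raise ValueError(f"range_area must be nonnegative, got {range_area!r}")
    if range_area == 0:
        return 0.0
    return model.q * range_area ** model.z


def portfolio_cost(
    ids: Sequence[str],
    records: Sequence[SpeciesRecord] | Mapping[str, SpeciesRecord],
    model: CostModel,
) -> float:
    """Total annual cost of managing every listed species over its full range.

    This is also the assumed-budget computation: the cost of a reference
    list becomes the budget constraining an optimized run.
    """
    if isinstance(records, Mapping):
        lookup = records
    else:
        lookup = {rec.species_id: rec for rec in records}
    missing = [sid for sid in ids if sid not in lookup]
    if missing:
        raise UnknownSpeciesError(f"unknown species ids: {missing}")
    return float(sum(action_cost(lookup[sid].range_area, model) for sid in ids))
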