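"""Greedy maximum-gains selection, exhaustive oracle and analyses.

The decision problem: choose a set of species to manage (each across its
entire range, all manageable threats) maximizing the total accrued
benefit subject to a budget on the summed power-law action costs.  The
greedy heuristic repeatedly selects the unselected species with the
highest marginal cost-effectiveness E_i = (scenario marginal benefit) /
(action cost), re-evaluated against the accrual ledger at every step.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .benefit import (
    AccrualLedger,
    BenefitCounts,
    accrue,
    count_benefitting,
    evaluate_selection,
    scenario_benefit,
)
from .cost import CostModel, action_cost, portfolio_cost
from .datamodel import (
    OverlapMatrix,
    RunConfig,
    SpeciesRecord,
    ThreatMatrix,
    UnknownSpeciesError,
)

logger = logging.getLogger("umbrellapick")

#: Marginal benefits below this are treated as zero when deciding whether
#: a candidate still yields any benefit.
BENEFIT_EPS = 1e-12


@dataclass(frozen=True)
class PriorityStep:
    rank: int
    species_id: str
    marginal_benefit: float
    ratio: float  # E_i = marginal benefit / cost at selection time
    cost: float
    cumulative_spend: float
    n_newly_benefitting: int


@dataclass
class PriorityList:
    """Ordered greedy selection with the final ledger and categorization."""

    steps: list[PriorityStep]
    budget: float
    final_ledger: AccrualLedger
    species_ids: tuple[str, ...]
    counts: BenefitCounts
    categories: dict[str, str] = field(default_factory=dict)

    @property
    def members(self) -> list[str]:
        return [s.species_id for s in self.steps]

    @property
    def spend(self) -> float:
        return self.steps[-1].cumulative_spend if self.steps else 0.0

    @property
    def total_benefit(self) -> float:
        return float(sum(s.marginal_benefit for s in self.steps))


def _prepare(records, T, config):
    """Strip unmanageable threats and find species eligible for selection."""
    T_eff = T.without(config.unmanageable_threats) if config.unmanageable_threats else T
    counts = T_eff.threat_counts()
    eligible = [i for i in range(len(records)) if counts[i] > 0]
    for i in range(len(records)):
        if counts[i] == 0:
            logger.warning(
                "species %s has no manageable threats; excluded from selection",
                records[i].species_id,
            )
    return T_eff, eligible


def greedy_prioritize(
    records: Sequence[SpeciesRecord],
    O: OverlapMatrix,
    T: ThreatMatrix,
    W: np.ndarray,
    config: RunConfig,
    ledger_mode: str = "matrix",
) -> PriorityList:
    """Budget-constrained greedy selection by marginal cost-effectiveness.

    At each step the candidate maximizing E_i = marginal scenario benefit
    / action cost is chosen among species with positive marginal benefit;
    when no remaining species yields any benefit, ranking falls back to
    1 / cost so cheap "additional" species fill the budget.  Ties in E_i
    break by lower cost, then lexicographic species id.  Under
    ``skip_and_continue`` unaffordable candidates are skipped and the
    scan continues; under ``stop_at_first`` the run ends at the first
    unaffordable best candidate.  Returns an empty list (not an error)
    when nothing is selectable.
    """
    T_eff, eligible = _prepare(records, T, config)
    model = CostModel.from_config(config)
    costs = {i: action_cost(records[i].range_area, model) for i in eligible}
    geometries = (
        [r.geometry for r in records] if ledger_mode == "geometry" else None
    )
    ledger = AccrualLedger(
        len(records), T_eff.n_threats, mode=ledger_mode, geometries=geometries
    )
    thr = config.benefit_threshold
    steps: list[PriorityStep] = []
    remaining = set(eligible)
    spend = 0.0
    rank = 0
    while remaining:
        budget_left = config.budget - spend
        candidates = []  # (sort key, i, breakdown, cost)
        for i in sorted(remaining, key=lambda i: records[i].species_id):
            bd = scenario_benefit(i, ledger, O, T_eff, W, config)
            candidates.append((i, bd, costs[i]))
        positive = [c for c in candidates if c[1].total > BENEFIT_EPS]
        pool = positive if positive else candidates
        use_fallback = not positive

        def sort_key(c):
            i, bd, cost = c
            if use_fallback:
                return (cost, records[i].species_id)
            # max E_i; ties -> lower cost, then lexicographic id
            return (-bd.total / cost, cost, records[i].species_id)

        pool = sorted(pool, key=sort_key)
        chosen = None
        if config.greedy_budget_rule == "stop_at_first":
            best = pool[0]
            if best[2] <= budget_left:
                chosen = best
        else:  # skip_and_continue
            for c in pool:
                if c[2] <= budget_left:
                    chosen = c
                    break
        if chosen is None:
            break
        i, bd, cost = chosen
        before = ledger.accrued_per_recipient()
        accrue(i, ledger, O, T_eff, breakdown=bd)
        after = ledger.accrued_per_recipient()
        newly = int(((before <= thr) & (after > thr)).sum())
        spend += cost
        rank += 1
        ei = bd.total / cost
        steps.append(
            PriorityStep(
                rank=rank,
                species_id=records[i].species_id,
                marginal_benefit=bd.total,
                ratio=ei,
                cost=cost,
                cumulative_spend=spend,
                n_newly_benefitting=newly,
            )
        )
        logger.info(
            "iteration=%d chosen=%s E_i=%.6g spend=%.6g",
            rank, records[i].species_id, ei, spend,
        )
        remaining.discard(i)
    id_to_index = {r.species_id: k for k, r in enumerate(records)}
    selected = [id_to_index[s.species_id] for s in steps]
    counts = count_benefitting(ledger, config, selected)
    categories: dict[str, str] = {}
    for i in selected:
        cross = ledger.contributions[i].copy()
        cross[i] = 0.0
        categories[records[i].species_id] = (
            "umbrella" if (cross > thr).any() else "additional"
        )
    return PriorityList(
        steps=steps,
        budget=config.budget,
        final_ledger=ledger,
        species_ids=tuple(r.species_id for r in records),
        counts=counts,
        categories=categories,
    )


def selection_benefit(
    indices: Sequence[int],
    O: OverlapMatrix,
    T: ThreatMatrix,
    W: np.ndarray,
    config: RunConfig,
) -> float:
    """Total accrued scenario benefit of a fixed selection.

    The selection is accrued in ascending index order.  With the
    ``recipient`` denominator (or unit weights and equal umbrella threat
    counts) the total is order-invariant because final capped coverage
    is; with the ``umbrella`` denominator the split of a capped increment
    between umbrellas can depend on order, so this canonical order makes
    subset values well defined and comparable.
    """
    ledger, bds = evaluate_selection(sorted(indices), O, T, W, config)
    return float(sum(bd.total for bd in bds))


def brute_force_optimum(
    records: Sequence[SpeciesRecord],
    O: OverlapMatrix,
    T: ThreatMatrix,
    W: np.ndarray,
    config: RunConfig,
    max_n: int = 15,
) -> tuple[tuple[str, ...], float]:
    """Exhaustive subset search for small instances (oracle for the greedy).

    Enumerates every subset of eligible species within budget and
    returns the one maximizing total accrued benefit (ties: smaller
    cost, then lexicographic id tuple), with the same ledger semantics
    as the greedy.  Refuses instances with more than ``max_n`` species.
    """
    n = len(records)
    if n > max_n:
        raise ValueError(
            f"brute force refused: {n} species exceeds max_n={max_n} "
            f"(2^{n} subsets)"
        )
    T_eff, eligible = _prepare(records, T, config)
    model = CostModel.from_config(config)
    costs = {i: action_cost(records[i].range_area, model) for i in eligible}
    best: tuple[float, float, tuple[str, ...], tuple[int, ...]] | None = None
    for r in range(len(eligible) + 1):
        for subset in itertools.combinations(sorted(eligible), r):
            cost = sum(costs[i] for i in subset)
            if cost > config.budget:
                continue
            benefit = selection_benefit(subset, O, T_eff, W, config)
            ids = tuple(sorted(records[i].species_id for i in subset))
            key = (-benefit, cost, ids)
            if best is None or key < (-best[0], best[1], best[2]):
                best = (benefit, cost, ids, subset)
    assert best is not None  # the empty subset is always feasible
    return best[2], float(best[0])


def consistency(list_a, list_b) -> float:
    """Jaccard membership overlap between two priority lists, in percent.

    Order is ignored; two empty lists are 100% consistent by convention.
    """
    a = set(list_a.members if isinstance(list_a, PriorityList) else list_a)
    b = set(list_b.members if isinstance(list_b, PriorityList) else list_b)
    if not a and not b:
        return 100.0
    return 100.0 * len(a & b) / len(a | b)


@dataclass
class SensitivityReport:
    """Greedy runs across cost exponents z and their pairwise consistency."""

    z_values: list[float]
    lists: dict[float, PriorityList]
    consistency: dict[tuple[float, float], float]


def sensitivity_analysis(
    records: Sequence[SpeciesRecord],
    O: OverlapMatrix,
    T: ThreatMatrix,
    W: np.ndarray,
    config: RunConfig,
    z_values: Sequence[float],
) -> SensitivityReport:
    """Rerun the greedy per z (same budget) and compare list membership."""
    if len(z_values) < 2:
        raise ValueError("sensitivity analysis needs at least 2 z values")
    lists: dict[float, PriorityList] = {}
    for z in z_values:
        lists[z] = greedy_prioritize(records, O, T, W, replace(config, cost_z=z))
    pairwise = {
        (za, zb): consistency(lists[za], lists[zb])
        for za, zb in itertools.combinations(z_values, 2)
    }
    return SensitivityReport(
        z_values=list(z_values), lists=lists, consistency=pairwise
    )


@dataclass
class EfficiencyComparison:
    """Reference list vs greedy optimization under the reference's budget."""

    assumed_budget: float
    reference_counts: BenefitCounts
    optimized_counts: BenefitCounts
    fold_ratio: float
    optimized: PriorityList


def efficiency_comparison(
    reference_ids: Sequence[str],
    records: Sequence[SpeciesRecord],
    O: OverlapMatrix,
    T: ThreatMatrix,
    W: np.ndarray,
    config: RunConfig,
) -> EfficiencyComparison:
    """Compare a reference management list against the optimized selection.

    The cost of managing the reference list becomes the assumed budget;
    the greedy is run under that budget and the benefitting-species
    counts (and their fold ratio) are reported.
    """
    if not reference_ids:
        raise ValueError("reference list is empty: assumed budget would be zero")
    id_to_index = {r.species_id: k for k, r in enumerate(records)}
    missing = [sid for sid in reference_ids if sid not in id_to_index]
    if missing:
        raise UnknownSpeciesError(f"unknown reference species: {missing}")
    model = CostModel.from_config(config)
    assumed = portfolio_cost(reference_ids, records, model)
    cfg = replace(config, budget=assumed)
    T_eff = T.without(cfg.unmanageable_threats) if cfg.unmanageable_threats else T
    ref_indices = [id_to_index[sid] for sid in reference_ids]
    ref_ledger, _ = evaluate_selection(ref_indices, O, T_eff, W, cfg)
    ref_counts = count_benefitting(ref_ledger, cfg, ref_indices)
    optimized = greedy_prioritize(records, O, T, W, cfg)
    fold = (
        optimized.counts.total_benefitting / ref_counts.total_benefitting
        if ref_counts.total_benefitting
        else float("inf")
    )
    return EfficiencyComparison(
        assumed_budget=assumed,
        reference_counts=ref_counts,
        optimized_counts=optimized.counts,
        fold_ratio=fold,
        optimized=optimized,
    )


def summarize(result: PriorityList, config: RunConfig) -> dict:
    """Run summary for summary.json."""
    return {
        "scenario": config.scenario,
        "benefit_denominator": config.benefit_denominator,
        "counts": {
            "umbrella": result.counts.umbrella,
            "benefitting": result.counts.benefitting,
            "additional": result.counts.additional,
            "total_benefitting": result.counts.total_benefitting,
        },
        "total_benefit": round(result.total_benefit, 9),
        "spend": round(result.spend, 9),
        "budget": result.budget,
    }
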