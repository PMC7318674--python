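"""Greedy selection, exhaustive oracle, sensitivity and efficiency analyses."""

from dataclasses import replace

import numpy as np
import pytest

from umbrellapick import (
    RunConfig,
    brute_force_optimum,
    consistency,
    efficiency_comparison,
    greedy_prioritize,
    selection_benefit,
    sensitivity_analysis,
    unit_weights,
)
from umbrellapick.cost import CostModel, action_cost, portfolio_cost
from umbrellapick.synthgen import make_two_list_fixture

from conftest import small_random_instance


def _cfg(**kw):
    kw.setdefault("budget", 1000.0)
    return RunConfig(**kw)


class TestGreedyOnHandDerivedInstance:
    """Frozen step-by-step derivation for the 6-species instance.

    With q=1, z=0.5 and the umbrella denominator, hand evaluation of
    E_i at each iteration gives (budget 40, skip_and_continue):
      step 1: d  E = (1 + 1/9)/5  = 0.2222  (d benefits e by 1/9)
      step 2: a  E = 1.5/10       = 0.15    (a benefits b by 0.5)
      step 3: f  E = 1/8          = 0.125   (best candidate; c's E = 0.1)
      step 4: b  E = 0.875/10     = 0.0875  (c at E=0.1 costs 20 > 17 left,
                                             so it is skipped)
      then nothing is affordable with 7 left -> stop.
    Under stop_at_first the run ends at step 4's unaffordable best (c).
    """

    def _run(self, six_species, **kw):
        records, O, T = six_species
        cfg = _cfg(cost_q=1.0, cost_z=0.5, budget=40.0, **kw)
        return greedy_prioritize(records, O, T, unit_weights(6), cfg)

    def test_selection_sequence_matches_hand_derivation(self, six_species):
        result = self._run(six_species)
        assert result.members == ["d", "a", "f", "b"]
        assert [s.marginal_benefit for s in result.steps] == pytest.approx(
            [1 + 1 / 9, 1.5, 1.0, 0.875]
        )
        assert [s.ratio for s in result.steps] == pytest.approx(
            [(1 + 1 / 9) / 5, 0.15, 0.125, 0.0875]
        )
        assert [s.cumulative_spend for s in result.steps] == pytest.approx(
            [5.0, 15.0, 23.0, 33.0]
        )
        assert [s.n_newly_benefitting for s in result.steps] == [2, 2, 1, 1]

    def test_stop_at_first_ends_at_unaffordable_best(self, six_species):
        result = self._run(six_species, greedy_budget_rule="stop_at_first")
        assert result.members == ["d", "a", "f"]

    def test_categorization_of_hand_instance(self, six_species):
        result = self._run(six_species)
        assert result.categories == {
            "d": "umbrella", "a": "umbrella", "b": "umbrella", "f": "additional",
        }
        c = result.counts
        assert (c.umbrella, c.benefitting, c.additional, c.total_benefitting) \
            == (3, 2, 1, 6)


class TestGreedyEdgeCases:
    def test_unconstrained_budget_selects_everyone_with_self_benefit(self, six_species):
        records, O, T = six_species
        cfg = _cfg(cost_q=1.0, cost_z=0.5, budget=1e6)
        result = greedy_prioritize(records, O, T, unit_weights(6), cfg)
        assert sorted(result.members) == ["a", "b", "c", "d", "e", "f"]

    def test_budget_below_every_cost_selects_nothing(self, six_species):
        records, O, T = six_species
        cfg = _cfg(cost_q=1.0, cost_z=0.5, budget=1.0)
        result = greedy_prioritize(records, O, T, unit_weights(6), cfg)
        assert result.members == []
        assert result.spend == 0.0

    def test_zero_threat_species_excluded_from_selection(self, six_species):
        records, O, T = six_species
        # make every threat of f unmanageable -> f drops out
        cfg = _cfg(cost_q=1.0, cost_z=0.5, budget=1e6,
                   unmanageable_threats=("t4",))
        result = greedy_prioritize(records, O, T, unit_weights(6), cfg)
        assert "f" not in result.members
        assert sorted(result.members) == ["a", "b", "c", "d", "e"]

    def test_selected_species_never_reappears(self, six_species):
        records, O, T = six_species
        cfg = _cfg(cost_q=1.0, cost_z=0.5, budget=1e6)
        result = greedy_prioritize(records, O, T, unit_weights(6), cfg)
        assert len(result.members) == len(set(result.members))


class TestBruteForceOracle:
    def test_singleton_universe_within_budget(self):
        from umbrellapick import OverlapMatrix, SpeciesRecord, ThreatMatrix

        recs = [SpeciesRecord("only", "x", 16.0, frozenset({"t"}))]
        O = OverlapMatrix(values=np.eye(1), species_ids=("only",))
        T = ThreatMatrix.from_records(recs)
        ids, benefit = brute_force_optimum(
            recs, O, T, unit_weights(1), _cfg(cost_q=1.0, cost_z=0.5)
        )
        assert ids == ("only",)
        assert benefit == pytest.approx(1.0)

    def test_refuses_oversized_instances(self):
        records, O, T, W, cfg = small_random_instance(0, n_species=8)
        with pytest.raises(ValueError, match="max_n"):
            brute_force_optimum(records, O, T, W, cfg, max_n=5)

    def test_cheap_complementary_pair_beats_greedy_favorite(self):
        """Constructed counterexample: greedy grabs the big umbrella whose
        cost then blocks the two cheap complementary species that jointly
        accrue more benefit."""
        from umbrellapick import OverlapMatrix, SpeciesRecord, ThreatMatrix

        # big: covers 60% of x and y; cheap1/cheap2: cover x and y fully
        cells_big = frozenset(range(0, 60)) | frozenset(range(100, 160))
        cells_x = frozenset(range(0, 100))
        cells_y = frozenset(range(100, 200))
        cells_c1 = cells_x
        cells_c2 = cells_y
        recs = [
            SpeciesRecord("big", "big", float(len(cells_big)),
                          frozenset({"t"}), cells_big),
            SpeciesRecord("c1", "c1", 100.0, frozenset({"t"}), cells_c1),
            SpeciesRecord("c2", "c2", 100.0, frozenset({"t"}), cells_c2),
            SpeciesRecord("x", "x", 100.0, frozenset({"t"}), cells_x),
            SpeciesRecord("y", "y", 100.0, frozenset({"t"}), cells_y),
        ]
        O = OverlapMatrix.from_geometries(recs)
        T = ThreatMatrix.from_records(recs)
        W = unit_weights(5)
        # costs: big = 120^0.5 ~ 10.95, c1 = c2 = 10; budget fits big alone
        # or both cheap species but not big + anything
        cfg = _cfg(cost_q=1.0, cost_z=0.5, budget=20.5,
                   benefit_denominator="recipient")
        greedy = greedy_prioritize(recs, O, T, W, cfg)
        best_ids, best_benefit = brute_force_optimum(recs, O, T, W, cfg)
        assert greedy.members[0] == "big"      # highest single E_i
        assert best_ids == ("c1", "c2")        # optimum is the cheap pair
        greedy_total = selection_benefit(
            [0], O, T, W, cfg
        )
        assert best_benefit > greedy_total

    def test_greedy_never_beats_oracle_and_dominates_best_single(self):
        rng_seeds = range(40)
        for seed in rng_seeds:
            records, O, T, W, cfg = small_random_instance(seed, n_species=7)
            greedy = greedy_prioritize(records, O, T, W, cfg)
            id_to_index = {r.species_id: k for k, r in enumerate(records)}
            greedy_total = selection_benefit(
                [id_to_index[s] for s in greedy.members], O, T, W, cfg
            )
            _, best = brute_force_optimum(records, O, T, W, cfg)
            assert greedy_total <= best + 1e-9
            model = CostModel.from_config(cfg)
            singles = [
                selection_benefit([i], O, T, W, cfg)
                for i, r in enumerate(records)
                if action_cost(r.range_area, model) <= cfg.budget
                and r.threats
            ]
            if singles:
                assert greedy_total >= max(singles) - 1e-9


class TestConsistency:
    def test_identical_lists_are_fully_consistent(self):
        assert consistency(["a", "b"], ["b", "a"]) == 100.0

    def test_disjoint_lists_have_zero_consistency(self):
        assert consistency(["a"], ["b"]) == 0.0

    def test_half_overlapping_lists(self):
        assert consistency(["a", "b", "c"], ["a", "b", "d"]) == pytest.approx(50.0)

    def test_two_empty_lists_by_convention(self):
        assert consistency([], []) == 100.0


class TestSensitivity:
    def test_duplicate_z_values_are_fully_consistent(self, six_species):
        records, O, T = six_species
        cfg = _cfg(cost_q=1.0, cost_z=0.5, budget=40.0)
        report = sensitivity_analysis(
            records, O, T, unit_weights(6), cfg, [0.3, 0.3001, 0.3]
        )
        assert report.consistency[(0.3, 0.3)] == 100.0

    def test_three_z_values_give_three_pairwise_entries(self, six_species):
        records, O, T = six_species
        cfg = _cfg(cost_q=1.0, cost_z=0.5, budget=40.0)
        report = sensitivity_analysis(
            records, O, T, unit_weights(6), cfg, [0.2, 0.3, 0.4]
        )
        assert len(report.consistency) == 3
        assert all(0 <= v <= 100 for v in report.consistency.values())

    def test_fewer_than_two_z_values_rejected(self, six_species):
        records, O, T = six_species
        with pytest.raises(ValueError):
            sensitivity_analysis(records, O, T, unit_weights(6),
                                 _cfg(), [0.3])

    def test_equal_areas_give_identical_lists_after_budget_rescaling(self):
        """With all ranges equal, changing z only rescales every cost by the
        same factor; rescaling the budget likewise leaves the run unchanged."""
        from umbrellapick import OverlapMatrix, SpeciesRecord, ThreatMatrix

        rng = np.random.default_rng(3)
        n = 6
        cells = []
        for i in range(n):
            start = int(rng.integers(0, 60))
            cells.append(frozenset(range(start, start + 40)))
        recs = [
            SpeciesRecord(f"s{i}", "x", 40.0,
                          frozenset({f"t{int(k)}" for k in
                                     rng.choice(3, size=2, replace=False)}),
                          cells[i])
            for i in range(n)
        ]
        O = OverlapMatrix.from_geometries(recs)
        T = ThreatMatrix.from_records(recs)
        W = unit_weights(n)
        members = {}
        for z in (0.2, 0.4):
            budget = 3.5 * action_cost(40.0, CostModel(q=1.0, z=z))
            cfg = _cfg(cost_q=1.0, cost_z=z, budget=budget)
            members[z] = greedy_prioritize(recs, O, T, W, cfg).members
        assert members[0.2] == members[0.4]


class TestEfficiencyComparison:
    def test_self_comparison_has_unit_fold_ratio(self, six_species):
        records, O, T = six_species
        W = unit_weights(6)
        cfg = _cfg(cost_q=1.0, cost_z=0.5, budget=40.0)
        greedy = greedy_prioritize(records, O, T, W, cfg)
        comp = efficiency_comparison(greedy.members, records, O, T, W, cfg)
        assert comp.fold_ratio == pytest.approx(1.0)

    def test_clustered_fixture_beats_reference_list(self):
        records, O, T, reference_ids = make_two_list_fixture()
        W = unit_weights(len(records))
        cfg = _cfg(cost_q=1.0, cost_z=0.3)
        comp = efficiency_comparison(reference_ids, records, O, T, W, cfg)
        assert comp.reference_counts.total_benefitting >= len(reference_ids)
        assert comp.fold_ratio > 1.0
        assert comp.optimized.spend <= comp.assumed_budget + 1e-9

    def test_empty_reference_list_is_an_error(self, six_species):
        records, O, T = six_species
        with pytest.raises(ValueError, match="empty"):
            efficiency_comparison([], records, O, T, unit_weights(6), _cfg())


class TestRunInvariants:
    @pytest.mark.parametrize("seed", range(8))
    def test_budget_feasibility_and_ledger_bounds(self, seed):
        records, O, T, W, cfg = small_random_instance(seed)
        result = greedy_prioritize(records, O, T, W, cfg)
        assert result.spend <= cfg.budget + 1e-9
        cov = result.final_ledger.coverage
        assert (cov >= 0).all() and (cov <= 1 + 1e-12).all()
        # each step's spend is the prefix sum of costs
        cum = 0.0
        for step in result.steps:
            cum += step.cost
            assert step.cumulative_spend == pytest.approx(cum)

    @pytest.mark.parametrize("seed", range(4))
    def test_chosen_ratio_is_maximal_among_candidates(self, seed):
        """Re-derive each step's E_i field from an independent replay of
        the ledger and confirm the chosen species maximizes it."""
        from umbrellapick.benefit import AccrualLedger, accrue, scenario_benefit

        records, O, T, W, cfg = small_random_instance(seed)
        result = greedy_prioritize(records, O, T, W, cfg)
        model = CostModel.from_config(cfg)
        ledger = AccrualLedger(len(records), T.n_threats)
        remaining = set(range(len(records)))
        id_to_index = {r.species_id: k for k, r in enumerate(records)}
        for step in result.steps:
            i = id_to_index[step.species_id]
            ratios = {}
            for j in remaining:
                cost = action_cost(records[j].range_area, model)
                if cost > cfg.budget - (step.cumulative_spend - step.cost):
                    continue
                bd = scenario_benefit(j, ledger, O, T, W, cfg)
                ratios[j] = bd.total / cost
            assert ratios[i] == pytest.approx(max(ratios.values()))
            assert step.ratio == pytest.approx(ratios[i])
            bd = scenario_benefit(i, ledger, O, T, W, cfg)
            accrue(i, ledger, O, T, breakdown=bd)
            remaining.discard(i)
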