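"""Core domain types for threat-aware umbrella-species prioritization.

The central objects are a species assemblage (identity, geographic range
area, species-specific threat profile, optional gridded geometry), a binary
species x threat matrix T, and an asymmetric range-overlap matrix O where
``O[i, j]`` is the fraction of the *recipient* species j's range that is
intersected by species i's range.  The overlap convention is
recipient-normalized throughout: ``O[i, j] * area_j`` equals the
intersection area, so ``O[i, j] * area_j == O[j, i] * area_i``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger("umbrellapick")

SCENARIOS = ("baseline", "optimistic", "pessimistic")
DENOMINATOR_MODES = ("umbrella", "recipient")
BUDGET_RULES = ("skip_and_continue", "stop_at_first")

#: Relative tolerance for the intersection-area consistency identity
#: O[i, j] * area_j == O[j, i] * area_i.
OVERLAP_CONSISTENCY_RTOL = 1e-9

#: Relative tolerance between a record's declared range area and the area
#: implied by its grid-cell geometry (cell count x cell area).
GEOMETRY_AREA_RTOL = 5e-3


class DataFormatError(ValueError):
    """A file or table does not have the expected structure."""


class DataValidationError(ValueError):
    """Structurally well-formed input violates a domain invariant."""


class ConfigError(ValueError):
    """A run-configuration value is out of its allowed domain."""


class UndefinedBenefitError(ValueError):
    """Benefit ratio requested for a species with an empty threat set."""


class DoubleAccrualError(RuntimeError):
    """A species was accrued to the management ledger twice."""


class UnknownSpeciesError(KeyError):
    """A species id was referenced that is not in the assemblage."""


@dataclass(frozen=True)
class SpeciesRecord:
    """One threatened species.

    Parameters
    ----------
    species_id
        Unique string token.
    name
        Free-text name.
    range_area
        Geographic range size in km^2 (> 0).
    threats
        Identifiers of the threatening processes affecting the species.
        A species with an empty threat set is accepted but has an
        undefined benefit ratio and is excluded from selection.
    geometry
        Optional set of landscape grid-cell indices on a shared grid.
    """

    species_id: str
    name: str
    range_area: float
    threats: frozenset[str]
    geometry: Optional[frozenset[int]] = None

    def validate(self, cell_area: float = 1.0) -> None:
        if not self.species_id:
            raise DataValidationError("species_id must be a non-empty string")
        if not np.isfinite(self.range_area) or self.range_area <= 0:
            raise DataValidationError(
                f"species {self.species_id!r}: range_area must be positive, "
                f"got {self.range_area!r}"
            )
        if self.geometry is not None:
            implied = len(self.geometry) * cell_area
            if implied == 0 or abs(implied - self.range_area) > GEOMETRY_AREA_RTOL * self.range_area:
                raise DataValidationError(
                    f"species {self.species_id!r}: geometry implies area "
                    f"{implied} but range_area is {self.range_area}"
                )


def validate_records(records: Sequence[SpeciesRecord], cell_area: float = 1.0) -> None:
    """Validate a full assemblage: per-record invariants plus id uniqueness.

    Species with empty threat sets are accepted with a logged warning;
    downstream selection and benefit accrual skip them.
    """
    seen: set[str] = set()
    dupes: list[str] = []
    for rec in records:
        rec.validate(cell_area=cell_area)
        if rec.species_id in seen:
            dupes.append(rec.species_id)
        seen.add(rec.species_id)
    if dupes:
        raise DataValidationError(f"duplicate species_id values: {sorted(set(dupes))}")
    for rec in records:
        if not rec.threats:
            logger.warning(
                "species %s has no listed threats; it will be excluded from "
                "selection and benefit accrual", rec.species_id,
            )


@dataclass
class ThreatMatrix:
    """Binary species x threat indicator matrix.

    ``values[i, k] == 1`` iff threat ``threat_ids[k]`` affects species
    ``species_ids[i]``.  Threat vocabulary order is the file/record
    encounter order and is fixed thereafter.
    """

    values: np.ndarray
    threat_ids: tuple[str, ...]
    species_ids: tuple[str, ...]

    @classmethod
    def from_records(
        cls,
        records: Sequence[SpeciesRecord],
        vocabulary: Optional[Sequence[str]] = None,
    ) -> "ThreatMatrix":
        """Build the matrix from per-record threat sets.

        The vocabulary defaults to encounter order over records (each
        record's threats in sorted order within a record, records in
        sequence order).
        """
        if vocabulary is None:
            vocab: list[str] = []
            seen: set[str] = set()
            for rec in records:
                for t in sorted(rec.threats):
                    if t not in seen:
                        seen.add(t)
                        vocab.append(t)
        else:
            vocab = list(vocabulary)
            missing = {t for rec in records for t in rec.threats} - set(vocab)
            if missing:
                raise DataValidationError(
                    f"threats outside supplied vocabulary: {sorted(missing)}"
                )
        index = {t: k for k, t in enumerate(vocab)}
        values = np.zeros((len(records), len(vocab)), dtype=np.int8)
        for i, rec in enumerate(records):
            for t in rec.threats:
                values[i, index[t]] = 1
        return cls(
            values=values,
            threat_ids=tuple(vocab),
            species_ids=tuple(r.species_id for r in records),
        )

    @property
    def n_species(self) -> int:
        return self.values.shape[0]

    @property
    def n_threats(self) -> int:
        return self.values.shape[1]

    def threat_counts(self) -> np.ndarray:
        """Number of threats per species (row sums)."""
        return self.values.sum(axis=1)

    def without(self, threat_ids: Iterable[str]) -> "ThreatMatrix":
        """Return a copy with the given threat columns zeroed.

        Used for threats with no feasible management action: they yield
        zero benefit but do not change range areas or costs.
        """
        drop = set(threat_ids)
        unknown = drop - set(self.threat_ids)
        if unknown:
            raise DataValidationError(f"unknown threat ids: {sorted(unknown)}")
        values = self.values.copy()
        for k, t in enumerate(self.threat_ids):
            if t in drop:
                values[:, k] = 0
        return ThreatMatrix(values=values, threat_ids=self.threat_ids,
                            species_ids=self.species_ids)

    def validate(self, records: Optional[Sequence[SpeciesRecord]] = None) -> None:
        if not np.isin(self.values, (0, 1)).all():
            raise DataValidationError("threat matrix entries must be exactly 0 or 1")
        if self.values.shape != (len(self.species_ids), len(self.threat_ids)):
            raise DataValidationError("threat matrix shape does not match id lists")
        if records is not None:
            for i, rec in enumerate(records):
                row = {self.threat_ids[k] for k in np.flatnonzero(self.values[i])}
                if row != set(rec.threats):
                    raise DataValidationError(
                        f"threat matrix row for {rec.species_id!r} disagrees "
                        f"with its record threat set"
                    )


@dataclass
class OverlapMatrix:
    """Asymmetric pairwise range-overlap matrix.

    ``values[i, j]`` is the fraction of species j's range intersected by
    species i's range: area(range_i & range_j) / area(range_j).  The
    diagonal is exactly 1.
    """

    values: np.ndarray
    species_ids: tuple[str, ...]

    @classmethod
    def from_geometries(cls, records: Sequence[SpeciesRecord]) -> "OverlapMatrix":
        """Exact overlaps from grid-cell sets on a shared landscape."""
        missing = [r.species_id for r in records if r.geometry is None]
        if missing:
            raise DataValidationError(
                f"species without geometry: {missing}; supply a precomputed "
                f"overlap matrix CSV instead"
            )
        n = len(records)
        geoms = [r.geometry for r in records]
        sizes = [len(g) for g in geoms]
        values = np.zeros((n, n), dtype=float)
        for i in range(n):
            for j in range(n):
                if i == j:
                    values[i, j] = 1.0
                else:
                    values[i, j] = len(geoms[i] & geoms[j]) / sizes[j]
        return cls(values=values, species_ids=tuple(r.species_id for r in records))

    @property
    def n_species(self) -> int:
        return self.values.shape[0]

    def validate(
        self,
        areas: Optional[Sequence[float]] = None,
        entry_quantum: float = 0.0,
    ) -> None:
        """Check invariants; ``entry_quantum`` is the absolute rounding
        step of the stored entries (e.g. 1e-6 for a 6-decimal CSV), which
        widens the intersection-consistency tolerance accordingly."""
        v = self.values
        n = v.shape[0]
        if v.shape != (n, n) or n != len(self.species_ids):
            raise DataValidationError("overlap matrix must be square and match ids")
        bad = np.argwhere((v < 0) | (v > 1))
        if bad.size:
            i, j = bad[0]
            raise DataValidationError(
                f"overlap entry out of [0, 1] at row {self.species_ids[i]!r}, "
                f"column {self.species_ids[j]!r}: {v[i, j]}"
            )
        if not np.allclose(np.diag(v), 1.0, rtol=0, atol=1e-12):
            k = int(np.argmax(np.abs(np.diag(v) - 1.0)))
            raise DataValidationError(
                f"diagonal overlap for {self.species_ids[k]!r} is {v[k, k]}, "
                f"must be exactly 1"
            )
        if areas is not None:
            a = np.asarray(areas, dtype=float)
            lhs = v * a[np.newaxis, :]      # O[i, j] * area_j
            rhs = (v * a[np.newaxis, :]).T  # O[j, i] * area_i
            scale = np.maximum(np.abs(lhs), np.abs(rhs))
            err = np.abs(lhs - rhs)
            quant = 0.6 * entry_quantum * (a[np.newaxis, :] + a[:, np.newaxis])
            bad = np.argwhere(
                err > OVERLAP_CONSISTENCY_RTOL * np.maximum(scale, 1.0) + quant
            )
            if bad.size:
                i, j = bad[0]
                raise DataValidationError(
                    f"inconsistent intersection areas for pair "
                    f"({self.species_ids[i]!r}, {self.species_ids[j]!r}): "
                    f"O[i,j]*area_j={lhs[i, j]} vs O[j,i]*area_i={rhs[i, j]}"
                )


def unit_weights(n: int) -> np.ndarray:
    """Default species weight vector: all ones."""
    return np.ones(n, dtype=float)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one prioritization run.

    Parameters
    ----------
    budget
        Available spend per year, in the same (unit-agnostic) currency as
        the cost model output.  Must be positive.
    scenario
        Benefit scenario: ``baseline`` (benefit proportional to managed
        overlap, per threat), ``optimistic`` (a species benefits once any
        one shared threat is managed over the overlap) or ``pessimistic``
        (benefit only on complete management of every threat across the
        species' entire range).
    benefit_denominator
        Threat-ratio denominator: ``umbrella`` divides shared threats by
        the managed species' threat count, ``recipient`` by the receiving
        species' threat count.
    cost_q
        Cost-model scale: cost units per km^{2z} per year.
    cost_z
        Diminishing-returns exponent of the power-law cost, in (0, 1].
    greedy_budget_rule
        ``skip_and_continue`` skips unaffordable candidates and keeps
        scanning; ``stop_at_first`` ends the run when the best candidate
        is unaffordable.
    benefit_threshold
        Accrued benefit a species must exceed to be counted as
        benefitting (default 0: any positive accrual counts).
    seed
        Seed for any randomized component (the optimizer itself is
        deterministic).
    unmanageable_threats
        Threats with no feasible action; stripped from the threat matrix
        before benefit computation, leaving costs unchanged.
    """

    budget: float
    scenario: str = "baseline"
    benefit_denominator: str = "umbrella"
    cost_q: float = 1.0
    cost_z: float = 0.3
    greedy_budget_rule: str = "skip_and_continue"
    benefit_threshold: float = 0.0
    seed: int = 0
    unmanageable_threats: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.budget > 0) or not np.isfinite(self.budget):
            raise ConfigError(f"budget must be positive, got {self.budget!r}")
        if self.scenario not in SCENARIOS:
            raise ConfigError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        if self.benefit_denominator not in DENOMINATOR_MODES:
            raise ConfigError(
                f"unknown benefit_denominator {self.benefit_denominator!r}; "
                f"expected one of {DENOMINATOR_MODES}"
            )
        if self.greedy_budget_rule not in BUDGET_RULES:
            raise ConfigError(
                f"unknown greedy_budget_rule {self.greedy_budget_rule!r}; "
                f"expected one of {BUDGET_RULES}"
            )
        if not (self.cost_q > 0):
            raise ConfigError(f"cost_q must be positive, got {self.cost_q!r}")
        if not (0 < self.cost_z <= 1):
            raise ConfigError(f"cost_z must be in (0, 1], got {self.cost_z!r}")
        if self.benefit_threshold < 0:
            raise ConfigError(
                f"benefit_threshold must be nonnegative, got {self.benefit_threshold!r}"
            )
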