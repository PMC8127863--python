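"""Expected pair counts under the random-mating null hypothesis.

Under random mating, pair composition reflects only the relative abundance
of available partners.  With P observed pairs:

* **Limited choice** (choosing class pairs with certainty, partners of its
  own sex absent): the expected number of homo-specific pairs is
  ``E_homo = P * F_homo / (F_homo + F_hetero)`` where ``F_x`` is the total
  number of partner-sex worms of species *x*, paired and single alike.
  This is the mean of the hypergeometric distribution that arises from
  drawing P partners uniformly without replacement.
* **Full choice** (all four combinations possible): the product-marginal
  form ``E(i, j) = P * (M_i / M) * (F_j / F)`` with class totals again
  counting paired plus single worms.

Both forms conserve the total: ``sum(E) == P`` exactly.  Expectations are
kept at full floating precision; the half-up-rounded integers exist only
for display, mirroring the bracketed values of the source tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .records import (
    FEMALE,
    FULL_CHOICE,
    LIMITED_CHOICE,
    MALE,
    DegenerateDataError,
    IncompleteDataError,
    MateChoiceDesign,
    MateChoiceError,
    PairCountTable,
    PairKey,
)

__all__ = ["NullExpectation", "expected_limited", "expected_full", "null_expectation", "round_half_up"]


def round_half_up(x: float) -> int:
    """Round a non-negative real to the nearest integer, ties away from zero."""
    if x < 0:
        raise ValueError(f"expected a non-negative value, got {x}")
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class NullExpectation:
    """Expected pair counts of one host under random mating."""

    expected: Mapping[PairKey, float]
    total_pairs: int

    @property
    def expected_rounded(self) -> dict[PairKey, int]:
        return {k: round_half_up(v) for k, v in self.expected.items()}

    def __post_init__(self) -> None:
        total = sum(self.expected.values())
        if not math.isclose(total, self.total_pairs, rel_tol=0, abs_tol=1e-9):
            raise MateChoiceError(
                f"expectations sum to {total}, not the observed {self.total_pairs} pairs"
            )


def _require_complete(table: PairCountTable) -> None:
    if table.incomplete:
        raise IncompleteDataError(
            f"host {table.host_id} is flagged incomplete; expectations are undefined"
        )


def expected_limited(table: PairCountTable, design: MateChoiceDesign) -> NullExpectation:
    """Random-mating expectations for a limited-choice host.

    The partner pool is the opposite sex; its per-species totals count both
    paired and single worms.  Raises :class:`DegenerateDataError` when the
    host has no pairs or no partner-sex worms.
    """
    if design.kind != LIMITED_CHOICE:
        raise MateChoiceError("expected_limited requires a limited-choice design")
    _require_complete(table)
    table.validate_against(design)

    P = table.total_pairs
    if P == 0:
        raise DegenerateDataError(f"host {table.host_id}: no pairs observed")
    partner_sex = design.partner_sex
    homo_key, hetero_key = design.pair_keys
    f_homo = table.class_total(partner_sex, design.choosing_species)
    f_hetero = table.class_total(partner_sex, design.other_species)
    f_total = f_homo + f_hetero
    if f_total == 0:
        raise DegenerateDataError(f"host {table.host_id}: no partner-sex worms")
    if f_total < P:
        raise MateChoiceError(
            f"host {table.host_id}: {P} pairs but only {f_total} partner-sex worms"
        )
    expected = {homo_key: P * f_homo / f_total, hetero_key: P * f_hetero / f_total}
    return NullExpectation(expected=expected, total_pairs=P)


def expected_full(table: PairCountTable, design: MateChoiceDesign | None = None) -> NullExpectation:
    """Random-mating expectations for a full-choice host (product-marginal form)."""
    if design is None:
        design = MateChoiceDesign(FULL_CHOICE, species_pair=_infer_species(table))
    if design.kind != FULL_CHOICE:
        raise MateChoiceError("expected_full requires a full-choice design")
    _require_complete(table)
    table.validate_against(design)

    P = table.total_pairs
    if P == 0:
        raise DegenerateDataError(f"host {table.host_id}: no pairs observed")
    m = {sp: table.class_total(MALE, sp) for sp in design.species_pair}
    f = {sp: table.class_total(FEMALE, sp) for sp in design.species_pair}
    m_total, f_total = sum(m.values()), sum(f.values())
    if m_total == 0 or f_total == 0:
        raise DegenerateDataError(f"host {table.host_id}: a sex has no worms at all")
    expected = {
        (i, j): P * (m[i] / m_total) * (f[j] / f_total) for (i, j) in design.pair_keys
    }
    return NullExpectation(expected=expected, total_pairs=P)


def _infer_species(table: PairCountTable) -> tuple[str, str]:
    species = []
    for m, f in table.pair_counts:
        for sp in (m, f):
            if sp not in species:
                species.append(sp)
    if len(species) != 2:
        raise MateChoiceError(f"cannot infer a species pair from {sorted(table.pair_counts)}")
    return tuple(species)  # type: ignore[return-value]


def null_expectation(table: PairCountTable, design: MateChoiceDesign) -> NullExpectation:
    """Dispatch to the limited- or full-choice expectation for *design*."""
    if design.kind == LIMITED_CHOICE:
        return expected_limited(table, design)
    return expected_full(table, design)
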