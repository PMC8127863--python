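"""Data model and I/O for per-host mate-choice observations.

The unit of observation is a *host* (a hamster perfused three months after
exposure): for every pairing combination (male species x female species) the
number of worm pairs recovered, and for every sex x species class the number
of worms that remained single.  Two experimental designs are supported:

* **limited choice** — one sex x species class (the "choosing" class) is
  supplied in deficit so that all of its members pair, and chooses between
  homo- and hetero-specific partners supplied in excess; exactly two pair
  categories are populated.
* **full choice** — both sexes of both species are present, so all four
  pairing combinations can occur.

Counts are observed worm counts at perfusion, not cercarial doses; doses
belong to the simulation layer (:mod:`matechoice.simulate`).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

MALE = "M"
FEMALE = "F"
SEXES = (MALE, FEMALE)

LIMITED_CHOICE = "limited_choice"
FULL_CHOICE = "full_choice"

#: pair-count keys are always (male_species, female_species)
PairKey = tuple[str, str]
#: single-count keys are (sex, species)
ClassKey = tuple[str, str]


class MateChoiceError(ValueError):
    """Base class for all validation and analysis errors in this package."""


class ParseError(MateChoiceError):
    """A malformed cell, row or header in a count-table CSV."""


class DegenerateDataError(MateChoiceError):
    """A table without the minimum structure a computation needs (e.g. no pairs)."""


class IncompleteDataError(MateChoiceError):
    """An operation was asked to consume a table flagged as incomplete."""


@dataclass(frozen=True)
class MateChoiceDesign:
    """Declares the structure of a mate-choice experiment.

    Parameters
    ----------
    kind
        ``"limited_choice"`` or ``"full_choice"``.
    choosing_sex, choosing_species
        The sex and species of the limiting (choosing) class for a
        limited-choice design; both ``None`` for full choice.
    species_pair
        The two species codes, e.g. ``("Sh", "Sb")`` for *Schistosoma
        haematobium* and *S. bovis*.
    """

    kind: str
    choosing_sex: str | None = None
    choosing_species: str | None = None
    species_pair: tuple[str, str] = ("Sh", "Sb")

    def __post_init__(self) -> None:
        if self.kind not in (LIMITED_CHOICE, FULL_CHOICE):
            raise MateChoiceError(f"unknown design kind: {self.kind!r}")
        if len(set(self.species_pair)) != 2:
            raise MateChoiceError("species_pair must hold two distinct labels")
        if self.kind == LIMITED_CHOICE:
            if self.choosing_sex not in SEXES:
                raise MateChoiceError("limited choice requires choosing_sex 'M' or 'F'")
            if self.choosing_species not in self.species_pair:
                raise MateChoiceError(
                    f"choosing_species {self.choosing_species!r} not in {self.species_pair}"
                )
        else:
            if self.choosing_sex is not None or self.choosing_species is not None:
                raise MateChoiceError("full choice admits no choosing class")

    @property
    def partner_sex(self) -> str | None:
        """The sex supplied in excess (the one being chosen among)."""
        if self.choosing_sex is None:
            return None
        return FEMALE if self.choosing_sex == MALE else MALE

    @property
    def other_species(self) -> str | None:
        if self.choosing_species is None:
            return None
        a, b = self.species_pair
        return b if self.choosing_species == a else a

    @property
    def pair_keys(self) -> tuple[PairKey, ...]:
        """Populated pair categories, homo-specific first."""
        a, b = self.species_pair
        if self.kind == FULL_CHOICE:
            return ((a, a), (b, b), (a, b), (b, a))
        s, o = self.choosing_species, self.other_species
        if self.choosing_sex == MALE:
            return ((s, s), (s, o))
        return ((s, s), (o, s))

    @property
    def classes(self) -> tuple[ClassKey, ...]:
        """Every sex x species class that can occur under this design."""
        keys: list[ClassKey] = []
        for m, f in self.pair_keys:
            for k in ((MALE, m), (FEMALE, f)):
                if k not in keys:
                    keys.append(k)
        return tuple(keys)


def _check_count(value: int | None, *, incomplete: bool, what: str) -> None:
    if value is None:
        if not incomplete:
            raise MateChoiceError(f"{what}: missing count on a table not flagged incomplete")
        return
    if not isinstance(value, (int,)) or isinstance(value, bool):
        raise MateChoiceError(f"{what}: count must be an integer, got {value!r}")
    if value < 0:
        raise MateChoiceError(f"{what}: negative count {value}")


@dataclass(frozen=True)
class PairCountTable:
    """Observed pair and single-worm counts for one host.

    ``pair_counts`` maps (male_species, female_species) to the number of
    pairs; ``single_counts`` maps (sex, species) to the number of unpaired
    worms.  A table may be flagged ``incomplete`` when a source cell is
    unreadable; the missing cell is stored as ``None`` and strict consumers
    must refuse the table.
    """

    host_id: str
    experiment_id: str
    pair_counts: Mapping[PairKey, int | None]
    single_counts: Mapping[ClassKey, int]
    incomplete: bool = False

    def __post_init__(self) -> None:
        for k, v in self.pair_counts.items():
            _check_count(v, incomplete=self.incomplete, what=f"host {self.host_id} pairs {k}")
        for k, v in self.single_counts.items():
            _check_count(v, incomplete=False, what=f"host {self.host_id} singles {k}")

    @property
    def total_pairs(self) -> int:
        """Number of observed pairs P (missing cells excluded)."""
        return sum(v for v in self.pair_counts.values() if v is not None)

    def class_total(self, sex: str, species: str) -> int:
        """Total worms of one sex x species class: singles plus every pair
        containing that class."""
        total = self.single_counts.get((sex, species), 0)
        idx = 0 if sex == MALE else 1
        for key, v in self.pair_counts.items():
            if v is not None and key[idx] == species:
                total += v
        return total

    def class_totals(self) -> dict[ClassKey, int]:
        keys: list[ClassKey] = []
        for m, f in self.pair_counts:
            for k in ((MALE, m), (FEMALE, f)):
                if k not in keys:
                    keys.append(k)
        for k in self.single_counts:
            if k not in keys:
                keys.append(k)
        return {k: self.class_total(*k) for k in keys}

    def validate_against(self, design: MateChoiceDesign) -> None:
        if set(self.pair_counts) != set(design.pair_keys):
            raise MateChoiceError(
                f"host {self.host_id}: pair categories {sorted(self.pair_counts)} "
                f"do not match design categories {sorted(design.pair_keys)}"
            )
        extra = set(self.single_counts) - set(design.classes)
        if any(self.single_counts[k] for k in extra):
            raise MateChoiceError(
                f"host {self.host_id}: single-worm classes {sorted(extra)} not in design"
            )


@dataclass(frozen=True)
class Dataset:
    """An ordered collection of per-host tables sharing one design."""

    design: MateChoiceDesign
    hosts: tuple[PairCountTable, ...]
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.host_id for t in self.hosts]
        if len(set(ids)) != len(ids):
            raise MateChoiceError(f"duplicate host_id in dataset: {ids}")
        for t in self.hosts:
            t.validate_against(self.design)

    def __iter__(self) -> Iterator[PairCountTable]:
        return iter(self.hosts)

    def __len__(self) -> int:
        return len(self.hosts)

    def host(self, host_id: str) -> PairCountTable:
        for t in self.hosts:
            if t.host_id == host_id:
                return t
        raise KeyError(host_id)

    @property
    def experiment_id(self) -> str:
        ids = {t.experiment_id for t in self.hosts}
        if len(ids) == 1:
            return next(iter(ids))
        return str(self.metadata.get("experiment_id", "dataset"))


# ---------------------------------------------------------------------------
# CSV I/O.  One row per host; the schema is fixed so files are portable
# between the CLI, the simulator and external spreadsheets.
# ---------------------------------------------------------------------------

_FIXED_COLUMNS = ("experiment_id", "host_id", "design_kind", "choosing_sex", "choosing_species")


def _pair_column(key: PairKey) -> str:
    return f"pairs_{key[0]}{key[1]}"


def _single_column(key: ClassKey) -> str:
    return f"single_{key[0]}_{key[1]}"


def csv_columns(species_pair: tuple[str, str] = ("Sh", "Sb")) -> list[str]:
    """Header of the count-table CSV schema for a given species pair."""
    a, b = species_pair
    pairs = [(a, a), (b, b), (a, b), (b, a)]
    singles = [(s, sp) for s in SEXES for sp in (a, b)]
    return list(_FIXED_COLUMNS) + [_pair_column(k) for k in pairs] + [
        _single_column(k) for k in singles
    ]


def _parse_cell(raw: str, *, row: int, column: str, allow_missing: bool) -> int | None:
    raw = raw.strip()
    if raw == "":
        return None if allow_missing else 0
    try:
        value = int(raw)
    except ValueError as exc:
        raise ParseError(f"row {row}, column {column}: not an integer: {raw!r}") from exc
    if value < 0:
        raise ParseError(f"row {row}, column {column}: negative count {value}")
    return value


def _design_from_row(row: Mapping[str, str], rownum: int, species_pair: tuple[str, str]) -> MateChoiceDesign:
    kind = row.get("design_kind", "").strip()
    sex = row.get("choosing_sex", "").strip() or None
    species = row.get("choosing_species", "").strip() or None
    try:
        return MateChoiceDesign(kind, sex, species, species_pair)
    except MateChoiceError as exc:
        raise ParseError(f"row {rownum}: invalid design: {exc}") from exc


def read_dataset(
    path_or_buffer,
    design: MateChoiceDesign | None = None,
    *,
    species_pair: tuple[str, str] = ("Sh", "Sb"),
) -> Dataset:
    """Read a count-table CSV into a validated :class:`Dataset`.

    If *design* is omitted it is inferred from the ``design_kind`` /
    ``choosing_sex`` / ``choosing_species`` columns, which must then agree
    across rows.  A populated pair column left empty marks the cell as
    missing and flags the host's table as incomplete.
    """
    if hasattr(path_or_buffer, "read"):
        return _read_dataset_file(path_or_buffer, design, species_pair)
    with open(path_or_buffer, newline="", encoding="utf-8") as fh:
        return _read_dataset_file(fh, design, species_pair)


def _read_dataset_file(fh, design, species_pair) -> Dataset:
    reader = csv.DictReader(fh)
    if reader.fieldnames is None:
        raise ParseError("empty file: header row is mandatory")
    missing_cols = [c for c in _FIXED_COLUMNS if c not in reader.fieldnames]
    if missing_cols:
        raise ParseError(f"header is missing columns: {missing_cols}")

    hosts: list[PairCountTable] = []
    for rownum, row in enumerate(reader, start=2):
        row_design = _design_from_row(row, rownum, species_pair)
        if design is None:
            design = row_design
        elif row_design != design:
            raise ParseError(f"row {rownum}: design differs from the dataset design")

        pair_counts: dict[PairKey, int | None] = {}
        incomplete = False
        for key in design.pair_keys:
            col = _pair_column(key)
            value = _parse_cell(row.get(col, ""), row=rownum, column=col, allow_missing=True)
            if value is None:
                incomplete = True
            pair_counts[key] = value
        single_counts: dict[ClassKey, int] = {}
        for key in design.classes:
            col = _single_column(key)
            value = _parse_cell(row.get(col, ""), row=rownum, column=col, allow_missing=False)
            single_counts[key] = int(value)

        try:
            hosts.append(
                PairCountTable(
                    host_id=row["host_id"].strip(),
                    experiment_id=row["experiment_id"].strip(),
                    pair_counts=pair_counts,
                    single_counts=single_counts,
                    incomplete=incomplete,
                )
            )
        except MateChoiceError as exc:
            raise ParseError(f"row {rownum}: {exc}") from exc

    if design is None:
        raise ParseError("file has a header but no rows and no design was supplied")
    try:
        return Dataset(design=design, hosts=tuple(hosts))
    except MateChoiceError as exc:
        raise ParseError(str(exc)) from exc


def write_dataset(dataset: Dataset, path_or_buffer) -> None:
    """Write a dataset back to the CSV schema (inverse of :func:`read_dataset`)."""
    if hasattr(path_or_buffer, "write"):
        _write_dataset_file(dataset, path_or_buffer)
    else:
        with open(path_or_buffer, "w", newline="", encoding="utf-8") as fh:
            _write_dataset_file(dataset, fh)


def _write_dataset_file(dataset: Dataset, fh) -> None:
    design = dataset.design
    columns = csv_columns(design.species_pair)
    writer = csv.DictWriter(fh, fieldnames=columns)
    writer.writeheader()
    for table in dataset:
        row = {c: "" for c in columns}
        row.update(
            experiment_id=table.experiment_id,
            host_id=table.host_id,
            design_kind=design.kind,
            choosing_sex=design.choosing_sex or "",
            choosing_species=design.choosing_species or "",
        )
        for key, v in table.pair_counts.items():
            row[_pair_column(key)] = "" if v is None else v
        for key, v in table.single_counts.items():
            row[_single_column(key)] = v
        writer.writerow(row)


def dataset_to_csv(dataset: Dataset) -> str:
    buf = io.StringIO()
    write_dataset(dataset, buf)
    return buf.getvalue()
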