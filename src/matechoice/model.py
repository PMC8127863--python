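"""Model/results interface over the random-mating analysis.

`RandomMatingModel` is constructed from a :class:`~matechoice.records.Dataset`
(or a CSV in the package schema) and, on :meth:`~RandomMatingModel.fit`,
computes per-host null expectations and Pearson statistics plus an
experiment-level combination, returned as a :class:`RandomMatingResults`
with a ``summary()`` table mirroring the layout of the source study's
result tables.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import pandas as pd

from .records import Dataset, IncompleteDataError, MateChoiceDesign, read_dataset
from .inference import ChiSquareResult, combine_pooled, combine_sum, host_test
from .nullmodel import NullExpectation

__all__ = ["RandomMatingModel", "RandomMatingResults"]


class RandomMatingModel:
    """Chi-square test of observed pairing against the random-mating null.

    Parameters
    ----------
    dataset
        Per-host pair-count tables sharing one design.
    method
        Experiment-level combination: ``"sum"`` (add independent host
        statistics and dfs) or ``"pooled"`` (sum counts first, test once).
    strict
        If True, a host flagged incomplete aborts the fit; otherwise it is
        skipped with a warning and listed in ``results.skipped_hosts``.

    Examples
    --------
    >>> from matechoice import RandomMatingModel, study_datasets
    >>> res = RandomMatingModel(study_datasets()["exp2"], method="sum").fit()
    >>> round(res.experiment_result.statistic, 3)
    3.118
    """

    def __init__(self, dataset: Dataset, method: str = "sum", strict: bool = False):
        if method not in ("sum", "pooled"):
            raise ValueError(f"unknown combination method: {method!r}")
        self.dataset = dataset
        self.method = method
        self.strict = strict

    @classmethod
    def from_csv(
        cls,
        path,
        design: MateChoiceDesign | None = None,
        method: str = "sum",
        strict: bool = False,
    ) -> "RandomMatingModel":
        """Build a model straight from a count-table CSV."""
        return cls(read_dataset(path, design), method=method, strict=strict)

    def fit(self) -> "RandomMatingResults":
        """Compute host-level and experiment-level tests."""
        host_results: list[ChiSquareResult] = []
        skipped: list[str] = []
        for table in self.dataset:
            if table.incomplete:
                if self.strict:
                    raise IncompleteDataError(
                        f"host {table.host_id} is flagged incomplete "
                        "(strict mode refuses flagged data)"
                    )
                _warnings.warn(
                    f"skipping incomplete host {table.host_id}", UserWarning, stacklevel=2
                )
                skipped.append(table.host_id)
                continue
            if table.total_pairs == 0:
                _warnings.warn(
                    f"skipping host {table.host_id}: no pairs observed",
                    UserWarning,
                    stacklevel=2,
                )
                skipped.append(table.host_id)
                continue
            host_results.append(host_test(table, self.dataset.design))

        if self.method == "pooled":
            usable = [
                t for t in self.dataset if not t.incomplete and t.total_pairs >= 0
            ]
            experiment = combine_pooled(usable, self.dataset.design, strict=False)
        else:
            experiment = combine_sum(host_results)
        return RandomMatingResults(self, tuple(host_results), experiment, tuple(skipped))


@dataclass(frozen=True)
class RandomMatingResults:
    """Fit output: per-host tests, the combined test, and report helpers."""

    model: RandomMatingModel
    host_results: tuple[ChiSquareResult, ...]
    experiment_result: ChiSquareResult
    skipped_hosts: tuple[str, ...] = ()

    @property
    def warnings(self) -> tuple[str, ...]:
        seen = list(self.experiment_result.warnings)
        for r in self.host_results:
            for w in r.warnings:
                if w not in seen:
                    seen.append(w)
        return tuple(seen)

    def host_result(self, host_id: str) -> ChiSquareResult:
        for r in self.host_results:
            if r.host_id == host_id:
                return r
        raise KeyError(host_id)

    def expectation(self, host_id: str) -> NullExpectation:
        exp = self.host_result(host_id).expectation
        assert exp is not None
        return exp

    def to_frame(self) -> pd.DataFrame:
        """One row per host plus an experiment row, in table layout:
        observed counts with rounded expectations in brackets, then the
        statistic, df and p-value."""
        design = self.model.dataset.design
        rows = []
        for r in self.host_results:
            table = self.model.dataset.host(r.host_id)
            exp = r.expectation
            row: dict = {"host": r.host_id}
            for key in design.pair_keys:
                label = f"{key[0]}x{key[1]}"
                row[label] = f"{table.pair_counts[key]} ({exp.expected_rounded[key]})"
            for cls in design.classes:
                row[f"single {cls[0]} {cls[1]}"] = table.single_counts.get(cls, 0)
            row.update(statistic=r.statistic, df=r.df, p_value=r.p_value)
            rows.append(row)
        exp_row: dict = {"host": f"experiment ({self.experiment_result.method})"}
        exp_row.update(
            statistic=self.experiment_result.statistic,
            df=self.experiment_result.df,
            p_value=self.experiment_result.p_value,
        )
        rows.append(exp_row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable report (3-decimal display, full precision kept
        on the result objects)."""
        design = self.model.dataset.design
        frame = self.to_frame().copy()
        for col in ("statistic", "p_value"):
            frame[col] = frame[col].map(lambda v: f"{v:.3f}" if pd.notna(v) else "")
        frame["df"] = frame["df"].map(lambda v: f"{int(v)}" if pd.notna(v) else "")
        for col in frame.columns:
            if col.startswith("single"):
                frame[col] = frame[col].map(lambda v: f"{int(v)}" if pd.notna(v) else "")
        lines = [
            "Random-mating chi-square analysis",
            f"design: {design.kind}"
            + (
                f" (choosing {design.choosing_sex} {design.choosing_species})"
                if design.choosing_species
                else ""
            ),
            f"combination method: {self.model.method}; hosts tested: "
            f"{len(self.host_results)}; skipped: {list(self.skipped_hosts) or 'none'}",
            "",
            frame.fillna("").to_string(index=False),
        ]
        if self.warnings:
            lines += ["", "validity warnings (do not alter results):"]
            lines += [f"  - {w}" for w in self.warnings]
        return "\n".join(lines) + "\n"
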