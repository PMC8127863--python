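"""Pearson chi-square tests of observed pair counts against random mating.

Per host the statistic is the classic goodness-of-fit sum
``sum_k (O_k - E_k)^2 / E_k`` over the pair categories (two under limited
choice, four under full choice), with unrounded expectations and no
continuity correction; df = categories - 1.

Two conventions exist for combining hosts into an experiment-level test and
both occur in practice, so both are implemented:

* ``combine_sum`` — sum the per-host statistics and their dfs (independent
  hosts; the additivity property of chi-square).
* ``combine_pooled`` — sum the observed counts across hosts first, then run
  a single test on the pooled table.  Pooling asks a different question
  (aggregate deviation) and can mask opposite-signed host effects.

Expected counts below 5 violate Cochran's rule of thumb; a warning is
attached but never alters the result.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, replace as _dc_replace
from typing import Iterable, Sequence

from scipy import stats

from .records import (
    Dataset,
    DegenerateDataError,
    IncompleteDataError,
    MateChoiceDesign,
    MateChoiceError,
    PairCountTable,
)
from .nullmodel import NullExpectation, null_expectation

__all__ = [
    "ChiSquareResult",
    "chisq_pvalue",
    "host_test",
    "combine_sum",
    "pool_hosts",
    "combine_pooled",
    "experiment_test",
    "study_test",
    "LOW_EXPECTED_THRESHOLD",
]

LOW_EXPECTED_THRESHOLD = 5.0


def chisq_pvalue(statistic: float, df: int) -> float:
    """Upper-tail chi-square probability."""
    if statistic < 0:
        raise ValueError("chi-square statistic must be non-negative")
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(stats.chi2.sf(statistic, df))


@dataclass(frozen=True)
class ChiSquareResult:
    """A chi-square comparison of observed vs expected pair counts."""

    statistic: float
    df: int
    p_value: float
    method: str  # host | combine_sum | combine_pooled | study_sum
    n_hosts: int
    warnings: tuple[str, ...] = ()
    expectation: NullExpectation | None = None
    host_id: str | None = None

    def __post_init__(self) -> None:
        if self.statistic < 0 or not 0.0 <= self.p_value <= 1.0 or self.df < 1:
            raise MateChoiceError("invalid chi-square result fields")


def host_test(table: PairCountTable, design: MateChoiceDesign) -> ChiSquareResult:
    """Pearson test of one host's pair composition against random mating.

    Raises :class:`IncompleteDataError` on a flagged table (the statistic is
    undefined when an observed cell is missing) and
    :class:`DegenerateDataError` when the host has no pairs.
    """
    expectation = null_expectation(table, design)
    statistic = 0.0
    warn: list[str] = []
    for key in design.pair_keys:
        observed = table.pair_counts[key]
        expected = expectation.expected[key]
        if expected == 0.0:
            if observed:
                raise MateChoiceError(
                    f"host {table.host_id}: observed pairs {key} with zero expectation"
                )
            continue
        statistic += (observed - expected) ** 2 / expected
        if expected < LOW_EXPECTED_THRESHOLD:
            warn.append(
                f"host {table.host_id}: expected count {expected:.2f} < "
                f"{LOW_EXPECTED_THRESHOLD:g} for pair {key[0]}x{key[1]}"
            )
    df = len(design.pair_keys) - 1
    return ChiSquareResult(
        statistic=statistic,
        df=df,
        p_value=chisq_pvalue(statistic, df),
        method="host",
        n_hosts=1,
        warnings=tuple(warn),
        expectation=expectation,
        host_id=table.host_id,
    )


def combine_sum(results: Sequence[ChiSquareResult]) -> ChiSquareResult:
    """Experiment-level test: sum independent host statistics and dfs."""
    if not results:
        raise MateChoiceError("combine_sum needs at least one host result")
    statistic = sum(r.statistic for r in results)
    df = sum(r.df for r in results)
    warn = tuple(w for r in results for w in r.warnings)
    return ChiSquareResult(
        statistic=statistic,
        df=df,
        p_value=chisq_pvalue(statistic, df),
        method="combine_sum",
        n_hosts=len(results),
        warnings=warn,
    )


def pool_hosts(tables: Sequence[PairCountTable], *, strict: bool = True) -> PairCountTable:
    """Element-wise sum of counts across hosts (host_id becomes ``"pooled"``).

    Flagged-incomplete tables cannot contribute (their missing cell is
    unknown): under ``strict`` they raise, otherwise they are skipped with a
    :class:`UserWarning`.
    """
    tables = list(tables)
    if not tables:
        raise MateChoiceError("pool_hosts needs at least one table")
    kept: list[PairCountTable] = []
    for t in tables:
        if t.incomplete:
            if strict:
                raise IncompleteDataError(
                    f"host {t.host_id} is flagged incomplete; cannot pool under strict mode"
                )
            _warnings.warn(
                f"skipping incomplete host {t.host_id} while pooling", UserWarning, stacklevel=2
            )
            continue
        kept.append(t)
    if not kept:
        raise DegenerateDataError("no complete tables left to pool")
    keys = set(kept[0].pair_counts)
    pair_counts: dict = {k: 0 for k in kept[0].pair_counts}
    single_counts: dict = {}
    for t in kept:
        if set(t.pair_counts) != keys:
            raise MateChoiceError(
                f"host {t.host_id}: pair categories differ from the first table"
            )
        for k, v in t.pair_counts.items():
            pair_counts[k] += v
        for k, v in t.single_counts.items():
            single_counts[k] = single_counts.get(k, 0) + v
    return PairCountTable(
        host_id="pooled",
        experiment_id=kept[0].experiment_id,
        pair_counts=pair_counts,
        single_counts=single_counts,
    )


def combine_pooled(
    tables: Sequence[PairCountTable], design: MateChoiceDesign, *, strict: bool = True
) -> ChiSquareResult:
    """Experiment-level test on counts pooled across hosts."""
    pooled = pool_hosts(tables, strict=strict)
    result = host_test(pooled, design)
    return _dc_replace(result, method="combine_pooled", n_hosts=len(tables), host_id=None)


def experiment_test(
    dataset: Dataset, method: str = "sum", *, strict: bool = True
) -> ChiSquareResult:
    """Run the experiment-level test on a dataset with the given convention.

    ``method`` is ``"sum"`` or ``"pooled"``.  Hosts without pairs, and (in
    permissive mode) flagged hosts, are skipped with a warning under the
    sum convention.
    """
    if method == "pooled":
        return combine_pooled(dataset.hosts, dataset.design, strict=strict)
    if method != "sum":
        raise MateChoiceError(f"unknown combination method: {method!r}")
    results = []
    for table in dataset:
        if table.incomplete:
            if strict:
                raise IncompleteDataError(
                    f"host {table.host_id} is flagged incomplete; "
                    "rerun in permissive mode to skip it"
                )
            _warnings.warn(
                f"skipping incomplete host {table.host_id}", UserWarning, stacklevel=2
            )
            continue
        if table.total_pairs == 0:
            _warnings.warn(
                f"skipping host {table.host_id}: no pairs observed", UserWarning, stacklevel=2
            )
            continue
        results.append(host_test(table, dataset.design))
    if not results:
        raise DegenerateDataError("no testable hosts in dataset")
    return combine_sum(results)


def study_test(experiment_results: Sequence[ChiSquareResult]) -> ChiSquareResult:
    """Study-level test: sum experiment statistics and dfs."""
    if not experiment_results:
        raise MateChoiceError("study_test needs at least one experiment result")
    statistic = sum(r.statistic for r in experiment_results)
    df = sum(r.df for r in experiment_results)
    warn = tuple(w for r in experiment_results for w in r.warnings)
    return ChiSquareResult(
        statistic=statistic,
        df=df,
        p_value=chisq_pvalue(statistic, df),
        method="study_sum",
        n_hosts=sum(r.n_hosts for r in experiment_results),
        warnings=warn,
    )
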