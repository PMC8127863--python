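"""Monte-Carlo calibration of the mate-choice chi-square test.

Estimates, under the simulator of :mod:`matechoice.simulate`:

* the empirical **type-I error** of the experiment-level test at ``rho = 1``
  (random mating): the fraction of replicate experiments rejected at level
  ``alpha``;
* the **power** to detect a species preference ``rho != 1`` over a grid of
  preference values.

Rejection-rate uncertainty is summarised by the Wilson score interval,
whose small-sample behaviour is far better than the Wald interval near 0
and 1.  Replicates in which no host yields a single pair carry no
information about the test; they are regenerated (fresh substream) and
counted separately in ``n_degenerate`` — silently dropping or keeping them
would bias the denominator.

A caution that matters at realistic scales: under the pairing mechanism
the homo-specific pair count given the class totals follows sampling
without replacement, whose variance is the multinomial variance shrunk by
the finite-population factor ``(F - P)/(F - 1)`` (F partner-pool size, P
pairs).  The Pearson reference distribution is therefore only attained
when ``P/F`` is small; at the bundled study's scale (P comparable to F)
the test is conservative.  :func:`estimate_type1` measures exactly this.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .records import Dataset, DegenerateDataError, MateChoiceDesign, MateChoiceError
from .inference import experiment_test
from .simulate import SimulationConfig, simulate_experiment

__all__ = ["CalibrationResult", "estimate_type1", "estimate_power", "power_frame", "plot_power"]


def wilson_interval(count: int, nobs: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(count, nobs, alpha=1.0 - level, method="wilson")
    # guard against numerical fuzz at the boundaries (e.g. lo = 4e-19 at count 0)
    rate = count / nobs
    return min(float(lo), rate), max(float(hi), rate)


@dataclass(frozen=True)
class CalibrationResult:
    """Empirical rejection rate of the test at one preference value."""

    rho: float
    n_replicates: int
    alpha: float
    rejection_rate: float
    ci_low: float
    ci_high: float
    method: str
    seed: int
    ci_level: float = 0.95
    n_degenerate: int = 0

    def __post_init__(self) -> None:
        if not self.ci_low <= self.rejection_rate <= self.ci_high:
            raise MateChoiceError("Wilson interval does not bracket the rejection rate")


def _replicate_pvalue(
    config: SimulationConfig,
    design: MateChoiceDesign,
    method: str,
    substream: tuple[int, ...],
) -> float | None:
    """p-value of one replicate experiment, or None if it is degenerate."""
    import warnings

    dataset = simulate_experiment(config, design, substream=substream)
    if all(t.total_pairs == 0 for t in dataset):
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # pair-less hosts are expected here
        try:
            return experiment_test(dataset, method).p_value
        except DegenerateDataError:
            return None


def _calibrate(
    config: SimulationConfig,
    design: MateChoiceDesign,
    method: str,
    alpha: float,
    n_replicates: int,
    ci_level: float,
    substream_prefix: tuple[int, ...],
) -> CalibrationResult:
    if not 0.0 < alpha <= 1.0:
        raise MateChoiceError(f"alpha must lie in (0, 1], got {alpha}")
    if n_replicates < 1:
        raise MateChoiceError("n_replicates must be positive")
    rejections = 0
    valid = 0
    degenerate = 0
    rep = 0
    # keep drawing fresh substreams until n_replicates informative replicates
    while valid < n_replicates:
        p = _replicate_pvalue(config, design, method, (*substream_prefix, rep))
        rep += 1
        if p is None:
            degenerate += 1
            if degenerate > 100 * n_replicates:
                raise DegenerateDataError(
                    "configuration produces almost no pairs; calibration impossible"
                )
            continue
        valid += 1
        if p < alpha or alpha >= 1.0:  # level 1 rejects everything by definition
            rejections += 1
    lo, hi = wilson_interval(rejections, n_replicates, ci_level)
    return CalibrationResult(
        rho=config.preference_rho,
        n_replicates=n_replicates,
        alpha=alpha,
        rejection_rate=rejections / n_replicates,
        ci_low=lo,
        ci_high=hi,
        method=method,
        seed=config.seed,
        ci_level=ci_level,
        n_degenerate=degenerate,
    )


def estimate_type1(
    config: SimulationConfig,
    design: MateChoiceDesign,
    method: str = "sum",
    alpha: float = 0.05,
    n_replicates: int = 2000,
    *,
    ci_level: float = 0.95,
) -> CalibrationResult:
    """Empirical type-I error of the experiment-level test at ``rho = 1``."""
    if config.preference_rho != 1.0:
        raise MateChoiceError("type-I error is defined under the null: preference_rho must be 1")
    return _calibrate(config, design, method, alpha, n_replicates, ci_level, (0,))


def estimate_power(
    config: SimulationConfig,
    design: MateChoiceDesign,
    method: str = "sum",
    alpha: float = 0.05,
    rho_grid: Sequence[float] = (1.0, 2.0, 4.0),
    n_replicates: int = 2000,
    *,
    ci_level: float = 0.95,
) -> list[CalibrationResult]:
    """Rejection rate per preference value over ``rho_grid``.

    Each grid point uses its own substream family derived from the master
    seed, so results are reproducible and extending the grid never changes
    earlier points.
    """
    if not rho_grid:
        raise MateChoiceError("rho_grid must not be empty")
    results = []
    for i, rho in enumerate(rho_grid):
        cfg = config.replace(preference_rho=float(rho))
        # a rho=1 grid point shares the type-I substream, so a {1} grid
        # reduces exactly to estimate_type1
        prefix = (0,) if float(rho) == 1.0 else (1, i)
        results.append(
            _calibrate(cfg, design, method, alpha, n_replicates, ci_level, prefix)
        )
    return results


def power_frame(results: Sequence[CalibrationResult]):
    """Calibration results as a tidy DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "rho": [r.rho for r in results],
            "rejection_rate": [r.rejection_rate for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "alpha": [r.alpha for r in results],
            "n_replicates": [r.n_replicates for r in results],
            "n_degenerate": [r.n_degenerate for r in results],
            "method": [r.method for r in results],
        }
    )


def plot_power(results: Sequence[CalibrationResult], ax=None):
    """Power curve with Wilson error bands (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    frame = power_frame(results).sort_values("rho")
    ax.plot(frame["rho"], frame["rejection_rate"], marker="o")
    ax.fill_between(frame["rho"], frame["ci_low"], frame["ci_high"], alpha=0.25)
    ax.axhline(results[0].alpha, linestyle="--", linewidth=1)
    ax.set_xscale("log", base=2)
    ax.set_xlabel(r"preference $\rho$ (homo- vs hetero-specific weight)")
    ax.set_ylabel("rejection rate")
    return ax
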