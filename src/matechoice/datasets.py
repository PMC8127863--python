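"""Bundled reference data: the five hamster mate-choice experiments.

The package ships the observed pair and single-worm counts from the
*Schistosoma haematobium* x *S. bovis* mate-choice study it reimplements:
four limited-choice experiments (each sex x species class in turn as the
limiting, choosing class) and one full-choice experiment, five hamsters per
experiment.  The counts are transcribed cell-for-cell from the published
summary tables; ``REPORTED`` carries the statistics printed alongside them,
used by golden tests and by the discrepancy appendix of the reproduction
report.

Known data-quality issues, preserved rather than repaired:

* Full-choice host 1 has an unreadable observed count for the Sb x Sb pair
  cell (only its bracketed expectation survives); the host is stored with
  ``incomplete=True`` and its printed statistic (3.358) cannot be
  reconstructed from any single imputation.
* Limited-choice experiment 3 retains only hosts 2 and 3; the other
  hamsters died prematurely or yielded too few paired worms.
"""

from __future__ import annotations

from importlib import resources

from .records import Dataset, MateChoiceDesign, read_dataset

__all__ = ["study_designs", "study_datasets", "REPORTED"]

_DESIGNS = {
    "exp1": MateChoiceDesign("limited_choice", "M", "Sh"),
    "exp2": MateChoiceDesign("limited_choice", "F", "Sh"),
    "exp3": MateChoiceDesign("limited_choice", "M", "Sb"),
    "exp4": MateChoiceDesign("limited_choice", "F", "Sb"),
    "exp5": MateChoiceDesign("full_choice"),
}


def study_designs() -> dict[str, MateChoiceDesign]:
    """Design declarations of the five bundled experiments."""
    return dict(_DESIGNS)


def study_csv() -> str:
    """The bundled observations in the package CSV schema."""
    return (
        resources.files("matechoice.data")
        .joinpath("mate_choice_experiments.csv")
        .read_text(encoding="utf-8")
    )


def study_datasets() -> dict[str, Dataset]:
    """Load the five bundled experiments as validated datasets.

    Returns a mapping ``"exp1" .. "exp5"`` -> :class:`~matechoice.records.Dataset`.
    Full-choice host 1 carries the ``incomplete`` flag (see module docstring).
    """
    import io

    text = study_csv()
    header, *rows = text.strip().splitlines()
    out: dict[str, Dataset] = {}
    for exp_id, design in _DESIGNS.items():
        block = [r for r in rows if r.startswith(exp_id + ",")]
        buf = io.StringIO("\n".join([header] + block) + "\n")
        out[exp_id] = read_dataset(buf, design)
    return out


#: Statistics as printed in the source tables: per-host (statistic, df, p),
#: per-experiment rows with the df convention used in print, and the
#: combined limited-choice row.  Items known not to be reproducible from the
#: printed counts are listed under "non_reproducible".
REPORTED: dict = {
    "hosts": {
        ("exp1", "1"): (1.838, 1, 0.175),
        ("exp1", "2"): (1.543, 1, 0.214),
        ("exp1", "3"): (5.057, 1, 0.025),
        ("exp1", "4"): (0.015, 1, 0.903),
        ("exp1", "5"): (2.651, 1, 0.103),
        ("exp2", "1"): (0.908, 1, 0.341),
        ("exp2", "2"): (0.429, 1, 0.513),
        ("exp2", "3"): (1.688, 1, 0.194),
        ("exp2", "4"): (0.094, 1, 0.759),
        ("exp2", "5"): (0.001, 1, 0.993),  # display floor: computed 7e-5 matches p
        ("exp3", "2"): (4.400, 1, 0.036),
        ("exp3", "3"): (0.742, 1, 0.389),
        ("exp4", "1"): (1.070, 1, 0.301),
        ("exp4", "2"): (1.061, 1, 0.303),
        ("exp4", "3"): (0.030, 1, 0.862),
        ("exp4", "4"): (0.188, 1, 0.665),
        ("exp4", "5"): (0.007, 1, 0.932),
        ("exp5", "2"): (1.786, 3, 0.618),
        ("exp5", "3"): (2.307, 3, 0.511),
        ("exp5", "4"): (4.806, 3, 0.187),
        ("exp5", "5"): (0.796, 3, 0.850),
    },
    # bracketed (rounded) expected pair counts, in design pair-key order
    "expected_rounded": {
        ("exp1", "1"): (14, 11),
        ("exp1", "2"): (15, 18),
        ("exp1", "3"): (20, 10),
        ("exp1", "4"): (9, 6),
        ("exp1", "5"): (13, 7),
        ("exp2", "1"): (9, 4),
        ("exp2", "2"): (5, 2),
        ("exp2", "3"): (10, 5),
        ("exp2", "4"): (15, 4),
        ("exp2", "5"): (12, 13),
        ("exp3", "2"): (2, 2),
        ("exp3", "3"): (1, 2),
        ("exp4", "1"): (12, 20),
        ("exp4", "2"): (8, 28),
        ("exp4", "3"): (3, 8),
        ("exp4", "4"): (8, 16),
        ("exp4", "5"): (49, 15),
        # full choice, key order (Sh,Sh), (Sb,Sb), (Sh,Sb), (Sb,Sh)
        ("exp5", "2"): (8, 1, 4, 2),
        ("exp5", "3"): (5, 2, 2, 3),
        ("exp5", "4"): (4, 3, 4, 3),
        ("exp5", "5"): (6, 1, 6, 1),
    },
    # experiment rows: (statistic, printed df, printed p, combination method
    # that reproduces the printed statistic)
    "experiments": {
        "exp1": (11.104, 4, 0.049, "sum"),
        "exp2": (3.118, 4, 0.682, "sum"),
        "exp3": (4.522, 1, 0.104, "pooled"),
        "exp4": (3.246, 4, 0.662, "pooled"),
        "exp5": (13.053, 12, 0.365, "sum"),  # includes the incomplete host 1
    },
    "all_limited": (21.719, 16, 0.152),
    "non_reproducible": [
        "full-choice host 1: the Sb x Sb observed cell is unreadable; printed "
        "statistic 3.358 cannot be reconstructed from any single imputation",
        "full-choice experiment row 13.053 sums all five printed host "
        "statistics, including the irreproducible host 1",
        "combined limited-choice statistic 21.719: the reproduced experiment "
        "statistics sum to 21.989 under every combination tried",
        "printed degrees of freedom disagree with their own p-values in "
        "several rows (e.g. 11.104 with p=0.049 matches df 5, not the printed "
        "4; 4.522 with p=0.104 matches df 2, not the printed 1)",
        "per-host statistics below 0.001 are printed as 0.001 (limited-choice "
        "experiment 2 host 5: computed 0.00007, printed 0.001 with p=0.993)",
    ],
}
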