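"""Random-mating expectations: worked examples, an exhaustive
without-replacement enumeration oracle, and structural properties."""

import itertools
import math
from decimal import ROUND_HALF_UP, Decimal

import pytest
from hypothesis import given
from hypothesis import strategies as st

from matechoice import (
    DegenerateDataError,
    IncompleteDataError,
    MateChoiceDesign,
    PairCountTable,
    expected_full,
    expected_limited,
    round_half_up,
)

MALE_SH = MateChoiceDesign("limited_choice", "M", "Sh")
FEMALE_SH = MateChoiceDesign("limited_choice", "F", "Sh")
FULL = MateChoiceDesign("full_choice")


def limited_table(pairs_homo, pairs_het, singles_homo, singles_het, design=MALE_SH):
    homo_key, het_key = design.pair_keys
    partner = design.partner_sex
    return PairCountTable(
        "1",
        "t",
        {homo_key: pairs_homo, het_key: pairs_het},
        {
            (partner, design.choosing_species): singles_homo,
            (partner, design.other_species): singles_het,
        },
    )


@pytest.mark.parametrize(
    "x, expected",
    [(8.5, 9), (3.5, 4), (0.0, 0), (2.4999, 2), (0.5, 1), (14.352, 14)],
)
def test_round_half_up_examples(x, expected):
    assert round_half_up(x) == expected


@given(st.floats(min_value=0, max_value=1e6, allow_nan=False))
def test_round_half_up_matches_decimal_oracle(x):
    oracle = int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    assert round_half_up(x) == oracle


def test_round_half_up_rejects_negative():
    with pytest.raises(ValueError):
        round_half_up(-0.5)


class TestLimitedChoice:
    def test_male_choice_worked_example(self):
        # 25 pairing males; female pool 31 homo / 23 hetero
        exp = expected_limited(limited_table(11, 14, 20, 9), MALE_SH)
        assert exp.expected[("Sh", "Sh")] == pytest.approx(25 * 31 / 54)
        assert exp.expected[("Sh", "Sb")] == pytest.approx(25 * 23 / 54)
        assert exp.expected_rounded == {("Sh", "Sh"): 14, ("Sh", "Sb"): 11}

    def test_female_choice_worked_example(self):
        exp = expected_limited(limited_table(10, 2, 7, 5, FEMALE_SH), FEMALE_SH)
        assert exp.expected[("Sh", "Sh")] == pytest.approx(8.5)
        assert exp.expected[("Sb", "Sh")] == pytest.approx(3.5)
        assert exp.expected_rounded == {("Sh", "Sh"): 9, ("Sb", "Sh"): 4}

    def test_symmetric_pool_splits_evenly(self):
        exp = expected_limited(limited_table(5, 5, 0, 0), MALE_SH)
        assert exp.expected == {("Sh", "Sh"): 5.0, ("Sh", "Sb"): 5.0}

    def test_no_pairs_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            expected_limited(limited_table(0, 0, 3, 3), MALE_SH)

    def test_empty_partner_pool_is_degenerate(self):
        table = PairCountTable(
            "1", "t", {("Sh", "Sh"): 0, ("Sh", "Sb"): 0}, {("F", "Sh"): 0, ("F", "Sb"): 0}
        )
        with pytest.raises(DegenerateDataError):
            expected_limited(table, MALE_SH)

    def test_matches_exhaustive_enumeration(self):
        """For every small pool, the formula equals the exact mean number of
        homo-specific pairs when P partners are drawn uniformly without
        replacement from the pool (hypergeometric mean)."""
        for f_total in range(1, 9):
            for f_homo in range(f_total + 1):
                f_het = f_total - f_homo
                for P in range(1, f_total + 1):
                    # enumerate every subset of partners that could pair
                    pool = [True] * f_homo + [False] * f_het
                    homo_counts = [
                        sum(draw) for draw in itertools.combinations(pool, P)
                    ]
                    exact_mean = sum(homo_counts) / len(homo_counts)
                    # realise the instance as a table (observed split is
                    # irrelevant to the expectation: totals are fixed)
                    h_obs = min(P, f_homo)
                    table = limited_table(
                        h_obs, P - h_obs, f_homo - h_obs, f_het - (P - h_obs)
                    )
                    exp = expected_limited(table, MALE_SH)
                    assert exp.expected[("Sh", "Sh")] == pytest.approx(
                        exact_mean, abs=1e-12
                    )


class TestFullChoice:
    def full_table(self, pairs, singles):
        keys = [("Sh", "Sh"), ("Sb", "Sb"), ("Sh", "Sb"), ("Sb", "Sh")]
        classes = [("M", "Sh"), ("M", "Sb"), ("F", "Sh"), ("F", "Sb")]
        return PairCountTable("1", "t", dict(zip(keys, pairs)), dict(zip(classes, singles)))

    def test_product_marginal_worked_example(self):
        # 16 pairs; males 21 Sh / 6 Sb; females 32 Sh / 15 Sb
        table = self.full_table((8, 2, 5, 1), (8, 3, 23, 8))
        exp = expected_full(table, FULL)
        assert exp.expected[("Sh", "Sh")] == pytest.approx(16 * (21 / 27) * (32 / 47))
        assert exp.expected[("Sb", "Sb")] == pytest.approx(16 * (6 / 27) * (15 / 47))
        assert exp.expected_rounded == {
            ("Sh", "Sh"): 8,
            ("Sb", "Sb"): 1,
            ("Sh", "Sb"): 4,
            ("Sb", "Sh"): 2,
        }

    def test_second_worked_example_rounds_to_brackets(self):
        table = self.full_table((5, 1, 6, 2), (20, 3, 17, 16))
        exp = expected_full(table, FULL)
        assert exp.expected_rounded == {
            ("Sh", "Sh"): 6,
            ("Sb", "Sb"): 1,
            ("Sh", "Sb"): 6,
            ("Sb", "Sh"): 1,
        }

    def test_absent_class_gets_zero_expectation(self):
        table = self.full_table((3, 0, 2, 0), (1, 0, 2, 3))  # no Sb males anywhere
        exp = expected_full(table, FULL)
        assert exp.expected[("Sb", "Sb")] == 0.0
        assert exp.expected[("Sb", "Sh")] == 0.0

    def test_incomplete_table_is_refused(self, study):
        with pytest.raises(IncompleteDataError):
            expected_full(study["exp5"].host("1"), FULL)


# -- structural properties ---------------------------------------------------

pair_strategy = st.tuples(
    st.integers(0, 40), st.integers(0, 40), st.integers(0, 60), st.integers(0, 60)
).filter(lambda t: t[0] + t[1] >= 1)


@given(pair_strategy)
def test_limited_expectations_conserve_total(counts):
    homo, het, s_homo, s_het = counts
    exp = expected_limited(limited_table(homo, het, s_homo, s_het), MALE_SH)
    assert math.isclose(sum(exp.expected.values()), homo + het, abs_tol=1e-9)


@given(pair_strategy)
def test_limited_label_swap_symmetry(counts):
    """Exchanging the two species everywhere permutes the expectations."""
    homo, het, s_homo, s_het = counts
    direct = expected_limited(limited_table(homo, het, s_homo, s_het), MALE_SH)
    swapped_design = MateChoiceDesign("limited_choice", "M", "Sb")
    swapped = expected_limited(
        limited_table(het, homo, s_het, s_homo, swapped_design), swapped_design
    )
    assert swapped.expected[("Sb", "Sb")] == pytest.approx(direct.expected[("Sh", "Sb")])
    assert swapped.expected[("Sb", "Sh")] == pytest.approx(direct.expected[("Sh", "Sh")])


@given(
    st.tuples(*[st.integers(0, 15)] * 4).filter(lambda t: sum(t) >= 1),
    st.tuples(*[st.integers(0, 20)] * 4),
)
def test_full_expectations_conserve_total(pairs, singles):
    keys = [("Sh", "Sh"), ("Sb", "Sb"), ("Sh", "Sb"), ("Sb", "Sh")]
    classes = [("M", "Sh"), ("M", "Sb"), ("F", "Sh"), ("F", "Sb")]
    table = PairCountTable("1", "t", dict(zip(keys, pairs)), dict(zip(classes, singles)))
    exp = expected_full(table, FULL)
    assert math.isclose(sum(exp.expected.values()), sum(pairs), abs_tol=1e-9)


def test_bracketed_integers_reproduced_for_every_host(study):
    """The display-rounded expectations equal the published bracketed values
    on every complete bundled host."""
    from matechoice import null_expectation
    from matechoice.datasets import REPORTED

    for (exp_id, host_id), brackets in REPORTED["expected_rounded"].items():
        ds = study[exp_id]
        exp = null_expectation(ds.host(host_id), ds.design)
        assert tuple(exp.expected_rounded[k] for k in ds.design.pair_keys) == brackets
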