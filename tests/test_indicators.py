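"""Unit and property tests for the ten biodiversity indicators."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divdyn.indicators import (
    INDICATOR_NAMES,
    EmptyCommunityError,
    alpha_indicators,
    community_cod,
    indicator_time_series,
    relative_abundances,
    standardized_cod,
    taxonomic_diversity,
)

communities = st.lists(st.integers(min_value=0, max_value=500), min_size=1, max_size=30).filter(
    lambda c: sum(c) > 0
)


class TestRelativeAbundances:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((10, 10, 10, 10), (0.25, 0.25, 0.25, 0.25)),
            ((3, 1), (0.75, 0.25)),
            ((0, 5, 0, 15), (0.25, 0.75)),  # zero-count species excluded
        ],
    )
    def test_examples(self, counts, expected):
        np.testing.assert_allclose(relative_abundances(counts), expected, atol=1e-12)

    def test_empty_community_errors(self):
        with pytest.raises(EmptyCommunityError):
            relative_abundances((0, 0))

    @settings(max_examples=100, deadline=None)
    @given(communities)
    def test_sum_to_one(self, counts):
        p = relative_abundances(counts)
        assert abs(p.sum() - 1.0) < 1e-12
        assert (p > 0).all()


class TestAlphaIndicators:
    def test_equal_abundances(self):
        rec = alpha_indicators((10, 10, 10, 10))
        assert rec["S"] == 4 and rec["N"] == 40
        assert rec["p_max"] == pytest.approx(0.25, abs=1e-12)
        assert rec["D"] == pytest.approx(0.75, abs=1e-12)
        assert rec["H"] == pytest.approx(math.log(4), abs=1e-12)
        for key in ("E_D", "E_H", "E_var"):
            assert rec[key] == pytest.approx(1.0, abs=1e-12)

    def test_single_species(self):
        rec = alpha_indicators((5,))
        assert rec["S"] == 1 and rec["N"] == 5
        assert rec["p_max"] == 1.0 and rec["D"] == 0.0 and rec["H"] == 0.0
        assert rec["E_var"] == 1.0
        assert math.isnan(rec["E_D"]) and math.isnan(rec["E_H"])

    def test_unbalanced_pair_closed_forms(self):
        # independent closed-form evaluation of the defining formulas
        rec = alpha_indicators((3, 1))
        h = -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))
        var_ln = (math.log(3) / 2) ** 2  # 1/S-normalized variance of (ln 3, ln 1)
        assert rec["D"] == pytest.approx(1 - 0.75**2 - 0.25**2, abs=1e-10)
        assert rec["H"] == pytest.approx(h, abs=1e-10)
        assert rec["E_D"] == pytest.approx(0.375 * 2 / 1, abs=1e-10)
        assert rec["E_H"] == pytest.approx(h / math.log(2), abs=1e-10)
        assert rec["E_var"] == pytest.approx(1 - (2 / math.pi) * math.atan(var_ln), abs=1e-10)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(min_value=2, max_value=40), st.integers(min_value=1, max_value=100))
    def test_equal_counts_force_perfect_evenness(self, s, n_each):
        rec = alpha_indicators([n_each] * s)
        assert rec["D"] == pytest.approx(1 - 1 / s, abs=1e-12)
        for key in ("E_D", "E_H", "E_var"):
            assert rec[key] == pytest.approx(1.0, abs=1e-10)

    @settings(max_examples=150, deadline=None)
    @given(communities)
    def test_bounds(self, counts):
        rec = alpha_indicators(counts)
        s = rec["S"]
        assert 0 <= rec["D"] < 1 and rec["D"] <= 1 - 1 / s + 1e-12
        assert -1e-12 <= rec["H"] <= math.log(s) + 1e-9
        assert 1 / s - 1e-12 <= rec["p_max"] <= 1
        assert 0 < rec["E_var"] <= 1 + 1e-12

    @settings(max_examples=80, deadline=None)
    @given(communities, st.randoms(use_true_random=False))
    def test_permutation_invariance(self, counts, rnd):
        shuffled = list(counts)
        rnd.shuffle(shuffled)
        a, b = alpha_indicators(counts), alpha_indicators(shuffled)
        for key, val in a.items():
            if math.isnan(val):
                assert math.isnan(b[key])
            else:
                assert b[key] == pytest.approx(val, abs=1e-12)


class TestTaxonomicDiversity:
    def test_congeneric_pair(self):
        tab = pd.DataFrame(
            {"genus": ["G", "G"], "family": ["F", "F"], "order": ["O", "O"],
             "cod_latitude": [20.0, 25.0]},
            index=["a", "b"],
        )
        assert taxonomic_diversity([1, 1], tab) == pytest.approx(1.0, abs=1e-12)

    def test_single_species_multiple_individuals(self, three_species_table):
        assert taxonomic_diversity([5, 0, 0], three_species_table) == 0.0

    def test_single_individual_undefined(self, three_species_table):
        assert math.isnan(taxonomic_diversity([1, 0, 0], three_species_table))

    def test_hand_enumeration(self, three_species_table):
        # pairs: (s1,s2) w=2 n=2*1; (s1,s3) w=4 n=2*1; (s2,s3) w=4 n=1*1
        # delta = (4 + 8 + 4) / (5 + 1) = 16/6
        got = taxonomic_diversity([2, 1, 1], three_species_table)
        assert got == pytest.approx(16 / 6, abs=1e-10)

    def test_relabeling_to_distant_orders_increases_delta(self, three_species_table):
        base = taxonomic_diversity([2, 1, 1], three_species_table)
        distant = three_species_table.copy()
        distant["genus"] = ["Ga", "Gb", "Gc"]
        distant["family"] = ["F1", "F2", "F3"]
        distant["order"] = ["O1", "O2", "O3"]
        assert taxonomic_diversity([2, 1, 1], distant) > base

    def test_label_scaling_invariance(self, three_species_table):
        renamed = three_species_table.copy()
        for col in ("genus", "family", "order"):
            renamed[col] = "x_" + renamed[col]
        a = taxonomic_diversity([2, 1, 1], three_species_table)
        b = taxonomic_diversity([2, 1, 1], renamed)
        assert a == pytest.approx(b, abs=1e-14)


class TestCOD:
    def test_two_point_symmetry(self):
        tab = pd.DataFrame(
            {"genus": ["G1", "G2"], "family": ["F1", "F2"], "order": ["O1", "O2"],
             "cod_latitude": [20.0, 40.0]},
            index=["a", "b"],
        )
        z = standardized_cod(tab, ["a", "b"])
        np.testing.assert_allclose(z.to_numpy(), [-1.0, 1.0], atol=1e-12)

    def test_degenerate_distribution_errors(self):
        tab = pd.DataFrame(
            {"genus": ["G1", "G2"], "family": ["F1", "F2"], "order": ["O1", "O2"],
             "cod_latitude": [30.0, 30.0]},
            index=["a", "b"],
        )
        with pytest.raises(ValueError, match="degenerate"):
            standardized_cod(tab, ["a", "b"])

    def test_restandardization(self, three_species_table):
        z = standardized_cod(three_species_table, ["s1", "s2", "s3"]).to_numpy()
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert np.mean(z**2) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "p, z, expected",
        [
            ((1.0,), (1.7,), 1.7),
            ((0.75, 0.25), (-1.0, 1.0), -0.5),
            ((0.5, 0.3, 0.2), (-1.2, 0.3, 0.9), -0.33),
        ],
    )
    def test_community_cod(self, p, z, expected):
        assert community_cod(p, z) == pytest.approx(expected, abs=1e-12)

    def test_equal_proportion_pool_gives_zero(self, three_species_table):
        z = standardized_cod(three_species_table, ["s1", "s2", "s3"]).to_numpy()
        assert community_cod(np.full(3, 1 / 3), z) == pytest.approx(0.0, abs=1e-12)


class TestIndicatorTimeSeries:
    def test_panel_shape_and_order(self, small_community, three_species_table):
        panel = indicator_time_series(small_community, three_species_table)
        assert list(panel.columns) == INDICATOR_NAMES
        assert len(panel) == len(small_community)

    def test_single_survey(self, three_species_table):
        community = pd.DataFrame(
            [[2, 1, 1]],
            index=pd.to_datetime(["2015-01-01"]),
            columns=three_species_table.index,
        )
        panel = indicator_time_series(community, three_species_table)
        assert panel.shape == (1, 10)
        assert panel.loc[panel.index[0], "delta"] == pytest.approx(16 / 6)

    def test_empty_survey_propagates_missing(self, small_community, three_species_table):
        community = small_community.copy()
        community.iloc[2] = 0
        with pytest.warns(UserWarning, match="empty community"):
            panel = indicator_time_series(community, three_species_table)
        assert panel.iloc[2].isna().all()
        assert panel.drop(panel.index[2]).drop(columns=["E_D", "E_H", "delta"]).notna().all().all()

    def test_unknown_species_named_in_error(self, small_community, three_species_table):
        community = small_community.rename(columns={"s3": "mystery"})
        with pytest.raises(KeyError, match="mystery"):
            indicator_time_series(community, three_species_table)

    def test_single_species_survey_flags_undefined_evenness(self, small_community, three_species_table):
        panel = indicator_time_series(small_community, three_species_table)
        row = panel.iloc[4]  # survey (5, 0, 0)
        assert math.isnan(row["E_D"]) and math.isnan(row["E_H"])
        assert row["S"] == 1 and row["delta"] == 0.0
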