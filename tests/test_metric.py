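import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tablesim.io_setups import SetupCollection
from tablesim.metric import (
    MetricWeights,
    UndefinedSimilarityError,
    instrument_scores,
    rot_distance,
    similarity_matrix,
    table_similarity,
    trans_distance,
)

from .conftest import collections_st, make_setup, placement, setups_st
from .oracle import brute_force_score

W_DEFAULT = MetricWeights()


class TestWeights:
    def test_defaults(self):
        assert (W_DEFAULT.w_trans, W_DEFAULT.w_rot, W_DEFAULT.w_miss) == (1.0, 1.0, 1000.0)

    @pytest.mark.parametrize("bad", [{"w_trans": -1}, {"w_rot": math.nan}, {"w_miss": math.inf}])
    def test_invalid_rejected(self, bad):
        with pytest.raises(ValueError):
            MetricWeights(**bad)


class TestTransDistance:
    def test_3_4_5_triangle(self):
        assert trans_distance(placement("I", 0, 0), placement("I", 3, 4)) == 5.0

    def test_identical_positions(self):
        assert trans_distance(placement("I", 7, 9), placement("I", 7, 9)) == 0.0

    def test_surface_diagonal(self):
        # hypotenuse of the full surface: sqrt(1920^2 + 1080^2) = sqrt(4852800)
        d = trans_distance(placement("I", 0, 0), placement("I", 1920, 1080))
        assert d == pytest.approx(math.sqrt(4852800), rel=1e-12)
        assert d == pytest.approx(2202.9071700823, abs=1e-9)


class TestRotDistance:
    @pytest.mark.parametrize(
        "a,b,expected", [(10, 350, 20), (0, 180, 180), (90, 90, 0), (350, 10, 20), (0, 0, 0)]
    )
    def test_examples(self, a, b, expected):
        assert rot_distance(a, b) == expected

    @given(
        st.floats(min_value=0, max_value=359.999),
        st.floats(min_value=0, max_value=359.999),
    )
    def test_range_and_symmetry(self, a, b):
        d = rot_distance(a, b)
        assert 0 <= d <= 180
        assert d == rot_distance(b, a)


class TestInstrumentScores:
    def test_single_matched(self, single_pair):
        a, b = single_pair
        (score,) = instrument_scores(a, b, W_DEFAULT)
        assert score.status == "matched"
        assert score.d_trans == 5.0 and score.d_rot == 20.0
        assert score.s_inst == 25.0  # 1*5 + 1*20

    def test_disjoint_instruments_each_penalized_once(self):
        a = make_setup("a", "c", placement("I1", 0, 0))
        b = make_setup("b", "c", placement("I2", 0, 0))
        scores = instrument_scores(a, b, W_DEFAULT)
        assert [(s.instrument_id, s.status, s.s_inst) for s in scores] == [
            ("I1", "missing", 1000.0),
            ("I2", "missing", 1000.0),
        ]

    def test_self_comparison_all_zero(self):
        s = make_setup("a", "c", placement("I1", 5, 6, 7), placement("I2", 8, 9, 10))
        scores = instrument_scores(s, s, W_DEFAULT)
        assert all(x.status == "matched" and x.s_inst == 0.0 for x in scores)
        assert len(scores) == 2

    def test_duplicates_optimal_assignment(self):
        # two I1 on each side; crosswise matching is cheaper than greedy order
        a = make_setup("a", "c", placement("I1", 0, 0), placement("I1", 100, 0))
        b = make_setup("b", "c", placement("I1", 101, 0), placement("I1", 1, 0))
        scores = instrument_scores(a, b, W_DEFAULT)
        assert sorted(s.s_inst for s in scores) == [1.0, 1.0]

    def test_duplicates_surplus_counts_missing(self):
        a = make_setup("a", "c", placement("I1", 0, 0), placement("I1", 50, 0))
        b = make_setup("b", "c", placement("I1", 0, 0))
        scores = instrument_scores(a, b, W_DEFAULT)
        by_status = sorted((s.status, s.s_inst) for s in scores)
        assert by_status == [("matched", 0.0), ("missing", 1000.0)]


class TestTableSimilarity:
    def test_identical_setups_zero(self):
        s = make_setup("a", "c", placement("I1", 10, 20, 30))
        assert table_similarity(s, s, W_DEFAULT) == 0.0

    def test_worked_single_instrument_pair(self, single_pair):
        a, b = single_pair
        assert table_similarity(a, b, W_DEFAULT) == 25.0

    def test_disjoint_pair_is_w_miss(self):
        a = make_setup("a", "c", placement("I1", 0, 0))
        b = make_setup("b", "c", placement("I2", 0, 0))
        # (1000 + 1000) / 2 under union normalization
        assert table_similarity(a, b, W_DEFAULT) == 1000.0

    def test_both_empty_undefined(self):
        a = make_setup("a", "c")
        b = make_setup("b", "c")
        with pytest.raises(UndefinedSimilarityError):
            table_similarity(a, b, W_DEFAULT)

    def test_normalization_strategies_differ(self):
        a = make_setup("a", "c", placement("I1", 0, 0), placement("I2", 0, 0))
        b = make_setup("b", "c", placement("I1", 3, 4))
        # matched I1 costs 5; missing I2 costs 1000
        assert table_similarity(a, b, W_DEFAULT, "union") == pytest.approx(1005 / 2)
        assert table_similarity(a, b, W_DEFAULT, "max-size") == pytest.approx(1005 / 2)
        assert table_similarity(a, b, W_DEFAULT, "matched-only") == pytest.approx(1005 / 1)


class TestSimilarityMatrix:
    def test_two_identical_setups(self):
        s1 = make_setup("a", "c", placement("I1", 1, 2, 3))
        s2 = make_setup("b", "c", placement("I1", 1, 2, 3))
        m = similarity_matrix(SetupCollection([s1, s2]), W_DEFAULT)
        assert np.array_equal(m.values, np.zeros((2, 2)))

    def test_duplicate_setup_id_rejected(self):
        s = make_setup("a", "c", placement("I1", 1, 2))
        with pytest.raises(ValueError, match="duplicate"):
            similarity_matrix(SetupCollection([s, s]), W_DEFAULT)

    def test_matches_per_pair_calls(self):
        setups = [
            make_setup("a", "c1", placement("I1", 0, 0, 10), placement("I2", 5, 5, 0)),
            make_setup("b", "c1", placement("I1", 30, 40, 350)),
            make_setup("c", "c2", placement("I3", 100, 100, 90)),
        ]
        c = SetupCollection(setups)
        m = similarity_matrix(c, W_DEFAULT)
        for i in range(3):
            for j in range(3):
                expected = 0.0 if i == j else table_similarity(setups[i], setups[j], W_DEFAULT)
                assert m.values[i, j] == expected


# --- properties ------------------------------------------------------------

weights_st = st.builds(
    MetricWeights,
    w_trans=st.floats(min_value=0, max_value=10),
    w_rot=st.floats(min_value=0, max_value=10),
    w_miss=st.floats(min_value=0, max_value=2000),
)


@settings(max_examples=200, deadline=None)
@given(setups_st(max_placements=5), setups_st(min_placements=1, max_placements=5), weights_st)
def test_symmetry_bitwise(a, b, w):
    assert table_similarity(a, b, w) == table_similarity(b, a, w)


@settings(max_examples=100, deadline=None)
@given(setups_st(min_placements=1))
def test_identity_zero(s):
    assert table_similarity(s, s, W_DEFAULT) == 0.0


@settings(max_examples=100, deadline=None)
@given(setups_st(max_placements=5), setups_st(min_placements=1, max_placements=5), weights_st)
def test_non_negative_and_bounded(a, b, w):
    s = table_similarity(a, b, w)
    bound = max(w.w_miss, w.w_trans * 2202.91 + w.w_rot * 180.0)
    assert 0.0 <= s <= bound + 1e-9


@settings(max_examples=100, deadline=None)
@given(setups_st(max_placements=4), setups_st(min_placements=1, max_placements=4))
def test_w_miss_monotonicity(a, b):
    ids_a = {p.instrument_id for p in a.placements}
    ids_b = {p.instrument_id for p in b.placements}
    low = table_similarity(a, b, MetricWeights(1, 1, 500))
    high = table_similarity(a, b, MetricWeights(1, 1, 1500))
    if ids_a != ids_b or any(
        sum(p.instrument_id == i for p in a.placements)
        != sum(p.instrument_id == i for p in b.placements)
        for i in ids_a
    ):
        assert high >= low
    else:
        assert high == low


def test_translation_monotonicity():
    a = make_setup("a", "c", placement("I1", 100, 100), placement("I2", 0, 0))
    scores = []
    for x in (100, 300, 900, 1900):
        b = make_setup("b", "c", placement("I1", x, 100), placement("I2", 0, 0))
        scores.append(table_similarity(a, b, W_DEFAULT))
    assert scores == sorted(scores)


@settings(max_examples=100, deadline=None)
@given(setups_st(min_placements=1, max_placements=4), st.floats(min_value=0.1, max_value=8))
def test_weight_linearity_on_matched_tables(a, factor):
    # b = a with jittered coordinates so every instrument matches
    b_placements = [
        placement(p.instrument_id, min(p.x + 7, 1920), p.y, (p.angle + 30) % 360)
        for p in a.placements
    ]
    b = make_setup("b", a.clinic_id, *b_placements)
    base = table_similarity(a, b, MetricWeights(1, 1, 0))
    scaled = table_similarity(a, b, MetricWeights(factor, factor, 0))
    assert scaled == pytest.approx(factor * base, rel=1e-12)


@settings(max_examples=150, deadline=None)
@given(setups_st(max_placements=6), setups_st(max_placements=6), weights_st)
def test_oracle_equivalence_pairwise(a, b, w):
    if not a.placements and not b.placements:
        return
    expected = brute_force_score(a, b, w.w_trans, w.w_rot, w.w_miss)
    got = table_similarity(a, b, w)
    assert got == pytest.approx(expected, rel=1e-9, abs=1e-12)


@settings(max_examples=30, deadline=None)
@given(collections_st(min_setups=2, max_setups=5), weights_st)
def test_matrix_oracle_equivalence(c, w):
    if any(len(s.placements) == 0 for s in c.setups):
        return
    m = similarity_matrix(c, w)
    assert np.array_equal(m.values, m.values.T)
    assert np.array_equal(np.diag(m.values), np.zeros(len(c)))
    for i, si in enumerate(c.setups):
        for j, sj in enumerate(c.setups):
            if i < j:
                expected = brute_force_score(si, sj, w.w_trans, w.w_rot, w.w_miss)
                assert m.values[i, j] == pytest.approx(expected, rel=1e-9)
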