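"""The clamped Gaussian compound score (KLS) and the correlation-matrix
library score (KLSC): analytic values, oracles and metric properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinaselike import (
    CorrelationMatrix,
    DegenerateProfileError,
    SchemaError,
    ScoringError,
    correlation_matrix,
    kbd_reference_matrix,
    kls,
    klsc,
    load_matrix,
    save_matrix,
    score_library,
)
from kinaselike.constants import DESCRIPTOR_NAMES, N_PAIRS

from conftest import make_table


class TestKLS:
    def test_nine_exactly_at_profile_means(self, kbd_profile):
        assert kls(kbd_profile.means(), kbd_profile) == 9.0

    def test_zero_when_every_descriptor_is_clamped(self, kbd_profile):
        x = kbd_profile.p90s() + 10 * kbd_profile.sds()
        assert kls(x, kbd_profile) == 0.0

    def test_single_sigma_displacement(self, kbd_profile):
        x = kbd_profile.means()
        x[0] += kbd_profile.Wt.sd  # still inside the P10-P90 window
        assert kls(x, kbd_profile) == pytest.approx(8 + np.exp(-1), abs=1e-12)

    def test_clamp_window_is_inclusive(self, kbd_profile):
        x = kbd_profile.means()
        x[0] = kbd_profile.Wt.p90  # exactly on the boundary: term still counts
        score = kls(x, kbd_profile)
        assert score > 8.0  # eight full terms plus a positive Wt term

    def test_non_finite_descriptor_names_the_culprit(self, kbd_profile):
        x = kbd_profile.means()
        x[5] = np.nan
        with pytest.raises(ScoringError, match="TPSA"):
            kls(x, kbd_profile)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 8), st.floats(0.05, 1.0), st.floats(0.05, 1.0))
    def test_monotone_decay_within_clamp(self, kbd_profile, idx, near, far):
        """KLS never increases as a descriptor moves away from its mean."""
        near, far = sorted([near, far])
        sd = kbd_profile.sds()[idx]
        x_near, x_far = kbd_profile.means(), kbd_profile.means()
        x_near[idx] += near * sd
        x_far[idx] += far * sd
        assert kls(x_far, kbd_profile) <= kls(x_near, kbd_profile) <= 9.0

    def test_score_bounded(self, kbd_profile):
        rng = np.random.default_rng(5)
        for _ in range(200):
            x = kbd_profile.means() + rng.normal(scale=3, size=9) * kbd_profile.sds()
            assert 0.0 <= kls(x, kbd_profile) <= 9.0


class TestScoreLibrary:
    def test_batch_equals_rowwise_oracle(self, kbd_profile):
        rng = np.random.default_rng(17)
        rows = kbd_profile.means() + rng.normal(size=(100, 9)) * kbd_profile.sds()
        table = make_table(rows)
        scored = score_library(table, kbd_profile)
        expected = [kls(row, kbd_profile) for row in rows]
        np.testing.assert_allclose(scored.df["kls"].to_numpy(), expected, atol=1e-12)
        assert scored.df["id"].tolist() == table.df["id"].tolist()

    def test_empty_table(self, kbd_profile):
        scored = score_library(make_table(np.empty((0, 9))), kbd_profile)
        assert len(scored) == 0 and scored.scored

    def test_missing_descriptor_column_is_schema_error(self, kbd_profile):
        table = make_table(np.ones((3, 9)))
        table.df = table.df.drop(columns=["TPSA"])
        with pytest.raises(SchemaError, match="TPSA"):
            score_library(table, kbd_profile)


def _random_corr(rng, n_rows=40):
    return correlation_matrix(make_table(rng.normal(size=(n_rows, 9))))


class TestCorrelationMatrix:
    def test_perfectly_correlated_columns(self):
        rng = np.random.default_rng(2)
        rows = rng.normal(size=(30, 9))
        rows[:, DESCRIPTOR_NAMES.index("nN")] = rows[:, DESCRIPTOR_NAMES.index("HBA")]
        m = correlation_matrix(make_table(rows))
        assert m.entry("HBA", "nN") == pytest.approx(1.0)

    def test_five_row_hand_table_matches_textbook_pearson(self):
        rows = np.array(
            [[1, 2, 1, 4, 0.5, 10, 1, 0, 1],
             [2, 1, 3, 3, 1.0, 20, 2, 1, 2],
             [3, 5, 2, 5, 1.5, 15, 1, 2, 1],
             [4, 3, 5, 2, 0.0, 30, 3, 1, 3],
             [5, 6, 4, 1, 2.0, 25, 2, 3, 2]], dtype=float,
        )
        m = correlation_matrix(make_table(rows))
        x, y = rows[:, 0], rows[:, 1]  # Wt vs RB, by the raw-sums formula
        n = len(x)
        num = n * (x * y).sum() - x.sum() * y.sum()
        den = np.sqrt(n * (x**2).sum() - x.sum() ** 2) * np.sqrt(
            n * (y**2).sum() - y.sum() ** 2
        )
        assert m.entry("Wt", "RB") == pytest.approx(num / den, abs=1e-12)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(3)
        n = 20_000
        m = correlation_matrix(make_table(rng.normal(size=(n, 9))))
        off = m.values[np.triu_indices(9, k=1)]
        assert np.abs(off).max() < 3 / np.sqrt(n)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        rows = rng.normal(size=(50, 9))
        m1 = correlation_matrix(make_table(rows))
        scaled = rows * np.array([2, 1, 5, 1, 0.1, 3, 1, 7, 1]) + 11
        m2 = correlation_matrix(make_table(scaled))
        np.testing.assert_allclose(m1.values, m2.values, atol=1e-10)

    def test_constant_column_rejected(self):
        rows = np.random.default_rng(5).normal(size=(10, 9))
        rows[:, 2] = 7.0
        with pytest.raises(DegenerateProfileError, match="HBA"):
            correlation_matrix(make_table(rows))

    def test_validation_rules(self):
        bad = np.eye(9)
        bad[0, 1] = 0.5  # asymmetric
        with pytest.raises(SchemaError):
            CorrelationMatrix(values=bad)
        with pytest.raises(SchemaError):
            CorrelationMatrix(values=np.eye(8))

    def test_csv_round_trip(self, tmp_path):
        m = _random_corr(np.random.default_rng(6))
        p = tmp_path / "corr.csv"
        save_matrix(m, p)
        back = load_matrix(p)
        np.testing.assert_allclose(back.values, m.values, atol=1e-12)


class TestKLSC:
    def test_zero_on_identical_matrices(self, kbd_matrix):
        assert klsc(kbd_matrix, kbd_matrix) == 0.0

    def test_single_pair_difference(self, kbd_matrix):
        vals = kbd_matrix.values.copy()
        i, j = 1, 6  # the RB/Rings entry is 0.00, room to move by +0.36
        vals[i, j] = vals[j, i] = vals[i, j] + 0.36
        other = CorrelationMatrix(values=vals)
        assert klsc(other, kbd_matrix) == pytest.approx(0.36 / N_PAIRS)
        assert klsc(other, kbd_matrix) == pytest.approx(0.01)

    def test_there_are_36_unordered_pairs(self):
        assert N_PAIRS == 36 == 9 * 8 // 2

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    def test_symmetry(self, seed_a, seed_b):
        a = _random_corr(np.random.default_rng(seed_a))
        b = _random_corr(np.random.default_rng(seed_b))
        assert klsc(a, b) == klsc(b, a)
        assert 0.0 <= klsc(a, b) <= 2.0

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = (_random_corr(rng) for _ in range(3))
        assert klsc(a, c) <= klsc(a, b) + klsc(b, c) + 1e-12


class TestReferenceMatrix:
    def test_published_entries(self, kbd_matrix):
        assert kbd_matrix.entry("Wt", "RB") == 0.70
        assert kbd_matrix.entry("HBA", "TPSA") == 0.62
        assert kbd_matrix.entry("SlogP", "TPSA") == -0.44
        assert kbd_matrix.entry("TPSA", "nO") == 0.66
        assert kbd_matrix.entry("nN", "nO") == -0.29

    def test_symmetrized_with_unit_diagonal(self, kbd_matrix):
        np.testing.assert_array_equal(kbd_matrix.values, kbd_matrix.values.T)
        np.testing.assert_array_equal(np.diag(kbd_matrix.values), np.ones(9))
        assert kbd_matrix.entry("RB", "Wt") == 0.70
        assert kbd_matrix.n_rows_used == 22615
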