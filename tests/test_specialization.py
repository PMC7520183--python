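import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietspec import specialization as spec


def _props(rows, taxa=None, ids=None):
    taxa = taxa or [f"t{j}" for j in range(len(rows[0]))]
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, columns=taxa, index=ids)


class TestPsi:
    def test_identity(self):
        assert spec.psi([0.2, 0.3, 0.5], [0.2, 0.3, 0.5]) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        assert spec.psi([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.0)

    def test_direct_evaluation(self):
        assert spec.psi([0.5, 0.5, 0.0], [0.25, 0.25, 0.5]) == pytest.approx(0.5)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            spec.psi([0.5, 0.5], [0.3, 0.3, 0.4])
        with pytest.raises(ValueError):
            spec.psi([0.6, 0.6], [0.5, 0.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8),
           st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8))
    def test_bounded_and_symmetric(self, a, b):
        k = min(len(a), len(b))
        p = np.array(a[:k]) / sum(a[:k])
        q = np.array(b[:k]) / sum(b[:k])
        v = spec.psi(p, q)
        assert 0.0 <= v <= 1.0 + 1e-12
        assert v == pytest.approx(spec.psi(q, p))


class TestPopulationDiet:
    def test_single_member_identity(self):
        m = _props([[0.3, 0.7]])
        pd.testing.assert_series_equal(spec.population_diet(m), m.iloc[0],
                                       check_names=False)

    def test_two_member_symmetry(self):
        m = _props([[1.0, 0.0], [0.0, 1.0]])
        assert spec.population_diet(m).tolist() == [0.5, 0.5]

    def test_sole_specialist_share(self):
        rows = [[1.0, 0.0]] + [[0.0, 1.0]] * 4
        assert spec.population_diet(_props(rows))["t0"] == pytest.approx(1 / 5)

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            spec.population_diet(_props([[1.0]]).iloc[:0])


class TestGroups:
    def _study(self):
        props = _props([[1, 0], [0, 1], [0.5, 0.5], [0.2, 0.8], [1, 0], [0, 1]],
                       ids=[f"s{i}" for i in range(6)])
        meta = pd.DataFrame({
            "location": ["A", "A", "B", "B", "A", "B"],
            "month": [6] * 6, "year": [2020] * 6},
            index=props.index)
        calls = pd.Series(["male", "female", "male", "female", "male", "female"],
                          index=props.index)
        return props, meta, calls

    def test_hand_partition(self):
        props, meta, calls = self._study()
        groups = spec.form_groups(props, meta, calls)
        assert len(groups) == 4
        assert sorted(groups[("A", "Male", 2020, 6)].members.index) == ["s0", "s4"]
        assert sorted(groups[("B", "Female", 2020, 6)].members.index) == ["s3", "s5"]

    def test_single_key_single_group(self):
        props, meta, _ = self._study()
        calls = pd.Series(["male"] * 6, index=props.index)
        meta = meta.assign(location="A")
        groups = spec.form_groups(props, meta, calls)
        assert len(groups) == 1 and groups.popitem()[1].n == 6

    def test_excluded_calls_dropped_partition_exhaustive(self):
        props, meta, calls = self._study()
        calls.iloc[0] = "excluded_no_zfx"
        groups = spec.form_groups(props, meta, calls)
        assert sum(g.n for g in groups.values()) == 5

    def test_filter_threshold_boundary(self):
        props = _props(np.full((9, 2), 0.5), ids=[f"s{i}" for i in range(9)])
        meta = pd.DataFrame({"location": ["A"] * 4 + ["B"] * 5,
                             "month": [6] * 9, "year": [2020] * 9},
                            index=props.index)
        calls = pd.Series(["male"] * 9, index=props.index)
        groups = spec.form_groups(props, meta, calls)
        flags = spec.filter_groups(groups, min_n=5)
        assert flags[("A", "Male", 2020, 6)] is False
        assert flags[("B", "Male", 2020, 6)] is True

    def test_identical_diets_psi_one_and_shared_entropy(self):
        rows = [[0.5, 0.25, 0.25]] * 4
        g = spec.Group(("A", "Male", 2020, 6), _props(rows))
        assert np.allclose(g.psi_values, 1.0)
        assert g.shannon == pytest.approx(spec.shannon(rows[0]))

    def test_sole_specialist_exact_theoretical_minimum(self):
        rows = [[1.0, 0.0]] + [[0.0, 1.0]] * 4
        g = spec.Group(("A", "Male", 2020, 6), _props(rows))
        assert g.psi_values.iloc[0] == pytest.approx(g.theoretical_min, abs=1e-12)
        assert (g.psi_values + 1e-12 >= g.theoretical_min).all()


class TestScalarMetrics:
    @pytest.mark.parametrize("n, expected", [(5, 0.2), (37, 1 / 37), (1, 1.0)])
    def test_theoretical_minimum(self, n, expected):
        assert spec.theoretical_minimum(n) == pytest.approx(expected)
        assert round(spec.theoretical_minimum(37), 4) == 0.0270

    def test_theoretical_minimum_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            spec.theoretical_minimum(0)

    def test_min_prey_density(self):
        m = _props([[0.01, 0.99], [0.002, 0.998]])
        assert spec.min_prey_density(m) == pytest.approx(0.002)
        assert spec.min_prey_density(_props([[1.0, 0.0]])) == 1.0

    @pytest.mark.parametrize("q, h", [
        ([1.0], 0.0),
        ([0.25] * 4, math.log(4)),
        ([0.5, 0.25, 0.25], 1.0397)])
    def test_shannon(self, q, h):
        assert spec.shannon(q) == pytest.approx(h, abs=1e-4)

    def test_logit_values(self):
        assert spec.logit(0.5) == 0.0
        assert spec.logit(0.399) == pytest.approx(-0.4097, abs=1e-4)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(0.01, 0.99))
    def test_logit_antisymmetric(self, x):
        assert spec.logit(x) == pytest.approx(-spec.logit(1 - x), abs=1e-10)

    def test_logit_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            v = spec.logit(1.0)
        assert v == pytest.approx(math.log((1 - 1e-6) / 1e-6))

    @pytest.mark.parametrize("month, season", [
        (4, "Spring"), (5, "Spring"), (6, "Summer"), (8, "Summer"),
        (9, "Fall"), (11, "Fall"), (1, "out-of-window")])
    def test_season_mapping(self, month, season):
        assert spec.season_of(month) == season


class TestBootstrap:
    def test_constant_vector_zero_width(self):
        mean, half, lo, hi = spec.bootstrap_mean_ci([2.0] * 10, 1000, seed=0)
        assert half == 0.0 and lo == hi == mean == 2.0

    def test_half_width_matches_clt(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 1000)
        _, half, _, _ = spec.bootstrap_mean_ci(x, 20_000, seed=1)
        assert half == pytest.approx(1.96 / math.sqrt(1000), rel=0.15)

    def test_seed_determinism(self):
        x = np.random.default_rng(2).normal(size=50)
        a = spec.bootstrap_mean_ci(x, 2000, seed=9)
        b = spec.bootstrap_mean_ci(x, 2000, seed=9)
        assert a == b

    def test_input_validation(self):
        with pytest.raises(ValueError):
            spec.bootstrap_mean_ci([1.0], 2000, seed=0)
        with pytest.raises(ValueError):
            spec.bootstrap_mean_ci([1.0, 2.0], 10, seed=0)


class TestMoments:
    def test_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(size=20)
        skew, kurt = spec.moment_stats(x)
        # independent recomputation from raw moment sums
        mu = sum(x) / 20
        m2 = sum((v - mu) ** 2 for v in x) / 20
        m3 = sum((v - mu) ** 3 for v in x) / 20
        m4 = sum((v - mu) ** 4 for v in x) / 20
        assert skew == pytest.approx(m3 / m2 ** 1.5, abs=1e-12)
        assert kurt == pytest.approx(m4 / m2 ** 2, abs=1e-12)

    def test_symmetric_and_normal_limits(self):
        x = np.concatenate([np.linspace(-1, 1, 101)])
        skew, _ = spec.moment_stats(x)
        assert skew == pytest.approx(0.0, abs=1e-12)
        z = np.random.default_rng(4).normal(size=200_000)
        _, kurt = spec.moment_stats(z)
        assert kurt == pytest.approx(3.0, abs=0.1)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            spec.moment_stats([1.0, 1.0, 1.0])


class TestWeightedMeanPsi:
    def test_single_group_identity(self):
        df = pd.DataFrame({"n": [7], "mean_psi": [0.4], "use": [True]})
        assert spec.weighted_mean_psi(df) == pytest.approx(0.4)

    def test_hand_weighting(self):
        df = pd.DataFrame({"n": [2, 8], "mean_psi": [0.4, 0.6],
                           "use": [True, True]})
        assert spec.weighted_mean_psi(df) == pytest.approx(0.56)

    def test_excluded_groups_ignored(self):
        df = pd.DataFrame({"n": [2, 8, 100], "mean_psi": [0.4, 0.6, 0.0],
                           "use": [True, True, False]})
        assert spec.weighted_mean_psi(df) == pytest.approx(0.56)
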