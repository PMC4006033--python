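import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sagloc import (
    InvalidParameterError,
    ListenerModel,
    PerformanceScores,
    Predictor,
    constant_parameter_eval,
    factor_sds,
    pearson,
    permutation_grid,
    relative_performance,
)
from sagloc.factors import PermutationGrid


@pytest.fixture(scope="module")
def grid3(small_group):
    targets = [d for d in small_group[0].dtf.directions if abs(d.lateral) <= 30.0]
    return permutation_grid(small_group, targets), targets


class TestPermutationGrid:
    def test_shape_and_sorting(self, grid3, small_group):
        grid, _ = grid3
        assert grid.PE_matrix.shape == (3, 3)
        assert np.all(np.diff(grid.uncertainties) > 0)

    def test_diagonal_equals_baseline(self, grid3, small_group):
        grid, targets = grid3
        by_id = {lm.dtf.listener_id: lm for lm in small_group}
        for j, lid in enumerate(grid.listener_order):
            lm = by_id[lid]
            s = Predictor(lm.dtf).predicted_scores(targets, lm.uncertainty)
            assert grid.PE_matrix[j, j] == s.pe  # bit-for-bit
            assert grid.QE_matrix[j, j] == s.qe

    def test_shared_dtf_gives_constant_columns(self, small_group):
        shared = small_group[0].dtf
        group = [
            ListenerModel(dtf=shared, uncertainty=lm.uncertainty)
            for lm in small_group
        ]
        targets = [d for d in shared.directions if abs(d.lateral) <= 30.0]
        grid = permutation_grid(group, targets)
        for j in range(3):
            assert np.allclose(grid.PE_matrix[:, j], grid.PE_matrix[0, j])
            assert np.allclose(grid.QE_matrix[:, j], grid.QE_matrix[0, j])

    def test_shared_u_gives_constant_rows(self, small_group):
        group = [ListenerModel(dtf=lm.dtf, uncertainty=2.0) for lm in small_group]
        targets = [d for d in group[0].dtf.directions if abs(d.lateral) <= 30.0]
        grid = permutation_grid(group, targets)
        for i in range(3):
            assert np.allclose(grid.PE_matrix[i, :], grid.PE_matrix[i, 0])

    def test_single_listener_rejected(self, small_group):
        with pytest.raises(InvalidParameterError):
            permutation_grid(small_group[:1], [])


class TestRelativePerformance:
    def test_hand_example(self):
        grid = PermutationGrid(
            listener_order=["A", "B"],
            uncertainties=np.array([1.0, 2.0]),
            PE_matrix=np.array([[30.0, 40.0], [34.0, 44.0]]),
            QE_matrix=np.zeros((2, 2)),
        )
        rel = relative_performance(grid)
        assert rel["dPE_mean"] == pytest.approx([-2.0, 2.0])

    def test_diagonal_deltas_vanish(self, grid3):
        grid, _ = grid3
        delta = grid.PE_matrix - np.diag(grid.PE_matrix)[None, :]
        assert np.all(np.diag(delta) == 0.0)

    def test_identical_rows_zero_means(self):
        m = np.tile(np.array([[10.0, 20.0, 30.0]]), (3, 1))
        grid = PermutationGrid(
            listener_order=["A", "B", "C"],
            uncertainties=np.array([1.0, 2.0, 3.0]),
            PE_matrix=m,
            QE_matrix=m,
        )
        rel = relative_performance(grid)
        assert np.allclose(rel["dPE_mean"], 0.0)


class TestFactorSds:
    def test_constant_matrix(self):
        m = np.full((3, 3), 25.0)
        grid = PermutationGrid(["A", "B", "C"], np.array([1.0, 2.0, 3.0]), m, m)
        c = factor_sds(grid)
        assert np.allclose(c.sd_over_U_pe, 0.0)
        assert np.allclose(c.sd_over_D_pe, 0.0)

    def test_column_only_variation(self):
        # varies with U (across columns) only: row SDs positive, column SDs 0
        m = np.tile(np.array([[10.0, 20.0, 30.0]]), (3, 1))
        grid = PermutationGrid(["A", "B", "C"], np.array([1.0, 2.0, 3.0]), m, m)
        c = factor_sds(grid)
        assert np.all(c.sd_over_U_pe > 0)
        assert np.allclose(c.sd_over_D_pe, 0.0)

    def test_summary_ratio(self, grid3):
        grid, _ = grid3
        s = factor_sds(grid).summary()
        assert s["ratio_U_to_D"]["PE"] > 0


class TestPearson:
    def test_identity(self):
        assert pearson([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_affine_invariance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson(x, 2.0 * x + 3.0) == pytest.approx(1.0)

    def test_anticorrelation(self):
        x = np.array([1.0, 2.0, 3.0])
        assert pearson(x, -x + 10.0) == pytest.approx(-1.0)

    def test_direct_formula_oracle(self):
        assert pearson([1.0, 2.0, 3.0], [1.0, 3.0, 2.0]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(InvalidParameterError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(InvalidParameterError):
            pearson([1.0, 2.0], [1.0, 2.0])

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_matches_brute_force_covariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        # brute force: covariance sums without vectorized shortcuts
        mx, my = sum(x) / 10, sum(y) / 10
        cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
        vx = sum((a - mx) ** 2 for a in x)
        vy = sum((b - my) ** 2 for b in y)
        assert pearson(x, y) == pytest.approx(cov / (vx * vy) ** 0.5, abs=1e-12)


class TestConstantParameterEval:
    def test_constant_u_keys_and_bounds(self, small_group, grid3):
        _, targets = grid3
        actual = [
            Predictor(lm.dtf).predicted_scores(targets, lm.uncertainty)
            for lm in small_group
        ]
        out = constant_parameter_eval(
            small_group, ("constant_U", 2.0), actual, targets
        )
        assert -1.0 <= out["r_PE"] <= 1.0
        assert out["group_sd_PE"] >= 0.0

    def test_constant_dtf_mode(self, small_group, grid3):
        _, targets = grid3
        actual = [
            Predictor(lm.dtf).predicted_scores(targets, lm.uncertainty)
            for lm in small_group
        ]
        out = constant_parameter_eval(
            small_group,
            ("constant_DTF", small_group[0].dtf.listener_id),
            actual,
            targets,
        )
        # shared DTF with own uncertainty tracks the baseline closely
        assert out["r_PE"] > 0.9
        assert out["r_QE"] > 0.9

    def test_perfect_predictions_correlate_fully(self, small_group, grid3):
        _, targets = grid3
        # actuals chosen equal to the constant-DTF predictions themselves
        shared = Predictor(small_group[0].dtf)
        actual = [
            shared.predicted_scores(targets, lm.uncertainty) for lm in small_group
        ]
        out = constant_parameter_eval(
            small_group,
            ("constant_DTF", small_group[0].dtf.listener_id),
            actual,
            targets,
        )
        assert out["r_PE"] == pytest.approx(1.0)
        assert out["r_QE"] == pytest.approx(1.0)

    def test_small_group_rejected(self, small_group, grid3):
        _, targets = grid3
        actual = [PerformanceScores(30.0, 10.0)] * 2
        with pytest.raises(InvalidParameterError):
            constant_parameter_eval(
                small_group[:2], ("constant_U", 2.0), actual, targets
            )

    def test_unknown_mode_rejected(self, small_group, grid3):
        _, targets = grid3
        actual = [PerformanceScores(30.0, 10.0)] * 3
        with pytest.raises(InvalidParameterError):
            constant_parameter_eval(small_group, ("bogus", 1), actual, targets)
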