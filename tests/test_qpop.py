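import itertools

import numpy as np
import pytest

from qpopscreen import (
    InputError,
    InsufficientDataError,
    ScreenMeasurements,
    SingularDesignError,
    band_sizes,
    build_model_matrix,
    build_oacd,
    build_three_level_oa,
    f_test_parameters,
    fit_quadratic,
    project_search_space,
    response_surface,
    score_two_drug_pairs,
    stratify_percentiles,
)
from qpopscreen.qpop import PairScore, QuadraticModel, n_terms

from conftest import make_screen


def make_model(k, coef, names=None):
    names = names or tuple(f"d{i}" for i in range(k))
    p = n_terms(k)
    coef = np.asarray(coef, dtype=float)
    assert coef.size == p
    return QuadraticModel(k=k, coef=coef, coef_cov=np.eye(p), residual_df=10, sigma2=1.0,
                         factor_names=names)


def constant_model(k, c=100.0):
    coef = np.zeros(n_terms(k))
    coef[0] = c
    return make_model(k, coef)


class TestModelMatrix:
    def test_direct_expansion_k2(self):
        row = build_model_matrix(np.array([[1, -1]]))
        np.testing.assert_array_equal(row[0], [1, 1, -1, 1, 1, -1])

    def test_66_columns_for_k10(self, oacd10_matrix):
        assert oacd10_matrix.shape == (91, 66)

    def test_all_zero_row(self):
        row = build_model_matrix(np.zeros((1, 3), dtype=int))
        np.testing.assert_array_equal(row[0], [1] + [0] * 9)

    def test_non_coded_input_rejected(self):
        with pytest.raises(InputError):
            build_model_matrix(np.array([[0.5, 1.0]]))

    def test_full_rank_66_on_composite_design(self, oacd10_matrix):
        assert np.linalg.matrix_rank(oacd10_matrix) == 66


class TestFitQuadratic:
    def test_noise_free_exact_recovery(self, oacd10, oacd10_matrix):
        rng = np.random.default_rng(11)
        beta = rng.normal(0, 5, 66)
        model = fit_quadratic(make_screen(oacd10, oacd10_matrix @ beta))
        assert np.abs(model.coef - beta).max() < 1e-6

    def test_exact_recovery_over_50_seeded_draws(self, oacd10, oacd10_matrix):
        for seed in range(50):
            beta = np.random.default_rng(seed).normal(0, 5, 66)
            model = fit_quadratic(make_screen(oacd10, oacd10_matrix @ beta))
            assert np.abs(model.coef - beta).max() < 1e-6

    def test_constant_response(self, oacd10):
        model = fit_quadratic(make_screen(oacd10, np.full(91, 42.0)))
        assert model.beta0 == pytest.approx(42.0)
        assert np.abs(model.coef[1:]).max() < 1e-9

    def test_singular_design_names_columns(self):
        oa = build_three_level_oa(2)  # 27 runs but squared terms collinear? no; use tiny FF-like
        # duplicate-column design: two identical factors make x1 - x2 unidentifiable
        runs = np.column_stack([oa.runs[:, 0], oa.runs[:, 0]]).astype(np.int8)
        from qpopscreen.design import CodedDesign

        d = CodedDesign(runs, np.full(27, "OA"), ("a", "b"))
        with pytest.raises(SingularDesignError):
            fit_quadratic(make_screen(d, np.arange(27.0)))

    def test_insufficient_runs(self):
        oa = build_three_level_oa(6)  # 27 runs < 28 coefficients
        with pytest.raises(InsufficientDataError):
            fit_quadratic(make_screen(oa, np.zeros(27)))

    def test_agreement_with_statsmodels(self, oacd10, oacd10_matrix):
        """Independent cross-check of coefficients, covariance and diagnostics."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        y = oacd10_matrix @ rng.normal(0, 3, 66) + rng.normal(0, 5, 91)
        screen = make_screen(oacd10, y)
        model = fit_quadratic(screen)
        diag = f_test_parameters(model, screen)
        ref = sm.OLS(y, oacd10_matrix).fit()
        np.testing.assert_allclose(model.coef, ref.params, rtol=1e-8, atol=1e-10)
        np.testing.assert_allclose(model.coef_cov, ref.cov_params(), rtol=1e-8, atol=1e-12)
        np.testing.assert_allclose(diag.f_stats, ref.tvalues**2, rtol=1e-8)
        assert diag.r2 == pytest.approx(ref.rsquared)
        assert diag.adj_r2 == pytest.approx(ref.rsquared_adj)


class TestFTests:
    def test_exact_fit_flagged_infinite(self, oacd10, oacd10_matrix):
        beta = np.random.default_rng(0).normal(0, 5, 66)
        screen = make_screen(oacd10, oacd10_matrix @ beta)
        diag = f_test_parameters(fit_quadratic(screen), screen)
        assert diag.exact_fit
        assert np.all(np.isinf(diag.f_stats))
        assert np.all(diag.p_values == 0)

    def test_adjusted_r2_below_r2(self, oacd10, oacd10_matrix):
        rng = np.random.default_rng(1)
        y = oacd10_matrix @ rng.normal(0, 2, 66) + rng.normal(0, 5, 91)
        screen = make_screen(oacd10, y)
        diag = f_test_parameters(fit_quadratic(screen), screen)
        assert diag.adj_r2 <= diag.r2 <= 1.0

    def test_null_coefficient_rejection_rate_calibrated(self, oacd10, oacd10_matrix):
        """Size of the partial F test at alpha=0.05 under a true zero (200 sims)."""
        beta = np.random.default_rng(123).normal(0, 3, 66)
        beta[30] = 0.0
        rej = 0
        for s in range(200):
            y = oacd10_matrix @ beta + np.random.default_rng(40_000 + s).normal(0, 5, 91)
            screen = make_screen(oacd10, y)
            diag = f_test_parameters(fit_quadratic(screen), screen)
            rej += diag.p_values[30] < 0.05
        assert 0.01 <= rej / 200 <= 0.10


class TestProjection:
    def test_constant_model_full_grid(self):
        grid = project_search_space(constant_model(3))
        assert grid.combos.shape == (27, 3)
        assert np.all(grid.predicted == 100.0)

    def test_full_grid_size_k10(self):
        grid = project_search_space(constant_model(10))
        assert grid.combos.shape[0] == 3**10

    def test_subset_exactly_two_active(self):
        grid = project_search_space(constant_model(4), subset=2)
        assert grid.combos.shape[0] == 6 * 4  # C(4,2) pairs x {0,1}^2
        active = np.sum(grid.combos != -1, axis=1)
        assert np.all(active == 2)

    def test_strongest_interaction_wins_exhaustively(self):
        """Brute-force check: a synergy block localized on one pair gives the
        best exactly-2-active combination for that pair.

        The block is -c (x_i+1)(x_j+1)/4, which vanishes whenever either
        drug is absent; a bare x_i x_j term would also fire at (-1, -1),
        i.e. when *neither* drug is present, and could not represent
        combination-specific synergy under this coding.
        """
        k = 4
        c = 30.0
        coef = np.zeros(n_terms(k))
        coef[0] = 100.0 - c / 4
        coef[1 : 1 + k] = -5.0
        i, j = 1, 3
        coef[1 + i] += -c / 4
        coef[1 + j] += -c / 4
        pairs = list(itertools.combinations(range(k), 2))
        coef[1 + 2 * k + pairs.index((i, j))] = -c / 4
        model = make_model(k, coef)
        grid = project_search_space(model, subset=2).sorted()
        best = grid.combos[0]
        assert set(np.flatnonzero(best != -1)) == {1, 3}
        assert np.all(best[[1, 3]] == 1)
        # agreement with direct evaluation over all exactly-2-active combos
        direct = {
            tuple(c): float(model.predict(c[None, :])[0]) for c in grid.combos
        }
        assert min(direct, key=direct.get) == tuple(best)


class TestPairScores:
    def test_constant_model_scores_100(self):
        scores = score_two_drug_pairs(constant_model(5))
        assert len(scores) == 10
        assert all(s.gmean_viability == pytest.approx(100.0) for s in scores)

    def test_negative_interaction_is_unique_minimum(self):
        # synergy block localized on pair (0, 3): zero unless both present
        k = 5
        c = 25.0
        coef = np.zeros(n_terms(k))
        coef[0] = 80.0 - c / 4
        coef[1 + 0] = coef[1 + 3] = -c / 4
        pairs = list(itertools.combinations(range(k), 2))
        coef[1 + 2 * k + pairs.index((0, 3))] = -c / 4
        scores = score_two_drug_pairs(make_model(k, coef))
        best = min(scores, key=lambda s: s.gmean_viability)
        assert best.indices == (0, 3)
        assert sum(s.gmean_viability == best.gmean_viability for s in scores) == 1

    def test_permutation_equivariance(self):
        """Relabeling drugs permutes pair scores coherently."""
        k = 4
        rng = np.random.default_rng(9)
        coef = rng.normal(0, 4, n_terms(k))
        coef[0] = 90
        model = make_model(k, coef, names=("a", "b", "c", "d"))
        perm = [2, 0, 3, 1]  # new order of old indices
        # build permuted model by permuting coefficient blocks
        pairs = list(itertools.combinations(range(k), 2))
        new_coef = np.empty_like(coef)
        new_coef[0] = coef[0]
        inv = np.argsort(perm)
        for new_i, old_i in enumerate(perm):
            new_coef[1 + new_i] = coef[1 + old_i]
            new_coef[1 + k + new_i] = coef[1 + k + old_i]
        for idx, (i, j) in enumerate(pairs):
            oi, oj = sorted((perm[i], perm[j]))
            new_coef[1 + 2 * k + idx] = coef[1 + 2 * k + pairs.index((oi, oj))]
        names = tuple("abcd"[i] for i in perm)
        permuted = make_model(k, new_coef, names=names)
        orig = {frozenset(s.pair): s.gmean_viability for s in score_two_drug_pairs(model)}
        new = {frozenset(s.pair): s.gmean_viability for s in score_two_drug_pairs(permuted)}
        for key in orig:
            assert new[key] == pytest.approx(orig[key])

    def test_nonpositive_predictions_are_clamped(self):
        coef = np.zeros(n_terms(2))
        coef[0] = -50.0
        scores = score_two_drug_pairs(make_model(2, coef))
        assert scores[0].gmean_viability == pytest.approx(1e-6)


class TestStratify:
    @staticmethod
    def scores(values):
        return [
            PairScore(pair=(f"p{i}", f"q{i}"), indices=(0, 1), gmean_viability=v)
            for i, v in enumerate(values)
        ]

    def test_45_distinct_scores_band_sizes(self):
        banded = stratify_percentiles(self.scores(np.linspace(1, 99, 45)))
        assert band_sizes(banded) == {"75-100": 12, "50-75": 11, "25-50": 11, "0-25": 11}

    def test_most_effective_band_holds_lowest_viability(self):
        banded = stratify_percentiles(self.scores(np.linspace(1, 99, 45)))
        top = [s.gmean_viability for s in banded if s.percentile_band == "75-100"]
        rest = [s.gmean_viability for s in banded if s.percentile_band != "75-100"]
        assert max(top) < min(rest)

    def test_ties_broken_lexicographically(self):
        banded = stratify_percentiles(self.scores([50.0] * 8))
        assert [s.pair[0] for s in banded] == sorted(s.pair[0] for s in banded)
        assert band_sizes(banded) == {"75-100": 2, "50-75": 2, "25-50": 2, "0-25": 2}

    def test_four_pairs_one_per_band(self):
        banded = stratify_percentiles(self.scores([10, 20, 30, 40]))
        assert [s.percentile_band for s in banded] == ["75-100", "50-75", "25-50", "0-25"]

    def test_fewer_than_four_rejected(self):
        with pytest.raises(InputError):
            stratify_percentiles(self.scores([1, 2, 3]))


class TestResponseSurface:
    def test_constant_model_flat_surface(self):
        surf = response_surface(constant_model(3), (0, 1), grid_size=5)
        assert np.all(surf.surface == 100.0)

    def test_corner_matches_two_active_prediction(self):
        rng = np.random.default_rng(2)
        model = make_model(4, rng.normal(0, 3, n_terms(4)))
        surf = response_surface(model, (1, 2), grid_size=3)
        row = np.full((1, 4), -1.0)
        row[0, 1] = row[0, 2] = 1.0
        assert surf.surface[-1, -1] == pytest.approx(float(model.predict(row)[0]))

    def test_pure_interaction_saddle(self):
        k = 2
        coef = np.zeros(n_terms(k))
        c = 7.0
        coef[0] = 0.0
        coef[-1] = -c  # single interaction term
        surf = response_surface(make_model(k, coef), (0, 1), grid_size=3)
        assert surf.surface[-1, -1] == pytest.approx(-c)   # (+1, +1)
        assert surf.surface[-1, 0] == pytest.approx(+c)    # (+1, -1)

    def test_bad_pair_rejected(self):
        with pytest.raises(InputError):
            response_surface(constant_model(3), (0, 5))
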