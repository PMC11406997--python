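"""PCA projection, Procrustes m2, PROTEST permutation test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist

from chassiskit import concordance
from chassiskit.concordance import (
    pca_project,
    per_category_concordance,
    procrustes_m2,
    protest,
)


def rotation(theta):
    return np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )


def brute_force_m2(X, Y, n_grid=3601):
    """Independent oracle: minimize the residual SS of the symmetric
    superimposition directly over rotation angle, reflection, and scale."""
    X = np.asarray(X, float) - np.asarray(X, float).mean(0)
    Y = np.asarray(Y, float) - np.asarray(Y, float).mean(0)
    X = X / np.sqrt((X**2).sum())
    Y = Y / np.sqrt((Y**2).sum())
    best = np.inf
    for refl in (1.0, -1.0):
        F = np.diag([1.0, refl])

        def objective(theta):
            YR = Y @ (rotation(theta) @ F)
            c = (X * YR).sum() / (YR**2).sum()  # 1-D least squares in c
            return float(((X - c * YR) ** 2).sum())

        thetas = np.linspace(0.0, 2 * np.pi, n_grid)
        coarse = [objective(t) for t in thetas]
        i0 = int(np.argmin(coarse))
        res = minimize_scalar(
            objective,
            bounds=(thetas[max(i0 - 1, 0)], thetas[min(i0 + 1, n_grid - 1)]),
            method="bounded",
            options={"xatol": 1e-13},
        )
        best = min(best, res.fun, coarse[i0])
    return best


class TestPcaProject:
    def test_two_column_input_reproduced_up_to_rotation(self, rng):
        X = rng.standard_normal((6, 2))
        X -= X.mean(0)
        conf = pca_project(pd.DataFrame(X))
        # a rotation/reflection preserves all pairwise distances
        assert np.allclose(pdist(conf.coords), pdist(X), rtol=1e-9)

    def test_rank_two_matrix_explains_all_variance(self, rng):
        basis = rng.standard_normal((2, 100))
        X = rng.standard_normal((6, 2)) @ basis
        conf = pca_project(pd.DataFrame(X))
        assert conf.variance_explained.sum() == pytest.approx(1.0)

    def test_duplicated_features_scale_scores(self, rng):
        X = pd.DataFrame(rng.standard_normal((6, 5)))
        doubled = pd.concat([X, X], axis=1)
        c1 = pca_project(X)
        c2 = pca_project(doubled)
        ratio = pdist(c2.coords) / pdist(c1.coords)
        assert np.allclose(ratio, np.sqrt(2), rtol=1e-9)

    def test_rank_deficient_input_warns_with_zero_component(self):
        X = pd.DataFrame(np.outer([1.0, 2, 3, 4], [1.0, 1, 2]))
        with pytest.warns(UserWarning, match="rank"):
            conf = pca_project(X)
        assert np.allclose(conf.coords[:, 1], 0.0)

    def test_sign_convention_is_deterministic(self, rng):
        X = pd.DataFrame(rng.standard_normal((7, 4)))
        a = pca_project(X).coords
        b = pca_project(X.copy()).coords
        assert np.array_equal(a, b)

    def test_too_few_items_raise(self):
        with pytest.raises(ValueError):
            pca_project(pd.DataFrame(np.eye(2)))


class TestProcrustesM2:
    def test_self_comparison_is_zero(self, rng):
        X = rng.standard_normal((6, 2))
        assert procrustes_m2(X, X).m2 == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("theta,scale,shift", [(0.3, 2.0, 1.0), (2.5, 0.1, -4.0)])
    def test_similarity_transform_invariance(self, rng, theta, scale, shift):
        X = rng.standard_normal((5, 2))
        Y = scale * (X @ rotation(theta)) + shift
        assert procrustes_m2(X, Y).m2 == pytest.approx(0.0, abs=1e-10)

    def test_reflection_handled(self, rng):
        X = rng.standard_normal((6, 2))
        assert procrustes_m2(X, X @ np.diag([1.0, -1.0])).m2 == pytest.approx(
            0.0, abs=1e-10
        )

    def test_symmetric_in_arguments(self, rng):
        X, Y = rng.standard_normal((2, 6, 2))
        assert procrustes_m2(X, Y).m2 == pytest.approx(
            procrustes_m2(Y, X).m2, abs=1e-12
        )

    def test_bounded_unit_interval(self, rng):
        for _ in range(20):
            X, Y = rng.standard_normal((2, 5, 2))
            m2 = procrustes_m2(X, Y).m2
            assert 0.0 <= m2 <= 1.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 7))
            X, Y = rng.standard_normal((2, n, 2))
            assert procrustes_m2(X, Y).m2 == pytest.approx(
                brute_force_m2(X, Y), abs=1e-6
            )

    def test_perturbed_triangle_against_oracle(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        Y = X.copy()
        Y[2] += [0.3, -0.2]
        assert procrustes_m2(X, Y).m2 == pytest.approx(brute_force_m2(X, Y), abs=1e-6)

    @given(
        theta=st.floats(0.0, 2 * np.pi),
        scale=st.floats(1e-3, 1e3),
        shift=st.floats(-100.0, 100.0),
        reflect=st.booleans(),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_m2_invariant_under_any_similarity_transform(
        self, theta, scale, shift, reflect
    ):
        X = np.random.default_rng(7).standard_normal((6, 2))
        T = rotation(theta) @ (np.diag([1.0, -1.0]) if reflect else np.eye(2))
        Y = scale * (X @ T) + shift
        assert procrustes_m2(X, Y).m2 == pytest.approx(0.0, abs=1e-9)

    def test_item_mismatch_raises(self, rng):
        X = concordance.Configuration2D(["a", "b", "c"], rng.standard_normal((3, 2)), np.ones(2))
        Y = concordance.Configuration2D(["a", "c", "b"], rng.standard_normal((3, 2)), np.ones(2))
        with pytest.raises(ValueError):
            procrustes_m2(X, Y)


class TestProtest:
    def test_self_test_p_is_one_over_720(self, rng):
        X = rng.standard_normal((6, 2))
        res = protest(X, X, n_perm=719, seed=0)
        assert res.p_value == pytest.approx(1.0 / 720.0)
        assert res.n_perm == 719 and res.exhaustive

    def test_deterministic_under_enumeration(self, rng):
        X, Y = rng.standard_normal((2, 6, 2))
        assert protest(X, Y, seed=1).p_value == protest(X, Y, seed=99).p_value

    def test_p_value_within_bounds(self, rng):
        X, Y = rng.standard_normal((2, 5, 2))
        res = protest(X, Y)
        assert 1.0 / (res.n_perm + 1) <= res.p_value <= 1.0

    def test_sampling_path_for_large_configurations(self, rng):
        X, Y = rng.standard_normal((2, 12, 2))
        res = protest(X, Y, n_perm=99, seed=5)
        assert not res.exhaustive and res.n_perm == 99
        assert protest(X, Y, n_perm=99, seed=5).p_value == res.p_value

    def test_invalid_n_perm_raises(self, rng):
        X = rng.standard_normal((6, 2))
        with pytest.raises(ValueError):
            protest(X, X, n_perm=0)

    def test_null_p_values_roughly_uniform(self, rng):
        # coarse calibration check; the fine-grained one runs at acceptance
        ps = []
        for i in range(100):
            X, Y = rng.standard_normal((2, 6, 2))
            ps.append(protest(X, Y, seed=i).p_value)
        assert 0.0 <= np.mean(np.array(ps) <= 0.05) <= 0.12
        assert np.mean(ps) == pytest.approx(0.5, abs=0.1)


class TestPerCategoryConcordance:
    def test_zero_category_untestable_and_planted_category_wins(self, rng):
        hosts = [f"h{i}" for i in range(6)]
        perf_latent = rng.standard_normal((6, 2))
        perf = concordance.pca_project(
            pd.DataFrame(perf_latent @ rng.standard_normal((2, 8)), index=hosts)
        )
        # category T carries the performance latents, J is noise, S is zero
        mat = pd.DataFrame(
            np.hstack(
                [
                    perf_latent @ rng.standard_normal((2, 10)),
                    rng.standard_normal((6, 10)),
                    np.zeros((6, 3)),
                ]
            ),
            index=hosts,
            columns=[f"c{i}" for i in range(23)],
        )
        cats = pd.Series(["T"] * 10 + ["J"] * 10 + ["S"] * 3, index=mat.columns)
        table = per_category_concordance(mat, cats, perf, seed=0).set_index(
            "cog_category"
        )
        assert not table.loc["S", "testable"]
        assert table.loc["T", "p_value"] == table["p_value"].min()

    def test_identical_submatrices_identical_results(self, rng):
        hosts = [f"h{i}" for i in range(6)]
        block = rng.standard_normal((6, 5))
        mat = pd.DataFrame(
            np.hstack([block, block]),
            index=hosts,
            columns=[f"c{i}" for i in range(10)],
        )
        cats = pd.Series(["A"] * 5 + ["B"] * 5, index=mat.columns)
        perf = concordance.pca_project(pd.DataFrame(rng.standard_normal((6, 6)), index=hosts))
        table = per_category_concordance(mat, cats, perf, seed=3).set_index("cog_category")
        assert table.loc["A", "m2"] == pytest.approx(table.loc["B", "m2"], abs=1e-12)
        assert table.loc["A", "p_value"] == table.loc["B", "p_value"]
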