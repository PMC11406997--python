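"""Count pooling, TPM, size factors, NB Wald stage, log2FC matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact

from chassiskit import expression
from chassiskit.expression import (
    build_logfc_matrix,
    compute_tpm,
    deg_cog_distribution,
    deg_frequency_enrichment,
    nb_wald_test,
    pool_counts,
    size_factors,
)
from chassiskit.simulate import nb_counts
from test_pangenome import hypergeom_tail_enrichment


def _counts(rng, n_genes=50, n_samples=6):
    df = pd.DataFrame(
        rng.integers(0, 500, size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return df


class TestPoolCounts:
    @given(seed=st.integers(0, 2**16), n_clusters=st.integers(1, 20))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_pooling_conserves_totals_for_any_grouping(self, seed, n_clusters):
        rng = np.random.default_rng(seed)
        counts = _counts(rng, n_genes=30)
        cmap = pd.Series(
            rng.integers(0, n_clusters, 30).astype(str), index=counts.index
        )
        pooled = pool_counts(counts, cmap)
        assert (pooled.sum() == counts.sum()).all()

    def test_small_examples(self):
        counts = pd.DataFrame(
            {"s1": [10, 15, 7], "s2": [1, 2, 3]}, index=["a", "b", "c"]
        )
        cmap = pd.Series({"a": "c1", "b": "c1", "c": "c2"})
        pooled = pool_counts(counts, cmap)
        assert pooled.loc["c1", "s1"] == 25
        assert pooled.loc["c2", "s1"] == 7  # single-gene cluster passthrough

    def test_column_totals_conserved_exactly(self, rng):
        counts = _counts(rng)
        cmap = pd.Series(
            [f"c{i % 12}" for i in range(50)], index=counts.index
        )
        pooled = pool_counts(counts, cmap)
        assert (pooled.sum() == counts.sum()).all()
        assert (pooled.to_numpy() >= 0).all()

    def test_unmapped_gene_handling(self, rng):
        counts = _counts(rng, n_genes=5)
        cmap = pd.Series({"g0": "c1", "g1": "c1", "g2": "c2", "g3": "c2"})
        with pytest.raises(KeyError):
            pool_counts(counts, cmap)
        with pytest.warns(UserWarning):
            pooled = pool_counts(counts, cmap, on_unmapped="drop")
        assert (pooled.sum() == counts.iloc[:4].sum()).all()


class TestComputeTpm:
    def test_single_gene_takes_the_million(self):
        counts = pd.DataFrame({"s1": [33]}, index=["g"])
        tpm = compute_tpm(counts, pd.Series({"g": 500}))
        assert tpm.loc["g", "s1"] == pytest.approx(1e6)

    def test_length_normalization_ratio(self):
        counts = pd.DataFrame({"s1": [100, 100]}, index=["a", "b"])
        tpm = compute_tpm(counts, pd.Series({"a": 1000, "b": 2000}))
        assert tpm.loc["a", "s1"] == pytest.approx(2e6 / 3)
        assert tpm.loc["b", "s1"] == pytest.approx(1e6 / 3)

    def test_columns_sum_to_million(self, rng):
        counts = _counts(rng)
        lengths = pd.Series(rng.integers(200, 3000, 50), index=counts.index)
        tpm = compute_tpm(counts, lengths)
        assert np.allclose(tpm.sum(), 1e6, rtol=1e-9)

    def test_zero_length_raises_and_zero_sample_flagged(self, rng):
        counts = _counts(rng, n_genes=4)
        with pytest.raises(ValueError):
            compute_tpm(counts, pd.Series(0, index=counts.index))
        counts["s_empty"] = 0
        with pytest.warns(UserWarning):
            tpm = compute_tpm(counts, pd.Series(1000, index=counts.index))
        assert tpm["s_empty"].isna().all()


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 20, 5], "s2": [10, 20, 5]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_sample_gets_double_factor(self):
        base = np.array([10, 50, 100, 200])
        counts = pd.DataFrame({"s1": base, "s2": base, "s3": 2 * base})
        sf = size_factors(counts)
        assert sf["s3"] / sf["s1"] == pytest.approx(2.0)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)

    def test_single_cluster_ratio(self):
        counts = pd.DataFrame({"s1": [100], "s2": [400]})
        sf = size_factors(counts)
        assert sf["s2"] / sf["s1"] == pytest.approx(4.0)

    def test_fallback_to_library_size(self):
        counts = pd.DataFrame({"s1": [10, 0], "s2": [0, 30]})
        with pytest.warns(UserWarning):
            sf = size_factors(counts)
        assert sf["s2"] / sf["s1"] == pytest.approx(3.0)


def _two_group_counts(rng, n_clusters=300, mean=100.0, disp=0.1, lfc=None):
    lfc = np.zeros(n_clusters) if lfc is None else lfc
    mu_a = mean * 2.0 ** (lfc / 2)
    mu_b = mean * 2.0 ** (-lfc / 2)
    counts = np.hstack(
        [
            nb_counts(rng, np.repeat(mu_a[:, None], 3, 1), disp),
            nb_counts(rng, np.repeat(mu_b[:, None], 3, 1), disp),
        ]
    )
    df = pd.DataFrame(
        counts,
        index=[f"c{i}" for i in range(n_clusters)],
        columns=[f"s{j}" for j in range(6)],
    )
    cond = pd.Series(["Ara"] * 3 + ["aTc"] * 3, index=df.columns)
    return df, cond


class TestNbWaldTest:
    def test_all_zero_clusters_excluded_from_family(self, rng):
        df, cond = _two_group_counts(rng, n_clusters=20)
        df.iloc[3] = 0
        res = nb_wald_test(df, cond)
        assert "c3" not in res.index
        assert len(res) == 19

    def test_result_invariants(self, rng):
        df, cond = _two_group_counts(rng)
        res = nb_wald_test(df, cond)
        assert (res["p_adj"] >= res["p_value"] - 1e-15).all()
        assert (res["significant"] == (res["p_adj"] < 0.05)).all()
        # BH is monotone: p ordering preserved in adjusted ranks
        order = res.sort_values("p_value")
        assert order["p_adj"].is_monotonic_increasing

    def test_log2fc_sign_matches_group_means(self, rng):
        lfc = np.zeros(30)
        lfc[0], lfc[1] = 4.0, -4.0
        df, cond = _two_group_counts(rng, n_clusters=30, lfc=lfc)
        res = nb_wald_test(df, cond)
        assert res.loc["c0", "log2fc"] > 0 > res.loc["c1", "log2fc"]

    def test_single_condition_rejected(self, rng):
        df, _ = _two_group_counts(rng, n_clusters=10)
        cond = pd.Series(["Ara"] * 6, index=df.columns)
        with pytest.raises(ValueError):
            nb_wald_test(df, cond)

    def test_one_sided_expression_gets_finite_estimate(self, rng):
        df, cond = _two_group_counts(rng, n_clusters=10)
        df.loc["c0", ["s3", "s4", "s5"]] = 0  # expressed under Ara only
        res = nb_wald_test(df, cond)
        assert np.isfinite(res.loc["c0", "log2fc"])


class TestLogfcMatrix:
    @pytest.fixture()
    def hand_fixture(self):
        groups = pd.DataFrame(
            {
                "bin": [6, 6, 3, 1],
                "group": ["core", "core", "accessory", "accessory"],
                "is_unique": [False, False, False, True],
            },
            index=["c1", "c2", "c3", "c4"],
        )

        def de(sig, lfc):
            return pd.DataFrame(
                {
                    "log2fc": lfc,
                    "significant": sig,
                    "p_adj": [0.01 if s else 0.5 for s in sig],
                },
                index=["c1", "c2", "c3", "c4"],
            )

        results = {
            "h1": de([True, False, True, True], [2.0, 1.0, -1.5, 3.0]),
            "h2": de([False, False, False, False], [0.5, 0.2, 0.1, 0.3]),
            "h3": de([True, True, False, False], [-1.0, 2.5, 0.8, 0.1]),
        }
        return results, groups

    def test_masking_matches_hand_construction(self, hand_fixture):
        results, groups = hand_fixture
        mat = build_logfc_matrix(results, groups, scope="all")
        assert mat.loc["h1", "c1"] == 2.0
        assert mat.loc["h2"].eq(0).all()  # no significant clusters
        assert mat.loc["h3", "c2"] == 2.5
        assert "c2" in mat.columns and mat.loc["h1", "c2"] == 0.0

    def test_accessory_scope_drops_unique_clusters(self, hand_fixture):
        results, groups = hand_fixture
        mat = build_logfc_matrix(results, groups, scope="accessory")
        assert "c4" not in mat.columns  # unique cluster omitted
        assert list(mat.columns) == ["c3"]

    def test_core_scope(self, hand_fixture):
        results, groups = hand_fixture
        mat = build_logfc_matrix(results, groups, scope="core")
        assert set(mat.columns) <= {"c1", "c2"}

    def test_empty_scope_raises(self, hand_fixture):
        results, groups = hand_fixture
        for host in results.values():
            host["significant"] = False
        with pytest.raises(ValueError):
            build_logfc_matrix(results, groups, scope="core")


class TestDegEnrichment:
    def test_background_composition_equal_gives_p_one(self):
        groups = pd.DataFrame(
            {
                "bin": [6] * 4 + [1] * 4,
                "group": ["core"] * 4 + ["accessory"] * 4,
                "is_unique": [False] * 4 + [True] * 4,
            },
            index=[f"c{i}" for i in range(8)],
        )
        de = pd.DataFrame(
            {
                "log2fc": [1.0] * 8,
                "significant": [True, True, False, False] * 2,
                "p_adj": [0.01, 0.01, 0.5, 0.5] * 2,
            },
            index=groups.index,
        )
        res = deg_frequency_enrichment({"h1": de}, groups)
        core = res[res["group"] == "core"].iloc[0]
        # DEG composition mirrors the background: odds ratio 1, nothing
        # significant in either direction, and the one-sided tests overlap
        assert core["odds_ratio"] == pytest.approx(1.0)
        assert min(core["p_enrich"], core["p_deplete"]) > 0.5
        assert core["p_enrich"] + core["p_deplete"] >= 1.0

    def test_hand_table_matches_enumeration(self):
        _, p = fisher_exact([[40, 60], [100, 300]], alternative="greater")
        assert p == pytest.approx(hypergeom_tail_enrichment(40, 60, 100, 300), rel=1e-12)


class TestDegCogDistribution:
    def test_counts_by_direction(self):
        groups = pd.DataFrame(
            {
                "bin": [6, 6, 1],
                "group": ["core", "core", "accessory"],
                "is_unique": [False, False, True],
            },
            index=["c1", "c2", "c3"],
        )
        de = pd.DataFrame(
            {
                "log2fc": [2.0, -1.0, 0.5],
                "significant": [True, True, False],
                "p_adj": [0.01, 0.01, 0.9],
            },
            index=groups.index,
        )
        cog = pd.Series({"c1": "T", "c2": "T", "c3": "J"})
        out = deg_cog_distribution({"h1": de}, cog, groups)
        row = out[(out["cog_category"] == "T")].iloc[0]
        assert row["up"] == 1 and row["down"] == 1
        assert (out.groupby("cog_category")[["up", "down"]].sum().sum().sum()) == 2

    def test_no_degs_gives_empty_table(self):
        groups = pd.DataFrame(
            {"bin": [6], "group": ["core"], "is_unique": [False]}, index=["c1"]
        )
        de = pd.DataFrame(
            {"log2fc": [1.0], "significant": [False], "p_adj": [0.9]}, index=["c1"]
        )
        out = deg_cog_distribution({"h1": de}, pd.Series({"c1": "T"}), groups)
        assert out[["up", "down"]].to_numpy().sum() == 0
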