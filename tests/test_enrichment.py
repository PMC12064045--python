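"""Normalization, dispersion, NB Wald testing, BH, and sample PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mirmodule.enrichment import (
    AgoEnrichment,
    EnrichmentConfig,
    SampleCountTable,
    bh_adjust,
    compute_size_factors,
    estimate_dispersion,
    pca_samples,
    relative_to_mean,
    select_enriched,
    test_differential,
    to_cpm,
)
from mirmodule.simulate import simulate_counts


def small_table(values, conditions=None):
    df = pd.DataFrame(values)
    df.index = [f"m{i}" for i in range(df.shape[0])]
    df.columns = [f"s{j}" for j in range(df.shape[1])]
    conditions = conditions or {c: "a" for c in df.columns}
    return SampleCountTable(df, conditions)


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        t = small_table({"s0": [5, 10, 20], "s1": [5, 10, 20]})
        np.testing.assert_allclose(compute_size_factors(t), [1.0, 1.0])

    def test_doubled_sample_gets_sqrt2_factors(self):
        a = np.array([10, 40, 100, 7])
        t = small_table(np.column_stack([a, 2 * a]))
        np.testing.assert_allclose(
            compute_size_factors(t), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    def test_scaling_one_sample_scales_factor_ratio(self):
        rng = np.random.default_rng(0)
        a = rng.integers(1, 1000, size=(50, 3))
        t1 = small_table(a)
        scaled = a.astype(float).copy()
        scaled[:, 2] *= 5
        t2 = small_table(scaled)
        f1, f2 = compute_size_factors(t1), compute_size_factors(t2)
        assert f2.iloc[2] / f2.iloc[0] == pytest.approx(5 * f1.iloc[2] / f1.iloc[0])

    def test_all_zero_sample_names_the_sample(self):
        with pytest.raises(ValueError, match="s1"):
            compute_size_factors(small_table({"s0": [5, 3], "s1": [0, 0]}))


class TestCpmAndScaling:
    def test_cpm_columns_sum_to_1e6(self):
        t = small_table({"s0": [5, 5], "s1": [7, 0]})
        cpm = to_cpm(t)
        np.testing.assert_allclose(cpm.sum(axis=0), [1e6, 1e6])
        np.testing.assert_allclose(cpm["s0"], [5e5, 5e5])
        np.testing.assert_allclose(cpm["s1"], [1e6, 0.0])

    def test_zero_total_sample_rejected(self):
        df = pd.DataFrame({"s0": [1], "s1": [0]}, index=["m0"])
        with pytest.raises(ValueError, match="s1"):
            to_cpm(df)

    def test_relative_to_mean_rows_have_unit_mean(self):
        df = pd.DataFrame(
            {"s0": [2.0, 3.0], "s1": [4.0, 3.0], "s2": [6.0, 3.0]}, index=["a", "b"]
        )
        out = relative_to_mean(df)
        np.testing.assert_allclose(out.loc["a"], [0.5, 1.0, 1.5])
        np.testing.assert_allclose(out.loc["b"], [1.0, 1.0, 1.0])
        np.testing.assert_allclose(out.mean(axis=1), 1.0)

    def test_relative_to_mean_drops_zero_rows_with_warning(self):
        df = pd.DataFrame({"s0": [0.0, 1.0], "s1": [0.0, 3.0]}, index=["z", "a"])
        with pytest.warns(UserWarning, match="zero"):
            out = relative_to_mean(df)
        assert list(out.index) == ["a"]


class TestDispersion:
    def test_poisson_counts_give_near_zero_dispersion(self):
        table, _ = simulate_counts(
            n_mirnas=200, conditions=("a", "b"), replicates=3, planted={},
            dispersion=0.0, base_mean_log=(np.log(500), 0.5),
            library_size_sigma=0.0, seed=5,
        )
        alpha = estimate_dispersion(table, ("a", "b"))
        assert float(alpha.median()) < 0.05

    def test_nb_dispersion_recovered(self):
        table, _ = simulate_counts(
            n_mirnas=300, conditions=("a",), replicates=6, planted={},
            dispersion=0.2, base_mean_log=(np.log(1000), 0.0),
            library_size_sigma=0.0, seed=7,
        )
        alpha = estimate_dispersion(table, ("a",))
        assert 0.1 <= float(alpha.median()) <= 0.3

    def test_constant_replicates_give_zero_dispersion(self):
        t = small_table(np.tile([[100], [50], [10]], (1, 4)))
        alpha = estimate_dispersion(t, ("a",))
        np.testing.assert_allclose(alpha, 0.0, atol=1e-12)

    def test_single_replicate_everywhere_errors(self):
        t = small_table({"s0": [5, 3]}, conditions={"s0": "a"})
        with pytest.raises(ValueError, match="replicates"):
            estimate_dispersion(t, ("a",))


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=2, max_size=30)
    )
    @settings(derandomize=True, max_examples=100)
    def test_monotone_in_input_pvalues(self, pvals):
        padj = bh_adjust(pvals)
        assert np.all((padj >= np.asarray(pvals) - 1e-12) & (padj <= 1 + 1e-12))
        order = np.argsort(pvals)
        assert np.all(np.diff(padj[order]) >= -1e-12)


class TestDifferential:
    def test_equal_group_means_give_zero_log2fc(self):
        values = np.tile([[100], [40]], (1, 6))
        t = small_table(values, conditions={f"s{j}": ("a" if j < 3 else "b") for j in range(6)})
        rec = test_differential(t, "a", "b")
        np.testing.assert_allclose(rec["log2fc"], 0.0, atol=1e-12)

    def test_null_pvalues_approximately_uniform(self):
        table, _ = simulate_counts(
            n_mirnas=500, conditions=("a", "b"), replicates=3, planted={},
            dispersion=0.05, seed=11,
        )
        rec = test_differential(table, "a", "b")
        ks = stats.kstest(rec["pvalue"], "uniform").statistic
        assert ks < 0.1

    def test_power_on_planted_fourfold_change(self):
        planted = {f"miR-sim-{i + 1:03d}": 2.0 for i in range(50)}
        table, _ = simulate_counts(
            n_mirnas=300, conditions=("a", "b"), replicates=3, planted=planted,
            planted_base_range=(2000.0, 2000.0), dispersion=0.05,
            focal_condition="a", seed=42,
        )
        rec = test_differential(table, "a", "b")
        sensitivity = float((rec.loc[list(planted), "padj"] < 0.05).mean())
        assert sensitivity >= 0.95

    def test_fdr_calibration_under_complete_null(self):
        fractions = []
        for rep in range(200):
            table, _ = simulate_counts(
                n_mirnas=300, conditions=("a", "b"), replicates=3, planted={},
                dispersion=0.05, seed=1000 + rep,
            )
            rec = test_differential(table, "a", "b")
            fractions.append(float((rec["padj"] < 0.05).mean()))
        fractions = np.asarray(fractions)
        mc_error = fractions.std(ddof=1) / np.sqrt(len(fractions))
        assert fractions.mean() <= 0.05 + 2 * mc_error

    def test_requires_two_replicates_per_condition(self):
        t = small_table(
            {"s0": [5], "s1": [5], "s2": [5]},
            conditions={"s0": "a", "s1": "a", "s2": "b"},
        )
        with pytest.raises(ValueError, match="replicates"):
            test_differential(t, "a", "b")


class TestSelectEnriched:
    @staticmethod
    def _records(padj, log2fc):
        return pd.DataFrame({"padj": padj, "log2fc": log2fc}, index=["m0"])

    @staticmethod
    def _table(focal_count, total=100000):
        # one miRNA of interest plus filler so cpm is controlled
        df = pd.DataFrame(
            {
                "n1": [focal_count, total - focal_count],
                "n2": [focal_count, total - focal_count],
                "e1": [10, total - 10],
                "e2": [10, total - 10],
            },
            index=["m0", "filler"],
        )
        return SampleCountTable(df, {"n1": "nab", "n2": "nab", "e1": "elav", "e2": "elav"})

    def test_passing_record_is_kept(self):
        # 1500 cpm in nab: 150 counts out of 100000
        table = self._table(150)
        kept = select_enriched(self._records([0.04], [2.0]), table, "nab")
        assert kept == ["m0"]

    def test_low_abundance_record_dropped_by_cpm_filter(self):
        table = self._table(80)  # 800 cpm < 1000
        kept = select_enriched(self._records([0.04], [2.0]), table, "nab")
        assert kept == []

    def test_non_significant_record_dropped(self):
        table = self._table(500)  # 5000 cpm
        kept = select_enriched(self._records([0.06], [2.0]), table, "nab")
        assert kept == []

    def test_wrong_sign_dropped(self):
        table = self._table(150)
        kept = select_enriched(self._records([0.01], [-2.0]), table, "nab")
        assert kept == []

    def test_invariant_to_row_and_column_order(self):
        table, _ = simulate_counts(
            n_mirnas=100, conditions=("nab", "elav"), replicates=3,
            n_planted=8, seed=3,
        )
        rec = test_differential(table, "nab", "elav")
        base = select_enriched(rec, table, "nab")
        rng = np.random.default_rng(0)
        shuffled = SampleCountTable(
            table.counts.sample(frac=1, random_state=1)[
                list(rng.permutation(table.counts.columns))
            ],
            table.conditions,
        )
        rec2 = test_differential(shuffled, "nab", "elav")
        assert sorted(select_enriched(rec2, shuffled, "nab")) == sorted(base)


class TestPCA:
    def test_duplicate_samples_share_coordinates(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 500, size=(30, 1))
        df = pd.DataFrame(
            np.column_stack([x, x, rng.integers(0, 500, size=(30, 1))]),
            columns=["a", "b", "c"],
        ).astype(float)
        coords, _ = pca_samples(df, 2)
        np.testing.assert_allclose(coords.loc["a"], coords.loc["b"], atol=1e-8)

    def test_coordinates_have_zero_mean(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.integers(0, 1000, size=(40, 6)).astype(float))
        coords, frac = pca_samples(df, 3)
        np.testing.assert_allclose(coords.mean(axis=0), 0.0, atol=1e-8)
        assert frac.sum() <= 1.0 + 1e-12

    def test_agreement_with_sklearn_oracle(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.integers(0, 1000, size=(20, 6)).astype(float))
        coords, frac = pca_samples(df, 3)
        x = np.log2(df.to_numpy().T + 1.0)
        ref = PCA(n_components=3).fit(x)
        expected = ref.transform(x)
        for k in range(3):
            dots = coords.iloc[:, k].to_numpy() @ expected[:, k]
            np.testing.assert_allclose(
                np.abs(coords.iloc[:, k]), np.abs(expected[:, k]), atol=1e-8
            )
            assert abs(abs(dots) - (expected[:, k] ** 2).sum()) < 1e-6
        np.testing.assert_allclose(frac, ref.explained_variance_ratio_, atol=1e-8)

    def test_too_many_components_rejected(self):
        df = pd.DataFrame(np.ones((5, 3)))
        with pytest.raises(ValueError):
            pca_samples(df, 4)


class TestModelResults:
    def test_fit_reports_and_summary(self):
        table, truth = simulate_counts(
            n_mirnas=150, conditions=("nab", "elav"), replicates=3,
            n_planted=10, seed=21,
        )
        res = AgoEnrichment(table, "nab", "elav").fit()
        assert {"log2fc", "pvalue", "padj"} <= set(res.records.columns)
        assert (res.records["padj"] >= res.records["pvalue"] - 1e-12).all()
        enriched = res.select_enriched("up")
        planted = set(truth.planted_mirnas)
        assert len(planted & set(enriched)) >= 9
        text = res.summary()
        assert "nab vs elav" in text and "padj" in text

    def test_unknown_condition_rejected(self):
        table, _ = simulate_counts(n_mirnas=20, conditions=("a", "b"), replicates=2, planted={}, seed=0)
        with pytest.raises(ValueError, match="glia"):
            AgoEnrichment(table, "glia", "b")
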