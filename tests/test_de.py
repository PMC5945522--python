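"""Size factors, dispersion, the NB Wald test and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from mirpanel.counts import CohortMetadata, CountMatrix
from mirpanel.de import (
    NormalizationError,
    SizeFactors,
    bh_adjust,
    estimate_dispersion,
    nb_wald_test,
    size_factors,
)
from mirpanel.simulate import SimulationConfig, generate_counts

from conftest import make_counts, make_metadata


class TestSizeFactors:
    def test_hand_computed_median_of_ratios(self):
        m = make_counts([[10, 20], [30, 60]])
        sf = size_factors(m).values.to_numpy()
        assert sf == pytest.approx([1 / np.sqrt(2), np.sqrt(2)], rel=1e-9)

    def test_identical_samples_give_unit_factors(self):
        m = make_counts([[5, 5], [100, 100], [7, 7]])
        assert size_factors(m).values.to_numpy() == pytest.approx([1.0, 1.0])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        # odd row count: the median picks one ratio, so the real-space and
        # log-space formulations agree exactly
        arr = rng.integers(1, 500, size=(41, 6))
        sf = size_factors(make_counts(arr)).values.to_numpy()
        # brute force: per-sample median of count/geomean over all-positive rows
        geo = np.exp(np.mean(np.log(arr), axis=1))
        raw = np.median(arr / geo[:, None], axis=0)
        expected = raw / np.exp(np.mean(np.log(raw)))
        assert sf == pytest.approx(expected, rel=1e-12)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(12)
        sf = size_factors(make_counts(rng.integers(1, 99, (30, 9))))
        assert np.mean(np.log(sf.values)) == pytest.approx(0.0, abs=1e-12)

    def test_no_all_positive_row_is_an_error(self):
        with pytest.raises(NormalizationError, match="pseudo-reference"):
            size_factors(make_counts([[0, 5], [5, 0]]))


class TestDispersion:
    @staticmethod
    def _unit_sf(m):
        return SizeFactors(pd.Series(1.0, index=m.sample_ids))

    def test_poisson_data_estimates_near_zero(self):
        rng = np.random.default_rng(1)
        arr = rng.poisson(500, size=(300, 100))
        m = make_counts(arr)
        groups = ["a"] * 50 + ["b"] * 50
        alpha = estimate_dispersion(m, groups, self._unit_sf(m))
        assert alpha.median() < 0.05

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(2)
        mu, a = 500.0, 0.2
        arr = rng.negative_binomial(1 / a, (1 / a) / (1 / a + mu), size=(300, 100))
        m = make_counts(arr)
        alpha = estimate_dispersion(m, ["a"] * 50 + ["b"] * 50, self._unit_sf(m))
        assert 0.1 < alpha.median() < 0.3

    def test_constant_within_groups_moment_estimate_zero(self):
        arr = np.tile(np.array([[10] * 4 + [40] * 4]), (12, 1))
        m = make_counts(arr)
        alpha = estimate_dispersion(
            m, ["a"] * 4 + ["b"] * 4, self._unit_sf(m), trend_weight=0.0
        )
        assert (alpha <= 1e-8).all()

    def test_few_mirnas_warns_and_uses_global_mean(self):
        rng = np.random.default_rng(3)
        m = make_counts(rng.poisson(100, size=(5, 20)))
        with pytest.warns(UserWarning, match="fewer than 10"):
            estimate_dispersion(m, ["a"] * 10 + ["b"] * 10, self._unit_sf(m))


class TestBHAdjust:
    def test_hand_applied_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_value_unchanged(self):
        assert bh_adjust([0.5]) == pytest.approx([0.5])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_adjust([0.2, 1.4])

    def test_nan_entries_excluded_from_family(self):
        adj = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(adj[1])
        assert adj[0] == pytest.approx(0.02)  # m = 2, not 3

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12)
    )
    def test_matches_step_up_definition_oracle(self, pvals):
        # brute force: adj_(k) = min_{j >= k} m p_(j) / j, capped at 1
        p = np.asarray(pvals)
        order = np.argsort(p, kind="mergesort")
        m = len(p)
        expected = np.empty(m)
        for pos, idx in enumerate(order):
            candidates = [
                m * p[order[j]] / (j + 1) for j in range(pos, m)
            ]
            expected[idx] = min(1.0, min(candidates))
        assert bh_adjust(p) == pytest.approx(expected, rel=1e-12)

    def test_agrees_with_statsmodels(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=200)
        from statsmodels.stats.multitest import multipletests

        expected = multipletests(p, method="fdr_bh")[1]
        assert bh_adjust(p) == pytest.approx(expected, rel=1e-12)


class TestNBWald:
    def test_planted_effect_recovered_at_high_abundance(self):
        # effect magnitude and abundance chosen like a strongly expressed
        # down-regulated miRNA (log2FC -1.8 at mean ~19000 reads)
        cfg = SimulationConfig(
            n_per_class={"control": 50, "MIBC": 50},
            n_mirna=200,
            baseline_log2_mean_range=(8, 15),
            planted_de=[("miR-target", "MIBC", -1.8)],
            seed=42,
        )
        cm, meta = generate_counts(cfg)
        res = nb_wald_test(cm, meta, "MIBC")
        row = res.loc["miR-target"]
        assert row["log2FC"] == pytest.approx(-1.8, abs=0.2)
        assert row["fdr"] <= 0.05
        assert res["p"].between(0, 1).all()
        assert (res["fdr"] >= res["p"] - 1e-12).all()

    def test_matches_statsmodels_nb_glm(self, small_cohort):
        _, cm, meta = small_cohort
        res = nb_wald_test(cm, meta, "MIBC")
        sf = size_factors(cm)
        s = sf.reindex(cm.sample_ids)
        y01 = (meta.classes == "MIBC").to_numpy(float)
        x = np.column_stack([np.ones(len(y01)), y01])
        for mid in ["miR-up", "miR-down", "miR-sim-0005"]:
            fit = sm.GLM(
                cm.row(mid).astype(float),
                x,
                family=sm.families.NegativeBinomial(
                    alpha=float(res.loc[mid, "dispersion"])
                ),
                offset=np.log(s),
            ).fit()
            assert res.loc[mid, "log2FC"] == pytest.approx(
                fit.params[1] / np.log(2), abs=1e-5
            )
            se_log2 = fit.bse[1] / np.log(2)
            wald = fit.params[1] / fit.bse[1]
            assert res.loc[mid, "wald_stat"] == pytest.approx(wald, rel=1e-4)

    def test_sample_permutation_invariance(self, small_cohort):
        _, cm, meta = small_cohort
        res = nb_wald_test(cm, meta, "MIBC")
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(cm.sample_ids))
        res_p = nb_wald_test(cm.subset_samples(perm), meta, "MIBC")
        pd.testing.assert_frame_equal(res, res_p, atol=1e-9, rtol=1e-7)

    def test_doubling_one_sample_only_moves_its_size_factor(self):
        # noiseless multiplicative construction: counts = g_i * 2^(group_j)
        g = np.array([10, 20, 40, 80, 160, 320, 640, 1280, 2560, 5120])
        groups = np.array([0, 0, 0, 1, 1, 1])
        arr = g[:, None] * (2 ** groups)[None, :]
        doubled = arr.copy()
        doubled[:, 0] *= 2
        meta = make_metadata(np.where(groups, "MIBC", "control"))
        res_a = nb_wald_test(make_counts(arr), meta, "MIBC")
        res_b = nb_wald_test(make_counts(doubled), meta, "MIBC")
        assert res_b["log2FC"].to_numpy() == pytest.approx(
            res_a["log2FC"].to_numpy(), abs=1e-6
        )
        sf_a = size_factors(make_counts(arr)).values
        sf_b = size_factors(make_counts(doubled)).values
        assert sf_b.iloc[0] / sf_a.iloc[0] == pytest.approx(
            2 * sf_b.iloc[1] / sf_a.iloc[1], rel=1e-9
        )

    def test_all_zero_mirna_flagged_and_excluded(self):
        rng = np.random.default_rng(5)
        arr = rng.poisson(100, (20, 12))
        arr[3] = 0
        meta = make_metadata(["control"] * 6 + ["MIBC"] * 6)
        with pytest.warns(UserWarning, match="excluded"):
            res = nb_wald_test(make_counts(arr), meta, "MIBC")
        assert not res.loc["miR-3", "converged"]
        assert np.isnan(res.loc["miR-3", "p"])
        assert np.isnan(res.loc["miR-3", "fdr"])

    def test_agrees_with_pydeseq2_on_planted_effects(self):
        # DESeq2 (via pydeseq2) is the reference NB Wald implementation;
        # fold-change estimates should agree closely on well-powered data
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        cfg = SimulationConfig(
            n_per_class={"control": 40, "MIBC": 40},
            n_mirna=60,
            baseline_log2_mean_range=(8, 12),
            planted_de=[("miR-up", "MIBC", 2.0), ("miR-down", "MIBC", -1.5)],
            seed=7,
        )
        cm, meta = generate_counts(cfg)
        res = nb_wald_test(cm, meta, "MIBC")

        adata_counts = pd.DataFrame(
            cm.counts.T, index=cm.sample_ids, columns=cm.mirna_ids
        )
        clinical = pd.DataFrame(
            {"condition": meta.classes.to_numpy()}, index=cm.sample_ids
        )
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            dds = DeseqDataSet(
                counts=adata_counts, metadata=clinical, design="~condition", quiet=True
            )
            dds.deseq2()
            stats = DeseqStats(
                dds, contrast=["condition", "MIBC", "control"], quiet=True
            )
            stats.summary()
        ds = stats.results_df
        for mid in ["miR-up", "miR-down"]:
            assert res.loc[mid, "log2FC"] == pytest.approx(
                ds.loc[mid, "log2FoldChange"], abs=0.3
            )
            assert ds.loc[mid, "padj"] < 0.05 and res.loc[mid, "fdr"] < 0.05
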