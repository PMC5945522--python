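"""ΔCt normalization, ΔΔCt fold changes, association and trend tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirpanel.qpcr import (
    CtMatrix,
    association_test,
    delta_ct,
    log2_fold_change,
    read_ct,
    trend_test,
)
from mirpanel.simulate import SimulationConfig, generate_counts, generate_ct, write_ct

from conftest import make_metadata


def _ct_matrix(values: dict, controls, index=None):
    df = pd.DataFrame(values, index=index or [f"S{i:03d}" for i in range(
        len(next(iter(values.values()))))])
    return CtMatrix(df, controls=controls)


class TestDeltaCt:
    def test_hand_arithmetic(self):
        ct = _ct_matrix(
            {"target": [25.0], "c1": [20.0], "c2": [22.0]}, controls=["c1", "c2"]
        )
        d = delta_ct(ct)
        assert d.values.loc["S000", "target"] == pytest.approx(4.0)

    def test_target_equal_to_single_control_gives_zero(self):
        ct = _ct_matrix({"target": [30.0], "c1": [30.0]}, controls=["c1"])
        assert delta_ct(ct).values.iloc[0, 0] == 0.0

    def test_matches_per_sample_oracle_loop(self):
        rng = np.random.default_rng(0)
        raw = 20 + rng.uniform(0, 10, size=(15, 4))
        df = pd.DataFrame(raw, columns=["a", "b", "c1", "c2"],
                          index=[f"S{i}" for i in range(15)])
        d = delta_ct(CtMatrix(df, controls=["c1", "c2"])).values
        for s in df.index:
            ref = (df.loc[s, "c1"] + df.loc[s, "c2"]) / 2
            for assay in ("a", "b"):
                assert d.loc[s, assay] == pytest.approx(df.loc[s, assay] - ref)

    def test_missing_control_excludes_sample_with_warning(self):
        df = pd.DataFrame(
            {"t": [25.0, 26.0], "c1": [20.0, np.nan]}, index=["s1", "s2"]
        )
        ct = CtMatrix(df, controls=["c1"])
        with pytest.warns(UserWarning, match="excluded"):
            d = delta_ct(ct)
        assert d.excluded_samples == ["s2"]
        assert list(d.values.index) == ["s1"]

    def test_per_sample_offset_invariance(self):
        # adding any constant to all of one sample's Ct values cancels in ΔCt
        rng = np.random.default_rng(1)
        raw = 22 + rng.uniform(0, 8, size=(10, 3))
        df = pd.DataFrame(raw, columns=["t", "c1", "c2"],
                          index=[f"S{i}" for i in range(10)])
        shifted = df.add(rng.uniform(-3, 3, size=10), axis=0)
        d0 = delta_ct(CtMatrix(df, controls=["c1", "c2"])).values
        d1 = delta_ct(CtMatrix(shifted, controls=["c1", "c2"])).values
        assert np.allclose(d0.to_numpy(), d1.to_numpy())

    def test_out_of_range_ct_rejected(self):
        with pytest.raises(ValueError, match="within"):
            _ct_matrix({"t": [50.0], "c1": [20.0]}, controls=["c1"])

    def test_long_tsv_roundtrip(self, tmp_path):
        cfg = SimulationConfig(
            n_per_class={"control": 4, "MIBC": 4},
            n_mirna=10,
            planted_de=[("miR-x", "MIBC", 1.5)],
            planted_stable=["hk"],
            seed=3,
        )
        cm, meta = generate_counts(cfg)
        ct = generate_ct(cfg, cm, meta, ["miR-x"], ["hk"])
        path = tmp_path / "ct.tsv"
        write_ct(ct, path)
        again = read_ct(path, controls=["hk"], spike_in="UniSp6")
        assert np.allclose(again.data[ct.columns].to_numpy(), ct.to_numpy())


class TestLog2FoldChange:
    def test_sign_convention_up_regulation(self):
        meta = make_metadata(["MIBC", "MIBC", "control", "control"])
        d = pd.DataFrame({"t": [3.0, 3.0, 5.0, 5.0]}, index=meta.sample_ids)
        lfc = log2_fold_change(d, meta, "MIBC")
        assert lfc["t"] == pytest.approx(2.0)  # ΔΔCt = -2 -> log2FC = +2

    def test_identical_groups_give_zero(self):
        meta = make_metadata(["MIBC", "control"])
        d = pd.DataFrame({"t": [4.0, 4.0]}, index=meta.sample_ids)
        assert log2_fold_change(d, meta, "MIBC")["t"] == 0.0

    def test_planted_effect_recovered(self):
        cfg = SimulationConfig(
            n_per_class={"control": 50, "MIBC": 50},
            n_mirna=12,
            planted_de=[("miR-x", "MIBC", 2.0)],
            planted_stable=["hk1", "hk2"],
            ct_noise_sd=0.5,
            seed=9,
        )
        cm, meta = generate_counts(cfg)
        ct = generate_ct(cfg, cm, meta, ["miR-x"], ["hk1", "hk2"])
        d = delta_ct(CtMatrix(ct, controls=["hk1", "hk2"], spike_in="UniSp6"))
        lfc = log2_fold_change(d, meta, "MIBC")
        assert lfc["miR-x"] == pytest.approx(2.0, abs=0.2)

    def test_empty_group_rejected(self):
        meta = make_metadata(["control", "control"])
        d = pd.DataFrame({"t": [4.0, 5.0]}, index=meta.sample_ids)
        with pytest.raises(ValueError, match="need both"):
            log2_fold_change(d, meta, "MIBC")


class TestAssociation:
    def test_strong_effect_is_significant_and_directional(self):
        cfg = SimulationConfig(
            n_per_class={"control": 50, "MIBC": 50},
            n_mirna=12,
            planted_de=[("miR-x", "MIBC", 3.0)],
            planted_stable=["hk1", "hk2"],
            ct_noise_sd=0.5,
            seed=12,
        )
        cm, meta = generate_counts(cfg)
        ct = generate_ct(cfg, cm, meta, ["miR-x"], ["hk1", "hk2"])
        d = delta_ct(CtMatrix(ct, controls=["hk1", "hk2"], spike_in="UniSp6"))
        res = association_test(d, meta, "MIBC")
        assert res.loc["miR-x", "p"] < 1e-3
        assert res.loc["miR-x", "coef"] > 0  # up-regulated -> positive log-odds

    def test_constant_assay_reports_missing_p(self):
        meta = make_metadata(["control"] * 10 + ["MIBC"] * 10)
        d = pd.DataFrame({"flat": np.zeros(20)}, index=meta.sample_ids)
        res = association_test(d, meta, "MIBC")
        assert np.isnan(res.loc["flat", "p"])

    def test_separation_falls_back_to_firth(self):
        meta = make_metadata(["control"] * 8 + ["MIBC"] * 8)
        d = pd.DataFrame(
            {"sep": np.r_[np.linspace(8, 9, 8), np.linspace(2, 3, 8)]},
            index=meta.sample_ids,
        )
        res = association_test(d, meta, "MIBC")
        assert bool(res.loc["sep", "firth"])
        assert np.isfinite(res.loc["sep", "p"])

    def test_null_assay_rejection_near_nominal(self):
        # class-independent ΔCt: the adjusted Wald test keeps its size
        rng = np.random.default_rng(42)
        meta = make_metadata(["control"] * 30 + ["MIBC"] * 30, seed=42)
        rejections, n_rep = 0, 300
        for rep in range(n_rep):
            d = pd.DataFrame(
                {"t": rng.normal(5, 1, 60)}, index=meta.sample_ids
            )
            rejections += association_test(d, meta, "MIBC").loc["t", "p"] < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_fdr_within_panel(self):
        meta = make_metadata(["control"] * 20 + ["MIBC"] * 20, seed=5)
        rng = np.random.default_rng(5)
        d = pd.DataFrame(
            rng.normal(5, 1, size=(40, 4)), columns=list("abcd"),
            index=meta.sample_ids,
        )
        res = association_test(d, meta, "MIBC")
        assert (res["fdr"].dropna() >= res["p"].dropna() - 1e-12).all()


class TestTrend:
    def test_monotone_group_means_detected(self):
        classes = (
            ["control"] * 25 + ["NMIBC_G1G2"] * 25 + ["NMIBC_G3"] * 25 + ["MIBC"] * 25
        )
        meta = make_metadata(classes, seed=3)
        rng = np.random.default_rng(3)
        score = np.repeat([0, 1, 2, 3], 25)
        # -ΔCt rises with severity: ΔCt falls
        d = pd.DataFrame(
            {"t": 6.0 - 0.5 * score + rng.normal(0, 0.8, 100)},
            index=meta.sample_ids,
        )
        res = trend_test(d, meta)
        assert res.loc["t", "slope"] > 0
        assert res.loc["t", "trend_p"] < 0.05

    def test_permuted_labels_lose_the_trend(self):
        classes = (
            ["control"] * 25 + ["NMIBC_G1G2"] * 25 + ["NMIBC_G3"] * 25 + ["MIBC"] * 25
        )
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 40
        for rep in range(n_rep):
            meta = make_metadata(rng.permutation(classes), seed=rep)
            d = pd.DataFrame(
                {"t": rng.normal(5, 1, 100)}, index=meta.sample_ids
            )
            rejections += trend_test(d, meta).loc["t", "trend_p"] < 0.05
        assert rejections <= 0.2 * n_rep

    def test_two_groups_unadjusted_equals_t_test(self):
        meta = make_metadata(["control"] * 12 + ["MIBC"] * 12, seed=9)
        rng = np.random.default_rng(9)
        d = pd.DataFrame(
            {"t": np.r_[rng.normal(5, 1, 12), rng.normal(4, 1, 12)]},
            index=meta.sample_ids,
        )
        res = trend_test(d, meta, adjust=False)
        expr = -d["t"].to_numpy()
        t_p = stats.ttest_ind(expr[12:], expr[:12], equal_var=True).pvalue
        assert res.loc["t", "trend_p"] == pytest.approx(t_p, abs=1e-6)

    def test_cases_only_mode_drops_controls_and_rescores(self):
        classes = ["control"] * 10 + ["NMIBC_G1G2"] * 10 + ["NMIBC_G3"] * 10
        meta = make_metadata(classes, seed=11)
        rng = np.random.default_rng(11)
        d = pd.DataFrame({"t": rng.normal(5, 1, 30)}, index=meta.sample_ids)
        res = trend_test(d, meta, cases_only=True)
        assert np.isfinite(res.loc["t", "trend_p"])

    def test_single_group_rejected(self):
        meta = make_metadata(["control"] * 6)
        d = pd.DataFrame({"t": np.arange(6.0)}, index=meta.sample_ids)
        with pytest.raises(ValueError, match="2 ordered groups"):
            trend_test(d, meta)
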