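"""Ct calling, efficiency QC, normalization and ΔΔCt quantification."""

import numpy as np
import pandas as pd
import pytest

from ccmgrn import synthetic
from ccmgrn.qpcr import (
    call_ct,
    estimate_efficiency,
    gdna_check,
    qc_filter_genes,
    quantile_normalize,
    reference_gene_expression,
    relative_expression,
    scale_profiles,
)


def _exp_curve(f0=1e-4, base=2.0, n=40):
    return f0 * base ** np.arange(1, n + 1, dtype=float)


class TestCallCt:
    def test_flat_curve_not_detected(self):
        assert np.isnan(call_ct(np.zeros(40)))

    def test_closed_form_crossing_of_exponential(self):
        # F(c) = 1e-4 * 2^c crosses 0.2 at c = log2(2000) ~ 10.9658; linear
        # interpolation between the bracketing cycles (the instrument
        # convention) chords the convex exponential, giving 10.9531
        ct = call_ct(_exp_curve(), threshold=0.2, baseline_cycles=None)
        assert ct == pytest.approx(np.log2(2000), abs=0.02)
        assert ct == pytest.approx(10.953125, abs=1e-9)

    def test_integer_crossing_is_exact(self):
        f = np.zeros(30)
        f[19:] = np.linspace(0.2, 3.0, 11)  # hits exactly 0.2 at cycle 20
        assert call_ct(f, baseline_cycles=(3, 15)) == pytest.approx(20.0)

    def test_linear_baseline_drift_removed(self):
        # late-crossing curve + linear drift: correction recovers the Ct
        f = _exp_curve(f0=1e-7)
        drift = 0.01 + 0.002 * np.arange(1, 41)
        ct_clean = call_ct(f, baseline_cycles=None)
        ct_drift = call_ct(f + drift, baseline_cycles=(3, 15))
        assert ct_drift == pytest.approx(ct_clean, abs=0.05)

    def test_monotone_in_template_amount(self):
        previous = np.inf
        for f0 in (1e-6, 1e-5, 1e-4, 1e-3):
            ct = call_ct(_exp_curve(f0=f0), baseline_cycles=None)
            assert ct < previous
            previous = ct

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            call_ct(_exp_curve(), threshold=0.0)
        with pytest.raises(ValueError):
            call_ct(np.zeros(10), baseline_cycles=(3, 15))


class TestEstimateEfficiency:
    @pytest.mark.parametrize("eff", [90.0, 95.0, 100.0])
    def test_noiseless_recovery_exact(self, eff):
        curve = synthetic.simulate_amplification_curve(
            eff, 1e-4, plateau=1.0, n_cycles=40)
        assert estimate_efficiency(curve) == pytest.approx(eff, abs=1e-9)

    def test_noiseless_exact_with_plain_ols(self):
        curve = synthetic.simulate_amplification_curve(
            95.0, 1e-4, plateau=1.0, n_cycles=40)
        assert estimate_efficiency(curve, weighted=False,
                                   criterion="slope") == pytest.approx(95.0)

    def test_flat_curve_indeterminate(self):
        with pytest.raises(ValueError):
            estimate_efficiency(np.zeros(40))

    def test_noisy_recovery_median_within_two_points(self):
        for eff in (90.0, 100.0):
            estimates = [
                estimate_efficiency(synthetic.simulate_amplification_curve(
                    eff, 1e-4, plateau=1.0, n_cycles=40, noise_sd=0.01,
                    seed=s))
                for s in range(100)
            ]
            assert abs(np.median(estimates) - eff) <= 2.0


class TestQcFilter:
    def test_boundary_fail_fraction_retained(self):
        # 1 of 4 reactions below 95%: fail fraction exactly 0.25, kept
        table = pd.DataFrame({
            "gene_id": ["g"] * 4, "efficiency_pct": [96, 97, 94, 98]})
        retained, report = qc_filter_genes(table)
        assert retained == ["g"]

    def test_half_failing_excluded(self):
        table = pd.DataFrame({
            "gene_id": ["g"] * 4, "efficiency_pct": [96, 94, 93, 98]})
        retained, report = qc_filter_genes(table)
        assert retained == []
        assert report.loc[0, "fail_frac"] == 0.5

    def test_all_passing_retained(self):
        table = pd.DataFrame({
            "gene_id": ["a"] * 3 + ["b"] * 3,
            "efficiency_pct": [95, 99, 100, 96, 97, 98]})
        retained, _ = qc_filter_genes(table)
        assert retained == ["a", "b"]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            qc_filter_genes(pd.DataFrame(columns=["gene_id",
                                                  "efficiency_pct"]))


class TestGdnaCheck:
    @pytest.mark.parametrize("ct, expected", [
        (38.0, True), (30.0, False), (float("nan"), True), (36.0, False),
    ])
    def test_contamination_rule(self, ct, expected):
        assert gdna_check(ct) is expected


class TestQuantileNormalize:
    def test_two_sample_worked_example(self):
        ct = pd.DataFrame({
            "gene_id": ["a", "b", "a", "b"],
            "condition": ["HC", "HC", "LC", "LC"],
            "timepoint_min": [0.0, 0.0, 60.0, 60.0],
            "replicate": [1, 1, 1, 1],
            "ct": [10.0, 20.0, 30.0, 40.0],
        })
        out = quantile_normalize(ct)
        wide = out.pivot(index="gene_id", columns="condition", values="ct")
        assert wide.loc["a"].tolist() == [20.0, 20.0]
        assert wide.loc["b"].tolist() == [30.0, 30.0]

    def test_identical_samples_unchanged(self, small_ct_table):
        flat = small_ct_table.copy()
        flat["ct"] = flat["gene_id"].map({"cah1": 24.0, "actin": 20.0})
        out = quantile_normalize(flat)
        merged = flat.merge(out, on=["gene_id", "condition", "timepoint_min",
                                     "replicate"], suffixes=("", "_norm"))
        assert np.allclose(merged["ct"], merged["ct_norm"])

    def test_idempotent(self, small_ct_table):
        once = quantile_normalize(small_ct_table)
        twice = quantile_normalize(once)
        key = ["gene_id", "condition", "timepoint_min", "replicate"]
        a = once.sort_values(key).reset_index(drop=True)
        b = twice.sort_values(key).reset_index(drop=True)
        assert np.allclose(a["ct"], b["ct"], atol=1e-12)

    def test_all_missing_sample_rejected(self, small_ct_table):
        bad = small_ct_table.copy()
        bad.loc[(bad.timepoint_min == 60.0) & (bad.replicate == 1),
                "ct"] = np.nan
        with pytest.raises(ValueError):
            quantile_normalize(bad)

    def test_incomplete_gene_restored_as_missing(self, small_ct_table):
        holey = small_ct_table.copy()
        holey.loc[holey.index[0], "ct"] = np.nan
        out = quantile_normalize(holey)
        assert "cah1" not in set(out.dropna()["gene_id"]) or \
            out[out.gene_id == "cah1"]["ct"].isna().all() or \
            out[out.gene_id == "cah1"].empty


class TestRelativeExpression:
    def test_formula_identity(self, small_ct_table):
        fc = relative_expression(small_ct_table)
        cah1 = fc[fc.gene_id == "cah1"]
        assert np.allclose(cah1["delta_delta_ct"], -2.0)
        assert np.allclose(cah1["fold_change"], 4.0)
        actin = fc[fc.gene_id == "actin"]
        assert np.allclose(actin["fold_change"], 1.0)

    def test_planted_fold_change_recovered_exactly(self):
        expression = np.ones((2, 4, 5))
        expression[0, 1:, :] = 8.0  # 8-fold induction after the shift
        ct = synthetic.expression_to_ct(expression, tech_sd=0.0)
        fc = relative_expression(ct)
        induced = fc[fc.gene_id == "g000"]
        assert np.allclose(induced["fold_change"], 8.0, atol=1e-9)

    def test_fc_reciprocity(self, rng):
        ddct = rng.normal(size=50)
        assert np.allclose(np.exp2(-ddct) * np.exp2(ddct), 1.0)

    def test_missing_reference_rejected(self, small_ct_table):
        lc_only = small_ct_table[small_ct_table.condition == "LC"]
        with pytest.raises(ValueError):
            relative_expression(lc_only)


class TestReferenceGeneExpression:
    def test_target_tracking_reference_gives_unity(self, small_ct_table):
        flat = small_ct_table.copy()
        flat["ct"] = 22.0
        out = reference_gene_expression(flat, "cah1", "actin")
        assert np.allclose(out["fold_change"], 1.0)

    def test_two_cycle_drop_gives_fourfold(self, small_ct_table):
        out = reference_gene_expression(small_ct_table, "cah1", "actin")
        lc = out[out.condition == "LC"]
        assert np.allclose(lc["fold_change"], 4.0)

    def test_planted_65fold_induction_recovered(self):
        expression = np.ones((2, 4, 3))
        expression[0, 1:, :] = 65.0   # marker gene
        ct = synthetic.expression_to_ct(expression, tech_sd=0.0,
                                        gene_ids=["cah1", "actin"])
        out = reference_gene_expression(ct, "cah1", "actin")
        lc = out[out.condition == "LC"]
        assert np.allclose(lc["fold_change"], 65.0, atol=1e-9)

    def test_undetected_reference_rejected(self, small_ct_table):
        bad = small_ct_table.copy()
        bad.loc[bad.gene_id == "actin", "ct"] = np.nan
        with pytest.raises(ValueError):
            reference_gene_expression(bad, "cah1", "actin")


class TestScaleProfiles:
    def test_hand_computed_example(self):
        profiles = pd.DataFrame([[1.0, 2.0, 4.0, 8.0]], index=["g"])
        scaled, excluded = scale_profiles(profiles)
        assert excluded == []
        assert np.allclose(scaled.loc["g"],
                           [-0.5, -1 / 6, 1 / 6, 0.5])

    def test_scaled_profiles_sum_to_zero(self, rng):
        profiles = pd.DataFrame(np.exp(rng.normal(size=(20, 6))))
        scaled, _ = scale_profiles(profiles)
        assert np.allclose(scaled.sum(axis=1), 0.0, atol=1e-12)

    def test_constant_profile_excluded(self):
        profiles = pd.DataFrame([[2.0, 2.0, 2.0], [1.0, 2.0, 4.0]],
                                index=["flat", "ok"])
        scaled, excluded = scale_profiles(profiles)
        assert excluded == ["flat"]
        assert list(scaled.index) == ["ok"]

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            scale_profiles(pd.DataFrame([[0.0, 1.0, 2.0]]))
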