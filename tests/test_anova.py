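"""Two-way ANOVA, significance sets, post hoc and descriptive statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import phenonet as pn
from phenonet.anova import _anova_matrix
from phenonet.tables import ProcessedTable

from conftest import study_factors

BALANCED_CELLS = np.repeat(list(pn.CELLS), 3)
BALANCED_BMI = np.where(
    np.char.startswith(BALANCED_CELLS.astype(str), "Obese"),
    "overweight_obese", "lean",
)
BALANCED_IPAQ = np.where(
    np.char.endswith(BALANCED_CELLS.astype(str), "High"), "high", "low"
)


class TestTwoWayAnova:
    def test_pure_bmi_shift_without_noise(self):
        """A noiseless +1 shift for obese gives zero IPAQ/interaction SS."""
        y = (BALANCED_BMI == "overweight_obese").astype(float)
        with pytest.warns(RuntimeWarning):
            rec = pn.two_way_anova(y, BALANCED_BMI, BALANCED_IPAQ)
        assert rec.F_ipaq == 0.0 and rec.F_interaction == 0.0
        assert rec.p_ipaq == 1.0 and rec.p_interaction == 1.0
        assert rec.p_bmi == 0.0
        assert rec.dir_bmi == "up"

    def test_constant_data_is_fully_null(self):
        y = np.full(12, 3.0)
        with pytest.warns(RuntimeWarning):
            rec = pn.two_way_anova(y, BALANCED_BMI, BALANCED_IPAQ)
        assert rec.F_bmi == rec.F_ipaq == rec.F_interaction == 0.0
        assert rec.p_bmi == rec.p_ipaq == rec.p_interaction == 1.0

    def test_empty_cell_rejected(self):
        bmi = ["lean"] * 6
        ipaq = ["low", "low", "low", "high", "high", "high"]
        with pytest.raises(ValueError):
            pn.two_way_anova(np.arange(6.0), bmi, ipaq)

    @pytest.mark.parametrize("ss_type,typ", [("I", 1), ("II", 2)])
    def test_matches_statsmodels_on_unbalanced_design(self, ss_type, typ):
        """F and p agree with statsmodels anova_lm on the 13/7/20/9 design."""
        smf = pytest.importorskip("statsmodels.formula.api")
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(4)
        _, bmi, ipaq = study_factors()
        for _ in range(5):
            y = rng.standard_normal(49) + 0.7 * (bmi == "overweight_obese")
            fit = smf.ols(
                "y ~ C(b) * C(i)",
                pd.DataFrame({"y": y, "b": bmi, "i": ipaq}),
            ).fit()
            tab = anova_lm(fit, typ=typ)
            rec = pn.two_way_anova(y, bmi, ipaq, ss_type=ss_type)
            expected_F = tab["F"][:3].to_numpy()
            got_F = [rec.F_bmi, rec.F_ipaq, rec.F_interaction]
            assert np.allclose(got_F, expected_F, atol=1e-8)
            expected_p = tab["PR(>F)"][:3].to_numpy()
            got_p = [rec.p_bmi, rec.p_ipaq, rec.p_interaction]
            assert np.allclose(got_p, expected_p, atol=1e-10)

    def test_null_pvalues_uniform(self):
        """200 null features on the unbalanced design pass KS uniformity."""
        rng = np.random.default_rng(0)
        _, bmi, ipaq = study_factors()
        Y = rng.standard_normal((49, 200))
        _, p, _, _ = _anova_matrix(Y, bmi, ipaq)
        for j in range(3):
            assert stats.kstest(p[j], "uniform").pvalue > 0.01

    def test_balanced_decomposition_and_type_equivalence(self):
        """On balanced data SS_total = SS_B + SS_I + SS_BI + SS_err to 1e-9,
        and Type I equals Type II."""
        rng = np.random.default_rng(8)
        Y = rng.standard_normal((12, 40))
        from phenonet.anova import _sequential_ss, _type2_ss, _factor_arrays

        b, i = _factor_arrays(BALANCED_BMI, BALANCED_IPAQ)
        ss1, err1 = _sequential_ss(Y, b, i)
        ss2, err2 = _type2_ss(Y, b, i)
        total = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
        assert np.allclose(ss1.sum(axis=0) + err1, total, atol=1e-9)
        assert np.allclose(ss1, ss2, atol=1e-9)


class TestRunAnova:
    def test_one_record_per_feature_sorted(self, records_small, processed_small):
        processed, _ = processed_small
        assert len(records_small) == processed.data.shape[1]
        assert list(records_small.index) == sorted(processed.feature_ids)

    def test_feature_permutation_equivariance(self, small_study, processed_small):
        meta, _ = small_study
        processed, _ = processed_small
        shuffled = ProcessedTable(processed.data.iloc[:, ::-1].copy())
        r1 = pn.run_anova(processed, meta)
        r2 = pn.run_anova(shuffled, meta)
        # column order changes BLAS summation order, so agreement is to
        # near-machine precision rather than bitwise
        pd.testing.assert_frame_equal(r1, r2, rtol=1e-10, atol=1e-12)

    def test_planted_features_have_smaller_p(self, small_study):
        """Planted BMI features at d=2 sit below null features in p_bmi."""
        meta, table = small_study
        cfg = pn.SimConfig(n_per_cell=(13, 7, 20, 9), n_features=120,
                           n_affected_bmi=15, n_fail_rsd=0, effect_size=2.0,
                           seed=13)
        meta, table = pn.generate_cohort(cfg)
        table = pn.add_qc_samples(table, cfg)
        processed, _ = pn.preprocess_pipeline(table)
        records = pn.run_anova(processed, meta)
        truth = table.truth_labels
        planted = records.loc[truth[truth == "bmi"].index, "p_bmi"]
        null = records.loc[truth[truth == "null"].index, "p_bmi"]
        assert planted.median() < null.median()


class TestSignificanceSets:
    def test_venn_regions_by_enumeration(self):
        """A={1..5}, B={4,5}, C={5,6} partition exactly as brute force says."""
        features = [f"f{k}" for k in range(1, 7)]
        p = pd.DataFrame(1.0, index=pd.Index(features), columns=[
            "p_bmi", "p_ipaq", "p_interaction"])
        for k in range(1, 6):
            p.loc[f"f{k}", "p_bmi"] = 0.01
        for k in (4, 5):
            p.loc[f"f{k}", "p_ipaq"] = 0.01
        for k in (5, 6):
            p.loc[f"f{k}", "p_interaction"] = 0.01
        sets = pn.select_significant(p, 0.05)
        assert sets.venn["bmi_only"] == {"f1", "f2", "f3"}
        assert sets.venn["bmi_ipaq"] == {"f4"}
        assert sets.venn["triple"] == {"f5"}
        assert sets.venn["ipaq_only"] == frozenset()
        assert sets.venn["interaction_only"] == {"f6"}
        assert len(sets.union) == 6

    def test_empty_records(self):
        empty = pd.DataFrame(columns=["p_bmi", "p_ipaq", "p_interaction"])
        sets = pn.select_significant(empty, 0.05)
        assert all(len(v) == 0 for v in sets.venn.values())

    def test_vacuous_threshold_selects_all(self, records_small):
        sets = pn.select_significant(records_small.assign(
            p_bmi=records_small["p_bmi"].clip(upper=0.999)), alpha=1.0)
        assert sets.set_bmi == frozenset(records_small.index)

    def test_region_disjointness_and_inclusion_exclusion(self, records_small):
        sets = pn.select_significant(records_small, 0.05)
        regions = list(sets.venn.values())
        for a in range(len(regions)):
            for b in range(a + 1, len(regions)):
                assert not (regions[a] & regions[b])
        assert frozenset().union(*regions) == sets.union
        a, b, c = sets.set_bmi, sets.set_ipaq, sets.set_interaction
        incl_excl = (len(a) + len(b) + len(c) - len(a & b) - len(a & c)
                     - len(b & c) + len(a & b & c))
        assert incl_excl == len(sets.union)
        assert len(a) == (len(sets.venn["bmi_only"]) + len(sets.venn["bmi_ipaq"])
                          + len(sets.venn["bmi_interaction"])
                          + len(sets.venn["triple"]))


class TestPosthoc:
    def test_per_contrast_type_I_error_calibrated(self):
        """Each LSD contrast rejects ~5% of null simulations."""
        rng = np.random.default_rng(6)
        cells, _, _ = study_factors()
        counts = {c: 0 for c in pn.CELLS if c != "ObeseLow"}
        n_sim = 500
        for _ in range(n_sim):
            rec = pn.posthoc_lsd(rng.standard_normal(49), cells, "ObeseLow")
            for c, contrast in rec.contrasts.items():
                counts[c] += contrast.significant
        for c, k in counts.items():
            assert 0.03 <= k / n_sim <= 0.07, (c, k / n_sim)

    def test_shifted_reference_forces_all_contrasts(self):
        rng = np.random.default_rng(7)
        cells, _, _ = study_factors()
        y = rng.standard_normal(49)
        y[cells == "ObeseLow"] += 10.0
        rec = pn.posthoc_lsd(y, cells, "ObeseLow")
        assert all(c.significant for c in rec.contrasts.values())
        assert all(c.difference < 0 for c in rec.contrasts.values())

    def test_two_cell_design_reduces_to_pooled_t(self):
        """With two cells the LSD contrast equals the pooled two-sample t."""
        rng = np.random.default_rng(9)
        y = rng.standard_normal(20)
        cells = np.array(["LeanLow"] * 8 + ["ObeseLow"] * 12)
        rec = pn.posthoc_lsd(y, cells, "ObeseLow")
        t, p = stats.ttest_ind(y[:8], y[8:], equal_var=True)
        contrast = rec.contrasts["LeanLow"]
        assert contrast.t == pytest.approx(t, abs=1e-12)
        assert contrast.p == pytest.approx(p, abs=1e-12)

    def test_empty_reference_rejected(self):
        cells = np.array(["LeanLow"] * 4 + ["LeanHigh"] * 4)
        with pytest.raises(ValueError):
            pn.posthoc_lsd(np.arange(8.0), cells, "ObeseLow")


class TestDirectionTable:
    @pytest.fixture()
    def small_run(self, small_study, processed_small, records_small):
        meta, _ = small_study
        processed, _ = processed_small
        sets = pn.select_significant(records_small, 0.05)
        posthoc = pn.run_posthoc(processed, meta, sorted(sets.union))
        return records_small, posthoc, sets

    def test_nonsignificant_ipaq_shows_dash(self, small_run):
        records, posthoc, sets = small_run
        table = pn.direction_table(records, posthoc, sets)
        merged = table.set_index("feature_id").join(records[["p_ipaq"]],
                                                    rsuffix="_rec")
        ns = merged[merged["p_ipaq"] >= 0.05]
        assert (ns["ipaq_dir"] == "-").all()
        sig = merged[merged["p_ipaq"] < 0.05]
        assert sig["ipaq_dir"].isin(["up", "down"]).all()

    def test_only_selected_features_appear(self, small_run):
        records, posthoc, sets = small_run
        table = pn.direction_table(records, posthoc, sets)
        assert set(table["feature_id"]) == set(sets.union)

    def test_bmi_arrow_matches_marginal_means(self, small_run):
        records, posthoc, sets = small_run
        table = pn.direction_table(records, posthoc, sets).set_index("feature_id")
        for fid, row in table.iterrows():
            if row["bmi_dir"] != "-":
                assert row["bmi_dir"] == records.loc[fid, "dir_bmi"]


class TestSubgroupCorrelations:
    def test_perfect_linearity(self):
        meta = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(6)],
            "bmi_value": [19.0, 20, 21, 26, 27, 28],
            "ipaq_score": [38.0, 40, 42, 52, 54, 56],
        })
        meta = pn.classify_cohort(meta)
        out = pn.subgroup_correlations(meta)
        assert out.loc["LeanLow", "r"] == pytest.approx(1.0)
        assert out.loc["ObeseLow", "r"] == pytest.approx(1.0)

    def test_hand_computed_five_point_oracle(self):
        x = np.array([19.0, 20.5, 21.0, 22.0, 24.0])
        y = np.array([100.0, 250.0, 180.0, 400.0, 320.0])
        meta = pn.classify_cohort(pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(5)],
            "bmi_value": x, "ipaq_score": y,
        }))
        out = pn.subgroup_correlations(meta)
        sx, sy = x - x.mean(), y - y.mean()
        r_manual = (sx @ sy) / np.sqrt((sx @ sx) * (sy @ sy))
        assert out.loc["LeanLow", "r"] == pytest.approx(r_manual, abs=1e-12)
        assert out.loc["overall", "r"] == pytest.approx(r_manual, abs=1e-12)

    def test_independent_null_cell_has_small_r(self):
        """|r| < 0.15 in >=95% of seeds for an independent cell of n=500."""
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            meta = pn.classify_cohort(pd.DataFrame({
                "subject_id": [f"S{i}" for i in range(500)],
                "bmi_value": rng.uniform(18, 24.9, 500),
                "ipaq_score": rng.uniform(0, 3000, 500),
            }))
            out = pn.subgroup_correlations(meta)
            hits += abs(out.loc["LeanLow", "r"]) < 0.15
        assert hits / 40 >= 0.95

    def test_small_cell_reports_nan(self):
        meta = pn.classify_cohort(pd.DataFrame({
            "subject_id": ["S0", "S1"],
            "bmi_value": [19.0, 20.0],
            "ipaq_score": [100.0, 200.0],
        }))
        out = pn.subgroup_correlations(meta)
        assert np.isnan(out.loc["LeanLow", "r"])


class TestGroupSummary:
    @staticmethod
    def _meta(seed=0, shift=0.0):
        rng = np.random.default_rng(seed)
        n = 30
        bmi = np.concatenate([rng.uniform(18, 24.9, 15),
                              rng.uniform(25, 35, 15)]) + 0.0
        meta = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(n)],
            "sex": ["F"] * n,
            "age": rng.integers(18, 60, n),
            "height": rng.uniform(1.5, 1.9, n),
            "bmi_value": bmi,
            "ipaq_score": rng.uniform(0, 8000, n) + shift * (bmi >= 25),
        })
        meta["body_mass"] = meta["bmi_value"] * meta["height"] ** 2
        return pn.classify_cohort(meta)

    def test_shifted_variable_is_significant(self):
        meta = self._meta(seed=1, shift=10 * 2300)
        out = pn.group_summary(meta)
        row = out[(out["grouping"] == "bmi_class")
                  & (out["variable"] == "ipaq_score")].iloc[0]
        assert row["p"] < 0.001

    def test_f_equals_squared_pooled_t(self):
        """Two-group one-way ANOVA F is the square of the pooled t statistic."""
        meta = self._meta(seed=2)
        out = pn.group_summary(meta)
        lean = meta[meta["bmi_class"] == "lean"]["age"].to_numpy(float)
        obese = meta[meta["bmi_class"] == "overweight_obese"]["age"].to_numpy(float)
        t, p_t = stats.ttest_ind(lean, obese, equal_var=True)
        row = out[(out["grouping"] == "bmi_class")
                  & (out["variable"] == "age")].iloc[0]
        F, p_f = stats.f_oneway(lean, obese)
        assert F == pytest.approx(t ** 2, rel=1e-12)
        assert row["p"] == pytest.approx(p_t, abs=1e-12)
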