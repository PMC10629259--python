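import numpy as np
import pandas as pd
import pytest

from lfqstats import differential as dd
from lfqstats.differential import ContrastSpec
from lfqstats.io import BIOREPLICATE, CONDITION, PROTEIN, RUN, ValidationError
from lfqstats.summarization import LOG2_ABUNDANCE

from _oracles import bh_adjust_oracle


def summaries(values_by_condition, paired=False, tech_reps=1, protein="P"):
    """Run-summary frame: condition -> list of per-subject values (or lists
    per subject when tech_reps > 1)."""
    rows = []
    for cond, subject_values in values_by_condition.items():
        for j, v in enumerate(subject_values):
            subj = f"S{j}" if paired else f"{cond}_S{j}"
            reps = v if isinstance(v, (list, tuple)) else [v] * tech_reps
            for k, z in enumerate(reps):
                rows.append(
                    {
                        PROTEIN: protein,
                        RUN: f"{cond}_{subj}_R{k}",
                        CONDITION: cond,
                        BIOREPLICATE: subj,
                        LOG2_ABUNDANCE: float(z),
                    }
                )
    return pd.DataFrame(rows)


class TestDetectDesign:
    def test_distinct_subjects_is_group_comparison(self):
        df = summaries({"C1": [1, 2, 3], "C2": [4, 5, 6]})
        d = dd.detect_design(df[[RUN, CONDITION, BIOREPLICATE]])
        assert d.design_type == "group_comparison"
        assert not d.has_tech_replicates
        assert d.balanced

    def test_shared_subjects_is_paired(self):
        df = summaries({"WT": [1] * 6, "KO": [2] * 6}, paired=True)
        d = dd.detect_design(df[[RUN, CONDITION, BIOREPLICATE]])
        assert d.design_type == "paired_or_timecourse"

    def test_multiple_runs_per_subject_flags_tech_replicates(self):
        df = summaries({"C1": [[1, 2]], "C2": [[3, 4]]}, tech_reps=2)
        d = dd.detect_design(df[[RUN, CONDITION, BIOREPLICATE]])
        assert d.has_tech_replicates
        assert d.design_type == "group_comparison"

    def test_single_condition_rejected(self):
        df = summaries({"C1": [1, 2, 3]})
        with pytest.raises(ValidationError):
            dd.detect_design(df[[RUN, CONDITION, BIOREPLICATE]])


class TestBalancedClosedForms:
    def build(self, rng, I=4, J=3, sigma=0.4):
        vals = {f"C{i+1}": rng.normal(10 + i, sigma, J).tolist() for i in range(I)}
        df = summaries(vals)
        design = dd.detect_design(df[[RUN, CONDITION, BIOREPLICATE]])
        return vals, df, design

    def test_condition_means_equal_sample_means(self, rng):
        vals, df, design = self.build(rng)
        model = dd.fit_protein_model(df, design)
        for cond, v in vals.items():
            assert model.condition_means[cond] == pytest.approx(np.mean(v), abs=1e-12)

    def test_pairwise_estimate_se_and_df(self, rng):
        vals, df, design = self.build(rng)
        model = dd.fit_protein_model(df, design)
        res = dd.test_contrast(model, ContrastSpec("C1 vs C2", {"C1": 1, "C2": -1}))
        I, J = 4, 3
        # ANOVA oracle: pooled within-condition variance
        sigma2 = sum(
            ((np.array(v) - np.mean(v)) ** 2).sum() for v in vals.values()
        ) / (I * (J - 1))
        assert res["log2FC"] == pytest.approx(np.mean(vals["C1"]) - np.mean(vals["C2"]), abs=1e-12)
        assert res["SE"] == pytest.approx(np.sqrt(2 * sigma2 / J), abs=1e-12)
        assert res["DF"] == I * (J - 1) == 8

    def test_average_versus_average_contrast(self, rng):
        vals, df, design = self.build(rng)
        model = dd.fit_protein_model(df, design)
        spec = ContrastSpec("12 vs 34", {"C1": 0.5, "C2": 0.5, "C3": -0.5, "C4": -0.5})
        res = dd.test_contrast(model, spec)
        expected = 0.5 * (np.mean(vals["C1"]) + np.mean(vals["C2"])) - 0.5 * (
            np.mean(vals["C3"]) + np.mean(vals["C4"])
        )
        assert res["log2FC"] == pytest.approx(expected, abs=1e-12)

    def test_scale_equivariance(self, rng):
        vals, df, design = self.build(rng)
        model = dd.fit_protein_model(df, design)
        res = dd.test_contrast(model, ContrastSpec("C1 vs C2", {"C1": 1, "C2": -1}))
        shifted = df.copy()
        shifted.loc[shifted[CONDITION] == "C1", LOG2_ABUNDANCE] += 2.5
        model2 = dd.fit_protein_model(shifted, design)
        res2 = dd.test_contrast(model2, ContrastSpec("C1 vs C2", {"C1": 1, "C2": -1}))
        assert res2["log2FC"] == pytest.approx(res["log2FC"] + 2.5, abs=1e-10)
        res3 = dd.test_contrast(model2, ContrastSpec("C3 vs C4", {"C3": 1, "C4": -1}))
        base3 = dd.test_contrast(model, ContrastSpec("C3 vs C4", {"C3": 1, "C4": -1}))
        assert res3["log2FC"] == pytest.approx(base3["log2FC"], abs=1e-10)

    def test_degenerate_identical_summaries_flagged(self):
        df = summaries({"C1": [5, 5, 5], "C2": [5, 5, 5]})
        design = dd.detect_design(df[[RUN, CONDITION, BIOREPLICATE]])
        model = dd.fit_protein_model(df, design)
        assert model.singular
        assert model.sigma_error2 == 0.0


class TestMixedModel:
    def test_paired_design_reproduces_paired_t_test(self, rng):
        subj = rng.normal(0, 1.0, 6)
        a = 10 + subj + rng.normal(0, 0.3, 6)
        b = 10.5 + subj + rng.normal(0, 0.3, 6)
        df = summaries({"A": a.tolist(), "B": b.tolist()}, paired=True)
        design = dd.detect_design(df[[RUN, CONDITION, BIOREPLICATE]])
        model = dd.fit_protein_model(df, design)
        res = dd.test_contrast(model, ContrastSpec("B vs A", {"B": 1, "A": -1}))

        diff = b - a
        se = diff.std(ddof=1) / np.sqrt(6)
        from scipy.stats import ttest_rel

        t, p = ttest_rel(b, a)
        assert res["log2FC"] == pytest.approx(diff.mean(), abs=1e-8)
        assert res["SE"] == pytest.approx(se, abs=1e-8)
        assert res["DF"] == pytest.approx(5.0, abs=1e-6)
        assert res["pvalue"] == pytest.approx(p, abs=1e-8)

    def test_reml_components_match_statsmodels_mixedlm(self, rng):
        import statsmodels.formula.api as smf

        subj = rng.normal(0, 0.8, 5)
        rows = {"A": [], "B": []}
        for cond, shift in (("A", 0.0), ("B", 0.7)):
            for j in range(5):
                rows[cond].append(
                    [10 + shift + subj[j] + rng.normal(0, 0.25) for _ in range(2)]
                )
        df = summaries(rows, paired=True, tech_reps=2)
        design = dd.detect_design(df[[RUN, CONDITION, BIOREPLICATE]])
        model = dd.fit_protein_model(df, design)

        md = smf.mixedlm(
            f"{LOG2_ABUNDANCE} ~ 0 + {CONDITION}", df, groups=df[BIOREPLICATE]
        ).fit(reml=True)
        assert model.sigma_subject2 == pytest.approx(
            float(md.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-6
        )
        assert model.sigma_error2 == pytest.approx(float(md.scale), rel=1e-3)
        for i, cond in enumerate(model.conditions):
            assert model.condition_means[cond] == pytest.approx(
                md.fe_params.iloc[i], abs=1e-5
            )

    def test_boundary_variance_falls_back_to_fixed_effect_df(self, rng):
        # no subject effect at all: REML hits the zero boundary
        df = summaries(
            {"A": rng.normal(10, 0.3, 4).tolist(), "B": rng.normal(10, 0.3, 4).tolist()},
            paired=True,
        )
        design = dd.detect_design(df[[RUN, CONDITION, BIOREPLICATE]])
        model = dd.fit_protein_model(df, design)
        if model.singular:
            res = dd.test_contrast(model, ContrastSpec("A vs B", {"A": 1, "B": -1}))
            assert res["DF"] == pytest.approx(model.residual_df)
            assert np.isfinite(res["pvalue"])


class TestContrastIssues:
    def test_missing_condition_flagged_without_pvalue(self, rng):
        df = summaries({"C1": [1.0, 1.2, 0.9], "C2": [2.0, 2.1, 1.9]})
        design = dd.DesignInfo(
            design_type="group_comparison",
            has_tech_replicates=False,
            conditions=["C1", "C2", "C3"],
            subjects_per_condition={"C1": 3, "C2": 3, "C3": 0},
            balanced=False,
        )
        model = dd.fit_protein_model(df, design)
        res = dd.test_contrast(model, ContrastSpec("C1 vs C3", {"C1": 1, "C3": -1}))
        assert res["issue"] == dd.ISSUE_ONE_CONDITION
        assert np.isnan(res["pvalue"])

    def test_all_zero_contrast_rejected(self):
        with pytest.raises(ValidationError):
            ContrastSpec("null", {"C1": 0, "C2": 0})

    def test_unknown_condition_in_contrast_rejected(self):
        df = summaries({"C1": [1, 2, 3], "C2": [4, 5, 6]})
        with pytest.raises(ValidationError, match="GHOST"):
            dd.group_comparison(df, [ContrastSpec("x", {"GHOST": 1, "C1": -1})])


class TestFDR:
    def test_matches_step_up_oracle(self, rng):
        pvals = rng.uniform(0, 1, 37)
        frame = pd.DataFrame(
            {
                PROTEIN: [f"P{i}" for i in range(len(pvals))],
                "Label": "C1 vs C2",
                "pvalue": pvals,
                "issue": dd.ISSUE_NONE,
            }
        )
        out = dd.adjust_fdr(frame)
        expected = bh_adjust_oracle(pvals.tolist())
        np.testing.assert_allclose(out["adj_pvalue"], expected, atol=1e-12)

    def test_three_pvalue_example(self):
        frame = pd.DataFrame(
            {
                PROTEIN: ["A", "B", "C"],
                "Label": "x",
                "pvalue": [0.01, 0.02, 0.03],
                "issue": dd.ISSUE_NONE,
            }
        )
        out = dd.adjust_fdr(frame)
        np.testing.assert_allclose(out["adj_pvalue"], [0.03, 0.03, 0.03], atol=1e-12)

    def test_single_pvalue_unchanged(self):
        frame = pd.DataFrame(
            {PROTEIN: ["A"], "Label": "x", "pvalue": [0.2], "issue": dd.ISSUE_NONE}
        )
        out = dd.adjust_fdr(frame)
        assert out["adj_pvalue"].iloc[0] == pytest.approx(0.2)

    def test_issue_rows_excluded_from_family(self):
        frame = pd.DataFrame(
            {
                PROTEIN: ["A", "B", "C"],
                "Label": "x",
                "pvalue": [0.01, 0.02, np.nan],
                "issue": [dd.ISSUE_NONE, dd.ISSUE_NONE, dd.ISSUE_COMPLETE],
            }
        )
        out = dd.adjust_fdr(frame)
        expected = bh_adjust_oracle([0.01, 0.02])
        np.testing.assert_allclose(out["adj_pvalue"].iloc[:2], expected, atol=1e-12)
        assert np.isnan(out["adj_pvalue"].iloc[2])


class TestNullCalibration:
    def test_null_pvalues_uniform_on_exact_gaussian_summaries(self, rng):
        """With Gaussian run summaries and no true difference the t-based
        p-values are exactly uniform; a KS test at 1% must not reject."""
        from scipy.stats import kstest

        pvals = []
        for i in range(400):
            df = summaries(
                {"C1": rng.normal(10, 0.5, 3).tolist(),
                 "C2": rng.normal(10, 0.5, 3).tolist()},
                protein=f"P{i}",
            )
            design = dd.detect_design(df[[RUN, CONDITION, BIOREPLICATE]])
            model = dd.fit_protein_model(df, design)
            res = dd.test_contrast(model, ContrastSpec("c", {"C1": 1, "C2": -1}))
            pvals.append(res["pvalue"])
        stat, p = kstest(pvals, "uniform")
        assert p > 0.01
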