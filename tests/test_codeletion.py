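"""Combined 1p/19q z-score and RNA-protein dosage regression."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from lggpc import (
    ArmAnnotation,
    DataError,
    ExpressionMatrix,
    SampleSheet,
    arm_rna_protein_regression,
    combined_zscore,
    compare_score_groups,
)


def _setup(n_feat=10, n_normal=4, n_tumour=4, shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    normal = rng.normal(5, 1, size=(n_feat, n_normal))
    tumour = rng.normal(5 + shift, 1, size=(n_feat, n_tumour))
    cols = [f"N{i}" for i in range(n_normal)] + [f"T{i}" for i in range(n_tumour)]
    feats = [f"F{i}" for i in range(n_feat)]
    m = ExpressionMatrix(
        pd.DataFrame(np.hstack([normal, tumour]), index=feats, columns=cols), "log2"
    )
    sheet = SampleSheet(
        pd.DataFrame(
            {"subtype": ["NORMAL"] * n_normal + ["TYPE_I"] * n_tumour},
            index=pd.Index(cols, name="sample_id"),
        )
    )
    arms = ArmAnnotation(pd.Series("1p", index=feats, name="arm_label"))
    return m, sheet, arms


class TestCombinedZscore:
    def test_sample_at_normal_mean_scores_zero(self):
        m, sheet, arms = _setup()
        mu = m.data.loc[:, sheet.samples_of("NORMAL")].mean(axis=1)
        m.data["T0"] = mu
        scores = {s.sample_id: s.z_combined for s in combined_zscore(m, sheet, arms)}
        assert scores["T0"] == pytest.approx(0.0, abs=1e-12)

    def test_shift_by_one_reference_sd_scores_minus_one(self):
        m, sheet, arms = _setup()
        normal = m.data.loc[:, sheet.samples_of("NORMAL")]
        m.data["T1"] = normal.mean(axis=1) - normal.std(axis=1, ddof=1)
        scores = {s.sample_id: s.z_combined for s in combined_zscore(m, sheet, arms)}
        assert scores["T1"] == pytest.approx(-1.0, abs=1e-12)

    def test_normal_group_self_centres_at_zero(self):
        m, sheet, arms = _setup(n_feat=30)
        scores = combined_zscore(m, sheet, arms)
        normal_mean = np.mean(
            [s.z_combined for s in scores if s.sample_id.startswith("N")]
        )
        assert normal_mean == pytest.approx(0.0, abs=1e-9)

    def test_not_invariant_to_global_sample_shift(self):
        """A per-sample constant moves the score: normalisation must happen
        before scoring, the metric does not absorb loading differences."""
        m, sheet, arms = _setup()
        base = {s.sample_id: s.z_combined for s in combined_zscore(m, sheet, arms)}
        m2 = ExpressionMatrix(m.data.copy(), "log2")
        m2.data["T2"] = m2.data["T2"] + 1.0
        shifted = {s.sample_id: s.z_combined for s in combined_zscore(m2, sheet, arms)}
        assert shifted["T2"] != pytest.approx(base["T2"], abs=1e-6)

    def test_zero_variance_reference_features_excluded(self):
        m, sheet, arms = _setup(n_feat=6)
        m.data.loc["F0", sheet.samples_of("NORMAL")] = 7.0  # flat reference
        scores = combined_zscore(m, sheet, arms)
        assert scores[0].n_features_used == 5
        flat = ExpressionMatrix(
            pd.DataFrame(np.ones((2, 8)), index=["F0", "F1"], columns=m.sample_ids),
            "log2",
        )
        flat_arms = ArmAnnotation(pd.Series("19q", index=["F0", "F1"]))
        with pytest.raises(DataError, match="zero NORMAL variance"):
            combined_zscore(flat, sheet, flat_arms)

    def test_requires_normal_reference_and_target_features(self):
        m, sheet, arms = _setup()
        no_arm = ArmAnnotation(pd.Series("other", index=m.feature_ids))
        with pytest.raises(DataError, match="no features"):
            combined_zscore(m, sheet, no_arm)

    def test_planted_dosage_ranks_type_i_lowest(self, cohort):
        protein, _, samples, arms, _ = cohort
        scores = combined_zscore(protein, samples, arms)
        by = {s.sample_id: s.z_combined for s in scores}
        means = {
            g: np.mean([by[s] for s in samples.samples_of(g)])
            for g in ("NORMAL", "TYPE_I", "TYPE_II", "TYPE_III")
        }
        assert means["TYPE_I"] == min(means.values())
        table = compare_score_groups(scores, samples).set_index(["group_a", "group_b"])

        def p(a, b):
            key = (a, b) if (a, b) in table.index else (b, a)
            return table.loc[key, "p_value"]

        assert p("TYPE_I", "TYPE_II") < 0.05
        assert p("TYPE_I", "TYPE_III") < 0.05


class TestCompareScoreGroups:
    def test_identical_groups_are_null(self):
        m, sheet, arms = _setup(seed=4)
        # make the tumour group a copy of the normal group
        m.data[sheet.samples_of("TYPE_I")] = m.data[sheet.samples_of("NORMAL")].to_numpy()
        scores = combined_zscore(m, sheet, arms)
        table = compare_score_groups(scores, sheet)
        assert table["p_value"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_all_tumour_groups_below_normal_are_each_significant(self):
        """When every tumour subtype sits below the reference, every
        tumour-vs-normal pair tests significant."""
        rng = np.random.default_rng(6)
        feats = [f"F{i}" for i in range(40)]
        cols, labels, blocks = [], [], []
        for g, n, shift in [("NORMAL", 6, 0.0), ("TYPE_I", 8, -2.0),
                            ("TYPE_II", 8, -1.5), ("TYPE_III", 8, -1.0)]:
            cols += [f"{g}_{i}" for i in range(n)]
            labels += [g] * n
            blocks.append(rng.normal(5 + shift, 0.5, size=(40, n)))
        m = ExpressionMatrix(
            pd.DataFrame(np.hstack(blocks), index=feats, columns=cols), "log2"
        )
        sheet = SampleSheet(pd.DataFrame({"subtype": labels},
                                         index=pd.Index(cols, name="sample_id")))
        arms = ArmAnnotation(pd.Series("1p", index=feats))
        table = compare_score_groups(combined_zscore(m, sheet, arms), sheet)
        table = table.set_index(["group_a", "group_b"])
        for g in ("TYPE_I", "TYPE_II", "TYPE_III"):
            key = ("NORMAL", g) if ("NORMAL", g) in table.index else (g, "NORMAL")
            assert table.loc[key, "padj"] < 0.05


class TestArmRnaProteinRegression:
    @staticmethod
    def _pair(n_genes=300, seed=0):
        rng = np.random.default_rng(seed)
        feats = [f"G{i}" for i in range(n_genes)]
        cols = [f"T{i}" for i in range(6)]
        rna = ExpressionMatrix(
            pd.DataFrame(rng.normal(8, 1, size=(n_genes, 6)), index=feats,
                         columns=cols),
            "log2",
        )
        sheet = SampleSheet(pd.DataFrame({"subtype": ["TYPE_I"] * 6},
                                         index=pd.Index(cols, name="sample_id")))
        arms = ArmAnnotation(pd.Series("1p", index=feats))
        return rna, sheet, arms

    def test_protein_equal_to_rna_gives_perfect_fit(self):
        rna, sheet, arms = self._pair()
        protein = ExpressionMatrix(rna.data.copy(), "log2")
        (res,) = arm_rna_protein_regression(rna, protein, sheet, arms, "TYPE_I")
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.slope == pytest.approx(1.0, abs=1e-9)
        assert res.intercept == pytest.approx(0.0, abs=1e-7)

    def test_shuffled_protein_is_uncorrelated(self):
        rna, sheet, arms = self._pair(seed=9)
        rng = np.random.default_rng(10)
        shuffled = rna.data.sample(frac=1.0, random_state=1).to_numpy()
        protein = ExpressionMatrix(
            pd.DataFrame(shuffled, index=rna.feature_ids, columns=rna.sample_ids),
            "log2",
        )
        (res,) = arm_rna_protein_regression(rna, protein, sheet, arms, "TYPE_I")
        assert res.r_squared < 0.05

    def test_r_squared_equals_squared_pearson(self):
        rna, sheet, arms = self._pair(seed=3)
        rng = np.random.default_rng(4)
        protein = ExpressionMatrix(rna.data + rng.normal(0, 1, rna.data.shape), "log2")
        (res,) = arm_rna_protein_regression(rna, protein, sheet, arms, "TYPE_I")
        x = rna.data.mean(axis=1).to_numpy()
        y = protein.data.mean(axis=1).to_numpy()
        r, _ = pearsonr(x, y)
        assert res.r_squared == pytest.approx(r**2, abs=1e-12)

    def test_arms_with_too_few_genes_are_skipped(self):
        rna, sheet, _ = self._pair(n_genes=5)
        arms = ArmAnnotation(
            pd.Series(["1p", "1p", "19q", "19q", "19q"], index=rna.feature_ids)
        )
        protein = ExpressionMatrix(rna.data.copy(), "log2")
        results = arm_rna_protein_regression(rna, protein, sheet, arms, "TYPE_I")
        assert [r.arm_label for r in results] == ["19q"]

    def test_default_cohort_lands_in_attenuated_regime(self, cohort):
        protein, rna, samples, arms, _ = cohort
        results = arm_rna_protein_regression(rna, protein, samples, arms, "TYPE_I")
        assert len(results) == 4
        for res in results:
            assert 0.05 <= res.r_squared <= 0.45  # loose per-seed envelope
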