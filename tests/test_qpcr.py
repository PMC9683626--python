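import numpy as np
import pandas as pd
import pytest

from lensgex import (
    ConfirmationRule,
    QpcrExperiment,
    confirm_candidates,
    group_test,
    relative_expression,
    simulate_qpcr,
)
from lensgex.errors import ConfigurationError, DegenerateInputError
from lensgex.qpcr import normalized_table

from conftest import exhaustive_permutation_p, student_t_p

GROUPS = ("control", "galactose", "C646", "CBP30", "CPTH2",
          "C646+CPTH2", "CBP30+CPTH2", "TH1834")

# Treatment-specific confirmation panels with synthetic Ct values: the gene
# names follow the study's confirmed candidates, but every number here is
# planted by the simulator, not measured.
COMBO1_GENES = ["Acta1", "Stmn4"]
COMBO2_GENES = ["Emd", "Prtfdc1"]
TH1834_GENES = ["Acta1", "Acta2", "Arrdc3", "Hebp2", "Hist2h2ab", "Pmf1", "Ppdpf",
                "Rbm3", "RGD1561694", "Slc16a6", "Slfn13", "Tagln", "Tgfb1i1", "Tuba1c"]


def planted_confirmation_expression():
    """gene x group relative expression planting the confirmation patterns:
    every gene is galactose-induced (4x) and suppressed back to baseline only
    under the treatments that confirm it."""
    genes = sorted(set(COMBO1_GENES) | set(COMBO2_GENES) | set(TH1834_GENES))
    expr = pd.DataFrame(4.0, index=pd.Index(genes, name="gene_id"), columns=list(GROUPS))
    expr["control"] = 1.0
    for g in genes:
        if g in COMBO1_GENES:
            expr.loc[g, "C646+CPTH2"] = 1.0
        if g in COMBO2_GENES:
            expr.loc[g, "CBP30+CPTH2"] = 1.0
        if g in TH1834_GENES:
            expr.loc[g, "TH1834"] = 1.0
    return expr


class TestRelativeExpression:
    def test_delta_ct_identities(self):
        assert relative_expression(20.0, 20.0) == 1.0
        assert relative_expression(21.0, 20.0) == 0.5
        assert relative_expression(19.0, 20.0) == 2.0

    def test_scale_consistency_under_cycle_shift(self):
        rng = np.random.default_rng(0)
        ct_t, ct_r = rng.uniform(18, 30, 10), rng.uniform(16, 20, 10)
        np.testing.assert_allclose(relative_expression(ct_t, ct_r),
                                   relative_expression(ct_t - 3.0, ct_r - 3.0))

    def test_group_mean_se_match_spreadsheet_oracle(self):
        """Six fixture rows normalised and summarised by hand."""
        table = pd.DataFrame({
            "gene": ["g"] * 6,
            "group": ["control"] * 3 + ["galactose"] * 3,
            "replicate": [1, 2, 3, 1, 2, 3],
            "ct_target": [24.0, 24.2, 23.8, 22.0, 22.1, 21.9],
            "ct_reference": [18.0, 18.0, 18.0, 18.0, 18.0, 18.0],
        })
        norm = normalized_table(table)
        ctrl = norm[norm["group"] == "control"]["expression"].to_numpy()
        hand = 2.0 ** (18.0 - np.array([24.0, 24.2, 23.8]))
        np.testing.assert_allclose(ctrl, hand)
        assert ctrl.mean() == pytest.approx(hand.mean())
        assert ctrl.std(ddof=1) / np.sqrt(3) == pytest.approx(hand.std(ddof=1) / np.sqrt(3))

    def test_missing_reference_ct_skipped_with_warning(self, caplog):
        table = pd.DataFrame({
            "gene": ["g", "g"], "group": ["control", "control"], "replicate": [1, 2],
            "ct_target": [24.0, 24.0], "ct_reference": [18.0, np.nan],
        })
        with caplog.at_level("WARNING"):
            norm = normalized_table(table)
        assert len(norm) == 1 and "skipped" in caplog.text


class TestGroupTest:
    @staticmethod
    def _table(a, g):
        rows = [("x", "treated", i, 20.0 - np.log2(v), 20.0) for i, v in enumerate(a)]
        rows += [("x", "galactose", i, 20.0 - np.log2(v), 20.0) for i, v in enumerate(g)]
        return normalized_table(
            pd.DataFrame(rows, columns=["gene", "group", "replicate", "ct_target", "ct_reference"])
        )

    def test_identical_replicates_p_one(self):
        table = self._table([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert group_test(table, "x", "treated") == 1.0

    def test_fixture_vectors_match_oracles(self):
        """[1.0, 1.1, 0.9] vs [2.0, 2.2, 1.8]: the Student p equals the
        closed-form pooled-t value and the split is the most extreme of the
        20 exhaustive permutations."""
        a = np.array([1.0, 1.1, 0.9])
        g = np.array([2.0, 2.2, 1.8])
        table = self._table(a, g)
        p = group_test(table, "x", "treated")
        assert p == pytest.approx(student_t_p(g, a), rel=1e-9)
        perm_p = exhaustive_permutation_p(a, g)
        assert perm_p == pytest.approx(2 / 20)
        assert p < perm_p  # agrees in direction, beyond the oracle's granularity

    def test_single_replicate_side_rejected(self):
        table = self._table([1.0], [2.0, 2.1, 1.9])
        with pytest.raises(DegenerateInputError):
            group_test(table, "x", "treated")


class TestConfirmation:
    def test_planted_patterns_confirm_expected_panels(self):
        """Noise-free Ct tables reproduce the planted confirmation pattern
        exactly: unchanged groups give p = 1, suppressed ones p -> 0."""
        expr = planted_confirmation_expression()
        table = simulate_qpcr(expr, groups=GROUPS, replicates=3, ct_noise_sd=0.0, seed=12)
        confirmed = confirm_candidates(table)
        assert confirmed["C646+CPTH2"].members == frozenset(COMBO1_GENES)
        assert confirmed["CBP30+CPTH2"].members == frozenset(COMBO2_GENES)
        assert confirmed["TH1834"].members == frozenset(TH1834_GENES)

    def test_all_groups_equal_galactose_confirm_nothing(self):
        expr = pd.DataFrame(2.0, index=["g1", "g2"], columns=list(GROUPS))
        table = simulate_qpcr(expr, groups=GROUPS, replicates=3, ct_noise_sd=0.05, seed=3)
        confirmed = confirm_candidates(table)
        assert all(len(s) == 0 for s in confirmed.values())

    def test_mono_significant_gene_excluded_from_combo(self):
        expr = planted_confirmation_expression()
        expr.loc["Stmn4", "C646"] = 1.0  # now also suppressed by the monotherapy
        table = simulate_qpcr(expr, groups=GROUPS, replicates=3, ct_noise_sd=0.0, seed=8)
        confirmed = confirm_candidates(table)
        assert "Stmn4" not in confirmed["C646+CPTH2"]
        assert "Acta1" in confirmed["C646+CPTH2"]

    def test_direction_enforced_not_just_p(self):
        expr = planted_confirmation_expression().loc[["Emd"]]
        expr.loc["Emd", "CBP30+CPTH2"] = 16.0  # significant *increase*
        table = simulate_qpcr(expr, groups=GROUPS, replicates=3, ct_noise_sd=0.0, seed=5)
        confirmed = confirm_candidates(table)
        assert "Emd" not in confirmed["CBP30+CPTH2"]

    def test_missing_monotherapy_group_is_config_error(self):
        expr = planted_confirmation_expression()
        groups = tuple(g for g in GROUPS if g != "CPTH2")
        table = simulate_qpcr(expr, groups=groups, replicates=3, ct_noise_sd=0.05, seed=2)
        with pytest.raises(ConfigurationError, match="CPTH2"):
            confirm_candidates(table)

    def test_end_to_end_truth_table_confirmation(self, sim400):
        """Genes planted as treatment-reversed confirm under every effective
        treatment; monotherapy-confounded genes confirm under none of the
        combos."""
        _, _, _, truth = sim400
        reversed_genes = truth.genes_of("galactose_up_reversed")[:5]
        confounded = truth.genes_of("monotherapy_confounded")[:5]
        table = simulate_qpcr(truth, groups=GROUPS, replicates=3, ct_noise_sd=0.1,
                              seed=9, genes=reversed_genes + confounded)
        res = QpcrExperiment(table).fit()
        for t in ("C646+CPTH2", "CBP30+CPTH2", "TH1834"):
            assert set(reversed_genes) <= res.confirmed[t].members
        for t in ("C646+CPTH2", "CBP30+CPTH2"):
            assert not set(confounded) & res.confirmed[t].members

    def test_results_summary_and_tests_frame(self):
        expr = planted_confirmation_expression().iloc[:3]
        table = simulate_qpcr(expr, groups=GROUPS, replicates=3, ct_noise_sd=0.05, seed=1)
        res = QpcrExperiment(table).fit()
        assert {"gene", "group", "mean_expression", "se", "p_vs_galactose"} <= set(res.tests.columns)
        assert "TH1834" in res.summary().as_text()
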