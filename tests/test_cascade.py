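import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lensgex import (
    GeneSet,
    ReversalCascade,
    assemble_candidates,
    day_overlap,
    fold_gate,
    intersect_replicate_sets,
    median_reversal_screen,
    monotherapy_subtraction,
    per_replicate_differential,
    reversal_screen,
)
from lensgex.cascade import median_probe_array
from lensgex.errors import ConfigurationError
from lensgex.io import CascadeConfig


def gs(name, members):
    return GeneSet(name, frozenset(members), [{"operation": "fixture", "params": {}}])


class TestSetAlgebra:
    def test_identical_sets_intersect_to_themselves(self):
        sets = [gs(n, {"a", "b", "c"}) for n in "ABC"]
        inter, venn = intersect_replicate_sets(sets)
        assert inter.members == frozenset({"a", "b", "c"})
        assert venn["A&B&C"] == 3
        assert venn["A"] == venn["B"] == venn["C"] == 0

    def test_disjoint_sets_partition_counts_sum(self):
        sets = [gs("A", {"a1", "a2"}), gs("B", {"b1"}), gs("C", {"c1", "c2", "c3"})]
        inter, venn = intersect_replicate_sets(sets)
        assert len(inter) == 0
        assert sum(venn.values()) == 6

    def test_day_overlap_subset_case(self):
        a, b = gs("A", {"x", "y"}), gs("B", {"x", "y", "z"})
        union, inter = day_overlap(a, b)
        assert union.members == b.members and inter.members == a.members

    @settings(max_examples=50, deadline=None)
    @given(st.sets(st.integers(0, 30)), st.sets(st.integers(0, 30)))
    def test_inclusion_exclusion_identity(self, a, b):
        """|A| + |B| = |A∪B| + |A∩B| for any pair of replicate-day sets."""
        sa, sb = gs("A", map(str, a)), gs("B", map(str, b))
        union, inter = day_overlap(sa, sb)
        assert len(sa) + len(sb) == len(union) + len(inter)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.sets(st.integers(0, 20)), min_size=2, max_size=4))
    def test_venn_partition_counts_cover_union(self, raw):
        sets = [gs(f"S{i}", map(str, s)) for i, s in enumerate(raw)]
        _, venn = intersect_replicate_sets(sets)
        union = set().union(*raw)
        assert sum(venn.values()) == len(union)

    def test_subtraction(self):
        combo = gs("combo", {"a", "b", "c", "d"})
        out = monotherapy_subtraction(combo, [gs("m1", {"b"}), gs("m2", {"c", "z"})])
        assert out.members == frozenset({"a", "d"})
        assert out.provenance[-1]["params"]["subtracted"] == 2

    def test_subtraction_empty_monos_is_identity(self):
        combo = gs("combo", {"a", "b"})
        assert monotherapy_subtraction(combo, []).members == combo.members

    def test_assemble_flags_and_overlap_bookkeeping(self):
        sets = {"t1": gs("t1", {"a", "b"}), "t2": gs("t2", {"b", "c"}), "t3": gs("t3", {"c"})}
        union, flags = assemble_candidates(sets)
        assert union.members == frozenset({"a", "b", "c"})
        # inclusion-exclusion bookkeeping: total memberships - union = shared count
        assert int(flags.to_numpy().sum()) - len(union) == 2
        assert flags.loc["b", "t1"] and flags.loc["b", "t2"] and not flags.loc["b", "t3"]

    def test_assemble_disjoint_sets_sums_sizes(self):
        sets = {"t1": gs("t1", {"a"}), "t2": gs("t2", {"b", "c"})}
        union, _ = assemble_candidates(sets)
        assert len(union) == 3


class TestScreens:
    def test_alpha_to_zero_empties_replicate_screen(self, sim400):
        _, probes, matrix, _ = sim400
        s = per_replicate_differential(matrix, probes, "control", "gal_d4_r1", 1e-12)
        assert len(s) == 0

    def test_null_design_replicate_screen_matches_binomial(self):
        """All-null simulation: hits at alpha within 3 binomial SDs of alpha*G."""
        from lensgex import SimulationDesign, simulate_microarray

        d = SimulationDesign(n_genes=1500, seed=21, class_sizes={})
        probes, matrix, _ = simulate_microarray(d)
        for alpha in (0.1, 0.05):
            s = per_replicate_differential(matrix, probes, "control", "gal_d4_r2", alpha)
            expect = alpha * 1500
            sd = np.sqrt(1500 * alpha * (1 - alpha))
            assert abs(len(s) - expect) <= 3 * sd

    def test_reversal_alpha_nesting(self, sim400):
        _, probes, matrix, _ = sim400
        sets = {a: reversal_screen(matrix, probes, "up", a) for a in (0.01, 0.05, 0.1)}
        assert sets[0.01].members <= sets[0.05].members <= sets[0.1].members

    def test_treatments_identical_to_galactose_give_empty_reversal(self, sim400):
        """If every galactose and effective-treatment array is the same array,
        nothing can qualify as reversed."""
        _, probes, matrix, _ = sim400
        clones = dict(probes)
        from lensgex.simulate import GALACTOSE_SAMPLES

        for s in (*GALACTOSE_SAMPLES, "C646+CPTH2", "CBP30+CPTH2", "TH1834"):
            clones[s] = type(probes[s])(s, probes["gal_d4_r1"].probes)
        s = reversal_screen(matrix, clones, "up", 0.1)
        assert len(s) == 0

    def test_reversal_recovers_planted_up_genes(self, sim400):
        _, probes, matrix, truth = sim400
        s = reversal_screen(matrix, probes, "up", 0.1)
        planted = set(truth.genes_of("galactose_up_reversed"))
        assert len(planted & s.members) / len(planted) >= 0.95

    def test_down_reversal_recovers_restored_genes(self, sim400):
        _, probes, matrix, truth = sim400
        s = reversal_screen(matrix, probes, "down", 0.1)
        planted = set(truth.genes_of("galactose_down_restored"))
        assert len(planted & s.members) / len(planted) >= 0.9

    def test_median_screen_recovers_planted_set_at_low_noise(self):
        from lensgex import SimulationDesign, simulate_microarray

        d = SimulationDesign(n_genes=300, seed=3, probe_sd=0.1,
                             class_sizes={"galactose_up_reversed": 25})
        probes, matrix, truth = simulate_microarray(d)
        s = median_reversal_screen(matrix, probes, 0.1)
        planted = frozenset(truth.genes_of("galactose_up_reversed"))
        # every planted gene recovered; null leakage (correlated via the
        # shared control array) stays below 2% of the universe
        assert planted <= s.members
        assert len(s.members - planted) <= 0.02 * d.n_genes

    def test_median_screen_constant_matrix_empty(self, sim400):
        _, probes, matrix, _ = sim400
        const = {k: type(v)(k, probes["control"].probes) for k, v in probes.items()}
        s = median_reversal_screen(matrix, const, 0.1)
        assert len(s) == 0

    def test_median_screen_requires_six_galactose_samples(self, sim400):
        _, probes, matrix, _ = sim400
        from lensgex.io import SignalMatrix

        keep = [s for s in matrix.sample_ids if s != "gal_d6_r3"]
        small = SignalMatrix(matrix.values[keep], matrix.sample_meta)
        with pytest.raises(ConfigurationError, match="galactose"):
            median_reversal_screen(small, probes, 0.1)

    def test_median_probe_array_is_per_probe_median(self, sim400):
        _, probes, _, _ = sim400
        gal = list(probes)[1:7]
        rep = median_probe_array(probes, gal)
        g = rep.probes.index[0]
        stacked = np.stack([probes[s].probes.loc[g].to_numpy() for s in gal])
        np.testing.assert_allclose(rep.probes.loc[g].to_numpy(), np.median(stacked, axis=0))


class TestFoldGate:
    def test_min_fold_one_keeps_everything(self, sim400):
        _, probes, matrix, truth = sim400
        s = gs("in", set(matrix.gene_ids[:50]))
        assert fold_gate(s, matrix, "TH1834", 1.0).members == s.members

    def test_known_folds_straddling_two(self, sim400):
        """Planted reversed genes drop ~2.8-fold under TH1834 and pass the
        2-fold gate; planted flat genes do not."""
        _, probes, matrix, truth = sim400
        reversed_genes = truth.genes_of("galactose_up_reversed")
        flat = truth.genes_of("early_plateau")
        s = gs("in", set(reversed_genes) | set(flat))
        out = fold_gate(s, matrix, "TH1834", 2.0)
        assert len(set(reversed_genes) & out.members) / len(reversed_genes) >= 0.9
        assert len(set(flat) & out.members) / len(flat) <= 0.1

    def test_missing_treatment_sample_is_config_error(self, sim400):
        _, _, matrix, _ = sim400
        with pytest.raises(ConfigurationError):
            fold_gate(gs("in", {"G00001"}), matrix, "nonexistent", 2.0)


class TestCascadeModel:
    def test_every_stage_within_universe(self, cascade400):
        results, _ = cascade400
        universe = set(results.filtered.gene_ids)
        for day_sets in results.replicate_sets.values():
            for s in day_sets:
                assert s.members <= universe
        for by_alpha in results.reversal.values():
            for s in by_alpha.values():
                assert s.members <= universe
        assert results.candidate_union.members <= universe

    def test_counts_equal_member_sizes(self, cascade400):
        results, _ = cascade400
        counts = results.stage_counts
        assert counts["candidates_union"] == len(results.candidate_union)
        for t, s in results.candidates.items():
            assert counts[f"candidates_{t}"] == len(s)

    def test_provenance_chains_nonempty(self, cascade400):
        results, _ = cascade400
        assert results.candidate_union.provenance
        for s in results.candidates.values():
            assert s.provenance

    def test_planted_sensitivity_and_confounder_exclusion(self, cascade400):
        results, truth = cascade400
        assert results.sensitivity(truth) >= 0.9
        assert results.confounder_specificity(truth) >= 0.9

    def test_combo_candidates_disjoint_from_mono_altered(self, cascade400):
        results, _ = cascade400
        for combo, monos in results.model.config.combo_components.items():
            for m in monos:
                assert not (results.candidates[combo].members & results.mono_altered[m].members)

    def test_gene_order_invariance(self, sim400):
        _, probes, matrix, _ = sim400
        from lensgex.io import ProbeLevelArray, SignalMatrix

        perm = list(reversed(matrix.gene_ids))
        shuffled_matrix = SignalMatrix(matrix.values.loc[perm], matrix.sample_meta)
        shuffled_probes = {k: ProbeLevelArray(k, v.probes.loc[perm]) for k, v in probes.items()}
        a = ReversalCascade(matrix, probes).fit()
        b = ReversalCascade(shuffled_matrix, shuffled_probes).fit()
        assert a.candidate_union.members == b.candidate_union.members
        assert a.stage_counts == b.stage_counts

    def test_summary_text_lists_stages(self, cascade400):
        results, _ = cascade400
        text = results.summary().as_text()
        assert "candidates_union" in text and "reversal_up_p0.1" in text
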