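import numpy as np
import pytest
from hypothesis import given, strategies as st

from numtclock import phylo_engine, substitution_mapping as sm
from numtclock.alignment import Alignment, SiteScoreTable
from numtclock.gtr import GTRModel
from numtclock.substitution_mapping import MappingError, MutationEvent, MutationSet
from numtclock.tree import Tree


@pytest.fixture
def simple_tree():
    return Tree.from_newick("((human:0.05,NUMT:0.1)anctr:0.05,chimp:0.1)luca;")


def reconstruct(tree, aln):
    return phylo_engine.marginal_ancestral_states(tree, aln, GTRModel())


class TestAssignMutations:
    def test_identical_sequences_give_no_events(self, simple_tree):
        aln = Alignment.from_sequences({"human": "ACGT", "NUMT": "ACGT", "chimp": "ACGT"})
        muts = sm.assign_mutations(simple_tree, reconstruct(simple_tree, aln), aln)
        assert len(muts) == 0

    def test_single_numt_substitution_assigned_to_numt_branch(self, simple_tree):
        aln = Alignment.from_sequences({"human": "C", "NUMT": "T", "chimp": "C"})
        muts = sm.assign_mutations(simple_tree, reconstruct(simple_tree, aln), aln)
        assert len(muts) == 1
        event = muts.events[0]
        assert (event.branch, event.from_state, event.to_state) == ("NUMT", "C", "T")

    def test_gap_columns_skipped_on_that_branch(self, simple_tree):
        aln = Alignment.from_sequences({"human": "C-", "NUMT": "-T", "chimp": "CC"})
        muts = sm.assign_mutations(simple_tree, reconstruct(simple_tree, aln), aln)
        assert all(e.branch != "NUMT" or e.column != 0 for e in muts.events)

    def test_event_count_bounded_by_columns(self, simple_tree):
        rng = np.random.default_rng(0)
        chars = np.array(list("ACGT"))
        aln = Alignment(
            ids=["human", "NUMT", "chimp"], data=chars[rng.integers(0, 4, (3, 50))]
        )
        muts = sm.assign_mutations(simple_tree, reconstruct(simple_tree, aln), aln)
        for branch in ("human", "NUMT", "chimp"):
            assert len(muts.on_branch(branch)) <= 50


class TestBinScore:
    @pytest.mark.parametrize(
        "score, expected",
        [(-9.75, "conserved"), (-2.45, "conserved"), (-2.44, "variable"), (4.87, "variable"), (0.0, "variable")],
    )
    def test_midpoint_binning(self, score, expected):
        assert sm.bin_score(score) == expected

    def test_out_of_range_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            assert sm.bin_score(-50.0) == "conserved"

    def test_non_finite_rejected(self):
        with pytest.raises(MappingError):
            sm.bin_score(float("nan"))


class TestColumnBins:
    def test_reference_gaps_have_no_bin(self):
        aln = Alignment.from_sequences({"ref": "A-CG", "x": "AACG"})
        table = SiteScoreTable(positions=[1, 2, 3], scores=[-5.0, 0.0, -9.0])
        bins = sm.column_bins(aln, "ref", table)
        assert bins == ["conserved", None, "variable", "conserved"]


class TestVariableFraction:
    def _events(self, cols):
        return [MutationEvent("NUMT", c, "A", "C") for c in cols]

    def test_arithmetic(self):
        bins = ["variable", "variable", "variable", "conserved"]
        assert sm.variable_fraction(self._events([0, 1, 2, 3]), bins) == 0.75

    def test_unscored_positions_excluded_with_warning(self):
        bins = ["variable", None, "conserved"]
        with pytest.warns(UserWarning):
            frac = sm.variable_fraction(self._events([0, 1, 2]), bins)
        assert frac == 0.5

    def test_zero_events_error(self):
        with pytest.raises(MappingError):
            sm.variable_fraction([], ["variable"])


class TestSimulatedPsdFraction:
    def test_entirely_variable_region(self):
        bins = ["variable"] * 30
        assert sm.simulated_psd_fraction(5, bins, n_sets=10, rng=0) == 1.0

    def test_matches_hypergeometric_expectation(self):
        """Mean over sets converges to the variable share of the region."""
        bins = ["variable"] * 60 + ["conserved"] * 40
        est = sm.simulated_psd_fraction(10, bins, n_sets=500, rng=1)
        se = np.sqrt(0.6 * 0.4 / 10) / np.sqrt(500)
        assert abs(est - 0.6) < 3 * se

    def test_more_events_than_region_rejected(self):
        with pytest.raises(MappingError):
            sm.simulated_psd_fraction(5, ["variable"] * 3, rng=0)

    def test_seed_determinism(self):
        bins = ["variable", "conserved"] * 20
        assert sm.simulated_psd_fraction(7, bins, rng=9) == sm.simulated_psd_fraction(7, bins, rng=9)


class TestMitoFraction:
    def test_pure_mitochondrial(self):
        assert sm.mito_fraction(0.8, 0.8, 0.2).f_mito == 1.0

    def test_pure_pseudogenic(self):
        assert sm.mito_fraction(0.2, 0.8, 0.2).f_mito == 0.0

    def test_midpoint(self):
        est = sm.mito_fraction(0.5, 0.8, 0.2)
        assert np.isclose(est.f_mito, 0.5)
        assert not est.clamped

    def test_clamped_below_zero(self):
        est = sm.mito_fraction(0.1, 0.8, 0.2)
        assert est.f_mito == 0.0 and est.clamped

    def test_degenerate_contrast_rejected(self):
        with pytest.raises(MappingError):
            sm.mito_fraction(0.5, 0.4, 0.4)

    def test_inverted_contrast_warns(self):
        with pytest.warns(UserWarning):
            sm.mito_fraction(0.5, 0.2, 0.8)

    @given(st.lists(st.floats(0.2, 0.8), min_size=2, max_size=2).map(sorted))
    def test_monotone_in_f_numt(self, pair):
        lo, hi = pair
        f_lo = sm.mito_fraction(lo, 0.9, 0.1).f_mito
        f_hi = sm.mito_fraction(hi, 0.9, 0.1).f_mito
        assert f_hi >= f_lo


class TestDetectHidden:
    @pytest.fixture
    def scenario(self):
        """An erroneous ancestral state manufactures a stem + reversion pair.

        All tips except the NUMT carry C at a conserved site; if 'anctr' is
        reconstructed as T, the events read T>C on the human branch and C>T
        on the stem - the true single C>T on the NUMT branch is hidden.
        """
        tree = Tree.from_newick(
            "((human:0.05,NUMT:0.1)anctr:0.05,chimp:0.1)luca;"
        )
        aln = Alignment.from_sequences({"human": "C", "NUMT": "T", "chimp": "C"})
        return tree, aln

    def _forced_ancestral(self, tree, aln, anctr_state_code):
        anc = reconstruct(tree, aln)
        anctr = tree.find("anctr")
        anc.states[anctr.index] = np.array([anctr_state_code], dtype=np.int8)
        luca = tree.find("luca")
        anc.states[luca.index] = np.array([1], dtype=np.int8)  # C
        return anc

    def test_hidden_substitution_reassigned_to_numt_branch(self, scenario):
        tree, aln = scenario
        anc = self._forced_ancestral(tree, aln, anctr_state_code=3)  # T, in error
        muts = sm.assign_mutations(tree, anc, aln)
        assert {e.branch for e in muts.events} == {"anctr", "human"}
        corrected = sm.detect_hidden(tree, anc, aln, muts, ["conserved"], "NUMT")
        assert len(corrected) == 1
        event = corrected.events[0]
        assert event.branch == "NUMT"
        assert (event.from_state, event.to_state) == ("C", "T")
        assert event.hidden_reassigned

    def test_correct_reconstruction_unchanged(self, scenario):
        tree, aln = scenario
        anc = self._forced_ancestral(tree, aln, anctr_state_code=1)  # C, correct
        muts = sm.assign_mutations(tree, anc, aln)
        corrected = sm.detect_hidden(tree, anc, aln, muts, ["conserved"], "NUMT")
        assert [e.branch for e in corrected.events] == ["NUMT"]
        assert not corrected.events[0].hidden_reassigned

    def test_variable_site_not_reassigned(self, scenario):
        tree, aln = scenario
        anc = self._forced_ancestral(tree, aln, anctr_state_code=3)
        muts = sm.assign_mutations(tree, anc, aln)
        corrected = sm.detect_hidden(tree, anc, aln, muts, ["variable"], "NUMT")
        assert {e.branch for e in corrected.events} == {"anctr", "human"}

    def test_tips_agreeing_with_numt_not_reassigned(self):
        tree = Tree.from_newick("((human:0.05,NUMT:0.1)anctr:0.05,chimp:0.1)luca;")
        aln = Alignment.from_sequences({"human": "T", "NUMT": "T", "chimp": "T"})
        anc = reconstruct(tree, aln)
        muts = sm.assign_mutations(tree, anc, aln)
        corrected = sm.detect_hidden(tree, anc, aln, muts, ["conserved"], "NUMT")
        assert len(corrected) == len(muts)

    def test_reassignment_shrinks_or_keeps_event_count(self, scenario):
        tree, aln = scenario
        anc = self._forced_ancestral(tree, aln, anctr_state_code=3)
        muts = sm.assign_mutations(tree, anc, aln)
        corrected = sm.detect_hidden(tree, anc, aln, muts, ["conserved"], "NUMT")
        assert len(corrected) <= len(muts)
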