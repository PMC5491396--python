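import json

import numpy as np
import pytest

from numtclock import synthetic_data as sd
from numtclock.alignment import Alignment
from numtclock.synthetic_data import ConfigurationError, SimulationConfig


@pytest.fixture(scope="module")
def small_config():
    return SimulationConfig(seq_length=600, seed=11)


@pytest.fixture(scope="module")
def small_dataset(small_config):
    return sd.simulate_dataset(small_config)


class TestConfigValidation:
    def test_insertion_after_branching_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(numt_insertion_time=5.0, numt_branch_time=4.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(mito_clock_rate=-0.01)

    def test_misordered_splits_rejected(self):
        times = sd._default_divergence_times()
        times["gorilla"] = 3.0
        with pytest.raises(ConfigurationError):
            SimulationConfig(divergence_times=times)

    def test_bad_conserved_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(conserved_site_fraction=1.2)


class TestSimulateDataset:
    def test_alignment_shape_and_taxa(self, small_config, small_dataset):
        aln, table, truth = small_dataset
        groups = small_config.taxon_groups()
        expected = set(groups.mtdna_ids) | {sd.NUMT_ID}
        assert set(aln.ids) == expected
        assert aln.n_columns == small_config.seq_length
        assert len(table.positions) == small_config.seq_length

    def test_seed_determinism(self, small_config, small_dataset):
        aln1, table1, truth1 = small_dataset
        aln2, table2, truth2 = sd.simulate_dataset(small_config)
        assert (aln1.data == aln2.data).all()
        assert (table1.scores == table2.scores).all()
        assert truth1.mutation_log == truth2.mutation_log

    def test_mutation_log_refers_to_real_branches_and_columns(self, small_dataset):
        aln, _, truth = small_dataset
        names = {n.name for n in truth.tree.postorder()}
        for event in truth.mutation_log:
            assert event.branch in names
            assert 0 <= event.column < aln.n_columns
            assert event.from_state != event.to_state

    def test_insertion_at_branching_time_gives_pure_pseudogene(self):
        cfg = SimulationConfig(
            seq_length=800, numt_insertion_time=4.5, numt_branch_time=4.5, seed=2
        )
        _, _, truth = sd.simulate_dataset(cfg)
        assert truth.true_mito_fraction == 0.0

    def test_insertion_at_present_gives_pure_mitochondrial(self):
        cfg = SimulationConfig(
            seq_length=800, numt_insertion_time=0.0, numt_branch_time=4.5, seed=2
        )
        _, _, truth = sd.simulate_dataset(cfg)
        assert truth.true_mito_fraction == 1.0

    def test_score_distributions_separate_site_classes(self, small_dataset):
        _, table, truth = small_dataset
        boundary = table.boundary
        conserved = truth.per_site_class == "conserved"
        assert (table.scores[conserved] < boundary).all()
        assert (table.scores[~conserved] >= boundary).all()

    def test_conserved_columns_accumulate_fewer_substitutions(self, small_dataset):
        """Purifying selection: pooled mito-branch events avoid conserved sites."""
        _, _, truth = small_dataset
        conserved = truth.per_site_class == "conserved"
        mito_events = [e for e in truth.mutation_log if e.regime == "mito"]
        hits = np.zeros(len(conserved))
        for e in mito_events:
            hits[e.column] += 1
        assert hits[conserved].mean() < hits[~conserved].mean()

    def test_substitution_counts_match_rate_times_duration(self):
        """Branch event counts agree with rate x duration x length (3 SE)."""
        counts = {"human_ref": [], "outgroup": []}
        cfg0 = SimulationConfig(seq_length=400)
        ages = cfg0.divergence_times
        for seed in range(120):
            cfg = SimulationConfig(seq_length=400, seed=seed)
            _, _, truth = sd.simulate_dataset(cfg)
            for name in counts:
                counts[name].append(len([e for e in truth.mutation_log if e.branch == name]))
        n_human_tips = cfg0.n_taxa_per_species + cfg0.n_ancient_humans
        groups_len = {
            # human_ref terminal branch ends at the first caterpillar join
            "human_ref": ages["human_tmrca"] / (n_human_tips - 1),
            "outgroup": ages["outgroup"],
        }
        pi = np.array(cfg0.gtr.base_freqs)

        def p_endpoint_differs(subs_per_site):
            P = cfg0.gtr.transition_probabilities(subs_per_site)
            return 1.0 - float(pi @ np.diag(P))

        csf, mult = cfg0.conserved_site_fraction, cfg0.conserved_rate_multiplier
        for name, duration in groups_len.items():
            lam = duration * cfg0.mito_clock_rate
            # the log records endpoint differences, so multiple hits collapse
            expected = 400 * (
                csf * p_endpoint_differs(lam * mult)
                + (1 - csf) * p_endpoint_differs(lam)
            )
            observed = np.mean(counts[name])
            se = np.std(counts[name], ddof=1) / np.sqrt(len(counts[name]))
            assert abs(observed - expected) < 3 * se + 0.02 * expected

    def test_gap_masking_applies_only_to_numt(self):
        cfg = SimulationConfig(seq_length=500, numt_gap_fraction=0.1, seed=4)
        aln, _, _ = sd.simulate_dataset(cfg)
        numt = aln.sequence(sd.NUMT_ID)
        assert numt.count("-") > 0
        assert aln.sequence("human_ref").count("-") == 0


class TestCohort:
    def test_cohort_sizes_and_truth(self):
        base = SimulationConfig(seq_length=300)
        cohort = sd.simulate_cohort(base, [1.0, 2.8, 4.9], seed=0)
        assert len(cohort) == 3
        times = [truth.insertion_time for _, _, truth in cohort]
        assert times == [1.0, 2.8, 4.9]
        # 4.9 exceeds the default branching time: branching moves with it
        assert cohort[2][2].numt_branch_time == 4.9

    def test_cohort_members_are_independent(self):
        base = SimulationConfig(seq_length=300)
        cohort = sd.simulate_cohort(base, [2.0, 2.0], seed=1)
        assert not (cohort[0][0].data == cohort[1][0].data).all()


class TestFixtureRoundTrip:
    def test_write_then_read_equal(self, small_dataset, tmp_path):
        aln, table, truth = small_dataset
        sd.write_fixture(small_dataset, tmp_path)
        aln2, table2, record = sd.read_fixture(tmp_path)
        assert (aln2.data == aln.data).all()
        assert aln2.ids == aln.ids
        assert np.allclose(table2.scores, table.scores)
        assert record["insertion_time"] == truth.insertion_time
        assert record["n_numt_events"] == len(truth.numt_events())

    def test_score_table_has_one_row_per_column(self, small_dataset, tmp_path):
        aln, _, _ = small_dataset
        sd.write_fixture(small_dataset, tmp_path)
        _, table, _ = sd.read_fixture(tmp_path)
        assert list(table.positions) == list(range(1, aln.n_columns + 1))

    def test_byte_identical_fixtures_for_same_seed(self, small_config, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        sd.write_fixture(sd.simulate_dataset(small_config), d1)
        sd.write_fixture(sd.simulate_dataset(small_config), d2)
        for name in ("alignment.fasta", "scores.tsv", "truth.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
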