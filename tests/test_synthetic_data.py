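import numpy as np
import pytest

from genesieve.sequence_io import FrameSpec, reverse_complement, translate
from genesieve.synthetic_data import (
    PseudogenizationEvent,
    SyntheticScenario,
    make_benchmark_suite,
    make_gene,
    make_reads,
    synthetic_query,
)


def cds_of(genomic: str, truth) -> str:
    return genomic[truth.cds_start : truth.cds_end]


class TestMakeGene:
    def test_zero_divergence_translation_equals_query(self, query):
        scen = SyntheticScenario(name="t", query_protein=query, seed=1)
        genomic, truth = make_gene(scen)
        peptide = translate(cds_of(genomic, truth), FrameSpec("+", 1))
        assert peptide == query.residues + "*"
        assert truth.true_state == "intact"

    def test_divergence_rate_reflected_in_protein(self, query):
        scen = SyntheticScenario(name="t", query_protein=query, aa_divergence=0.2, seed=2)
        _, truth = make_gene(scen)
        diffs = sum(a != b for a, b in zip(truth.diverged_protein, query.residues))
        # binomial(120, 0.2): a 5-sigma envelope around the mean of 24
        assert 4 <= diffs <= 46

    def test_segment_deletion_bookkeeping(self, query):
        n = len(query)
        span = (11, 11 + int(0.4 * n) - 1)
        scen = SyntheticScenario(
            name="t", query_protein=query,
            events=(PseudogenizationEvent("segment_deletion", span=span),), seed=3,
        )
        genomic, truth = make_gene(scen)
        assert truth.deleted_fraction == pytest.approx(0.4)
        assert truth.true_state == "degraded"
        assert len(cds_of(genomic, truth)) == 3 * (n - int(0.4 * n) + 1)

    def test_stop_gain_lands_at_requested_residue(self, query):
        scen = SyntheticScenario(
            name="t", query_protein=query,
            events=(PseudogenizationEvent("stop_gain", residue=50),), seed=4,
        )
        genomic, truth = make_gene(scen)
        peptide = translate(cds_of(genomic, truth), FrameSpec("+", 1))
        assert peptide[49] == "*"

    def test_frameshift_garbles_downstream_translation(self, query):
        scen = SyntheticScenario(
            name="t", query_protein=query,
            events=(PseudogenizationEvent("frameshift", nucleotide=150, indel=1),),
            seed=5,
        )
        genomic, truth = make_gene(scen)
        peptide = translate(cds_of(genomic, truth), FrameSpec("+", 1))
        assert peptide[:45] == query.residues[:45]
        downstream_matches = sum(
            a == b for a, b in zip(peptide[50:100], query.residues[50:100])
        )
        assert downstream_matches < 25

    def test_overlapping_events_rejected(self, query):
        with pytest.raises(ValueError, match="overlap"):
            make_gene(
                SyntheticScenario(
                    name="t", query_protein=query,
                    events=(
                        PseudogenizationEvent("segment_deletion", span=(10, 20)),
                        PseudogenizationEvent("stop_gain", residue=15),
                    ),
                )
            )

    def test_out_of_bounds_event_rejected(self, query):
        with pytest.raises(ValueError, match="out of bounds"):
            make_gene(
                SyntheticScenario(
                    name="t", query_protein=query,
                    events=(PseudogenizationEvent("stop_gain", residue=500),),
                )
            )

    def test_deterministic_under_seed(self, query):
        scen = SyntheticScenario(name="t", query_protein=query, aa_divergence=0.05, seed=9)
        assert make_gene(scen) == make_gene(scen)


class TestMakeReads:
    def test_zero_coverage_zero_reads(self, query):
        scen = SyntheticScenario(name="t", query_protein=query, coverage=0.0, seed=1)
        genomic, _ = make_gene(scen)
        assert make_reads(genomic, scen) == []

    def test_error_free_reads_are_exact_substrings(self, query):
        scen = SyntheticScenario(name="t", query_protein=query, coverage=30, seed=2)
        genomic, _ = make_gene(scen)
        for read in make_reads(genomic, scen):
            assert read.bases in genomic or reverse_complement(read.bases) in genomic

    def test_read_longer_than_sequence_rejected(self, query):
        scen = SyntheticScenario(
            name="t", query_protein=query, read_length=10_000, flank_length=10
        )
        genomic, _ = make_gene(scen)
        with pytest.raises(ValueError):
            make_reads(genomic, scen)

    def test_mean_depth_tracks_poisson_expectation(self, query):
        depths = []
        for seed in range(20):
            scen = SyntheticScenario(name="t", query_protein=query, coverage=20, seed=seed)
            genomic, _ = make_gene(scen)
            reads = make_reads(genomic, scen)
            depths.append(len(reads) * scen.read_length / len(genomic))
        expected = 20.0
        tol = 3 * np.sqrt(expected / len(depths))
        assert abs(np.mean(depths) - expected) < 3 * tol

    def test_deterministic_under_seed(self, query):
        scen = SyntheticScenario(
            name="t", query_protein=query, base_error_rate=0.01, seed=3
        )
        genomic, _ = make_gene(scen)
        assert make_reads(genomic, scen) == make_reads(genomic, scen)


class TestBenchmarkSuite:
    def test_composition_and_truth_table(self, tmp_path):
        results, truth = make_benchmark_suite(seed=0)
        assert len(results) == 20 and len(truth) == 20
        states = truth["true_state"].value_counts()
        assert states.get("intact", 0) >= 10
        assert states.get("degraded", 0) + states.get("lost", 0) >= 10

    def test_regeneration_is_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        make_benchmark_suite(out_dir=d1, seed=5)
        make_benchmark_suite(out_dir=d2, seed=5)
        files = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        assert files
        for rel in files:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()

    def test_total_loss_scenarios_have_no_coding_signal(self):
        results, _ = make_benchmark_suite(seed=1)
        lost = [(s, g, t) for s, g, t, _ in results if t.true_state == "lost"]
        assert lost
        for scen, genomic, truth in lost:
            assert truth.deleted_fraction == 1.0
            assert truth.expected_call == "likely_lost"
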