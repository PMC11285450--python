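import math

import numpy as np
import pytest

from genesieve.hit_profiling import build_profile, call_table, summarize_profile
from genesieve.sequence_io import SequenceRecord
from conftest import make_hit
from oracles import scan_profile

Q20 = SequenceRecord(id="q", residues="A" * 20)


class TestBuildProfile:
    def test_no_hits_leaves_everything_uncovered(self):
        prof = build_profile(Q20, [])
        assert not prof.covered.any()
        assert np.isnan(prof.best_identity).all()

    def test_full_span_perfect_hit(self):
        prof = build_profile(Q20, [make_hit(qstart=1, qend=20, identity=100.0)])
        assert prof.covered.all()
        assert (prof.best_identity == 100.0).all()

    def test_overlapping_hits_take_higher_identity(self):
        # A spans 1-10 at 80%, B spans 6-15 at 90% on a 20-residue query:
        # positions 1-5 -> 80, 6-15 -> 90, 16-20 uncovered, loss 25%
        hits = [
            make_hit(read_id="A", qstart=1, qend=10, identity=80.0),
            make_hit(read_id="B", qstart=6, qend=15, identity=90.0),
        ]
        prof = build_profile(Q20, hits)
        assert (prof.best_identity[0:5] == 80.0).all()
        assert (prof.best_identity[5:15] == 90.0).all()
        assert not prof.covered[15:].any()
        summ = summarize_profile(prof)
        assert summ.position_loss_percent == pytest.approx(25.0)
        # median of the multiset {80 x5, 90 x10}
        assert summ.median_best_identity == pytest.approx(90.0)

    def test_min_evalue_tracked_independently_of_best_identity(self):
        hits = [
            make_hit(read_id="hi_id", qstart=1, qend=10, identity=95.0, evalue=1e-3),
            make_hit(read_id="lo_id", qstart=1, qend=10, identity=60.0, evalue=1e-12),
        ]
        prof = build_profile(Q20, hits)
        assert (prof.best_identity[:10] == 95.0).all()
        assert (prof.min_evalue[:10] == 1e-12).all()

    def test_out_of_bounds_hit_names_offender(self):
        with pytest.raises(ValueError, match="badread"):
            build_profile(Q20, [make_hit(read_id="badread", qstart=15, qend=25)])

    def test_wrong_query_rejected(self):
        with pytest.raises(ValueError, match="other"):
            build_profile(Q20, [make_hit(query_id="other")])

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        hits = [
            make_hit(
                read_id=f"r{i}",
                qstart=int(rng.integers(1, 15)),
                qend=int(rng.integers(15, 21)),
                identity=float(rng.integers(30, 101)),
                evalue=float(10.0 ** -rng.integers(2, 12)),
            )
            for i in range(8)
        ]
        fwd = build_profile(Q20, hits)
        rev = build_profile(Q20, hits[::-1])
        np.testing.assert_array_equal(fwd.best_identity, rev.best_identity)
        np.testing.assert_array_equal(fwd.min_evalue, rev.min_evalue)

    def test_adding_hits_is_monotone(self):
        rng = np.random.default_rng(1)
        hits = []
        prev = build_profile(Q20, hits)
        for i in range(6):
            hits.append(
                make_hit(
                    read_id=f"r{i}",
                    qstart=int(rng.integers(1, 10)),
                    qend=int(rng.integers(10, 21)),
                    identity=float(rng.integers(30, 101)),
                )
            )
            cur = build_profile(Q20, hits)
            s_prev, s_cur = summarize_profile(prev), summarize_profile(cur)
            assert s_cur.position_loss_percent <= s_prev.position_loss_percent
            both = prev.covered & cur.covered
            assert (cur.best_identity[both] >= prev.best_identity[both]).all()
            prev = cur

    def test_matches_per_position_scan_oracle(self):
        rng = np.random.default_rng(2)
        query = SequenceRecord(id="q", residues="A" * 30)
        for _ in range(20):
            hits = []
            for i in range(int(rng.integers(0, 6))):
                a = int(rng.integers(1, 30))
                b = int(rng.integers(a, 31))
                hits.append(
                    make_hit(
                        read_id=f"r{i}",
                        qstart=a,
                        qend=b,
                        aln_len=b - a + 1,
                        identity=float(rng.integers(20, 101)),
                        evalue=float(10.0 ** -rng.integers(1, 15)),
                    )
                )
            prof = build_profile(query, hits)
            ref = scan_profile(30, hits)
            for p in range(30):
                assert prof.covered[p] == ref["covered"][p]
                if ref["covered"][p]:
                    assert prof.best_identity[p] == ref["best_identity"][p]
                    assert prof.min_evalue[p] == ref["min_evalue"][p]


class TestSummarize:
    def test_no_hits_gives_total_loss_and_undefined_median(self):
        summ = summarize_profile(build_profile(Q20, []))
        assert summ.position_loss_percent == 100.0
        assert math.isnan(summ.median_best_identity)

    def test_uniform_identity(self):
        summ = summarize_profile(
            build_profile(Q20, [make_hit(qstart=1, qend=20, identity=73.0)])
        )
        assert summ.median_best_identity == pytest.approx(73.0)

    def test_loss_as_zero_reading(self):
        prof = build_profile(Q20, [make_hit(qstart=1, qend=10, identity=80.0)])
        assert summarize_profile(prof).median_best_identity == pytest.approx(80.0)
        assert summarize_profile(prof, loss_as_zero=True).median_best_identity == pytest.approx(40.0)


class TestCallTable:
    def _summaries(self):
        prof = build_profile(Q20, [make_hit(qstart=1, qend=20, identity=95.0)])
        s = summarize_profile(prof)
        return {
            (sp, g): s for sp in ("mouse", "rat") for g in ("CD1a", "CD1b", "CD1d")
        }

    def test_full_grid(self):
        table = call_table(self._summaries())
        assert len(table) == 6
        assert set(table["call"]) == {"present"}

    def test_missing_combination_kept_as_na(self):
        summaries = self._summaries()
        del summaries[("rat", "CD1d")]
        table = call_table(summaries, species=["mouse", "rat"], genes=["CD1a", "CD1b", "CD1d"])
        row = table[(table.species == "rat") & (table.gene == "CD1d")].iloc[0]
        assert row["call"] == "NA" and math.isnan(row["median_identity"])

    def test_duplicate_key_rejected(self):
        s = summarize_profile(build_profile(Q20, []))
        with pytest.raises(ValueError, match="duplicate"):
            call_table([(("m", "CD1a"), s), (("m", "CD1a"), s)])

    def test_tsv_round_trip(self, tmp_path):
        import pandas as pd

        table = call_table(self._summaries())
        p = tmp_path / "calls.tsv"
        table.to_csv(p, sep="\t", index=False)
        back = pd.read_csv(p, sep="\t")
        assert back.equals(table)
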