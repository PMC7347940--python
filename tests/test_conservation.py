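"""Score-track reading, exon-set partitioning and conservation summaries."""

import numpy as np
import pytest

from conftest import make_tx
from _oracles import per_base_mean

from nmdscan.annotation_db import (
    DataError,
    GenomicInterval,
    TranscriptDatabase,
    extract_junction_labels,
)
from nmdscan.conservation import (
    ConservationConfig,
    ConservationTrack,
    conserved_fraction,
    load_score_track,
    mean_conservation,
    partition_exon_sets,
)
from nmdscan.event_catalog import classify_events, enumerate_events


def iv(start, end, chrom="chr1", strand="+"):
    return GenomicInterval(chrom, start, end, strand)


class TestTrack:
    def test_bedgraph_half_open_semantics(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t100\t110\t0.95\n")
        track = load_score_track(p)
        vals = track.scores(iv(99, 111))
        assert np.isnan(vals[0]) and np.isnan(vals[-1])
        assert (vals[1:-1] == 0.95).all()

    def test_adjacent_runs_boundary_base(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t0\t10\t0.2\nchr1\t10\t20\t0.8\n")
        track = load_score_track(p)
        assert track.scores(iv(10, 11))[0] == 0.8
        assert track.scores(iv(9, 10))[0] == 0.2

    def test_empty_track_has_no_data(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("")
        track = load_score_track(p)
        assert np.isnan(track.scores(iv(0, 50))).all()

    def test_fixed_wig_dialect(self, tmp_path):
        p = tmp_path / "t.wig"
        p.write_text("fixedStep chrom=chr1 start=101 step=1\n0.5\n0.6\n0.7\n")
        track = load_score_track(p, "fixed_wig")
        assert list(track.scores(iv(100, 103))) == [0.5, 0.6, 0.7]

    def test_overlapping_runs_rejected(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t0\t10\t0.2\nchr1\t5\t15\t0.8\n")
        with pytest.raises(DataError, match="overlap"):
            load_score_track(p)

    def test_score_outside_unit_interval_rejected(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t0\t10\t1.5\n")
        with pytest.raises(DataError, match="outside"):
            load_score_track(p)


class TestMean:
    def test_uniform_exon(self):
        track = ConservationTrack.from_runs([("chr1", 0, 100, 1.0)])
        mean, nodata = mean_conservation(iv(10, 20), track)
        assert mean == 1.0 and nodata == 0.0

    def test_two_half_scores_average(self):
        track = ConservationTrack.from_runs(
            [("chr1", 0, 5, 0.6), ("chr1", 5, 10, 1.0)]
        )
        mean, _ = mean_conservation(iv(0, 10), track)
        assert mean == pytest.approx(0.8)

    def test_outside_track_is_undefined(self):
        track = ConservationTrack.from_runs([("chr1", 0, 10, 0.5)])
        mean, nodata = mean_conservation(iv(100, 110), track)
        assert mean is None and nodata == 1.0

    def test_flank_extends_the_region(self):
        track = ConservationTrack.from_runs([("chr1", 0, 30, 0.3)])
        mean_noflank, _ = mean_conservation(iv(10, 20), track)
        track2 = ConservationTrack.from_runs(
            [("chr1", 0, 10, 0.9), ("chr1", 10, 20, 0.3), ("chr1", 20, 30, 0.9)]
        )
        mean_flank, _ = mean_conservation(iv(10, 20), track2, flank=10)
        assert mean_noflank == pytest.approx(0.3)
        assert mean_flank == pytest.approx((0.9 * 20 + 0.3 * 10) / 30)

    def test_matches_per_base_loop_oracle(self, rng):
        runs = []
        pos = 0
        for _ in range(60):
            pos += int(rng.integers(0, 15))
            width = int(rng.integers(1, 25))
            runs.append(("chr1", pos, pos + width, float(rng.uniform(0, 1))))
            pos += width
        track = ConservationTrack.from_runs(runs)
        for _ in range(500):
            start = int(rng.integers(0, pos))
            end = start + int(rng.integers(1, 40))
            interval = iv(start, end)
            got_mean, got_nodata = mean_conservation(interval, track)
            exp_mean, exp_nodata = per_base_mean(interval, runs)
            assert got_nodata == pytest.approx(exp_nodata)
            if exp_mean is None:
                assert got_mean is None
            else:
                assert got_mean == pytest.approx(exp_mean)


class TestPartition:
    def _db_and_events(self):
        # poison-exon gene + non-NMD cassette gene
        g1_inc = make_tx("G1.n", [(100, 200), (300, 400), (500, 600)],
                         gene="G1", biotype="nmd")
        g1_skip = make_tx("G1.p", [(100, 200), (500, 600)], gene="G1")
        g2_inc = make_tx("G2.a", [(1100, 1200), (1300, 1400), (1500, 1600)],
                         gene="G2")
        g2_skip = make_tx("G2.b", [(1100, 1200), (1500, 1600)], gene="G2")
        db = TranscriptDatabase([g1_inc, g1_skip, g2_inc, g2_skip])
        labels = extract_junction_labels(db)
        return db, classify_events(enumerate_events(db), labels)

    def test_three_sets_are_disjoint_and_complementary(self):
        db, pairs = self._db_and_events()
        part = partition_exon_sets(db, pairs)
        assert part.set1 == {iv(300, 400)}
        assert part.set2 == {iv(1300, 1400)}
        assert not part.set1 & part.set2
        assert not part.set1 & part.set3 and not part.set2 & part.set3
        # set3 holds every remaining protein-coding exon
        coding = {e for tx in db if tx.biotype == "protein_coding"
                  for e in tx.exons}
        assert part.set3 == coding - part.set1 - part.set2

    def test_nmd_membership_wins_over_cassette(self):
        # the same exon is EI_NMD under one flank pair and cassette under
        # another
        nmd_inc = make_tx("T1", [(0, 100), (300, 400), (600, 700)],
                          biotype="nmd")
        nmd_skip = make_tx("T2", [(0, 100), (600, 700)])
        cod_inc = make_tx("T3", [(40, 150), (300, 400), (550, 720)])
        cod_skip = make_tx("T4", [(40, 150), (550, 720)])
        db = TranscriptDatabase([nmd_inc, nmd_skip, cod_inc, cod_skip])
        labels = extract_junction_labels(db)
        pairs = classify_events(enumerate_events(db), labels)
        got = {label for _, label in pairs}
        assert got == {"EI_NMD", "cassette_exon"}
        part = partition_exon_sets(db, pairs)
        assert iv(300, 400) in part.set1
        assert iv(300, 400) not in part.set2

    def test_partition_holds_on_synthetic_databases(self):
        from nmdscan.synthetic_data import SimConfig, generate_annotation

        db, _ = generate_annotation(SimConfig(n_genes=30, seed=5))
        labels = extract_junction_labels(db)
        pairs = classify_events(enumerate_events(db), labels)
        part = partition_exon_sets(db, pairs)
        assert not part.set1 & part.set2
        assert not part.set1 & part.set3
        assert not part.set2 & part.set3


class TestConservedFraction:
    def test_all_conserved(self):
        track = ConservationTrack.from_runs([("chr1", 0, 100, 1.0)])
        frac, means = conserved_fraction([iv(0, 10), iv(20, 30)], track)
        assert frac == 1.0 and means == [1.0, 1.0]

    def test_threshold_zero_gives_one(self):
        track = ConservationTrack.from_runs([("chr1", 0, 100, 0.01)])
        frac, _ = conserved_fraction([iv(0, 10)], track,
                                     ConservationConfig(0.0))
        assert frac == 1.0

    def test_monotone_in_threshold(self, rng):
        runs = [("chr1", i * 10, i * 10 + 10, float(rng.uniform(0, 1)))
                for i in range(100)]
        track = ConservationTrack.from_runs(runs)
        exons = [iv(i * 10, i * 10 + 10) for i in range(100)]
        fracs = [conserved_fraction(exons, track, ConservationConfig(t))[0]
                 for t in (0.0, 0.3, 0.6, 0.9, 1.0)]
        assert fracs == sorted(fracs, reverse=True)

    def test_undefined_exons_excluded_from_denominator(self):
        track = ConservationTrack.from_runs([("chr1", 0, 10, 0.9)])
        frac, means = conserved_fraction([iv(0, 10), iv(500, 510)], track)
        assert frac == 1.0 and len(means) == 1

    def test_planted_exceedance_recovered(self):
        """Generator-planted 16% exceedance at threshold 0.8 is recovered
        from the written track within +/-0.03 at n=1000 exons."""
        from nmdscan.conservation import load_score_track
        from nmdscan.synthetic_data import (
            SimConfig, generate_annotation, simulate_track_and_tables,
        )

        mix = {"EI": 1.0, "ES": 0.0, "A3": 0.0, "A5": 0.0, "AI": 0.0,
               "none": 0.0}
        cfg = SimConfig(n_genes=1000, event_type_mix=mix, seed=3)
        db, truth = generate_annotation(cfg)
        runs, *_ = simulate_track_and_tables(truth, cfg, seed=4, db=db)
        track = ConservationTrack.from_runs(runs)
        set1 = [iv(s, e, chrom=c, strand=st)
                for name, c, s, e, st, _, _ in truth.conservation
                if name == "set1"]
        assert len(set1) == 1000
        frac, _ = conserved_fraction(set1, track, ConservationConfig(0.8))
        assert abs(frac - 0.16) <= 0.03
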