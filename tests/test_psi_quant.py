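"""PSI estimators, SJ.out.tab reading, filters and the gene catalog."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nmdscan.annotation_db import JunctionKey, extract_junction_labels
from nmdscan.event_catalog import classify_events, enumerate_events
from nmdscan.psi_quant import (
    CountTableError,
    FilterConfig,
    JunctionCountTable,
    PsiRecord,
    apply_filters,
    pool_count_tables,
    psi_alt_intron,
    psi_alt_ss,
    psi_cassette,
    quantify_sample,
    read_star_sj,
    records_to_frame,
    summarize_gene_catalog,
)

counts = st.integers(min_value=0, max_value=10**6)


class TestReadStarSj:
    def test_field_mapping(self, tmp_path):
        p = tmp_path / "sj.tab"
        p.write_text("chr1\t1001\t1100\t1\t0\t1\t7\t2\t38\n")
        table = read_star_sj(p, "S1")
        assert table.get(JunctionKey("chr1", 1000, 1100, "+")) == 7
        assert len(table) == 1

    def test_empty_file(self, tmp_path):
        p = tmp_path / "sj.tab"
        p.write_text("")
        assert len(read_star_sj(p, "S1")) == 0

    def test_strand_code_2_is_minus(self, tmp_path):
        p = tmp_path / "sj.tab"
        p.write_text("chr2\t501\t600\t2\t0\t1\t4\t0\t30\n")
        table = read_star_sj(p, "S1")
        assert table.get(JunctionKey("chr2", 500, 600, "-")) == 4
        assert table.get(JunctionKey("chr2", 500, 600, "+")) == 0

    def test_undefined_strand_matchable_only_when_allowed(self, tmp_path):
        p = tmp_path / "sj.tab"
        p.write_text("chr1\t101\t200\t0\t0\t0\t9\t0\t20\n")
        strict = read_star_sj(p, "S1")
        assert strict.get(JunctionKey("chr1", 100, 200, "+")) == 0
        lax = read_star_sj(p, "S1", allow_undefined_strand=True)
        assert lax.get(JunctionKey("chr1", 100, 200, "+")) == 9

    def test_wrong_column_count_raises(self, tmp_path):
        p = tmp_path / "sj.tab"
        p.write_text("chr1\t100\t200\t1\t0\t1\t5\n")
        with pytest.raises(CountTableError, match="9 columns"):
            read_star_sj(p, "S1")

    def test_negative_count_raises(self, tmp_path):
        p = tmp_path / "sj.tab"
        p.write_text("chr1\t100\t200\t1\t0\t1\t-5\t0\t38\n")
        with pytest.raises(CountTableError, match="negative"):
            read_star_sj(p, "S1")


class TestPsiFormulas:
    @pytest.mark.parametrize("inc,skip,orientation,expected", [
        (12, 3, "EI", 12 / 18),
        (12, 3, "ES", 1 - 12 / 18),
        (5, 0, "EI", 1.0),
        (0, 5, "EI", 0.0),
        (0, 0, "EI", None),
    ])
    def test_cassette(self, inc, skip, orientation, expected):
        got = psi_cassette(inc, skip, orientation)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected)

    @pytest.mark.parametrize("nmd,coding,expected", [
        (3, 97, 0.03),
        (0, 50, 0.0),
        (5, 0, 1.0),
        (0, 0, None),
    ])
    def test_alt_ss(self, nmd, coding, expected):
        got = psi_alt_ss(nmd, coding)
        assert got == expected if expected is not None else got is None

    @pytest.mark.parametrize("ai,p3,p5,expected", [
        (10, 8, 12, 1.0),   # numerator meets the expression estimate
        (0, 8, 12, 0.0),    # full intron retention
        (25, 8, 12, 1.0),   # clipping branch
        (5, 8, 12, 0.5),
        (3, 0, 0, None),
    ])
    def test_alt_intron(self, ai, p3, p5, expected):
        got = psi_alt_intron(ai, p3, p5)
        assert got == expected if expected is not None else got is None

    @given(inc=counts, skip=counts)
    def test_complementarity_and_bounds(self, inc, skip):
        ei = psi_cassette(inc, skip, "EI")
        es = psi_cassette(inc, skip, "ES")
        if inc + skip == 0:
            assert ei is None and es is None
        else:
            assert 0.0 <= ei <= 1.0
            assert ei + es == pytest.approx(1.0)

    @given(nmd=counts, coding=counts, ai=counts, p3=counts, p5=counts)
    def test_all_estimators_bounded(self, nmd, coding, ai, p3, p5):
        for v in (psi_alt_ss(nmd, coding), psi_alt_intron(ai, p3, p5)):
            assert v is None or 0.0 <= v <= 1.0


def _record(psi, nmd_count, label="EI_NMD"):
    return PsiRecord("E", "S", "G", label, psi=psi, nmd_role_count=nmd_count)


class TestFilters:
    @pytest.mark.parametrize("psi,nmd_count,expected_pass,reason", [
        (0.05, 2, False, "min_reads"),
        (0.030, 3, True, None),          # both thresholds inclusive
        (0.0299, 3, False, "min_psi"),
        (None, 10, False, "zero_denominator"),
        (0.5, 3, True, None),
    ])
    def test_threshold_boundaries(self, psi, nmd_count, expected_pass, reason):
        (rec,) = apply_filters([_record(psi, nmd_count)], FilterConfig())
        assert rec.passed_filters is expected_pass
        if reason:
            assert reason in rec.fail_reasons

    def test_monotone_in_thresholds(self, rng):
        records = [
            _record(float(rng.uniform(0, 0.2)), int(rng.integers(0, 10)))
            for _ in range(200)
        ]
        passing = []
        for min_psi, min_reads in [(0.0, 0), (0.03, 3), (0.05, 3), (0.05, 6)]:
            apply_filters(records, FilterConfig(min_reads, min_psi))
            passing.append(sum(r.passed_filters for r in records))
        assert passing == sorted(passing, reverse=True)


class TestQuantify:
    def test_se_counts_and_aggregation(self, cassette_gene_db):
        labels = extract_junction_labels(cassette_gene_db)
        pairs = classify_events(enumerate_events(cassette_gene_db), labels)
        table = JunctionCountTable("S1", {
            JunctionKey("chr1", 400, 500, "+"): 4,   # upstream inclusion
            JunctionKey("chr1", 600, 700, "+"): 8,   # downstream inclusion
            JunctionKey("chr1", 400, 700, "+"): 3,   # skipping
        })
        (rec,) = quantify_sample(pairs, table, labels=labels)
        assert rec.counts == {"sj_inc": 12, "sj_skip": 3}
        assert rec.psi == pytest.approx(12 / 18)
        assert rec.nmd_role_count == 12
        assert rec.passed_filters

    def test_unobserved_event_is_undefined(self, cassette_gene_db):
        labels = extract_junction_labels(cassette_gene_db)
        pairs = classify_events(enumerate_events(cassette_gene_db), labels)
        (rec,) = quantify_sample(pairs, JunctionCountTable("S1"), labels=labels)
        assert rec.psi is None
        assert not rec.passed_filters
        assert "zero_denominator" in rec.fail_reasons

    def test_pooled_counts_mode(self):
        jk = JunctionKey("chr1", 100, 200, "+")
        pooled = pool_count_tables([
            JunctionCountTable("A", {jk: 3}),
            JunctionCountTable("B", {jk: 4}),
        ])
        assert pooled.get(jk) == 7


class TestCatalog:
    def _frame(self):
        records = [
            PsiRecord("E1", "S1", "G1", "EI_NMD", psi=0.2, nmd_role_count=9,
                      passed_filters=True),
            PsiRecord("E1", "S2", "G1", "EI_NMD", psi=0.4, nmd_role_count=9,
                      passed_filters=True),
            PsiRecord("E2", "S1", "G1", "AI_NMD", psi=0.1, nmd_role_count=5,
                      passed_filters=True),
            PsiRecord("E3", "S1", "G2", "ES_NMD", psi=0.01, nmd_role_count=5,
                      passed_filters=False, fail_reasons=["min_psi"]),
        ]
        return records_to_frame(records)

    def test_gene_counted_once_across_event_types(self):
        catalog, summary = summarize_gene_catalog(self._frame())
        assert summary["unique_genes"] == 1
        assert summary["genes_per_event_type"]["EI_NMD"] == 1
        assert summary["genes_per_event_type"]["AI_NMD"] == 1

    def test_reported_psi_is_max_across_samples(self):
        catalog, _ = summarize_gene_catalog(self._frame())
        e1 = catalog[catalog.event_id == "E1"]
        assert float(e1.max_psi.iloc[0]) == pytest.approx(0.4)
        assert int(e1.n_passing_samples.iloc[0]) == 2

    def test_failing_records_never_catalogued(self):
        catalog, summary = summarize_gene_catalog(self._frame())
        assert "E3" not in set(catalog.event_id)
        assert summary["genes_per_event_type"]["ES_NMD"] == 0

    def test_empty_input_gives_empty_catalog(self):
        catalog, summary = summarize_gene_catalog(records_to_frame([]))
        assert len(catalog) == 0 and summary["unique_genes"] == 0

    def test_disease_flags_counted_once(self):
        catalog, summary = summarize_gene_catalog(
            self._frame(), disease_flags={"G1": True}
        )
        assert summary["unique_disease_genes"] == 1


class TestEstimatorConsistency:
    @pytest.mark.parametrize("psi_true", [0.05, 0.3, 0.89])
    def test_mean_psi_converges_under_chx(self, psi_true):
        """With NMD blocked and deep coverage the PSI estimators are
        unbiased for the true splicing fraction."""
        from nmdscan.synthetic_data import (
            SimConfig, generate_annotation, simulate_counts,
        )

        mix = {"EI": 0.3, "ES": 0.2, "A3": 0.2, "A5": 0.2, "AI": 0.1, "none": 0.0}
        cfg = SimConfig(n_genes=15, event_type_mix=mix, psi_fixed=psi_true,
                        chx=True, depth=1e5, seed=11)
        db, truth = generate_annotation(cfg)
        labels = extract_junction_labels(db)
        pairs = classify_events(enumerate_events(db), labels)
        table = simulate_counts(truth, cfg, "S", seed=13, chx=True)
        recs = quantify_sample(pairs, table, FilterConfig(min_psi=0.0),
                               labels=labels)
        psis = [r.psi for r in recs if r.psi is not None]
        assert len(psis) == 15
        assert abs(float(np.mean(psis)) - psi_true) < 0.02
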