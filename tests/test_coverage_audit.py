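"""Per-base coverage audit: interval arithmetic, failed-base classification,
per-gene aggregation and the published benchmark arithmetic."""

import numpy as np
import pytest

from famexome.coverage_audit import (
    AuditConfig,
    BaseTrack,
    GeneIntervals,
    audit_gene,
    benchmark_reports,
    build_ccds_splice_intervals,
    classify_base,
    genes_exceeding,
    load_coverage_benchmark,
    overall_failed_fraction,
    percent,
    round_half_up,
)

CFG = AuditConfig()


class TestIntervalConstruction:
    def test_single_exon_flank_10(self):
        gi = build_ccds_splice_intervals("G", [("1", 100, 200)], flank=10)
        assert gi.intervals == [("1", 90, 210)]
        assert gi.total_bases == 121

    def test_overlapping_expansions_merge_without_double_count(self):
        gi = build_ccds_splice_intervals("G", [("1", 100, 150), ("1", 160, 200)], flank=10)
        assert gi.intervals == [("1", 90, 210)]
        assert gi.total_bases == 121

    def test_empty_exon_list(self):
        assert build_ccds_splice_intervals("G", [], flank=10).total_bases == 0

    def test_invalid_exon_rejected(self):
        with pytest.raises(ValueError):
            build_ccds_splice_intervals("G", [("1", 200, 100)], flank=10)

    def test_flank_clamped_at_chromosome_start(self):
        gi = build_ccds_splice_intervals("G", [("1", 5, 20)], flank=10)
        assert gi.intervals == [("1", 1, 30)]

    def test_idempotent_on_merged_intervals_with_zero_flank(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, 6))
            exons = []
            pos = 1
            for _ in range(n):
                start = pos + int(rng.integers(0, 50))
                end = start + int(rng.integers(0, 100))
                exons.append(("3", start, end))
                pos = end + int(rng.integers(2, 60))
            gi = build_ccds_splice_intervals("G", exons, flank=7)
            again = build_ccds_splice_intervals("G", gi.intervals, flank=0)
            assert again.intervals == gi.intervals

    def test_union_equals_base_set_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            exons = []
            for _ in range(int(rng.integers(1, 6))):
                start = int(rng.integers(1, 400))
                exons.append(("5", start, start + int(rng.integers(0, 80))))
            flank = int(rng.integers(1, 15))
            gi = build_ccds_splice_intervals("G", exons, flank=flank)
            explicit = set()
            for _, s, e in exons:
                explicit.update(range(max(1, s - flank), e + flank + 1))
            assert gi.total_bases == len(explicit)
            assert {p for _, p in gi.bases()} == explicit


class TestClassifyBase:
    @pytest.mark.parametrize("depth,qual,failed", [
        (9, 500.0, True),     # one read short of the depth floor
        (10, 50.0, False),    # both thresholds met exactly
        (1000, 49.9, True),   # quality alone fails the base
        (0, 0.0, True),
    ])
    def test_threshold_boundaries(self, depth, qual, failed):
        assert classify_base(depth, qual, CFG) is failed

    def test_absent_quality_is_failed(self):
        assert classify_base(30, None, CFG) is True
        assert classify_base(None, 100.0, CFG) is True


def _track(base_values):
    return BaseTrack({(c, p): v for (c, p), v in base_values.items()})


class TestAuditGene:
    def test_all_bases_passed(self):
        gi = build_ccds_splice_intervals("G", [("1", 100, 120)], flank=10)
        track = _track({("1", p): (60, 900.0) for p in range(90, 131)})
        rep = audit_gene(gi, {"s1": track, "s2": track}, CFG)
        assert rep.failed_all_samples == 0
        assert rep.pct_all_samples == 0.0
        assert all(v == 0 for v in rep.failed_per_sample.values())

    def test_absent_bases_count_as_failed(self):
        gi = build_ccds_splice_intervals("G", [("1", 100, 109)], flank=10)
        # track covers only half the 30-base region
        track = _track({("1", p): (60, 900.0) for p in range(90, 105)})
        rep = audit_gene(gi, {"s1": track}, CFG)
        assert rep.failed_per_sample["s1"] == 15

    def test_chromosome_mismatch_raises(self):
        gi = build_ccds_splice_intervals("G", [("1", 100, 109)], flank=10)
        track = _track({("chr9", 100): (60, 900.0)})
        with pytest.raises(ValueError, match="no data on chromosome"):
            audit_gene(gi, {"s1": track}, CFG)

    def test_chr_prefix_is_not_a_mismatch(self):
        gi = build_ccds_splice_intervals("G", [("chr1", 100, 100)], flank=10)
        track = _track({("1", p): (60, 900.0) for p in range(90, 111)})
        rep = audit_gene(gi, {"s1": track}, CFG)
        assert rep.failed_per_sample["s1"] == 0

    def test_matches_brute_force_oracle_on_random_models(self):
        """audit_gene equals an explicit per-base loop on random small genes."""
        rng = np.random.default_rng(42)
        for trial in range(300):
            exons = []
            pos = 1
            for _ in range(int(rng.integers(1, 6))):
                start = pos + int(rng.integers(0, 30))
                end = start + int(rng.integers(0, 99))
                exons.append(("2", start, end))
                pos = end + int(rng.integers(2, 40))
            gi = build_ccds_splice_intervals("G", exons, flank=int(rng.integers(1, 12)))
            samples = [f"s{i}" for i in range(int(rng.integers(1, 4)))]
            tracks = {}
            raw = {}
            for s in samples:
                vals = {}
                for chrom, p in gi.bases():
                    if rng.random() < 0.9:  # 10% of bases have no record
                        vals[(chrom, p)] = (int(rng.integers(0, 30)),
                                            float(rng.integers(0, 200)))
                tracks[s] = _track(vals)
                raw[s] = vals
            rep = audit_gene(gi, tracks, CFG)
            # brute force
            expected_per_sample = {s: 0 for s in samples}
            expected_all = 0
            for chrom, p in gi.bases():
                fails = []
                for s in samples:
                    rec = raw[s].get((chrom, p))
                    failed = rec is None or rec[0] < 10 or rec[1] < 50
                    fails.append(failed)
                    if failed:
                        expected_per_sample[s] += 1
                if all(fails):
                    expected_all += 1
            assert rep.failed_per_sample == expected_per_sample, f"trial {trial}"
            assert rep.failed_all_samples == expected_all, f"trial {trial}"

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(3)
        gi = build_ccds_splice_intervals("G", [("1", 100, 400)], flank=10)
        track = _track({("1", p): (int(rng.integers(0, 40)), float(rng.integers(0, 120)))
                        for _, p in gi.bases()})
        loose = audit_gene(gi, {"s": track}, AuditConfig(depth_min=5, qual_min=20))
        strict = audit_gene(gi, {"s": track}, AuditConfig(depth_min=15, qual_min=80))
        assert strict.failed_per_sample["s"] >= loose.failed_per_sample["s"]
        assert strict.failed_all_samples >= loose.failed_all_samples

    def test_all_samples_failed_bounded_by_each_sample(self, small_bundle):
        truth = small_bundle.manifest["coverage_truth"]
        for gene, rec in truth.items():
            for count in rec["failed_per_sample"].values():
                assert rec["failed_all_samples"] <= count <= rec["total_bases"]


class TestRounding:
    def test_half_up_not_bankers(self):
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(30.175, 2) == 30.18

    def test_percent_exact_decimal_division(self):
        assert percent(975, 1045) == 93.30
        assert percent(672, 2227) == 30.18
        assert percent(223, 588) == 37.93


class TestBenchmarkArithmetic:
    """The published 24-gene coverage table is reproduced from its counts."""

    def test_every_printed_all_cases_pct_recomputes(self):
        df = load_coverage_benchmark()
        assert len(df) == 24
        for row in df.itertuples(index=False):
            assert percent(int(row.failed_all_cases), int(row.total_bases)) == \
                pytest.approx(float(row.pct_all_cases), abs=1e-9), row.gene

    def test_threshold_30_any_sample_selects_all_24(self):
        reports = benchmark_reports()
        assert len(genes_exceeding(reports, 30.0, "any-sample")) == 24

    def test_threshold_30_all_samples_selects_the_8_never_covered(self):
        reports = benchmark_reports()
        assert genes_exceeding(reports, 30.0, "all-samples") == [
            "BIN1", "CRYAB", "DES", "FKRP", "KBTBD13", "PABPN1", "PLEC", "SMN1"]

    def test_threshold_above_100_selects_none(self):
        assert genes_exceeding(benchmark_reports(), 101.0, "any-sample") == []


class TestOverallFailedFraction:
    def test_simple_arithmetic(self):
        from famexome.coverage_audit import GeneCoverageReport
        r1 = GeneCoverageReport.from_counts("A", 10, {"s": 1}, 1)
        r2 = GeneCoverageReport.from_counts("B", 10, {"s": 0}, 0)
        assert overall_failed_fraction([r1, r2]) == 5.0

    def test_fully_failed_gene_set(self):
        from famexome.coverage_audit import GeneCoverageReport
        r = GeneCoverageReport.from_counts("A", 50, {"s": 50}, 50)
        assert overall_failed_fraction([r]) == 100.0

    def test_zero_bases_rejected(self):
        with pytest.raises(ValueError):
            overall_failed_fraction([])

    def test_synthetic_gene_set_matches_planted_counts(self, small_bundle):
        """Global fraction equals brute-force arithmetic over the planted truth."""
        from decimal import Decimal, ROUND_HALF_UP
        from famexome.coverage_audit import GeneCoverageReport
        truth = small_bundle.manifest["coverage_truth"]
        reports = [GeneCoverageReport.from_counts(
            g, rec["total_bases"], rec["failed_per_sample"], rec["failed_all_samples"])
            for g, rec in truth.items()]
        total = sum(r["total_bases"] for r in truth.values())
        failed = sum(r["failed_all_samples"] for r in truth.values())
        expected = float((Decimal(failed * 100) / Decimal(total))
                         .quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
        assert overall_failed_fraction(reports) == expected
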