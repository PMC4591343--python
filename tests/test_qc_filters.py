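"""Hard filters, genotype-quality filtering, and exon proximity."""

import numpy as np
import pytest

from quartet_prioritizer import (
    DEFAULT_INDEL_FILTER,
    DEFAULT_SNV_FILTER,
    ExonIntervalMap,
    FormatError,
    Genotype,
    GenotypeCall,
    HardFilterExpr,
    QcConfig,
    SamplesRequired,
    apply_hard_filters,
    filter_exon_proximity,
    filter_genotype_quality,
    make_site,
)
from conftest import make_calls

SNV_EXPR = HardFilterExpr.parse(DEFAULT_SNV_FILTER)
INDEL_EXPR = HardFilterExpr.parse(DEFAULT_INDEL_FILTER)


def oracle_fails(expr: HardFilterExpr, metrics: dict) -> bool:
    """Brute-force clause loop, independent of HardFilterExpr.fails."""
    for name, cmp, thr in expr.clauses:
        if name in metrics:
            if cmp == "<" and metrics[name] < thr:
                return True
            if cmp == ">" and metrics[name] > thr:
                return True
    return False


class TestHardFilterExpr:
    def test_parse_default_snv_expression(self):
        assert SNV_EXPR.clauses == (
            ("QD", "<", 2.0),
            ("MQ", "<", 40.0),
            ("FS", ">", 60.0),
            ("HaplotypeScore", ">", 13.0),
            ("MQRankSum", "<", -12.5),
            ("ReadPosRankSum", "<", -8.0),
        )

    def test_unknown_comparator_fatal_at_parse_time(self):
        with pytest.raises(FormatError):
            HardFilterExpr.parse("QD >= 2.0")

    def test_low_qd_fails_with_all_other_metrics_absent(self):
        site = make_site("chr1", 100, "A", "G", info_metrics={"QD": 1.9})
        passed, failed = apply_hard_filters([site], SNV_EXPR, INDEL_EXPR)
        assert failed == [site]

    def test_metrics_exactly_at_thresholds_pass(self):
        """Strict inequalities: boundary values never trip a clause."""
        site = make_site(
            "chr1", 100, "A", "G",
            info_metrics={"QD": 2.0, "MQ": 40.0, "FS": 60.0, "HaplotypeScore": 13.0,
                          "MQRankSum": -12.5, "ReadPosRankSum": -8.0},
        )
        passed, _ = apply_hard_filters([site], SNV_EXPR, INDEL_EXPR)
        assert passed == [site]

    def test_missing_metrics_never_trigger_failure(self):
        site = make_site("chr1", 100, "A", "G")  # no metrics at all
        passed, _ = apply_hard_filters([site], SNV_EXPR, INDEL_EXPR)
        assert passed == [site]

    def test_indels_use_the_indel_expression(self):
        # MQ 10 fails the SNV expression but is not in the indel expression
        site = make_site("chr1", 100, "A", "AG", info_metrics={"MQ": 10.0})
        passed, _ = apply_hard_filters([site], SNV_EXPR, INDEL_EXPR)
        assert passed == [site]

    def test_partition_matches_per_clause_oracle_on_random_sites(self):
        """1,000 random sites: partition equals the brute-force clause loop."""
        rng = np.random.default_rng(42)
        ranges = {"QD": (0, 10), "MQ": (20, 60), "FS": (0, 250),
                  "HaplotypeScore": (0, 30), "MQRankSum": (-25, 5), "ReadPosRankSum": (-25, 5)}
        sites = []
        for i in range(1000):
            metrics = {
                m: float(np.round(rng.uniform(*ranges[m]), 3))
                for m in ranges if rng.random() > 0.3
            }
            alt = "G" if rng.random() < 0.8 else "GT"
            sites.append(make_site("chr1", i + 1, "A", alt, info_metrics=metrics))
        passed, failed = apply_hard_filters(sites, SNV_EXPR, INDEL_EXPR)
        assert set(s.key for s in passed) | set(s.key for s in failed) == {s.key for s in sites}
        assert not (set(s.key for s in passed) & set(s.key for s in failed))
        for s in sites:
            expr = SNV_EXPR if len(s.alt_allele) == 1 else INDEL_EXPR
            expected_fail = oracle_fails(expr, dict(s.info_metrics))
            assert (s in failed) == expected_fail

    def test_idempotent_on_own_pass_list(self):
        rng = np.random.default_rng(0)
        sites = [
            make_site("chr1", i + 1, "A", "G", info_metrics={"QD": float(rng.uniform(0, 10))})
            for i in range(100)
        ]
        passed, _ = apply_hard_filters(sites, SNV_EXPR, INDEL_EXPR)
        again, none_failed = apply_hard_filters(passed, SNV_EXPR, INDEL_EXPR)
        assert again == passed and none_failed == []


class TestGenotypeQuality:
    def _records(self, calls):
        return [(make_site("chr1", 100, "A", "G"), calls)]

    def test_confident_quartet_retained(self, quartet):
        calls = make_calls(Genotype.HET, Genotype.HET, Genotype.HOM_ALT, Genotype.HOM_ALT)
        assert len(filter_genotype_quality(self._records(calls), quartet)) == 1

    def test_one_low_gq_child_removes_site_under_all_samples(self, quartet):
        calls = make_calls(Genotype.HET, Genotype.HET, Genotype.HOM_ALT, Genotype.HOM_ALT)
        calls["CHILD1"] = GenotypeCall("CHILD1", Genotype.HOM_ALT, gq=19, dp=40)
        assert filter_genotype_quality(self._records(calls), quartet) == []

    def test_affected_only_scope_ignores_parents(self, quartet):
        calls = make_calls(Genotype.HET, Genotype.HET, Genotype.HOM_ALT, Genotype.HOM_ALT)
        calls["FATHER"] = GenotypeCall("FATHER", Genotype.HET, gq=5, dp=2)
        cfg = QcConfig(samples_required=SamplesRequired.AFFECTED_ONLY)
        assert len(filter_genotype_quality(self._records(calls), quartet, cfg)) == 1

    def test_missing_genotype_removes_site(self, quartet):
        calls = make_calls(Genotype.MISSING, Genotype.HET, Genotype.HOM_ALT, Genotype.HOM_ALT)
        assert filter_genotype_quality(self._records(calls), quartet) == []

    def test_absent_pedigree_sample_fatal(self, quartet):
        calls = make_calls(Genotype.HET, Genotype.HET, Genotype.HOM_ALT, Genotype.HOM_ALT)
        del calls["CHILD2"]
        with pytest.raises(FormatError, match="CHILD2"):
            filter_genotype_quality(self._records(calls), quartet)

    def test_retained_count_matches_exhaustive_oracle(self, quartet):
        """500 random sites: per-sample brute-force check agrees."""
        rng = np.random.default_rng(11)
        records = []
        for i in range(500):
            calls = {
                s: GenotypeCall(
                    s,
                    Genotype.HET if rng.random() > 0.05 else Genotype.MISSING,
                    gq=int(rng.integers(0, 100)),
                    dp=int(rng.integers(0, 80)),
                )
                for s in quartet.all_ids
            }
            records.append((make_site("chr1", i + 1, "A", "G"), calls))
        kept = filter_genotype_quality(records, quartet)
        expected = [
            (site, calls)
            for site, calls in records
            if all(
                calls[s].alleles is not Genotype.MISSING
                and calls[s].gq >= 20
                and calls[s].dp >= 15
                for s in quartet.all_ids
            )
        ]
        assert kept == expected


class TestExonProximity:
    EXONS = ExonIntervalMap({"chr1": [(100, 200)]})

    def test_inside_exon_passes(self):
        site = make_site("chr1", 101, "A", "G")
        assert filter_exon_proximity([site], self.EXONS) == [site]

    def test_boundary_arithmetic_brute_force(self):
        """Every pos in 80..240 against first-principles base counting."""
        for pos in range(80, 241):
            site = make_site("chr1", pos, "A", "G")
            kept = filter_exon_proximity([site], self.EXONS, max_dist_bp=10)
            exon_bases = set(range(101, 201))  # 1-based bases of [100,200)
            gap = 0 if pos in exon_bases else min(abs(pos - b) for b in exon_bases) - 1
            assert (kept == [site]) == (gap <= 10), f"pos={pos} gap={gap}"

    def test_frozen_boundary_examples(self):
        pass_site = make_site("chr1", 90, "A", "G")
        fail_site = make_site("chr1", 89, "A", "G")
        assert filter_exon_proximity([pass_site], self.EXONS) == [pass_site]
        assert filter_exon_proximity([fail_site], self.EXONS) == []

    def test_chromosome_without_intervals_fails_all(self):
        site = make_site("chr9", 100, "A", "G")
        assert filter_exon_proximity([site], self.EXONS) == []

    def test_snv_only_mode_exempts_indels(self):
        indel = make_site("chr9", 100, "A", "AG")
        assert filter_exon_proximity([indel], self.EXONS, snv_only=True) == [indel]

    def test_random_intervals_match_scan_oracle(self):
        """Pass set equals a per-variant scan over every interval."""
        rng = np.random.default_rng(5)
        ivs = sorted(
            {(int(s), int(s + rng.integers(20, 200))) for s in rng.integers(0, 50_000, size=40)}
        )
        exons = ExonIntervalMap({"chr1": ivs})
        merged = exons.intervals("chr1")
        sites = [make_site("chr1", int(p), "A", "G") for p in rng.integers(1, 55_000, size=500)]
        kept = {s.key for s in filter_exon_proximity(sites, exons, max_dist_bp=10)}
        for s in sites:
            x = s.pos - 1
            dists = []
            for start, end in merged:
                if start <= x < end:
                    dists.append(0)
                else:
                    dists.append(start - x - 1 if x < start else x - end)
            assert ((min(dists) <= 10) == (s.key in kept)), s.pos

    def test_order_insensitive_with_genotype_filter(self, quartet):
        """Hard-filter then GQ/DP equals the reverse order on the pass set."""
        rng = np.random.default_rng(3)
        records = []
        for i in range(300):
            site = make_site("chr1", i + 1, "A", "G",
                             info_metrics={"QD": float(rng.uniform(0, 6))})
            calls = {
                s: GenotypeCall(s, Genotype.HET, gq=int(rng.integers(0, 60)), dp=40)
                for s in quartet.all_ids
            }
            records.append((site, calls))

        def hard_then_gq(recs):
            passed, _ = apply_hard_filters([s for s, _ in recs], SNV_EXPR, INDEL_EXPR)
            keys = {s.key for s in passed}
            return filter_genotype_quality([(s, c) for s, c in recs if s.key in keys], quartet)

        def gq_then_hard(recs):
            kept = filter_genotype_quality(recs, quartet)
            passed, _ = apply_hard_filters([s for s, _ in kept], SNV_EXPR, INDEL_EXPR)
            keys = {s.key for s in passed}
            return [(s, c) for s, c in kept if s.key in keys]

        assert {s.key for s, _ in hard_then_gq(records)} == {s.key for s, _ in gq_then_hard(records)}
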