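"""Variant filter rules, panel polishing, severity ranking, and VCF IO."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctdna_mpnst.core import GenomicInterval
from ctdna_mpnst.snv import (
    FilterThresholds,
    Severity,
    VariantCall,
    background_panel_filter,
    classify_consequence,
    filter_cfdna_variant,
    filter_tumor_variant,
    filter_variants,
    gene_severity_summary,
    read_vcf,
    write_vcf,
)


def make_variant(af=0.01, alt_depth=10, total_depth=1000, flags=(), gene="TP53",
                 consequence="missense_variant", pos=7_577_000, chrom="17",
                 polyphen=None, sift=None, is_coding=True, pop_af=None):
    return VariantCall(
        interval=GenomicInterval(chrom, pos, pos + 1),
        ref="C", alt="T", sample_id="S1",
        af=af, alt_depth=alt_depth, total_depth=total_depth,
        filter_flags=frozenset(flags), gene=gene, consequence=consequence,
        polyphen_damaging=polyphen, sift_deleterious=sift,
        is_coding=is_coding, population_af=pop_af,
    )


class TestCfdnaFilter:
    def test_passing_call_retained(self):
        d = filter_cfdna_variant(make_variant(af=0.001, alt_depth=10))
        assert d.retained and d.reason_codes == []

    def test_af_boundary_is_strict(self):
        d = filter_cfdna_variant(make_variant(af=0.0005, alt_depth=20))
        assert not d.retained and "AF_BELOW_MIN" in d.reason_codes

    def test_alt_depth_boundary(self):
        d = filter_cfdna_variant(make_variant(af=0.01, alt_depth=7))
        assert not d.retained and d.reason_codes == ["ALT_DEPTH_LOW"]

    def test_reasons_accumulate_not_short_circuit(self):
        d = filter_cfdna_variant(make_variant(af=0.0001, alt_depth=2))
        assert set(d.reason_codes) == {"AF_BELOW_MIN", "ALT_DEPTH_LOW"}

    def test_zero_depth_is_input_error(self):
        v = make_variant(af=0.0, alt_depth=0, total_depth=1)
        v.total_depth = 0
        with pytest.raises(ValueError):
            filter_cfdna_variant(v)

    def test_population_frequency_filter(self):
        d = filter_cfdna_variant(make_variant(pop_af=0.01))
        assert "POPULATION_FREQ" in d.reason_codes
        assert filter_cfdna_variant(make_variant(pop_af=0.0001)).retained


class TestTumorFilter:
    def test_clonal_call_retained(self):
        assert filter_tumor_variant(make_variant(af=0.30, alt_depth=50)).retained

    def test_germline_flag_rejects(self):
        d = filter_tumor_variant(make_variant(af=0.30, alt_depth=50, flags=("germline",)))
        assert not d.retained and "GERMLINE_MATCH" in d.reason_codes

    @pytest.mark.parametrize("flag,code", [
        ("contamination", "CONTAMINATION"), ("normal_artifact", "NORMAL_ARTIFACT"),
    ])
    def test_other_disqualifying_flags(self, flag, code):
        d = filter_tumor_variant(make_variant(af=0.30, alt_depth=50, flags=(flag,)))
        assert code in d.reason_codes

    def test_af_boundary_strict(self):
        assert not filter_tumor_variant(make_variant(af=0.05, alt_depth=50)).retained


class TestBackgroundPanel:
    @pytest.mark.parametrize("carriers,removed", [(0, False), (1, False), (2, True), (5, True)])
    def test_ten_percent_rule_with_panel_of_12(self, carriers, removed):
        v = make_variant()
        decisions = background_panel_filter([v], {v.key: carriers}, panel_size=12)
        assert decisions[0].retained == (not removed)

    def test_integer_threshold_matches_floor_oracle(self):
        """Removal starts at floor(0.10 * panel_size) + 1 carriers, any panel size."""
        for panel_size in range(1, 31):
            threshold = int(np.floor(0.10 * panel_size))
            for carriers in range(panel_size + 1):
                v = make_variant()
                (d,) = background_panel_filter([v], {v.key: carriers}, panel_size)
                assert d.retained == (carriers <= threshold)

    def test_empty_panel_is_configuration_error(self):
        with pytest.raises(ValueError):
            background_panel_filter([make_variant()], {}, panel_size=0)


class TestFilterChain:
    def test_conservation_partition(self):
        rng = np.random.default_rng(0)
        variants = [
            make_variant(af=float(rng.uniform(0, 0.01)),
                         alt_depth=int(rng.integers(0, 30)), pos=7_577_000 + i)
            for i in range(50)
        ]
        decisions = filter_variants(variants, "cfdna")
        assert len(decisions) == len(variants)
        retained = [d for d in decisions if d.retained]
        rejected = [d for d in decisions if not d.retained]
        assert len(retained) + len(rejected) == len(variants)
        assert all((d.retained) == (not d.reason_codes) for d in decisions)

    @given(
        af_thresh=st.floats(min_value=0.0001, max_value=0.05),
        depth_thresh=st.integers(min_value=1, max_value=30),
        seed=st.integers(min_value=0, max_value=100),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_raising_thresholds_shrinks_retained_set(self, af_thresh, depth_thresh, seed):
        rng = np.random.default_rng(seed)
        variants = [
            make_variant(af=float(rng.uniform(0, 0.1)),
                         alt_depth=int(rng.integers(0, 40)), pos=7_577_000 + i)
            for i in range(30)
        ]
        base = FilterThresholds(cfdna_min_af=af_thresh, min_alt_depth=depth_thresh)
        raised = FilterThresholds(cfdna_min_af=af_thresh * 2,
                                  min_alt_depth=depth_thresh + 5)
        keep = {d.variant.key for d in filter_variants(variants, "cfdna", base)
                if d.retained}
        keep_raised = {d.variant.key for d in filter_variants(variants, "cfdna", raised)
                       if d.retained}
        assert keep_raised <= keep


class TestSeverity:
    @pytest.mark.parametrize("csq,expected", [
        ("stop_gained", Severity.LOF),
        ("frameshift_variant", Severity.LOF),
        ("start_lost", Severity.LOF),
        ("splice_donor_variant", Severity.SPLICE_ALTERING),
        ("splice_acceptor_variant", Severity.SPLICE_ALTERING),
        ("synonymous_variant", Severity.SYNONYMOUS),
        ("intron_variant", Severity.OTHER),
    ])
    def test_direct_term_mapping(self, csq, expected):
        assert classify_consequence(make_variant(consequence=csq)) is expected

    def test_rank_values_span_0_to_6(self):
        ranks = sorted(int(s) for s in Severity)
        assert ranks == list(range(7))
        assert int(Severity.LOF) == 6
        assert int(Severity.SPLICE_ALTERING) == 4
        assert int(Severity.SYNONYMOUS) == 1

    def test_missense_splits_on_predictions(self):
        both = make_variant(consequence="missense_variant", polyphen=True, sift=True)
        assert classify_consequence(both) is Severity.PROTEIN_DISRUPTING_MISSENSE
        neither = make_variant(consequence="missense_variant", polyphen=False, sift=False)
        assert classify_consequence(neither) is Severity.NON_DISRUPTING_MISSENSE
        one = make_variant(consequence="missense_variant", polyphen=True, sift=False)
        assert classify_consequence(one) is Severity.VUS
        absent = make_variant(consequence="missense_variant")
        assert classify_consequence(absent) is Severity.VUS

    def test_unrecognized_term_maps_to_other_without_crash(self):
        assert classify_consequence(make_variant(consequence="mystery_term")) is Severity.OTHER


class TestGeneSeveritySummary:
    def test_empty_gene_ranks_zero(self, registry):
        summary = gene_severity_summary([], registry)
        assert summary["TP53"] == {"max_rank": 0, "multi_hit": False, "n_variants": 0}

    def test_max_rank_and_multi_hit(self, registry):
        variants = [
            make_variant(consequence="missense_variant", polyphen=True, sift=False),  # VUS, 3
            make_variant(consequence="stop_gained", pos=7_578_000),  # LoF, 6
        ]
        summary = gene_severity_summary(variants, registry)
        assert summary["TP53"]["max_rank"] == 6
        assert summary["TP53"]["multi_hit"] is True

    def test_single_splice_variant(self, registry):
        variants = [make_variant(gene="SUZ12", consequence="splice_donor_variant",
                                 chrom="17", pos=30_300_000)]
        summary = gene_severity_summary(variants, registry)
        assert summary["SUZ12"] == {"max_rank": 4, "multi_hit": False, "n_variants": 1}

    def test_cdkn2a_and_b_collapse_to_merged_locus(self, registry):
        variants = [
            make_variant(gene="CDKN2A", consequence="stop_gained", chrom="9", pos=21_970_000),
            make_variant(gene="CDKN2B", consequence="synonymous_variant", chrom="9",
                         pos=22_005_000),
        ]
        summary = gene_severity_summary(variants, registry)
        assert summary["CDKN2AB"]["max_rank"] == 6
        assert summary["CDKN2AB"]["multi_hit"] is True

    @given(st.lists(
        st.tuples(
            st.sampled_from(["TP53", "SUZ12", "EED", "CDKN2A"]),
            st.sampled_from(["stop_gained", "missense_variant", "synonymous_variant",
                             "splice_region_variant", "intron_variant"]),
        ),
        max_size=12,
    ))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_summary_equals_bruteforce_max(self, registry, gene_csqs):
        variants = [
            make_variant(gene=g, consequence=c, pos=1000 + i, chrom="17")
            for i, (g, c) in enumerate(gene_csqs)
        ]
        summary = gene_severity_summary(variants, registry)
        for locus in ("CDKN2AB", "TP53", "SUZ12", "EED"):
            expected = [int(classify_consequence(v)) for v in variants
                        if registry.snv_gene(v.gene) == locus]
            assert summary[locus]["max_rank"] == (max(expected) if expected else 0)
            assert summary[locus]["multi_hit"] == (len(expected) >= 2)


class TestVcfRoundTrip:
    def _variants(self):
        return [
            make_variant(af=120 / 1000, alt_depth=120, total_depth=1000,
                         consequence="stop_gained", gene="TP53"),
            make_variant(af=9 / 950, alt_depth=9, total_depth=950, chrom="9",
                         pos=21_970_000, gene="CDKN2A",
                         consequence="missense_variant", polyphen=True, sift=True),
        ]

    def test_write_read_preserves_calls(self, tmp_path):
        path = tmp_path / "s1.vcf"
        variants = self._variants()
        write_vcf(variants, path, "S1")
        back = read_vcf(path)
        assert {v.key for v in back} == {v.key for v in variants}
        by_key = {v.key: v for v in back}
        for v in variants:
            r = by_key[v.key]
            assert r.alt_depth == v.alt_depth
            assert r.total_depth == v.total_depth
            assert r.consequence == v.consequence
            assert r.gene == v.gene
            assert abs(r.af - v.af) < 1e-6

    def test_independent_reader_agrees(self, tmp_path):
        """Cross-check our pysam-based reader against cyvcf2."""
        cyvcf2 = pytest.importorskip("cyvcf2")
        path = tmp_path / "s1.vcf"
        write_vcf(self._variants(), path, "S1")
        ours = {(v.interval.chrom, v.interval.start + 1, v.ref, v.alt, v.alt_depth)
                for v in read_vcf(path)}
        theirs = set()
        for rec in cyvcf2.VCF(str(path)):
            theirs.add((rec.CHROM, rec.POS, rec.REF, rec.ALT[0],
                        int(rec.format("AD")[0][1])))
        assert ours == theirs
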