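"""Indel filtering, exclusivity and window intersection."""

import numpy as np
import pytest

from conftest import random_indel_calls
from oracles import (
    oracle_all_pairs_hits,
    oracle_exclusive_windowed,
    oracle_filter_predicate,
)

from editqc.crossref import (
    CrossrefInputError,
    FilterParams,
    IndelCall,
    exclusive_indels,
    filter_indels,
    intersect_windows,
    read_indels_vcf,
    site_indel_distance,
)
from editqc.offtarget import CandidateSite


def call(pos=1000, ref="ATTT", alt="A", qual=50.0, mq=60.0, support=10,
         chrom="chr1", sample="edited"):
    return IndelCall(chrom=chrom, pos=pos, ref=ref, alt=alt, qual=qual,
                     mq=mq, support=support, sample=sample)


def site(start=100, end=120, chrom="chr1"):
    return CandidateSite(chrom=chrom, start=start, end=end, strand="+",
                         penalty=0, mismatches=0, dna_bulge_bases=0,
                         rna_bulge_bases=0)


class TestFilter:
    def test_low_support_removed_despite_high_quality(self):
        """Fewer than 4 supporting reads fails on its own, even with
        excellent mapping and site quality."""
        res = filter_indels([call(support=3, mq=60, qual=50)])
        assert res.kept == [] and res.removed[0][1] == "support"

    def test_empty_input(self):
        res = filter_indels([])
        assert res.kept == [] and res.removed == []

    @pytest.mark.parametrize("kwargs,reason", [
        (dict(support=3), "support"),
        (dict(mq=29.9), "mq"),
        (dict(qual=19.9), "qual"),
        (dict(ref="A" + "T" * 50, alt="A"), "indel_len"),
    ])
    def test_first_failing_rule_reported(self, kwargs, reason):
        res = filter_indels([call(**kwargs)])
        assert res.removed[0][1] == reason

    def test_threshold_boundaries_inclusive(self):
        kept = filter_indels([
            call(support=4, mq=30.0, qual=20.0),
            call(pos=2000, ref="A" + "T" * 49, alt="A"),  # 49 < 50
        ]).kept
        assert len(kept) == 2

    def test_near_variant_removal(self):
        a, b = call(pos=1000), call(pos=1008)  # 8 bp apart, within 10
        res = filter_indels([a, b])
        assert res.kept == []
        assert {r for _, r in res.removed} == {"near_variant"}
        # with SNV positions supplied externally
        res2 = filter_indels([a], all_variants=[("chr1", 1000), ("chr1", 1005)])
        assert res2.kept == [] and res2.removed[0][1] == "near_variant"

    def test_exclusion_bed(self):
        par = (("chrX", 10000, 2781479),)
        inside = call(pos=20000, chrom="chrX")
        outside = call(pos=3000000, chrom="chrX")
        res = filter_indels([inside, outside],
                            FilterParams(exclusion_bed=par))
        assert res.kept == [outside]
        assert res.removed[0][1] == "exclusion_region"

    def test_predicate_oracle_on_random_records(self):
        """Each surviving record is exactly the set passing the
        per-record threshold predicate (calls spaced so proximity rules
        are inert)."""
        rng = np.random.default_rng(7)
        calls = random_indel_calls(rng, 200)
        res = filter_indels(calls)
        expected = [c for c in calls if oracle_filter_predicate(c)]
        assert res.kept == expected

    def test_filter_monotonicity(self):
        """Raising any threshold never enlarges the surviving set."""
        rng = np.random.default_rng(21)
        calls = random_indel_calls(rng, 150)
        base = FilterParams()
        kept0 = {c.key() for c in filter_indels(calls, base).kept}
        tighter = [
            FilterParams(min_support=base.min_support + 3),
            FilterParams(min_mq=base.min_mq + 10),
            FilterParams(min_qual=base.min_qual + 15),
            FilterParams(max_indel_len=base.max_indel_len - 20),
        ]
        for params in tighter:
            assert {c.key() for c in filter_indels(calls, params).kept} <= kept0


class TestExclusivity:
    def test_identical_sets_yield_nothing(self):
        calls = [call(), call(pos=2000, ref="A", alt="ACC")]
        ctl = [IndelCall(c.chrom, c.pos, c.ref, c.alt, c.qual, c.mq,
                         c.support, sample="control") for c in calls]
        assert exclusive_indels(calls, ctl) == []

    def test_empty_control_returns_all(self):
        calls = [call(), call(pos=2000)]
        assert exclusive_indels(calls, []) == calls

    def test_single_novel_call(self):
        shared = call()
        novel = call(pos=5000, ref="A", alt="ATG")
        ctl = [IndelCall(shared.chrom, shared.pos, shared.ref, shared.alt,
                         50, 60, 10, sample="control")]
        assert exclusive_indels([shared, novel], ctl) == [novel]

    def test_mixed_sample_labels_refused(self):
        with pytest.raises(CrossrefInputError):
            exclusive_indels([call(sample="edited"), call(pos=2, sample="control")], [])

    def test_windowed_mode_matches_bruteforce(self):
        rng = np.random.default_rng(11)
        edited = random_indel_calls(rng, 80, sample="edited")
        control = random_indel_calls(rng, 80, sample="control")
        got = exclusive_indels(edited, control, match_mode="windowed", window=3)
        assert got == oracle_exclusive_windowed(edited, control, 3)

    def test_windowed_requires_same_length(self):
        e = call(pos=1000, ref="ATT", alt="A")
        c1 = IndelCall("chr1", 1002, "ATT", "A", 50, 60, 10, "control")
        c2 = IndelCall("chr1", 1000, "ATTT", "A", 50, 60, 10, "control")
        assert exclusive_indels([e], [c1], match_mode="windowed") == []
        assert exclusive_indels([e], [c2], match_mode="windowed") == [e]


class TestIntersection:
    def test_boundary_16bp_outside_15_window(self):
        """An indel 16 bp from the site boundary falls in the 200-bp
        window only; 15 bp falls in both."""
        s = site(100, 120)
        at16 = call(pos=136, ref="AT", alt="A")   # deleted base at 136 -> dist 16
        at15 = call(pos=135, ref="AT", alt="A")
        r16 = intersect_windows([s], [at16])
        assert r16.sites_within == {15: 0, 200: 1}
        assert [h.window_class for h in r16.hits] == ["within_200"]
        r15 = intersect_windows([s], [at15])
        assert r15.sites_within == {15: 1, 200: 1}

    def test_no_indels(self):
        r = intersect_windows([site()], [])
        assert r.hits == [] and r.sites_within == {15: 0, 200: 0}

    def test_overlap_distance_zero(self):
        s = site(100, 120)
        assert site_indel_distance(s, call(pos=110, ref="AT", alt="A")) == 0
        assert site_indel_distance(s, call(pos=110, ref="A", alt="ATTT")) == 0
        assert site_indel_distance(s, call(pos=50, ref="AT", alt="A",
                                           chrom="chr2")) is None

    def test_insertion_point_distance(self):
        # insertion point just right of the site end
        s = site(100, 120)
        assert site_indel_distance(s, call(pos=125, ref="A", alt="AGG")) == 5

    def test_all_pairs_oracle(self):
        rng = np.random.default_rng(23)
        sites = [site(int(p), int(p) + 20) for p in rng.integers(0, 50000, size=100)]
        indels = []
        for p in rng.integers(0, 50000, size=100):
            L = int(rng.integers(1, 8))
            if rng.random() < 0.5:
                indels.append(call(pos=int(p) + 1, ref="A" + "T" * L, alt="A"))
            else:
                indels.append(call(pos=int(p) + 1, ref="A", alt="A" + "C" * L))
        got = intersect_windows(sites, indels)
        per_window, hits = oracle_all_pairs_hits(sites, indels, (15, 200))
        assert got.sites_within == {w: len(v) for w, v in per_window.items()}
        assert len(got.hits) == len(hits)

    def test_window_nesting(self):
        rng = np.random.default_rng(29)
        sites = [site(int(p), int(p) + 20) for p in rng.integers(0, 20000, size=50)]
        indels = [call(pos=int(p) + 1, ref="AT", alt="A")
                  for p in rng.integers(0, 20000, size=50)]
        r = intersect_windows(sites, indels)
        in15 = {id(h.site) for h in r.hits if h.window_class == "within_15"}
        in200 = {id(h.site) for h in r.hits if h.window_class == "within_200"}
        assert in15 <= in200
        assert r.sites_within[15] <= r.sites_within[200]

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            intersect_windows([site()], [call()], windows=[-1])


class TestVcfInput:
    def test_roundtrip_through_vcf(self, tmp_path):
        from editqc.simulate import write_vcf

        genome = {"chr1": "A" * 5000}
        records = [
            {"chrom": "chr1", "pos": 100, "ref": "AAAA", "alt": "A",
             "support": 12, "mq": 55.0, "qual": 88.0},
            {"chrom": "chr1", "pos": 900, "ref": "A", "alt": "ATG",
             "support": 3, "mq": 20.0, "qual": 10.0},
        ]
        path = tmp_path / "x.vcf"
        write_vcf(records, genome, path, sample="edited")
        calls = read_indels_vcf(path, sample="edited")
        assert [(c.pos, c.ref, c.alt, c.support) for c in calls] == \
            [(100, "AAAA", "A", 12), (900, "A", "ATG", 3)]
        assert calls[0].mq == pytest.approx(55.0) and calls[0].qual == pytest.approx(88.0)

    def test_multiallelic_refused(self, tmp_path):
        path = tmp_path / "m.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t100\t.\tAT\tA,ATT\t50\t.\t.\n")
        with pytest.raises(CrossrefInputError, match="bcftools norm"):
            read_indels_vcf(path, sample="edited")

    def test_impure_indel_call_refused(self):
        with pytest.raises(CrossrefInputError):
            IndelCall("chr1", 1, "AT", "GC", 50, 60, 10)
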