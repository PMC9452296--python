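"""Off-target scanner: identity cases, oracle equivalence, invariants."""

import numpy as np
import pytest

from conftest import planted_world
from oracles import oracle_scan, oracle_scan_fast

from editqc import GuideSpec, ScanParams, scan_offtargets
from editqc.guides import GuideError, revcomp
from editqc.offtarget import (
    CandidateSite,
    ScanInputError,
    dedup_sites,
    read_sites_bed,
    write_sites_bed,
)


def site_key(s: CandidateSite):
    return (s.chrom, s.start, s.end, s.strand, s.penalty, s.bulge_bases)


GUIDE = GuideSpec("GACGCATAAAGATGAGACGC", name="t1")


class TestBasicMatching:
    def test_exact_site_identity(self):
        genome = {"chrT": "T" * 60 + GUIDE.protospacer + "AGG" + "T" * 60}
        res = scan_offtargets(genome, GUIDE)
        assert len(res.sites) == 1
        s = res.sites[0]
        assert (s.start, s.end, s.strand) == (60, 80, "+")
        assert (s.penalty, s.mismatches, s.bulge_bases) == (0, 0, 0)
        assert s.pam_observed == "AGG"

    def test_pam_constraint_rejects(self):
        genome = {"chrT": "T" * 60 + GUIDE.protospacer + "ATT" + "T" * 60}
        assert len(scan_offtargets(genome, GUIDE).sites) == 0

    def test_minus_strand_site(self):
        element = revcomp(GUIDE.protospacer + "TGG")
        genome = {"chrT": "T" * 50 + element + "T" * 50}
        res = scan_offtargets(genome, GUIDE)
        assert len(res.sites) == 1
        s = res.sites[0]
        assert s.strand == "-" and s.penalty == 0
        assert (s.start, s.end) == (53, 73)  # PAM occupies the 3 leftmost bases

    def test_n_bases_never_match(self):
        spaced = GUIDE.protospacer[:10] + "N" + GUIDE.protospacer[11:]
        genome = {"chrT": "T" * 60 + spaced + "AGG" + "T" * 60}
        res = scan_offtargets(genome, GUIDE)
        # the N counts as one mismatch, never as a match
        assert all(s.penalty >= 1 for s in res.sites)
        assert any(s.penalty == 1 and s.mismatches == 1 for s in res.sites)

    def test_on_target_exclusion(self):
        guide = GuideSpec(GUIDE.protospacer, on_target=("chrT", 61, "+"), name="t1")
        genome = {"chrT": "T" * 60 + GUIDE.protospacer + "AGG" + "T" * 60}
        res = scan_offtargets(genome, guide)
        assert len(res.sites) == 0
        assert len(res.on_target_sites) == 1


class TestPenaltyBudget:
    def test_planted_five_mismatches_in_six_out(self, pd1_guide):
        """Five substitutions sit at the budget edge; a bulge plus four
        substitutions (penalty 6) must be absent."""
        from editqc.simulate import PlantSpec, PlantedSite, make_genome

        spec = PlantSpec(guide=pd1_guide, sites=(
            PlantedSite(500, "+", 5),
            PlantedSite(1500, "+", 4, (("dna", 10, 1),)),
        ), genome_len=2500, seed=42)
        genome, truth = make_genome(spec)
        res = scan_offtargets(genome, pd1_guide)
        starts = {s.start: s for s in res.sites}
        assert 500 in starts and starts[500].penalty == 5
        assert not any(s.start < truth[1].end and s.end > truth[1].start
                       for s in res.sites)
        # the exhaustive oracle agrees that nothing <= 5 exists there
        oracle = oracle_scan_fast(genome, pd1_guide.protospacer, "NRG", 5, 2, 2)
        assert sorted(site_key(s) for s in res.sites) == oracle

    def test_monotonic_in_budget(self, pd1_guide):
        genome, _ = planted_world(pd1_guide, seed=3)
        previous = set()
        for k in range(0, 7):
            params = ScanParams(max_penalty=k)
            keys = {(s.chrom, s.start, s.end, s.strand)
                    for s in scan_offtargets(genome, pd1_guide, params).sites}
            assert previous <= keys
            previous = keys


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [1, 7, 42])
    def test_matches_exhaustive_dp(self, pd1_guide, seed):
        genome, _ = planted_world(pd1_guide, seed=seed)
        res = scan_offtargets(genome, pd1_guide, ScanParams())
        oracle = oracle_scan_fast(genome, pd1_guide.protospacer, "NRG", 5, 2, 2)
        assert sorted(site_key(s) for s in res.sites) == oracle

    def test_both_oracles_agree(self, pd1_guide):
        """Vectorized and loop oracles triangulate on one small genome."""
        genome, _ = planted_world(pd1_guide, seed=11, genome_len=1300)
        slow = oracle_scan(genome, pd1_guide.protospacer, "NRG", 5, 2, 2)
        fast = oracle_scan_fast(genome, pd1_guide.protospacer, "NRG", 5, 2, 2)
        assert sorted(slow) == sorted(fast)

    def test_nondefault_params(self, pd1_guide):
        genome, _ = planted_world(pd1_guide, seed=13, genome_len=1300)
        params = ScanParams(max_penalty=3, bulge_cost_per_base=1, max_bulge_len=1)
        res = scan_offtargets(genome, pd1_guide, params)
        oracle = oracle_scan_fast(genome, pd1_guide.protospacer, "NRG", 3, 1, 1)
        assert sorted(site_key(s) for s in res.sites) == oracle


class TestInvariants:
    def test_strand_symmetry(self, pd1_guide):
        genome, _ = planted_world(pd1_guide, seed=5)
        n = len(genome["chrS"])
        mirrored = {"chrS": revcomp(genome["chrS"])}
        fwd = scan_offtargets(genome, pd1_guide).sites
        rev = scan_offtargets(mirrored, pd1_guide).sites
        flip = {"+": "-", "-": "+"}
        expected = sorted((s.chrom, n - s.end, n - s.start, flip[s.strand],
                           s.penalty, s.bulge_bases) for s in fwd)
        assert expected == sorted(site_key(s) for s in rev)

    def test_penalty_decomposition_and_pam(self, pd1_guide):
        from editqc.guides import iupac_match

        genome, _ = planted_world(pd1_guide, seed=9)
        params = ScanParams()
        for s in scan_offtargets(genome, pd1_guide, params).sites:
            assert s.penalty == s.mismatches + params.bulge_cost_per_base * s.bulge_bases
            assert s.penalty <= params.max_penalty
            assert s.end > s.start
            assert iupac_match(params.pam_pattern, s.pam_observed)
            assert len(s.aligned_guide) == len(s.aligned_target)
            # alignment strings re-derive the decomposition
            mm = sum(1 for a, b in zip(s.aligned_guide, s.aligned_target)
                     if "-" not in (a, b) and a != b)
            assert mm == s.mismatches
            assert s.aligned_guide.count("-") == s.dna_bulge_bases
            assert s.aligned_target.count("-") == s.rna_bulge_bases

    def test_dedup_keeps_best(self):
        mk = lambda start, end, pen, nb: CandidateSite(
            "c", start, end, "+", pen, pen - 2 * nb, nb, 0)
        best = mk(10, 30, 1, 0)
        kept = dedup_sites([mk(9, 29, 4, 1), best, mk(11, 31, 3, 0), mk(100, 120, 2, 0)])
        assert best in kept and len(kept) == 2


class TestArtifacts:
    def test_bed_roundtrip_random_sites(self, tmp_path):
        rng = np.random.default_rng(0)
        sites = []
        for i in range(50):
            start = int(rng.integers(0, 10000))
            nb = int(rng.integers(0, 3))
            mm = int(rng.integers(0, 4))
            sites.append(CandidateSite(
                chrom=f"chr{int(rng.integers(1, 4))}", start=start,
                end=start + 20 + int(rng.integers(-2, 3)),
                strand="+-"[int(rng.integers(0, 2))],
                penalty=mm + 2 * nb, mismatches=mm,
                dna_bulge_bases=nb, rna_bulge_bases=0,
                pam_observed="AGG", guide_name="g"))
        path = tmp_path / "sites.bed"
        write_sites_bed(sites, path)
        back = read_sites_bed(path)
        assert sorted(s.key() for s in back) == sorted(s.key() for s in sites)

    def test_single_site_bed_line(self, tmp_path):
        s = CandidateSite("chrT", 100, 120, "-", 3, 3, 0, 0, pam_observed="TGG")
        path = tmp_path / "one.bed"
        write_sites_bed([s], path)
        line = [l for l in path.read_text().splitlines() if not l.startswith("#")][0]
        assert line.startswith("chrT\t100\t120\t") and line.endswith("\t3\t-")

    def test_empty_bed_has_header(self, tmp_path):
        path = tmp_path / "empty.bed"
        write_sites_bed([], path)
        content = path.read_text()
        assert content.startswith("#") and read_sites_bed(path) == []


class TestErrors:
    def test_bad_pam_pattern(self):
        with pytest.raises(ScanInputError):
            ScanParams(pam_pattern="NXG")

    def test_ambiguous_protospacer(self):
        with pytest.raises(GuideError):
            GuideSpec("ACGTNACGTACGTACGTACG")

    def test_empty_genome(self):
        with pytest.raises(ScanInputError):
            scan_offtargets({}, GUIDE)
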