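"""Inverted-pair enumeration, alignment and scan reporting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from irscan import (
    GenomicInterval,
    Region,
    RepeatElement,
    ScanConfig,
    align_inverted_pair,
    bin_pairs,
    build_dataset,
    collect_elements_in_region,
    enumerate_inverted_pairs,
    evaluate_pair,
    mutate_to_identity,
    random_background,
    reverse_complement,
    scan_regions,
    substitute_spaced,
)
from irscan.ir_discovery import AlignmentResult, IRPairResult, PairCandidate


def _elem(start, end, strand="+", family="SINE/Alu", chrom="chr1", name=""):
    return RepeatElement(GenomicInterval(chrom, start, end, strand), family, name)


class TestReverseComplement:
    @pytest.mark.parametrize("seq,expected", [("ACGT", "ACGT"), ("AAAC", "GTTT"), ("N", "N")])
    def test_known_values(self, seq, expected):
        assert reverse_complement(seq) == expected

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=200))
    @settings(derandomize=True, max_examples=50)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_invalid_character(self):
        with pytest.raises(ValueError):
            reverse_complement("ACGU")


class TestCollectElements:
    def test_overlap_semantics(self):
        region = Region(GenomicInterval("chr1", 350, 900), "r")
        inside = _elem(100, 400)  # overlaps by 50 bp
        adjacent = _elem(900, 1200)  # half-open adjacency: excluded
        before = _elem(100, 350)
        assert collect_elements_in_region([inside, adjacent, before], region) == [inside]

    def test_matches_brute_force(self, rng):
        region = Region(GenomicInterval("chr1", 2000, 6000), "r")
        elements = []
        for _ in range(50):
            start = int(rng.integers(0, 9000))
            elements.append(_elem(start, start + int(rng.integers(50, 500))))
        expected = sorted(
            (e for e in elements if e.start < region.end and region.start < e.end),
            key=lambda e: (e.start, e.end),
        )
        assert collect_elements_in_region(elements, region) == expected


def _brute_force_pairs(elements, config):
    """Independent re-statement of the candidate rules, as a double loop."""
    out = set()
    for a in elements:
        for b in elements:
            if a is b or a.start > b.start or (a.start == b.start and a.end >= b.end):
                continue
            if a.chrom != b.chrom or a.family != b.family or a.strand == b.strand:
                continue
            if a.end > b.start:
                continue
            sep = b.start - a.end
            limit_ok = (
                sep < config.max_separation
                if config.inequality_mode == "strict"
                else sep <= config.max_separation
            )
            if limit_ok:
                out.add((a.start, a.end, b.start, b.end))
    return out


class TestEnumeratePairs:
    def test_three_element_example(self):
        e1, e2, e3 = _elem(0, 320, "+"), _elem(1320, 1640, "-"), _elem(2640, 2960, "+")
        pairs = enumerate_inverted_pairs([e1, e2, e3])
        assert [(p.elementA.start, p.elementB.start) for p in pairs] == [(0, 1320), (1320, 2640)]
        assert [p.orientation_class for p in pairs] == ["convergent", "divergent"]
        assert all(p.separation_bp == 1000 for p in pairs)

    def test_same_strand_yields_nothing(self):
        assert enumerate_inverted_pairs([_elem(0, 320, "+"), _elem(1000, 1320, "+")]) == []

    def test_separation_boundary_strict_vs_inclusive(self):
        make = lambda gap: [_elem(0, 320, "+"), _elem(320 + gap, 640 + gap, "-")]
        assert enumerate_inverted_pairs(make(30_000)) == []
        assert len(enumerate_inverted_pairs(make(29_999))) == 1
        inclusive = ScanConfig(inequality_mode="inclusive")
        assert len(enumerate_inverted_pairs(make(30_000), inclusive)) == 1

    def test_overlapping_inverted_elements_skipped(self):
        assert enumerate_inverted_pairs([_elem(0, 320, "+"), _elem(200, 520, "-")]) == []

    def test_cross_chromosome_rejected(self):
        with pytest.raises(ValueError):
            enumerate_inverted_pairs([_elem(0, 100), _elem(0, 100, "-", chrom="chr2")])

    @pytest.mark.parametrize("mode", ["strict", "inclusive"])
    def test_agrees_with_brute_force(self, rng, mode):
        config = ScanConfig(inequality_mode=mode, max_separation=5000)
        for _ in range(200):
            elements = []
            for _ in range(int(rng.integers(0, 7))):
                start = int(rng.integers(0, 12_000))
                elements.append(
                    _elem(
                        start,
                        start + int(rng.integers(50, 600)),
                        strand=["+", "-"][int(rng.integers(2))],
                        family=["SINE/Alu", "LINE/L1"][int(rng.integers(2))],
                    )
                )
            got = {
                (p.elementA.start, p.elementA.end, p.elementB.start, p.elementB.end)
                for p in enumerate_inverted_pairs(elements, config)
            }
            assert got == _brute_force_pairs(elements, config)


class TestAlignInvertedPair:
    def test_perfect_inverted_copy(self):
        seq = random_background(320, seed=1)
        res = align_inverted_pair(seq, reverse_complement(seq))
        assert res.identity_fraction == 1.0
        assert res.matched_length == 320
        assert res.spanA == (0, 320) and res.spanB == (0, 320)

    def test_gap_free_mismatch_oracle(self):
        # Prohibitive gap penalties force a gapless alignment: identity is
        # exactly 1 - k/L for k planted substitutions. Substitutions are
        # spaced >=3 apart and away from the ends so that no prefix or
        # suffix of the full alignment scores negative (a mismatch within
        # 2 bp of an end would be trimmed by any optimal local alignment).
        config = ScanConfig(gap_open=100_000, gap_extend=100_000)
        seq = random_background(300, seed=2)
        mutated, k = substitute_spaced(seq, 30, seed=3)
        assert k == 30
        res = align_inverted_pair(seq, reverse_complement(mutated), config)
        assert res.matched_length == 300
        assert res.identity_fraction == pytest.approx(0.90, abs=1e-12)

    def test_random_sequences_fail_length_threshold(self):
        for seed in range(20):
            a = random_background(320, seed=10_000 + seed)
            b = random_background(320, seed=20_000 + seed)
            assert align_inverted_pair(a, b).matched_length < 100

    def test_symmetry_under_swap(self):
        seq = random_background(320, seed=4)
        mutated, _ = mutate_to_identity(seq, 86, seed=5)
        partner = reverse_complement(mutated)
        r1 = align_inverted_pair(seq, partner)
        r2 = align_inverted_pair(partner, seq)
        assert r1.score == r2.score
        assert r1.matched_length == r2.matched_length
        assert r1.identity_fraction == r2.identity_fraction

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_inverted_pair("", "ACGT")

    def test_n_scores_as_mismatch(self):
        seq = "ACGTACGTACGT"
        partner = reverse_complement("ACGTNCGTACGT")
        res = align_inverted_pair(seq, partner, ScanConfig(gap_open=1000, gap_extend=1000))
        assert res.identities == 11
        assert res.matched_length == 12

    def test_shorter_element_denominator(self):
        config = ScanConfig(identity_denominator="shorter_element")
        seq = random_background(320, seed=6)
        res = align_inverted_pair(seq, reverse_complement(seq[:200]), config)
        assert res.identity_fraction == pytest.approx(res.identities / 200)


class TestEvaluatePair:
    def _planted(self, identity, spacer, seed=7):
        arm = random_background(320, seed=seed)
        mutated, _ = mutate_to_identity(arm, identity, seed=seed + 1)
        spacer_seq = random_background(spacer, seed=seed + 2) if spacer else ""
        chrom = (
            random_background(500, seed=seed + 3)
            + arm + spacer_seq + reverse_complement(mutated)
            + random_background(500, seed=seed + 4)
        )
        a = _elem(500, 820, "+")
        b = _elem(820 + spacer, 1140 + spacer, "-")
        cand = PairCandidate("r", a, b, spacer, "convergent")
        return {"chr1": chrom}, cand

    def test_planted_94_percent_passes(self):
        genome, cand = self._planted(94, 1500)
        assert evaluate_pair(cand, genome).pass_filter

    def test_planted_65_percent_fails(self):
        genome, cand = self._planted(65, 1500)
        res = evaluate_pair(cand, genome)
        assert not res.pass_filter
        assert res.alignment.identity_fraction < 0.75

    def test_matched_length_boundary(self):
        # Identical 100 bp arms: matched_length 100 fails the strict
        # > 100 bp rule; 101 bp arms pass.
        for L, expected in [(100, False), (101, True)]:
            arm = random_background(L, seed=30 + L)
            chrom = (
                random_background(200, seed=40 + L)
                + arm + random_background(50, seed=50 + L) + reverse_complement(arm)
                + random_background(200, seed=60 + L)
            )
            a = _elem(200, 200 + L, "+")
            b = _elem(250 + L, 250 + 2 * L, "-")
            cand = PairCandidate("r", a, b, 50, "convergent")
            assert evaluate_pair(cand, {"chr1": chrom}).pass_filter is expected

    def test_out_of_bounds_element(self):
        genome = {"chr1": random_background(500, seed=8)}
        a = _elem(100, 420, "+")
        b = _elem(430, 750, "-")
        cand = PairCandidate("r", a, b, 10, "convergent")
        with pytest.raises(ValueError, match="outside chromosome bounds"):
            evaluate_pair(cand, genome)

    def test_threshold_monotonicity(self):
        # Lowering min_identity / raising max_separation never loses pairs.
        genome, cand = self._planted(80, 1500)
        strictest = evaluate_pair(cand, genome, ScanConfig(min_identity=0.95))
        looser = evaluate_pair(cand, genome, ScanConfig(min_identity=0.75))
        assert looser.pass_filter >= strictest.pass_filter


class TestScanRegions:
    def test_planted_region_counts(self, small_dataset):
        report, results = scan_regions(
            small_dataset.genome, small_dataset.elements, small_dataset.regions
        )
        assert report.n_regions == 20
        assert report.per_family_region_counts == {"SINE/Alu": 12}
        assert report.n_passing_pairs == 12

    def test_empty_regions_preserved(self, small_dataset):
        report, _ = scan_regions(
            small_dataset.genome, small_dataset.elements, small_dataset.regions
        )
        zero_regions = [r for r, v in report.per_region.items() if v["total"] == 0]
        assert len(zero_regions) == 8

    def test_gt10_tally(self):
        plan = [[(94, 200)] * 12, [(94, 200)]]
        ds = build_dataset(plan, seed=3)
        report, _ = scan_regions(ds.genome, ds.elements, ds.regions)
        assert report.regions_with_gt10 == {"SINE/Alu": 1}
        assert report.regions_with_gt1 == {"SINE/Alu": 1}
        assert report.per_family_region_counts == {"SINE/Alu": 2}

    def test_missing_chromosome_error(self, small_dataset):
        bad = Region(GenomicInterval("chrMissing", 0, 100), "ghost")
        with pytest.raises(KeyError, match="ghost"):
            scan_regions(
                small_dataset.genome,
                small_dataset.elements,
                list(small_dataset.regions) + [bad],
            )

    def test_deterministic_ordering(self, small_dataset):
        _, r1 = scan_regions(small_dataset.genome, small_dataset.elements, small_dataset.regions)
        _, r2 = scan_regions(small_dataset.genome, small_dataset.elements, small_dataset.regions)
        assert [(p.candidate.region_id, p.candidate.elementA.start) for p in r1] == [
            (p.candidate.region_id, p.candidate.elementA.start) for p in r2
        ]


def _passing_pair(sep, identity_pct):
    a = _elem(0, 320, "+")
    b = _elem(320 + sep, 640 + sep, "-")
    cand = PairCandidate("r", a, b, sep, "convergent")
    aln = AlignmentResult(
        score=400.0,
        matched_length=320,
        identities=round(identity_pct / 100 * 320),
        identity_fraction=identity_pct / 100,
    )
    return IRPairResult(cand, aln, True)


class TestBinPairs:
    def test_one_per_distance_bin(self):
        pairs = [_passing_pair(s, 90) for s in (5000, 15_000, 25_000)]
        dist, _ = bin_pairs(pairs)
        assert dist == {"0-10kb": 1, "10-20kb": 1, "20-30kb": 1}

    def test_identity_boundary_left_closed(self):
        (_, ident) = bin_pairs([_passing_pair(100, 80)])
        assert ident["80-85"] == 1 and ident["75-80"] == 0

    def test_full_identity_in_last_bin(self):
        (_, ident) = bin_pairs([_passing_pair(100, 100)])
        assert ident["95-100"] == 1

    def test_histograms_match_brute_force(self, rng):
        seps = rng.integers(0, 30_000, size=50)
        idents = rng.uniform(75.5, 100.0, size=50)
        pairs = [_passing_pair(int(s), float(i)) for s, i in zip(seps, idents)]
        dist, ident = bin_pairs(pairs)
        assert sum(dist.values()) == 50 and sum(ident.values()) == 50
        expected_dist = [
            sum(1 for s in seps if lo <= s < hi)
            for lo, hi in [(0, 10_000), (10_000, 20_000), (20_000, 30_000)]
        ]
        assert list(dist.values()) == expected_dist

    def test_out_of_range_pair_rejected(self):
        with pytest.raises(ValueError, match="identity"):
            bin_pairs([_passing_pair(100, 50)])
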