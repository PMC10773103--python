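"""TPM filter, vector/foreign screens, and exon-coverage quantification."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taxdecon.align import AlignmentHit, local_align
from taxdecon.postassembly import (
    COVERAGE_BINS,
    CoverageCall,
    GenomeHSP,
    IsoformModel,
    QuantRecord,
    bin_coverage_report,
    bin_for,
    exon_coverage,
    filter_tpm,
    foreign_transcript_screen,
    hsp_from_hit,
    load_isoforms,
    vector_screen,
)


class TestTpmFilter:
    def test_cutoff_is_inclusive(self):
        quants = [QuantRecord("keep", 2.5), QuantRecord("drop", 2.49)]
        assert filter_tpm(quants) == ["keep"]

    def test_matches_predicate_oracle(self):
        rng = random.Random(12)
        quants = [QuantRecord(f"t{i}", round(rng.uniform(0, 10), 2)) for i in range(200)]
        oracle = [q.transcript_id for q in quants if q.tpm >= 2.5]
        assert filter_tpm(quants) == oracle

    def test_duplicate_ids_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            filter_tpm([QuantRecord("t", 3.0), QuantRecord("t", 4.0)])

    def test_empty_and_idempotent(self):
        assert filter_tpm([]) == []
        quants = [QuantRecord(f"t{i}", float(i)) for i in range(6)]
        kept = filter_tpm(quants)
        again = filter_tpm([q for q in quants if q.transcript_id in kept])
        assert again == kept


class TestVectorScreen:
    def test_planted_vector_segment_is_flagged(self):
        """A 60-bp vector insert inside a 600-bp transcript must be caught
        even though it covers only 10% of the transcript."""
        rng = random.Random(7)
        vector = "".join(rng.choice("ACGT") for _ in range(60))
        flank = lambda n: "".join(rng.choice("ACGT") for _ in range(n))  # noqa: E731
        transcript = flank(270) + vector + flank(270)
        (h,) = local_align(vector, transcript, query_id="pUC-like", subject_id="tr1")[:1]
        transcript_view = AlignmentHit(
            "tr1", "pUC-like", h.percent_identity, h.align_length, h.mismatches,
            h.gap_opens, h.sstart, h.send, h.qstart, h.qend, h.evalue, h.bitscore,
            query_length=len(transcript),
        )
        assert vector_screen([transcript_view]) == {"tr1"}
        # with the full read criteria the same hit fails transcript coverage
        assert vector_screen([transcript_view], require_query_coverage=True) == set()

    def test_no_hits_flags_nothing(self):
        assert vector_screen([]) == set()

    def test_equals_any_passing_hit_oracle(self):
        from taxdecon.align import MatchCriteria

        rng = random.Random(21)
        hits = []
        for i in range(300):
            qlen = 100
            qend = rng.randint(50, 100)
            hits.append(
                AlignmentHit(
                    f"t{i % 40}", "vec", round(rng.uniform(60, 100), 1), qend, 0, 0,
                    1, qend, 1, qend, rng.random() * 1e-4, 100.0, query_length=qlen,
                )
            )
        criteria = MatchCriteria()
        oracle = {
            h.query_id
            for h in hits
            if h.percent_identity > criteria.min_identity and h.evalue < criteria.max_evalue
        }
        assert vector_screen(hits) == oracle


class TestForeignTranscriptScreen:
    def _hit(self, tid, taxid, bitscore, evalue=1e-40):
        return AlignmentHit(
            tid, f"subj{taxid}", 98.0, 95, 1, 0, 1, 95, 1, 95, evalue, bitscore,
            subject_taxid=taxid, query_length=100,
        )

    def test_bacterial_best_hit_flags_transcript(self, world):
        group_of = world.taxid_partition().assignment
        hits = [self._hit("tr1", 294, 180.0)]  # Pseudomonas
        result = foreign_transcript_screen(hits, "Eudicotyledons", group_of)
        assert result == {"tr1": "Bacteria"}

    def test_target_best_hit_wins_over_weaker_foreign(self, world):
        group_of = world.taxid_partition().assignment
        hits = [self._hit("tr1", 4081, 200.0), self._hit("tr1", 294, 150.0)]
        result = foreign_transcript_screen(hits, "Eudicotyledons", group_of)
        assert result == {}

    def test_unresolvable_taxid_errors(self, world):
        group_of = world.taxid_partition().assignment
        with pytest.raises(KeyError, match="555555"):
            foreign_transcript_screen(
                [self._hit("tr1", 555555, 100.0)], "Eudicotyledons", group_of
            )

    def test_equals_argmax_bitscore_oracle(self, world):
        from taxdecon.align import MatchCriteria, passes_match_criteria

        group_of = world.taxid_partition().assignment
        taxids = list(group_of)
        rng = random.Random(31)
        hits = []
        for i in range(400):
            hits.append(
                self._hit(
                    f"t{i % 60}",
                    rng.choice(taxids),
                    round(rng.uniform(50, 250), 1),
                    rng.random() * 1e-4,
                )
            )
        criteria = MatchCriteria()
        best = {}
        for h in hits:
            if not passes_match_criteria(h, criteria):
                continue
            if h.query_id not in best or (h.bitscore, -h.evalue) > (
                best[h.query_id].bitscore,
                -best[h.query_id].evalue,
            ):
                best[h.query_id] = h
        oracle = {
            tid: group_of[h.subject_taxid]
            for tid, h in best.items()
            if group_of[h.subject_taxid] != "Eudicotyledons"
        }
        assert foreign_transcript_screen(hits, "Eudicotyledons", group_of) == oracle


def _hsp(tid, chrom, gstart, gend, tstart=1, tend=None):
    return GenomeHSP(tid, chrom, tstart, tend or abs(gend - gstart) + 1, gstart, gend, 99.0, 100.0)


class TestExonCoverage:
    def test_full_cover_of_two_exon_isoform(self):
        isoform = IsoformModel("iso1", "chr1", "+", [(101, 200), (301, 400)])
        hsps = [_hsp("tr", "chr1", 101, 400)]
        call = exon_coverage(hsps, [isoform])
        assert call.coverage == 100.0
        assert call.bin == "gt80"
        assert call.best_isoform == "iso1"

    def test_half_cover(self):
        isoform = IsoformModel("iso1", "chr1", "+", [(101, 200), (301, 400)])
        call = exon_coverage([_hsp("tr", "chr1", 101, 200)], [isoform])
        assert call.coverage == 50.0
        assert call.bin == "b40_60"

    def test_minus_strand_hsp_coords_normalised(self):
        isoform = IsoformModel("iso1", "chr1", "+", [(101, 200)])
        call = exon_coverage([_hsp("tr", "chr1", 200, 101)], [isoform])
        assert call.coverage == 100.0

    def test_no_hsps_or_zero_overlap_is_no_match(self):
        isoform = IsoformModel("iso1", "chr1", "+", [(101, 200)])
        assert exon_coverage([], [isoform]).bin == "no_match"
        off = exon_coverage([_hsp("tr", "chr1", 1000, 1100)], [isoform])
        assert off.bin == "no_match" and off.best_isoform is None

    def test_other_chromosome_is_no_candidate(self):
        isoform = IsoformModel("iso1", "chr2", "+", [(101, 200)])
        assert exon_coverage([_hsp("tr", "chr1", 101, 200)], [isoform]).bin == "no_match"

    def test_ties_prefer_longer_isoform_then_id(self):
        short_a = IsoformModel("a", "chr1", "+", [(101, 200)])
        short_b = IsoformModel("b", "chr1", "+", [(101, 200)])
        long_c = IsoformModel("c", "chr1", "+", [(101, 200), (301, 400)])
        full = [_hsp("tr", "chr1", 101, 200), _hsp("tr", "chr1", 301, 400)]
        assert exon_coverage(full, [short_a, long_c]).best_isoform == "c"
        assert exon_coverage([_hsp("tr", "chr1", 101, 200)], [short_b, short_a]).best_isoform == "a"

    def test_matches_per_base_bitmask_oracle(self):
        rng = random.Random(41)
        for _ in range(200):
            genome_len = 2000
            exons, cursor = [], rng.randint(1, 100)
            for _e in range(rng.randint(1, 4)):
                length = rng.randint(20, 200)
                if cursor + length >= genome_len:
                    break
                exons.append((cursor, cursor + length - 1))
                cursor += length + rng.randint(10, 100)
            if not exons:
                continue
            isoform = IsoformModel("iso", "chr1", "+", exons)
            hsps = []
            for _h in range(rng.randint(0, 5)):
                a = rng.randint(1, genome_len - 1)
                b = min(genome_len, a + rng.randint(10, 300))
                if rng.random() < 0.5:
                    a, b = b, a
                hsps.append(_hsp("tr", "chr1", a, b))
            call = exon_coverage(hsps, [isoform])
            mask = [False] * (genome_len + 2)
            for h in hsps:
                lo, hi = sorted((h.gstart, h.gend))
                for p in range(lo, hi + 1):
                    mask[p] = True
            covered = sum(
                1 for s, e in exons for p in range(s, e + 1) if mask[p]
            )
            expected = 100.0 * covered / isoform.exon_bases
            if expected == 0:
                assert call.bin == "no_match"
            else:
                assert call.coverage == pytest.approx(expected)

    @given(st.data())
    @settings(derandomize=True, max_examples=60)
    def test_coverage_monotone_and_split_invariant(self, data):
        """Adding an HSP never decreases coverage; splitting one HSP into two
        abutting halves never changes it; HSP order is irrelevant."""
        exons = [(101, 200), (301, 420)]
        isoform = IsoformModel("iso", "chr1", "+", exons)
        starts = data.draw(st.lists(st.integers(1, 500), min_size=1, max_size=4))
        hsps = [_hsp("tr", "chr1", s, s + data.draw(st.integers(10, 120))) for s in starts]
        base = exon_coverage(hsps, [isoform]).coverage
        extra = hsps + [_hsp("tr", "chr1", 150, 320)]
        assert exon_coverage(extra, [isoform]).coverage >= base
        first = hsps[0]
        mid = (first.gstart + first.gend) // 2
        split = hsps[1:] + [
            _hsp("tr", "chr1", first.gstart, mid),
            _hsp("tr", "chr1", mid + 1, first.gend),
        ]
        assert exon_coverage(split, [isoform]).coverage == pytest.approx(base)
        shuffled = list(reversed(hsps))
        assert exon_coverage(shuffled, [isoform]).coverage == pytest.approx(base)


class TestBinning:
    def test_gt80_edge_is_strict(self):
        assert bin_for(80.0) == "b60_80"
        assert bin_for(80.01) == "gt80"
        assert bin_for(20.0) == "le20"
        assert bin_for(0.0) == "le20"

    def test_empty_histogram(self):
        report = bin_coverage_report([])
        assert set(report) == set(COVERAGE_BINS)
        assert sum(report.values()) == 0

    def test_histogram_conserves_calls(self):
        rng = random.Random(2)
        calls = []
        for i in range(100):
            cov = round(rng.uniform(0, 100), 2)
            calls.append(CoverageCall(f"t{i}", "iso", cov, bin_for(cov)))
        report = bin_coverage_report(calls)
        assert sum(report.values()) == 100


def test_load_isoforms_groups_exons_by_parent(tmp_path):
    gff = tmp_path / "ann.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\ttest\tmRNA\t101\t400\t.\t+\t.\tID=iso1\n"
        "chr1\ttest\texon\t101\t200\t.\t+\t.\tID=e1;Parent=iso1\n"
        "chr1\ttest\texon\t301\t400\t.\t+\t.\tID=e2;Parent=iso1\n"
        "chr1\ttest\tmRNA\t501\t700\t.\t-\t.\tID=iso2\n"
        "chr1\ttest\texon\t501\t700\t.\t-\t.\tID=e3;Parent=iso2\n"
    )
    isoforms = load_isoforms(gff)
    assert [i.isoform_id for i in isoforms] == ["iso1", "iso2"]
    assert isoforms[0].exons == [(101, 200), (301, 400)]
    assert isoforms[0].exon_bases == 200
    assert isoforms[1].strand == "-"


def test_hsp_from_hit_preserves_coordinates():
    hit = AlignmentHit(
        "tr1", "chr1", 97.0, 300, 5, 1, 1, 300, 5000, 4701, 1e-60, 400.0, query_length=300
    )
    hsp = hsp_from_hit(hit)
    assert hsp.chrom == "chr1"
    assert hsp.genome_interval() == (4700, 5000)
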