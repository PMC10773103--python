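"""Two-step screening, chunking, report aggregation, and read filtering."""

import pytest

from taxdecon.align import AlignmentHit
from taxdecon.classify import (
    BuiltinAligner,
    DecontaminationConfig,
    FastqParseError,
    PrecomputedAligner,
    ReadFate,
    classify_reads,
    fastq_to_fasta_chunks,
    mate_key,
    step1_screen,
    step2_screen,
    write_filtered_reads,
)
from taxdecon.dbbuild import GroupDatabase
from taxdecon.simulate import tile_reads
import taxdecon.classify as classify_mod


def _write_fastq(path, reads):
    with open(path, "w") as handle:
        for read_id, seq in reads:
            handle.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


class TestChunking:
    def test_chunk_sizes_follow_ceiling_division(self, tmp_path):
        reads = [(f"r{i}", "ACGTACGTAC") for i in range(23)]
        _write_fastq(tmp_path / "in.fq", reads)
        chunks = fastq_to_fasta_chunks(tmp_path / "in.fq", chunk_size=10, out_dir=tmp_path / "c")
        sizes = [sum(1 for line in open(p) if line.startswith(">")) for p in chunks]
        assert sizes == [10, 10, 3]

    def test_single_read_single_chunk(self, tmp_path):
        _write_fastq(tmp_path / "in.fq", [("only", "ACGT")])
        chunks = fastq_to_fasta_chunks(tmp_path / "in.fq", chunk_size=50_000, out_dir=tmp_path / "c")
        assert len(chunks) == 1

    def test_exact_multiple_leaves_no_empty_chunk(self, tmp_path):
        reads = [(f"r{i}", "ACGT") for i in range(20)]
        _write_fastq(tmp_path / "in.fq", reads)
        chunks = fastq_to_fasta_chunks(tmp_path / "in.fq", chunk_size=10, out_dir=tmp_path / "c")
        assert len(chunks) == 2

    def test_order_and_ids_preserved_across_chunks(self, tmp_path):
        reads = [(f"r{i}", "ACGTACGT") for i in range(17)]
        _write_fastq(tmp_path / "in.fq", reads)
        chunks = fastq_to_fasta_chunks(tmp_path / "in.fq", chunk_size=5, out_dir=tmp_path / "c")
        ids = []
        for chunk in chunks:
            ids += [line[1:].strip() for line in open(chunk) if line.startswith(">")]
        assert ids == [r for r, _s in reads]

    def test_truncated_record_reports_index(self, tmp_path):
        (tmp_path / "bad.fq").write_text("@r0\nACGT\n+\nIIII\n@r1\nACGT\n")
        with pytest.raises(FastqParseError, match="record 1"):
            fastq_to_fasta_chunks(tmp_path / "bad.fq", 10, tmp_path / "c")


class TestScreening:
    def test_target_tiles_all_match_step1(self, world, group_dbs):
        reads = tile_reads(world.transcriptome[:3], source_group="target")
        pairs = [(r.read_id, r.sequence) for r in reads]
        matched, unmatched = step1_screen(
            pairs, group_dbs[world.target_group], BuiltinAligner()
        )
        assert unmatched == []
        assert len(matched) == len(pairs)

    def test_random_reads_all_unmatched(self, world, group_dbs):
        import random

        rng = random.Random(99)
        pairs = [
            (f"rand{i}", "".join(rng.choice("ACGT") for _ in range(100))) for i in range(30)
        ]
        matched, unmatched = step1_screen(
            pairs, group_dbs[world.target_group], BuiltinAligner()
        )
        assert matched == []
        assert len(unmatched) == 30

    def test_step1_partition_equals_any_passing_hit_oracle(self, world, group_dbs, spiked_sample):
        from taxdecon.align import MatchCriteria, passes_match_criteria

        sample = spiked_sample[:300]
        pairs = [(r.read_id, r.sequence) for r in sample]
        aligner = BuiltinAligner()
        db = group_dbs[world.target_group]
        matched, unmatched = step1_screen(pairs, db, aligner)
        criteria = MatchCriteria()
        oracle_matched = {
            rid
            for rid, seq in pairs
            if any(passes_match_criteria(h, criteria) for h in aligner.hits_for(rid, seq, db))
        }
        assert set(matched) == oracle_matched
        assert set(matched) | set(unmatched) == {r for r, _ in pairs}
        assert not set(matched) & set(unmatched)

    def test_fungal_read_lands_in_fungi_group(self, world, group_dbs):
        source = world.sources["Fungi"]
        read = source.sequence[1000:1100]
        others = {g: db for g, db in group_dbs.items() if g != world.target_group}
        assignment = step2_screen([("fread", read)], others, BuiltinAligner())
        assert assignment == {"fread": "Fungi"}

    def test_step2_picks_max_bitscore_group(self):
        dbs = {
            "Fungi": GroupDatabase("Fungi", "x.fa", "x.tsv", "x.off"),
            "Bacteria": GroupDatabase("Bacteria", "y.fa", "y.tsv", "y.off"),
        }

        def hit(group, bitscore, evalue=1e-30):
            return AlignmentHit(
                "r", f"{group}_subj", 99.0, 100, 1, 0, 1, 100, 1, 100, evalue, bitscore,
                subject_taxid=1, query_length=100,
            )

        class Stub:
            call_log = []

            def hits_for(self, rid, seq, db):
                return {"Fungi": [hit("Fungi", 90.0)], "Bacteria": [hit("Bacteria", 80.0)]}[db.group]

        assignment = step2_screen([("r", "A" * 100)], dbs, Stub())
        assert assignment == {"r": "Fungi"}

    def test_step2_assignments_equal_argmax_oracle(self, world, group_dbs, spiked_sample):
        from taxdecon.align import MatchCriteria, passes_match_criteria

        contaminants = [r for r in spiked_sample if r.truth_group != "target"][:150]
        pairs = [(r.read_id, r.sequence) for r in contaminants]
        others = {g: db for g, db in group_dbs.items() if g != world.target_group}
        aligner = BuiltinAligner()
        assignment = step2_screen(pairs, others, aligner)
        criteria = MatchCriteria()
        for rid, seq in pairs:
            best_group, best_key = None, None
            for group, db in others.items():
                for h in aligner.hits_for(rid, seq, db):
                    if passes_match_criteria(h, criteria):
                        key = (h.bitscore, -h.evalue)
                        if best_key is None or key > best_key:
                            best_group, best_key = group, key
            assert assignment[rid] == best_group


class TestClassifyReads:
    def test_spiked_fixture_recovers_fractions(self, world, group_dbs, spiked_sample):
        pairs = [(r.read_id, r.sequence) for r in spiked_sample]
        config = DecontaminationConfig(target_group=world.target_group, chunk_size=1000)
        fates, report = classify_reads(pairs, group_dbs, config)
        counts = {f: 0 for f in ("correct", "contaminant", "unidentified")}
        for fate in fates:
            counts[fate.fate] += 1
        assert counts["correct"] == 1600
        assert counts["contaminant"] == 400
        assert counts["unidentified"] == 0
        assert report.reads_for_assembly == 1600
        assert report.percentages()["Fungi"] == 10.0

    def test_target_only_mode_drops_unidentified(self, world, group_dbs):
        import random

        rng = random.Random(1)
        noise = [(f"n{i}", "".join(rng.choice("ACGT") for _ in range(100))) for i in range(10)]
        tiles = tile_reads(world.transcriptome[:1], source_group="target")[:10]
        pairs = [(r.read_id, r.sequence) for r in tiles] + noise
        for mode, expected in (("include_unidentified", 20), ("target_only", 10)):
            config = DecontaminationConfig(target_group=world.target_group, mode=mode)
            _fates, report = classify_reads(pairs, group_dbs, config)
            assert report.reads_for_assembly == expected

    def test_all_random_reads_fully_unidentified(self, world, group_dbs):
        import random

        rng = random.Random(2)
        pairs = [(f"n{i}", "".join(rng.choice("ACGT") for _ in range(100))) for i in range(25)]
        config = DecontaminationConfig(target_group=world.target_group)
        _fates, report = classify_reads(pairs, group_dbs, config)
        assert report.counts["unidentified"] == 25
        assert report.reads_for_assembly_percent == 100.0

    def test_matched_reads_never_screened_against_other_groups(self, world, group_dbs):
        tiles = tile_reads(world.transcriptome[:2], source_group="target")
        pairs = [(r.read_id, r.sequence) for r in tiles]
        aligner = BuiltinAligner()
        config = DecontaminationConfig(target_group=world.target_group)
        fates, _report = classify_reads(pairs, group_dbs, config, aligner=aligner)
        assert all(f.fate == "correct" for f in fates)
        foreign_calls = [(r, g) for r, g in aligner.call_log if g != world.target_group]
        assert foreign_calls == []

    def test_missing_target_database_is_config_error(self, group_dbs):
        config = DecontaminationConfig(target_group="Atlantis")
        with pytest.raises(ValueError, match="Atlantis"):
            classify_reads([("r", "ACGT" * 25)], group_dbs, config)

    def test_report_counts_sum_and_percentages(self, world, group_dbs, spiked_sample):
        pairs = [(r.read_id, r.sequence) for r in spiked_sample[:500]]
        config = DecontaminationConfig(target_group=world.target_group)
        _fates, report = classify_reads(pairs, group_dbs, config)
        assert sum(report.counts.values()) == report.total_reads == 500
        assert abs(sum(report.percentages().values()) - 100.0) <= 0.05


class TestWriteFilteredReads:
    def _fates(self, spec):
        return {
            rid: ReadFate(rid, fate, group, None) for rid, (fate, group) in spec.items()
        }

    def test_output_is_byte_preserved_and_contaminant_free(self, tmp_path):
        reads = [("a", "ACGT"), ("b", "CCCC"), ("c", "GGGG")]
        _write_fastq(tmp_path / "in.fq", reads)
        fates = self._fates(
            {"a": ("correct", "X"), "b": ("contaminant", "Fungi"), "c": ("unidentified", "")}
        )
        config = DecontaminationConfig(target_group="X")
        n = write_filtered_reads(tmp_path / "in.fq", fates, config, tmp_path / "out.fq")
        assert n == 2
        text = (tmp_path / "out.fq").read_text()
        assert text == "@a\nACGT\n+\nIIII\n@c\nGGGG\n+\nIIII\n"

    def test_target_only_excludes_unidentified(self, tmp_path):
        reads = [("a", "ACGT"), ("c", "GGGG")]
        _write_fastq(tmp_path / "in.fq", reads)
        fates = self._fates({"a": ("correct", "X"), "c": ("unidentified", "")})
        config = DecontaminationConfig(target_group="X", mode="target_only")
        n = write_filtered_reads(tmp_path / "in.fq", fates, config, tmp_path / "out.fq")
        assert n == 1
        assert "@c" not in (tmp_path / "out.fq").read_text()

    def test_paired_mates_dropped_together(self, tmp_path):
        _write_fastq(tmp_path / "r1.fq", [("p1/1", "ACGT"), ("p2/1", "TTTT")])
        _write_fastq(tmp_path / "r2.fq", [("p1/2", "ACGT"), ("p2/2", "TTTT")])
        fates = self._fates(
            {
                "p1/1": ("correct", "X"),
                "p1/2": ("correct", "X"),
                "p2/1": ("contaminant", "Fungi"),
                "p2/2": ("contaminant", "Fungi"),
            }
        )
        config = DecontaminationConfig(target_group="X", paired=True)
        n = write_filtered_reads(
            tmp_path / "r1.fq",
            fates,
            config,
            tmp_path / "o1.fq",
            reads2_source=tmp_path / "r2.fq",
            out2_path=tmp_path / "o2.fq",
        )
        assert n == 2
        assert "p2" not in (tmp_path / "o1.fq").read_text()
        assert "p2" not in (tmp_path / "o2.fq").read_text()

    def test_missing_fate_errors(self, tmp_path):
        _write_fastq(tmp_path / "in.fq", [("a", "ACGT")])
        config = DecontaminationConfig(target_group="X")
        with pytest.raises(KeyError, match="a"):
            write_filtered_reads(tmp_path / "in.fq", {}, config, tmp_path / "out.fq")


def test_pair_policy_contaminant_dominates():
    fates = [
        ReadFate("p/1", "correct", "X", 50.0),
        ReadFate("p/2", "contaminant", "Fungi", 80.0),
    ]
    classify_mod._apply_pair_policy(fates)
    assert all(f.fate == "contaminant" and f.group == "Fungi" for f in fates)


def test_pair_policy_correct_over_unidentified():
    fates = [
        ReadFate("p/1", "unidentified", "", None),
        ReadFate("p/2", "correct", "X", 60.0),
    ]
    classify_mod._apply_pair_policy(fates)
    assert all(f.fate == "correct" for f in fates)


def test_mate_key_strips_suffixes():
    assert mate_key("read/1") == mate_key("read/2") == "read"
    assert mate_key("read.1") == mate_key("read.2")
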