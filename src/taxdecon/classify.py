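"""Two-step read decontamination.

Step 1 screens every read against the database of the target organism's
taxonomy group; any read with a passing hit is *correct* and is never
looked at again (this deliberately keeps horizontally transferred genes
present in the target group).  Step 2 screens the remaining reads against
the other 18 group databases: a read is a *contaminant* of the group
holding its best passing hit (highest bitscore), and *unidentified* if no
group produces a passing hit.

Reads kept for assembly are correct + unidentified by default
(``include_unidentified``), or correct only (``target_only``) for
well-annotated organisms.

Reads are processed in chunks (default 50,000 sequences, mirroring the
FASTQ→FASTA splitting used at production scale); chunking is purely an I/O
optimisation and never changes the classification.
"""

from __future__ import annotations

import gzip
import json
import logging
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align import (
    AlignmentHit,
    MatchCriteria,
    ScoringScheme,
    local_align,
    parse_blast_tab,
    passes_match_criteria,
    revcomp,
)
from .dbbuild import GroupDatabase
from .taxonomy import DEFAULT_GROUP_ORDER

__all__ = [
    "ReadFate",
    "ScreenReport",
    "DecontaminationConfig",
    "BuiltinAligner",
    "PrecomputedAligner",
    "FastqParseError",
    "fastq_to_fasta_chunks",
    "step1_screen",
    "step2_screen",
    "classify_reads",
    "write_filtered_reads",
    "read_sequences",
]

logger = logging.getLogger(__name__)

FATES = ("correct", "contaminant", "unidentified")


@dataclass
class ReadFate:
    read_id: str
    fate: str  # "correct" | "contaminant" | "unidentified"
    group: str  # target group, best foreign group, or "" for unidentified
    best_bitscore: float | None = None


@dataclass
class DecontaminationConfig:
    target_group: str
    criteria: MatchCriteria = field(default_factory=MatchCriteria)
    mode: str = "include_unidentified"  # or "target_only"
    chunk_size: int = 50_000
    paired: bool = False
    group_order: Sequence[str] = DEFAULT_GROUP_ORDER

    def __post_init__(self) -> None:
        if self.chunk_size <= 0:
            raise ValueError("chunk_size must be positive")
        if self.mode not in ("include_unidentified", "target_only"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class ScreenReport:
    """Per-group aggregate of a classification run.

    ``counts`` maps each group name (plus ``"unidentified"``) to a read
    count; the target group's row holds the correct reads.  Percentages are
    reported at two decimals and may sum to 99.99/100.01 by rounding, so
    exact counts always travel with them.
    """

    target_group: str
    mode: str
    total_reads: int
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total_reads:
            raise ValueError("report counts do not sum to total_reads")

    def percentages(self) -> dict[str, float]:
        if self.total_reads == 0:
            return {k: 0.0 for k in self.counts}
        return {k: round(100.0 * v / self.total_reads, 2) for k, v in self.counts.items()}

    @property
    def reads_for_assembly(self) -> int:
        kept = self.counts.get(self.target_group, 0)
        if self.mode == "include_unidentified":
            kept += self.counts.get("unidentified", 0)
        return kept

    @property
    def reads_for_assembly_percent(self) -> float:
        if self.total_reads == 0:
            return 0.0
        return round(100.0 * self.reads_for_assembly / self.total_reads, 2)

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages()
        frame = pd.DataFrame(
            {
                "reads": [self.counts[k] for k in self.counts],
                "percent": [pct[k] for k in self.counts],
            },
            index=list(self.counts),
        )
        frame.index.name = "group"
        return frame

    def to_tsv(self, path: str | os.PathLike) -> None:
        frame = self.to_frame()
        with open(path, "w") as handle:
            frame.to_csv(handle, sep="\t", float_format="%.2f")
            handle.write(
                f"# reads for assembly\t{self.reads_for_assembly}"
                f"\t{self.reads_for_assembly_percent:.2f}\n"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "target_group": self.target_group,
                "mode": self.mode,
                "total_reads": self.total_reads,
                "counts": self.counts,
                "percentages": self.percentages(),
                "reads_for_assembly": self.reads_for_assembly,
                "reads_for_assembly_percent": self.reads_for_assembly_percent,
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# aligner backends


class BuiltinAligner:
    """Seed-and-verify screening over a group database.

    A database is indexed once into an exact k-mer table (default k=31).
    A read's k-mers (both strands) nominate candidate (subject, diagonal)
    placements; exact full-length placements become perfect hits directly,
    anything else is verified with the affine-gap local aligner on a window
    around the seed.  A read with no shared k-mer produces no hit, so
    sequences sharing no k-mer of length >= k can never cross-match.
    """

    def __init__(
        self,
        scoring: ScoringScheme | None = None,
        seed_length: int = 31,
        min_score: int = 20,
    ) -> None:
        self.scoring = scoring or ScoringScheme()
        self.seed_length = seed_length
        self.min_score = min_score
        self._indexes: dict[str, tuple] = {}
        #: (read_id, group) pairs, appended once per screened read — lets
        #: callers assert the step-1 shortcut (no step-2 work for matched reads).
        self.call_log: list[tuple[str, str]] = []

    def _index(self, db: GroupDatabase):
        key = str(db.fasta_path)
        if key not in self._indexes:
            sequences = list(db.iter_sequences())  # (accession, taxid, sequence)
            k = self.seed_length
            table: dict[str, list[tuple[int, int]]] = {}
            for idx, (_acc, _taxid, seq) in enumerate(sequences):
                for pos in range(len(seq) - k + 1):
                    table.setdefault(seq[pos : pos + k], []).append((idx, pos))
            total = sum(len(s[2]) for s in sequences)
            self._indexes[key] = (sequences, table, total)
        return self._indexes[key]

    def hits_for(self, read_id: str, sequence: str, db: GroupDatabase) -> list[AlignmentHit]:
        self.call_log.append((read_id, db.group))
        sequences, table, total = self._index(db)
        k = self.seed_length
        if len(sequence) < k:
            return []

        hits: dict[tuple[str, str], AlignmentHit] = {}  # (subject, strand) -> best hit
        for strand, oriented in (("+", sequence), ("-", revcomp(sequence))):
            candidates: dict[tuple[int, int], int] = {}  # (subject idx, diagonal) -> seed qpos
            for qpos in range(len(oriented) - k + 1):
                for idx, spos in table.get(oriented[qpos : qpos + k], ()):
                    diag = spos - qpos
                    if (idx, diag) not in candidates:
                        candidates[(idx, diag)] = qpos
            for (idx, diag), qpos in candidates.items():
                accession, taxid, subject = sequences[idx]
                hit = self._verify(
                    read_id, sequence, oriented, strand, subject, diag, accession, taxid, total
                )
                if hit is None:
                    continue
                key = (accession, strand)
                if key not in hits or hit.bitscore > hits[key].bitscore:
                    hits[key] = hit
        return sorted(hits.values(), key=lambda h: -h.bitscore)

    def _verify(
        self,
        read_id: str,
        sequence: str,
        oriented: str,
        strand: str,
        subject: str,
        diag: int,
        accession: str,
        taxid: int,
        db_length: int,
    ) -> AlignmentHit | None:
        L = len(oriented)
        # Fast path: the read sits on this diagonal as an exact substring.
        if 0 <= diag and diag + L <= len(subject) and subject[diag : diag + L] == oriented:
            score = self.scoring.match * L
            sstart, send = diag + 1, diag + L
            if strand == "-":
                sstart, send = send, sstart
            return AlignmentHit(
                query_id=read_id,
                subject_id=accession,
                percent_identity=100.0,
                align_length=L,
                mismatches=0,
                gap_opens=0,
                qstart=1,
                qend=L,
                sstart=sstart,
                send=send,
                evalue=self.scoring.evalue(score, L, db_length),
                bitscore=self.scoring.bitscore(score),
                subject_taxid=taxid,
                query_length=L,
            )
        # General path: affine local alignment on a window around the diagonal.
        start = max(0, diag - L)
        stop = min(len(subject), diag + 2 * L)
        window = subject[start:stop]
        if not window:
            return None
        best = None
        for hit in local_align(
            sequence if strand == "+" else oriented,
            window,
            scoring=self.scoring,
            min_score=self.min_score,
            query_id=read_id,
            subject_id=accession,
            subject_taxid=taxid,
            db_length=db_length,
        ):
            if best is None or hit.bitscore > best.bitscore:
                best = hit
        if best is None:
            return None
        # Shift window coordinates back to the subject, fix strand direction.
        forward = best.sstart <= best.send
        sstart, send = best.sstart + start, best.send + start
        if strand == "-":
            # query was reverse-complemented before alignment: restore forward
            # query coordinates and flip the subject interval
            if forward:
                best.qstart, best.qend = (
                    len(sequence) - best.qend + 1,
                    len(sequence) - best.qstart + 1,
                )
                sstart, send = send, sstart
        best.sstart, best.send = sstart, send
        return best


class PrecomputedAligner:
    """Bring-your-own-aligner backend: outfmt-6 hit files, one per group."""

    def __init__(self, hit_files: Mapping[str, str | os.PathLike]):
        self._by_group: dict[str, dict[str, list[AlignmentHit]]] = {}
        for group, path in hit_files.items():
            per_read: dict[str, list[AlignmentHit]] = {}
            with open(path) as handle:
                for hit in parse_blast_tab(handle):
                    per_read.setdefault(hit.query_id, []).append(hit)
            self._by_group[group] = per_read
        self.call_log: list[tuple[str, str]] = []

    def hits_for(self, read_id: str, sequence: str, db: GroupDatabase) -> list[AlignmentHit]:
        self.call_log.append((read_id, db.group))
        return self._by_group.get(db.group, {}).get(read_id, [])


# ---------------------------------------------------------------------------
# FASTQ/FASTA plumbing


class FastqParseError(ValueError):
    """Truncated or malformed FASTQ record; message carries the record index."""


def _open_text(path: str | os.PathLike):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_sequences(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from FASTA or FASTQ (gz supported)."""
    pairs: list[tuple[str, str]] = []
    with _open_text(path) as handle:
        first = handle.read(1)
        handle.seek(0)
        if first == "@":
            for read_id, seq, _qual in _iter_fastq(handle):
                pairs.append((read_id, seq))
        else:
            current, chunks = None, []
            for line in handle:
                line = line.rstrip("\n")
                if line.startswith(">"):
                    if current is not None:
                        pairs.append((current, "".join(chunks)))
                    current, chunks = line[1:].split()[0], []
                elif line:
                    chunks.append(line)
            if current is not None:
                pairs.append((current, "".join(chunks)))
    return pairs


def _iter_fastq(handle):
    index = 0
    while True:
        header = handle.readline()
        if not header:
            return
        if not header.startswith("@"):
            raise FastqParseError(f"record {index}: header does not start with '@'")
        seq = handle.readline()
        plus = handle.readline()
        qual = handle.readline()
        if not qual:
            raise FastqParseError(f"record {index}: truncated record")
        if not plus.startswith("+"):
            raise FastqParseError(f"record {index}: missing '+' separator line")
        seq, qual = seq.rstrip("\n"), qual.rstrip("\n")
        if len(seq) != len(qual):
            raise FastqParseError(f"record {index}: sequence/quality length mismatch")
        yield header[1:].rstrip("\n").split()[0], seq, qual
        index += 1


def fastq_to_fasta_chunks(
    fastq_source: str | os.PathLike, chunk_size: int = 50_000, out_dir: str | os.PathLike = "."
) -> list[Path]:
    """Convert FASTQ to FASTA split into files of ``chunk_size`` sequences.

    Every chunk except possibly the last holds exactly ``chunk_size`` reads;
    concatenating the chunks preserves the input order and read ids.
    """
    if chunk_size <= 0:
        raise ValueError("chunk_size must be positive")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    handle = None
    written = 0
    try:
        with _open_text(fastq_source) as fastq:
            for read_id, seq, _qual in _iter_fastq(fastq):
                if handle is None or written == chunk_size:
                    if handle is not None:
                        handle.close()
                    paths.append(out / f"chunk_{len(paths) + 1:05d}.fa")
                    handle = open(paths[-1], "w")
                    written = 0
                handle.write(f">{read_id}\n{seq}\n")
                written += 1
    finally:
        if handle is not None:
            handle.close()
    return paths


# ---------------------------------------------------------------------------
# two-step screening


def _best_passing_hit(hits, criteria) -> AlignmentHit | None:
    best = None
    for hit in hits:
        if passes_match_criteria(hit, criteria):
            if best is None or (hit.bitscore, -hit.evalue) > (best.bitscore, -best.evalue):
                best = hit
    return best


def step1_screen(
    reads: Sequence[tuple[str, str]],
    target_db: GroupDatabase,
    aligner,
    criteria: MatchCriteria | None = None,
) -> tuple[list[str], list[str]]:
    """Split reads into (matched, unmatched) against the target group database."""
    criteria = criteria or MatchCriteria()
    matched, unmatched = [], []
    for read_id, seq in reads:
        if _best_passing_hit(aligner.hits_for(read_id, seq, target_db), criteria):
            matched.append(read_id)
        else:
            unmatched.append(read_id)
    return matched, unmatched


def _step2_with_hits(
    unmatched_reads: Sequence[tuple[str, str]],
    other_group_dbs: Mapping[str, GroupDatabase],
    aligner,
    criteria: MatchCriteria,
    group_order: Sequence[str],
) -> dict[str, tuple[str, AlignmentHit] | None]:
    rank = {name: i for i, name in enumerate(group_order)}
    out: dict[str, tuple[str, AlignmentHit] | None] = {}
    for read_id, seq in unmatched_reads:
        candidates: list[tuple[str, AlignmentHit]] = []
        for group, db in other_group_dbs.items():
            best = _best_passing_hit(aligner.hits_for(read_id, seq, db), criteria)
            if best is not None:
                candidates.append((group, best))
        if not candidates:
            out[read_id] = None
            continue
        candidates.sort(
            key=lambda gh: (-gh[1].bitscore, gh[1].evalue, rank.get(gh[0], len(rank)))
        )
        if len(candidates) > 1 and candidates[0][1].bitscore == candidates[1][1].bitscore:
            logger.info(
                "read %s: bitscore tie between groups %s and %s, keeping %s",
                read_id,
                candidates[0][0],
                candidates[1][0],
                candidates[0][0],
            )
        out[read_id] = candidates[0]
    return out


def step2_screen(
    unmatched_reads: Sequence[tuple[str, str]],
    other_group_dbs: Mapping[str, GroupDatabase],
    aligner,
    criteria: MatchCriteria | None = None,
    group_order: Sequence[str] = DEFAULT_GROUP_ORDER,
) -> dict[str, str | None]:
    """Assign each unmatched read to the group of its best passing hit.

    The winner is the maximum bitscore over all groups; ties break by lower
    e-value, then by group order (logged).  Reads with no passing hit map
    to ``None`` (unidentified).
    """
    results = _step2_with_hits(
        unmatched_reads, other_group_dbs, aligner, criteria or MatchCriteria(), group_order
    )
    return {rid: (res[0] if res else None) for rid, res in results.items()}


def _chunks(items: Sequence, size: int):
    for start in range(0, len(items), size):
        yield items[start : start + size]


_MATE_SUFFIX = re.compile(r"[/._][12]$")


def mate_key(read_id: str) -> str:
    """Pair key for a read id (strips a trailing /1, /2, .1, _2 ... suffix)."""
    return _MATE_SUFFIX.sub("", read_id)


def _apply_pair_policy(fates: list[ReadFate]) -> None:
    """Harmonise mate fates in place.

    A pair is contaminant if either mate is contaminant; otherwise correct
    if either mate is correct; otherwise unidentified.
    """
    pairs: dict[str, list[ReadFate]] = {}
    for fate in fates:
        pairs.setdefault(mate_key(fate.read_id), []).append(fate)
    for group in pairs.values():
        if len(group) < 2:
            continue
        contaminants = [f for f in group if f.fate == "contaminant"]
        corrects = [f for f in group if f.fate == "correct"]
        if contaminants:
            lead = max(contaminants, key=lambda f: f.best_bitscore or 0.0)
            for f in group:
                f.fate, f.group, f.best_bitscore = "contaminant", lead.group, lead.best_bitscore
        elif corrects:
            lead = max(corrects, key=lambda f: f.best_bitscore or 0.0)
            for f in group:
                f.fate, f.group, f.best_bitscore = "correct", lead.group, lead.best_bitscore


def classify_reads(
    reads: Sequence[tuple[str, str]],
    databases: Mapping[str, GroupDatabase],
    config: DecontaminationConfig,
    aligner=None,
) -> tuple[list[ReadFate], ScreenReport]:
    """Run the two-step screen over all reads and aggregate a report.

    ``databases`` maps group name -> :class:`GroupDatabase` and must contain
    the target group.  Results are independent of ``config.chunk_size``.
    """
    if config.target_group not in databases:
        raise ValueError(
            f"target group {config.target_group!r} absent from databases "
            f"({sorted(databases)})"
        )
    aligner = aligner if aligner is not None else BuiltinAligner()
    target_db = databases[config.target_group]
    others = {g: db for g, db in databases.items() if g != config.target_group}
    criteria = config.criteria

    fate_of: dict[str, ReadFate] = {}
    reads = list(reads)
    for chunk in _chunks(reads, config.chunk_size):
        best_target: dict[str, AlignmentHit] = {}
        unmatched: list[tuple[str, str]] = []
        for read_id, seq in chunk:
            best = _best_passing_hit(aligner.hits_for(read_id, seq, target_db), criteria)
            if best is not None:
                best_target[read_id] = best
            else:
                unmatched.append((read_id, seq))
        assignments = _step2_with_hits(
            unmatched, others, aligner, criteria, config.group_order
        )
        for read_id, seq in chunk:
            if read_id in best_target:
                fate_of[read_id] = ReadFate(
                    read_id, "correct", config.target_group, best_target[read_id].bitscore
                )
            else:
                assigned = assignments[read_id]
                if assigned is None:
                    fate_of[read_id] = ReadFate(read_id, "unidentified", "", None)
                else:
                    group, hit = assigned
                    fate_of[read_id] = ReadFate(read_id, "contaminant", group, hit.bitscore)

    fates = [fate_of[read_id] for read_id, _seq in reads]
    if config.paired:
        _apply_pair_policy(fates)

    counts = {name: 0 for name in config.group_order}
    counts["unidentified"] = 0
    for fate in fates:
        if fate.fate == "correct":
            counts[config.target_group] += 1
        elif fate.fate == "contaminant":
            counts[fate.group] = counts.get(fate.group, 0) + 1
        else:
            counts["unidentified"] += 1
    report = ScreenReport(
        target_group=config.target_group,
        mode=config.mode,
        total_reads=len(fates),
        counts=counts,
    )
    return fates, report


def write_filtered_reads(
    reads_source: str | os.PathLike,
    fates: Mapping[str, ReadFate] | Sequence[ReadFate],
    config: DecontaminationConfig,
    out_path: str | os.PathLike,
    reads2_source: str | os.PathLike | None = None,
    out2_path: str | os.PathLike | None = None,
) -> int:
    """Copy the reads kept for assembly to ``out_path``, records byte-preserved.

    Keeps correct reads, plus unidentified ones in ``include_unidentified``
    mode; contaminants never pass.  In paired mode both mates of a pair are
    kept or dropped together (supply ``reads2_source``/``out2_path`` for
    the second mate file).  Returns the number of records written.
    """
    if not isinstance(fates, Mapping):
        fates = {f.read_id: f for f in fates}

    keep_fates = {"correct"}
    if config.mode == "include_unidentified":
        keep_fates.add("unidentified")

    def keep(read_id: str) -> bool:
        key = read_id
        if key not in fates and config.paired:
            # per-pair fate tables may be keyed by the mate key
            key = mate_key(read_id)
        if key not in fates:
            raise KeyError(f"no fate recorded for read {read_id!r}")
        return fates[key].fate in keep_fates

    written = 0
    sources = [(reads_source, out_path)]
    if reads2_source is not None:
        if out2_path is None:
            raise ValueError("out2_path required when reads2_source is given")
        sources.append((reads2_source, out2_path))
    for src, dst in sources:
        with _open_text(src) as handle, open(dst, "w") as out:
            for record_id, record in _iter_raw_records(handle):
                if keep(record_id):
                    out.write(record)
                    written += 1
    return written


def _iter_raw_records(handle):
    """Yield (id, raw_record_text) from FASTQ or FASTA without re-formatting."""
    first = handle.read(1)
    handle.seek(0)
    if first == "@":
        while True:
            lines = [handle.readline() for _ in range(4)]
            if not lines[0]:
                return
            if not lines[3]:
                raise FastqParseError("truncated FASTQ record at end of file")
            yield lines[0][1:].split()[0], "".join(lines)
    else:
        record_id, chunk = None, []
        for line in handle:
            if line.startswith(">"):
                if record_id is not None:
                    yield record_id, "".join(chunk)
                record_id, chunk = line[1:].split()[0], [line]
            else:
                chunk.append(line)
        if record_id is not None:
            yield record_id, "".join(chunk)
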