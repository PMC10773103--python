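"""Synthetic data: fixture taxonomies and genomes, read generation, spiking.

This module produces the controlled study conditions used throughout the
test suite and examples:

* a small taxonomy tree (~60 nodes) spanning all 19 database groups, with
  one species per group (plus a mollusc whose group, by the hierarchy, is
  Eukaryota — modelling the "Metazoan" contaminant category);
* one random genome per species, generated so that no 31-mer (canonical,
  i.e. strand-collapsed) is shared between any two species — reads can then
  only ever align to their own source, which makes classification recovery
  exactly checkable;
* clean reads from the target transcriptome, either tiled (100 bp windows
  every 50 bp) or randomly sampled as error-free paired ends;
* contamination spiking at fixed per-group proportions with the truth label
  encoded in each read id (``group|accession|offset|serial``), defaulting
  to 4% Bacteria, 1% Archaea, 10% Fungi, 1% Arthropoda, 1% Chordata,
  1% Metazoa, 1% Eukaryota and 1% Viruses — 20% of the final sample.

All randomness flows through a single seeded ``numpy`` generator, so equal
seeds give byte-identical output.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import ReadFate
from .dbbuild import AssemblyRecord, SequenceEntry
from .taxonomy import (
    GroupSpec,
    TaxonomyTree,
    default_group_table,
    load_taxdump,
    partition,
)

__all__ = [
    "SpikeProfile",
    "LabeledRead",
    "GroupSource",
    "FixtureWorld",
    "tile_reads",
    "sample_reads",
    "spike_contamination",
    "make_fixture_world",
    "evaluate_classification",
    "truth_from_read_id",
    "write_fastq",
    "write_fasta",
]

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
DEFAULT_QUALITY_CHAR = "I"


@dataclass(frozen=True)
class LabeledRead:
    """A simulated read whose id encodes its ground truth as
    ``group|source_accession|offset|serial`` (plus ``/1``/``/2`` for mates)."""

    read_id: str
    sequence: str
    quality: str = ""

    def with_default_quality(self) -> "LabeledRead":
        if self.quality:
            return self
        return LabeledRead(self.read_id, self.sequence, DEFAULT_QUALITY_CHAR * len(self.sequence))

    @property
    def truth_group(self) -> str:
        return truth_from_read_id(self.read_id)


def truth_from_read_id(read_id: str) -> str:
    """Recover the source-group truth label encoded in a simulated read id."""
    return read_id.split("|", 1)[0]


@dataclass(frozen=True)
class SpikeProfile:
    """Per-source contaminant fractions of the *total* spiked sample."""

    fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "Bacteria": 0.04,
            "Archaea": 0.01,
            "Fungi": 0.10,
            "Arthropoda": 0.01,
            "Chordata": 0.01,
            "Metazoa": 0.01,
            "Eukaryota": 0.01,
            "Viruses": 0.01,
        }
    )

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("spike fractions must be non-negative")
        if sum(self.fractions.values()) >= 1:
            raise ValueError("spike fractions must sum to < 1")

    @property
    def total_fraction(self) -> float:
        return sum(self.fractions.values())


# ---------------------------------------------------------------------------
# read generation


def tile_reads(
    transcripts: Sequence[tuple[str, str]],
    read_length: int = 100,
    step: int = 50,
    source_group: str = "target",
) -> list[LabeledRead]:
    """Tile overlapping single-end reads across each transcript.

    Reads start at offsets 0, step, 2*step, ... while a full window fits;
    a transcript of length L yields floor((L - read_length)/step) + 1 reads,
    and transcripts shorter than ``read_length`` yield none (warned).
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    if not 0 < step <= read_length:
        raise ValueError("step must satisfy 0 < step <= read_length")
    reads: list[LabeledRead] = []
    serial = 0
    for accession, seq in transcripts:
        if len(seq) < read_length:
            logger.warning(
                "transcript %s (%d bp) shorter than read length %d, skipped",
                accession,
                len(seq),
                read_length,
            )
            continue
        for offset in range(0, len(seq) - read_length + 1, step):
            reads.append(
                LabeledRead(
                    f"{source_group}|{accession}|{offset}|{serial}",
                    seq[offset : offset + read_length],
                    DEFAULT_QUALITY_CHAR * read_length,
                )
            )
            serial += 1
    return reads


def sample_reads(
    transcripts: Sequence[tuple[str, str]],
    n_pairs: int,
    read_length: int = 100,
    fragment_mean: float = 300.0,
    fragment_sd: float = 30.0,
    seed: int | np.random.Generator = 0,
    source_group: str = "target",
) -> list[LabeledRead]:
    """Sample error-free paired-end reads from a transcript set.

    Transcripts are chosen proportionally to their length; a fragment is
    placed uniformly, the forward mate reads its 5' end and the reverse
    mate the reverse complement of its 3' end.  Deterministic per seed.
    """
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    if n_pairs == 0:
        return []
    usable = [(acc, seq) for acc, seq in transcripts if len(seq) >= read_length]
    if not usable:
        raise ValueError("no transcript is at least one read length long")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    lengths = np.array([len(seq) for _acc, seq in usable], dtype=float)
    choice = rng.choice(len(usable), size=n_pairs, p=lengths / lengths.sum())
    frags = rng.normal(fragment_mean, fragment_sd, size=n_pairs)
    starts_unit = rng.random(size=n_pairs)

    reads: list[LabeledRead] = []
    for serial in range(n_pairs):
        accession, seq = usable[int(choice[serial])]
        frag = int(round(frags[serial]))
        frag = max(read_length, min(frag, len(seq)))
        start = int(starts_unit[serial] * (len(seq) - frag + 1))
        fragment = seq[start : start + frag]
        fwd = fragment[:read_length]
        rev = _revcomp(fragment)[:read_length]
        stem = f"{source_group}|{accession}|{start}|{serial}"
        qual = DEFAULT_QUALITY_CHAR * read_length
        reads.append(LabeledRead(f"{stem}/1", fwd, qual))
        reads.append(LabeledRead(f"{stem}/2", rev, qual))
    return reads


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _largest_remainder(fractions: Mapping[str, float], total: int, n_target: int) -> dict[str, int]:
    """Integer per-group counts: round(f*total) corrected to sum to n_target."""
    raw = {g: f * total for g, f in fractions.items()}
    counts = {g: int(np.floor(v)) for g, v in raw.items()}
    remainder = n_target - sum(counts.values())
    if remainder < 0:
        raise ValueError("spike fractions inconsistent with contaminant budget")
    order = sorted(raw, key=lambda g: (-(raw[g] - counts[g]), list(fractions).index(g)))
    for g in order[:remainder]:
        counts[g] += 1
    return counts


def spike_contamination(
    clean_reads: Sequence[LabeledRead],
    group_sources: Mapping[str, "GroupSource"],
    profile: SpikeProfile | None = None,
    read_length: int = 100,
    seed: int | np.random.Generator = 0,
) -> list[LabeledRead]:
    """Mix contaminant reads into a clean sample at the profile proportions.

    The total output size N is chosen so the clean reads make up
    (1 - sum(fractions)) of it; per-source counts are the rounded
    fraction*N with a largest-remainder correction so they sum exactly to
    N - len(clean_reads).  Output order is shuffled under the seed.
    """
    profile = profile or SpikeProfile()
    if not profile.fractions:
        return list(clean_reads)
    missing = [g for g in profile.fractions if g not in group_sources]
    if missing:
        raise KeyError(f"no contaminant source sequence for profile groups {missing}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_clean = len(clean_reads)
    total = int(round(n_clean / (1.0 - profile.total_fraction)))
    n_contaminant = total - n_clean
    counts = _largest_remainder(profile.fractions, total, n_contaminant)

    spiked: list[LabeledRead] = list(clean_reads)
    serial = 0
    for label in profile.fractions:
        source = group_sources[label]
        seq = source.sequence
        if len(seq) < read_length:
            raise ValueError(f"source {label} shorter than read length")
        positions = rng.integers(0, len(seq) - read_length + 1, size=counts[label])
        strands = rng.integers(0, 2, size=counts[label])
        for pos, strand in zip(positions, strands):
            fragment = seq[int(pos) : int(pos) + read_length]
            if strand:
                fragment = _revcomp(fragment)
            spiked.append(
                LabeledRead(
                    f"{label}|{source.accession}|{int(pos)}|c{serial}",
                    fragment,
                    DEFAULT_QUALITY_CHAR * read_length,
                )
            )
            serial += 1
    order = rng.permutation(len(spiked))
    return [spiked[i] for i in order]


# ---------------------------------------------------------------------------
# fixture world


@dataclass(frozen=True)
class GroupSource:
    """One contaminant source species: its chromosome accession, taxid,
    genome sequence, and the database group its taxid partitions into."""

    accession: str
    taxid: int
    sequence: str
    group: str


@dataclass
class FixtureWorld:
    """A complete synthetic study setting (taxonomy + genomes + transcriptome)."""

    tree: TaxonomyTree
    groups: list[GroupSpec]
    assemblies: list[AssemblyRecord]
    transcriptome: list[tuple[str, str]]
    sources: dict[str, GroupSource]  # keyed by truth label, incl. "Metazoa"
    target_group: str
    target_taxid: int
    nodes_dmp: str
    names_dmp: str

    def taxid_partition(self):
        taxids = sorted({a.taxid for a in self.assemblies})
        return partition(self.tree, self.groups, taxids)

    def expected_group(self, truth_label: str) -> str:
        """Database group a contaminant with this truth label should land in
        (the target label maps to the target group)."""
        if truth_label == "target":
            return self.target_group
        return self.sources[truth_label].group

    def write_taxdump(self, out_dir: str | os.PathLike) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "nodes.dmp").write_text(self.nodes_dmp)
        (out / "names.dmp").write_text(self.names_dmp)


# (taxid, parent, rank, scientific name) — a miniature of the public
# taxonomy covering every group anchor plus the edge-case clades the
# partition must get right (plants split three ways, mammals under
# Sarcopterygii, tunicates directly under Chordata, molluscs falling
# through Metazoa to Eukaryota, unclassified entries outside everything).
_FIXTURE_TAXA: tuple[tuple[int, int, str, str], ...] = (
    (1, 1, "no rank", "root"),
    (131567, 1, "no rank", "cellular organisms"),
    (12908, 1, "no rank", "unclassified sequences"),
    # Bacteria
    (2, 131567, "superkingdom", "Bacteria"),
    (1224, 2, "phylum", "Pseudomonadota"),
    (1236, 1224, "class", "Gammaproteobacteria"),
    (286, 1236, "genus", "Pseudomonas"),
    (294, 286, "species", "Pseudomonas fluorescens"),
    # Archaea
    (2157, 131567, "superkingdom", "Archaea"),
    (183939, 2157, "class", "Methanococci"),
    (2190, 183939, "species", "Methanocaldococcus jannaschii"),
    # Viruses
    (10239, 1, "superkingdom", "Viruses"),
    (2559587, 10239, "clade", "Riboviria"),
    (197911, 2559587, "genus", "Alphainfluenzavirus"),
    (11320, 197911, "species", "Influenza A virus"),
    # Eukaryota: plants
    (2759, 131567, "superkingdom", "Eukaryota"),
    (33090, 2759, "kingdom", "Viridiplantae"),
    (35493, 33090, "phylum", "Streptophyta"),
    (4447, 35493, "class", "Liliopsida"),
    (4530, 4447, "species", "Oryza sativa"),
    (71240, 35493, "clade", "eudicotyledons"),
    (4081, 71240, "species", "Solanum lycopersicum"),
    (3041, 33090, "phylum", "Chlorophyta"),
    (3055, 3041, "species", "Chlamydomonas reinhardtii"),
    # Eukaryota: fungi and other opisthokonts
    (33154, 2759, "clade", "Opisthokonta"),
    (4751, 33154, "kingdom", "Fungi"),
    (4932, 4751, "species", "Saccharomyces cerevisiae"),
    (33208, 33154, "kingdom", "Metazoa"),
    (6656, 33208, "phylum", "Arthropoda"),
    (7227, 6656, "species", "Drosophila melanogaster"),
    (6447, 33208, "phylum", "Mollusca"),
    (29159, 6447, "species", "Crassostrea gigas"),
    # Chordates
    (7711, 33208, "phylum", "Chordata"),
    (7712, 7711, "subphylum", "Tunicata"),
    (7719, 7712, "species", "Ciona intestinalis"),
    (89593, 7711, "subphylum", "Craniata"),
    (7742, 89593, "clade", "Vertebrata"),
    (7776, 7742, "clade", "Gnathostomata"),
    (117571, 7776, "clade", "Euteleostomi"),
    (7898, 117571, "class", "Actinopterygii"),
    (7955, 7898, "species", "Danio rerio"),
    (123365, 7898, "clade", "Neoteleostei"),
    (31033, 123365, "species", "Takifugu rubripes"),
    (8287, 117571, "superclass", "Sarcopterygii"),
    (7897, 8287, "species", "Latimeria chalumnae"),
    (32523, 8287, "clade", "Tetrapoda"),
    (8292, 32523, "class", "Amphibia"),
    (8364, 8292, "species", "Xenopus tropicalis"),
    (32524, 32523, "clade", "Amniota"),
    (8457, 32524, "clade", "Sauropsida"),
    (9031, 8457, "species", "Gallus gallus"),
    (40674, 32524, "class", "Mammalia"),
    (314147, 40674, "clade", "Glires"),
    (10090, 314147, "species", "Mus musculus"),
    (9443, 40674, "order", "Primates"),
    (9606, 9443, "species", "Homo sapiens"),
    (33554, 40674, "order", "Carnivora"),
    (9669, 33554, "species", "Mustela putorius furo"),
    (91561, 40674, "order", "Artiodactyla"),
    (9913, 91561, "species", "Bos taurus"),
    # Other eukaryotes
    (554915, 2759, "clade", "Amoebozoa"),
    (44689, 554915, "species", "Dictyostelium discoideum"),
)

# (truth label, species taxid) in generation order; the label is what the
# read ids carry, the group is derived from the taxonomy partition.
_SOURCE_SPECIES: tuple[tuple[str, int], ...] = (
    ("Bacteria", 294),
    ("Archaea", 2190),
    ("Liliopsida", 4530),
    ("Eudicotyledons", 4081),
    ("Viridiplantae", 3055),
    ("Fungi", 4932),
    ("Arthropoda", 7227),
    ("Neoteleostei", 31033),
    ("Actinopterygii", 7955),
    ("Glires", 10090),
    ("Primates", 9606),
    ("Carnivora", 9669),
    ("Artiodactyla", 9913),
    ("Amphibia", 8364),
    ("Sauropsida", 9031),
    ("Sarcopterygii", 7897),
    ("Chordata", 7719),
    ("Eukaryota", 44689),
    ("Viruses", 11320),
    ("Metazoa", 29159),
)

TARGET_LABEL = "Eudicotyledons"
KMER_GUARD = 31  # no canonical k-mer of this length is shared between sources


def fixture_taxdump() -> tuple[str, str]:
    """Render the fixture taxonomy as nodes.dmp / names.dmp text."""
    nodes = "".join(
        f"{taxid}\t|\t{parent}\t|\t{rank}\t|\n" for taxid, parent, rank, _name in _FIXTURE_TAXA
    )
    names = "".join(
        f"{taxid}\t|\t{name}\t|\t\t|\tscientific name\t|\n"
        for taxid, _parent, _rank, name in _FIXTURE_TAXA
    )
    return nodes, names


def _canonical_kmers(seq: str, k: int) -> set[str]:
    rc = _revcomp(seq)
    n = len(seq)
    return {min(seq[i : i + k], rc[n - i - k : n - i]) for i in range(n - k + 1)}


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def make_fixture_world(seed: int = 0) -> FixtureWorld:
    """Build the full synthetic study setting, deterministic under ``seed``.

    One genome (6-12 kb) per source species, regenerated on the (vanishingly
    rare) event of a cross-source canonical 31-mer collision; a 20-transcript
    target transcriptome cut from the target genome; one reference assembly
    per species carrying the chromosome plus an unplaced scaffold that the
    database build must discard.
    """
    rng = np.random.default_rng(seed)
    nodes_dmp, names_dmp = fixture_taxdump()
    tree = load_taxdump(io.StringIO(nodes_dmp), io.StringIO(names_dmp))
    groups = default_group_table()
    taxid_group = partition(tree, groups, [taxid for _label, taxid in _SOURCE_SPECIES])

    sources: dict[str, GroupSource] = {}
    claimed: set[str] = set()
    assemblies: list[AssemblyRecord] = []
    for i, (label, taxid) in enumerate(_SOURCE_SPECIES):
        length = int(rng.integers(6000, 12001))
        while True:
            genome = _random_sequence(rng, length)
            kmers = _canonical_kmers(genome, KMER_GUARD)
            if not (kmers & claimed):
                break
        claimed |= kmers
        accession = f"NC_{900001 + i}.1"
        sources[label] = GroupSource(accession, taxid, genome, taxid_group[taxid])
        assemblies.append(
            AssemblyRecord(
                assembly_accession=f"GCF_{900001 + i:09d}.1",
                taxid=taxid,
                refseq_category="reference_genome",
                release_date=date(2021, 1, 1) + timedelta(days=i),
                sequences=[
                    SequenceEntry(accession, "assembled_molecule", length, genome),
                    SequenceEntry(
                        f"NW_{900001 + i}.1", "unplaced_scaffold", 500, genome[:500]
                    ),
                ],
            )
        )

    target_genome = sources[TARGET_LABEL].sequence
    transcriptome: list[tuple[str, str]] = []
    for t in range(20):
        t_len = int(rng.integers(300, 1501))
        start = int(rng.integers(0, len(target_genome) - t_len + 1))
        transcriptome.append((f"FT{t:04d}", target_genome[start : start + t_len]))

    return FixtureWorld(
        tree=tree,
        groups=groups,
        assemblies=assemblies,
        transcriptome=transcriptome,
        sources=sources,
        target_group=taxid_group[sources[TARGET_LABEL].taxid],
        target_taxid=sources[TARGET_LABEL].taxid,
        nodes_dmp=nodes_dmp,
        names_dmp=names_dmp,
    )


# ---------------------------------------------------------------------------
# evaluation harness


@dataclass
class EvaluationResult:
    confusion: pd.DataFrame  # rows = truth label, columns = assigned group/fate
    recovery: dict[str, float]  # truth label -> fraction assigned as expected


def evaluate_classification(
    fates: Sequence[ReadFate],
    truth: Mapping[str, str],
    expected_assignment: Mapping[str, str] | None = None,
) -> EvaluationResult:
    """Score classifier output against simulator truth labels.

    ``truth`` maps read id -> truth label; ``expected_assignment`` maps a
    truth label to the group it should land in (defaults to the label
    itself; needed e.g. for Metazoa sources whose group is Eukaryota).
    Recovery for a truth label is the fraction of its reads assigned to the
    expected group; confusion rows sum to the truth counts.
    """
    missing = [f.read_id for f in fates if f.read_id not in truth]
    if missing:
        raise KeyError(f"{len(missing)} classified reads without truth labels, e.g. {missing[0]!r}")
    extra = set(truth) - {f.read_id for f in fates}
    if extra:
        raise KeyError(f"{len(extra)} truth reads never classified, e.g. {next(iter(extra))!r}")
    expected = dict(expected_assignment or {})

    cells: dict[tuple[str, str], int] = {}
    for fate in fates:
        assigned = fate.group if fate.fate != "unidentified" else "unidentified"
        key = (truth[fate.read_id], assigned)
        cells[key] = cells.get(key, 0) + 1

    rows = sorted({t for t, _a in cells})
    cols = sorted({a for _t, a in cells})
    confusion = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for (t, a), count in cells.items():
        confusion.loc[t, a] = count

    recovery = {}
    for label in rows:
        want = expected.get(label, label)
        got = int(confusion.loc[label, want]) if want in confusion.columns else 0
        recovery[label] = got / int(confusion.loc[label].sum())
    return EvaluationResult(confusion=confusion, recovery=recovery)


# ---------------------------------------------------------------------------
# output writers


def write_fastq(reads: Sequence[LabeledRead], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for read in reads:
            read = read.with_default_quality()
            handle.write(f"@{read.read_id}\n{read.sequence}\n+\n{read.quality}\n")


def write_fasta(records: Sequence[tuple[str, str]], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for name, seq in records:
            handle.write(f">{name}\n{seq}\n")
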