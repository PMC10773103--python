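"""Per-group sequence database construction.

From assembly metadata this module selects one assembly per taxon (the
RefSeq reference genome when one exists, otherwise the latest assembly),
drops unplaced scaffolds and disallowed accession prefixes, and writes one
database per taxonomy group as three files:

* ``<group>.fa``            — the sequences (FASTA, fixed 80-column wrap);
* ``<group>.taxid_map.tsv`` — accession <TAB> taxid (BLAST ``-taxid_map``
  compatible);
* ``<group>.offsets.tsv``   — accession <TAB> taxid <TAB> byte offset of the
  record's ``>`` in the FASTA, for direct extraction without a scan.

Builds are deterministic: the same inputs always produce byte-identical
files (fixed record order and line wrapping).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .taxonomy import DEFAULT_GROUP_ORDER, GroupPartition

__all__ = [
    "AssemblyRecord",
    "SequenceEntry",
    "GroupDatabase",
    "select_assembly",
    "accession_prefix_allowed",
    "filter_sequences",
    "filter_refseq",
    "build_group_databases",
    "extract_by_offset",
    "load_assembly_metadata",
    "write_assembly_metadata",
    "from_ncbi_datasets_report",
]

logger = logging.getLogger(__name__)

PLACEMENTS = ("assembled_molecule", "unplaced_scaffold", "unlocalized_scaffold")

#: Accession prefixes dropped during sequence filtering, and the exceptions
#: re-admitted (complete chromosomes submitted through GenBank).
EXCLUDED_PREFIXES = ("NW_", "NZ_")
PREFIX_EXCEPTIONS = ("NZ_CM", "NZ_CP")

FASTA_WRAP = 80


@dataclass
class SequenceEntry:
    accession: str
    placement: str
    length: int
    sequence: str = ""

    def __post_init__(self) -> None:
        if self.placement not in PLACEMENTS:
            raise ValueError(f"{self.accession}: unknown placement {self.placement!r}")
        if self.sequence and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.accession}: declared length {self.length} != sequence "
                f"length {len(self.sequence)}"
            )


@dataclass
class AssemblyRecord:
    assembly_accession: str
    taxid: int
    refseq_category: str  # "reference_genome" | "na"
    release_date: date
    sequences: list[SequenceEntry] = field(default_factory=list)
    refseq: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.release_date, str):
            self.release_date = date.fromisoformat(self.release_date)


@dataclass
class GroupDatabase:
    """Paths of one group's three database files, plus a lazy offset index."""

    group: str
    fasta_path: Path
    taxid_map_path: Path
    offset_index_path: Path
    _offsets: dict[str, tuple[int, int]] | None = field(default=None, repr=False)

    def offsets(self) -> dict[str, tuple[int, int]]:
        """accession -> (taxid, byte offset), loaded once from the index file."""
        if self._offsets is None:
            table: dict[str, tuple[int, int]] = {}
            with open(self.offset_index_path) as handle:
                for line in handle:
                    acc, taxid, offset = line.rstrip("\n").split("\t")
                    table[acc] = (int(taxid), int(offset))
            self._offsets = table
        return self._offsets

    def accessions(self) -> list[str]:
        return list(self.offsets())

    def taxid_of(self, accession: str) -> int:
        return self.offsets()[accession][0]

    def iter_sequences(self):
        """Yield (accession, taxid, sequence) by a sequential FASTA scan."""
        offsets = self.offsets()
        with open(self.fasta_path) as handle:
            acc = None
            chunks: list[str] = []
            for line in handle:
                if line.startswith(">"):
                    if acc is not None:
                        yield acc, offsets[acc][0], "".join(chunks)
                    acc = line[1:].split()[0]
                    chunks = []
                else:
                    chunks.append(line.strip())
            if acc is not None:
                yield acc, offsets[acc][0], "".join(chunks)


def select_assembly(records: Sequence[AssemblyRecord]) -> AssemblyRecord:
    """Pick one assembly for a taxon: the reference genome if present,
    otherwise the latest release (ties broken by accession, descending)."""
    if not records:
        raise ValueError("select_assembly: empty record list")
    taxids = {r.taxid for r in records}
    if len(taxids) > 1:
        raise ValueError(f"select_assembly: mixed taxids {sorted(taxids)}")
    references = [r for r in records if r.refseq_category == "reference_genome"]
    if references:
        return max(references, key=lambda r: (r.release_date, r.assembly_accession))
    return max(records, key=lambda r: (r.release_date, r.assembly_accession))


def accession_prefix_allowed(
    accession: str,
    excluded: Sequence[str] = EXCLUDED_PREFIXES,
    exceptions: Sequence[str] = PREFIX_EXCEPTIONS,
) -> bool:
    """True unless the accession carries an excluded RefSeq prefix.

    NW_ (unplaced genomic) and NZ_ (WGS projects) records are dropped, except
    NZ_CM/NZ_CP which denote complete chromosomes.
    """
    if not accession:
        raise ValueError("empty accession")
    if any(accession.startswith(p) for p in exceptions):
        return True
    return not any(accession.startswith(p) for p in excluded)


def filter_sequences(assembly: AssemblyRecord) -> list[SequenceEntry]:
    """Drop unplaced scaffolds and disallowed accession prefixes, keeping order."""
    kept = [
        entry
        for entry in assembly.sequences
        if entry.placement != "unplaced_scaffold" and accession_prefix_allowed(entry.accession)
    ]
    if not kept:
        logger.warning(
            "assembly %s: all %d sequences filtered out",
            assembly.assembly_accession,
            len(assembly.sequences),
        )
    return kept


def filter_refseq(records: Iterable[AssemblyRecord]) -> list[AssemblyRecord]:
    """Keep only RefSeq assemblies (applied before per-taxon selection)."""
    return [r for r in records if r.refseq]


def _wrap(sequence: str, width: int = FASTA_WRAP) -> str:
    return "\n".join(sequence[i : i + width] for i in range(0, len(sequence), width))


def build_group_databases(
    assemblies: Sequence[AssemblyRecord],
    partition: GroupPartition | Mapping[int, str],
    out_dir: str | os.PathLike,
) -> list[GroupDatabase]:
    """Write one three-file database per non-empty group.

    Assemblies are routed to groups through ``partition`` (taxid -> group
    name); a taxid missing from the partition is an error.  Within a group,
    records are ordered by (taxid, assembly accession, input sequence order)
    so rebuilds are byte-identical.
    """
    assignment = partition.assignment if isinstance(partition, GroupPartition) else dict(partition)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    by_group: dict[str, list[AssemblyRecord]] = {}
    for assembly in assemblies:
        if assembly.taxid not in assignment:
            raise KeyError(
                f"assembly {assembly.assembly_accession}: taxid {assembly.taxid} "
                f"not covered by the partition"
            )
        by_group.setdefault(assignment[assembly.taxid], []).append(assembly)

    order = {name: i for i, name in enumerate(DEFAULT_GROUP_ORDER)}
    databases: list[GroupDatabase] = []
    for group in sorted(by_group, key=lambda g: (order.get(g, len(order)), g)):
        members = sorted(by_group[group], key=lambda a: (a.taxid, a.assembly_accession))
        records = [
            (entry, assembly.taxid)
            for assembly in members
            for entry in filter_sequences(assembly)
        ]
        if not records:
            logger.warning("group %s: no sequences survive filtering, no database emitted", group)
            continue

        fasta_path = out / f"{group}.fa"
        map_path = out / f"{group}.taxid_map.tsv"
        offsets_path = out / f"{group}.offsets.tsv"
        try:
            with open(fasta_path, "w", newline="") as fasta, open(
                map_path, "w", newline=""
            ) as taxmap, open(offsets_path, "w", newline="") as offsets:
                position = 0
                for entry, taxid in records:
                    record = f">{entry.accession}\n{_wrap(entry.sequence)}\n"
                    fasta.write(record)
                    taxmap.write(f"{entry.accession}\t{taxid}\n")
                    offsets.write(f"{entry.accession}\t{taxid}\t{position}\n")
                    position += len(record.encode())
        except OSError as exc:
            raise OSError(f"failed writing database for group {group} under {out}: {exc}") from exc
        databases.append(GroupDatabase(group, fasta_path, map_path, offsets_path))
    return databases


def extract_by_offset(database: GroupDatabase, accession: str) -> SequenceEntry:
    """Fetch one record by its stored byte offset (no file scan)."""
    try:
        _taxid, offset = database.offsets()[accession]
    except KeyError as exc:
        raise KeyError(
            f"accession {accession!r} not in offset index of group {database.group}"
        ) from exc
    with open(database.fasta_path) as handle:
        handle.seek(offset)
        header = handle.readline()
        if not header.startswith(">") or header[1:].split()[0] != accession:
            raise ValueError(
                f"offset index of group {database.group} is stale: expected "
                f"{accession} at byte {offset}, found {header.strip()!r}"
            )
        chunks: list[str] = []
        while True:
            pos = handle.tell()
            line = handle.readline()
            if not line or line.startswith(">"):
                handle.seek(pos)
                break
            chunks.append(line.strip())
    sequence = "".join(chunks)
    return SequenceEntry(
        accession=accession,
        placement="assembled_molecule",
        length=len(sequence),
        sequence=sequence,
    )


# ---------------------------------------------------------------------------
# metadata I/O (JSON-lines dialect)


def load_assembly_metadata(path: str | os.PathLike) -> list[AssemblyRecord]:
    """Read assembly records from a JSON-lines metadata file."""
    records: list[AssemblyRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            try:
                raw = json.loads(line)
                records.append(
                    AssemblyRecord(
                        assembly_accession=raw["assembly_accession"],
                        taxid=int(raw["taxid"]),
                        refseq_category=raw.get("refseq_category", "na"),
                        release_date=raw["release_date"],
                        refseq=bool(raw.get("refseq", True)),
                        sequences=[
                            SequenceEntry(
                                accession=s["accession"],
                                placement=s["placement"],
                                length=int(s["length"]),
                                sequence=s.get("sequence", ""),
                            )
                            for s in raw.get("sequences", [])
                        ],
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise ValueError(f"{path}: bad metadata record on line {lineno}: {exc}") from exc
    return records


def write_assembly_metadata(records: Iterable[AssemblyRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for record in records:
            handle.write(
                json.dumps(
                    {
                        "assembly_accession": record.assembly_accession,
                        "taxid": record.taxid,
                        "refseq_category": record.refseq_category,
                        "release_date": record.release_date.isoformat(),
                        "refseq": record.refseq,
                        "sequences": [
                            {
                                "accession": s.accession,
                                "placement": s.placement,
                                "length": s.length,
                                "sequence": s.sequence,
                            }
                            for s in record.sequences
                        ],
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def from_ncbi_datasets_report(report: dict) -> AssemblyRecord:
    """Converter stub for a real NCBI Datasets assembly report object.

    Maps the metadata fields only; sequence entries must be attached
    separately (reports do not embed sequence data).
    """
    info = report.get("assembly_info", {})
    return AssemblyRecord(
        assembly_accession=report["accession"],
        taxid=int(report["organism"]["tax_id"]),
        refseq_category=(
            "reference_genome"
            if info.get("refseq_category", "").replace(" ", "_") == "reference_genome"
            else "na"
        ),
        release_date=info["release_date"],
        refseq=report["accession"].startswith("GCF_"),
        sequences=[],
    )
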