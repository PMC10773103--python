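"""Post-assembly transcript filters and exon-coverage quantification.

After de novo assembly, transcript sets are cleaned in three passes:
a TPM cutoff (>= 2.5 keeps a transcript) removes lowly expressed contigs;
a vector screen flags transcripts with passing hits against a vector
database (UniVec-style); and a foreign-transcript screen assigns each
transcript to the taxonomy group of its best passing nucleotide hit and
flags those whose best hit is a non-target group.

The remaining transcripts are then compared to the annotated genome:
for each transcript, its genome HSPs are intersected with the exon
intervals of every candidate isoform, coverage is the percentage of the
isoform's exon bases touched by at least one HSP, and the best isoform is
reported with the coverage binned (>80%, 60-80, 40-60, 20-40, <=20,
no-match).  Interval arithmetic is positional — strand is ignored and
minus-strand HSP coordinates are normalised before the overlap.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from .align import AlignmentHit, MatchCriteria, passes_match_criteria, query_coverage

__all__ = [
    "QuantRecord",
    "GenomeHSP",
    "IsoformModel",
    "CoverageCall",
    "COVERAGE_BINS",
    "filter_tpm",
    "vector_screen",
    "foreign_transcript_screen",
    "exon_coverage",
    "bin_coverage_report",
    "read_quant_table",
    "load_isoforms",
    "hsp_from_hit",
    "write_coverage_calls",
]


@dataclass(frozen=True)
class QuantRecord:
    transcript_id: str
    tpm: float

    def __post_init__(self) -> None:
        if not (self.tpm >= 0 and self.tpm == self.tpm and self.tpm != float("inf")):
            raise ValueError(f"{self.transcript_id}: TPM must be finite and >= 0")


@dataclass
class GenomeHSP:
    """One transcript-vs-genome HSP; genome coords may run backwards on the
    minus strand (gend < gstart)."""

    transcript_id: str
    chrom: str
    tstart: int
    tend: int
    gstart: int
    gend: int
    identity: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.tstart > self.tend:
            raise ValueError(f"{self.transcript_id}: tstart > tend")

    def genome_interval(self) -> tuple[int, int]:
        """0-based half-open genome interval, strand-normalised."""
        lo, hi = sorted((self.gstart, self.gend))
        return lo - 1, hi


@dataclass
class IsoformModel:
    isoform_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # 1-based inclusive, sorted, non-overlapping

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.isoform_id}: overlapping exons {s1}-{e1}, {s2}-{e2}")

    @property
    def exon_bases(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


COVERAGE_BINS = ("gt80", "b60_80", "b40_60", "b20_40", "le20", "no_match")

#: (bin name, exclusive lower edge) — a call falls in the first bin whose
#: edge its coverage strictly exceeds; ">80%" is strict per the top class.
DEFAULT_BIN_EDGES: tuple[tuple[str, float], ...] = (
    ("gt80", 80.0),
    ("b60_80", 60.0),
    ("b40_60", 40.0),
    ("b20_40", 20.0),
    ("le20", 0.0),
)


def bin_for(coverage: float, edges: Sequence[tuple[str, float]] = DEFAULT_BIN_EDGES) -> str:
    for name, edge in edges[:-1]:
        if coverage > edge:
            return name
    return edges[-1][0]


@dataclass(frozen=True)
class CoverageCall:
    transcript_id: str
    best_isoform: str | None
    coverage: float  # % of the best isoform's exon bases covered
    bin: str

    def __post_init__(self) -> None:
        if not 0 <= self.coverage <= 100:
            raise ValueError(f"{self.transcript_id}: coverage outside [0, 100]")
        if (self.best_isoform is None) != (self.bin == "no_match"):
            raise ValueError(f"{self.transcript_id}: no_match bin inconsistent with isoform")


# ---------------------------------------------------------------------------
# expression filter


def filter_tpm(
    quants: Iterable[QuantRecord] | pd.DataFrame, cutoff: float = 2.5
) -> list[str]:
    """Keep transcript ids with TPM >= cutoff (inclusive).  Duplicate ids error."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    if isinstance(quants, pd.DataFrame):
        quants = [QuantRecord(str(t), float(v)) for t, v in zip(quants.iloc[:, 0], quants.iloc[:, 1])]
    seen: set[str] = set()
    kept: list[str] = []
    for record in quants:
        if record.transcript_id in seen:
            raise ValueError(f"duplicate transcript id {record.transcript_id!r} in quant table")
        seen.add(record.transcript_id)
        if record.tpm >= cutoff:
            kept.append(record.transcript_id)
    return kept


def read_quant_table(path: str | os.PathLike) -> list[QuantRecord]:
    """Read a two-column (transcript id, TPM) TSV, with or without a header."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    if not str(frame.iloc[0, 1]).replace(".", "", 1).replace("e-", "", 1).lstrip("-").isdigit():
        frame = frame.iloc[1:]
    return [QuantRecord(str(t), float(v)) for t, v in zip(frame.iloc[:, 0], frame.iloc[:, 1])]


# ---------------------------------------------------------------------------
# contamination screens


def vector_screen(
    hits: Iterable[AlignmentHit],
    policy: MatchCriteria | None = None,
    require_query_coverage: bool = False,
) -> set[str]:
    """Transcripts with at least one vector hit passing the policy thresholds.

    Identity and e-value bounds of ``policy`` apply (strict, as for reads).
    The query-coverage bound is off by default: a vector insert is normally
    a small fraction of the transcript carrying it, so demanding >75%
    transcript coverage would miss nearly all real vector contamination.
    Set ``require_query_coverage=True`` to screen with the full criteria.
    """
    policy = policy or MatchCriteria()
    flagged = set()
    for hit in hits:
        if hit.percent_identity <= policy.min_identity or hit.evalue >= policy.max_evalue:
            continue
        if require_query_coverage and query_coverage(hit) <= policy.min_query_coverage:
            continue
        flagged.add(hit.query_id)
    return flagged


def foreign_transcript_screen(
    hits: Iterable[AlignmentHit],
    target_group: str,
    group_of: Mapping[int, str],
    criteria: MatchCriteria | None = None,
) -> dict[str, str]:
    """Flag transcripts whose best passing hit belongs to a non-target group.

    ``group_of`` maps subject taxids to group names (build it with
    :func:`taxdecon.taxonomy.partition`); an unresolvable taxid on a passing
    hit is an error.  Returns {transcript_id: contaminant group}.
    """
    criteria = criteria or MatchCriteria()
    best: dict[str, AlignmentHit] = {}
    for hit in hits:
        if not passes_match_criteria(hit, criteria):
            continue
        if hit.subject_taxid not in group_of:
            raise KeyError(
                f"hit {hit.query_id}->{hit.subject_id}: taxid {hit.subject_taxid} "
                f"not resolvable to a taxonomy group"
            )
        current = best.get(hit.query_id)
        if current is None or (hit.bitscore, -hit.evalue) > (current.bitscore, -current.evalue):
            best[hit.query_id] = hit
    return {
        tid: group_of[hit.subject_taxid]
        for tid, hit in best.items()
        if group_of[hit.subject_taxid] != target_group
    }


# ---------------------------------------------------------------------------
# exon coverage


def _merged_tree(intervals: Iterable[tuple[int, int]]) -> IntervalTree:
    tree = IntervalTree.from_tuples((lo, hi) for lo, hi in intervals if hi > lo)
    tree.merge_overlaps()
    return tree


def exon_coverage(
    hsps: Sequence[GenomeHSP],
    isoforms: Sequence[IsoformModel],
    edges: Sequence[tuple[str, float]] = DEFAULT_BIN_EDGES,
) -> CoverageCall:
    """Coverage of the best-matching annotated isoform by one transcript's HSPs.

    For every isoform on a chromosome the HSPs touch, coverage is
    100 * |union(HSP intervals) ∩ union(exon intervals)| / exon bases.
    Best isoform = argmax coverage, ties to the larger exon total then the
    lexicographically smaller id; zero coverage everywhere (or no HSPs) is
    a ``no_match``.
    """
    transcript_id = hsps[0].transcript_id if hsps else ""
    if not hsps or not isoforms:
        return CoverageCall(transcript_id, None, 0.0, "no_match")

    by_chrom: dict[str, IntervalTree] = {}
    for chrom in {h.chrom for h in hsps}:
        by_chrom[chrom] = _merged_tree(
            h.genome_interval() for h in hsps if h.chrom == chrom
        )

    best: tuple[float, int, str] | None = None  # (coverage, exon_bases, id)
    for isoform in isoforms:
        tree = by_chrom.get(isoform.chrom)
        if tree is None:
            continue
        covered = 0
        for start, end in isoform.exons:
            lo, hi = start - 1, end
            for overlap in tree.overlap(lo, hi):
                covered += min(overlap.end, hi) - max(overlap.begin, lo)
        coverage = 100.0 * covered / isoform.exon_bases
        key = (coverage, isoform.exon_bases, isoform.isoform_id)
        if best is None or (
            key[0] > best[0]
            or (key[0] == best[0] and key[1] > best[1])
            or (key[0] == best[0] and key[1] == best[1] and key[2] < best[2])
        ):
            best = key
    if best is None or best[0] == 0.0:
        return CoverageCall(transcript_id, None, 0.0, "no_match")
    coverage, _bases, isoform_id = best
    return CoverageCall(transcript_id, isoform_id, coverage, bin_for(coverage, edges))


def bin_coverage_report(calls: Iterable[CoverageCall]) -> dict[str, int]:
    """Histogram of calls over the six coverage bins (all keys always present)."""
    counts = {name: 0 for name in COVERAGE_BINS}
    for call in calls:
        counts[call.bin] += 1
    return counts


# ---------------------------------------------------------------------------
# format adapters


def hsp_from_hit(hit: AlignmentHit) -> GenomeHSP:
    """View a transcript-vs-genome tabular hit as a :class:`GenomeHSP`."""
    return GenomeHSP(
        transcript_id=hit.query_id,
        chrom=hit.subject_id,
        tstart=hit.qstart,
        tend=hit.qend,
        gstart=hit.sstart,
        gend=hit.send,
        identity=hit.percent_identity,
        bitscore=hit.bitscore,
    )


def load_isoforms(gff3_path: str | os.PathLike) -> list[IsoformModel]:
    """Group GFF3 exon features by Parent into isoform models.

    Overlapping exon records of the same isoform (rare, but legal GFF3) are
    merged so the model invariant holds.
    """
    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="merge"
    )
    grouped: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [exon.id])
        for parent in parents:
            entry = grouped.setdefault(
                parent, {"chrom": exon.seqid, "strand": exon.strand or ".", "exons": []}
            )
            entry["exons"].append((exon.start, exon.end))
    models = []
    for isoform_id in sorted(grouped):
        entry = grouped[isoform_id]
        merged: list[tuple[int, int]] = []
        for start, end in sorted(entry["exons"]):
            if merged and start <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], end))
            else:
                merged.append((start, end))
        models.append(IsoformModel(isoform_id, entry["chrom"], entry["strand"], merged))
    return models


def write_coverage_calls(calls: Sequence[CoverageCall], path: str | os.PathLike) -> None:
    frame = pd.DataFrame(
        {
            "transcript_id": [c.transcript_id for c in calls],
            "best_isoform": [c.best_isoform or "." for c in calls],
            "coverage": [round(c.coverage, 2) for c in calls],
            "bin": [c.bin for c in calls],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
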