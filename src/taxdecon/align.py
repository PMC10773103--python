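"""Alignment hits, match criteria, and a built-in local aligner.

The classifier consumes :class:`AlignmentHit` records regardless of where
they came from: parsed from BLAST outfmt-6 tabular output (bring your own
aligner) or computed by :func:`local_align`, a Smith–Waterman/Gotoh
affine-gap local aligner suitable for desk-scale databases.  A hit is a
*match* when it clears all three screening thresholds — identity strictly
above 75%, query coverage strictly above 75%, e-value strictly below 1e-5 —
with a nucleotide mismatch penalty of −3 in the scoring scheme.

Default scoring is the classic blastn set for a −3 mismatch penalty:
match +2, mismatch −3, gap open 5, gap extend 2 (a gap of length L costs
open + L·extend).  Bitscores and e-values follow Karlin–Altschul
statistics, ``E = K·m·n·exp(−λS)``, with m the query length and n the
length of the database searched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Iterator, Sequence, TextIO

__all__ = [
    "AlignmentHit",
    "MatchCriteria",
    "ScoringScheme",
    "BlastTabError",
    "DEFAULT_COLUMNS",
    "parse_blast_tab",
    "write_blast_tab",
    "query_coverage",
    "passes_match_criteria",
    "local_align",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass
class AlignmentHit:
    """One local alignment (HSP) in BLAST tabular terms.

    Coordinates are 1-based inclusive.  The query is always given forward;
    a minus-strand alignment has ``send < sstart``.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    subject_taxid: int = 0
    query_length: int = 0

    def __post_init__(self) -> None:
        if self.qstart > self.qend:
            raise ValueError(f"{self.query_id}: qstart {self.qstart} > qend {self.qend}")
        if not 0 < self.percent_identity <= 100:
            raise ValueError(f"{self.query_id}: identity {self.percent_identity} outside (0,100]")
        if self.evalue < 0:
            raise ValueError(f"{self.query_id}: negative e-value")


@dataclass(frozen=True)
class MatchCriteria:
    """Screening thresholds; all bounds strict (larger-than / smaller-than)."""

    min_identity: float = 75.0
    min_query_coverage: float = 75.0
    max_evalue: float = 1e-5
    mismatch_penalty: int = -3

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 100 or not 0 < self.min_query_coverage <= 100:
            raise ValueError("identity/coverage bounds must lie in (0, 100]")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")


def query_coverage(hit: AlignmentHit) -> float:
    """Aligned query span as a percentage of the full query length."""
    if hit.query_length <= 0:
        raise ValueError(f"{hit.query_id}: query_length must be positive to compute coverage")
    return 100.0 * (hit.qend - hit.qstart + 1) / hit.query_length


def passes_match_criteria(hit: AlignmentHit, criteria: MatchCriteria | None = None) -> bool:
    """True iff identity, query coverage and e-value all clear their strict bounds."""
    criteria = criteria or MatchCriteria()
    return (
        hit.percent_identity > criteria.min_identity
        and query_coverage(hit) > criteria.min_query_coverage
        and hit.evalue < criteria.max_evalue
    )


# ---------------------------------------------------------------------------
# BLAST tabular I/O

DEFAULT_COLUMNS: tuple[str, ...] = (
    "qseqid sseqid pident length mismatch gapopen qstart qend "
    "sstart send evalue bitscore staxids qlen"
).split()

_FIELD_OF_COLUMN = {
    "qseqid": ("query_id", str),
    "sseqid": ("subject_id", str),
    "pident": ("percent_identity", float),
    "length": ("align_length", int),
    "mismatch": ("mismatches", int),
    "gapopen": ("gap_opens", int),
    "qstart": ("qstart", int),
    "qend": ("qend", int),
    "sstart": ("sstart", int),
    "send": ("send", int),
    "evalue": ("evalue", float),
    "bitscore": ("bitscore", float),
    "staxids": ("subject_taxid", int),
    "qlen": ("query_length", int),
}


class BlastTabError(ValueError):
    """Malformed tabular alignment row; message carries the line number."""


def parse_blast_tab(
    stream: TextIO | Iterable[str], columns: Sequence[str] = DEFAULT_COLUMNS
) -> Iterator[AlignmentHit]:
    """Parse tab-delimited hits (outfmt 6; ``#`` comment lines of outfmt 7 skipped)."""
    converters = [_FIELD_OF_COLUMN[c] for c in columns]
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != len(columns):
            raise BlastTabError(
                f"line {lineno}: expected {len(columns)} columns, got {len(fields)}"
            )
        kwargs = {}
        for raw, (name, cast) in zip(fields, converters):
            try:
                kwargs[name] = cast(raw)
            except ValueError as exc:
                raise BlastTabError(
                    f"line {lineno}: column {name!r} has non-{cast.__name__} value {raw!r}"
                ) from exc
        yield AlignmentHit(**kwargs)


def write_blast_tab(
    hits: Iterable[AlignmentHit], stream: TextIO, columns: Sequence[str] = DEFAULT_COLUMNS
) -> None:
    """Write hits as tab-delimited rows; floats use repr so rows round-trip."""
    fields = [_FIELD_OF_COLUMN[c][0] for c in columns]
    for hit in hits:
        stream.write("\t".join(str(getattr(hit, f)) for f in fields) + "\n")


# ---------------------------------------------------------------------------
# built-in local aligner


@dataclass(frozen=True)
class ScoringScheme:
    """Nucleotide scoring: match reward, mismatch penalty, affine gap costs.

    ``gap_open``/``gap_extend`` are positive costs; a gap run of length L
    costs ``gap_open + L * gap_extend`` (BLAST convention: the first gapped
    column pays both open and extend).
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0:
            raise ValueError("match reward must be positive and mismatch penalty negative")
        if self.gap_open < 0 or self.gap_extend <= 0:
            raise ValueError("gap costs must be non-negative (extend strictly positive)")

    @property
    def karlin_lambda(self) -> float:
        return _karlin_lambda(self.match, self.mismatch)

    @property
    def karlin_k(self) -> float:
        # Published ungapped K for blastn-style schemes; adequate for the
        # e-value screen at the scales this aligner serves.
        return 0.41

    def bitscore(self, raw_score: int) -> float:
        return (self.karlin_lambda * raw_score - math.log(self.karlin_k)) / math.log(2)

    def evalue(self, raw_score: int, query_length: int, db_length: int) -> float:
        exponent = -self.karlin_lambda * raw_score
        return self.karlin_k * query_length * db_length * math.exp(exponent)


@lru_cache(maxsize=None)
def _karlin_lambda(match: int, mismatch: int) -> float:
    """Ungapped Karlin–Altschul lambda for uniform base composition.

    Solves sum_ij p_i p_j exp(lambda * s_ij) = 1 with p = 1/4, i.e.
    (1/4) e^(lambda*match) + (3/4) e^(lambda*mismatch) = 1, by bisection.
    For +2/−3 this gives the published 0.625.
    """

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    lo, hi = 1e-9, 1.0
    while f(hi) < 0:
        hi *= 2
    for _ in range(200):
        mid = (lo + hi) / 2
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _gotoh_local(query: str, subject: str, scoring: ScoringScheme):
    """Affine-gap local DP with traceback.

    Returns (score, qstart, qend, sstart, send, matches, mismatches,
    gap_opens, align_length) with 1-based inclusive coordinates, or None if
    the best local score is 0.  The highest-scoring cell wins; ties go to
    the first cell in row-major order.
    """
    m, n = len(query), len(subject)
    match, mismatch = scoring.match, scoring.mismatch
    first_gap = scoring.gap_open + scoring.gap_extend
    extend = scoring.gap_extend

    neg = float("-inf")
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[neg] * (n + 1) for _ in range(m + 1)]  # gap in query (move along subject)
    F = [[neg] * (n + 1) for _ in range(m + 1)]  # gap in subject (move along query)

    best, best_i, best_j = 0, 0, 0
    for i in range(1, m + 1):
        qc = query[i - 1]
        Hi, Hi1, Ei, Fi, Fi1 = H[i], H[i - 1], E[i], F[i], F[i - 1]
        for j in range(1, n + 1):
            e = max(Hi[j - 1] - first_gap, Ei[j - 1] - extend)
            f = max(Hi1[j] - first_gap, Fi1[j] - extend)
            diag = Hi1[j - 1] + (match if qc == subject[j - 1] else mismatch)
            h = diag
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            Ei[j], Fi[j], Hi[j] = e, f, h
            if h > best:
                best, best_i, best_j = h, i, j

    if best <= 0:
        return None

    # Traceback from the best cell through the three-state machine.
    i, j, state = best_i, best_j, "H"
    matches = mismatches = gap_opens = align_length = 0
    end_i, end_j = best_i, best_j
    while i > 0 and j > 0:
        if state == "H":
            h = H[i][j]
            if h == 0:
                break
            if h == E[i][j]:
                state = "E"
                continue
            if h == F[i][j]:
                state = "F"
                continue
            align_length += 1
            if query[i - 1] == subject[j - 1]:
                matches += 1
            else:
                mismatches += 1
            i -= 1
            j -= 1
        elif state == "E":  # gap in query, consume subject
            align_length += 1
            if E[i][j] == H[i][j - 1] - first_gap:
                gap_opens += 1
                state = "H"
            j -= 1
        else:  # "F": gap in subject, consume query
            align_length += 1
            if F[i][j] == H[i - 1][j] - first_gap:
                gap_opens += 1
                state = "H"
            i -= 1
    qstart, sstart = i + 1, j + 1
    return best, qstart, end_i, sstart, end_j, matches, mismatches, gap_opens, align_length


def local_align(
    query: str,
    subject: str,
    scoring: ScoringScheme | None = None,
    min_score: int = 20,
    query_id: str = "query",
    subject_id: str = "subject",
    subject_taxid: int = 0,
    db_length: int | None = None,
) -> list[AlignmentHit]:
    """Local-align a query against a subject on both strands.

    Reports the best alignment per strand with raw score >= ``min_score``
    as :class:`AlignmentHit` records (best first).  ``db_length`` sets the
    Karlin–Altschul search-space n term (defaults to the subject length);
    pass the total database length when the subject is one of many.
    """
    if not query or not subject:
        raise ValueError("local_align: empty query or subject")
    scoring = scoring or ScoringScheme()
    n = db_length if db_length is not None else len(subject)

    hits: list[AlignmentHit] = []
    for strand, oriented in (("+", query), ("-", revcomp(query))):
        result = _gotoh_local(oriented, subject, scoring)
        if result is None:
            continue
        score, qstart, qend, sstart, send, matches, mismatches, gap_opens, length = result
        if score < min_score:
            continue
        if strand == "-":
            qstart, qend = len(query) - qend + 1, len(query) - qstart + 1
            sstart, send = send, sstart
        hits.append(
            AlignmentHit(
                query_id=query_id,
                subject_id=subject_id,
                percent_identity=100.0 * matches / length,
                align_length=length,
                mismatches=mismatches,
                gap_opens=gap_opens,
                qstart=qstart,
                qend=qend,
                sstart=sstart,
                send=send,
                evalue=scoring.evalue(score, len(query), n),
                bitscore=scoring.bitscore(score),
                subject_taxid=subject_taxid,
                query_length=len(query),
            )
        )
    hits.sort(key=lambda h: -h.bitscore)
    return hits
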