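"""In-silico chromosome placement of candidate loci from precomputed BLASTn
tabular output.

The module consumes standard 12-column tabular hits (query, subject, percent
identity, alignment length, mismatches, gap opens, query start/end, subject
start/end, e-value, bit score) of candidate-locus sequences against a
chromosome-level assembly, keeps hits strictly exceeding the identity and
alignment-length bounds, picks the most significant surviving hit per query
(highest bit score, ties broken by lowest e-value then input order), and
tallies mapped loci per chromosome.  Running BLAST itself is out of scope.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass


class BlastFormatError(ValueError):
    """Malformed tabular BLAST line."""


@dataclass(frozen=True)
class BlastHit:
    query: str
    subject: str
    identity: float  # percent, 0-100
    length: int  # aligned bp
    evalue: float
    bitscore: float
    sstart: int
    send: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise BlastFormatError(f"identity {self.identity} out of [0, 100]")
        if self.length < 1:
            raise BlastFormatError(f"alignment length {self.length} < 1")


def parse_blast_tab(path) -> list[BlastHit]:
    """Parse outfmt-6-style tabular BLAST output, preserving row order."""
    hits: list[BlastHit] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 12:
                raise BlastFormatError(
                    f"{path}: line {lineno} has {len(row)} fields, expected >= 12"
                )
            try:
                hits.append(
                    BlastHit(
                        query=row[0],
                        subject=row[1],
                        identity=float(row[2]),
                        length=int(row[3]),
                        sstart=int(row[8]),
                        send=int(row[9]),
                        evalue=float(row[10]),
                        bitscore=float(row[11]),
                    )
                )
            except ValueError as exc:
                if isinstance(exc, BlastFormatError):
                    raise
                raise BlastFormatError(
                    f"{path}: line {lineno}: {exc}"
                ) from exc
    return hits


def filter_hits(
    hits: list[BlastHit], min_identity: float = 95.0, min_len: int = 65
) -> tuple[dict[str, BlastHit], list[str]]:
    """Strictly filter hits and keep the best survivor per query.

    Returns ``(best_hit_by_query, unmapped_queries)``.  Bounds are strict
    (identity must *exceed* ``min_identity``, length must *exceed*
    ``min_len``).  Best = highest bit score, then lowest e-value, then first
    occurrence in the input; the outcome is therefore independent of input
    row order up to that documented tie-break.
    """
    first_seen: dict[str, int] = {}
    surviving: dict[str, tuple] = {}
    queries: list[str] = []
    for pos, h in enumerate(hits):
        if h.query not in first_seen:
            first_seen[h.query] = pos
            queries.append(h.query)
        if h.identity <= min_identity or h.length <= min_len:
            continue
        key = (-h.bitscore, h.evalue, pos)
        if h.query not in surviving or key < surviving[h.query][0]:
            surviving[h.query] = (key, h)
    best = {q: surviving[q][1] for q in queries if q in surviving}
    unmapped = [q for q in queries if q not in surviving]
    return best, unmapped


@dataclass
class ChromosomeTally:
    per_chromosome: dict[str, int]
    n_chromosomes_hit: int
    n_mapped: int
    n_unmapped: int
    unknown_subjects: list[str]


def chromosome_tally(
    best_hits: dict[str, BlastHit],
    assembly_map: dict[str, str],
    unmapped: list[str] | None = None,
) -> ChromosomeTally:
    """Count mapped loci per chromosome via the subject → chromosome map.

    Subjects absent from ``assembly_map`` are flagged (their queries count as
    unmapped).  Per-chromosome counts always sum to the mapped total.
    """
    counts: Counter[str] = Counter()
    unknown: list[str] = []
    n_unmapped = len(unmapped or [])
    for q, h in best_hits.items():
        chrom = assembly_map.get(h.subject)
        if chrom is None:
            unknown.append(h.subject)
            n_unmapped += 1
        else:
            counts[chrom] += 1
    return ChromosomeTally(
        per_chromosome=dict(counts),
        n_chromosomes_hit=len(counts),
        n_mapped=sum(counts.values()),
        n_unmapped=n_unmapped,
        unknown_subjects=unknown,
    )
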