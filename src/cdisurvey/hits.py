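"""BLAST tabular hit handling: parsing, composite filtering, HSP chaining.

The survey starts from a nucleotide homology search of a full-length *cdiA*
gene against a sequence database, exported in the standard 12-column
tabular dialect (``qseqid sseqid pident length mismatch gapopen qstart
qend sstart send evalue bitscore``).  Fragmented and non-specific hits are
stripped with a composite rule; a hit is REMOVED when any clause fires::

    (aln_length < 2000 and pct_identity < 80.5)
        or (aln_length < 3000 and evalue == 0)
        or (aln_length < 1000)

All inequalities are strict and boundary values (1000/2000/3000 bp, 80.5 %)
are kept.  The e-value clause compares against literal zero — tabular
output prints ``0.0`` when the e-value underflows — and can be disabled via
:class:`FilterRule.evalue_exact_zero_flag` for databases where that clause
is not wanted.

Surviving hits on the same replicon and strand are then chained: *cdiA* is
a single long ORF whose alignment is frequently split into several HSPs by
the indel-rich FHA repeat regions, so hits that overlap or lie within
``max_gap`` of each other are merged into one candidate locus whose span is
the envelope of its hits.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .regions import MINUS, PLUS, CdiLocus

#: standard tabular column order (``-outfmt 6`` default)
BLAST_TAB_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


@dataclass(frozen=True)
class BlastHit:
    """One tabular homology hit (HSP), normalized so ``s_start <= s_end``
    with the original orientation kept in ``strand``."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    strand: str = PLUS

    def __post_init__(self) -> None:
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity must be in [0, 100]")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.s_start > self.s_end:
            raise ValueError("hit not normalized: s_start > s_end")
        if self.strand not in (PLUS, MINUS):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class FilterRule:
    """Composite removal rule for fragmented/non-specific hits.

    Defaults are the thresholds of the published rule; see the module
    docstring for the Boolean expression.
    """

    min_keep_len_a: int = 2000
    min_pid_a: float = 80.5
    min_keep_len_b: int = 3000
    evalue_exact_zero_flag: bool = True
    min_keep_len_c: int = 1000

    def __post_init__(self) -> None:
        if min(self.min_keep_len_a, self.min_keep_len_b, self.min_keep_len_c) <= 0:
            raise ValueError("all length thresholds must be > 0")
        if not 0.0 < self.min_pid_a <= 100.0:
            raise ValueError("min_pid_a must be in (0, 100]")


@dataclass(frozen=True)
class ChainParams:
    """HSP chaining parameters: hits on the same (replicon, strand) closer
    than ``max_gap`` are merged into one candidate locus."""

    max_gap: int = 1000
    same_strand_required: bool = True

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


def parse_blast_tab(path: str | Path) -> list[BlastHit]:
    """Parse a BLAST tabular file into normalized hits, preserving row order.

    Rows with ``sstart > send`` encode minus-strand alignments; they are
    normalized (coordinates swapped) with the orientation recorded in
    ``strand``.  Columns beyond the standard 12 are ignored.  A malformed
    row raises ``ValueError`` naming the offending line; an empty file
    yields an empty list.
    """
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}: malformed BLAST tabular row at line {lineno}: "
                    f"expected >=12 tab-separated columns, got {len(fields)}"
                )
            try:
                s_start = int(fields[8])
                s_end = int(fields[9])
                strand = PLUS
                if s_start > s_end:
                    s_start, s_end = s_end, s_start
                    strand = MINUS
                hit = BlastHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=s_start,
                    s_end=s_end,
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    strand=strand,
                )
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed BLAST tabular row at line {lineno}: {exc}"
                ) from exc
            hits.append(hit)
    return hits


def hit_passes_filter(hit: BlastHit, rule: FilterRule = FilterRule()) -> bool:
    """True iff the hit survives the composite removal rule."""
    removed = (
        (hit.aln_length < rule.min_keep_len_a and hit.pct_identity < rule.min_pid_a)
        or (
            rule.evalue_exact_zero_flag
            and hit.aln_length < rule.min_keep_len_b
            and hit.evalue == 0.0
        )
        or (hit.aln_length < rule.min_keep_len_c)
    )
    return not removed


def filter_hits(
    hits: Iterable[BlastHit], rule: FilterRule = FilterRule()
) -> list[BlastHit]:
    """Order-preserving subsequence of hits passing :func:`hit_passes_filter`."""
    return [h for h in hits if hit_passes_filter(h, rule)]


def chain_hits(
    hits: Iterable[BlastHit], params: ChainParams = ChainParams()
) -> list[CdiLocus]:
    """Merge filtered HSPs into candidate loci.

    Hits are grouped by (subject, strand) — or by subject alone when
    ``same_strand_required`` is off — sorted by position, and merged while
    consecutive intervals overlap or are separated by at most ``max_gap``
    bases.  The locus span is the envelope of its member hits.  Output is
    sorted by (replicon, start, strand) and is therefore independent of the
    input hit order.
    """
    groups: dict[tuple[str, str], list[BlastHit]] = defaultdict(list)
    for h in hits:
        key_strand = h.strand if params.same_strand_required else PLUS
        groups[(h.subject_id, key_strand)].append(h)

    loci: list[CdiLocus] = []
    for (subject, _), members in groups.items():
        intervals = sorted((h.s_start - 1, h.s_end, h.strand) for h in members)
        cur_start, cur_end, strands, n = (
            intervals[0][0],
            intervals[0][1],
            {intervals[0][2]},
            1,
        )
        for start, end, strand in intervals[1:]:
            if start - cur_end <= params.max_gap:
                cur_end = max(cur_end, end)
                strands.add(strand)
                n += 1
            else:
                loci.append(_make_locus(subject, cur_start, cur_end, strands, n))
                cur_start, cur_end, strands, n = start, end, {strand}, 1
        loci.append(_make_locus(subject, cur_start, cur_end, strands, n))

    loci.sort(key=lambda l: (l.replicon, l.gene_start, l.strand))
    return loci


def _make_locus(
    subject: str, start: int, end: int, strands: set[str], n_hits: int
) -> CdiLocus:
    strand = strands.pop() if len(strands) == 1 else "."
    return CdiLocus(
        replicon=subject, gene_start=start, gene_end=end, strand=strand, n_hits=n_hits
    )


def write_hits_tsv(hits: Sequence[BlastHit], path: str | Path) -> None:
    """Write hits back in the standard tabular dialect; minus-strand hits are
    denormalized (subject coordinates swapped) as an aligner would print them."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for h in hits:
            s_start, s_end = (
                (h.s_end, h.s_start) if h.strand == MINUS else (h.s_start, h.s_end)
            )
            writer.writerow(
                [
                    h.query_id,
                    h.subject_id,
                    f"{h.pct_identity:.3f}",
                    h.aln_length,
                    h.mismatches,
                    h.gap_opens,
                    h.q_start,
                    h.q_end,
                    s_start,
                    s_end,
                    _format_evalue(h.evalue),
                    f"{h.bitscore:.1f}",
                ]
            )


def _format_evalue(evalue: float) -> str:
    return "0.0" if evalue == 0.0 else f"{evalue:.2e}"


def write_loci_tsv(loci: Sequence[CdiLocus], path: str | Path) -> None:
    """Candidate-locus table; coordinates are 1-based inclusive."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["accession", "strand", "start", "end", "length", "n_hits"])
        for locus in loci:
            writer.writerow(
                [
                    locus.replicon,
                    locus.strand,
                    locus.gene_start + 1,
                    locus.gene_end,
                    locus.locus_length,
                    locus.n_hits,
                ]
            )
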