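"""Replicon records and genomic-neighborhood extraction around candidate loci.

A candidate *cdiA* locus is examined together with its flanking context:
*cdiB* lies immediately upstream and *cdiI* immediately downstream of *cdiA*
in the canonical ``cdiBAI`` operon, so the neighborhood window is taken
relative to the reading strand of the gene — 20 kb upstream of the gene
start and 30 kb downstream of the gene end by default.  Windows are clamped
to the replicon ends unless the replicon is circular and wrap-around is
explicitly requested.

Coordinate conventions
----------------------
Internal coordinates are 0-based half-open throughout.  External formats
follow their own conventions and are converted at the I/O boundary only:
FASTA headers and GFF3 are 1-based inclusive, BED is 0-based half-open.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PLUS = "+"
MINUS = "-"

TOPOLOGIES = ("linear", "circular", "unknown")


@dataclass
class RepliconMeta:
    """One replicon (chromosome or plasmid): metadata plus optional sequence."""

    accession: str
    description: str
    length: int
    topology: str = "unknown"
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"replicon {self.accession}: length must be >= 1")
        if self.topology not in TOPOLOGIES:
            raise ValueError(
                f"replicon {self.accession}: topology {self.topology!r} "
                f"not one of {TOPOLOGIES}"
            )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"replicon {self.accession}: sequence length "
                f"{len(self.sequence)} != declared length {self.length}"
            )


@dataclass
class CdiLocus:
    """A chained candidate *cdiA* locus on one replicon.

    ``gene_start``/``gene_end`` are the envelope of the chained homology
    hits (0-based half-open); ``window_start``/``window_end`` the extraction
    neighborhood once attached.  Classification fields are filled in by the
    survey stages downstream of chaining.
    """

    replicon: str
    gene_start: int
    gene_end: int
    strand: str
    n_hits: int = 1
    window_start: int | None = None
    window_end: int | None = None
    window_clamped: bool = False
    window_seq: str | None = None
    intact: bool | None = None
    replicon_class: str = "unknown"
    strain_id: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.gene_start < self.gene_end:
            raise ValueError(
                f"locus on {self.replicon}: invalid interval "
                f"[{self.gene_start}, {self.gene_end})"
            )

    @property
    def locus_length(self) -> int:
        return self.gene_end - self.gene_start


@dataclass(frozen=True)
class Window:
    """A half-open extraction interval; ``clamped`` records edge truncation."""

    start: int
    end: int
    clamped: bool = False

    def __len__(self) -> int:
        return self.end - self.start


def locus_window(
    locus: CdiLocus,
    replicon: RepliconMeta,
    upstream: int = 20_000,
    downstream: int = 30_000,
    circular_wrap: bool = False,
) -> Window:
    """Neighborhood window around a locus, relative to its reading strand.

    For a plus-strand gene the window is ``[gene_start - upstream,
    gene_end + downstream)``; for a minus-strand gene the margins swap
    roles, so the upstream margin always precedes the gene in its own
    reading direction.  The window is clamped to ``[0, replicon.length)``
    unless ``circular_wrap`` is set and the replicon topology is circular,
    in which case coordinates may run off either end (modular extraction),
    with the total width capped at the replicon length.
    """
    if not (0 <= locus.gene_start < locus.gene_end <= replicon.length):
        raise ValueError(
            f"locus [{locus.gene_start}, {locus.gene_end}) outside replicon "
            f"{replicon.accession} of length {replicon.length}"
        )
    if locus.strand == PLUS:
        raw_start = locus.gene_start - upstream
        raw_end = locus.gene_end + downstream
    else:
        raw_start = locus.gene_start - downstream
        raw_end = locus.gene_end + upstream

    if circular_wrap and replicon.topology == "circular":
        if raw_end - raw_start > replicon.length:
            # Window cannot exceed the circle; keep the gene and trim the
            # margins proportionally from both ends.
            excess = (raw_end - raw_start) - replicon.length
            left = min(excess // 2, locus.gene_start - raw_start)
            raw_start += left
            raw_end -= excess - left
        return Window(raw_start, raw_end, clamped=False)

    start = max(0, raw_start)
    end = min(replicon.length, raw_end)
    return Window(start, end, clamped=(start != raw_start or end != raw_end))


def extract_window_sequence(
    replicon: RepliconMeta, window: Window, strand: str = PLUS
) -> str:
    """Extract the window subsequence, reverse-complemented for minus-strand
    loci so the gene reads left-to-right in the output."""
    if replicon.sequence is None:
        raise ValueError(
            f"replicon {replicon.accession} carries no sequence; supply the "
            "replicon FASTA to enable window extraction"
        )
    seq = replicon.sequence
    n = len(seq)
    if 0 <= window.start and window.end <= n:
        sub = seq[window.start : window.end]
    else:
        # wrap-around extraction on a circular replicon
        width = window.end - window.start
        if width > n:
            raise ValueError("window wider than circular replicon")
        s = window.start % n
        sub = (seq + seq)[s : s + width]
    if strand == MINUS:
        sub = str(Seq(sub).reverse_complement())
    return sub


def attach_window(
    locus: CdiLocus,
    replicon: RepliconMeta,
    upstream: int = 20_000,
    downstream: int = 30_000,
    circular_wrap: bool = False,
    extract: bool = True,
) -> CdiLocus:
    """Compute and store the window (and its sequence) on the locus in place."""
    window = locus_window(locus, replicon, upstream, downstream, circular_wrap)
    locus.window_start = window.start
    locus.window_end = window.end
    locus.window_clamped = window.clamped
    if extract and replicon.sequence is not None:
        locus.window_seq = extract_window_sequence(replicon, window, locus.strand)
    return locus


# ---------------------------------------------------------------------------
# I/O


def read_replicon_fasta(path: str | Path) -> dict[str, RepliconMeta]:
    """Read replicons from FASTA; the record id is the accession and the full
    definition line is kept for classification."""
    replicons: dict[str, RepliconMeta] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        replicons[record.id] = RepliconMeta(
            accession=record.id,
            description=record.description,
            length=len(seq),
            sequence=seq,
        )
    return replicons


def read_metadata_tsv(path: str | Path) -> dict[str, RepliconMeta]:
    """Read a replicon metadata table (accession, description, length,
    optional topology); sequences are not carried here."""
    replicons: dict[str, RepliconMeta] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            replicons[row["accession"]] = RepliconMeta(
                accession=row["accession"],
                description=row["description"],
                length=int(row["length"]),
                topology=row.get("topology") or "unknown",
            )
    return replicons


def write_metadata_tsv(replicons: Mapping[str, RepliconMeta], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["accession", "description", "length", "topology"])
        for acc in sorted(replicons):
            meta = replicons[acc]
            writer.writerow([meta.accession, meta.description, meta.length, meta.topology])


def merge_metadata(
    sequences: Mapping[str, RepliconMeta], metadata: Mapping[str, RepliconMeta]
) -> dict[str, RepliconMeta]:
    """Overlay a metadata table on FASTA-derived replicons: the table wins for
    description/topology, the FASTA supplies sequence and length."""
    merged: dict[str, RepliconMeta] = dict(sequences)
    for acc, meta in metadata.items():
        if acc in merged:
            base = merged[acc]
            merged[acc] = RepliconMeta(
                accession=acc,
                description=meta.description,
                length=base.length,
                topology=meta.topology,
                sequence=base.sequence,
            )
        else:
            merged[acc] = meta
    return merged


def _window_header(locus: CdiLocus) -> str:
    # 1-based inclusive coordinates in headers
    return f"{locus.replicon}:{locus.window_start + 1}-{locus.window_end}({locus.strand})"


def write_windows_fasta(loci: Sequence[CdiLocus], path: str | Path) -> None:
    records = []
    for locus in loci:
        if locus.window_seq is None:
            continue
        records.append(
            SeqRecord(Seq(locus.window_seq), id=_window_header(locus), description="")
        )
    SeqIO.write(records, str(path), "fasta")


def write_windows_bed(loci: Sequence[CdiLocus], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for i, locus in enumerate(loci):
            if locus.window_start is None:
                continue
            writer.writerow(
                [
                    locus.replicon,
                    locus.window_start,
                    locus.window_end,
                    f"cdi_window_{i + 1}",
                    0,
                    locus.strand,
                ]
            )


def write_windows_gff3(loci: Sequence[CdiLocus], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("##gff-version 3\n")
        for i, locus in enumerate(loci):
            if locus.window_start is None:
                continue
            attrs = (
                f"ID=cdi_window_{i + 1};locus_length={locus.locus_length};"
                f"clamped={str(locus.window_clamped).lower()}"
            )
            fh.write(
                "\t".join(
                    [
                        locus.replicon,
                        "cdisurvey",
                        "region",
                        str(locus.window_start + 1),
                        str(locus.window_end),
                        ".",
                        locus.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
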