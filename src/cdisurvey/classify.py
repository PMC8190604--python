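"""Chromosome/plasmid classification, intactness, deduplication, summary.

A replicon is classified from its definition line and size: a description
containing "plasmid" marks a plasmid; "complete genome" or "chromosome"
marks a chromosome; a replicon larger than 4 Mbp with no matching keyword
is taken as chromosomal; anything else is unknown.  By default plasmid
keywords take precedence because plasmid definition lines frequently also
mention the parent genome ("... plasmid pX, complete sequence"); the
alternative precedence is available via :class:`ClassificationRule`.

A candidate locus counts as an intact *cdiA* when its chained span exceeds
9070 bp (strict), the size bar for a full-length gene.  Because public
sequence collections over-represent some strains, loci are deduplicated to
one representative per (strain, exact window sequence) before summary
statistics are computed.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .regions import CdiLocus, RepliconMeta

CHROMOSOME = "chromosome"
PLASMID = "plasmid"
UNKNOWN = "unknown"

#: default intactness bar for a full-length cdiA locus span, in bp (strict >)
MIN_INTACT_LENGTH = 9070


@dataclass(frozen=True)
class ClassificationRule:
    chromosome_keywords: tuple[str, ...] = ("complete genome", "chromosome")
    plasmid_keywords: tuple[str, ...] = ("plasmid",)
    size_threshold: int = 4_000_000
    keyword_precedence: str = "plasmid_first"  # or "chromosome_first"

    def __post_init__(self) -> None:
        if not self.chromosome_keywords or not self.plasmid_keywords:
            raise ValueError("keyword lists must be non-empty")
        if self.size_threshold <= 0:
            raise ValueError("size_threshold must be > 0")
        if self.keyword_precedence not in ("plasmid_first", "chromosome_first"):
            raise ValueError(
                "keyword_precedence must be 'plasmid_first' or 'chromosome_first'"
            )


def classify_replicon(
    meta: RepliconMeta, rule: ClassificationRule = ClassificationRule()
) -> str:
    """Classify a replicon as ``chromosome``, ``plasmid`` or ``unknown``.

    Keyword matching is case-insensitive substring matching on the
    description; the size test applies only when no keyword matched.
    """
    desc = meta.description.lower()
    is_plasmid = any(k.lower() in desc for k in rule.plasmid_keywords)
    is_chromosome = any(k.lower() in desc for k in rule.chromosome_keywords)
    if rule.keyword_precedence == "plasmid_first":
        if is_plasmid:
            return PLASMID
        if is_chromosome:
            return CHROMOSOME
    else:
        if is_chromosome:
            return CHROMOSOME
        if is_plasmid:
            return PLASMID
    if meta.length > rule.size_threshold:
        return CHROMOSOME
    return UNKNOWN


def is_intact(locus: CdiLocus, min_len: int = MIN_INTACT_LENGTH) -> bool:
    """True iff the chained locus span strictly exceeds ``min_len`` bases."""
    return locus.locus_length > min_len


_STRAIN_RE = re.compile(r"\bstrain\s+([^\s,;]+)", re.IGNORECASE)


def parse_strain_id(
    description: str,
    accession: str,
    overrides: Mapping[str, str] | None = None,
) -> str:
    """Strain identifier: the token after "strain" in the definition line,
    falling back to the accession; ``overrides`` maps accession → strain."""
    if overrides and accession in overrides:
        return overrides[accession]
    match = _STRAIN_RE.search(description)
    if match:
        return match.group(1).rstrip(".,;")
    return accession


def dedupe_strains(loci: Sequence[CdiLocus]) -> list[CdiLocus]:
    """One representative per (strain, exact window sequence).

    Duplicate deposits of the same strain collapse to the lexicographically
    first accession (ties broken by position); loci of the same strain with
    *different* sequences are all retained — a strain may genuinely carry
    two distinct systems.  Loci lacking an extracted window sequence fall
    back to their (replicon, coordinates, strand) as the identity key.
    Output is sorted by (replicon, start, strand), making the operation
    idempotent and input-order-insensitive.
    """
    best: dict[tuple, CdiLocus] = {}
    for locus in loci:
        seq_key = (
            locus.window_seq
            if locus.window_seq is not None
            else (locus.replicon, locus.gene_start, locus.gene_end, locus.strand)
        )
        key = (locus.strain_id, seq_key)
        current = best.get(key)
        if current is None or (locus.replicon, locus.gene_start) < (
            current.replicon,
            current.gene_start,
        ):
            best[key] = locus
    out = list(best.values())
    out.sort(key=lambda l: (l.replicon, l.gene_start, l.strand))
    return out


@dataclass
class SurveySummary:
    """Class counts and percentages plus the per-plasmid breakdown."""

    n_chromosome: int
    n_plasmid: int
    n_unknown: int
    pct_chromosome: float | None
    pct_plasmid: float | None
    per_plasmid_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_total(self) -> int:
        return self.n_chromosome + self.n_plasmid


def summarize(
    loci: Sequence[CdiLocus],
    replicons: Mapping[str, RepliconMeta] | None = None,
) -> SurveySummary:
    """Tally classified loci into the survey summary.

    Percentages are computed over chromosome + plasmid loci only (unknowns
    are reported but excluded from the denominator) and rounded to one
    decimal; with no classified loci they are ``None`` (written as NA).
    The per-plasmid table groups plasmid loci by accession with the number
    of systems, plasmid size (when metadata is available) and strain.
    """
    n_chr = sum(1 for l in loci if l.replicon_class == CHROMOSOME)
    n_pla = sum(1 for l in loci if l.replicon_class == PLASMID)
    n_unk = sum(1 for l in loci if l.replicon_class == UNKNOWN)
    denom = n_chr + n_pla
    pct_chr = round(100.0 * n_chr / denom, 1) if denom else None
    pct_pla = round(100.0 * n_pla / denom, 1) if denom else None

    rows = []
    plasmid_loci = [l for l in loci if l.replicon_class == PLASMID]
    for acc in sorted({l.replicon for l in plasmid_loci}):
        members = [l for l in plasmid_loci if l.replicon == acc]
        size = replicons[acc].length if replicons and acc in replicons else pd.NA
        rows.append(
            {
                "accession": acc,
                "n_cdi_systems": len(members),
                "plasmid_size": size,
                "strain": members[0].strain_id,
            }
        )
    table = pd.DataFrame(
        rows, columns=["accession", "n_cdi_systems", "plasmid_size", "strain"]
    )
    return SurveySummary(n_chr, n_pla, n_unk, pct_chr, pct_pla, table)


def load_known_cdi_plasmids() -> pd.DataFrame:
    """Curated table of *E. coli* plasmids reported to carry at least one
    intact *cdi* system (accession, system count, plasmid size, strain)."""
    with resources.files("cdisurvey.data").joinpath("ecoli_cdi_plasmids.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def write_summary_tsv(summary: SurveySummary, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["location", "n_cdi_systems", "pct_of_classified"])
        writer.writerow(
            [
                CHROMOSOME,
                summary.n_chromosome,
                "NA" if summary.pct_chromosome is None else summary.pct_chromosome,
            ]
        )
        writer.writerow(
            [
                PLASMID,
                summary.n_plasmid,
                "NA" if summary.pct_plasmid is None else summary.pct_plasmid,
            ]
        )
        writer.writerow([UNKNOWN, summary.n_unknown, "NA"])


def write_plasmid_table_tsv(summary: SurveySummary, path: str | Path) -> None:
    summary.per_plasmid_table.to_csv(path, sep="\t", index=False, na_rep="NA")
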