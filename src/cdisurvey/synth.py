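"""Synthetic inputs with the statistical structure the survey assumes.

The generator emulates, end to end, the data the pipeline consumes:

* a community of replicons (chromosomes of a few Mbp, plasmids of ~100 kb)
  with full-length or truncated *cdiA*-like cassettes implanted at a
  controlled nucleotide identity, and definition lines that carry the
  classification keywords;
* the homology hit table such a community would produce, including split
  HSPs (gaps below the chaining threshold) and short decoy hits that the
  composite filter must remove;
* two-strain competition CFU trajectories whose log10 CI is normally
  distributed around a chosen effect;
* two-population flow-cytometry event mixtures on a lognormal intensity
  scale.

Every generator is deterministic under its seed.  The point-substitution
mutation model (no indels by default) keeps implant footprints exactly the
retained template length, so planted truth is exact; an indel-free model
also means a single un-split hit per implant is a faithful rendering.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import MIN_INTACT_LENGTH
from .hits import BlastHit, write_hits_tsv
from .regions import (
    MINUS,
    PLUS,
    RepliconMeta,
    write_metadata_tsv,
)
from .stats import CompetitionReplicate, FlowSample

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"TGCA"):
    _COMPLEMENT[_a] = _b


def random_sequence(rng: np.random.Generator, length: int) -> str:
    """Uniform-random nucleotide string."""
    return _BASES[rng.integers(0, 4, length)].tobytes().decode("ascii")


def mutate_sequence(template: str, identity: float, rng: np.random.Generator) -> str:
    """Point-substitute each base with probability (100 − identity)%; a
    substituted base always changes (uniform over the other three)."""
    arr = np.frombuffer(template.encode("ascii"), dtype=np.uint8)
    codes = _CODE[arr].copy()
    mask = rng.random(len(codes)) < (100.0 - identity) / 100.0
    shift = rng.integers(1, 4, int(mask.sum()))
    codes[mask] = (codes[mask] + shift) % 4
    return _BASES[codes].tobytes().decode("ascii")


def reverse_complement(seq: str) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _COMPLEMENT[arr][::-1].tobytes().decode("ascii")


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a synthetic replicon community.

    Size ranges are inclusive.  Plasmid sizes bracket the observed sizes of
    *cdi*-carrying *E. coli* plasmids (~120–210 kb); chromosomes sit in the
    typical *E. coli* range so the >4 Mbp size rule is exercised.  The gene
    template is 9372 bp — just above the 9070 bp intactness bar, leaving
    room for truncation tests — and truncated implants retain
    ``truncated_length`` bases (default 5000, well below the bar).
    """

    n_chromosomes: int = 9
    n_plasmids: int = 1
    chromosome_size_range: tuple[int, int] = (4_200_000, 5_500_000)
    plasmid_size_range: tuple[int, int] = (80_000, 250_000)
    gene_template_length: int = 9372
    identity_range: tuple[float, float] = (85.0, 99.0)
    truncation_fraction: float = 0.0
    truncated_length: int = 5000
    decoy_hit_rate: float = 2.0
    loci_per_chromosome: int = 1
    loci_per_plasmid: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.chromosome_size_range, self.plasmid_size_range):
            if not 0 < lo <= hi:
                raise ValueError("size ranges must be positive and ordered")
        if self.gene_template_length <= 0 or self.truncated_length <= 0:
            raise ValueError("template and truncated lengths must be > 0")
        lo, hi = self.identity_range
        if not (50.0 < lo <= hi <= 100.0):
            raise ValueError("identity_range must lie in (50, 100]")
        if not 0.0 <= self.truncation_fraction <= 1.0:
            raise ValueError("truncation_fraction must be in [0, 1]")
        if self.decoy_hit_rate < 0:
            raise ValueError("decoy_hit_rate must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one implanted cassette."""

    accession: str
    replicon_class: str
    start: int  # 0-based half-open footprint on the replicon
    end: int
    strand: str
    identity: float
    retained_length: int
    intact: bool


@dataclass
class Community:
    replicons: dict[str, RepliconMeta]
    truth: list[TruthRecord]
    template: str
    spec: CommunitySpec


#: minimum spacing between implant footprints on one replicon, in bp; kept
#: well above the default chaining gap so distinct implants never merge
_IMPLANT_SPACING = 5000


def make_community(spec: CommunitySpec) -> Community:
    """Generate replicons with implanted cassettes and their truth table.

    Deterministic under ``spec.seed``: the same spec yields byte-identical
    sequences, metadata and truth.
    """
    rng = np.random.default_rng(spec.seed)
    template = random_sequence(rng, spec.gene_template_length)
    replicons: dict[str, RepliconMeta] = {}
    truth: list[TruthRecord] = []

    plan = [
        ("chromosome", f"SYNC{i:04d}.1", spec.chromosome_size_range, spec.loci_per_chromosome)
        for i in range(1, spec.n_chromosomes + 1)
    ] + [
        ("plasmid", f"SYNP{i:04d}.1", spec.plasmid_size_range, spec.loci_per_plasmid)
        for i in range(1, spec.n_plasmids + 1)
    ]

    for idx, (cls, accession, (lo, hi), n_loci) in enumerate(plan, start=1):
        size = int(rng.integers(lo, hi + 1))
        if spec.gene_template_length > size:
            raise ValueError(
                f"gene template ({spec.gene_template_length} bp) longer than "
                f"replicon {accession} ({size} bp)"
            )
        arr = _BASES[rng.integers(0, 4, size)].copy()
        strain = f"SYN{idx:04d}"
        if cls == "chromosome":
            description = (
                f"{accession} Escherichia coli strain {strain} chromosome, complete genome"
            )
        else:
            description = (
                f"{accession} Escherichia coli strain {strain} plasmid p{strain}, "
                "complete sequence"
            )

        occupied: list[tuple[int, int]] = []
        for _ in range(n_loci):
            truncated = rng.random() < spec.truncation_fraction
            retained = spec.truncated_length if truncated else spec.gene_template_length
            start = _place_implant(rng, size, retained, occupied)
            occupied.append((start, start + retained))
            identity = float(rng.uniform(*spec.identity_range))
            strand = PLUS if rng.random() < 0.5 else MINUS
            insert = mutate_sequence(template[:retained], identity, rng)
            if strand == MINUS:
                insert = reverse_complement(insert)
            arr[start : start + retained] = np.frombuffer(
                insert.encode("ascii"), dtype=np.uint8
            )
            truth.append(
                TruthRecord(
                    accession=accession,
                    replicon_class=cls,
                    start=start,
                    end=start + retained,
                    strand=strand,
                    identity=identity,
                    retained_length=retained,
                    intact=retained > MIN_INTACT_LENGTH,
                )
            )
        replicons[accession] = RepliconMeta(
            accession=accession,
            description=description,
            length=size,
            topology="circular",
            sequence=arr.tobytes().decode("ascii"),
        )
    return Community(replicons=replicons, truth=truth, template=template, spec=spec)


def _place_implant(
    rng: np.random.Generator, size: int, length: int, occupied: list[tuple[int, int]]
) -> int:
    for _ in range(200):
        start = int(rng.integers(0, size - length + 1))
        if all(
            start + length + _IMPLANT_SPACING <= s or e + _IMPLANT_SPACING <= start
            for s, e in occupied
        ):
            return start
    raise ValueError("could not place implant without overlap; replicon too crowded")


def write_community(community: Community, out_dir: str | Path) -> dict[str, Path]:
    """Write replicons.fasta, metadata.tsv, truth.tsv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "replicons.fasta"
    with open(fasta, "w") as fh:
        for acc in community.replicons:
            meta = community.replicons[acc]
            fh.write(f">{meta.description}\n")
            seq = meta.sequence or ""
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    meta_path = out / "metadata.tsv"
    write_metadata_tsv(community.replicons, meta_path)
    truth_rows = [asdict(t) for t in community.truth]
    truth_tsv = out / "truth.tsv"
    pd.DataFrame(truth_rows).to_csv(truth_tsv, sep="\t", index=False)
    truth_json = out / "truth.json"
    with open(truth_json, "w") as fh:
        json.dump(truth_rows, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {
        "fasta": fasta,
        "metadata": meta_path,
        "truth_tsv": truth_tsv,
        "truth_json": truth_json,
    }


# ---------------------------------------------------------------------------
# Hit simulation


#: bitscore above which the simulated e-value underflows to literal 0.0.
#: With bitscore = 2·len·pid/100 this cap guarantees evalue == 0 only for
#: alignments longer than 3000 bp, so genuine split HSPs are never caught
#: by the (len < 3000 and evalue == 0) removal clause.
DEFAULT_BITSCORE_CAP = 6000.0


def simulate_hits(
    community: Community,
    seed: int | None = None,
    split_probability: float = 0.3,
    split_gap_range: tuple[int, int] = (100, 900),
    min_piece: int = 1200,
    bitscore_cap: float = DEFAULT_BITSCORE_CAP,
    decoy_hit_rate: float | None = None,
    query_id: str = "cdiA_query",
) -> list[BlastHit]:
    """Emulate the tabular hit file the community would produce.

    Each implant emits one HSP spanning its footprint, or (with
    ``split_probability``) 2–3 HSPs tiling the footprint with gaps below
    the chaining threshold.  Decoy hits — too short, or short with low
    identity — are sprinkled per replicon at ``decoy_hit_rate`` (Poisson);
    every decoy is constructed to fail the composite filter.
    """
    rng = np.random.default_rng(community.spec.seed + 1 if seed is None else seed)
    rate = community.spec.decoy_hit_rate if decoy_hit_rate is None else decoy_hit_rate
    hits: list[BlastHit] = []

    for rec in community.truth:
        pieces = _split_footprint(
            rng, rec.retained_length, split_probability, split_gap_range, min_piece
        )
        for q_off, s_off, plen in pieces:
            hits.append(
                _implant_hit(
                    rec, query_id, q_off, s_off, plen, bitscore_cap, rng
                )
            )

    for acc, meta in community.replicons.items():
        for _ in range(int(rng.poisson(rate))):
            hits.append(_decoy_hit(rng, acc, meta.length, query_id))
    return hits


def _split_footprint(
    rng: np.random.Generator,
    length: int,
    split_probability: float,
    gap_range: tuple[int, int],
    min_piece: int,
) -> list[tuple[int, int, int]]:
    """(query_offset, subject_offset, piece_length) triples tiling
    [0, length); first piece starts at 0 and last ends at length, so the
    chained envelope equals the true footprint."""
    if length < 3 * min_piece or rng.random() >= split_probability:
        return [(0, 0, length)]
    k = int(rng.integers(2, 4))
    gaps = rng.integers(gap_range[0], gap_range[1] + 1, k - 1)
    budget = length - int(gaps.sum()) - k * min_piece
    if budget < 0:
        return [(0, 0, length)]
    extra = rng.multinomial(budget, np.full(k, 1.0 / k))
    lengths = min_piece + extra
    pieces = []
    q = s = 0
    for i in range(k):
        pieces.append((q, s, int(lengths[i])))
        q += int(lengths[i])
        s += int(lengths[i])
        if i < k - 1:
            gap = int(gaps[i])
            q += gap
            s += gap
    return pieces


def _evalue_for(bitscore: float, cap: float) -> float:
    if bitscore > cap:
        return 0.0
    return 10 ** (-min(180.0, bitscore / 30.0))


def _implant_hit(
    rec: TruthRecord,
    query_id: str,
    q_off: int,
    s_off: int,
    plen: int,
    bitscore_cap: float,
    rng: np.random.Generator,
) -> BlastHit:
    pid = round(rec.identity, 2)
    bitscore = round(2.0 * plen * pid / 100.0, 1)
    s_start = rec.start + s_off + 1  # 1-based
    s_end = rec.start + s_off + plen
    return BlastHit(
        query_id=query_id,
        subject_id=rec.accession,
        pct_identity=pid,
        aln_length=plen,
        mismatches=int(round(plen * (100.0 - pid) / 100.0)),
        gap_opens=0,
        q_start=q_off + 1,
        q_end=q_off + plen,
        s_start=s_start,
        s_end=s_end,
        evalue=_evalue_for(bitscore, bitscore_cap),
        bitscore=bitscore,
        strand=rec.strand,
    )


def _decoy_hit(
    rng: np.random.Generator, accession: str, replicon_length: int, query_id: str
) -> BlastHit:
    if rng.random() < 0.5:
        # too short: removed regardless of identity
        plen = int(rng.integers(100, 1000))
        pid = round(float(rng.uniform(70.0, 99.0)), 2)
    else:
        # short and low-identity: removed by the length/identity clause
        plen = int(rng.integers(1000, 2000))
        pid = round(float(rng.uniform(60.0, 80.49)), 2)
    start = int(rng.integers(0, max(1, replicon_length - plen)))
    strand = PLUS if rng.random() < 0.5 else MINUS
    bitscore = round(2.0 * plen * pid / 100.0, 1)
    return BlastHit(
        query_id=query_id,
        subject_id=accession,
        pct_identity=pid,
        aln_length=plen,
        mismatches=int(round(plen * (100.0 - pid) / 100.0)),
        gap_opens=0,
        q_start=1,
        q_end=plen,
        s_start=start + 1,
        s_end=start + plen,
        evalue=_evalue_for(bitscore, DEFAULT_BITSCORE_CAP),
        bitscore=bitscore,
        strand=strand,
    )


def write_simulated_hits(hits: Sequence[BlastHit], path: str | Path) -> Path:
    path = Path(path)
    write_hits_tsv(hits, path)
    return path


# ---------------------------------------------------------------------------
# Competition and flow simulation


def simulate_competition(
    true_log10_ci: float,
    noise_sd_log10: float,
    n_reps: int,
    ratio: float = 10.0,
    seed: int | None = None,
    label: str = "competition",
    target_t0: float = 1e6,
    inhibitor_growth: float = 100.0,
) -> list[CompetitionReplicate]:
    """Replicate CFU trajectories with log10 CI ~ Normal(true, sd).

    The starting counts follow the inhibitor:target mixing ratio (default
    10:1, the standard competition setup; 5:1 is the short toxicity-assay
    variant); the inhibitor grows ``inhibitor_growth``-fold and the target
    end count is solved from the drawn CI.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    inhibitor_t0 = ratio * target_t0
    inhibitor_tend = inhibitor_t0 * inhibitor_growth
    reps = []
    for _ in range(n_reps):
        log_ci = true_log10_ci + (
            rng.normal(0.0, noise_sd_log10) if noise_sd_log10 > 0 else 0.0
        )
        ci = 10.0 ** log_ci
        target_tend = inhibitor_tend * target_t0 / (inhibitor_t0 * ci)
        reps.append(
            CompetitionReplicate(
                inhibitor_t0=inhibitor_t0,
                target_t0=target_t0,
                inhibitor_tend=inhibitor_tend,
                target_tend=target_tend,
                label=label,
            )
        )
    return reps


def write_cfu_tsv(reps: Sequence[CompetitionReplicate], path: str | Path) -> Path:
    df = pd.DataFrame(
        [
            {
                "label": r.label,
                "replicate": i + 1,
                "inhibitor_t0": r.inhibitor_t0,
                "target_t0": r.target_t0,
                "inhibitor_tend": r.inhibitor_tend,
                "target_tend": r.target_tend,
            }
            for i, r in enumerate(reps)
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


#: lognormal (mean, sigma of log intensity) for the polarized / depolarized
#: readout populations and the target-marker channel; chosen ~3 log-SD apart
#: so a 99.5 % control-quantile gate separates them almost perfectly
DEFAULT_LOW_PARAMS = (4.6, 0.4)
DEFAULT_HIGH_PARAMS = (7.6, 0.4)
DEFAULT_RFP_PARAMS = (8.0, 0.3)


def simulate_flow(
    planted_fraction: float,
    n_events: int = 20_000,
    low_params: tuple[float, float] = DEFAULT_LOW_PARAMS,
    high_params: tuple[float, float] = DEFAULT_HIGH_PARAMS,
    rfp_params: tuple[float, float] = DEFAULT_RFP_PARAMS,
    seed: int | None = None,
    positive_channel: str = "RFP",
    readout_channel: str = "DiBAC",
) -> FlowSample:
    """Two-component lognormal mixture on the readout channel; each event is
    independently in the high (depolarized) component with the planted
    probability.  All events are marker-positive targets."""
    if not 0.0 <= planted_fraction <= 1.0:
        raise ValueError("planted_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    high = rng.random(n_events) < planted_fraction
    readout = np.where(
        high,
        rng.lognormal(high_params[0], high_params[1], n_events),
        rng.lognormal(low_params[0], low_params[1], n_events),
    )
    rfp = rng.lognormal(rfp_params[0], rfp_params[1], n_events)
    events = pd.DataFrame({positive_channel: rfp, readout_channel: readout})
    return FlowSample(
        events=events,
        positive_gate_channel=positive_channel,
        readout_channel=readout_channel,
    )


def write_flow_csv(sample: FlowSample, path: str | Path) -> Path:
    sample.events.to_csv(path, index=False, float_format="%.4f")
    return Path(path)


def read_flow_csv(
    path: str | Path,
    positive_channel: str = "RFP",
    readout_channel: str = "DiBAC",
) -> FlowSample:
    return FlowSample(
        events=pd.read_csv(path),
        positive_gate_channel=positive_channel,
        readout_channel=readout_channel,
    )
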