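"""Survey orchestration: parse → filter → chain → extract → classify →
intact-filter → dedupe → summarize, with every intermediate written out and
a JSON run report of per-stage counts, plus thin drivers for the
competition and flow statistics."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classify as cls
from . import hits as hmod
from . import regions as rmod
from . import stats as smod
from .classify import ClassificationRule, SurveySummary
from .hits import ChainParams, FilterRule
from .stats import FlowSample, GateSpec

logger = logging.getLogger("cdisurvey")


@dataclass
class SurveyConfig:
    """Paths and parameters for one survey run; every threshold of the
    procedure is a named field with its standard default."""

    hits: Path
    fasta: Path
    out_dir: Path
    meta: Path | None = None
    filter_rule: FilterRule = field(default_factory=FilterRule)
    chain_params: ChainParams = field(default_factory=ChainParams)
    upstream: int = 20_000
    downstream: int = 30_000
    circular_wrap: bool = False
    classification_rule: ClassificationRule = field(default_factory=ClassificationRule)
    min_intact: int = cls.MIN_INTACT_LENGTH

    @classmethod
    def from_yaml(cls_, path: str | Path) -> "SurveyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kwargs = dict(
            hits=Path(raw["hits"]),
            fasta=Path(raw["fasta"]),
            out_dir=Path(raw["out_dir"]),
            meta=Path(raw["meta"]) if raw.get("meta") else None,
        )
        if "filter_rule" in raw:
            kwargs["filter_rule"] = FilterRule(**raw["filter_rule"])
        if "chain_params" in raw:
            kwargs["chain_params"] = ChainParams(**raw["chain_params"])
        if "classification_rule" in raw:
            kwargs["classification_rule"] = ClassificationRule(
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in raw["classification_rule"].items()
                }
            )
        for key in ("upstream", "downstream", "circular_wrap", "min_intact"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls_(**kwargs)


@dataclass
class SurveyResult:
    summary: SurveySummary
    report: dict
    loci: list[rmod.CdiLocus]


def run_survey(config: SurveyConfig) -> SurveyResult:
    """Run the full survey and write all artifacts into ``config.out_dir``.

    Artifacts: filtered_hits.tsv, loci_candidates.tsv, loci_windows.{bed,
    gff3}, windows.fasta, table1_summary.tsv, table2_plasmids.tsv and
    report.json (parameters plus per-stage counts).  Outputs are
    deterministic for a fixed config: re-running reproduces identical
    bytes.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    all_hits = hmod.parse_blast_tab(config.hits)
    logger.info("parsed %d hits from %s", len(all_hits), config.hits)
    if not all_hits:
        logger.warning("hit file %s contains no hits; survey will be empty", config.hits)

    kept = hmod.filter_hits(all_hits, config.filter_rule)
    logger.info("filter kept %d / %d hits", len(kept), len(all_hits))
    hmod.write_hits_tsv(kept, out / "filtered_hits.tsv")

    loci = hmod.chain_hits(kept, config.chain_params)
    logger.info("chained into %d candidate loci", len(loci))
    hmod.write_loci_tsv(loci, out / "loci_candidates.tsv")

    replicons = rmod.read_replicon_fasta(config.fasta)
    if config.meta is not None:
        replicons = rmod.merge_metadata(replicons, rmod.read_metadata_tsv(config.meta))

    for locus in loci:
        meta = replicons.get(locus.replicon)
        if meta is None:
            raise ValueError(
                f"window stage: accession {locus.replicon!r} present in hits "
                "but missing from the replicon FASTA/metadata"
            )
        rmod.attach_window(
            locus,
            meta,
            upstream=config.upstream,
            downstream=config.downstream,
            circular_wrap=config.circular_wrap,
        )
        locus.replicon_class = cls.classify_replicon(meta, config.classification_rule)
        locus.strain_id = cls.parse_strain_id(meta.description, meta.accession)
        locus.intact = cls.is_intact(locus, config.min_intact)

    rmod.write_windows_bed(loci, out / "loci_windows.bed")
    rmod.write_windows_gff3(loci, out / "loci_windows.gff3")
    rmod.write_windows_fasta(loci, out / "windows.fasta")

    intact = [l for l in loci if l.intact]
    logger.info("%d / %d loci intact (> %d bp)", len(intact), len(loci), config.min_intact)
    deduped = cls.dedupe_strains(intact)
    logger.info("%d loci after strain deduplication", len(deduped))

    summary = cls.summarize(deduped, replicons)
    cls.write_summary_tsv(summary, out / "table1_summary.tsv")
    cls.write_plasmid_table_tsv(summary, out / "table2_plasmids.tsv")

    report = {
        "parameters": {
            "filter_rule": vars(config.filter_rule),
            "chain_params": vars(config.chain_params),
            "upstream": config.upstream,
            "downstream": config.downstream,
            "circular_wrap": config.circular_wrap,
            "classification_rule": {
                k: list(v) if isinstance(v, tuple) else v
                for k, v in vars(config.classification_rule).items()
            },
            "min_intact": config.min_intact,
        },
        "stage_counts": {
            "hits_parsed": len(all_hits),
            "hits_filtered": len(kept),
            "loci_candidates": len(loci),
            "loci_intact": len(intact),
            "loci_deduped": len(deduped),
            "classified": {
                "chromosome": summary.n_chromosome,
                "plasmid": summary.n_plasmid,
                "unknown": summary.n_unknown,
            },
        },
        "summary": {
            "pct_chromosome": summary.pct_chromosome,
            "pct_plasmid": summary.pct_plasmid,
        },
        "outputs": [
            "filtered_hits.tsv",
            "loci_candidates.tsv",
            "loci_windows.bed",
            "loci_windows.gff3",
            "windows.fasta",
            "table1_summary.tsv",
            "table2_plasmids.tsv",
        ],
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return SurveyResult(summary=summary, report=report, loci=loci)


# ---------------------------------------------------------------------------
# Competition / flow drivers


def read_cfu_tsv(path: str | Path) -> list[smod.CompetitionReplicate]:
    df = pd.read_csv(path, sep="\t")
    return [
        smod.CompetitionReplicate(
            inhibitor_t0=row.inhibitor_t0,
            target_t0=row.target_t0,
            inhibitor_tend=row.inhibitor_tend,
            target_tend=row.target_tend,
            label=str(row.label),
        )
        for row in df.itertuples()
    ]


def run_competition(
    cfu_path: str | Path,
    out_dir: str | Path | None = None,
    on_log: bool = True,
) -> dict:
    """Per-replicate CIs, per-label summaries and pairwise t-tests.

    Returns a dict with DataFrames ``replicates``, ``summaries`` and
    ``tests``; writes TSVs when ``out_dir`` is given.
    """
    reps = read_cfu_tsv(cfu_path)
    if not reps:
        raise ValueError(f"CFU table {cfu_path} contains no replicates")
    rep_rows = [
        {"label": r.label, "ci": smod.competitive_index(r)} for r in reps
    ]
    rep_df = pd.DataFrame(rep_rows)

    labels = list(dict.fromkeys(rep_df["label"]))
    sum_rows = []
    for label in labels:
        group = [r for r in reps if r.label == label]
        s = smod.ci_summary(group)
        sum_rows.append(
            {
                "label": label,
                "n": s.n,
                "mean_ci": s.mean,
                "sem_ci": s.sem,
                "geometric_mean_ci": s.geometric_mean,
                "log10_mean": s.log10_mean,
                "log10_sem": s.log10_sem,
            }
        )
    sum_df = pd.DataFrame(sum_rows)

    test_rows = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            a = rep_df.loc[rep_df.label == la, "ci"].tolist()
            b = rep_df.loc[rep_df.label == lb, "ci"].tolist()
            if len(a) >= 2 and len(b) >= 2:
                res = smod.ci_ttest(a, b, on_log=on_log)
                test_rows.append(
                    {
                        "group_a": la,
                        "group_b": lb,
                        "t_statistic": res.statistic,
                        "p_value": res.pvalue,
                        "degenerate": res.degenerate,
                        "on_log": on_log,
                    }
                )
    test_df = pd.DataFrame(
        test_rows,
        columns=["group_a", "group_b", "t_statistic", "p_value", "degenerate", "on_log"],
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rep_df.to_csv(out / "per_replicate_ci.tsv", sep="\t", index=False)
        sum_df.to_csv(out / "ci_summary.tsv", sep="\t", index=False)
        test_df.to_csv(out / "ci_tests.tsv", sep="\t", index=False)
    return {"replicates": rep_df, "summaries": sum_df, "tests": test_df}


def run_flow(
    events_path: str | Path,
    control_path: str | Path,
    quantile: float = 0.995,
    positive_channel: str = "RFP",
    readout_channel: str = "DiBAC",
    min_events: int = 20_000,
    out_dir: str | Path | None = None,
) -> dict:
    """Gated depolarized fraction of a sample against a control.

    The positive (target) gate and the readout gate are both placed at the
    control's empirical ``quantile`` on the respective channel.
    """
    from .synth import read_flow_csv  # tabular flow I/O lives beside the simulator

    sample = read_flow_csv(events_path, positive_channel, readout_channel)
    control = read_flow_csv(control_path, positive_channel, readout_channel)
    readout_gate = GateSpec("control_quantile", quantile, control)
    # tabular exports are already restricted to marker-positive events, so
    # the positive gate only needs to exclude genuinely dark debris: place
    # it below the dimmest marker-positive control event
    thr_pos = 0.5 * float(control.events[positive_channel].min())
    thr_read = smod.gate_threshold(control, readout_gate, readout_channel)
    fraction = smod.depolarized_fraction(
        sample,
        GateSpec("fixed", thr_pos),
        GateSpec("fixed", thr_read),
        min_events=min_events,
    )
    result = {
        "positive_threshold": thr_pos,
        "readout_threshold": thr_read,
        "fraction": fraction,
        "n_events": sample.n_events,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([result]).to_csv(out / "gated_fraction.tsv", sep="\t", index=False)
    return result


def run_expression(
    sample_path: str | Path,
    reference_path: str | Path,
    background_path: str | Path,
    channel: str = "sYFP2",
    out_dir: str | Path | None = None,
) -> dict:
    """Background-subtracted median expression of two reporters and their
    fold ratio (sample over reference)."""
    from .synth import read_flow_csv

    sample = read_flow_csv(sample_path, readout_channel=channel)
    reference = read_flow_csv(reference_path, readout_channel=channel)
    background = read_flow_csv(background_path, readout_channel=channel)
    value_sample = smod.relative_expression(sample, background)
    value_reference = smod.relative_expression(reference, background)
    fold = smod.fold_ratio(value_sample, value_reference)
    result = {
        "value_sample": value_sample,
        "value_reference": value_reference,
        "fold": fold,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([result]).to_csv(out / "expression.tsv", sep="\t", index=False)
    return result
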