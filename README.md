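# cdisurvey

Contact-dependent growth inhibition (CDI) lets a bacterium deliver protein
toxins into neighbouring cells through the CdiB/CdiA two-partner secretion
system, with CdiI conferring immunity; the three genes form the *cdiBAI*
operon. A recurring question about these systems is *where they live*:
most *E. coli* *cdi* loci sit on the chromosome, but some ride on large
plasmids — and at least one plasmid carries two complete systems.

`cdisurvey` is a reusable, tested pipeline for answering that question
from a nucleotide homology search, together with the statistics used to
characterize such systems experimentally:

* **Survey** — parse BLAST tabular (`-outfmt 6`) hits of a *cdiA* query,
  strip fragmented/non-specific hits with the composite rule
  *remove iff* `(length < 2000 ∧ identity < 80.5 %) ∨ (length < 3000 ∧
  E = 0) ∨ (length < 1000)`, chain surviving HSPs on the same replicon and
  strand into candidate loci, extract each locus with 20 kb upstream and
  30 kb downstream of flanking context (strand-relative), classify the
  carrying replicon as chromosome or plasmid from its definition line and
  size (> 4 Mbp), keep loci whose chained span exceeds 9070 bp (a
  full-length *cdiA*), deduplicate strains, and tabulate counts and
  percentages per location plus a per-plasmid breakdown.
* **Competition statistics** — the competitive index of a two-strain
  co-culture, CI = (I_end/T_end) / (I_0/T_0) from inhibitor (I) and
  target (T) CFU counts; replicate summaries (mean ± SEM, geometric mean)
  and unpaired two-tailed Student's *t*-tests on log₁₀ CI.
* **Flow cytometry** — reproducible gating thresholds (control quantile,
  mean + k·SD, or fixed), the depolarized fraction of marker-positive
  target cells (e.g. DiBAC₄(3) uptake after toxin delivery), and
  background-subtracted median reporter expression with fold ratios.
* **Synthetic data** — seeded generators for replicon communities with
  implanted full-length or truncated *cdiA*-like cassettes at controlled
  identity, the hit tables they would produce (split HSPs, decoys),
  competition CFU trajectories, and two-population flow-event mixtures,
  so every stage is testable without any download.

## Worked example

Generate a synthetic community of 9 chromosomes and 1 plasmid, each
carrying one implanted cassette, then run every stage:

```bash
cdisurvey synth  --out demo --seed 1 --chromosomes 9 --plasmids 1
cdisurvey survey --hits demo/hits.tsv --fasta demo/replicons.fasta \
                 --meta demo/metadata.tsv --out demo/survey
cdisurvey compete --cfu demo/cfu.tsv
cdisurvey flow   --events demo/flow_sample.csv --control demo/flow_control.csv
```

prints

```
chromosome: 9 (90.0 %)  plasmid: 1 (10.0 %)  unknown: 0
      label  n     mean_ci      sem_ci  geometric_mean_ci  log10_mean  log10_sem
competition  3 8627.251441 1392.926687        8420.233591    3.925324   0.066379
depolarized fraction: 0.6332 (20000 events)
```

The survey recovered all ten planted loci and their locations exactly
(9 chromosomal, 1 plasmid-borne → 90.0 % / 10.0 %). The competition table
summarizes three simulated replicates of a 4-log competition (true
log₁₀ CI = 4; the geometric mean of ~8.4 × 10³ and log₁₀ mean 3.93 sit
within replicate noise). The flow sample was simulated with 63 % of
target events drawn from the depolarized population; the
control-quantile gate recovers 0.6332. `demo/survey/` additionally holds
the filtered hits, the candidate-locus table, BED/GFF3/FASTA of the
extraction windows, the two summary tables and `report.json` with
per-stage counts.

All of this is also available as a library (`import cdisurvey`); the CLI
is a thin layer over `cdisurvey.pipeline`.

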