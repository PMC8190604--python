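"""Competition and flow-cytometry statistics.

Competitive index (CI)
----------------------
For a two-strain co-culture with inhibitor and target CFU counts at the
start (t0) and end (t_end) of the competition::

    CI = (inhibitor_tend / target_tend) / (inhibitor_t0 / target_t0)

CI = 1 means neutral competition; CI >> 1 means the inhibitor outcompeted
the target.  Replicate CIs span orders of magnitude, so group comparisons
default to log10(CI); summaries report both the arithmetic mean ± SEM and
the geometric mean with the SEM of log10 CI.  Significance uses the
classical unpaired, two-tailed, equal-variance Student's t-test.

Flow cytometry
--------------
Events arrive as a table with one row per event and one column per
channel.  Gating thresholds are derived reproducibly from a control sample
(empirical quantile or mean + k·SD) or fixed explicitly.  The depolarized
fraction is the share of gate-positive (target) events whose readout
channel (e.g. the membrane-potential dye DiBAC4(3)) also exceeds its
threshold.  Reporter expression is summarized as the background-subtracted
median single-cell intensity, compared between constructs as a fold ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class CompetitionReplicate:
    """CFU/ml counts for one competition replicate."""

    inhibitor_t0: float
    target_t0: float
    inhibitor_tend: float
    target_tend: float
    label: str = ""


def competitive_index(rep: CompetitionReplicate) -> float:
    """CI = (inhibitor/target ratio at t_end) / (ratio at t0).

    All four counts must be positive; a zero count (e.g. a target below the
    plating detection limit) leaves the CI undefined — substitute the
    detection limit explicitly and report that substitution rather than
    passing a zero.
    """
    counts = (
        rep.inhibitor_t0,
        rep.target_t0,
        rep.inhibitor_tend,
        rep.target_tend,
    )
    if any(c <= 0 for c in counts):
        raise ValueError(
            "competitive index undefined for non-positive CFU counts; "
            "substitute the detection limit explicitly if a count was below it"
        )
    return (rep.inhibitor_tend / rep.target_tend) / (rep.inhibitor_t0 / rep.target_t0)


@dataclass(frozen=True)
class CISummary:
    n: int
    mean: float
    sem: float
    geometric_mean: float
    log10_mean: float
    log10_sem: float


def ci_summary(reps: Sequence[CompetitionReplicate]) -> CISummary:
    """Arithmetic mean ± SEM of replicate CIs, plus the log-scale summary
    (geometric mean; SEM of log10 CI) used for log-scaled figures.

    SEM uses the n−1 sample SD; with a single replicate it is NaN.
    """
    if len(reps) == 0:
        raise ValueError("ci_summary requires at least one replicate")
    cis = np.array([competitive_index(r) for r in reps], dtype=float)
    logs = np.log10(cis)
    n = len(cis)
    sem = float(np.std(cis, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    log_sem = float(np.std(logs, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return CISummary(
        n=n,
        mean=float(np.mean(cis)),
        sem=sem,
        geometric_mean=float(10 ** np.mean(logs)),
        log10_mean=float(np.mean(logs)),
        log10_sem=log_sem,
    )


class TTestResult(NamedTuple):
    statistic: float
    pvalue: float
    degenerate: bool = False


def ci_ttest(
    group_a: Sequence[float], group_b: Sequence[float], on_log: bool = True
) -> TTestResult:
    """Unpaired, two-tailed, equal-variance Student's t-test between two
    groups of competitive indices, on log10 CI by default.

    Degrees of freedom are nA + nB − 2.  When both groups have zero
    variance the test is degenerate: equal means give (t=0, p=1), unequal
    means give (t=±inf, p=0), flagged via ``degenerate``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two replicates")
    if on_log:
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("log-scale test requires strictly positive CIs")
        a, b = np.log10(a), np.log10(b)
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        if np.mean(a) == np.mean(b):
            return TTestResult(0.0, 1.0, degenerate=True)
        t = math.copysign(math.inf, float(np.mean(a) - np.mean(b)))
        return TTestResult(t, 0.0, degenerate=True)
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(t), float(p), degenerate=False)


# ---------------------------------------------------------------------------
# Flow cytometry


@dataclass
class FlowSample:
    """Per-event channel intensities with the channels used for gating."""

    events: pd.DataFrame
    positive_gate_channel: str = "RFP"
    readout_channel: str = "DiBAC"

    def __post_init__(self) -> None:
        values = self.events.to_numpy(dtype=float, copy=False)
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("flow event intensities must be finite")

    @property
    def n_events(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class GateSpec:
    """How to place a gating threshold.

    ``control_quantile``: empirical q-quantile of a control sample;
    ``mean_plus_k_sd``: control mean + k·SD; ``fixed``: absolute threshold.
    """

    method: str
    parameter: float
    control: FlowSample | None = None

    def __post_init__(self) -> None:
        if self.method not in ("control_quantile", "mean_plus_k_sd", "fixed"):
            raise ValueError(f"unknown gate method {self.method!r}")
        if self.method == "control_quantile" and not 0.0 < self.parameter < 1.0:
            raise ValueError("quantile must be in (0, 1)")
        if self.method == "mean_plus_k_sd" and self.parameter <= 0:
            raise ValueError("k must be > 0")


MIN_CONTROL_EVENTS = 100


def gate_threshold(
    control: FlowSample | None, spec: GateSpec, channel: str | None = None
) -> float:
    """Intensity threshold for a gate; control-based methods require at
    least 100 control events on the relevant channel."""
    if spec.method == "fixed":
        return float(spec.parameter)
    ctrl = control if control is not None else spec.control
    if ctrl is None:
        raise ValueError(f"gate method {spec.method!r} requires a control sample")
    channel = channel if channel is not None else ctrl.readout_channel
    values = ctrl.events[channel].to_numpy(dtype=float)
    if len(values) < MIN_CONTROL_EVENTS:
        raise ValueError(
            f"control has {len(values)} events; at least "
            f"{MIN_CONTROL_EVENTS} are required to place a gate"
        )
    if spec.method == "control_quantile":
        return float(np.quantile(values, spec.parameter))
    return float(np.mean(values) + spec.parameter * np.std(values, ddof=1))


def depolarized_fraction(
    sample: FlowSample,
    positive_gate: GateSpec,
    readout_gate: GateSpec,
    min_events: int = 20_000,
) -> float:
    """Fraction of gate-positive (target) events whose readout channel also
    exceeds its threshold.

    ``min_events`` is the floor on gate-positive events (default 20 000,
    matching the usual acquisition target for RFP+ cells); fewer raises an
    error rather than returning an under-powered estimate.
    """
    thr_pos = gate_threshold(positive_gate.control, positive_gate, sample.positive_gate_channel)
    thr_read = gate_threshold(readout_gate.control, readout_gate, sample.readout_channel)
    pos = sample.events[sample.positive_gate_channel].to_numpy(dtype=float) > thr_pos
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ValueError("no events pass the positive gate")
    if n_pos < min_events:
        raise ValueError(
            f"{n_pos} events pass the positive gate; at least {min_events} "
            "are required (lower min_events to override)"
        )
    readout = sample.events[sample.readout_channel].to_numpy(dtype=float)
    both = int(np.sum(pos & (readout > thr_read)))
    return both / n_pos


def relative_expression(sample: FlowSample, background: FlowSample) -> float:
    """Background-subtracted median readout intensity:
    median(sample) − median(background), both on the readout channel."""
    if sample.n_events == 0 or background.n_events == 0:
        raise ValueError("both samples must contain events")
    med_s = float(np.median(sample.events[sample.readout_channel]))
    med_b = float(np.median(background.events[background.readout_channel]))
    return med_s - med_b


def fold_ratio(value_a: float, value_b: float) -> float:
    """Fold ratio of two background-subtracted expression values."""
    if value_b <= 0:
        raise ValueError(
            "fold ratio undefined: denominator expression is not positive "
            "after background subtraction"
        )
    return value_a / value_b
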