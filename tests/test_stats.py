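"""Competitive-index and flow-cytometry statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cdisurvey.stats import (
    CompetitionReplicate,
    FlowSample,
    GateSpec,
    ci_summary,
    ci_ttest,
    competitive_index,
    depolarized_fraction,
    fold_ratio,
    gate_threshold,
    relative_expression,
)


def rep(i0=1e7, t0=1e6, iend=1e9, tend=1e8, label=""):
    return CompetitionReplicate(i0, t0, iend, tend, label)


class TestCompetitiveIndex:
    def test_neutral_competition(self):
        assert competitive_index(rep(1e7, 1e6, 1e9, 1e8)) == pytest.approx(1.0)

    def test_four_log_inhibition(self):
        assert competitive_index(rep(1e7, 1e6, 1e9, 1e4)) == pytest.approx(1e4)

    def test_swapping_roles_inverts_ci(self):
        r = rep(3e7, 4e6, 8e9, 5e5)
        swapped = CompetitionReplicate(
            r.target_t0, r.inhibitor_t0, r.target_tend, r.inhibitor_tend
        )
        assert competitive_index(swapped) == pytest.approx(1 / competitive_index(r))

    def test_zero_count_is_an_error_with_guidance(self):
        with pytest.raises(ValueError, match="detection limit"):
            competitive_index(rep(1e7, 1e6, 1e9, 0.0))

    @given(
        counts=st.tuples(*[st.floats(min_value=1e2, max_value=1e12) for _ in range(4)]),
        scale=st.floats(min_value=1e-6, max_value=1e6),
    )
    def test_scale_invariance(self, counts, scale):
        r = CompetitionReplicate(*counts)
        scaled = CompetitionReplicate(*(c * scale for c in counts))
        assert competitive_index(scaled) == pytest.approx(
            competitive_index(r), rel=1e-9
        )

    @given(counts=st.tuples(*[st.floats(min_value=1e2, max_value=1e12) for _ in range(4)]))
    def test_reciprocity(self, counts):
        i0, t0, iend, tend = counts
        forward = competitive_index(CompetitionReplicate(i0, t0, iend, tend))
        backward = competitive_index(CompetitionReplicate(t0, i0, tend, iend))
        assert forward * backward == pytest.approx(1.0, rel=1e-9)


class TestCISummary:
    def test_identical_replicates(self):
        s = ci_summary([rep(), rep(), rep()])
        assert s.mean == pytest.approx(1.0)
        assert s.sem == pytest.approx(0.0)
        assert s.n == 3

    def test_arithmetic_and_geometric_means(self):
        reps = [rep(tend=1e6), rep(tend=1e4)]  # CIs 100 and 10000
        s = ci_summary(reps)
        assert s.mean == pytest.approx(5050.0)
        assert s.geometric_mean == pytest.approx(1000.0)

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            ci_summary([])

    def test_single_replicate_sem_undefined(self):
        s = ci_summary([rep()])
        assert math.isnan(s.sem)

    def test_sem_tracks_lognormal_noise(self):
        # Monte-Carlo check: with log10 CI ~ N(2, 0.3) the observed SEM of
        # n=3 batches should sit near the theoretical SD/sqrt(3) of the CI
        rng = np.random.default_rng(0)
        sigma = 0.3 * math.log(10)
        theo_sd = math.sqrt((math.exp(sigma**2) - 1) * math.exp(2 * math.log(100) + sigma**2))
        sems = []
        for _ in range(1000):
            cis = np.exp(rng.normal(math.log(100), sigma, 3))
            reps = [rep(1e7, 1e6, 1e9, 1e9 * 1e6 / (1e7 * c)) for c in cis]
            sems.append(ci_summary(reps).sem)
        mean_sem = float(np.mean(sems))
        assert theo_sd / math.sqrt(3) / 3 < mean_sem < 3 * theo_sd / math.sqrt(3)


class TestCITTest:
    def test_identical_groups(self):
        res = ci_ttest([10.0, 10.0, 10.0], [10.0, 10.0, 10.0])
        assert (res.statistic, res.pvalue) == (0.0, 1.0)
        assert res.degenerate

    def test_zero_variance_distinct_means(self):
        res = ci_ttest([1.0, 1.0, 1.0], [10.0, 10.0, 10.0])
        assert math.isinf(res.statistic)
        assert res.pvalue == 0.0
        assert res.degenerate

    def test_matches_classical_student_formula(self):
        a = [1.2, 3.4, 0.9, 2.2]
        b = [10.0, 22.0, 15.0]
        res = ci_ttest(a, b, on_log=False)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
        t = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
        assert res.statistic == pytest.approx(t)
        assert not res.degenerate

    def test_log_scale_default(self):
        a, b = [1e2, 1e3, 1e2], [1e5, 1e6, 1e5]
        log_res = ci_ttest(a, b)
        raw_res = ci_ttest(a, b, on_log=False)
        assert log_res.pvalue != pytest.approx(raw_res.pvalue)

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            ci_ttest([1.0], [2.0, 3.0])

    def test_type_one_error_near_nominal(self):
        # quick null calibration; the full 10k-trial check runs with the
        # acceptance suite
        rng = np.random.default_rng(7)
        n_trials, alpha = 2000, 0.05
        rejections = 0
        for _ in range(n_trials):
            a = 10 ** rng.normal(2.0, 0.5, 4)
            b = 10 ** rng.normal(2.0, 0.5, 4)
            if ci_ttest(a, b).pvalue < alpha:
                rejections += 1
        assert 0.03 < rejections / n_trials < 0.07


def flow(values, channel="DiBAC", positive=None):
    data = {channel: np.asarray(values, dtype=float)}
    if positive is not None:
        data["RFP"] = np.asarray(positive, dtype=float)
    else:
        data["RFP"] = np.full(len(values), 1000.0)
    return FlowSample(pd.DataFrame(data), "RFP", channel)


class TestGateThreshold:
    def test_constant_control(self):
        ctrl = flow(np.full(500, 5.0))
        assert gate_threshold(ctrl, GateSpec("control_quantile", 0.995)) == 5.0

    def test_fixed(self):
        assert gate_threshold(None, GateSpec("fixed", 1000.0)) == 1000.0

    def test_quantile_matches_sorted_array_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.lognormal(0.0, 1.0, 100_000)
        ctrl = flow(values)
        thr = gate_threshold(ctrl, GateSpec("control_quantile", 0.995))
        v = np.sort(values)
        h = (len(v) - 1) * 0.995
        lo = int(math.floor(h))
        expected = v[lo] + (v[lo + 1] - v[lo]) * (h - lo)
        assert thr == pytest.approx(expected, rel=1e-12)

    def test_mean_plus_k_sd(self):
        rng = np.random.default_rng(4)
        values = rng.normal(100.0, 10.0, 10_000)
        thr = gate_threshold(flow(values), GateSpec("mean_plus_k_sd", 3.0))
        assert thr == pytest.approx(np.mean(values) + 3 * np.std(values, ddof=1))

    def test_too_few_control_events(self):
        with pytest.raises(ValueError, match="at least 100"):
            gate_threshold(flow(np.ones(50)), GateSpec("control_quantile", 0.995))


class TestDepolarizedFraction:
    def test_planted_mixture_recovered(self):
        rng = np.random.default_rng(11)
        n = 20_000
        high = rng.random(n) < 0.30
        readout = np.where(
            high, rng.lognormal(7.6, 0.4, n), rng.lognormal(4.6, 0.4, n)
        )
        sample = flow(readout)
        frac = depolarized_fraction(
            sample, GateSpec("fixed", 0.0), GateSpec("fixed", 600.0)
        )
        assert abs(frac - 0.30) <= 3 * math.sqrt(0.3 * 0.7 / n)

    def test_all_events_above_both_gates(self):
        sample = flow(np.full(25_000, 1e4))
        assert depolarized_fraction(
            sample, GateSpec("fixed", 0.0), GateSpec("fixed", 10.0)
        ) == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(12)
        readout = rng.lognormal(5.0, 1.0, 30_000)
        base = depolarized_fraction(
            flow(readout), GateSpec("fixed", 0.0), GateSpec("fixed", 150.0)
        )
        logged = depolarized_fraction(
            flow(np.log(readout)), GateSpec("fixed", -1.0), GateSpec("fixed", math.log(150.0))
        )
        assert logged == base

    def test_event_floor_enforced(self):
        sample = flow(np.ones(500))
        with pytest.raises(ValueError, match="at least 20000"):
            depolarized_fraction(
                sample, GateSpec("fixed", 0.0), GateSpec("fixed", 10.0)
            )
        # configurable floor
        assert depolarized_fraction(
            sample, GateSpec("fixed", 0.0), GateSpec("fixed", 10.0), min_events=100
        ) == 0.0


class TestExpression:
    def test_background_subtracted_fold(self):
        a = flow(np.full(1001, 460.0), channel="sYFP2")
        b = flow(np.full(1001, 110.0), channel="sYFP2")
        bg = flow(np.full(1001, 10.0), channel="sYFP2")
        va = relative_expression(a, bg)
        vb = relative_expression(b, bg)
        assert (va, vb) == (450.0, 100.0)
        assert fold_ratio(va, vb) == pytest.approx(4.5)

    def test_sample_equal_to_background_is_zero(self):
        s = flow(np.full(200, 35.0), channel="sYFP2")
        assert relative_expression(s, s) == 0.0

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError, match="not positive"):
            fold_ratio(10.0, 0.0)

    def test_median_recovered_from_lognormal_sample(self):
        rng = np.random.default_rng(13)
        mu = math.log(500.0)
        s = flow(rng.lognormal(mu, 0.4, 100_000), channel="sYFP2")
        bg = flow(np.zeros(1000), channel="sYFP2")
        assert relative_expression(s, bg) == pytest.approx(500.0, rel=0.01)
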