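import numpy as np
import pytest

from hrvb import datasets, pacing, simulate
from hrvb.errors import (
    BoundaryWarning,
    DegenerateSweepWarning,
    SeriesQualityError,
    TrialExclusionWarning,
)
from hrvb.rf import (
    STEPPED_GRID,
    FrequencyTrial,
    METRICS,
    evaluate_trials,
    hybrid_rf,
    rank_trials,
    sliding_assess,
    stepped_and_ranked,
    time_domain_only_rf,
    trials_from_metric_values,
)
from hrvb.signals import RRSeries


def make_trials(amp, lf, plv):
    """Trials from three {freq: value} dicts."""
    return trials_from_metric_values({"mean_amp": amp, "lf_ratio": lf, "plv": plv})


def sweep_rr(freqs, amps, rr0=900.0):
    """Synthesise a sweep RR series: one sinusoidal breath per (freq, amp)."""
    dt = 0.25
    t_parts, rr_parts, starts, t0 = [], [], [0.0], 0.0
    for f, a in zip(freqs, amps):
        dur = 60.0 / f
        tt = np.arange(0.0, dur, dt)
        t_parts.append(t0 + tt)
        rr_parts.append(rr0 + a * np.sin(2 * np.pi * tt / dur + np.pi))
        t0 += dur
        starts.append(t0)
    t = np.concatenate(t_parts)
    rr_of_t = np.concatenate(rr_parts)
    tb, beats = 0.0, [0.0]
    while tb < t0:
        tb += float(np.interp(tb, t, rr_of_t)) / 1000.0
        beats.append(tb)
    return RRSeries.from_beat_times(beats), np.asarray(starts)


class TestSteppedAndRanked:
    def test_worked_example(self):
        trials = datasets.trials_for_worked_example()
        d = stepped_and_ranked(trials)
        assert d.rf == 4.5
        assert d.candidates == frozenset({4.5, 5.0})
        assert d.rule_used == "amplitude_tiebreak"

    def test_dominant_candidate(self):
        amp = {4.5: 1.0, 5.0: 9.0, 5.5: 2.0, 6.0: 3.0}
        lf = {4.5: 0.2, 5.0: 0.9, 5.5: 0.3, 6.0: 0.1}
        plv = {4.5: 0.4, 5.0: 0.8, 5.5: 0.1, 6.0: 0.2}
        d = stepped_and_ranked(make_trials(amp, lf, plv))
        assert d.rf == 5.0
        assert d.rule_used in ("intersection_unique", "amplitude_tiebreak")

    def test_fallback_matches_brute_force(self):
        # disjoint top-3 sets by construction over 9 frequencies
        freqs = [4.5 + 0.5 * k for k in range(9)]
        amp = {f: v for f, v in zip(freqs, [9, 8, 7, 1, 2, 3, 4, 5, 6])}
        lf = {f: v for f, v in zip(freqs, [1, 2, 3, 9, 8, 7, 4, 5, 6])}
        plv = {f: v for f, v in zip(freqs, [4, 5, 6, 1, 2, 3, 9, 8, 7])}
        trials = make_trials(amp, lf, plv)
        d = stepped_and_ranked(trials)
        assert d.rule_used == "fallback_ranksum"

        # independent oracle: exhaustive rank-sum with literal competition ranks
        def comp_rank(vals, f):
            return 1 + sum(v > vals[f] for v in vals.values())

        sums = {
            f: comp_rank(amp, f) + comp_rank(lf, f) + comp_rank(plv, f) for f in freqs
        }
        best = min(sums.values())
        winners = [f for f, s in sums.items() if s == best]
        expected = max(winners, key=lambda f: amp[f]) if len(winners) > 1 else winners[0]
        assert d.rf == expected

    @pytest.mark.parametrize(
        "transform", [lambda x: 3 * x + 1, np.exp, lambda x: x**3]
    )
    @pytest.mark.parametrize("metric", METRICS)
    def test_monotone_transform_invariance(self, transform, metric):
        amp = {4.5: 1.0, 5.0: 4.0, 5.5: 2.0, 6.0: 3.0, 6.5: 5.0}
        lf = {4.5: 0.5, 5.0: 0.8, 5.5: 0.6, 6.0: 0.2, 6.5: 0.7}
        plv = {4.5: 0.3, 5.0: 0.9, 5.5: 0.8, 6.0: 0.4, 6.5: 0.5}
        values = {"mean_amp": amp, "lf_ratio": lf, "plv": plv}
        base = stepped_and_ranked(make_trials(**{
            "amp": amp, "lf": lf, "plv": plv
        }))
        mutated = {m: dict(v) for m, v in values.items()}
        mutated[metric] = {f: float(transform(v)) for f, v in mutated[metric].items()}
        after = stepped_and_ranked(trials_from_metric_values(mutated))
        assert after.evidence.ranks == base.evidence.ranks
        # the decision itself may only change if amplitude was transformed
        # (the tie-break compares raw amplitudes), but ranks never do
        if metric != "mean_amp":
            assert after.rf == base.rf

    def test_too_few_trials(self):
        with pytest.raises(SeriesQualityError):
            stepped_and_ranked(make_trials({4.5: 1}, {4.5: 1}, {4.5: 1}))

    def test_majority_tiebreak_switch(self):
        # 5.0 leads two metrics, 4.5 has the larger amplitude
        amp = {4.5: 9.0, 5.0: 8.0, 5.5: 2.0, 6.0: 1.0}
        lf = {4.5: 0.5, 5.0: 0.9, 5.5: 0.4, 6.0: 0.1}
        plv = {4.5: 0.6, 5.0: 0.9, 5.5: 0.2, 6.0: 0.1}
        trials = make_trials(amp, lf, plv)
        assert stepped_and_ranked(trials, tiebreak="amplitude").rf == 4.5
        assert stepped_and_ranked(trials, tiebreak="majority").rf == 5.0

    def test_rank_table_orderings_are_permutations(self):
        trials = datasets.trials_for_worked_example()
        table = rank_trials(trials)
        freqs = sorted(t.freq for t in trials)
        for m in METRICS:
            assert sorted(table.ordering(m)) == freqs


class TestTimeDomainOnly:
    def test_recovers_simulated_rf(self, stepped_session_factory):
        profile = simulate.SubjectProfile(rf_true=5.5, zeta=0.12)
        _, session = stepped_session_factory(profile)
        trials = evaluate_trials(session)
        assert time_domain_only_rf(trials).rf == 5.5

    def test_tie_goes_to_lower_frequency(self):
        amp = {5.0: 7.0, 5.5: 7.0, 6.0: 3.0}
        lf = {5.0: 0.5, 5.5: 0.6, 6.0: 0.4}
        plv = {5.0: 0.5, 5.5: 0.6, 6.0: 0.4}
        assert time_domain_only_rf(make_trials(amp, lf, plv)).rf == 5.0

    def test_single_trial(self):
        t = FrequencyTrial(6.0, None, 5.0, 0.5, 0.5)
        assert time_domain_only_rf([t]).rf == 6.0


class TestEvaluateTrials:
    def test_simulated_session_gives_eight_trials(self, stepped_session_factory):
        profile = simulate.SubjectProfile(rf_true=5.0, zeta=0.12)
        _, session = stepped_session_factory(profile)
        trials = evaluate_trials(session)
        assert len(trials) == 8
        for t in trials:
            assert np.isfinite(t.mean_amp) and np.isfinite(t.lf_ratio)
            assert 0.0 <= t.plv <= 1.0

    def test_short_segment_excluded_with_warning(self, stepped_session_factory):
        profile = simulate.SubjectProfile(rf_true=5.0, zeta=0.12)
        _, session = stepped_session_factory(profile)
        freq, seg = session[3]
        session[3] = (freq, seg.slice_time(seg.beat_times[0], seg.beat_times[0] + 30))
        with pytest.warns(TrialExclusionWarning):
            trials = evaluate_trials(session)
        assert len(trials) == 7

    def test_duplicate_frequency_is_error(self, stepped_session_factory):
        profile = simulate.SubjectProfile(rf_true=5.0, zeta=0.12)
        _, session = stepped_session_factory(profile)
        session[1] = (session[0][0], session[1][1])
        with pytest.raises(ValueError, match="duplicate"):
            evaluate_trials(session)

    def test_too_few_frequencies(self, stepped_session_factory):
        profile = simulate.SubjectProfile(rf_true=5.0, zeta=0.12)
        _, session = stepped_session_factory(profile)
        with pytest.raises(ValueError):
            evaluate_trials(session[:2])


class TestSliding:
    def test_simulated_sweep_recovers_rf(self):
        profile = simulate.SubjectProfile(rf_true=5.0, zeta=0.12)
        proto = pacing.build_sliding_protocol(8.0, 4.5, 200.0)
        sess = simulate.simulate_session(profile, proto)
        starts = pacing.breath_starts(sess.trace)
        freqs = 60.0 / np.diff(starts)
        res = sliding_assess(
            sess.rr, freqs, breath_starts=starts + sess.rr.beat_times[0]
        )
        assert 4.75 <= res.rf <= 5.25

    def test_monotone_amplitude_returns_endpoint_with_warning(self):
        freqs = np.linspace(8.0, 4.5, 15)
        amps = 2.0 ** np.arange(15)  # geometric growth to the sweep end
        rr, starts = sweep_rr(freqs, 10 + 60 * amps / amps.max())
        with pytest.warns(BoundaryWarning):
            res = sliding_assess(rr, freqs, breath_starts=starts)
        assert res.rf == pytest.approx(4.5, abs=0.01)
        assert res.at_boundary

    def test_degenerate_sweep_returns_lowest_frequency(self):
        freqs = np.linspace(8.0, 4.5, 12)
        rr, starts = sweep_rr(freqs, np.zeros(12))  # constant intervals
        with pytest.warns(DegenerateSweepWarning):
            res = sliding_assess(rr, freqs, breath_starts=starts)
        assert res.rf == pytest.approx(4.5, abs=0.01)

    def test_sweep_too_short_is_error(self):
        freqs = np.linspace(8.0, 4.5, 5)
        rr, starts = sweep_rr(freqs, np.full(5, 40.0))
        with pytest.raises(SeriesQualityError):
            sliding_assess(rr, freqs, breath_starts=starts)

    def test_sweep_too_narrow_is_error(self):
        freqs = np.linspace(6.0, 5.5, 12)
        rr, starts = sweep_rr(freqs, np.full(12, 40.0))
        with pytest.raises(SeriesQualityError):
            sliding_assess(rr, freqs, breath_starts=starts)

    def test_result_always_inside_swept_range(self, rng):
        freqs = np.linspace(7.5, 5.0, 14)
        for _ in range(5):
            amps = rng.uniform(10, 60, size=14)
            rr, starts = sweep_rr(freqs, amps)
            res = sliding_assess(rr, freqs, breath_starts=starts)
            assert 5.0 <= res.rf <= 7.5

    def test_two_decimal_resolution(self):
        freqs = np.linspace(8.0, 4.5, 20)
        rng = np.random.default_rng(0)
        rr, starts = sweep_rr(freqs, 30 + 10 * rng.standard_normal(20))
        res = sliding_assess(rr, freqs, breath_starts=starts)
        assert res.rf == round(res.rf, 2)


class TestHybrid:
    def test_range_is_half_bpm_around_stepped(self):
        seen = {}

        def sweep_fn_full(lo, hi):
            seen["range"] = (lo, hi)
            freqs = np.linspace(hi, lo, 15)
            rr, starts = sweep_rr(freqs, np.linspace(20, 40, 15))
            return rr, freqs, starts

        from hrvb.rf import RFDecision

        d = RFDecision(4.5, frozenset({4.5}), "intersection_unique", None)
        rf_val = hybrid_rf(d, sweep_fn_full)
        assert seen["range"] == (4.0, 5.0)
        assert 4.0 <= rf_val <= 5.0

    def test_simulated_fine_tuning(self):
        def sweep_fn(lo, hi):
            proto = pacing.build_sliding_protocol(hi, lo, 240.0)
            sess = simulate.simulate_session(
                simulate.SubjectProfile(rf_true=4.8, zeta=0.12, seed=2), proto
            )
            starts = pacing.breath_starts(sess.trace)
            return sess.rr, 60.0 / np.diff(starts), starts + sess.rr.beat_times[0]

        from hrvb.rf import RFDecision

        d = RFDecision(5.0, frozenset({5.0}), "intersection_unique", None)
        rf_val = hybrid_rf(d, sweep_fn)
        assert 4.55 <= rf_val <= 5.05

    def test_out_of_range_result_clamped(self):
        def sweep_fn(lo, hi):
            # annotation extends past the requested range; maximum outside it
            freqs = np.linspace(hi + 1.0, lo - 1.0, 15)
            amps = np.where(freqs > hi, 60.0, 20.0)
            rr, starts = sweep_rr(freqs, amps)
            return rr, freqs, starts

        from hrvb.rf import RFDecision

        d = RFDecision(5.5, frozenset({5.5}), "intersection_unique", None)
        with pytest.warns(BoundaryWarning):
            rf_val = hybrid_rf(d, sweep_fn)
        assert 5.0 <= rf_val <= 6.0


class TestParameterRecovery:
    @pytest.mark.parametrize("zeta", [0.08, 0.12])
    def test_zero_noise_on_grid_recovery(self, zeta, stepped_session_factory):
        for rf_true in (4.5, 5.0, 5.5, 6.0, 6.5):
            profile = simulate.SubjectProfile(rf_true=rf_true, zeta=zeta)
            _, session = stepped_session_factory(profile)
            d = stepped_and_ranked(evaluate_trials(session))
            assert d.rf == rf_true, f"rf_true={rf_true}, zeta={zeta} -> {d.rf}"

    def test_zero_noise_off_grid_brackets_truth(self, stepped_session_factory):
        for rf_true in (4.7, 5.3, 5.8, 6.2):
            profile = simulate.SubjectProfile(rf_true=rf_true, zeta=0.12)
            _, session = stepped_session_factory(profile)
            d = stepped_and_ranked(evaluate_trials(session))
            below = max(f for f in STEPPED_GRID if f <= rf_true)
            above = min(f for f in STEPPED_GRID if f >= rf_true)
            assert d.rf in (below, above)

    def test_noisy_recovery_small_batch(self, stepped_session_factory):
        # the full 50-replicate >=90% criterion lives in test_acceptance
        rng = np.random.default_rng(99)
        hits = 0
        for _ in range(10):
            rf_true = float(rng.uniform(4.5, 6.5))
            profile = simulate.SubjectProfile(
                rf_true=rf_true,
                zeta=float(rng.uniform(0.08, 0.15)),
                sigma_rr=10.0,
                a_lf=15.0,
                phase_jitter=0.2,
                seed=int(rng.integers(2**31)),
            )
            _, session = stepped_session_factory(profile)
            d = stepped_and_ranked(evaluate_trials(session))
            hits += abs(d.rf - rf_true) <= 0.5
        assert hits >= 8
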