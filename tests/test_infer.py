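import numpy as np
import pytest

from strandex.fret import compute_fret
from strandex.infer import (
    EventCall,
    EventThresholds,
    detect_events,
    fit_bimolecular,
    fit_exponential_decay,
    fit_first_passage,
    fit_spot_decay,
    hetero_exchange_analysis,
    measure_dwell_times,
    synchronize_traces,
    SpotCountSeries,
)
from strandex.kinetics import ExperimentCondition, TransferRates, analytic_occupancy, build_transfer_scheme
from strandex.optics import GREEN, ExcitationPattern, OpticsModel
from strandex.presets import get_preset
from strandex.synth import MoleculeTrace, synthesize_ensemble


class TestExponentialDecay:
    def test_noiseless_recovery(self):
        t = np.arange(0.0, 601.0, 30.0)
        fit = fit_exponential_decay(t, np.exp(-0.01 * t))
        assert fit.k_obs == pytest.approx(0.01, abs=1e-6)
        assert not fit.degenerate

    def test_constant_input_degenerate(self):
        t = np.linspace(0, 100, 11)
        fit = fit_exponential_decay(t, np.ones_like(t), with_plateau=True)
        assert fit.degenerate

    def test_plateau_recovery(self):
        t = np.linspace(0, 120, 25)
        v = 0.4 + 0.6 * np.exp(-0.05 * t)
        fit = fit_exponential_decay(t, v, with_plateau=True)
        assert fit.amplitude == pytest.approx(0.6, abs=1e-6)
        assert fit.k_obs == pytest.approx(0.05, abs=1e-6)
        assert fit.plateau == pytest.approx(0.4, abs=1e-6)

    def test_fraction_range_check(self):
        t = np.linspace(0, 10, 6)
        with pytest.raises(ValueError):
            fit_exponential_decay(t, [2.0, 1.0, 0.5, 0.2, 0.1, 0.0], expect_fraction=True)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_exponential_decay([0, 1, 2], [1.0, 0.5, 0.2])

    def test_recovers_kobs_from_analytic_occupancy_curve(self):
        # fast ternary equilibration: bound occupancy ~ single exponential
        r = TransferRates(1e6, 1e-9, 9.0, 1.0)  # k_obs = 1e-4, k_on*c = 1e-3 << 10
        s = build_transfer_scheme(r, 0.8, 0.2)
        t = np.linspace(0.0, 3e4, 40)
        occ = np.array([analytic_occupancy(s, ti)[0] for ti in t])
        fit = fit_exponential_decay(t, occ)
        from strandex.kinetics import effective_kobs

        assert fit.k_obs == pytest.approx(effective_kobs(r).kobs, rel=1e-4)


class TestBimolecular:
    def test_exact_line_through_origin(self):
        concs = np.array([10, 30, 50, 75, 100]) * 1e-9
        pts = [(c, 6.1e4 * c, 0.0) for c in concs]
        fit = fit_bimolecular(pts)
        assert fit.slope == pytest.approx(6.1e4, rel=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_flat_points_zero_slope(self):
        pts = [(c, 5e-3, 1e-4) for c in (1e-8, 2e-8, 3e-8)]
        assert fit_bimolecular(pts).slope == pytest.approx(0.0, abs=1e-9)

    def test_known_intercept_recovered(self):
        concs = np.array([1, 2, 4, 8]) * 1e-8
        pts = [(c, 1e-3 + 5e4 * c, 1e-5) for c in concs]
        fit = fit_bimolecular(pts)
        assert fit.intercept == pytest.approx(1e-3, rel=1e-6)
        assert fit.slope == pytest.approx(5e4, rel=1e-6)

    def test_needs_three_distinct_concentrations(self):
        with pytest.raises(ValueError):
            fit_bimolecular([(1e-8, 1e-3, 0), (1e-8, 1.1e-3, 0), (2e-8, 2e-3, 0)])


class TestCensoredFirstPassage:
    def test_censoring_regression(self):
        # horizon = 1/k: naive fit errs >25%, censored estimators within 10%
        rng = np.random.default_rng(0)
        k = 0.01
        true_t = rng.exponential(1.0 / k, 3000)
        horizon = 1.0 / k
        observed = true_t < horizon
        durations = np.minimum(true_t, horizon)
        naive_k = 1.0 / true_t[observed].mean()
        assert abs(naive_k - k) / k > 0.25
        fit = fit_first_passage(durations, observed)
        assert abs(fit.k_mle - k) / k < 0.10
        assert abs(fit.k_km - k) / k < 0.10

    def test_uncensored_agrees_with_mean(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10.0, 5000)
        fit = fit_first_passage(t, np.ones_like(t, bool))
        assert fit.k_mle == pytest.approx(1.0 / t.mean(), rel=1e-9)
        assert fit.k_km == pytest.approx(0.1, rel=0.05)
        assert fit.n_censored == 0

    def test_needs_an_event(self):
        with pytest.raises(ValueError):
            fit_first_passage([1.0, 2.0], [False, False])


def _planted_trace(
    n_frames=400, rise_at=100, settle_at=106, baseline=1200.0, boost=1000.0,
    bound_e=0.8, free_e=0.3, frame_time=0.05, noise=None, seed=0,
):
    """Deterministic labeled-competitor trace with one transfer event."""
    total = np.full(n_frames, baseline)
    total[rise_at:settle_at] += boost
    e = np.full(n_frames, bound_e)
    e[settle_at:] = free_e
    i_a = e * total  # boost feeds both channels; E stays at the state level
    i_d = total - i_a
    if noise:
        rng = np.random.default_rng(seed)
        i_d = np.clip(i_d + rng.normal(0, noise, n_frames), 0, None)
        i_a = np.clip(i_a + rng.normal(0, noise, n_frames), 0, None)
    return MoleculeTrace(
        frame_time * np.arange(n_frames), np.full(n_frames, GREEN, dtype=object),
        i_d, i_a, frame_time, molecule_id=7, meta={"flow_start": 0.0},
    )


class TestDetectEvents:
    def test_planted_event_exact_dwell(self):
        # rise at frame 100, E settles at frame 106 -> dwell = 6 * 0.05 = 0.30 s
        tr = _planted_trace()
        s = compute_fret(tr, 0.0)
        events = detect_events(tr, s, EventThresholds())
        assert len(events) == 1
        ev = events[0]
        assert ev.dwell == pytest.approx(0.30, abs=1e-9)
        assert ev.t_bind == pytest.approx(100 * 0.05, abs=1e-9)
        assert ev.n_failed_attempts == 0

    def test_failed_attempts_counted(self):
        tr = _planted_trace()
        tr.I_D[40:42] += 1000.0  # two isolated pre-binding spikes
        tr.I_D[60:61] += 1000.0
        s = compute_fret(tr, 0.0)
        events = detect_events(tr, s, EventThresholds())
        assert len(events) == 1
        assert events[0].n_failed_attempts == 2

    def test_quiet_trace_no_events(self):
        tr = _planted_trace(rise_at=0, settle_at=0)  # no rise, never settles at free
        tr.I_D[:] = 400.0
        tr.I_A[:] = 800.0
        s = compute_fret(tr, 0.0)
        assert detect_events(tr, s, EventThresholds(free_E=0.3)) == []

    def test_event_call_invariant(self):
        with pytest.raises(ValueError):
            EventCall(0, t_bind=2.0, t_transfer=1.0, n_failed_attempts=0)

    def test_too_short_trace_errors(self):
        tr = _planted_trace(n_frames=6, rise_at=2, settle_at=4)
        s = compute_fret(tr, 0.0)
        with pytest.raises(ValueError):
            detect_events(tr, s, EventThresholds())

    def test_attempt_recovery_on_simulated_ensemble(self):
        # geometric attempts with mean 10 at the 100 ms attempt-duration preset
        r = TransferRates(9.8e5, 5e-8, k_fail=9.0, k_succ=1.0)
        sch = build_transfer_scheme(
            r, 0.8, 0.3, labeled_competitor=True,
            resolution_substeps=4, substep_rate=15.0,
        )
        optics = OpticsModel()
        pat = ExcitationPattern(mode="continuous_green")
        cond = ExperimentCondition(
            "transfer", competitor_conc=5e-8, flow_start=10.0, n_molecules=150, seed=21
        )
        traces = synthesize_ensemble(
            cond, sch, optics, pat, horizon=2000.0, max_trace_duration=20.0
        )
        i_t1 = sch.index("ternary_1")
        detected, truth = [], []
        for tr in traces:
            s = compute_fret(tr, optics.leakage, total_intensity=optics.total_intensity)
            evs = detect_events(tr, s)
            if evs:
                detected.append(evs[0].n_failed_attempts)
                truth.append(int((tr.truth.states == i_t1).sum()) - 1)
        assert len(detected) > 100
        # detection fidelity: recovered mean attempts within 10% of this
        # ensemble's true mean
        assert np.mean(detected) == pytest.approx(np.mean(truth), rel=0.10)
        # and the generator obeys the geometric law (mean (kf+ks)/ks = 10
        # visits, i.e. 9 failures) within 3 sigma
        sd = np.sqrt(10 * 9) / np.sqrt(len(truth))
        assert np.mean(truth) == pytest.approx(9.0, abs=3 * sd)


class TestDwellTimes:
    def test_identical_dwells_binning_limited(self):
        events = [EventCall(i, 0.0, 0.30, 0) for i in range(50)]
        d = measure_dwell_times(events)
        assert d.fit_available
        assert d.gaussian_mean == pytest.approx(0.30)
        assert d.gaussian_sd <= 0.05

    def test_few_events_flagged(self):
        events = [EventCall(i, 0.0, 0.2 + 0.01 * i, 0) for i in range(5)]
        d = measure_dwell_times(events)
        assert not d.fit_available
        assert d.deltas.size == 5
        assert d.sample_mean == pytest.approx(np.mean([e.dwell for e in events]))

    def test_gaussian_recovery_on_peaked_sample(self):
        rng = np.random.default_rng(3)
        deltas = rng.normal(0.31, 0.08, 400).clip(0.01)
        events = [EventCall(i, 0.0, d, 0) for i, d in enumerate(deltas)]
        d = measure_dwell_times(events)
        assert d.fit_available
        assert d.gaussian_mean == pytest.approx(0.31, abs=0.02)


class TestSynchronize:
    def test_identical_traces_average_equals_single(self):
        traces = [_planted_trace() for _ in range(4)]
        for i, tr in enumerate(traces):
            tr.molecule_id = i
        events = [EventCall(i, 100 * 0.05, 106 * 0.05, 0) for i in range(4)]
        avg = synchronize_traces(traces, events, window=(-1.0, 1.0))
        i0 = np.argmin(np.abs(avg.offsets))
        single = traces[0]
        ref = single.I_D[100] + single.I_A[100]
        assert avg.mean_total[i0] == pytest.approx(ref)

    def test_alignment_index_definition(self):
        traces = [_planted_trace(noise=20.0, seed=s) for s in range(6)]
        for i, tr in enumerate(traces):
            tr.molecule_id = i
        events = [EventCall(i, 100 * 0.05, 106 * 0.05, 0) for i in range(6)]
        avg = synchronize_traces(traces, events, window=(-0.5, 0.5))
        i0 = np.argmin(np.abs(avg.offsets))
        manual = np.mean([tr.I_A[100] for tr in traces])
        assert avg.mean_I_A[i0] == pytest.approx(manual)

    def test_ternary_boost_visible_in_average(self):
        traces = [_planted_trace(noise=30.0, seed=s) for s in range(30)]
        for i, tr in enumerate(traces):
            tr.molecule_id = i
        events = [EventCall(i, 100 * 0.05, 106 * 0.05, 0) for i in range(30)]
        avg = synchronize_traces(traces, events, window=(-1.0, 1.0))
        pre = avg.mean_total[avg.offsets < -0.1].mean()
        during = avg.mean_total[(avg.offsets >= 0) & (avg.offsets < 0.25)].mean()
        after = avg.mean_total[avg.offsets > 0.5].mean()
        assert during > pre + 500
        assert after < during - 500

    def test_empty_events_rejected(self):
        with pytest.raises(ValueError):
            synchronize_traces([_planted_trace()], [])


class TestSpotDecay:
    def test_noiseless_fraction_90(self):
        t = np.linspace(0, 1000, 12)
        n = 30 + 270 * np.exp(-0.005 * t)
        res = fit_spot_decay(SpotCountSeries(t, np.round(n), 300))
        assert res.exchange_fraction == pytest.approx(0.90, abs=0.01)
        assert res.decay.k_obs == pytest.approx(0.005, rel=0.01)

    def test_noiseless_fraction_60(self):
        t = np.linspace(0, 1000, 12)
        n = 120 + 180 * np.exp(-0.005 * t)
        res = fit_spot_decay(SpotCountSeries(t, np.round(n), 300))
        assert res.exchange_fraction == pytest.approx(0.60, abs=0.01)

    def test_constant_counts_degenerate(self):
        t = np.linspace(0, 1000, 10)
        res = fit_spot_decay(SpotCountSeries(t, np.full(10, 300), 300))
        assert res.decay.degenerate

    def test_increasing_counts_flagged(self):
        t = np.linspace(0, 1000, 10)
        res = fit_spot_decay(SpotCountSeries(t, np.linspace(100, 300, 10).astype(int), 100))
        assert res.increasing_flagged


class TestHeteroExchange:
    def _traces(self, preset_name, n, seed, horizon=200.0):
        preset = get_preset(preset_name)
        sch = preset.scheme()
        optics = OpticsModel(flow_background_step=0.0)
        pat = ExcitationPattern(mode="continuous_green")
        cond = ExperimentCondition(
            "hetero_exchange", flow_start=preset.flow_start, n_molecules=n, seed=seed
        )
        return preset, synthesize_ensemble(cond, sch, optics, pat, horizon=horizon)

    def test_one_step_rate_recovery(self):
        preset, traces = self._traces("hetero_ssb_to_rpa_dT40", 400, 31, horizon=150.0)
        res = hetero_exchange_analysis(
            traces, preset.flow_start, final_E=preset.fret_ladder[-1], leakage=0.08
        )
        assert res.first_passage.k_mle == pytest.approx(0.08, rel=0.12)

    def test_two_step_classification_and_mean(self):
        preset, traces = self._traces("hetero_ssb_to_rpa_dT70", 300, 32, horizon=400.0)
        res = hetero_exchange_analysis(
            traces, preset.flow_start, final_E=preset.fret_ladder[-1],
            intermediate_E=preset.fret_ladder[1], leakage=0.08,
        )
        # Erlang(2, 0.05): mean completion 2/0.05 = 40 s
        completed = np.concatenate([res.completion_times, res.censored_times])
        assert res.completion_times.mean() == pytest.approx(40.0, rel=0.15)
        assert res.two_step_fraction >= 0.90

    def test_flow_after_horizon_all_censored(self):
        preset, traces = self._traces("hetero_ssb_to_rpa_dT40", 10, 33, horizon=9.0)
        res = hetero_exchange_analysis(
            traces, flow_start=9.0, final_E=preset.fret_ladder[-1], leakage=0.08
        )
        assert res.completion_times.size == 0
        assert res.first_passage is None
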