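import numpy as np
import pytest

from ercflow.mvar import MVARModel, UnstableModelError
from ercflow.preprocess import Channel
from ercflow.synthetic import (
    STG_BURST_WINDOW,
    ActivationEvent,
    BehaviorParams,
    CouplingEvent,
    EpochCollisionError,
    NetworkSpec,
    build_default_cohort,
    default_session_network,
    independent_network,
    mvar_generate,
    sample_behavior,
    simulate_session,
)


class TestCouplingEvent:
    def test_valid(self):
        c = CouplingEvent("a", "b", 0.5, 1, (-0.45, -0.40), "word")
        assert c.window == (-0.45, -0.40)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(source="a", target="a", gain=0.5, lag=1, window=(-1, 0)),
            dict(source="a", target="b", gain=0.5, lag=0, window=(-1, 0)),
            dict(source="a", target="b", gain=0.5, lag=1, window=(0, 0)),
            dict(source="a", target="b", gain=np.inf, lag=1, window=(-1, 0)),
            dict(source="a", target="b", gain=0.5, lag=1, window=(-1, 0), condition="x"),
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            CouplingEvent(**kwargs)


class TestNetworkSpec:
    def test_unstable_coupling_loop_rejected(self):
        # a reciprocal high-gain loop on near-unit-radius carriers is unstable
        net = independent_network([("a", "STN"), ("b", "STG")], r=0.97)
        with pytest.raises(UnstableModelError, match="radius"):
            NetworkSpec(
                channels=net.channels,
                base_model=net.base_model,
                couplings=(
                    CouplingEvent("b", "a", 0.9, 1, (-0.2, 0.0)),
                    CouplingEvent("a", "b", 0.9, 1, (-0.2, 0.0)),
                ),
            )

    def test_condition_exclusive_couplings_not_summed(self):
        # each gain alone is stable; their (never-realized) sum would not be
        net = independent_network([("a", "STN"), ("b", "STG")], r=0.9)
        couplings = tuple(
            CouplingEvent("b", "a", 0.9, 1, (-0.2, 0.0), cond)
            for cond in ("word", "pseudoword")
        )
        NetworkSpec(channels=net.channels, base_model=net.base_model, couplings=couplings)

    def test_unknown_channel_rejected(self):
        net = independent_network([("a", "STN"), ("b", "STG")])
        with pytest.raises(ValueError, match="unknown channel"):
            NetworkSpec(
                channels=net.channels,
                base_model=net.base_model,
                couplings=(CouplingEvent("zz", "a", 0.1, 1, (-0.2, 0.0)),),
            )


class TestMvarGenerate:
    def test_zero_coefficients_returns_noise_exactly(self):
        model = MVARModel(np.zeros((1, 2, 2)), np.eye(2))
        x = mvar_generate(model, 500, seed=0, burn_in=100)
        rng = np.random.default_rng(0)
        e = rng.standard_normal((600, 2)) @ np.linalg.cholesky(
            np.eye(2) + 1e-15 * np.eye(2)
        ).T
        assert np.array_equal(x, e[100:].T)

    def test_ar1_stationary_variance(self):
        model = MVARModel(np.array([[[0.9]]]), np.eye(1))
        x = mvar_generate(model, 100_000, seed=1)
        expected = 1.0 / (1.0 - 0.81)
        assert abs(x.var() - expected) / expected < 0.10

    def test_lagged_cross_correlation_direction(self):
        coeffs = np.zeros((1, 2, 2))
        coeffs[0] = [[0.3, 0.0], [0.5, 0.3]]  # 1 -> 2 at lag 1
        model = MVARModel(coeffs, np.eye(2))
        x = mvar_generate(model, 50_000, seed=2)
        fwd = np.corrcoef(x[0, :-1], x[1, 1:])[0, 1]
        rev = np.corrcoef(x[1, :-1], x[0, 1:])[0, 1]
        assert fwd > rev

    def test_unstable_model_rejected_with_radius(self):
        model = MVARModel(np.array([[[1.01]]]), np.eye(1))
        with pytest.raises(UnstableModelError, match="radius"):
            mvar_generate(model, 100, seed=0)

    def test_seed_determinism(self):
        model = MVARModel(np.array([[[0.5]]]), np.eye(1))
        assert np.array_equal(
            mvar_generate(model, 1000, seed=7), mvar_generate(model, 1000, seed=7)
        )


class TestSampleBehavior:
    def test_default_latency_means(self):
        p = BehaviorParams()
        assert p.latency_mean == {"word": 0.736, "pseudoword": 0.818}

    def test_alternation_and_counts(self):
        trials = sample_behavior(BehaviorParams(), 60, seed=0)
        conds = [t.condition for t in trials]
        assert conds == ["word", "pseudoword"] * 30
        assert conds.count("word") == 30

    def test_zero_variance_gives_means_exactly(self):
        p = BehaviorParams(
            latency_sd={"word": 0.0, "pseudoword": 0.0},
            c1_sd={"word": 0.0, "pseudoword": 0.0},
            v_sd={"word": 0.0, "pseudoword": 0.0},
            c2_sd={"word": 0.0, "pseudoword": 0.0},
        )
        trials = sample_behavior(p, 10, seed=3)
        for t in trials:
            assert t.latency_s == pytest.approx(p.latency_mean[t.condition])
            assert t.c1_dur_s == pytest.approx(p.c1_mean[t.condition])

    def test_odd_trial_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            sample_behavior(BehaviorParams(), 7, seed=0)

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            BehaviorParams(latency_mean={"word": -0.1, "pseudoword": 0.8})

    def test_event_ordering_invariant(self):
        for t in sample_behavior(BehaviorParams(), 20, seed=5):
            assert t.cue_onset_s < t.stimulus_onset_s < t.speech_onset_s


class TestSimulateSession:
    def test_event_table_schema_and_counts(self):
        net = independent_network([("a", "STN"), ("b", "STG")])
        sim = simulate_session(net, n_trials=10, seed=0)
        ev = sim.recording.events
        assert len(ev) == 10
        for col in ("cue_onset_s", "stimulus_onset_s", "speech_onset_s", "condition"):
            assert col in ev.columns
        assert sim.recording.duration_s > ev["speech_onset_s"].max() + 0.5

    def test_truth_coupling_window_preserved(self):
        net = default_session_network(0)
        sim = simulate_session(net, n_trials=4, seed=0)
        burst = [c for c in sim.truth.couplings if c.window == STG_BURST_WINDOW]
        assert burst and burst[0].source == "STG1" and burst[0].target == "STN1"

    def test_coupling_active_only_inside_window(self):
        """Lag-1 cross-correlation is elevated inside the window, not outside."""
        net = independent_network([("s", "STG"), ("t", "STN")], centers_hz=[100, 120])
        net = NetworkSpec(
            channels=net.channels,
            base_model=net.base_model,
            couplings=(CouplingEvent("s", "t", 0.5, 1, (-0.45, -0.40)),),
        )
        sim = simulate_session(net, n_trials=40, seed=1)
        rec = sim.recording
        fs = rec.sampling_rate

        def lag_corr(t0, t1):
            vals = []
            for tr in sim.trials:
                a = int(round((tr.speech_onset_s + t0) * fs))
                b = int(round((tr.speech_onset_s + t1) * fs))
                vals.append(
                    np.corrcoef(rec.signals[0, a - 1 : b - 1], rec.signals[1, a:b])[0, 1]
                )
            return np.mean(vals)

        assert lag_corr(-0.45, -0.40) > 0.2
        assert abs(lag_corr(-0.90, -0.60)) < 0.1

    def test_null_network_uncorrelated_channels(self):
        net = independent_network([("a", "STN"), ("b", "STG"), ("c", "PoCG")])
        sim = simulate_session(net, n_trials=10, seed=2)
        x = sim.recording.signals
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                c = np.corrcoef(x[i, :-1], x[j, 1:])[0, 1]
                assert abs(c) < 0.02

    def test_two_seeds_differ_same_schema(self):
        net = independent_network([("a", "STN"), ("b", "STG")])
        s1 = simulate_session(net, n_trials=6, seed=1)
        s2 = simulate_session(net, n_trials=6, seed=2)
        assert not np.array_equal(s1.recording.signals, s2.recording.signals)
        assert len(s1.trials) == len(s2.trials) == 6
        assert list(s1.recording.events.columns) == list(s2.recording.events.columns)

    def test_seed_determinism_bit_identical(self):
        net = independent_network([("a", "STN"), ("b", "STG")])
        s1 = simulate_session(net, n_trials=6, seed=9)
        s2 = simulate_session(net, n_trials=6, seed=9)
        assert np.array_equal(s1.recording.signals, s2.recording.signals)
        assert s1.recording.events.equals(s2.recording.events)

    def test_epoch_collision_error_names_trials(self):
        net = independent_network([("a", "STN"), ("b", "STG")])
        params = BehaviorParams(intertrial_gap=-0.9)
        with pytest.raises(EpochCollisionError, match=r"\(0, 1\)"):
            simulate_session(net, params=params, n_trials=4, seed=0)


@pytest.fixture(scope="module")
def cohort():
    return build_default_cohort(seed=0, n_sessions=10, n_trials=4)


class TestDefaultCohort:
    def test_ten_sessions(self, cohort):
        assert len(cohort) == 10

    def test_three_stn_sites_per_session(self, cohort):
        for sim in cohort:
            stn = [c for c in sim.truth.channels if c.region == "STN"]
            assert len(stn) == 3

    def test_four_subjects(self, cohort):
        assert len({s.subject for s in cohort}) == 4

    def test_word_gain_exceeds_pseudoword_gain(self, cohort):
        for sim in cohort:
            wg = [c.gain for c in sim.truth.couplings if c.condition == "word"]
            pg = [c.gain for c in sim.truth.couplings if c.condition == "pseudoword"]
            assert wg and pg and min(wg) > max(pg)

    def test_stability_guard_on_emitted_models(self, cohort):
        for sim in cohort:
            assert sim.truth.base_model.spectral_radius() < 1.0
            sim.truth.require_stable()
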