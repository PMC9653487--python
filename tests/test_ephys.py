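"""Patch-clamp trace analysis: conductance, activation pressures,
sensitivity ratios."""

import numpy as np
import pytest

from mscgate.ephys import (
    Recording,
    amplitude_class_for,
    estimate_unitary_conductance,
    first_activation_pressure,
    tension_sensitivity_ratio,
)
from mscgate.errors import NoActivationError, NoEventsError
from mscgate.synthetic import (
    ChannelPopulation,
    RecordingSpec,
    simulate_patch_recording,
)

MSCK_G = 895.0  # pS
MSCL_G = 3650.0  # pS
V = -30.0  # mV
MSCK_STEP = MSCK_G * abs(V) / 1000.0  # 26.85 pA


def square_trace(
    levels, seg_len=2000, sample_rate=5000.0, noise_sd=0.0, seed=0, voltage=V
):
    """Recording whose current visits the given levels in order."""
    rng = np.random.default_rng(seed)
    current = np.concatenate([np.full(seg_len, lv) for lv in levels])
    if noise_sd > 0:
        current = current + rng.normal(0, noise_sd, len(current))
    n = len(current)
    t = np.arange(n) / sample_rate
    return Recording(
        time=t,
        current=current,
        pressure=-4.0 * t,
        voltage=voltage,
        sample_rate=sample_rate,
    )


class TestUnitaryConductance:
    def test_noiseless_two_level_trace(self):
        """Levels 0 and -26.85 pA at -30 mV give exactly 895 pS."""
        rec = square_trace([0, -MSCK_STEP, 0, -MSCK_STEP, 0])
        est = estimate_unitary_conductance(rec)
        assert est.g == pytest.approx(MSCK_G, abs=1.0)
        assert est.n_events >= 2

    def test_noisy_seeded_within_reported_band(self):
        """With 2 pA noise the estimate stays in the 895 +/- 25 pS band."""
        rec = square_trace([0, -MSCK_STEP] * 6 + [0], noise_sd=2.0, seed=4)
        est = estimate_unitary_conductance(rec)
        assert abs(est.g - MSCK_G) <= 25.0
        assert est.se > 0

    def test_stacked_openings_use_first_step(self):
        """With two channels open simultaneously (levels 0, -1x, -2x) the
        unitary estimate still comes from the first conductance step."""
        rec = square_trace(
            [0, -MSCK_STEP, -2 * MSCK_STEP, -MSCK_STEP, 0, -MSCK_STEP, 0],
            noise_sd=1.0,
            seed=2,
        )
        est = estimate_unitary_conductance(rec)
        assert est.g == pytest.approx(MSCK_G, rel=0.03)

    def test_invariant_under_offset_and_voltage_sign(self):
        rec0 = square_trace([0, -MSCK_STEP] * 4, noise_sd=1.5, seed=7)
        g0 = estimate_unitary_conductance(rec0).g
        shifted = Recording(
            time=rec0.time,
            current=rec0.current + 11.0,
            pressure=rec0.pressure,
            voltage=rec0.voltage,
            sample_rate=rec0.sample_rate,
        )
        assert estimate_unitary_conductance(shifted).g == pytest.approx(g0, abs=0.5)
        pos_v = Recording(
            time=rec0.time,
            current=-rec0.current,
            pressure=rec0.pressure,
            voltage=-rec0.voltage,
            sample_rate=rec0.sample_rate,
        )
        assert estimate_unitary_conductance(pos_v).g == pytest.approx(g0, abs=0.5)

    def test_flat_trace_raises_no_events(self):
        rec = square_trace([0, 0, 0], noise_sd=1.0, seed=1)
        with pytest.raises(NoEventsError):
            estimate_unitary_conductance(rec)

    def test_mean_recovery_over_seeds(self):
        """Simulated flickering patches at both reported conductances are
        recovered within 2% on average (10 seeds each)."""
        for g_true in (MSCK_G, MSCL_G):
            estimates = []
            for seed in range(10):
                spec = RecordingSpec(
                    duration=10.0,
                    pressure_mode="hold",
                    hold_pressure=40.0,
                    channels=(
                        ChannelPopulation(
                            conductance_ps=g_true,
                            activation_pressure=40.0,
                            gating="flicker",
                            flicker_rate=6.0,
                        ),
                    ),
                    seed=seed,
                )
                rec = simulate_patch_recording(spec)
                estimates.append(estimate_unitary_conductance(rec).g)
            assert np.mean(estimates) == pytest.approx(g_true, rel=0.02)

    def test_se_shrinks_with_more_events(self):
        def patch(duration, seed=0):
            return simulate_patch_recording(
                RecordingSpec(
                    duration=duration,
                    pressure_mode="hold",
                    hold_pressure=40.0,
                    channels=(
                        ChannelPopulation(
                            conductance_ps=MSCK_G,
                            activation_pressure=40.0,
                            gating="flicker",
                            flicker_rate=8.0,
                        ),
                    ),
                    seed=seed,
                )
            )

        short = estimate_unitary_conductance(patch(6.0))
        long = estimate_unitary_conductance(patch(60.0))
        assert long.n_events > short.n_events
        assert long.se < short.se


class TestFirstActivation:
    def test_event_inserted_at_40mmHg(self):
        spec = RecordingSpec(
            duration=20.0,
            channels=(ChannelPopulation(conductance_ps=MSCK_G, activation_pressure=40.0),),
            seed=3,
        )
        rec = simulate_patch_recording(spec)
        p = first_activation_pressure(rec, amplitude_class_for(MSCK_G, V))
        assert p == pytest.approx(40.0, abs=0.1)

    def test_event_at_trace_start(self):
        """A channel already open at the first sample reports the first
        sample's pressure."""
        n = 10000
        t = np.arange(n) / 5000.0
        current = np.where(t < 1.0, -MSCK_STEP, 0.0)
        current += np.random.default_rng(0).normal(0, 1.0, n)
        rec = Recording(
            time=t, current=current, pressure=-(10.0 + 4.0 * t), voltage=V,
            sample_rate=5000.0,
        )
        p = first_activation_pressure(rec, amplitude_class_for(MSCK_G, V))
        assert p == pytest.approx(10.0, abs=1e-9)

    def test_interleaved_classes_are_separated(self):
        """With MscK and MscL events interleaved on one ramp, class bands
        select the correct first event for each population."""
        spec = RecordingSpec(
            duration=30.0,
            channels=(
                ChannelPopulation(conductance_ps=MSCK_G, activation_pressure=40.0),
                ChannelPopulation(conductance_ps=MSCL_G, activation_pressure=100.0),
            ),
            seed=5,
        )
        rec = simulate_patch_recording(spec)
        p_k = first_activation_pressure(rec, amplitude_class_for(MSCK_G, V))
        p_l = first_activation_pressure(rec, amplitude_class_for(MSCL_G, V))
        assert p_k == pytest.approx(40.0, abs=0.1)
        assert p_l == pytest.approx(100.0, abs=0.1)

    def test_no_event_in_class_raises(self):
        spec = RecordingSpec(
            duration=10.0,
            channels=(ChannelPopulation(conductance_ps=MSCK_G, activation_pressure=200.0),),
            seed=1,
        )
        rec = simulate_patch_recording(spec)
        with pytest.raises(NoActivationError):
            first_activation_pressure(rec, amplitude_class_for(MSCK_G, V))

    def test_non_monotone_pressure_rejected(self):
        rec = square_trace([0, -MSCK_STEP])
        rec.pressure = np.sin(rec.time * 3.0) * 20.0
        with pytest.raises(NoActivationError):
            first_activation_pressure(rec, amplitude_class_for(MSCK_G, V))


class TestSensitivityRatio:
    def two_pop(self, p_test, p_cal, seed=0):
        return simulate_patch_recording(
            RecordingSpec(
                duration=max(p_cal, p_test) / 4.0 + 5.0,
                channels=(
                    ChannelPopulation(conductance_ps=MSCK_G, activation_pressure=p_test),
                    ChannelPopulation(conductance_ps=MSCL_G, activation_pressure=p_cal),
                ),
                seed=seed,
            )
        )

    def test_ratio_of_40_and_100_is_2_5(self):
        rec = self.two_pop(40.0, 100.0)
        res = tension_sensitivity_ratio(
            rec, amplitude_class_for(MSCK_G, V), amplitude_class_for(MSCL_G, V)
        )
        assert res.ratio == pytest.approx(2.5, abs=0.01)

    def test_identical_classes_give_unity(self):
        rec = self.two_pop(40.0, 100.0)
        k_class = amplitude_class_for(MSCK_G, V)
        res = tension_sensitivity_ratio(rec, k_class, k_class)
        assert res.ratio == 1.0

    def test_sensitized_mutant_increases_ratio(self):
        """A lowered test-channel threshold (30 vs 40 mmHg) raises the
        calibrator/test ratio, mirroring a gain-of-function mutant."""
        wild = self.two_pop(40.0, 100.0, seed=1)
        mutant = self.two_pop(30.0, 100.0, seed=1)
        k, l = amplitude_class_for(MSCK_G, V), amplitude_class_for(MSCL_G, V)
        r_wild = tension_sensitivity_ratio(wild, k, l).ratio
        r_mut = tension_sensitivity_ratio(mutant, k, l).ratio
        assert r_mut > r_wild
        assert r_mut == pytest.approx(100.0 / 30.0, abs=0.05)


def test_recording_csv_round_trip(tmp_path):
    spec = RecordingSpec(duration=2.0, seed=9)
    rec = simulate_patch_recording(spec)
    path = tmp_path / "rec.csv"
    rec.to_csv(path)
    back = Recording.from_csv(path)
    np.testing.assert_allclose(back.current, rec.current, atol=1e-9)
    np.testing.assert_allclose(back.pressure, rec.pressure, atol=1e-9)
    assert back.voltage == rec.voltage
    assert back.ground_truth["seed"] == 9
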