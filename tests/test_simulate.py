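"""Synthetic EEG generation: component injection, noise, artifacts."""

import numpy as np
import pytest

from tonemmn.design import BLOCK_CONDITIONS, build_experiment, generate_block
from tonemmn.measures import build_difference_waves, sort_epochs
from tonemmn.preprocess import (
    RejectionRules,
    baseline_correct,
    epoch,
    reject_artifacts,
    rereference_mastoids,
)
from tonemmn.simulate import (
    ArtifactSpec,
    CohortJitter,
    ComponentSpec,
    EffectSpec,
    NoiseSpec,
    component_waveform,
    inject_artifacts,
    simulate_block,
    simulate_cohort,
    topography_weights,
)

SILENT = NoiseSpec(sd_uv=0.0)


def small_block(seed=3, n_trials=40, n_deviants=5):
    return generate_block(n_trials, n_deviants, 5, 11, seed=seed,
                          block=BLOCK_CONDITIONS[0])


def quiet_pipeline_waves(rec, montage, seq):
    """Epoch -> baseline -> re-reference -> difference waves, no filtering."""
    ep = epoch(rec)
    ep = baseline_correct(ep)
    ep = rereference_mastoids(ep, montage)
    return build_difference_waves(ep, sort_epochs(ep, seq))


class TestSimulateBlock:
    def test_no_noise_no_components_all_zero(self, paper_montage):
        seq = small_block()
        rec = simulate_block(seq, [], SILENT, paper_montage, seed=1,
                             obligatory=())
        assert np.all(rec.data == 0)

    def test_component_spec_polarity_enforced(self):
        with pytest.raises(ValueError, match="MMN"):
            ComponentSpec("MMN", +1.0, 132.0)
        with pytest.raises(ValueError, match="P3a"):
            ComponentSpec("P3a", -1.0, 202.0)
        with pytest.raises(ValueError, match="width"):
            ComponentSpec("MMN", -1.0, 132.0, width_ms=0.0)

    def test_injected_mmn_recovered_exactly_noise_free(self, paper_montage):
        """True difference wave equals the analytic component waveform."""
        seq = small_block()
        mmn = ComponentSpec("MMN", -1.0, 132.0)
        rec = simulate_block(seq, [mmn], SILENT, paper_montage, seed=1,
                             divergence_ms=100.0)
        true_w, dummy_w = quiet_pipeline_waves(rec, paper_montage, seq)
        fcz = true_w.channel("FCz")
        k = np.argmin(fcz)
        assert true_w.times_ms[k] == pytest.approx(232.0, abs=2.0)
        assert fcz[k] == pytest.approx(-1.0, abs=0.01)
        # full waveform matches the analytic Gaussian (post-reref FCz gain 1)
        expected = component_waveform(true_w.times_ms, mmn, 232.0)
        window = np.abs(true_w.times_ms - 232.0) < 150
        assert np.allclose(fcz[window], expected[window], atol=0.02)
        assert np.abs(dummy_w.data).max() < 1e-5

    def test_filtered_wave_matches_analytic_filtered_template(
        self, paper_montage
    ):
        """Noise-free, with the 1-20 Hz bandpass: the true difference
        wave equals the analytically filtered component shape, and
        template regression recovers the injected amplitude exactly."""
        from tonemmn.preprocess import bandpass, reject_artifacts, \
            RejectionRules
        from tonemmn.validation import _filtered_template

        seq = small_block()
        mmn = ComponentSpec("MMN", -1.0, 132.0)
        rec = simulate_block(seq, [mmn], SILENT, paper_montage, seed=1,
                             divergence_ms=100.0)
        rec = bandpass(rec)
        ep = epoch(rec)
        ep = baseline_correct(ep)
        ep = rereference_mastoids(ep, paper_montage)
        seq_waves = build_difference_waves(ep, sort_epochs(ep, seq))
        true_w = seq_waves[0]
        template = _filtered_template(true_w.times_ms, 232.0, 45.0, 0.0,
                                      500.0)
        fcz = true_w.channel("FCz")
        # compare where the component lives; the far epoch tail also
        # carries the adjacent trial's filter ringing (epochs overlap)
        win = (true_w.times_ms >= -100) & (true_w.times_ms <= 600)
        assert np.allclose(fcz[win], -template[win], atol=0.02)
        # latency preserved by the zero-phase filter
        k = np.argmin(fcz)
        assert true_w.times_ms[k] == pytest.approx(232.0, abs=2.0)
        # regression against the filtered shape recovers -1.0
        fit = (true_w.times_ms >= 100.0) & (true_w.times_ms <= 450.0)
        a_hat = fcz[fit] @ template[fit] / (template[fit] @ template[fit])
        assert a_hat == pytest.approx(-1.0, abs=0.02)

    def test_standard_average_variance_matches_sigma2_over_n(
        self, paper_montage
    ):
        """Monte Carlo: var of the standard-trial average ~ sigma^2 / n."""
        seq = small_block(n_trials=30, n_deviants=3)
        n_std = 27
        sigma = 3.0
        sample_vals = []
        for seed in range(200):
            rec = simulate_block(seq, [], NoiseSpec(sd_uv=sigma),
                                 paper_montage, seed=seed, obligatory=())
            ep = epoch(rec)
            std_mask = np.array(
                [l == "standard" for l in ep.trial_labels]
            )
            avg = ep.data[:, :, std_mask].mean(axis=2)
            sample_vals.append(avg[10, 450])
        var = np.var(sample_vals)
        assert var == pytest.approx(sigma**2 / n_std, rel=0.15)

    def test_seed_determinism(self, paper_montage):
        seq = small_block()
        spec = [ComponentSpec("MMN", -1.0, 132.0)]
        a = simulate_block(seq, spec, NoiseSpec(sd_uv=5.0), paper_montage, 9)
        b = simulate_block(seq, spec, NoiseSpec(sd_uv=5.0), paper_montage, 9)
        assert np.array_equal(a.data, b.data)
        assert a.events == b.events

    def test_one_over_f_and_alpha_noise_shapes(self, paper_montage):
        seq = small_block(n_trials=10, n_deviants=0)
        rec = simulate_block(
            seq, [], NoiseSpec(sd_uv=5.0, spectrum="one_over_f",
                               alpha_amplitude_uv=2.0),
            paper_montage, seed=4, obligatory=(),
        )
        # low frequencies dominate a 1/f spectrum
        spec = np.abs(np.fft.rfft(rec.data[0].astype(float)))
        freqs = np.fft.rfftfreq(rec.n_samples, d=1 / 500.0)
        low = spec[(freqs > 0.5) & (freqs < 2)].mean()
        high = spec[(freqs > 40) & (freqs < 60)].mean()
        assert low > 3 * high


class TestTopography:
    def test_fronto_central_maximum_in_mastoid_reference(self, paper_montage):
        spec = ComponentSpec("MMN", -1.0, 132.0)
        w = topography_weights(paper_montage, spec)
        i_fcz = paper_montage.index("FCz")
        m1 = paper_montage.index("M1")
        m2 = paper_montage.index("M2")
        # mean-mastoid-referenced gain at the maximum is exactly 1
        assert w[i_fcz] - 0.5 * (w[m1] + w[m2]) == pytest.approx(1.0)
        # mastoids carry the opposite sign (polarity inversion)
        assert w[m1] < 0 and w[m2] < 0
        # vertex-referenced FCz is weaker: re-referencing enhances the MMN
        assert w[i_fcz] < 1.0


class TestSimulateCohort:
    def test_cohort_size_and_groups(self, paper_montage):
        plan = build_experiment(1, seed=0)
        cohort = simulate_cohort(
            20, plan, EffectSpec({}), SILENT, paper_montage, seed=1
        )
        assert len(cohort.participants) == 40
        groups = {p.group for p in cohort.participants}
        assert groups == {"control", "dissociation"}

    def test_zero_effects_zero_noise_all_zero(self, paper_montage):
        plan = build_experiment(1, seed=0)
        cohort = simulate_cohort(
            1, plan, EffectSpec({}, obligatory=()), SILENT, paper_montage, 1
        )
        rec = cohort.simulate_recording(cohort.participants[0], 0)
        assert np.all(rec.data == 0)

    def test_group_specific_p3a_present_only_in_control(self, paper_montage):
        plan = build_experiment(1, seed=0)
        p3a = ComponentSpec("P3a", 1.0, 202.0, width_ms=50.0)
        t16 = frozenset({"T1", "T6"})
        effects = EffectSpec({("control", "fu", t16): (p3a,)})
        cohort = simulate_cohort(
            1, plan, effects, SILENT, paper_montage, seed=2,
            jitter=CohortJitter(latency_sd_ms=0.0, amplitude_sd=0.0),
        )
        by_group = {p.group: p for p in cohort.participants}
        for group, expected_amp in (("control", 1.0), ("dissociation", 0.0)):
            rec = cohort.simulate_recording(by_group[group], 0)
            seq = plan.blocks[0]
            true_w, _ = quiet_pipeline_waves(rec, paper_montage, seq)
            peak = true_w.channel("FCz").max()
            assert peak == pytest.approx(expected_amp, abs=0.02)


class TestArtifacts:
    def test_zero_rates_leave_recording_unchanged(self, paper_montage):
        seq = small_block()
        rec = simulate_block(seq, [], NoiseSpec(sd_uv=2.0), paper_montage, 5)
        out, log = inject_artifacts(rec, ArtifactSpec(), seed=1)
        assert np.array_equal(out.data, rec.data)
        assert log == []

    def test_extreme_excursion_fails_300uv_screen(self, paper_montage):
        seq = small_block()
        rec = simulate_block(seq, [], SILENT, paper_montage, 5,
                             obligatory=())
        out, log = inject_artifacts(
            rec, ArtifactSpec(extreme_rate=0.08), seed=3
        )
        hit_trials = {e["trial"] for e in log if e["kind"] == "extreme"}
        assert hit_trials
        ep = epoch(out)
        kept, report = reject_artifacts(ep, RejectionRules.screening())
        rejected = set(report["rejected_trials"])
        # epochs overlap (1800 ms windows at 1200 ms onsets), so an
        # excursion may also fall inside a neighboring trial's window
        assert hit_trials <= rejected
        assert all(
            any(abs(t - h) <= 1 for h in hit_trials) for t in rejected
        )

    def test_linear_drift_fails_trend_rule(self, paper_montage):
        seq = small_block()
        rec = simulate_block(seq, [], SILENT, paper_montage, 5,
                             obligatory=())
        out, log = inject_artifacts(
            rec, ArtifactSpec(drift_rate=0.1, drift_uv=100.0), seed=7
        )
        drift_trials = {e["trial"] for e in log if e["kind"] == "drift"}
        assert drift_trials
        ep = epoch(out)
        kept, report = reject_artifacts(
            ep, RejectionRules(abs_uv=None, trend_uv=75.0,
                               improbable_sd=None, kurtosis_sd=None),
        )
        assert set(report["rejected_trials"]) == drift_trials

    def test_blinks_land_on_frontal_channels(self, paper_montage):
        seq = small_block()
        rec = simulate_block(seq, [], SILENT, paper_montage, 5,
                             obligatory=())
        out, log = inject_artifacts(
            rec, ArtifactSpec(blink_rate=0.2), seed=11
        )
        assert any(e["kind"] == "blink" for e in log)
        touched = np.flatnonzero(np.abs(out.data).max(axis=1) > 0)
        frontal = {paper_montage.index(c)
                   for c in ("FP1", "FPz", "FP2", "AF3", "AF4")}
        assert set(touched.tolist()) <= frontal

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError, match="rates"):
            ArtifactSpec(blink_rate=1.5)
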