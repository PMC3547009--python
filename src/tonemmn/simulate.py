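"""Synthetic multi-channel EEG for the oddball experiment.

Stands in for unavailable raw recordings: a 64-channel, 500 Hz continuous
signal per block with event markers, injected ERP components and
configurable noise/artifacts.

Components are Gaussian bumps in time with a spherical-cap spatial profile
peaking fronto-centrally (FCz by default) and carrying opposite-sign
weights at the mastoids, the classic MMN topography whose fronto-central
amplitude *grows* under mean-mastoid re-referencing.  Component amplitudes
are specified in the mean-mastoid measurement reference (the convention in
which MMN/P3a amplitudes are reported), i.e. after re-referencing the
component peaks at exactly ``amplitude_uv`` on the topography maximum.

Obligatory onset responses (N1/P2) go into every trial identically so they
cancel in deviant-minus-standard difference waves; deviant-specific
components (MMN, P3a) are time-locked to the block's divergence point and
added to deviant trials only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .design import BlockCondition, ExperimentPlan, TrialSequence
from .montage import Montage
from .stimuli import contrast_divergence_ms

__all__ = [
    "ComponentSpec",
    "EffectSpec",
    "NoiseSpec",
    "ArtifactSpec",
    "ContinuousRecording",
    "Participant",
    "Cohort",
    "CohortJitter",
    "DEFAULT_OBLIGATORY",
    "paper_pattern_effects",
    "topography_weights",
    "component_waveform",
    "simulate_block",
    "simulate_cohort",
    "inject_artifacts",
]

RATE_HZ = 500.0
PRE_ROLL_MS = 1000.0   # silence before the first stimulus (covers baselines)
POST_ROLL_MS = 1400.0  # tail after the last stimulus onset


@dataclass(frozen=True)
class ComponentSpec:
    """One injected ERP component.

    ``peak_latency_ms`` is measured from the block's divergence point for
    deviance-related components (``latency_ref='divergence'``) and from
    stimulus onset for obligatory ones (``latency_ref='onset'``).
    ``width_ms`` is the temporal Gaussian standard deviation.
    ``amplitude_uv`` is the peak value at the topography maximum in the
    mean-mastoid reference.
    """

    kind: str                     # 'MMN' | 'P3a' | 'N1' | 'P2' | ...
    amplitude_uv: float
    peak_latency_ms: float
    width_ms: float = 45.0
    latency_ref: str = "divergence"
    center_label: str = "FCz"
    spread_rad: float = 0.9
    mastoid_weight: float = -0.2

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError("width_ms must be > 0")
        if self.latency_ref not in ("divergence", "onset"):
            raise ValueError("latency_ref must be 'divergence' or 'onset'")
        if self.kind == "MMN" and self.amplitude_uv > 0:
            raise ValueError("MMN amplitude must be <= 0 (fronto-central negativity)")
        if self.kind == "P3a" and self.amplitude_uv < 0:
            raise ValueError("P3a amplitude must be >= 0 (fronto-central positivity)")


#: Obligatory onset responses shared by standards and deviants.
DEFAULT_OBLIGATORY: tuple[ComponentSpec, ...] = (
    ComponentSpec("N1", -2.0, 125.0, width_ms=30.0, latency_ref="onset"),
    ComponentSpec("P2", 1.5, 225.0, width_ms=40.0, latency_ref="onset"),
)


@dataclass(frozen=True)
class ArtifactSpec:
    """Per-trial artifact injection probabilities and magnitudes."""

    blink_rate: float = 0.0
    drift_rate: float = 0.0
    extreme_rate: float = 0.0
    blink_uv: float = 150.0
    drift_uv: float = 100.0
    extreme_uv: float = 400.0

    def __post_init__(self) -> None:
        for r in (self.blink_rate, self.drift_rate, self.extreme_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("artifact rates must lie in [0, 1]")


@dataclass(frozen=True)
class NoiseSpec:
    """Stationary zero-mean background noise plus optional artifacts."""

    sd_uv: float = 10.0
    spectrum: str = "white"          # 'white' | 'one_over_f'
    alpha_amplitude_uv: float = 0.0  # optional 10 Hz rhythm
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)

    def __post_init__(self) -> None:
        if self.sd_uv < 0:
            raise ValueError("sd_uv must be >= 0")
        if self.spectrum not in ("white", "one_over_f"):
            raise ValueError("spectrum must be 'white' or 'one_over_f'")


@dataclass
class ContinuousRecording:
    """Continuous multi-channel signal with event markers (µV)."""

    data: np.ndarray               # (n_channels, n_samples) float32
    rate_hz: float
    ch_names: list[str]
    events: list[tuple[int, str, str]]  # (sample, label, stimulus_id)
    reference: str = "Cz"
    block_id: str = ""
    divergence_ms: float | None = None
    processing: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        samples = [s for s, _, _ in self.events]
        if any(b <= a for a, b in zip(samples, samples[1:])):
            raise ValueError("event samples must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


class EffectSpec:
    """Deviant-trial component table per group x syllable x contrast.

    Standards receive only the obligatory components.  Conditions missing
    from the table receive no deviance-related components.
    """

    def __init__(
        self,
        table: dict[tuple[str, str, frozenset], tuple[ComponentSpec, ...]],
        obligatory: Sequence[ComponentSpec] = DEFAULT_OBLIGATORY,
    ) -> None:
        self.table = dict(table)
        self.obligatory = tuple(obligatory)

    def components_for(
        self, group: str, condition: BlockCondition
    ) -> tuple[ComponentSpec, ...]:
        key = (group, condition.syllable, frozenset(condition.contrast))
        return self.table.get(key, ())

    @classmethod
    def uniform(
        cls,
        components: Sequence[ComponentSpec],
        groups: Sequence[str] = ("control", "dissociation"),
        obligatory: Sequence[ComponentSpec] = DEFAULT_OBLIGATORY,
    ) -> "EffectSpec":
        """Same deviant components in every condition for every group."""
        table = {}
        for g in groups:
            for syl in ("fu", "lu"):
                for con in (frozenset({"T1", "T6"}), frozenset({"T4", "T6"})):
                    table[(g, syl, con)] = tuple(components)
        return cls(table, obligatory=obligatory)


def paper_pattern_effects(
    strong_mmn_uv: float = -1.4,
    weak_mmn_uv: float = -0.4,
    p3a_uv: float = 1.2,
) -> EffectSpec:
    """Default effect table encoding the study's qualitative outcome.

    Control group: robust MMN plus P3a for the lexical T1/T6 contrast,
    weak (sub-threshold) MMN for lexical T4/T6 and nonlexical T1/T6, a
    robust P3a for nonlexical T1/T6, and nothing for nonlexical T4/T6.
    Dissociation group: robust MMN for lexical T1/T6 only — the tone
    near-merger signature.
    """
    mmn = lambda a: ComponentSpec("MMN", a, 132.0, width_ms=45.0)
    p3a = ComponentSpec("P3a", p3a_uv, 202.0, width_ms=50.0)
    t16, t46 = frozenset({"T1", "T6"}), frozenset({"T4", "T6"})
    table = {
        ("control", "fu", t16): (mmn(strong_mmn_uv), p3a),
        ("control", "fu", t46): (mmn(weak_mmn_uv),),
        ("control", "lu", t16): (mmn(weak_mmn_uv), p3a),
        ("control", "lu", t46): (),
        ("dissociation", "fu", t16): (mmn(strong_mmn_uv),),
        ("dissociation", "fu", t46): (),
        ("dissociation", "lu", t16): (),
        ("dissociation", "lu", t46): (),
    }
    return EffectSpec(table)


def topography_weights(montage: Montage, spec: ComponentSpec) -> np.ndarray:
    """Per-channel spatial weights of a component.

    Gaussian decay with angular distance from the topography maximum,
    overridden by ``mastoid_weight`` at M1/M2, then normalized so the
    weight at the maximum equals 1 *after* mean-mastoid re-referencing.
    """
    pos = montage.positions
    center = pos[montage.index(spec.center_label)]
    ang = np.arccos(np.clip(pos @ center, -1.0, 1.0))
    w = np.exp(-0.5 * (ang / spec.spread_rad) ** 2)
    m1, m2 = (montage.index(m) for m in montage.mastoid_labels)
    w[m1] = w[m2] = spec.mastoid_weight
    gain = w[montage.index(spec.center_label)] - 0.5 * (w[m1] + w[m2])
    return w / gain


def component_waveform(
    times_ms: np.ndarray, spec: ComponentSpec, peak_ms: float
) -> np.ndarray:
    """Gaussian bump evaluated on an absolute time axis (ms)."""
    return spec.amplitude_uv * np.exp(
        -0.5 * ((np.asarray(times_ms, float) - peak_ms) / spec.width_ms) ** 2
    )


def _background(
    rng: np.random.Generator, n_ch: int, n_samp: int, noise: NoiseSpec,
    rate_hz: float,
) -> np.ndarray:
    if noise.sd_uv == 0 and noise.alpha_amplitude_uv == 0:
        return np.zeros((n_ch, n_samp), dtype=np.float32)
    if noise.spectrum == "white":
        data = rng.standard_normal((n_ch, n_samp), dtype=np.float32)
        data *= noise.sd_uv
    else:  # 1/f amplitude spectrum, unit-variance, scaled to sd_uv
        freqs = np.fft.rfftfreq(n_samp, d=1.0 / rate_hz)
        shape = np.zeros_like(freqs)
        shape[1:] = 1.0 / np.sqrt(freqs[1:])
        spec = (
            rng.standard_normal((n_ch, len(freqs)))
            + 1j * rng.standard_normal((n_ch, len(freqs)))
        ) * shape
        data = np.fft.irfft(spec, n=n_samp, axis=1)
        data *= noise.sd_uv / data.std(axis=1, keepdims=True)
        data = data.astype(np.float32)
    if noise.alpha_amplitude_uv > 0:
        t = np.arange(n_samp) / rate_hz
        phases = rng.uniform(0, 2 * np.pi, size=n_ch)
        data += (
            noise.alpha_amplitude_uv
            * np.sin(2 * np.pi * 10.0 * t[None, :] + phases[:, None])
        ).astype(np.float32)
    return data


def simulate_block(
    seq: TrialSequence,
    deviant_components: Sequence[ComponentSpec],
    noise: NoiseSpec,
    montage: Montage,
    seed: int,
    *,
    divergence_ms: float = 100.0,
    obligatory: Sequence[ComponentSpec] = DEFAULT_OBLIGATORY,
    latency_shift_ms: float = 0.0,
    amplitude_scale: float = 1.0,
    rate_hz: float = RATE_HZ,
) -> ContinuousRecording:
    """Simulate one block as a continuous recording with event markers.

    Deviant components are time-locked to ``divergence_ms`` after each
    deviant onset; obligatory components are locked to every onset.
    ``latency_shift_ms``/``amplitude_scale`` apply the simulated
    participant's deviance-response idiosyncrasy (obligatory components
    are left untouched).  Identical seeds reproduce identical recordings;
    the expected value of every sample equals the summed injected
    component values.
    """
    rng = np.random.default_rng(seed)
    n_ch = len(montage)
    onset_samples = np.round(
        (seq.onsets_ms + PRE_ROLL_MS) / 1000.0 * rate_hz
    ).astype(int)
    n_samp = int(onset_samples[-1] + round(POST_ROLL_MS / 1000.0 * rate_hz))
    data = _background(rng, n_ch, n_samp, noise, rate_hz)

    def add(comp: ComponentSpec, trial_mask: np.ndarray,
            shift: float, scale: float) -> None:
        # place one kernel per trial via an impulse-train convolution
        offset = comp.peak_latency_ms + shift
        if comp.latency_ref == "divergence":
            offset += divergence_ms
        half = 4.0 * comp.width_ms
        k0 = int(np.floor((offset - half) / 1000.0 * rate_hz))
        k1 = int(np.ceil((offset + half) / 1000.0 * rate_hz))
        t_rel = np.arange(k0, k1 + 1) / rate_hz * 1000.0
        kernel = scale * component_waveform(t_rel, comp, offset)
        imp = np.zeros(n_samp)
        imp[onset_samples[trial_mask]] = 1.0
        from scipy.signal import fftconvolve

        full = fftconvolve(imp, kernel)  # index m-k0 holds sample m
        y = np.zeros(n_samp)
        a = max(k0, 0)
        b = min(k0 + len(full), n_samp)
        if a < b:
            y[a:b] = full[a - k0 : b - k0]
        y32 = y.astype(np.float32)
        w = topography_weights(montage, comp).astype(np.float32)
        for c in range(n_ch):  # row-wise to avoid a full-size temporary
            data[c] += w[c] * y32

    all_trials = np.ones(len(seq), dtype=bool)
    for comp in obligatory:
        add(comp, all_trials, 0.0, 1.0)
    for comp in deviant_components:
        add(comp, seq.deviant_mask, latency_shift_ms, amplitude_scale)

    events = [
        (int(s), lab, sid)
        for s, lab, sid in zip(onset_samples, seq.labels, seq.stimulus_ids)
    ]
    return ContinuousRecording(
        data=data,
        rate_hz=rate_hz,
        ch_names=montage.labels,
        events=events,
        reference=montage.reference_label,
        block_id=seq.block_id,
        divergence_ms=divergence_ms,
    )


@dataclass(frozen=True)
class Participant:
    participant_id: str
    group: str
    latency_shift_ms: float
    amplitude_scale: float
    block_seeds: tuple[int, ...]


@dataclass(frozen=True)
class CohortJitter:
    """Between-participant variability of the deviance response."""

    latency_sd_ms: float = 25.0
    amplitude_sd: float = 0.25


@dataclass
class Cohort:
    """Lazily materialized cohort: descriptors plus a per-block simulator.

    Recordings are synthesized on demand (one block of one participant at
    a time) so a 40-participant experiment never resides in memory at
    once.
    """

    participants: list[Participant]
    plan: ExperimentPlan
    effects: EffectSpec
    noise: NoiseSpec
    montage: Montage

    def block_condition(self, block_index: int) -> BlockCondition:
        return self.plan.conditions[block_index]

    def simulate_recording(
        self, participant: Participant, block_index: int
    ) -> ContinuousRecording:
        cond = self.plan.conditions[block_index]
        seq = self.plan.blocks[block_index]
        div = contrast_divergence_ms(cond.syllable, *cond.contrast)
        comps = self.effects.components_for(participant.group, cond)
        return simulate_block(
            seq,
            comps,
            self.noise,
            self.montage,
            participant.block_seeds[block_index],
            divergence_ms=div,
            obligatory=self.effects.obligatory,
            latency_shift_ms=participant.latency_shift_ms,
            amplitude_scale=participant.amplitude_scale,
        )


def simulate_cohort(
    n_per_group: int,
    plan: ExperimentPlan,
    effects: EffectSpec,
    noise: NoiseSpec,
    montage: Montage,
    seed: int,
    jitter: CohortJitter = CohortJitter(),
    groups: Sequence[str] = ("control", "dissociation"),
) -> Cohort:
    """Draw per-participant response idiosyncrasies and per-block seeds."""
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    participants = []
    n_blocks = len(plan.blocks)
    for group in groups:
        for i in range(n_per_group):
            shift = rng.normal(0.0, jitter.latency_sd_ms)
            scale = max(rng.normal(1.0, jitter.amplitude_sd), 0.0)
            block_seeds = tuple(
                int(s) for s in
                np.random.SeedSequence(
                    entropy=int(rng.integers(0, 2**31))
                ).generate_state(n_blocks) % (2**31)
            )
            participants.append(
                Participant(f"{group}-{i + 1:02d}", group, shift, scale,
                            block_seeds)
            )
    return Cohort(participants, plan, effects, noise, montage)


def inject_artifacts(
    recording: ContinuousRecording,
    artifacts: ArtifactSpec,
    seed: int,
    *,
    epoch_pre_ms: float = 800.0,
    epoch_post_ms: float = 1000.0,
) -> tuple[ContinuousRecording, list[dict]]:
    """Inject blink/drift/extreme artifacts into randomly chosen trials.

    Blinks are Gaussian transients on the frontal pole channels; drifts
    are linear ramps spanning one epoch on one randomly chosen channel;
    extreme excursions are rectangular pulses exceeding the +/-300 µV
    screening rule.  Returns the modified recording (a copy) and an
    injection log.
    """
    rng = np.random.default_rng(seed)
    data = recording.data.copy()
    rate = recording.rate_hz
    n_samp = data.shape[1]
    pre = int(round(epoch_pre_ms / 1000.0 * rate))
    post = int(round(epoch_post_ms / 1000.0 * rate))
    frontal = [c for c in ("FP1", "FPz", "FP2", "AF3", "AF4")
               if c in recording.ch_names]
    log: list[dict] = []
    for trial, (sample, _, _) in enumerate(recording.events):
        lo, hi = sample - pre, sample + post
        if lo < 0 or hi > n_samp:
            continue
        if rng.random() < artifacts.blink_rate:
            center = rng.uniform(lo + 0.1 * (hi - lo), hi - 0.1 * (hi - lo))
            t = np.arange(lo, hi)
            bump = artifacts.blink_uv * np.exp(
                -0.5 * ((t - center) / (0.05 * rate)) ** 2
            )
            for c in frontal:
                data[recording.ch_names.index(c), lo:hi] += bump.astype(
                    np.float32
                )
            log.append({"trial": trial, "kind": "blink",
                        "channels": list(frontal),
                        "magnitude_uv": artifacts.blink_uv})
        if rng.random() < artifacts.drift_rate:
            ch = int(rng.integers(0, data.shape[0]))
            ramp = np.linspace(
                -artifacts.drift_uv / 2, artifacts.drift_uv / 2, hi - lo
            )
            data[ch, lo:hi] += ramp.astype(np.float32)
            log.append({"trial": trial, "kind": "drift",
                        "channels": [recording.ch_names[ch]],
                        "magnitude_uv": artifacts.drift_uv})
        if rng.random() < artifacts.extreme_rate:
            ch = int(rng.integers(0, data.shape[0]))
            width = int(0.1 * rate)
            start = int(rng.integers(lo, hi - width))
            data[ch, start : start + width] += np.float32(artifacts.extreme_uv)
            log.append({"trial": trial, "kind": "extreme",
                        "channels": [recording.ch_names[ch]],
                        "magnitude_uv": artifacts.extreme_uv})
    out = replace(recording, data=data)
    return out, log
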