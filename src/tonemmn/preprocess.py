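"""Preprocessing chain: bandpass, epoching, baseline, re-reference, rejection.

The chain mirrors the study's order — 1–20 Hz zero-phase bandpass on the
continuous signal, segmentation into 1800 ms epochs (800 ms pre-stimulus),
screening of extreme (±300 µV) epochs, an optional ICA hook, baseline
correction over the pre-stimulus interval, mean-mastoid re-referencing,
and the remaining artifact rules (100 µV amplitude, 75 µV trend, improbable
samples beyond 5 SD, abnormal kurtosis).  A stage tuple on each object
enforces the order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import signal

from .montage import Montage
from .simulate import ContinuousRecording

__all__ = [
    "EpochSet",
    "RejectionRules",
    "bandpass",
    "epoch",
    "baseline_correct",
    "rereference_mastoids",
    "reject_artifacts",
    "apply_ica_hook",
    "write_epochs",
    "read_epochs",
]

PRE_MS = 800.0
POST_MS = 1000.0


@dataclass
class EpochSet:
    """channels x time x trials array with epoch metadata (µV)."""

    data: np.ndarray
    rate_hz: float
    times_ms: np.ndarray          # relative to stimulus onset
    ch_names: list[str]
    trial_labels: tuple[str, ...]
    stimulus_ids: tuple[str, ...]
    trial_indices: np.ndarray     # positions in the original sequence
    stages: tuple[str, ...] = ()
    rejection_log: list = field(default_factory=list)
    block_id: str = ""
    divergence_ms: float | None = None

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def baseline_mask(self) -> np.ndarray:
        return self.times_ms < 0

    def channel(self, label: str) -> int:
        try:
            return self.ch_names.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None


def _require(stages: Sequence[str], present: Sequence[str] = (),
             absent: Sequence[str] = ()) -> None:
    for s in present:
        if s not in stages:
            raise RuntimeError(f"stage {s!r} must run first (have {stages})")
    for s in absent:
        if s in stages:
            raise RuntimeError(f"stage {s!r} already applied (have {stages})")


def design_bandpass(
    low_hz: float, high_hz: float, rate_hz: float
) -> np.ndarray:
    """Second-order-sections Butterworth bandpass (order 4 effective after
    the forward-backward pass)."""
    if not 0 < low_hz < high_hz < rate_hz / 2:
        raise ValueError(
            f"invalid band edges ({low_hz}, {high_hz}) at rate {rate_hz}"
        )
    return signal.butter(
        2, [low_hz, high_hz], btype="bandpass", fs=rate_hz, output="sos"
    )


def bandpass(
    recording: ContinuousRecording,
    low_hz: float = 1.0,
    high_hz: float = 20.0,
    method: str = "auto",
) -> ContinuousRecording:
    """Zero-phase 1–20 Hz bandpass of the continuous recording.

    ``method='sos'`` runs the forward-backward second-order-sections pass;
    ``method='fft'`` applies the identical squared magnitude response
    |H(f)|² in the frequency domain (the zero-phase transfer function of
    the forward-backward pass, cheaper on long recordings and equal away
    from the edges); ``'auto'`` picks FFT beyond 10^5 samples.
    """
    sos = design_bandpass(low_hz, high_hz, recording.rate_hz)
    x = recording.data
    if method == "auto":
        method = "fft" if x.shape[1] > 100_000 else "sos"
    if method == "sos":
        filtered = signal.sosfiltfilt(sos, x, axis=1).astype(x.dtype)
    elif method == "fft":
        import scipy.fft as sfft

        n = x.shape[1]
        freqs = sfft.rfftfreq(n, d=1.0 / recording.rate_hz)
        _, H = signal.sosfreqz(sos, worN=2 * np.pi * freqs / recording.rate_hz)
        gain = (np.abs(H) ** 2).astype(np.float32)
        filtered = sfft.irfft(sfft.rfft(x, axis=1) * gain, n=n, axis=1).astype(
            x.dtype
        )
    else:
        raise ValueError(f"unknown filter method {method!r}")
    return replace(
        recording,
        data=filtered,
        processing=recording.processing + ("bandpass",),
    )


def epoch(
    recording: ContinuousRecording,
    events: Sequence[tuple[int, str, str]] | None = None,
    pre_ms: float = PRE_MS,
    post_ms: float = POST_MS,
) -> EpochSet:
    """Cut one epoch per event; out-of-bounds events are skipped and logged.

    The sample at time 0 of each epoch equals the recording sample at the
    event marker.
    """
    if events is None:
        events = recording.events
    rate = recording.rate_hz
    n_pre = int(round(pre_ms / 1000.0 * rate))
    n_post = int(round(post_ms / 1000.0 * rate))
    times = (np.arange(-n_pre, n_post)) * (1000.0 / rate)
    labels, sids, idx, samples = [], [], [], []
    n_skipped = 0
    for trial, (sample, label, sid) in enumerate(events):
        if sample - n_pre < 0 or sample + n_post > recording.n_samples:
            n_skipped += 1
            continue
        samples.append(sample)
        labels.append(label)
        sids.append(sid)
        idx.append(trial)
    if samples:
        gather = (
            np.asarray(samples)[None, :] + np.arange(-n_pre, n_post)[:, None]
        )
        data = recording.data[:, gather]  # (ch, time, trials), dtype kept
    else:
        data = np.empty(
            (recording.data.shape[0], n_pre + n_post, 0),
            dtype=recording.data.dtype,
        )
    log = []
    if n_skipped:
        log.append({"stage": "epoch", "skipped_out_of_bounds": n_skipped})
    return EpochSet(
        data=data,
        rate_hz=rate,
        times_ms=times,
        ch_names=list(recording.ch_names),
        trial_labels=tuple(labels),
        stimulus_ids=tuple(sids),
        trial_indices=np.asarray(idx, dtype=int),
        stages=recording.processing + ("epoch",),
        rejection_log=log,
        block_id=recording.block_id,
        divergence_ms=recording.divergence_ms,
    )


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract the mean of the 800 ms pre-stimulus interval per channel
    and trial."""
    _require(epochs.stages, present=["epoch"], absent=["baseline", "reref"])
    base = epochs.data[:, epochs.baseline_mask, :].mean(axis=1, keepdims=True)
    return replace(
        epochs, data=epochs.data - base, stages=epochs.stages + ("baseline",)
    )


def rereference_mastoids(epochs: EpochSet, montage: Montage) -> EpochSet:
    """Re-reference every channel to the mean of the two mastoids."""
    _require(epochs.stages, present=["baseline"], absent=["reref"])
    for m in montage.mastoid_labels:
        if m not in epochs.ch_names:
            raise KeyError(f"mastoid channel {m!r} missing from epochs")
    m1 = epochs.channel(montage.mastoid_labels[0])
    m2 = epochs.channel(montage.mastoid_labels[1])
    ref = 0.5 * (epochs.data[m1] + epochs.data[m2])
    return replace(
        epochs,
        data=epochs.data - ref[None, :, :],
        stages=epochs.stages + ("reref",),
    )


@dataclass(frozen=True)
class RejectionRules:
    """Thresholds of the artifact rules; ``None`` disables a rule.

    ``extreme_uv`` is the pre-ICA ±300 µV screening; ``abs_uv`` the 100 µV
    amplitude rule; ``trend_uv`` flags least-squares linear trends whose
    rise over the epoch exceeds the bound; ``improbable_sd`` flags samples
    further than k across-trial SDs from the across-trial mean at the same
    latency; ``kurtosis_sd`` flags epochs whose per-channel sample kurtosis
    is an outlier of the across-trial kurtosis distribution.
    """

    extreme_uv: float | None = None
    abs_uv: float | None = 100.0
    trend_uv: float | None = 75.0
    improbable_sd: float | None = 5.0
    kurtosis_sd: float | None = 5.0

    def __post_init__(self) -> None:
        for name in ("extreme_uv", "abs_uv", "trend_uv",
                     "improbable_sd", "kurtosis_sd"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive or None")

    @classmethod
    def screening(cls, extreme_uv: float = 300.0) -> "RejectionRules":
        return cls(extreme_uv=extreme_uv, abs_uv=None, trend_uv=None,
                   improbable_sd=None, kurtosis_sd=None)


def reject_artifacts(
    epochs: EpochSet,
    rules: RejectionRules = RejectionRules(),
    channels: Sequence[str] | None = None,
) -> tuple[EpochSet, dict]:
    """Drop every trial on which any enabled rule fires on any channel.

    Returns the surviving epochs plus a report with per-rule counts and
    the percentage removed.  ``channels`` restricts the scan (default: all
    channels in the epoch set).
    """
    if epochs.n_trials == 0:
        report = {"n_total": 0, "n_rejected": 0, "pct_rejected": 0.0,
                  "per_rule": {}}
        return epochs, report
    if channels is None:
        x = epochs.data  # (ch, time, trials), no copy
    else:
        ch_idx = np.array([epochs.channel(c) for c in channels])
        x = epochs.data[ch_idx]
    n_trials = epochs.n_trials
    bad = np.zeros(n_trials, dtype=bool)
    per_rule: dict[str, int] = {}

    def mark(rule: str, mask: np.ndarray) -> None:
        per_rule[rule] = int(mask.sum())
        np.logical_or(bad, mask, out=bad)

    absmax = np.abs(x).max(axis=(0, 1))
    if rules.extreme_uv is not None:
        mark("extreme", absmax > rules.extreme_uv)
    if rules.abs_uv is not None:
        mark("amplitude", absmax > rules.abs_uv)
    if rules.trend_uv is not None:
        t = epochs.times_ms - epochs.times_ms.mean()
        denom = (t**2).sum()
        slope = np.tensordot(x, t, axes=([1], [0])) / denom  # µV per ms
        span = epochs.times_ms[-1] - epochs.times_ms[0]
        mark("trend", (np.abs(slope) * span > rules.trend_uv).any(axis=0))
    if rules.improbable_sd is not None and n_trials >= 3:
        mean = x.mean(axis=2, keepdims=True)
        sd = x.std(axis=2, ddof=1, keepdims=True)
        dev = np.abs(x - mean)
        exceeds = dev > rules.improbable_sd * sd  # sd==0 never exceeds
        mark("improbable", exceeds.any(axis=(0, 1)))
    if rules.kurtosis_sd is not None and n_trials >= 3:
        # excess kurtosis per (channel, trial) over time, from raw moments
        xc = x - x.mean(axis=1, keepdims=True)
        x2 = xc * xc
        m2 = x2.mean(axis=1)
        m4 = (x2 * x2).mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            kurt = m4 / (m2 * m2) - 3.0
        kurt = np.where(np.isfinite(kurt), kurt, 0.0)
        km = kurt.mean(axis=1, keepdims=True)
        ks = kurt.std(axis=1, ddof=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            kz = np.abs(kurt - km) / ks
        kz = np.where(np.isfinite(kz), kz, 0.0)
        mark("kurtosis", (kz > rules.kurtosis_sd).any(axis=0))

    keep = ~bad
    report = {
        "n_total": int(n_trials),
        "n_rejected": int(bad.sum()),
        "pct_rejected": float(100.0 * bad.mean()),
        "per_rule": per_rule,
        "rejected_trials": epochs.trial_indices[bad].tolist(),
    }
    kept = replace(
        epochs,
        data=epochs.data[:, :, keep],
        trial_labels=tuple(np.asarray(epochs.trial_labels)[keep]),
        stimulus_ids=tuple(np.asarray(epochs.stimulus_ids)[keep]),
        trial_indices=epochs.trial_indices[keep],
        stages=epochs.stages + ("reject",),
        rejection_log=epochs.rejection_log + [report],
    )
    return kept, report


def apply_ica_hook(
    epochs: EpochSet, hook: Callable[[EpochSet], EpochSet] | None
) -> EpochSet:
    """Optional pass-through for an external ocular-correction step.

    The pipeline never implements ICA itself; supply a callable wrapping
    an established decomposition if the data need it (synthetic data
    default: ``None``).
    """
    if hook is None:
        return replace(epochs, stages=epochs.stages + ("ica:skipped",))
    out = hook(epochs)
    return replace(out, stages=out.stages + ("ica",))


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Write epochs as a JSON header plus a raw float64 array file."""
    path = Path(path)
    header = {
        "shape": list(epochs.data.shape),
        "dtype": "float64",
        "rate_hz": epochs.rate_hz,
        "times_ms": epochs.times_ms.tolist(),
        "ch_names": epochs.ch_names,
        "trial_labels": list(epochs.trial_labels),
        "stimulus_ids": list(epochs.stimulus_ids),
        "trial_indices": epochs.trial_indices.tolist(),
        "stages": list(epochs.stages),
        "block_id": epochs.block_id,
        "divergence_ms": epochs.divergence_ms,
    }
    path.with_suffix(".json").write_text(json.dumps(header))
    epochs.data.astype(np.float64).tofile(path.with_suffix(".raw"))


def read_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    data = np.fromfile(path.with_suffix(".raw"), dtype=np.float64).reshape(
        header["shape"]
    )
    return EpochSet(
        data=data,
        rate_hz=header["rate_hz"],
        times_ms=np.asarray(header["times_ms"]),
        ch_names=header["ch_names"],
        trial_labels=tuple(header["trial_labels"]),
        stimulus_ids=tuple(header["stimulus_ids"]),
        trial_indices=np.asarray(header["trial_indices"], dtype=int),
        stages=tuple(header["stages"]),
        block_id=header["block_id"],
        divergence_ms=header["divergence_ms"],
    )
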