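"""Trial sorting, true/dummy difference waves and MMN/P3a measurement.

Surviving trials are sorted into (i) deviants, (ii) the standard
immediately before each deviant and (iii) the standard before that.  The
true difference wave is avg(i) − avg(ii); the dummy wave avg(ii) −
avg(iii) is a null reference built from physically identical stimuli, so
anything surviving in it is labeling noise rather than deviance response.

MMN peak latency is the most negative sample of the (true) difference
wave at FCz within 100–250 ms after the divergence point; P3a is the most
positive sample after the individual MMN peak.  Component amplitudes are
quantified as the mean of (true − dummy) over a 100 ms window centered on
a peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import TrialSequence
from .preprocess import EpochSet

__all__ = [
    "SortedTrials",
    "DifferenceWave",
    "ComponentMeasure",
    "MMN_WINDOW_MS",
    "sort_trials",
    "sort_epochs",
    "build_difference_waves",
    "measure_mmn",
    "measure_p3a",
    "mean_amplitude",
    "crop_wave",
    "measures_to_frame",
]

#: MMN peak search window, ms after the divergence point.
MMN_WINDOW_MS: tuple[float, float] = (100.0, 250.0)
#: Width of the mean-amplitude window centered on a peak (ms).
AMPLITUDE_WINDOW_MS: float = 100.0
#: Grand-average window centers (ms post divergence) used by the fixed
#: windowing convention: T1/T6 MMN, lexical T4/T6 MMN, and P3a.
GRAND_AVERAGE_CENTERS_MS = {"MMN_T1T6": 132.0, "MMN_T4T6": 136.0, "P3a": 202.0}


@dataclass(frozen=True)
class SortedTrials:
    """Index triplets (into the original presentation order)."""

    deviant_idx: np.ndarray
    std_before_deviant_idx: np.ndarray
    std_before_that_idx: np.ndarray

    def __post_init__(self) -> None:
        for name in ("deviant_idx", "std_before_deviant_idx",
                     "std_before_that_idx"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=int))
        if not (
            len(self.deviant_idx)
            == len(self.std_before_deviant_idx)
            == len(self.std_before_that_idx)
        ):
            raise ValueError("index lists must have equal length")

    @property
    def n_triplets(self) -> int:
        return len(self.deviant_idx)


@dataclass(frozen=True)
class DifferenceWave:
    """channels x time average wave (µV), true or dummy."""

    kind: str  # 'true' | 'dummy'
    data: np.ndarray
    times_ms: np.ndarray
    ch_names: list[str]
    divergence_ms: float
    participant: str = ""
    condition: str = ""

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.ch_names.index(label)]


@dataclass(frozen=True)
class ComponentMeasure:
    component: str                 # 'MMN' | 'P3a'
    peak_latency_ms: float         # post-divergence
    peak_amplitude_uv: float
    mean_amplitude_uv: float | None = None
    window_center_ms: float | None = None
    boundary_peak: bool = False
    low_confidence: bool = False


def sort_trials(
    seq: TrialSequence, surviving: Sequence[int] | np.ndarray
) -> SortedTrials:
    """Form (deviant, standard-before, standard-before-that) triplets.

    ``surviving`` holds the original trial indices that passed rejection.
    A triplet is formed only when all three members survived; the two
    trials preceding a deviant are standards by design (minimum leading
    run of 2 and minimum gap of 5).
    """
    alive = set(int(i) for i in np.asarray(surviving, dtype=int))
    dev, std1, std2 = [], [], []
    for i, label in enumerate(seq.labels):
        if label != "deviant":
            continue
        if i in alive and (i - 1) in alive and (i - 2) in alive and i >= 2:
            dev.append(i)
            std1.append(i - 1)
            std2.append(i - 2)
    return SortedTrials(np.array(dev), np.array(std1), np.array(std2))


def sort_epochs(epochs: EpochSet, seq: TrialSequence) -> SortedTrials:
    """Sort an epoch set's surviving trials against its sequence."""
    return sort_trials(seq, epochs.trial_indices)


def build_difference_waves(
    epochs: EpochSet,
    sorted_trials: SortedTrials,
    participant: str = "",
    condition: str = "",
) -> tuple[DifferenceWave, DifferenceWave]:
    """True (avg(i) − avg(ii)) and dummy (avg(ii) − avg(iii)) waves."""
    if sorted_trials.n_triplets == 0:
        raise ValueError("no complete trial triplets survive rejection")
    pos = {int(t): k for k, t in enumerate(epochs.trial_indices)}
    def avg(idx: np.ndarray) -> np.ndarray:
        rows = [pos[int(i)] for i in idx]
        return epochs.data[:, :, rows].mean(axis=2)

    a_i = avg(sorted_trials.deviant_idx)
    a_ii = avg(sorted_trials.std_before_deviant_idx)
    a_iii = avg(sorted_trials.std_before_that_idx)
    div = epochs.divergence_ms if epochs.divergence_ms is not None else 0.0
    common = dict(
        times_ms=epochs.times_ms,
        ch_names=list(epochs.ch_names),
        divergence_ms=float(div),
        participant=participant,
        condition=condition or epochs.block_id,
    )
    return (
        DifferenceWave(kind="true", data=a_i - a_ii, **common),
        DifferenceWave(kind="dummy", data=a_ii - a_iii, **common),
    )


def _window_indices(
    times_ms: np.ndarray, lo_ms: float, hi_ms: float
) -> np.ndarray:
    idx = np.flatnonzero((times_ms >= lo_ms) & (times_ms <= hi_ms))
    if len(idx) == 0:
        raise ValueError(
            f"window [{lo_ms}, {hi_ms}] ms outside the epoch time axis"
        )
    return idx


def measure_mmn(
    wave: DifferenceWave,
    channel: str = "FCz",
    window_ms: tuple[float, float] = MMN_WINDOW_MS,
) -> ComponentMeasure:
    """Most negative sample at ``channel`` within the post-divergence window.

    Ties break to the earliest sample; a peak landing on a window edge is
    flagged ``boundary_peak``.
    """
    x = wave.channel(channel)
    lo = wave.divergence_ms + window_ms[0]
    hi = wave.divergence_ms + window_ms[1]
    idx = _window_indices(wave.times_ms, lo, hi)
    k = idx[int(np.argmin(x[idx]))]
    latency = float(wave.times_ms[k] - wave.divergence_ms)
    return ComponentMeasure(
        component="MMN",
        peak_latency_ms=latency,
        peak_amplitude_uv=float(x[k]),
        boundary_peak=bool(k == idx[0] or k == idx[-1]),
    )


def measure_p3a(
    wave: DifferenceWave,
    mmn: ComponentMeasure,
    channel: str = "FCz",
) -> ComponentMeasure:
    """Most positive sample strictly after the individual MMN peak.

    A wave with no positive excursion after the MMN still returns its
    least-negative sample, flagged ``low_confidence``, so cohort tables
    stay rectangular.
    """
    x = wave.channel(channel)
    t_peak = wave.divergence_ms + mmn.peak_latency_ms
    idx = np.flatnonzero(wave.times_ms > t_peak)
    if len(idx) == 0:
        raise ValueError("no samples after the MMN peak")
    k = idx[int(np.argmax(x[idx]))]
    return ComponentMeasure(
        component="P3a",
        peak_latency_ms=float(wave.times_ms[k] - wave.divergence_ms),
        peak_amplitude_uv=float(x[k]),
        boundary_peak=bool(k == idx[-1]),
        low_confidence=bool(x[k] <= 0),
    )


def mean_amplitude(
    true_wave: DifferenceWave,
    dummy_wave: DifferenceWave,
    center_ms: float,
    width_ms: float = AMPLITUDE_WINDOW_MS,
    channel: str = "FCz",
    relative_to_divergence: bool = True,
) -> float:
    """Mean of (true − dummy) at ``channel`` over center ± width/2 (µV).

    ``center_ms`` is post-divergence by default.
    """
    offset = true_wave.divergence_ms if relative_to_divergence else 0.0
    lo = offset + center_ms - width_ms / 2
    hi = offset + center_ms + width_ms / 2
    if lo < true_wave.times_ms[0] or hi > true_wave.times_ms[-1]:
        raise ValueError("amplitude window overflows the epoch")
    idx = _window_indices(true_wave.times_ms, lo, hi)
    diff = true_wave.channel(channel) - dummy_wave.channel(channel)
    return float(diff[idx].mean())


def crop_wave(wave: DifferenceWave, window_ms: tuple[float, float]) -> DifferenceWave:
    """Restrict a difference wave to a time window (ms, onset-relative)."""
    from dataclasses import replace

    mask = (wave.times_ms >= window_ms[0]) & (wave.times_ms <= window_ms[1])
    return replace(wave, data=wave.data[:, mask], times_ms=wave.times_ms[mask])


def measures_to_frame(rows: list[dict]) -> pd.DataFrame:
    """Tidy per-participant measures table."""
    return pd.DataFrame(
        rows,
        columns=[
            "participant", "group", "condition", "component",
            "peak_latency_ms", "peak_amplitude_uv", "mean_amplitude_uv",
            "boundary_peak", "low_confidence",
        ],
    )


def write_measures_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, float_format="%.6f")
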