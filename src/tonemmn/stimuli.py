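"""Schematic F0 contours of the tone stimuli and divergence-point detection.

Each 400 ms syllable has a 100 ms unvoiced onset (F0 = 0) and a 300 ms
voiced vowel.  Tones are modelled as piecewise-linear F0 trajectories
constrained to reproduce the study's printed vowel-mean F0 values and
divergence points:

* T1 and T6 are level tones at their respective vowel means, so the T1/T6
  pair separates at the vowel onset (100 ms post stimulus onset).
* T4 coincides with T6 sample-for-sample over the early vowel and departs
  linearly from the contrast's divergence point (200 ms for *fu*, 180 ms
  for *lu*); the ramp endpoint is solved so the vowel-mean F0 matches the
  printed T4 mean.

Vowel-mean F0 (Hz): fu1 254.9, fu4 178.6, fu6 170.9; lu1 284.7, lu4 180.2,
lu6 184.3.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "PitchContour",
    "ContrastSpec",
    "F0_MEANS_HZ",
    "DIVERGENCE_MS",
    "synthesize_contour",
    "divergence_point",
    "mean_f0_difference",
    "write_contour_csv",
]

ONSET_DUR_MS = 100.0
VOWEL_DUR_MS = 300.0
TOTAL_DUR_MS = ONSET_DUR_MS + VOWEL_DUR_MS

#: Vowel-segment mean F0 per syllable and tone (Hz).
F0_MEANS_HZ: dict[str, dict[str, float]] = {
    "fu": {"T1": 254.9, "T4": 178.6, "T6": 170.9},
    "lu": {"T1": 284.7, "T4": 180.2, "T6": 184.3},
}

#: First moment (ms post stimulus onset) at which the two contours of a
#: contrast deviate.  T1/T6 separates at the vowel onset; the T4/T6
#: divergence differs between the syllables.
DIVERGENCE_MS: dict[tuple[str, frozenset], float] = {
    ("fu", frozenset({"T1", "T6"})): 100.0,
    ("lu", frozenset({"T1", "T6"})): 100.0,
    ("fu", frozenset({"T4", "T6"})): 200.0,
    ("lu", frozenset({"T4", "T6"})): 180.0,
}


def contrast_divergence_ms(syllable: str, tone_a: str, tone_b: str) -> float:
    """Divergence point of a tonal contrast on a syllable (ms post onset)."""
    key = (syllable, frozenset({tone_a, tone_b}))
    if key not in DIVERGENCE_MS:
        raise KeyError(f"unknown contrast {tone_a}/{tone_b} on {syllable!r}")
    return DIVERGENCE_MS[key]


@dataclass(frozen=True)
class PitchContour:
    """Sampled F0 trajectory of one syllable (0 Hz during the onset)."""

    syllable: str
    tone: str
    times_ms: np.ndarray
    f0_hz: np.ndarray
    onset_dur_ms: float = ONSET_DUR_MS
    vowel_dur_ms: float = VOWEL_DUR_MS

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_ms", np.asarray(self.times_ms, float))
        object.__setattr__(self, "f0_hz", np.asarray(self.f0_hz, float))
        if self.times_ms.shape != self.f0_hz.shape:
            raise ValueError("times_ms and f0_hz must align")

    @property
    def vowel_mask(self) -> np.ndarray:
        return self.times_ms >= self.onset_dur_ms

    @property
    def vowel_mean_hz(self) -> float:
        return float(self.f0_hz[self.vowel_mask].mean())


@dataclass(frozen=True)
class ContrastSpec:
    """A tonal contrast on one syllable with its divergence point."""

    syllable: str
    pair: tuple[str, str]
    divergence_ms: float


def synthesize_contour(
    syllable: str,
    tone: str,
    sampling_rate_hz: float = 500.0,
    f0_means_hz: dict | None = None,
) -> PitchContour:
    """Synthesize the schematic contour of one tone on one syllable.

    The sample grid runs from 0 to just under 400 ms with
    ``round(0.4 * rate)`` samples, shared by all contours at a given rate.
    The discrete vowel-segment mean equals the configured mean to well
    within 0.05 Hz (T1/T6 exactly; T4 by construction of the ramp slope).
    """
    table = F0_MEANS_HZ if f0_means_hz is None else f0_means_hz
    if syllable not in table:
        raise KeyError(f"unknown syllable {syllable!r}")
    if tone not in table[syllable]:
        raise KeyError(f"unknown tone {tone!r} for syllable {syllable!r}")
    n = int(round(TOTAL_DUR_MS / 1000.0 * sampling_rate_hz))
    times = np.arange(n) * (1000.0 / sampling_rate_hz)
    vowel = times >= ONSET_DUR_MS
    f0 = np.zeros(n)
    mean = table[syllable][tone]
    if tone in ("T1", "T6"):
        f0[vowel] = mean
    elif tone == "T4":
        t6 = table[syllable]["T6"]
        div = contrast_divergence_ms(syllable, "T4", "T6")
        ramp = np.maximum(times - div, 0.0)[vowel]
        # slope solved so the discrete vowel mean hits the target exactly
        slope = (mean - t6) / ramp.mean()
        f0[vowel] = t6 + slope * ramp
    else:
        raise KeyError(f"unknown tone {tone!r}")
    return PitchContour(syllable=syllable, tone=tone, times_ms=times, f0_hz=f0)


def _check_grids(a: PitchContour, b: PitchContour) -> None:
    if a.syllable != b.syllable:
        raise ValueError("contours must share a syllable")
    if a.times_ms.shape != b.times_ms.shape or not np.allclose(
        a.times_ms, b.times_ms
    ):
        raise ValueError("contours must share the sample grid")


def divergence_point(
    a: PitchContour, b: PitchContour, tol_hz: float = 0.0
) -> float | None:
    """Time (ms post stimulus onset) where the contours begin to deviate.

    Finds the first sample from which |f0_a - f0_b| exceeds ``tol_hz`` and
    stays above it, then refines the onset to sub-sample precision by
    back-extrapolating the initial slope of the difference (clamped to one
    sample period).  A step-like separation (level tones turning on with
    different heights) therefore reports the first differing sample, while
    a ramp-like departure reports the instant the ramp leaves zero.
    Returns ``None`` if the contours never deviate.
    """
    _check_grids(a, b)
    diff = np.abs(a.f0_hz - b.f0_hz)
    above = diff > tol_hz
    if not above.any():
        return None
    # earliest k such that above[k:] is all True
    below_idx = np.flatnonzero(~above)
    k = 0 if len(below_idx) == 0 else int(below_idx[-1]) + 1
    if k >= len(diff):
        return None
    t = a.times_ms
    if k == 0:
        return float(t[0])
    period = float(t[1] - t[0])
    d1 = diff[k] - tol_hz
    slope = (diff[k + 1] - diff[k]) / period if k + 1 < len(diff) else 0.0
    if slope > 1e-12:
        est = float(t[k]) - d1 / slope
        return float(min(max(est, t[k - 1]), t[k]))
    return float(t[k])


def mean_f0_difference(a: PitchContour, b: PitchContour) -> float:
    """Vowel-segment mean F0 of ``a`` minus that of ``b`` (Hz)."""
    _check_grids(a, b)
    return a.vowel_mean_hz - b.vowel_mean_hz


def write_contour_csv(contour: PitchContour, path: str | Path) -> None:
    lines = ["time_ms,f0_hz"]
    lines += [
        f"{t:g},{f:.6f}" for t, f in zip(contour.times_ms, contour.f0_hz)
    ]
    Path(path).write_text("\n".join(lines) + "\n")
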