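"""European Data Format I/O for continuous recordings.

Writing uses a minimal in-package EDF encoder (16-bit samples, one-second
data records, per-channel physical scaling); no EDF writer ships with the
scientific stack here, and the format's fixed-width header is small enough
to emit directly.  Reading goes through ``mne.io.read_raw_edf``, which
doubles as an independent check on the writer in the round-trip tests.

Event markers travel in a tab-separated sidecar (``<name>.events.tsv``)
with columns onset_sample / label / stimulus_id plus ``#key=value``
comment lines carrying recording metadata (true sample count before
record padding, block id, divergence point, reference state).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .simulate import ContinuousRecording

__all__ = ["write_edf", "read_edf", "events_sidecar_path"]


def events_sidecar_path(edf_path: str | Path) -> Path:
    p = Path(edf_path)
    return p.with_suffix(p.suffix + ".events.tsv")


def _ascii(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: ContinuousRecording, path: str | Path) -> None:
    """Write the recording as EDF plus the event sidecar TSV.

    Samples are quantized to 16 bits over each channel's observed range,
    so round-trip error is at most one quantization step per channel.
    The last data record is zero-padded; the sidecar stores the true
    sample count.
    """
    path = Path(path)
    data = np.asarray(recording.data, dtype=np.float64)
    n_ch, n_samp = data.shape
    spr = int(round(recording.rate_hz))  # samples per 1 s record
    n_records = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_records * spr))
    padded[:, :n_samp] = data

    phys_max = np.abs(padded).max(axis=1)
    phys_max = np.where(phys_max > 0, phys_max, 1.0)
    phys_min = -phys_max
    dig_min, dig_max = -32768, 32767
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round(
        (padded - phys_min[:, None]) / scale[:, None] + dig_min
    ).astype("<i2")

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X X X X", 80),                      # patient id
            _ascii(f"Startdate X {recording.block_id or 'X'}", 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(256 * (1 + n_ch), 8),
            _ascii("", 44),
            _ascii(n_records, 8),
            _ascii(1, 8),                               # record duration (s)
            _ascii(n_ch, 4),
        ]
    )
    fields = [
        (recording.ch_names, 16),
        (["" for _ in range(n_ch)], 80),                # transducer
        (["uV"] * n_ch, 8),
        ([f"{v:.6g}" for v in phys_min], 8),
        ([f"{v:.6g}" for v in phys_max], 8),
        ([dig_min] * n_ch, 8),
        ([dig_max] * n_ch, 8),
        (["" for _ in range(n_ch)], 80),                # prefiltering
        ([spr] * n_ch, 8),
        (["" for _ in range(n_ch)], 32),
    ]
    for values, width in fields:
        header += b"".join(_ascii(v, width) for v in values)

    with open(path, "wb") as fh:
        fh.write(header)
        # records: for each record, all samples of signal 1, then signal 2, ...
        rec = digital.reshape(n_ch, n_records, spr).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(rec).tobytes())

    lines = [
        f"# n_samples={n_samp}",
        f"# rate_hz={recording.rate_hz:g}",
        f"# reference={recording.reference}",
        f"# block_id={recording.block_id}",
        f"# divergence_ms={'' if recording.divergence_ms is None else format(recording.divergence_ms, 'g')}",
        "onset_sample\tlabel\tstimulus_id",
    ]
    lines += [f"{s}\t{lab}\t{sid}" for s, lab, sid in recording.events]
    events_sidecar_path(path).write_text("\n".join(lines) + "\n")


def read_edf(path: str | Path) -> ContinuousRecording:
    """Read an EDF recording and its event sidecar.

    Raises ``FileNotFoundError`` with a pointed message when the sidecar
    is missing; an empty event table is allowed (downstream epoching then
    yields zero epochs).
    """
    import mne

    path = Path(path)
    sidecar = events_sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"event sidecar {sidecar.name} not found next to {path.name}; "
            "EDF recordings need their onset_sample/label/stimulus_id table"
        )
    meta: dict[str, str] = {}
    events: list[tuple[int, str, str]] = []
    body = False
    for line in sidecar.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            continue
        if not body:
            body = True  # header row
            continue
        s, lab, sid = line.split("\t")
        events.append((int(s), lab, sid))

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = (raw.get_data() * 1e6).astype(np.float32)  # V -> µV
    n_samp = int(meta.get("n_samples", data.shape[1]))
    data = data[:, :n_samp]
    div = meta.get("divergence_ms", "")
    return ContinuousRecording(
        data=data,
        rate_hz=float(meta.get("rate_hz", raw.info["sfreq"])),
        ch_names=list(raw.ch_names),
        events=events,
        reference=meta.get("reference", "Cz"),
        block_id=meta.get("block_id", ""),
        divergence_ms=float(div) if div else None,
    )
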