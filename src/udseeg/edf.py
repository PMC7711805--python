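"""European Data Format (EDF+) persistence for marked recordings.

Writing produces a minimal standards-conforming 16-bit EDF+C file: one
ordinary signal per EEG channel (physical unit uV, per-channel physical
range, digital range -32768..32767) plus an ``EDF Annotations`` signal
carrying the event markers as timestamped annotation lists.  Reading goes
through :func:`mne.io.read_raw_edf`, which also validates the writer in
the round-trip tests.

Quantization: 16-bit amplitude resolution means values survive a
round-trip to within (phys_max - phys_min) / 65535 of the original.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .containers import ContinuousRecording

__all__ = ["write_edf", "read_edf"]

_DIG_MIN, _DIG_MAX = -32768, 32767
_ANN_SAMPLES_PER_RECORD = 30  # 60 bytes of annotation space per record


def _fixed(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def write_edf(rec: ContinuousRecording, path) -> Path:
    """Write a recording (uV) and its markers to an EDF+C file.

    The record duration is 1 s, so the sampling rate must be a positive
    integer; the final partial record is zero-padded.  Marker annotations
    are placed in the record containing their onset.
    """
    fs = rec.fs
    if fs != int(fs) or fs <= 0:
        raise ValueError("EDF writing requires an integer sampling rate")
    fs = int(fs)
    n_chan, n_samples = rec.data.shape
    n_records = max(1, math.ceil(n_samples / fs))
    ns = n_chan + 1  # + annotations signal

    # Per-channel physical range (guard against constant channels).
    phys_min = np.floor(rec.data.min(axis=1))
    phys_max = np.ceil(rec.data.max(axis=1))
    same = phys_max - phys_min < 1.0
    phys_max[same] = phys_min[same] + 1.0

    header = b"".join(
        [
            _fixed("0", 8),
            _fixed("X X X X", 80),                      # local patient id
            _fixed("Startdate X X X X", 80),            # local recording id
            _fixed("01.01.00", 8),
            _fixed("00.00.00", 8),
            _fixed(str(256 * (ns + 1)), 8),
            _fixed("EDF+C", 44),
            _fixed(str(n_records), 8),
            _fixed("1", 8),                             # record duration (s)
            _fixed(str(ns), 4),
        ]
    )

    labels = [_fixed(lab, 16) for lab in rec.channel_labels]
    labels.append(_fixed("EDF Annotations", 16))
    transducer = [_fixed("", 80)] * ns
    phys_dim = [_fixed("uV", 8)] * n_chan + [_fixed("", 8)]
    pmin = [_fixed(f"{v:g}", 8) for v in phys_min] + [_fixed("0", 8)]
    pmax = [_fixed(f"{v:g}", 8) for v in phys_max] + [_fixed("1", 8)]
    dmin = [_fixed(str(_DIG_MIN), 8)] * ns
    dmax = [_fixed(str(_DIG_MAX), 8)] * ns
    prefilter = [_fixed("", 80)] * ns
    n_samp = [_fixed(str(fs), 8)] * n_chan + [
        _fixed(str(_ANN_SAMPLES_PER_RECORD), 8)
    ]
    reserved = [_fixed("", 32)] * ns
    signal_header = b"".join(
        b"".join(group)
        for group in (labels, transducer, phys_dim, pmin, pmax, dmin, dmax,
                      prefilter, n_samp, reserved)
    )

    # Digitize: phys -> int16 per channel.
    scale = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    padded = np.zeros((n_chan, n_records * fs))
    padded[:, :n_samples] = rec.data
    digital = np.rint(
        (padded - phys_min[:, None]) * scale[:, None] + _DIG_MIN
    ).astype("<i2")

    # Annotation TALs grouped by the record containing each onset.
    tals_by_record: dict[int, list[bytes]] = {}
    for onset_sample, label in rec.markers:
        onset = onset_sample / fs
        tal = f"+{onset:.4f}\x14{label}\x14\x00".encode("ascii")
        tals_by_record.setdefault(int(onset), []).append(tal)

    ann_bytes = 2 * _ANN_SAMPLES_PER_RECORD
    out = Path(path)
    with out.open("wb") as fh:
        fh.write(header)
        fh.write(signal_header)
        for r in range(n_records):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())
            block = f"+{r}\x14\x14\x00".encode("ascii") + b"".join(
                tals_by_record.get(r, [])
            )
            if len(block) > ann_bytes:
                raise ValueError(
                    f"record {r}: annotation block ({len(block)} B) exceeds "
                    f"the {ann_bytes} B annotation signal capacity"
                )
            fh.write(block.ljust(ann_bytes, b"\x00"))
    return out


def read_edf(path) -> ContinuousRecording:
    """Load an EDF+ recording back into uV with its event markers."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne returns SI volts
    fs = float(raw.info["sfreq"])
    markers = [
        (int(round(onset * fs)), desc)
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description)
        if desc in ("UDS", "NUDS")
    ]
    return ContinuousRecording(
        data_uv, fs, list(raw.ch_names), markers
    )
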