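"""Minimal EDF (European Data Format) reader/writer.

Implements the plain EDF subset this pipeline needs: identical integer
sampling rate on all channels, 1-second data records, 16-bit samples.
Written because no EDF library is available in the target environment;
the format is a fixed-width ASCII header followed by little-endian
int16 records (Kemp et al.'s published layout).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .recording import EEGRecording

_DIG_MAX = 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds {width} ASCII bytes")
    return s.ljust(width).encode("ascii")


def write_edf(rec: EEGRecording, path: str | Path) -> Path:
    """Write ``rec`` as a 16-bit EDF file with 1-s data records.

    The sampling rate must be a positive integer.  Any trailing partial
    second of data is dropped (EDF stores whole records only).
    """
    path = Path(path)
    fs = rec.sampling_rate
    if fs != int(fs) or fs <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    n_records = rec.n_samples // fs
    if n_records == 0:
        raise ValueError("recording shorter than one EDF record (1 s)")
    ns = rec.n_channels
    data = rec.data[:, : n_records * fs]

    # Integer physical range per channel keeps the header ASCII exact.
    phys_max = np.maximum(np.ceil(np.abs(data).max(axis=1)), 1.0).astype(int)

    header = b""
    header += _ascii("0", 8)  # version
    header += _ascii("synthetic", 80)  # patient id
    header += _ascii("resting EEG", 80)  # recording id
    header += _ascii("01.01.00", 8)  # start date
    header += _ascii((rec.start_time or "00.00.00")[:8], 8)  # start time
    header += _ascii(256 * (1 + ns), 8)  # header bytes
    header += _ascii("", 44)  # reserved
    header += _ascii(n_records, 8)
    header += _ascii(1, 8)  # record duration, s
    header += _ascii(ns, 4)

    header += b"".join(_ascii(name, 16) for name in rec.channel_names)
    header += b"".join(_ascii("AgAgCl electrode", 80) for _ in range(ns))
    header += b"".join(_ascii("uV", 8) for _ in range(ns))
    header += b"".join(_ascii(-p, 8) for p in phys_max)
    header += b"".join(_ascii(p, 8) for p in phys_max)
    header += b"".join(_ascii(-_DIG_MAX, 8) for _ in range(ns))
    header += b"".join(_ascii(_DIG_MAX, 8) for _ in range(ns))
    header += b"".join(_ascii("", 80) for _ in range(ns))  # prefiltering
    header += b"".join(_ascii(fs, 8) for _ in range(ns))
    header += b"".join(_ascii("", 32) for _ in range(ns))

    scale = phys_max[:, None] / _DIG_MAX
    digital = np.clip(np.round(data / scale), -_DIG_MAX, _DIG_MAX).astype("<i2")
    # records: for each second, all channels' samples consecutively
    records = digital.reshape(ns, n_records, fs).transpose(1, 0, 2)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(records.tobytes())
    return path


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (microvolts)."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise ValueError(f"not an EDF file (truncated header): {path}")

    def fixed(offset: int, width: int) -> str:
        return raw[offset : offset + width].decode("ascii", "replace").strip()

    header_bytes = int(fixed(184, 8))
    n_records = int(fixed(236, 8))
    record_dur = float(fixed(244, 8))
    ns = int(fixed(252, 4))
    if header_bytes != 256 * (1 + ns):
        raise ValueError(f"inconsistent EDF header in {path}")

    # offsets within the per-signal block: label 16, transducer 80,
    # dimension 8, phys_min 8, phys_max 8, dig_min 8, dig_max 8,
    # prefilter 80, samples 8, reserved 32
    off = 256
    sizes = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
    fields = []
    for width in sizes:
        block = [fixed(off + i * width, width) for i in range(ns)]
        fields.append(block)
        off += width * ns
    labels = fields[0]
    phys_min = np.array([float(v) for v in fields[3]])
    phys_max = np.array([float(v) for v in fields[4]])
    dig_min = np.array([float(v) for v in fields[5]])
    dig_max = np.array([float(v) for v in fields[6]])
    samples_per_record = np.array([int(v) for v in fields[8]])
    if len(set(samples_per_record)) != 1:
        raise ValueError("mixed per-channel rates are not supported")
    spr = int(samples_per_record[0])
    fs = spr / record_dur
    if fs != int(fs):
        raise ValueError("non-integer sampling rate is not supported")

    payload = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    expected = n_records * ns * spr
    if payload.size < expected:
        raise ValueError(f"EDF data shorter than header promises: {path}")
    digital = (
        payload[:expected].reshape(n_records, ns, spr).transpose(1, 0, 2).reshape(ns, -1)
    )
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    data = (digital - dig_min[:, None]) * gain[:, None] + phys_min[:, None]
    return EEGRecording(
        data=data, sampling_rate=int(fs), channel_names=labels
    )
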