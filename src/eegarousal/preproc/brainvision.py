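"""BrainVision triad (.vhdr/.vmrk/.eeg) reader/writer.

Supports the multiplexed binary layout with IEEE_FLOAT_32 or INT_16
samples, which covers amplifier exports and this package's own output.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .recording import EEGRecording

_HEADER_MAGIC = "Brain Vision Data Exchange Header File Version 1.0"


def write_brainvision(rec: EEGRecording, vhdr_path: str | Path) -> Path:
    """Write ``rec`` as a BrainVision triad next to ``vhdr_path``.

    Data are stored multiplexed as IEEE float32 microvolts
    (resolution 1).
    """
    vhdr_path = Path(vhdr_path)
    stem = vhdr_path.stem
    eeg_path = vhdr_path.with_suffix(".eeg")
    vmrk_path = vhdr_path.with_suffix(".vmrk")

    interval_us = 1e6 / rec.sampling_rate
    lines = [
        _HEADER_MAGIC,
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_path.name}",
        f"MarkerFile={vmrk_path.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={interval_us:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, name in enumerate(rec.channel_names, start=1):
        lines.append(f"Ch{i}={name},,1,µV")
    vhdr_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    vmrk_path.write_text(
        "Brain Vision Data Exchange Marker File, Version 1.0\n\n"
        "[Common Infos]\n"
        f"DataFile={eeg_path.name}\n\n"
        "[Marker Infos]\n"
        "Mk1=New Segment,,1,1,0\n",
        encoding="utf-8",
    )

    eeg_path.write_bytes(rec.data.T.astype("<f4").tobytes())
    return vhdr_path


def _parse_vhdr(text: str) -> tuple[dict[str, str], dict[str, str]]:
    common: dict[str, str] = {}
    channels: dict[str, str] = {}
    section = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(";"):
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].lower()
            continue
        if "=" not in line:
            continue
        key, value = line.split("=", 1)
        if section in ("common infos", "binary infos"):
            common[key.strip().lower()] = value.strip()
        elif section == "channel infos":
            channels[key.strip().lower()] = value.strip()
    return common, channels


def read_brainvision(vhdr_path: str | Path) -> EEGRecording:
    """Read a BrainVision triad given its ``.vhdr`` header file."""
    vhdr_path = Path(vhdr_path)
    text = vhdr_path.read_text(encoding="utf-8", errors="replace")
    if _HEADER_MAGIC.rsplit(" ", 1)[0] not in text.splitlines()[0]:
        raise ValueError(f"not a BrainVision header: {vhdr_path}")
    common, channel_info = _parse_vhdr(text)

    if common.get("dataformat", "BINARY").upper() != "BINARY":
        raise ValueError("only BINARY BrainVision data are supported")
    orientation = common.get("dataorientation", "MULTIPLEXED").upper()
    if orientation != "MULTIPLEXED":
        raise ValueError("only MULTIPLEXED orientation is supported")
    fmt = common.get("binaryformat", "IEEE_FLOAT_32").upper()
    n_channels = int(common["numberofchannels"])
    fs = 1e6 / float(common["samplinginterval"])

    names: list[str] = []
    scales: list[float] = []
    for i in range(1, n_channels + 1):
        entry = channel_info.get(f"ch{i}")
        if entry is None:
            raise ValueError(f"missing Ch{i} in {vhdr_path}")
        parts = entry.split(",")
        names.append(parts[0])
        res = parts[2] if len(parts) > 2 and parts[2] else "1"
        scales.append(float(res))

    eeg_path = vhdr_path.parent / common["datafile"]
    raw = eeg_path.read_bytes()
    if fmt == "IEEE_FLOAT_32":
        flat = np.frombuffer(raw, dtype="<f4")
    elif fmt == "INT_16":
        flat = np.frombuffer(raw, dtype="<i2").astype(float)
    else:
        raise ValueError(f"unsupported BinaryFormat: {fmt}")
    n_samples = flat.size // n_channels
    data = flat[: n_samples * n_channels].reshape(n_samples, n_channels).T
    data = data * np.asarray(scales)[:, None]
    return EEGRecording(
        data=np.ascontiguousarray(data, dtype=float),
        sampling_rate=fs,
        channel_names=names,
    )
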