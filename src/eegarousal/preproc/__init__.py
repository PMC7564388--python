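"""EEG file IO and the preprocessing chain (filter, resample, segment,
artifact flagging, graphoelement detection)."""

from .recording import (
    EEGRecording,
    DEFAULT_MONTAGE,
    ROLE_MAP,
    assign_roles,
)
from .edf import read_edf, write_edf
from .brainvision import read_brainvision, write_brainvision
from .chain import (
    EpochGrid,
    ArtifactParams,
    GraphoelementParams,
    preprocess,
    segment,
    mark_artifacts,
    detect_graphoelements,
    read_annotation_overrides,
)


def read_eeg(path, format=None):
    """Read an EEG file, dispatching on ``format`` or the file suffix.

    Supported formats: ``"edf"`` and ``"brainvision"`` (pass the
    ``.vhdr`` header file).
    """
    from pathlib import Path

    p = Path(path)
    if format is None:
        format = {".edf": "edf", ".vhdr": "brainvision"}.get(p.suffix.lower())
    if format == "edf":
        return read_edf(p)
    if format == "brainvision":
        return read_brainvision(p)
    raise ValueError(f"unsupported EEG format for {path!r}: {format!r}")


def write_eeg(rec, path, format=None):
    """Write an EEG file; counterpart of :func:`read_eeg`."""
    from pathlib import Path

    p = Path(path)
    if format is None:
        format = {".edf": "edf", ".vhdr": "brainvision"}.get(p.suffix.lower())
    if format == "edf":
        return write_edf(rec, p)
    if format == "brainvision":
        return write_brainvision(rec, p)
    raise ValueError(f"unsupported EEG format for {path!r}: {format!r}")


__all__ = [
    "EEGRecording",
    "DEFAULT_MONTAGE",
    "ROLE_MAP",
    "assign_roles",
    "read_eeg",
    "write_eeg",
    "read_edf",
    "write_edf",
    "read_brainvision",
    "write_brainvision",
    "EpochGrid",
    "ArtifactParams",
    "GraphoelementParams",
    "preprocess",
    "segment",
    "mark_artifacts",
    "detect_graphoelements",
    "read_annotation_overrides",
]
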