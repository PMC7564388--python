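"""Vigilance-stage vocabulary and per-second stage sequences.

A 20-minute resting recording is classified second by second into one of
seven vigilance stages spanning the continuum from active wakefulness to
sleep onset:

====== =====================================================
Stage  Meaning
====== =====================================================
0      low-voltage EEG without slow horizontal eye movements
A1     dominant alpha rhythm, occipital centre of gravity
A2     dominant alpha rhythm, central centre of gravity
A3     dominant alpha rhythm, frontal centre of gravity
B1     low-amplitude non-alpha EEG with slow eye movements
B2/3   high delta and theta power
C      sleep onset (sleep spindles / K-complexes)
====== =====================================================

Segments excluded from classification carry the sentinel label
``ARTIFACT``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

STAGE_0 = "0"
STAGE_A1 = "A1"
STAGE_A2 = "A2"
STAGE_A3 = "A3"
STAGE_B1 = "B1"
STAGE_B23 = "B2/3"
STAGE_C = "C"
ARTIFACT = "ARTIFACT"

#: The seven classifiable vigilance stages, high arousal first.
STAGES: tuple[str, ...] = (
    STAGE_0,
    STAGE_A1,
    STAGE_A2,
    STAGE_A3,
    STAGE_B1,
    STAGE_B23,
    STAGE_C,
)

#: Full label vocabulary including the artifact sentinel.
LABELS: tuple[str, ...] = STAGES + (ARTIFACT,)

A_STAGES = frozenset({STAGE_A1, STAGE_A2, STAGE_A3})
#: Stages counted as "0/A" for the predominance criteria.
ZERO_A = frozenset({STAGE_0, STAGE_A1, STAGE_A2, STAGE_A3})
#: Stages counted as "0/A1" for the strictest predominance criterion.
ZERO_A1 = frozenset({STAGE_0, STAGE_A1})

#: Segments per recording (20 min at one segment per second).
RECORDING_SEGMENTS = 1200


def validate_labels(labels: Iterable[str], *, allow_artifact: bool = True) -> list[str]:
    """Return ``labels`` as a list, raising ``ValueError`` on unknown stages."""
    allowed = set(LABELS) if allow_artifact else set(STAGES)
    out = list(labels)
    bad = sorted({lab for lab in out if lab not in allowed})
    if bad:
        raise ValueError(f"unknown stage labels: {bad}")
    return out


@dataclass
class StageSequence:
    """Per-second stage labels for one recording.

    Parameters
    ----------
    labels
        One label per 1-s segment, each in :data:`LABELS`.
    """

    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = validate_labels(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, i):
        return self.labels[i]

    @property
    def n_classified(self) -> int:
        """Number of non-artifact segments."""
        return sum(1 for lab in self.labels if lab != ARTIFACT)

    def to_tsv(self, path: str | Path) -> None:
        """Write the sequence as TSV with columns ``segment_index``, ``stage``."""
        lines = ["segment_index\tstage"]
        lines += [f"{i}\t{lab}" for i, lab in enumerate(self.labels)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StageSequence":
        """Read a sequence written by :meth:`to_tsv` (rows may be unordered)."""
        rows: dict[int, str] = {}
        text = Path(path).read_text().strip().splitlines()
        if not text:
            raise ValueError(f"empty stage file: {path}")
        header = text[0].rstrip("\n").split("\t")
        try:
            idx_col = header.index("segment_index")
            stage_col = header.index("stage")
        except ValueError as exc:
            raise ValueError(f"missing columns in {path}: {header}") from exc
        for line in text[1:]:
            parts = line.rstrip("\n").split("\t")
            rows[int(parts[idx_col])] = parts[stage_col]
        missing = set(range(len(rows))) - set(rows)
        if missing:
            raise ValueError(f"non-contiguous segment indices in {path}")
        return cls([rows[i] for i in range(len(rows))])


def stage_script_to_tsv(labels: Sequence[str], path: str | Path) -> None:
    """Write a ground-truth stage script as TSV.

    Columns: ``segment_index`` (0-based), ``onset_s``, ``stage``.
    """
    validate_labels(labels, allow_artifact=False)
    lines = ["segment_index\tonset_s\tstage"]
    lines += [f"{i}\t{i}\t{lab}" for i, lab in enumerate(labels)]
    Path(path).write_text("\n".join(lines) + "\n")


def stage_script_from_tsv(path: str | Path) -> list[str]:
    """Read a stage script written by :func:`stage_script_to_tsv`."""
    text = Path(path).read_text().strip().splitlines()
    header = text[0].split("\t")
    idx_col = header.index("segment_index")
    stage_col = header.index("stage")
    rows = {}
    for line in text[1:]:
        parts = line.split("\t")
        rows[int(parts[idx_col])] = parts[stage_col]
    return validate_labels(
        [rows[i] for i in range(len(rows))], allow_artifact=False
    )
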