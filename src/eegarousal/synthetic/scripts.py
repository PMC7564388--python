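"""Ground-truth per-second stage trajectories ("stage scripts").

Two canonical profiles are provided: ``hyperaroused`` subjects remain in
high-arousal stages (0/A1) for the whole recording, while ``declining``
subjects pass through B1, B2/3 and C at configurable emergence minutes,
with per-epoch stage fractions guaranteed to reach the scoring
thresholds.  A ``custom`` profile accepts arbitrary emergence minutes
without ordering checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..stages import (
    RECORDING_SEGMENTS,
    STAGE_0,
    STAGE_A1,
    STAGE_B1,
    STAGE_B23,
    STAGE_C,
    validate_labels,
)

PROFILES = ("hyperaroused", "declining", "custom")

#: Fraction of a minute's segments given to an emerging stage.  Chosen
#: above the 1/3 emergence threshold with margin, so that occasional
#: misclassification in the EEG round-trip does not drop the epoch
#: below threshold.
EMERGENCE_FILL = 0.5


@dataclass
class StageScript:
    """A 1200-label ground-truth trajectory with its provenance."""

    labels: list[str]
    seed: int
    profile_name: str

    def __post_init__(self):
        self.labels = validate_labels(self.labels, allow_artifact=False)
        if len(self.labels) != RECORDING_SEGMENTS:
            raise ValueError(
                f"a stage script has exactly {RECORDING_SEGMENTS} labels, "
                f"got {len(self.labels)}"
            )

    def __len__(self) -> int:
        return len(self.labels)


def _validate_minutes(params: dict, ordered: bool) -> dict[str, int]:
    minutes = {
        stage: int(params[stage])
        for stage in (STAGE_B1, STAGE_B23, STAGE_C)
        if stage in params
    }
    for stage, minute in minutes.items():
        if not (1 <= minute <= 20):
            raise ValueError(f"emergence minute for {stage} out of 1..20: {minute}")
    if ordered:
        seq = [minutes[s] for s in (STAGE_B1, STAGE_B23, STAGE_C) if s in minutes]
        if any(a > b for a, b in zip(seq, seq[1:])):
            raise ValueError(
                "declining profile requires emergence order B1 <= B2/3 <= C; "
                "use profile='custom' for other orderings"
            )
    return minutes


def generate_stage_script(
    profile: str, params: dict | None = None, seed: int = 0
) -> StageScript:
    """Generate a ground-truth stage script.

    Parameters
    ----------
    profile
        ``"hyperaroused"`` — labels drawn from {0, A1} only, A1
        predominant in every minute.
        ``"declining"`` / ``"custom"`` — ``params`` maps stage labels
        (``"B1"``, ``"B2/3"``, ``"C"``) to 1-based emergence minutes;
        the declining profile enforces B1 <= B2/3 <= C among the minutes
        given.  Optional ``params["c_count"]`` sets how many C segments
        are placed in the C emergence minute (default 1).
    seed
        Seeds a dedicated random generator; scripts are reproducible.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; expected one of {PROFILES}")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    n_min = RECORDING_SEGMENTS // 60

    if profile == "hyperaroused":
        # A1-dominant wakefulness with brief desynchronized (stage 0)
        # interludes; every minute stays > 2/3 in {0, A1} by construction.
        labels = [STAGE_A1] * RECORDING_SEGMENTS
        for minute in range(n_min):
            n_zero = int(rng.integers(0, 9))  # up to 8 s of stage 0
            start = 60 * minute + int(rng.integers(0, 60 - n_zero + 1))
            labels[start : start + n_zero] = [STAGE_0] * n_zero
        return StageScript(labels, seed, profile)

    minutes = _validate_minutes(params, ordered=(profile == "declining"))
    c_count = int(params.get("c_count", 1))
    fill = float(params.get("fill_fraction", EMERGENCE_FILL))

    labels = [STAGE_A1] * RECORDING_SEGMENTS
    # Background stage per minute: from each emergence minute onwards the
    # newest (deepest) emerged stage shares the minute with the previous
    # background.
    current = STAGE_A1
    for minute in range(1, n_min + 1):
        emerged = [s for s in (STAGE_B1, STAGE_B23) if minutes.get(s) == minute]
        for stage in emerged:
            current = stage
        if current != STAGE_A1:
            seg0 = 60 * (minute - 1)
            n_fill = int(round(fill * 60))
            # contiguous run, placed at a seeded offset inside the minute
            start = seg0 + int(rng.integers(0, 60 - n_fill + 1))
            labels[start : start + n_fill] = [current] * n_fill
    if STAGE_C in minutes:
        seg0 = 60 * (minutes[STAGE_C] - 1)
        spots = rng.choice(60, size=min(c_count, 60), replace=False)
        for spot in spots:
            labels[seg0 + spot] = STAGE_C
    return StageScript(labels, seed, profile)
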