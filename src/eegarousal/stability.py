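"""Arousal Stability Score (1-14) and the hyperarousal dichotomy.

The score summarizes how quickly arousal declines over a 20-minute
resting recording of 1200 one-second stage labels.  The recording is cut
into twenty 1-min epochs grouped in four 5-min blocks.  Fourteen ordered
criteria are evaluated:

* scores 1-4   — at least one C segment; value = block of its earliest
  occurrence (block 1 -> 1, ..., block 4 -> 4);
* scores 5-8   — some epoch has >= 1/3 of its classified segments in
  B2/3; value = 4 + block of the earliest such epoch;
* scores 9-12  — likewise for B1; value = 8 + block;
* score 13     — every evaluable epoch has > 2/3 of segments in {0, A};
* score 14     — every evaluable epoch has > 2/3 of segments in {0, A1}.

Lower values mean earlier/deeper decline.  When several decline criteria
fire the minimum (deepest) value wins; 14 is preferred over 13 when both
predominance criteria hold.  Scores >= 13 define the hyperaroused group.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .stages import (
    ARTIFACT,
    STAGE_B1,
    STAGE_B23,
    STAGE_C,
    STAGES,
    ZERO_A,
    ZERO_A1,
    StageSequence,
)

HYPERAROUSED = "hyperaroused"
NON_HYPERAROUSED = "non_hyperaroused"


@dataclass(frozen=True)
class ScoringRules:
    """Numeric constants of the scoring grid.

    The defaults encode the published criteria; they are exposed so the
    brute-force oracle in the test-suite can share them.
    """

    predominance_fraction: float = 2.0 / 3.0  # strict ">"
    emergence_fraction: float = 1.0 / 3.0  # ">="
    epoch_length: int = 60  # s, the 1-min epoch
    block_length: int = 300  # s, the 5-min block
    cutoff: int = 13  # hyperaroused iff score >= cutoff

    def __post_init__(self) -> None:
        if not (0 < self.predominance_fraction < 1):
            raise ValueError("predominance_fraction must be in (0,1)")
        if not (0 < self.emergence_fraction < 1):
            raise ValueError("emergence_fraction must be in (0,1)")
        if self.block_length % self.epoch_length:
            raise ValueError("block_length must be a multiple of epoch_length")

    @property
    def n_epochs(self) -> int:
        return 1200 // self.epoch_length

    @property
    def epochs_per_block(self) -> int:
        return self.block_length // self.epoch_length


@dataclass
class StabilityResult:
    """Outcome of scoring one stage sequence."""

    score: int
    triggered_rule: str
    group: str
    fallback_used: bool
    per_epoch_fractions: list[dict[str, float]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "StabilityResult":
        return cls(**json.loads(Path(path).read_text()))


def epoch_fractions(
    seq: StageSequence, rules: ScoringRules | None = None
) -> list[dict[str, float]]:
    """Per-epoch stage fractions over the classified (non-artifact) segments.

    Returns one dict per 1-min epoch mapping each stage to its fraction
    of that epoch's classified segments.  An epoch in which every segment
    is an artifact is unevaluable: all its fractions are NaN.
    """
    rules = rules or ScoringRules()
    if len(seq) != 1200:
        raise ValueError(f"expected 1200 segments, got {len(seq)}")
    out: list[dict[str, float]] = []
    step = rules.epoch_length
    for start in range(0, 1200, step):
        chunk = seq.labels[start : start + step]
        classified = [lab for lab in chunk if lab != ARTIFACT]
        if not classified:
            out.append({stage: math.nan for stage in STAGES})
            continue
        n = len(classified)
        out.append(
            {stage: sum(1 for lab in classified if lab == stage) / n for stage in STAGES}
        )
    return out


def _block_of_epoch(epoch_idx: int, rules: ScoringRules) -> int:
    """1-based block (1..4) containing the 0-based 1-min epoch index."""
    return epoch_idx // rules.epochs_per_block + 1


def arousal_stability_score(
    seq: StageSequence, rules: ScoringRules | None = None
) -> StabilityResult:
    """Score a 1200-segment stage sequence on the 1-14 stability scale."""
    rules = rules or ScoringRules()
    if len(seq) != 1200:
        raise ValueError(f"expected 1200 segments, got {len(seq)}")
    if seq.n_classified == 0:
        raise ValueError("unscorable: sequence has zero classified segments")

    fractions = epoch_fractions(seq, rules)
    fired: list[tuple[int, str]] = []

    # Scores 1-4: earliest C segment, by block of its second.
    c_first = next((i for i, lab in enumerate(seq.labels) if lab == STAGE_C), None)
    if c_first is not None:
        block = c_first // rules.block_length + 1
        fired.append((block, f"C emerged in block {block}"))

    # Scores 5-8 (B2/3) and 9-12 (B1): earliest epoch reaching the
    # emergence fraction.
    for stage, base in ((STAGE_B23, 4), (STAGE_B1, 8)):
        for epoch_idx, frac in enumerate(fractions):
            value = frac[stage]
            if not math.isnan(value) and value >= rules.emergence_fraction:
                block = _block_of_epoch(epoch_idx, rules)
                fired.append((base + block, f"{stage} emerged in block {block}"))
                break

    if fired:
        score, rule = min(fired)
        group = assign_group(score, rules)
        return StabilityResult(score, rule, group, False, fractions)

    # Scores 13/14: predominance of 0/A (13) or 0/A1 (14) in every
    # evaluable epoch; 14 preferred when both hold.
    evaluable = [f for f in fractions if not math.isnan(f[STAGES[0]])]

    def _predominant(stage_set) -> bool:
        return all(
            sum(f[s] for s in stage_set) > rules.predominance_fraction
            for f in evaluable
        )

    if _predominant(ZERO_A1):
        return StabilityResult(
            14, "0/A1 predominant in every epoch", HYPERAROUSED, False, fractions
        )
    if _predominant(ZERO_A):
        return StabilityResult(
            13, "0/A predominant in every epoch", HYPERAROUSED, False, fractions
        )

    # No criterion fired (diffuse sub-threshold decline): report the
    # closest non-hyperaroused score and flag the fallback for audit.
    return StabilityResult(
        12, "fallback: no criterion fired", NON_HYPERAROUSED, True, fractions
    )


def assign_group(score: int, rules: ScoringRules | None = None) -> str:
    """Dichotomize a stability score into the arousal group."""
    rules = rules or ScoringRules()
    if not (1 <= score <= 14):
        raise ValueError(f"score out of range [1,14]: {score}")
    return HYPERAROUSED if score >= rules.cutoff else NON_HYPERAROUSED
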