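"""Stage-faithful synthetic EEG.

Every second of the output carries the spectral/EOG signature of its
stage label:

* ``A1``/``A2``/``A3`` — an alpha sinusoid whose amplitude peaks on the
  occipital / central / frontal ROI respectively;
* ``0`` — broadband low-voltage noise, flat EOG;
* ``B1`` — low-voltage noise plus a slow sinusoidal horizontal EOG sweep;
* ``B2/3`` — strong delta/theta sinusoids;
* ``C`` — attenuated delta/theta background plus a sleep-spindle burst
  or a K-complex-like biphasic transient on the central ROI.

Amplitudes are defaults of this artifact, chosen so the default
classifier thresholds separate the stages with margin; no attempt is
made at realistic 1/f texture or volume conduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..preproc.recording import (
    CENTRAL,
    DEFAULT_MONTAGE,
    EOG,
    FRONTAL,
    OCCIPITAL,
    OTHER,
    EEGRecording,
    assign_roles,
)
from ..stages import (
    STAGE_0,
    STAGE_A1,
    STAGE_A2,
    STAGE_A3,
    STAGE_B1,
    STAGE_B23,
    STAGE_C,
    validate_labels,
)
from .scripts import StageScript


@dataclass(frozen=True)
class SynthesisConfig:
    """Signal parameters of the synthetic EEG generator (all µV / Hz)."""

    sampling_rate: int = 1000
    channel_names: tuple[str, ...] = DEFAULT_MONTAGE
    alpha_freq: float = 10.0
    alpha_amp_occipital: float = 30.0
    low_voltage_amp: float = 4.0  # RMS of the stage-0/B1 background
    delta_theta_amp: float = 20.0  # per delta/theta component
    spindle_freq: float = 13.0
    spindle_amp: float = 50.0
    kcomplex_amp: float = 75.0
    sem_freq: float = 0.25
    sem_amp: float = 120.0  # EOG sweep amplitude
    noise_amp: float = 3.0  # RMS of the everywhere-noise

    def __post_init__(self):
        if self.sampling_rate < 200:
            raise ValueError("sampling_rate must be >= 200 Hz")
        for name in (
            "alpha_amp_occipital",
            "low_voltage_amp",
            "delta_theta_amp",
            "spindle_amp",
            "kcomplex_amp",
            "sem_amp",
            "noise_amp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


#: Relative alpha amplitude per (stage, role); scaled by
#: ``alpha_amp_occipital``.  The dominant ROI carries the full
#: amplitude, the others enough to keep the segment alpha-dominant
#: overall while preserving a clear ROI argmax.
_ALPHA_TOPOGRAPHY = {
    STAGE_A1: {OCCIPITAL: 1.0, CENTRAL: 0.4, FRONTAL: 0.2, OTHER: 0.4},
    STAGE_A2: {OCCIPITAL: 0.4, CENTRAL: 1.0, FRONTAL: 0.4, OTHER: 0.4},
    STAGE_A3: {OCCIPITAL: 0.2, CENTRAL: 0.4, FRONTAL: 1.0, OTHER: 0.4},
}


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of contiguous True runs."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out


def synthesize_eeg(
    script: StageScript | Sequence[str],
    config: SynthesisConfig | None = None,
    seed: int = 0,
) -> EEGRecording:
    """Render a stage script into a multichannel µV recording.

    ``script`` may be a :class:`StageScript` or any sequence of stage
    labels (one per second); the output duration equals the label count.
    Generation is bit-reproducible for a given ``(script, config, seed)``.
    """
    config = config or SynthesisConfig()
    labels = script.labels if isinstance(script, StageScript) else list(script)
    labels = validate_labels(labels, allow_artifact=False)
    if not labels:
        raise ValueError("empty stage script")

    fs = int(config.sampling_rate)
    n_sec = len(labels)
    n_samples = n_sec * fs
    names = list(config.channel_names)
    roles = assign_roles(names)
    role_rows = {
        role: [i for i, name in enumerate(names) if roles[name] == role]
        for role in (OCCIPITAL, CENTRAL, FRONTAL, OTHER, EOG)
    }
    eeg_rows = [i for i, name in enumerate(names) if roles[name] != EOG]

    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / fs
    data = rng.normal(0.0, config.noise_amp, size=(len(names), n_samples))

    alpha_wave = np.sin(2 * np.pi * config.alpha_freq * t)
    theta_wave = config.delta_theta_amp * (
        np.sin(2 * np.pi * 3.0 * t) + np.sin(2 * np.pi * 5.5 * t + 1.0)
    )
    labels_arr = np.array(labels)

    # --- alpha stages: per-second ROI-weighted amplitude
    for stage, topo in _ALPHA_TOPOGRAPHY.items():
        for sec in np.nonzero(labels_arr == stage)[0]:
            sl = slice(sec * fs, (sec + 1) * fs)
            for role, weight in topo.items():
                rows = role_rows[role]
                if rows:
                    data[rows, sl] += (
                        weight * config.alpha_amp_occipital * alpha_wave[sl]
                    )

    # --- low-voltage stages: extra broadband noise up to the configured RMS
    lv_extra = max(config.low_voltage_amp**2 - config.noise_amp**2, 0.0) ** 0.5
    if lv_extra > 0:
        for sec in np.nonzero((labels_arr == STAGE_0) | (labels_arr == STAGE_B1))[0]:
            sl = slice(sec * fs, (sec + 1) * fs)
            data[eeg_rows, sl] += rng.normal(0.0, lv_extra, size=(len(eeg_rows), fs))

    # --- delta/theta background (full for B2/3, halved under graphoelements)
    for sec in np.nonzero(labels_arr == STAGE_B23)[0]:
        sl = slice(sec * fs, (sec + 1) * fs)
        data[eeg_rows, sl] += theta_wave[sl]
    for sec in np.nonzero(labels_arr == STAGE_C)[0]:
        sl = slice(sec * fs, (sec + 1) * fs)
        data[eeg_rows, sl] += 0.5 * theta_wave[sl]

    # --- slow horizontal eye movements on contiguous B1 runs
    eog_rows = role_rows[EOG]
    if eog_rows:
        for start, stop in _runs(labels_arr == STAGE_B1):
            sl = slice(start * fs, stop * fs)
            phase = 2 * np.pi * config.sem_freq * (t[sl] - t[sl.start])
            sweep = config.sem_amp * np.sin(phase)
            data[eog_rows[0], sl] += sweep
            if len(eog_rows) > 1:  # vertical EOG picks up a reduced sweep
                data[eog_rows[1], sl] += 0.3 * sweep

    # --- C stages: spindle burst or K-complex on the central ROI
    central = role_rows[CENTRAL] or eeg_rows
    for sec in np.nonzero(labels_arr == STAGE_C)[0]:
        kind = rng.choice(["spindle", "kcomplex"])
        if kind == "spindle":
            dur = 0.8
            n_burst = int(dur * fs)
            offset = int(rng.integers(0, fs - n_burst + 1))
            start = sec * fs + offset
            tt = np.arange(n_burst) / fs
            envelope = np.hanning(n_burst)
            burst = config.spindle_amp * envelope * np.sin(
                2 * np.pi * config.spindle_freq * tt
            )
            data[central, start : start + n_burst] += burst
        else:
            dur = 0.8
            n_kc = int(dur * fs)
            offset = int(rng.integers(0, fs - n_kc + 1))
            start = sec * fs + offset
            tt = np.arange(n_kc) / fs
            # single biphasic cycle, tapered: sharp negative then positive
            shape = -np.sin(2 * np.pi * tt / dur) * np.hanning(n_kc) ** 0.5
            data[central, start : start + n_kc] += config.kcomplex_amp * shape

    return EEGRecording(
        data=data,
        sampling_rate=fs,
        channel_names=names,
        start_time="00.00.00",
    )
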