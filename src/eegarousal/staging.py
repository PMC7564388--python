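"""Per-second vigilance stage classification from spectral + EOG features.

Each non-artifact 1-s segment is mapped to one of the seven vigilance
stages through a fixed decision cascade (first match wins):

1. graphoelement present                          -> C
2. delta/theta dominant and alpha not dominant    -> B2/3
3. alpha dominant -> substage by the ROI with the most alpha power
   (occipital -> A1, central -> A2, frontal -> A3; ties favour the
   posterior ROI)
4. low-voltage   -> B1 if slow eye movements else 0
5. fallback      -> B1 if slow eye movements else 0

The numeric thresholds are this package's defaults (tuned against the
synthetic generator and exposed in configuration); the published
algorithm's constants live in its own manual and are not reproduced
here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .preproc.chain import EpochGrid
from .preproc.recording import CENTRAL, EOG, FRONTAL, OCCIPITAL, EEGRecording
from .stages import (
    ARTIFACT,
    STAGE_0,
    STAGE_A1,
    STAGE_A2,
    STAGE_A3,
    STAGE_B1,
    STAGE_B23,
    STAGE_C,
    StageSequence,
)

#: Spectral band edges, Hz (inclusive at 1 Hz periodogram resolution).
ALPHA_BAND = (8.0, 12.0)
DELTA_THETA_BAND = (2.0, 7.0)
TOTAL_BAND = (2.0, 30.0)


@dataclass(frozen=True)
class ClassifierThresholds:
    """Decision-cascade constants (package defaults, configurable)."""

    alpha_dominance_fraction: float = 0.4
    low_voltage_rms: float = 10.0  # µV
    delta_theta_ratio: float = 0.5
    sem_band: tuple[float, float] = (0.1, 1.0)  # Hz
    sem_amp: float = 60.0  # µV peak-to-peak on filtered EOG

    def __post_init__(self):
        if not (0 < self.alpha_dominance_fraction < 1):
            raise ValueError("alpha_dominance_fraction must be in (0,1)")
        if not (0 < self.delta_theta_ratio < 1):
            raise ValueError("delta_theta_ratio must be in (0,1)")
        if self.low_voltage_rms <= 0 or self.sem_amp <= 0:
            raise ValueError("amplitudes must be positive")


@dataclass
class EpochFeatures:
    """Spectral and EOG features of one 1-s segment."""

    alpha_power: dict[str, float]  # per ROI, µV²
    delta_theta_power: float  # µV²
    total_power: float  # µV²
    alpha_fraction: float
    rms_amplitude: float  # µV
    sem_present: bool
    graphoelement_present: bool = False


def _band_power(psd: np.ndarray, freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return psd[..., mask].sum(axis=-1)


def _segment_psd(data: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Boxcar periodogram of each channel row; power per 1-Hz bin, µV²."""
    freqs, psd = scipy.signal.periodogram(
        data, fs=fs, window="boxcar", detrend="constant", axis=-1
    )
    # integrate to per-bin power so band sums are in µV²
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0
    return freqs, psd * df


def compute_features(
    segment: np.ndarray,
    roles_by_index: dict[int, str],
    thresholds: ClassifierThresholds | None = None,
    *,
    sem_present: bool | None = None,
    graphoelement_present: bool = False,
    fs: float = 100.0,
) -> EpochFeatures:
    """Compute :class:`EpochFeatures` for one channels x samples segment.

    ``roles_by_index`` maps row index to a channel role.  When
    ``sem_present`` is not supplied it is estimated from the segment's
    EOG rows alone (peak-to-peak of the detrended EOG against the SEM
    amplitude threshold); recording-level classification passes a
    context-aware value instead.
    """
    thresholds = thresholds or ClassifierThresholds()
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    eeg_rows = [i for i, r in roles_by_index.items() if r != EOG]
    eog_rows = [i for i, r in roles_by_index.items() if r == EOG]

    freqs, psd = _segment_psd(segment, fs)
    alpha_by_roi: dict[str, float] = {}
    for roi in (OCCIPITAL, CENTRAL, FRONTAL):
        rows = [i for i in eeg_rows if roles_by_index[i] == roi]
        alpha_by_roi[roi] = (
            float(_band_power(psd[rows], freqs, ALPHA_BAND).mean()) if rows else 0.0
        )
    alpha = float(_band_power(psd[eeg_rows], freqs, ALPHA_BAND).mean()) if eeg_rows else 0.0
    dt = (
        float(_band_power(psd[eeg_rows], freqs, DELTA_THETA_BAND).mean())
        if eeg_rows
        else 0.0
    )
    total = float(_band_power(psd[eeg_rows], freqs, TOTAL_BAND).mean()) if eeg_rows else 0.0
    alpha_fraction = alpha / total if total > 0 else 0.0
    rms = float(np.sqrt(np.mean(segment[eeg_rows] ** 2))) if eeg_rows else 0.0

    if sem_present is None:
        if eog_rows:
            eog = segment[eog_rows] - segment[eog_rows].mean(axis=-1, keepdims=True)
            p2p = (eog.max(axis=-1) - eog.min(axis=-1)).max()
            sem_present = bool(p2p >= thresholds.sem_amp)
        else:
            warnings.warn("no EOG channel: sem_present defaults to False")
            sem_present = False

    return EpochFeatures(
        alpha_power=alpha_by_roi,
        delta_theta_power=dt,
        total_power=total,
        alpha_fraction=float(alpha_fraction),
        rms_amplitude=rms,
        sem_present=bool(sem_present),
        graphoelement_present=bool(graphoelement_present),
    )


def classify_stage(
    f: EpochFeatures, t: ClassifierThresholds | None = None
) -> str:
    """Apply the decision cascade to one segment's features."""
    t = t or ClassifierThresholds()
    if f.graphoelement_present:
        return STAGE_C
    dt_ratio = f.delta_theta_power / f.total_power if f.total_power > 0 else 0.0
    alpha_dominant = f.alpha_fraction >= t.alpha_dominance_fraction
    if dt_ratio > t.delta_theta_ratio and not alpha_dominant:
        return STAGE_B23
    if alpha_dominant:
        # ROI argmax; ties resolved posterior-first (occipital > central
        # > frontal), matching the prevalence of posterior alpha
        order = (OCCIPITAL, CENTRAL, FRONTAL)
        best = max(order, key=lambda roi: (f.alpha_power.get(roi, 0.0), -order.index(roi)))
        return {OCCIPITAL: STAGE_A1, CENTRAL: STAGE_A2, FRONTAL: STAGE_A3}[best]
    if f.rms_amplitude < t.low_voltage_rms:
        return STAGE_B1 if f.sem_present else STAGE_0
    return STAGE_B1 if f.sem_present else STAGE_0


def _sem_flags(rec: EEGRecording, n_segments: int, t: ClassifierThresholds) -> np.ndarray:
    """Slow-eye-movement presence per segment from the EOG channels.

    The EOG is band-passed to the SEM band and each segment's
    peak-to-peak is measured over a 3-s window centred on the segment
    (slow sweeps outlast a single second).
    """
    eog_rows = rec.channels_with_role(EOG)
    flags = np.zeros(n_segments, dtype=bool)
    if not eog_rows:
        warnings.warn("no EOG channel: slow-eye-movement detection disabled")
        return flags
    fs = int(rec.sampling_rate)
    low, high = t.sem_band
    sos = scipy.signal.butter(2, [low, high], btype="bandpass", fs=fs, output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, rec.data[eog_rows], axis=-1)
    for i in range(n_segments):
        lo = max((i - 1) * fs, 0)
        hi = min((i + 2) * fs, filtered.shape[1])
        window = filtered[:, lo:hi]
        p2p = (window.max(axis=-1) - window.min(axis=-1)).max()
        flags[i] = p2p >= t.sem_amp
    return flags


def classify_recording(
    grid: EpochGrid, thresholds: ClassifierThresholds | None = None
) -> StageSequence:
    """Classify every segment of a grid; artifact segments get ARTIFACT."""
    thresholds = thresholds or ClassifierThresholds()
    rec = grid.rec
    rec.require_staging_channels()
    n = grid.n_segments
    roles_by_index = {
        i: rec.channel_roles[name] for i, name in enumerate(rec.channel_names)
    }
    sem = _sem_flags(rec, n, thresholds)
    labels: list[str] = []
    for i in range(n):
        if grid.artifact_flags[i]:
            labels.append(ARTIFACT)
            continue
        feats = compute_features(
            grid.segment_data(i),
            roles_by_index,
            thresholds,
            sem_present=bool(sem[i]),
            graphoelement_present=bool(grid.graphoelement_flags[i]),
            fs=rec.sampling_rate,
        )
        labels.append(classify_stage(feats, thresholds))
    return StageSequence(labels)
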