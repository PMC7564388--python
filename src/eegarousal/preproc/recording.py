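"""Multichannel EEG recordings with channel-role metadata.

Channel roles drive both the synthetic generator and the stage
classifier: alpha topography is compared across the occipital, central
and frontal regions of interest (ROIs), and slow eye movements are read
from the EOG channels.  Roles are auto-assigned from standard 10-20
labels via :data:`ROLE_MAP`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

OCCIPITAL = "occipital"
CENTRAL = "central"
FRONTAL = "frontal"
OTHER = "other"
EOG = "eog"

ROIS = (OCCIPITAL, CENTRAL, FRONTAL)

#: Label -> role assignment for the channels the classifier uses.
#: Unlisted labels get the role "other".
ROLE_MAP: dict[str, str] = {
    "O1": OCCIPITAL,
    "O2": OCCIPITAL,
    "Oz": OCCIPITAL,
    "C3": CENTRAL,
    "C4": CENTRAL,
    "Cz": CENTRAL,
    "F3": FRONTAL,
    "F4": FRONTAL,
    "Fz": FRONTAL,
    "Fp1": FRONTAL,
    "Fp2": FRONTAL,
    "HEOG": EOG,
    "VEOG": EOG,
    "EOGH": EOG,
    "EOGV": EOG,
}

#: 31 extended-10-20 EEG sites plus horizontal/vertical EOG.
DEFAULT_MONTAGE: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "PO9", "PO3", "PO4", "PO10", "O1", "O2",
    "HEOG", "VEOG",
)

#: A reduced montage (one ROI pair each + EOG) for fast runs.
SMALL_MONTAGE: tuple[str, ...] = (
    "O1", "O2", "C3", "C4", "F3", "F4", "HEOG", "VEOG",
)


def assign_roles(channel_names: list[str]) -> dict[str, str]:
    """Map channel labels to roles; case-insensitive on the map keys."""
    lowered = {k.lower(): v for k, v in ROLE_MAP.items()}
    return {name: lowered.get(name.lower(), OTHER) for name in channel_names}


@dataclass
class EEGRecording:
    """Channels x samples voltage data in microvolts.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)``, in microvolts.
    sampling_rate
        Sampling frequency in Hz.
    channel_names
        One 10-20 style label per channel.
    channel_roles
        Optional explicit role map; derived from the labels when absent.
    """

    data: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    channel_roles: dict[str, str] | None = None
    start_time: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel_names length must match data rows")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.channel_roles is None:
            self.channel_roles = assign_roles(self.channel_names)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n_samples / self.sampling_rate

    def channels_with_role(self, role: str) -> list[int]:
        """Indices of channels carrying ``role``."""
        return [
            i
            for i, name in enumerate(self.channel_names)
            if self.channel_roles.get(name) == role
        ]

    def require_staging_channels(self) -> None:
        """Raise naming every ROI/EOG role that has no channel."""
        missing = [
            role for role in (*ROIS, EOG) if not self.channels_with_role(role)
        ]
        if missing:
            raise ValueError(
                "recording lacks channels for roles: " + ", ".join(missing)
            )

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            data=self.data.copy(),
            sampling_rate=self.sampling_rate,
            channel_names=list(self.channel_names),
            channel_roles=dict(self.channel_roles),
            start_time=self.start_time,
        )
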