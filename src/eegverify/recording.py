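"""Core containers for multi-channel EEG data.

A :class:`Recording` holds one subject-session's channel x sample voltage
matrix in microvolts, together with the sampling rate and the 10-20 montage
labels. A :class:`Segment` is a short, fixed-duration window cut from a
recording, the unit on which spectral features are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Canonical 19-electrode 10-20 montage order. All internal matrices use it.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

N_CHANNELS = len(CHANNELS_1020)  # CH = 19


class DataError(ValueError):
    """Raised when input data violate a contract (shape, rate, finiteness)."""


class ConfigurationError(ValueError):
    """Raised when a configuration value is out of its valid range."""


@dataclass
class Recording:
    """One subject-session of multi-channel EEG.

    Parameters
    ----------
    subject_id
        Cohort-unique subject identifier.
    session_index
        1-based chronological session number.
    data
        ``(19, n_samples)`` float array of voltages in microvolts.
    fs
        Sampling rate in samples per second.
    channel_labels
        Channel names; must be the canonical 10-20 set.
    role
        ``"genuine"`` (enrolled, multi-session) or ``"impostor"``
        (external, single-session attacker).
    """

    subject_id: str
    session_index: int
    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = CHANNELS_1020
    role: str = "genuine"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != N_CHANNELS:
            raise DataError(
                f"Recording {self.subject_id}/s{self.session_index}: expected "
                f"({N_CHANNELS}, n) data, got {self.data.shape}"
            )
        if tuple(self.channel_labels) != CHANNELS_1020:
            raise DataError("channel labels must be the canonical 10-20 order")
        if self.fs <= 2 * 70.0:
            raise DataError(f"fs={self.fs} too low: need fs > 140 Hz")
        if not np.all(np.isfinite(self.data)):
            raise DataError(
                f"Recording {self.subject_id}/s{self.session_index} contains "
                "non-finite samples"
            )
        if self.role not in ("genuine", "impostor"):
            raise DataError(f"unknown role {self.role!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray) -> "Recording":
        """Copy of this recording with ``data`` replaced."""
        return replace(self, data=data)


@dataclass
class Segment:
    """A contiguous fixed-length window of a recording (default 7.5 s)."""

    subject_id: str
    session_index: int
    segment_index: int  # 1-based within the session
    data: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != N_CHANNELS:
            raise DataError(f"Segment: expected ({N_CHANNELS}, n), got {self.data.shape}")

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs
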