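"""Continuous multichannel EEG recordings with movement-onset triggers.

A :class:`Recording` is the package's central in-memory container: a few
channels of continuous signal in microvolts (typically C3, C4 and a bipolar
EOG), a sampling rate, and the movement-onset times detected by an external
switch.  Time is measured in seconds with t = 0 at the first sample; all
windows elsewhere in the package are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Recording", "RecordingMeta", "bipolar_eog"]


@dataclass
class RecordingMeta:
    """Run descriptor attached to a recording.

    Parameters
    ----------
    subject : str
        Subject identifier.
    hand : {"left", "right"}
        The moving hand for this run.
    hand_status : {"healthy", "paretic", "non_paretic"}
        Clinical status of the moving hand.
    imi : float or None
        Designated inter-movement interval in seconds (3 / 2 / 1 s in the
        study design; any positive value is accepted).
    session : str
        Session / sub-session identifier.
    """

    subject: str = ""
    hand: str = "right"
    hand_status: str = "healthy"
    imi: float | None = None
    session: str = ""


@dataclass
class Recording:
    """Continuous multichannel signal (µV) with movement-onset triggers.

    Attributes
    ----------
    channels : list of str
        Ordered channel labels, e.g. ``["C3", "C4", "EOG"]``.
    fs : float
        Sampling rate in Hz.
    data : ndarray, shape (n_channels, n_samples)
        Per-channel time series in microvolts.
    triggers : ndarray
        Movement-onset times in seconds from recording start, strictly
        increasing and within ``[0, duration]``.
    meta : RecordingMeta
        Run metadata (subject, hand, designated IMI, ...).
    """

    channels: list[str]
    fs: float
    data: np.ndarray
    triggers: np.ndarray
    meta: RecordingMeta = field(default_factory=RecordingMeta)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.triggers = np.asarray(self.triggers, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_channels, n_samples)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{len(self.channels)} channel labels but data has "
                f"{self.data.shape[0]} rows"
            )
        if self.data.shape[1] == 0:
            raise ValueError("empty recording: zero samples")
        if self.triggers.ndim != 1:
            raise ValueError("triggers must be a 1-D array of onset times")
        if len(self.triggers) and np.any(np.diff(self.triggers) <= 0):
            raise ValueError("triggers must be strictly increasing")
        if len(self.triggers) and (
            self.triggers[0] < 0 or self.triggers[-1] > self.duration
        ):
            raise ValueError("triggers must lie within [0, duration]")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.data.shape[1] / self.fs

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds, t = 0 at the first sample."""
        return np.arange(self.data.shape[1]) / self.fs

    def channel_index(self, label: str) -> int:
        """Index of ``label``; lookup is case-insensitive, labels preserved."""
        wanted = label.strip().lower()
        for i, ch in enumerate(self.channels):
            if ch.strip().lower() == wanted:
                return i
        raise KeyError(f"channel {label!r} not in {self.channels}")

    def get_channel(self, label: str) -> np.ndarray:
        """One channel's time series (µV)."""
        return self.data[self.channel_index(label)]

    def copy(self) -> "Recording":
        return replace(
            self,
            channels=list(self.channels),
            data=self.data.copy(),
            triggers=self.triggers.copy(),
            meta=replace(self.meta),
        )


def bipolar_eog(above: np.ndarray, canthus: np.ndarray) -> np.ndarray:
    """Bipolar electro-oculogram: EOG+ (above the eye) minus EOG- (canthus).

    Parameters
    ----------
    above, canthus : ndarray
        Monopolar traces in µV; must have equal length.

    Returns
    -------
    ndarray
        Elementwise difference ``above - canthus``.
    """
    above = np.asarray(above, dtype=float)
    canthus = np.asarray(canthus, dtype=float)
    if above.shape != canthus.shape:
        raise ValueError(
            f"EOG electrode traces differ in shape: {above.shape} vs {canthus.shape}"
        )
    return above - canthus
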