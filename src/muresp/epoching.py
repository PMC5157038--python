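"""Movement-anchored epoching, retention rules, and 60-epoch block averaging.

Envelope segments are anchored to movement onsets over the half-open window
[-1.5, 2.0) s.  An epoch survives only if it is artifact-free (peak |EOG|
within the window below 300 µV) and its inter-movement duration — the time
from the previous onset to this one — deviates from the designated
inter-movement interval by less than 0.5 s.  Retained epochs are averaged in
consecutive, non-overlapping blocks of 60 to form event-related oscillatory
responses.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace

import numpy as np

from .envelope import EnvelopeSignal

__all__ = [
    "EpochSet",
    "EventRelatedResponse",
    "InsufficientEpochsError",
    "inter_movement_durations",
    "segment_epochs",
    "retention_flags",
    "apply_retention",
    "retention_rate",
    "block_average",
]

logger = logging.getLogger(__name__)

RETAINED = "retained"
REJECTED_ARTIFACT = "rejected_artifact"
REJECTED_TIMING = "rejected_timing"
REJECTED_FIRST = "rejected_first"
REJECTED_EDGE = "rejected_edge"

#: Flags counted in the retention-rate denominator (timing/artifact
#: compliance); first-of-run and edge rejections are excluded.
_ELIGIBLE = (RETAINED, REJECTED_ARTIFACT, REJECTED_TIMING)


class InsufficientEpochsError(ValueError):
    """Raised when fewer retained epochs exist than a block average needs."""


@dataclass
class EpochSet:
    """Movement-anchored envelope segments with retention bookkeeping.

    Attributes
    ----------
    window : (float, float)
        Half-open epoch window (s) relative to movement onset.
    fs : float
        Sampling rate (Hz).
    epochs : ndarray, shape (n_triggers, n_samples)
        Envelope segment per trigger (µV); NaN rows for out-of-bounds
        triggers.
    imd : ndarray
        Inter-movement duration per trigger (s); NaN for the first trigger
        of each run.
    eog_peak : ndarray
        max |EOG| within each epoch window (µV); NaN for edge rejections.
    flags : ndarray of str
        Per-trigger status: retained / rejected_artifact / rejected_timing /
        rejected_first / rejected_edge.
    band, channel : str
        Provenance of the envelope.
    """

    window: tuple[float, float]
    fs: float
    epochs: np.ndarray
    imd: np.ndarray
    eog_peak: np.ndarray
    flags: np.ndarray
    band: str = ""
    channel: str = ""
    designated_imi: float | None = None
    deviation_threshold: float | None = None
    eog_threshold: float | None = None

    @property
    def n_triggers(self) -> int:
        return self.epochs.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Time axis (s) relative to movement onset."""
        n = self.epochs.shape[1]
        return self.window[0] + np.arange(n) / self.fs

    @property
    def retained_mask(self) -> np.ndarray:
        return self.flags == RETAINED

    def counts(self) -> dict[str, int]:
        """Trigger count per flag; values sum to the trigger count."""
        c = Counter(self.flags.tolist())
        return {k: c.get(k, 0) for k in
                (RETAINED, REJECTED_ARTIFACT, REJECTED_TIMING, REJECTED_FIRST, REJECTED_EDGE)}


@dataclass
class EventRelatedResponse:
    """Pointwise mean envelope over one block of retained epochs."""

    times: np.ndarray
    values: np.ndarray
    n_epochs: int
    band: str = ""
    channel: str = ""
    block_index: int = 0


def inter_movement_durations(
    triggers: np.ndarray, run_starts: np.ndarray | None = None
) -> np.ndarray:
    """Onset-to-onset duration per movement.

    ``duration[k] = t_k - t_{k-1}``; the first movement of the recording —
    and, if ``run_starts`` gives sub-session boundaries, the first movement
    at or after each boundary — has no previous onset in its run and is
    marked NaN.
    """
    triggers = np.asarray(triggers, dtype=float)
    if triggers.ndim != 1:
        raise ValueError("triggers must be 1-D")
    if triggers.size and np.any(np.diff(triggers) <= 0):
        raise ValueError("triggers must be strictly increasing")
    out = np.full(triggers.size, np.nan)
    if triggers.size > 1:
        out[1:] = np.diff(triggers)
    if run_starts is not None:
        for b in np.asarray(run_starts, dtype=float):
            idx = np.searchsorted(triggers, b, side="left")
            if idx < triggers.size:
                out[idx] = np.nan
    return out


def segment_epochs(
    env: EnvelopeSignal,
    eog: np.ndarray,
    triggers: np.ndarray,
    window: tuple[float, float] = (-1.5, 2.0),
    run_starts: np.ndarray | None = None,
) -> EpochSet:
    """Cut movement-anchored envelope segments and record per-epoch EOG peaks.

    One epoch per trigger whose full half-open window lies inside the
    recording; triggers too close to either end are flagged
    ``rejected_edge``.  Onset times are converted to sample indices by
    rounding to the nearest sample.  Retention rules are applied separately
    by :func:`apply_retention`.
    """
    start, end = window
    if not (start < 0 < end):
        raise ValueError(f"window must straddle the onset, got {window}")
    triggers = np.asarray(triggers, dtype=float)
    eog = np.asarray(eog, dtype=float)
    if eog.shape != env.values.shape:
        raise ValueError("EOG trace and envelope must have equal length")
    fs = env.fs
    n_samp = int(round((end - start) * fs))
    n_total = env.values.size

    epochs = np.full((triggers.size, n_samp), np.nan)
    eog_peak = np.full(triggers.size, np.nan)
    flags = np.array([RETAINED] * triggers.size, dtype=object)
    n_in = 0
    for k, tk in enumerate(triggers):
        i0 = int(round((tk + start) * fs))
        if i0 < 0 or i0 + n_samp > n_total:
            flags[k] = REJECTED_EDGE
            continue
        epochs[k] = env.values[i0 : i0 + n_samp]
        eog_peak[k] = np.max(np.abs(eog[i0 : i0 + n_samp]))
        n_in += 1
    if n_in == 0:
        raise ValueError("no trigger window fits inside the recording")

    return EpochSet(
        window=window,
        fs=fs,
        epochs=epochs,
        imd=inter_movement_durations(triggers, run_starts),
        eog_peak=eog_peak,
        flags=flags,
        band=env.band,
        channel=env.channel,
    )


def retention_flags(
    imd: np.ndarray,
    eog_peak: np.ndarray,
    designated_imi: float,
    deviation_threshold: float = 0.5,
    eog_threshold: float = 300.0,
    current_flags: np.ndarray | None = None,
) -> np.ndarray:
    """Per-epoch retention decisions.

    Retained requires (strict inequalities on the retained side)
    ``eog_peak < eog_threshold`` and ``|imd - designated_imi| <
    deviation_threshold``.  Undefined duration (first movement of a run) ->
    ``rejected_first``; the artifact rule takes precedence over the timing
    rule; pre-existing edge rejections are preserved.
    """
    imd = np.asarray(imd, dtype=float)
    eog_peak = np.asarray(eog_peak, dtype=float)
    n = imd.size
    out = np.array([RETAINED] * n, dtype=object)
    for k in range(n):
        if current_flags is not None and current_flags[k] == REJECTED_EDGE:
            out[k] = REJECTED_EDGE
        elif np.isnan(imd[k]):
            out[k] = REJECTED_FIRST
        elif not np.isnan(eog_peak[k]) and eog_peak[k] >= eog_threshold:
            out[k] = REJECTED_ARTIFACT
        elif abs(imd[k] - designated_imi) >= deviation_threshold:
            out[k] = REJECTED_TIMING
    return out


def apply_retention(
    es: EpochSet,
    designated_imi: float,
    deviation_threshold: float = 0.5,
    eog_threshold: float = 300.0,
) -> EpochSet:
    """Apply the artifact and timing retention rules to an epoch set."""
    flags = retention_flags(
        es.imd,
        es.eog_peak,
        designated_imi,
        deviation_threshold=deviation_threshold,
        eog_threshold=eog_threshold,
        current_flags=es.flags,
    )
    return replace(
        es,
        flags=flags,
        designated_imi=designated_imi,
        deviation_threshold=deviation_threshold,
        eog_threshold=eog_threshold,
    )


def retention_rate(es: EpochSet | np.ndarray) -> float:
    """Percentage of eligible epochs that survived retention.

    Eligible = retained + rejected_timing + rejected_artifact; first-of-run
    and edge rejections do not describe timing/artifact compliance and are
    excluded from the denominator.
    """
    flags = es.flags if isinstance(es, EpochSet) else np.asarray(es, dtype=object)
    eligible = int(np.isin(flags, _ELIGIBLE).sum())
    if eligible == 0:
        raise ValueError("no eligible epochs (denominator empty)")
    retained = int((flags == RETAINED).sum())
    return 100.0 * retained / eligible


def block_average(
    es: EpochSet, block_size: int = 60, min_blocks: int = 1
) -> list[EventRelatedResponse]:
    """Average retained epochs in consecutive non-overlapping blocks.

    Retained epochs, in chronological order, are partitioned into blocks of
    ``block_size``; each block's pointwise mean is one event-related
    oscillatory response.  A final partial block is discarded with a logged
    warning.
    """
    retained = es.epochs[es.retained_mask]
    n_blocks = retained.shape[0] // block_size
    if n_blocks < min_blocks:
        raise InsufficientEpochsError(
            f"{retained.shape[0]} retained epochs: need at least "
            f"{block_size * min_blocks} for {min_blocks} block(s) of {block_size}"
        )
    remainder = retained.shape[0] - n_blocks * block_size
    if remainder:
        logger.warning(
            "discarding %d retained epochs beyond the last full block of %d",
            remainder,
            block_size,
        )
    times = es.times
    return [
        EventRelatedResponse(
            times=times,
            values=retained[b * block_size : (b + 1) * block_size].mean(axis=0),
            n_epochs=block_size,
            band=es.band,
            channel=es.channel,
            block_index=b,
        )
        for b in range(n_blocks)
    ]
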