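"""Amplitude-response metrics: Amp_resp, PAmp_resp, and the laterality index.

From one event-related oscillatory response (a 60-epoch-averaged envelope),
the amplitude response is

    Amp_resp  = Amp_max - Amp_min                       [µV]
    PAmp_resp = 100 * Amp_resp / ((Amp_max + Amp_min)/2)  [%]

where Amp_min is the response minimum over the pre-onset window [-1.5, 0) s
and Amp_max the maximum over the post-onset window [0, 2.0) s.  Because the
denominator is the response midpoint, PAmp_resp is invariant to overall
signal scale (and to the envelope estimator's gain).  Inter-hemispheric
asymmetry is summarized by the laterality index

    LI = (PAmp_contra - PAmp_ipsi) / (PAmp_contra + PAmp_ipsi),

positive when the hemisphere contralateral to the moving hand dominates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epoching import EventRelatedResponse

__all__ = [
    "ResponseMetrics",
    "LateralityResult",
    "amp_extrema",
    "amp_resp",
    "pamp_resp",
    "laterality_index",
    "contralateral_map",
    "compute_response_metrics",
    "aggregate_blocks",
]

PRE_WINDOW = (-1.5, 0.0)
POST_WINDOW = (0.0, 2.0)


@dataclass
class ResponseMetrics:
    """Per-block amplitude-response metrics for one channel/band."""

    channel: str
    band: str
    block_index: int
    amp_min: float
    amp_max: float
    amp_resp: float
    pamp_resp: float
    pre_window: tuple[float, float] = PRE_WINDOW
    post_window: tuple[float, float] = POST_WINDOW


@dataclass
class LateralityResult:
    """PAmp_resp of both hemispheres and their laterality index."""

    pamp_contra: float
    pamp_ipsi: float
    li: float


def amp_extrema(
    resp: EventRelatedResponse,
    pre_window: tuple[float, float] = PRE_WINDOW,
    post_window: tuple[float, float] = POST_WINDOW,
) -> tuple[float, float]:
    """(Amp_min, Amp_max): minimum over the half-open pre-onset window and
    maximum over the half-open post-onset window.

    Ties resolve to the earliest time (first occurrence).
    """
    t = resp.times
    pre = (t >= pre_window[0]) & (t < pre_window[1])
    post = (t >= post_window[0]) & (t < post_window[1])
    if not pre.any() or not post.any():
        raise ValueError(
            f"search windows {pre_window}/{post_window} fall outside the "
            f"response time axis [{t[0]:.3f}, {t[-1]:.3f}]"
        )
    return float(resp.values[pre].min()), float(resp.values[post].max())


def amp_resp(amp_min: float, amp_max: float) -> float:
    """Amplitude response Amp_max - Amp_min (µV)."""
    return amp_max - amp_min


def pamp_resp(amp_min: float, amp_max: float) -> float:
    """Normalized amplitude response (%): Amp_resp over the response midpoint
    (Amp_max + Amp_min)/2."""
    denom = (amp_max + amp_min) / 2.0
    if denom <= 0:
        raise ValueError(
            f"PAmp_resp undefined: response midpoint {denom} is not positive"
        )
    return 100.0 * (amp_max - amp_min) / denom


def laterality_index(pamp_contra: float, pamp_ipsi: float) -> float:
    """Inter-hemispheric difference of PAmp_resp over their sum."""
    total = pamp_contra + pamp_ipsi
    if total <= 0:
        raise ValueError("laterality index undefined: PAmp sum is not positive")
    return (pamp_contra - pamp_ipsi) / total


def contralateral_map(hand: str) -> tuple[str, str]:
    """(contralateral, ipsilateral) sensorimotor channel for a moving hand.

    Standard M1 somatotopy: right hand -> ("C3", "C4"), left -> ("C4", "C3").
    """
    if hand == "right":
        return ("C3", "C4")
    if hand == "left":
        return ("C4", "C3")
    raise ValueError(f"hand must be 'left' or 'right', got {hand!r}")


def compute_response_metrics(
    resp: EventRelatedResponse,
    pre_window: tuple[float, float] = PRE_WINDOW,
    post_window: tuple[float, float] = POST_WINDOW,
    denominator: str = "midpoint",
) -> ResponseMetrics:
    """All amplitude metrics of one block-averaged response.

    ``denominator`` selects the PAmp_resp normalization: ``"midpoint"``
    (the canonical (Amp_max + Amp_min)/2) or ``"time_mean"`` (the time mean
    of the averaged response over its full window).
    """
    amin, amax = amp_extrema(resp, pre_window, post_window)
    if denominator == "midpoint":
        p = pamp_resp(amin, amax)
    elif denominator == "time_mean":
        m = float(resp.values.mean())
        if m <= 0:
            raise ValueError("PAmp_resp undefined: time-mean denominator not positive")
        p = 100.0 * (amax - amin) / m
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    return ResponseMetrics(
        channel=resp.channel,
        band=resp.band,
        block_index=resp.block_index,
        amp_min=amin,
        amp_max=amax,
        amp_resp=amp_resp(amin, amax),
        pamp_resp=p,
        pre_window=pre_window,
        post_window=post_window,
    )


def aggregate_blocks(values: list[float] | np.ndarray) -> tuple[float, float]:
    """Across-block mean and sample sd (ddof=1; sd = 0 for a single block)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no blocks to aggregate")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return mean, sd
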