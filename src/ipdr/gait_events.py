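"""Toe-Off and Mid-Stance detection inside segmented strides.

Both detectors operate on the gyroscope z-axis (sagittal rate).  At Toe-Off
the ankle moves from plantar flexion into dorsal extension, so the signal
crosses zero on the rising flank before the large positive swing peak.
Detection therefore anchors on the *global* maximum peak of the stride and
takes the nearest zero-crossing before it — anchoring on the first
zero-crossing instead is fooled by early spurious positive blips in jogging
and running strides.

Mid-Stance is the part of stance where the foot is flat and stationary and
the gyroscope-z energy is minimal.  The stride is interpolated to 200
samples; the search is restricted first to [max peak, sample 160] (stance is
roughly the last 60% of a walking stride and 40% of a jogging/running
stride, so Mid-Stance lies before the 80% mark), then from the Heel-Strike
(the minimum peak of that portion) onward; sliding 20-sample windows with
10-sample overlap are scored by energy (sum of squares) and the centre of
the lowest-energy window — earliest on ties — is mapped back to original
stride coordinates.

Strides are restitched Toe-Off to Toe-Off: the end of one stride is the next
stride's Toe-Off, eliminating inter-segment holes.  A TO-to-TO span longer
than 2 s (the subject stood still or sat down) is truncated to its first
1.5 s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EventError
from .msdtw import SegmentationResult
from .templates import interpolate_stride

log = logging.getLogger(__name__)

MS_GRID = 200          # interpolation grid for Mid-Stance detection
MS_UPPER = 160         # 80%-of-stride bound on the interpolated grid
MS_WINDOW = 20         # energy window, samples on the interpolated grid
MS_STEP = 10           # window overlap of 10 -> step of 10

MAX_STRIDE_S = 2.0     # TO-to-TO spans longer than this are truncated ...
KEEP_STRIDE_S = 1.5    # ... to this duration


@dataclass
class StrideSegment:
    """One stride: half-open interval plus detected event sample indices."""

    start: int
    end: int
    to_idx: int
    ms_idx: int = -1
    hs_idx: int = -1          # internal; not a reported output
    activity: str = ""

    def __post_init__(self) -> None:
        if not (self.start <= self.to_idx < self.end):
            raise EventError(
                f"TO index {self.to_idx} outside stride [{self.start}, {self.end})"
            )

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def detect_toe_off(stride, with_confidence: bool = False):
    """Index of the zero-crossing nearest before the global maximum peak.

    A crossing is an index ``i`` with ``stride[i-1] <= 0 < stride[i]``;
    "nearest" is the largest such ``i`` at or before the maximum.  If no
    crossing precedes the maximum the stride's first index is returned and
    flagged low-confidence.  A stride with no strictly positive sample has
    no swing peak and raises :class:`EventError`.
    """
    s = np.asarray(stride, dtype=float)
    if s.ndim != 1 or len(s) < 2:
        raise EventError("stride must be a 1-D sequence of length >= 2")
    if not np.any(s > 0):
        raise EventError("no positive swing peak in stride")
    peak = int(np.argmax(s))
    crossings = np.flatnonzero((s[1:peak + 1] > 0) & (s[:peak] <= 0)) + 1
    if len(crossings):
        idx, confident = int(crossings[-1]), True
    else:
        idx, confident = 0, False
        log.warning("no zero-crossing before the swing peak; TO set to "
                    "stride start (low confidence)")
    return (idx, confident) if with_confidence else idx


def detect_mid_stance(stride, with_heel_strike: bool = False):
    """Centre of the minimum-energy window of the late-stride portion.

    Returns the Mid-Stance index in original stride coordinates (nearest
    original sample to the fractional 200-grid position).  With
    ``with_heel_strike=True`` also returns the internal Heel-Strike index.
    """
    s = np.asarray(stride, dtype=float)
    if len(s) < 40:
        raise EventError(f"stride of {len(s)} samples too short for "
                         "Mid-Stance detection (>= 40)")
    g = interpolate_stride(s, MS_GRID)
    if not np.any(g > 0):
        raise EventError("no positive swing peak in stride")
    peak = int(np.argmax(g))
    upper = MS_UPPER
    portion = g[peak:upper]
    if len(portion) < MS_WINDOW:
        raise EventError("portion after the swing peak shorter than one "
                         "energy window")
    hs = peak + int(np.argmin(portion))
    tail = g[hs:upper]
    if len(tail) < MS_WINDOW:
        # Heel-Strike fell within one window of the 80% bound; slide the
        # window back so exactly one full window fits.
        hs = upper - MS_WINDOW
        tail = g[hs:upper]
    starts = np.arange(0, len(tail) - MS_WINDOW + 1, MS_STEP)
    energies = np.array([np.sum(tail[w:w + MS_WINDOW] ** 2) for w in starts])
    w_best = int(starts[int(np.argmin(energies))])   # argmin -> earliest tie
    ms_grid = hs + w_best + MS_WINDOW // 2
    scale = (len(s) - 1) / (MS_GRID - 1)
    ms = int(round(ms_grid * scale))
    if with_heel_strike:
        return ms, int(round(hs * scale))
    return ms


def restitch_to_to(
    segments: SegmentationResult | Sequence[tuple[int, int]],
    signal,
    rate_hz: float = 200.0,
    activity: str = "",
) -> list[StrideSegment]:
    """Re-cut msDTW segments into TO-to-TO strides.

    Detects the Toe-Off inside every segment, then emits strides
    [TO_k, TO_{k+1}).  Every Toe-Off starts a stride — the terminal one runs
    from the last Toe-Off to the end of the signal, so the bout's final
    stance phase (and with it the loop endpoint) is kept.  Spans longer
    than MAX_STRIDE_S are truncated to the first KEEP_STRIDE_S (scaled by
    the actual sampling rate); strides shorter than 40 samples are
    discarded.  Segments with no detectable swing peak are skipped.
    """
    sig = np.asarray(signal, dtype=float)
    if isinstance(segments, SegmentationResult):
        intervals = segments.segments
    else:
        intervals = [tuple(map(int, s)) for s in segments]
    tos = []
    for s0, s1 in intervals:
        try:
            to = s0 + detect_toe_off(sig[s0:s1])
        except EventError:
            log.info("segment [%d, %d) has no swing peak; skipped", s0, s1)
            continue
        tos.append(to)
    if not tos:
        return []
    max_n = int(round(MAX_STRIDE_S * rate_hz))
    keep_n = int(round(KEEP_STRIDE_S * rate_hz))
    min_n = 40
    strides = []
    # Every Toe-Off starts a stride; the terminal stride runs to the end of
    # the signal so the bout's final stance is not dropped (the 2 s rule
    # caps it when the subject keeps standing).
    bounds = tos[1:] + [len(sig)]
    for to, nxt in zip(tos, bounds):
        end = nxt if (nxt - to) <= max_n else to + keep_n
        if end - to >= min_n:
            strides.append(StrideSegment(start=to, end=end, to_idx=to,
                                         activity=activity))
    return strides


def annotate_events(strides: list[StrideSegment], signal) -> list[StrideSegment]:
    """Fill Mid-Stance (and internal Heel-Strike) for restitched strides.

    Strides whose Mid-Stance cannot be detected are dropped with a log entry.
    """
    sig = np.asarray(signal, dtype=float)
    out = []
    for seg in strides:
        try:
            ms, hs = detect_mid_stance(sig[seg.start:seg.end],
                                       with_heel_strike=True)
        except EventError as exc:
            log.info("stride [%d, %d): %s; dropped", seg.start, seg.end, exc)
            continue
        seg.ms_idx = seg.start + ms
        seg.hs_idx = seg.start + hs
        out.append(seg)
    return out
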