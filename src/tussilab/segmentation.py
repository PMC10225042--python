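"""Automatic trimming and energy normalization of single-maneuver recordings.

A manually pre-split maneuver recording still carries silent margins, and the
offset of a cough decays without a sharp boundary.  The trimming rule keeps
the span between the first and last frame of the signal energy contour lying
above -30 dB relative to the contour maximum, then rescales the trimmed slice
so its average energy (mean squared sample) equals one.  Normalization removes
the influence of pre-amplifier gain and microphone distance, so downstream
amplitude features are relative, not absolute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import Waveform

#: Default trim threshold relative to the contour maximum.
DEFAULT_THRESHOLD_DB = -30.0
#: Default contour frame length (non-overlapping frames).
DEFAULT_FRAME_S = 0.010


@dataclass(frozen=True)
class EnvelopeContour:
    """Per-frame energy level of a waveform in dB relative to the maximum.

    Frames tile the signal from sample 0 with the given hop; a final partial
    frame (shorter than ``frame_s``) is kept as its own frame so that drawn-out
    offsets are never silently dropped.  ``level_db`` is
    10*log10(frame mean square / max frame mean square), hence max = 0 dB.
    """

    times: np.ndarray          # frame centers, seconds
    level_db: np.ndarray       # <= 0, max exactly 0
    starts: np.ndarray         # frame start sample indices
    stops: np.ndarray          # frame stop sample indices (exclusive)
    frame_s: float
    hop_s: float


def _frame_bounds(n: int, n_frame: int, n_hop: int) -> tuple[np.ndarray, np.ndarray]:
    starts = np.arange(0, n, n_hop)
    stops = np.minimum(starts + n_frame, n)
    return starts, stops


def envelope_contour(
    w: Waveform,
    frame_s: float = DEFAULT_FRAME_S,
    hop_s: float | None = None,
) -> EnvelopeContour:
    """Compute the dB energy contour used by the trimming rule.

    Raises
    ------
    ValueError
        If the signal is identically zero ("no acoustic content") or the
        frame/hop parameters are degenerate.
    """
    if hop_s is None:
        hop_s = frame_s
    n_frame = int(round(frame_s * w.rate))
    n_hop = int(round(hop_s * w.rate))
    if n_frame < 2:
        raise ValueError(f"frame of {frame_s} s spans {n_frame} < 2 samples")
    if not 0 < n_hop <= n_frame:
        raise ValueError("hop must satisfy 0 < hop <= frame")
    if not np.any(w.samples):
        raise ValueError("no acoustic content: signal is identically zero")

    starts, stops = _frame_bounds(len(w), n_frame, n_hop)
    csum = np.concatenate(([0.0], np.cumsum(np.square(w.samples))))
    mean_sq = (csum[stops] - csum[starts]) / (stops - starts)
    ref = mean_sq.max()
    with np.errstate(divide="ignore"):
        level = 10.0 * np.log10(mean_sq / ref)
    times = (starts + stops) / 2.0 / w.rate
    return EnvelopeContour(
        times=times, level_db=level, starts=starts, stops=stops,
        frame_s=frame_s, hop_s=hop_s,
    )


def auto_trim(
    w: Waveform,
    contour: EnvelopeContour | None = None,
    threshold_db: float = DEFAULT_THRESHOLD_DB,
) -> tuple[int, int]:
    """Locate the acoustic extent of the maneuver.

    Returns the half-open sample range ``[onset, offset)`` spanning the first
    through last contour frame whose level is strictly greater than
    ``threshold_db`` (equality excluded).  The maximum frame sits at 0 dB, so
    for any threshold below zero at least one frame qualifies.
    """
    if contour is None:
        contour = envelope_contour(w)
    above = np.flatnonzero(contour.level_db > threshold_db)
    first, last = above[0], above[-1]
    onset = int(contour.starts[first])
    offset = int(contour.stops[last])
    return onset, offset


@dataclass(frozen=True)
class Segment:
    """A trimmed, energy-normalized maneuver signal.

    ``onset``/``offset`` index the parent waveform (0-based, half-open).  The
    mean squared sample of ``samples`` equals one by construction.
    """

    samples: np.ndarray
    rate: float
    onset: int
    offset: int

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError("segment must have positive duration")
        ms = float(np.mean(np.square(self.samples)))
        if abs(ms - 1.0) > 1e-9:
            raise ValueError(f"segment not energy-normalized: mean square {ms}")

    @property
    def duration(self) -> float:
        return (self.offset - self.onset) / self.rate

    def __len__(self) -> int:
        return self.samples.size


def normalize_energy(w: Waveform, onset: int = 0, offset: int | None = None) -> Segment:
    """Trim ``w`` to ``[onset, offset)`` and rescale to unit average energy.

    Raises
    ------
    ValueError
        If the slice has zero energy.
    """
    if offset is None:
        offset = len(w)
    sl = w.samples[onset:offset]
    ms = float(np.mean(np.square(sl)))
    if ms <= 0.0:
        raise ValueError(f"zero-energy slice [{onset}, {offset})")
    return Segment(samples=sl / np.sqrt(ms), rate=w.rate, onset=onset, offset=offset)


def segment_waveform(
    w: Waveform,
    frame_s: float = DEFAULT_FRAME_S,
    threshold_db: float = DEFAULT_THRESHOLD_DB,
) -> Segment:
    """Convenience: contour -> trim -> normalize in one call."""
    contour = envelope_contour(w, frame_s=frame_s)
    onset, offset = auto_trim(w, contour, threshold_db=threshold_db)
    return normalize_energy(w, onset, offset)
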