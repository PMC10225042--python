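"""Temporal contours of a maneuver segment and their DCT shape descriptors.

Three per-frame statistics describe how a transient maneuver evolves in time:

* **amplitude** — mean squared sample per frame.  Because segments are
  normalized to unit average energy, the duration-weighted contour average is
  exactly one, so only the contour *shape* is informative.
* **sample entropy** — the degree of unpredictability of the frame
  (turbulence noise scores high, locally periodic oscillation low).
* **kurtosis** — Pearson (non-excess) kurtosis of the frame sample histogram;
  3 for Gaussian noise, 1.5 for a sinusoid, large for burst-like onsets.

Each contour is then summarized by its first three DCT coefficients, read as
(average, slope, curvature).  Sign conventions: a positive slope coefficient
means the contour *decreases* with time; a positive curvature coefficient
means a downward-upward (convex) contour; negative means upward-downward
(concave).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft
from scipy import signal as ssig
from scipy import stats as sstats

from .segmentation import Segment

DEFAULT_FRAME_S = 0.020
DEFAULT_HOP_S = 0.010
DEFAULT_SAMPEN_M = 2
DEFAULT_SAMPEN_R_FACTOR = 0.2
DEFAULT_SAMPEN_DECIMATE_HZ = 4410.0


class ContourKind(str, enum.Enum):
    AMPLITUDE = "amplitude"
    SAMPLE_ENTROPY = "sample_entropy"
    KURTOSIS = "kurtosis"


@dataclass(frozen=True)
class Contour:
    """Frame-indexed sequence of a per-frame statistic.

    Undefined frames (zero-variance kurtosis, matchless sample entropy) are
    stored as NaN and excluded from shape fitting.
    """

    values: np.ndarray
    times: np.ndarray
    kind: ContourKind
    frame_s: float
    hop_s: float

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of frames whose statistic is defined."""
        return ~np.isnan(self.values)

    def defined_values(self) -> np.ndarray:
        return self.values[self.defined]


@dataclass(frozen=True)
class ContourShape:
    """(average, slope, curvature) from the first three DCT-II coefficients.

    ``average`` is the plain mean of the contour.  ``slope`` and ``curvature``
    carry the 2/N scaling, making them comparable across contour lengths.
    """

    average: float
    slope: float
    curvature: float


def frame_segment(
    samples: np.ndarray,
    rate: float,
    frame_s: float = DEFAULT_FRAME_S,
    hop_s: float = DEFAULT_HOP_S,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Split a signal into (possibly overlapping) analysis frames.

    Frames start every ``hop_s`` from time zero and cover the whole signal;
    trailing frames shorter than ``frame_s`` are kept at their true length.
    A signal shorter than one frame yields a single whole-signal frame.
    Returns the frame list and the frame-center times in seconds.
    """
    n = len(samples)
    n_frame = int(round(frame_s * rate))
    n_hop = int(round(hop_s * rate))
    if n_frame < 16:
        raise ValueError(f"frame of {frame_s} s spans {n_frame} < 16 samples")
    if n_hop < 1:
        raise ValueError("hop must be positive")
    if n <= n_frame:
        return [np.asarray(samples, dtype=np.float64)], np.array([n / 2.0 / rate])
    starts = np.arange(0, n, n_hop)
    stops = np.minimum(starts + n_frame, n)
    frames = [np.asarray(samples[a:b], dtype=np.float64) for a, b in zip(starts, stops)]
    times = (starts + stops) / 2.0 / rate
    return frames, times


def amplitude_contour(
    seg: Segment,
    frame_s: float = DEFAULT_FRAME_S,
    hop_s: float = DEFAULT_HOP_S,
) -> Contour:
    """Per-frame mean energy (mean squared sample).

    With non-overlapping tiling frames (hop = frame) the frame-length-weighted
    mean of the contour is exactly the segment's average energy, i.e. one.
    """
    frames, times = frame_segment(seg.samples, seg.rate, frame_s, hop_s)
    values = np.array([float(np.mean(np.square(f))) for f in frames])
    return Contour(values, times, ContourKind.AMPLITUDE, frame_s, hop_s)


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy SampEn(m, r) of a short series.

    SampEn = -ln(A/B) where B counts pairs of length-``m`` templates within
    Chebyshev distance ``r`` of each other and A counts pairs of length-
    ``m+1`` templates, both over template starts 0..n-m-1, self-matches
    excluded.  ``r`` defaults to 0.2 times the sample SD.

    A constant series is perfectly predictable and returns 0.  If either
    count is zero the statistic is undefined and NaN is returned.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n <= m + 1:
        return math.nan
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0
    if r is None:
        r = DEFAULT_SAMPEN_R_FACTOR * sd

    # Chebyshev distances between length-(m+1) templates, built incrementally;
    # the length-m distance is the running max over the first m offsets.
    n_templ = n - m  # template starts for both lengths
    d = np.zeros((n_templ, n_templ))
    for k in range(m):
        dk = np.abs(x[k:k + n_templ, None] - x[None, k:k + n_templ])
        np.maximum(d, dk, out=d)
    iu = np.triu_indices(n_templ, k=1)
    b = int(np.count_nonzero(d[iu] <= r))
    dk = np.abs(x[m:m + n_templ, None] - x[None, m:m + n_templ])
    np.maximum(d, dk, out=d)
    a = int(np.count_nonzero(d[iu] <= r))
    if a == 0 or b == 0:
        return math.nan
    return -math.log(a / b)


def _decimate(x: np.ndarray, factor: int) -> np.ndarray:
    if factor <= 1 or x.size < 4 * factor:
        return x
    return ssig.decimate(x, factor, zero_phase=True)


def sample_entropy_contour(
    seg: Segment,
    frame_s: float = DEFAULT_FRAME_S,
    hop_s: float = DEFAULT_HOP_S,
    m: int = DEFAULT_SAMPEN_M,
    r_factor: float = DEFAULT_SAMPEN_R_FACTOR,
    decimate_to_hz: float = DEFAULT_SAMPEN_DECIMATE_HZ,
) -> Contour:
    """Per-frame sample entropy with tolerance r = ``r_factor`` x frame SD.

    Frames are decimated (anti-aliased) to about ``decimate_to_hz`` before
    template matching, which bounds the O(n^2) match count per frame; the
    tolerance is taken from the SD of the decimated frame actually matched.
    """
    frames, times = frame_segment(seg.samples, seg.rate, frame_s, hop_s)
    factor = max(1, int(round(seg.rate / decimate_to_hz)))
    values = np.empty(len(frames))
    for i, f in enumerate(frames):
        fd = _decimate(f, factor)
        sd = float(np.std(fd))
        values[i] = sample_entropy(fd, m=m, r=r_factor * sd if sd > 0 else None)
    return Contour(values, times, ContourKind.SAMPLE_ENTROPY, frame_s, hop_s)


def kurtosis_contour(
    seg: Segment,
    frame_s: float = DEFAULT_FRAME_S,
    hop_s: float = DEFAULT_HOP_S,
) -> Contour:
    """Per-frame Pearson kurtosis m4/m2^2 (1/n central moments; normal -> 3).

    Zero-variance frames are undefined (NaN).
    """
    frames, times = frame_segment(seg.samples, seg.rate, frame_s, hop_s)
    values = np.empty(len(frames))
    for i, f in enumerate(frames):
        if f.size < 4 or np.ptp(f) == 0.0:
            values[i] = math.nan
        else:
            values[i] = sstats.kurtosis(f, fisher=False, bias=True)
    return Contour(values, times, ContourKind.KURTOSIS, frame_s, hop_s)


def contour_shape(c: Contour | np.ndarray) -> ContourShape:
    """Summarize a contour by its first three DCT-II coefficients.

    With x_n the defined contour values and N their count:

    * average   = (1/N) sum x_n                        (plain mean)
    * slope     = (2/N) sum x_n cos(pi (n+1/2) / N)    (positive = decreasing)
    * curvature = (2/N) sum x_n cos(pi (n+1/2) 2 / N)  (positive = convex)

    Raises
    ------
    ValueError
        If fewer than three defined values remain.
    """
    x = c.defined_values() if isinstance(c, Contour) else np.asarray(c, dtype=np.float64)
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 defined contour values, got {n}")
    # Unnormalized DCT-II: y_k = 2 sum x_n cos(pi k (2n+1) / (2N))
    y = sfft.dct(x, type=2, norm=None)
    return ContourShape(
        average=float(y[0] / (2 * n)),
        slope=float(y[1] / n),
        curvature=float(y[2] / n),
    )
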