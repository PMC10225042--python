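"""Exact DCT filter-bank decomposition and band-wise spectral features.

A transient maneuver (average length about 0.3 s) evolves too quickly for a
spectrogram to represent well, so the spectrum is summarized band by band
instead.  The segment is decomposed into five band-limited constituent
signals over the edges 0 / 400 / 800 / 1600 / 3200 Hz / Nyquist by
partitioning its orthonormal DCT-II coefficients.  Unlike the DFT, the DCT
implicitly extends the signal evenly about its endpoints, so the abrupt
onset is never juxtaposed with the decayed offset and no wrap-around
spectral artifacts arise.  The decomposition is exact: the constituents sum
to the original signal and their energies sum to its energy (Parseval).

Each band is further described by a typical frequency estimated from its
count of unidirectional (upward) zero crossings per second; the band
frequencies weighted by the relative band energies sum to the *weighted
frequency*, an approximation of the spectral centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft

from .segmentation import Segment

#: Interior band edges in Hz; the outer edges are 0 and rate/2.
DEFAULT_BAND_EDGES = (400.0, 800.0, 1600.0, 3200.0)


@dataclass(frozen=True)
class BandDecomposition:
    """Five band-limited constituents of a segment with their features."""

    edges: tuple[float, ...]          # (0, 400, 800, 1600, 3200, rate/2)
    constituents: list[np.ndarray]    # each same length as the segment
    relative_energy: np.ndarray       # sums to 1
    band_frequency: np.ndarray        # Hz, unidirectional zero-crossing rate
    rate: float

    @property
    def weighted_frequency(self) -> float:
        """Energy-weighted mean of the band frequencies (centroid proxy)."""
        return float(np.dot(self.relative_energy, self.band_frequency))


def band_frequency(constituent: np.ndarray, rate: float) -> float:
    """Typical frequency from unidirectional zero crossings.

    Counts transitions from a negative sample to a non-negative one (zero is
    treated as non-negative) and divides by the duration; a sinusoid at f Hz
    crosses upward f times per second.  An all-zero or crossing-free signal
    yields 0 Hz.
    """
    x = np.asarray(constituent)
    if x.size < 2:
        return 0.0
    nonneg = x >= 0.0
    crossings = int(np.count_nonzero(~nonneg[:-1] & nonneg[1:]))
    return crossings * rate / x.size


def dct_band_decompose(
    seg: Segment,
    edges: tuple[float, ...] = DEFAULT_BAND_EDGES,
) -> BandDecomposition:
    """Split a segment into band-limited constituents via its DCT-II.

    Coefficient k of the length-N orthonormal DCT corresponds to frequency
    f_k = k * rate / (2N); each coefficient is assigned to the half-open band
    [lo, hi) containing f_k (an edge frequency goes to the higher band).  Each
    constituent is the inverse DCT of its band's coefficients with all others
    zeroed; relative energies are coefficient energies by Parseval.
    """
    x = seg.samples
    n = x.size
    if n < 2:
        raise ValueError("segment must have at least 2 samples")
    nyquist = seg.rate / 2.0
    full_edges = (0.0, *map(float, edges), nyquist)
    if any(b <= a for a, b in zip(full_edges, full_edges[1:])):
        raise ValueError(f"band edges must be increasing below Nyquist: {full_edges}")

    coeffs = sfft.dct(x, type=2, norm="ortho")
    freqs = np.arange(n) * seg.rate / (2.0 * n)
    total_energy = float(np.sum(np.square(coeffs)))

    constituents: list[np.ndarray] = []
    rel_energy = np.empty(len(full_edges) - 1)
    band_freq = np.empty(len(full_edges) - 1)
    for b, (lo, hi) in enumerate(zip(full_edges, full_edges[1:])):
        # half-open [lo, hi); f_k < Nyquist always, so the top band is complete
        mask = (freqs >= lo) & (freqs < hi)
        banded = np.where(mask, coeffs, 0.0)
        constituent = sfft.idct(banded, type=2, norm="ortho")
        constituents.append(constituent)
        rel_energy[b] = np.sum(np.square(banded)) / total_energy
        band_freq[b] = band_frequency(constituent, seg.rate)
    return BandDecomposition(
        edges=full_edges,
        constituents=constituents,
        relative_energy=rel_energy,
        band_frequency=band_freq,
        rate=seg.rate,
    )


def weighted_frequency(decomp: BandDecomposition) -> float:
    """Relative-energy-weighted sum of band frequencies, in Hz."""
    return decomp.weighted_frequency
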