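"""Signal-intensity histogram features of segmented regions.

A healthy disc on T2-weighted MRI shows a bimodal intensity histogram: the
water-rich nucleus pulposus forms a bright mode and the annulus fibrosus a
dark one.  Degeneration blurs the nucleus/annulus boundary and the two
modes merge.  The normalized peak difference

    ΔSI = (SI₂ − SI₁) / SI_CSF × 255

(SI₁, SI₂ the locations of the two disc-histogram peaks, SI_CSF the peak of
the CSF histogram, 255 an amplification factor) quantifies the remaining
contrast independently of scanner gain, since CSF signal is stable across
acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .maskio import BinaryRegion

__all__ = [
    "Histogram",
    "PeakPair",
    "NoPeakError",
    "NormalizationError",
    "region_histogram",
    "find_two_peaks",
    "csf_reference",
    "delta_si",
]

DEFAULT_N_BINS = 64
DEFAULT_SMOOTHING_WINDOW = 3
DEFAULT_MIN_SEPARATION = 4      # bins
DEFAULT_MIN_PROMINENCE = 0.02   # fraction of region pixel count


class NoPeakError(ValueError):
    """Histogram has no admissible peak (e.g. flat counts)."""


class NormalizationError(ValueError):
    """CSF reference intensity is nonpositive; ΔSI undefined."""


@dataclass
class Histogram:
    bin_edges: np.ndarray    # length n_bins + 1, strictly increasing
    counts: np.ndarray       # length n_bins, sums to region pixel count
    class_id: int | None = None

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class PeakPair:
    """Locations (SI units) of the two disc-histogram peaks, SI_1 <= SI_2.

    ``degenerate`` is True when only one admissible peak was found, in which
    case SI_1 == SI_2 (severely degenerate discs lose their second mode).
    """

    SI_1: float
    SI_2: float
    prominence_1: float
    prominence_2: float
    degenerate: bool = False


def region_histogram(image: np.ndarray, region: BinaryRegion | np.ndarray,
                     n_bins: int = DEFAULT_N_BINS,
                     intensity_range: tuple[float, float] | None = None) -> Histogram:
    """Histogram of image intensities restricted to the region pixels.

    The default range is [0, image max] over the whole image, so histograms
    of different regions of one image share a common intensity axis.
    """
    if n_bins < 16:
        raise ValueError("n_bins must be >= 16")
    pix = region.pixels if isinstance(region, BinaryRegion) else np.asarray(region, bool)
    if not pix.any():
        raise ValueError("empty region")
    if intensity_range is None:
        hi = float(np.max(image))
        intensity_range = (0.0, hi if hi > 0 else 1.0)
    counts, edges = np.histogram(image[pix], bins=n_bins, range=intensity_range)
    cid = region.class_id if isinstance(region, BinaryRegion) else None
    return Histogram(bin_edges=edges, counts=counts, class_id=cid)


def _smooth(counts: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edges use the shrunken window."""
    if window <= 1:
        return counts.astype(float)
    kernel = np.ones(window) / window
    num = np.convolve(counts.astype(float), kernel, mode="same")
    norm = np.convolve(np.ones_like(counts, dtype=float), kernel, mode="same")
    return num / norm


def find_two_peaks(hist: Histogram,
                   smoothing_window: int = DEFAULT_SMOOTHING_WINDOW,
                   min_separation: int = DEFAULT_MIN_SEPARATION,
                   min_prominence: float = DEFAULT_MIN_PROMINENCE) -> PeakPair:
    """Locate the two dominant modes of a (smoothed) region histogram.

    Counts are smoothed with a centered moving average; local maxima with
    prominence >= ``min_prominence`` (a fraction of the region pixel count)
    and pairwise separation >= ``min_separation`` bins are candidates.  The
    two highest candidates are returned ordered by location; a single
    candidate yields a degenerate pair with SI_1 == SI_2.
    """
    smoothed = _smooth(hist.counts, smoothing_window)
    total = hist.counts.sum()
    prom = min_prominence * total
    # pad so maxima in the first/last bin are admissible
    padded = np.concatenate([[0.0], smoothed, [0.0]])
    idx, props = find_peaks(padded, prominence=prom, distance=max(1, min_separation))
    idx = idx - 1
    if idx.size == 0:
        raise NoPeakError("no histogram peak with sufficient prominence")
    order = np.argsort(padded[idx + 1], kind="stable")[::-1]  # by height, desc
    centers = hist.centers
    if idx.size == 1:
        si = float(centers[idx[0]])
        p = float(props["prominences"][0])
        return PeakPair(si, si, p, p, degenerate=True)
    top = order[:2]
    by_loc = top[np.argsort(idx[top])]
    lo, hi = (float(centers[idx[i]]) for i in by_loc)
    pl, ph = (float(props["prominences"][i]) for i in by_loc)
    return PeakPair(lo, hi, pl, ph, degenerate=False)


def csf_reference(image: np.ndarray, csf_region: BinaryRegion | np.ndarray,
                  n_bins: int = DEFAULT_N_BINS,
                  smoothing_window: int = DEFAULT_SMOOTHING_WINDOW,
                  intensity_range: tuple[float, float] | None = None) -> float:
    """Peak location of the CSF histogram (the ΔSI normalization reference)."""
    hist = region_histogram(image, csf_region, n_bins, intensity_range)
    smoothed = _smooth(hist.counts, smoothing_window)
    # middle of the maximal plateau (smoothing a spike makes a flat top)
    top = np.flatnonzero(smoothed >= smoothed.max() - 1e-12)
    runs = np.split(top, np.flatnonzero(np.diff(top) > 1) + 1)
    longest = max(runs, key=len)
    return float(hist.centers[longest[len(longest) // 2]])


def delta_si(peaks: PeakPair, si_csf: float) -> float:
    """ΔSI = (SI₂ − SI₁)/SI_CSF × 255; a degenerate (unimodal) pair gives 0."""
    if si_csf <= 0:
        raise NormalizationError(f"CSF reference must be positive, got {si_csf}")
    if peaks.degenerate:
        return 0.0
    return (peaks.SI_2 - peaks.SI_1) / si_csf * 255.0
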