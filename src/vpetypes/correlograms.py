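"""Auto- and cross-correlograms of spike trains.

The correlogram is the shared primitive of e-type classification (burst and
rhythmicity indices read off the autocorrelogram) and synchrony detection
(cross-correlogram features against jitter-surrogate bands).

Conventions
-----------
* Lag bins are centered on integer multiples of ``bin_ms`` and are half-open,
  bin *k* covering ``[k*bin - bin/2, k*bin + bin/2)`` ms, so no pair is
  double counted at an edge.  ``window_ms`` is the largest bin *center*.
* The autocorrelogram counts ordered pairs in both directions, is symmetric
  by construction, and has its zero-lag bin set to 0 (self-coincidences are
  uninformative).  The cross-correlogram keeps its zero-lag bin and bins the
  lag ``target - ref``.
* Counting is sort-merge based (O(n log n + pairs)), but correctness is
  defined by brute-force pair enumeration, which the test suite checks
  against exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .exceptions import ParameterError
from .session import SpikeTrain


@dataclass
class Correlogram:
    """Binned auto- or cross-correlogram.

    Attributes
    ----------
    lags : ndarray
        Bin centers in milliseconds, symmetric about 0.
    counts : ndarray
        Coincidences per bin (float after smoothing/normalization).
    bin_ms : float
        Bin width in milliseconds.
    n_ref_spikes : int
        Number of reference-train spikes.
    kind : {"auto", "cross"}
    normalization : {"raw_counts", "per_ref_spike"}
    ci_lower, ci_upper : ndarray, optional
        Pointwise surrogate confidence bands (same length as ``counts``).
    """

    lags: np.ndarray
    counts: np.ndarray
    bin_ms: float
    n_ref_spikes: int
    kind: str
    normalization: str = "raw_counts"
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return len(self.lags)

    @property
    def window_ms(self) -> float:
        return float(self.lags[-1])

    def per_ref_spike(self) -> "Correlogram":
        """Counts normalized by the number of reference spikes."""
        if self.normalization == "per_ref_spike":
            return self
        n = max(self.n_ref_spikes, 1)
        return replace(
            self,
            counts=self.counts / n,
            ci_lower=None if self.ci_lower is None else self.ci_lower / n,
            ci_upper=None if self.ci_upper is None else self.ci_upper / n,
            normalization="per_ref_spike",
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"lag_ms": self.lags, "count": self.counts}
        data["ci_lower"] = self.ci_lower if self.ci_lower is not None else np.nan
        data["ci_upper"] = self.ci_upper if self.ci_upper is not None else np.nan
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _times(spikes) -> np.ndarray:
    if isinstance(spikes, SpikeTrain):
        return spikes.times
    return np.asarray(spikes, dtype=float)


def compute_isis(spikes) -> np.ndarray:
    """Inter-spike intervals of a sorted train, in milliseconds.

    Returns an array of length ``max(n_spikes - 1, 0)``; all values are
    positive for a strictly increasing train.
    """
    t = _times(spikes)
    return np.diff(t) * 1000.0


def _check_bins(bin_ms: float, window_ms: float) -> int:
    if bin_ms <= 0:
        raise ParameterError(f"bin_ms must be > 0, got {bin_ms}")
    if window_ms < bin_ms:
        raise ParameterError(f"window_ms ({window_ms}) must be >= bin_ms ({bin_ms})")
    return int(round(window_ms / bin_ms))


def pair_lag_diffs(ref, target, max_lag_s: float):
    """All (ref, target) time differences ``target - ref`` with absolute value
    below ``max_lag_s`` (sort-merge, both trains sorted).

    Returns ``(diffs_s, target_index)`` where ``target_index[i]`` is the index
    into the target train of the pair's target spike (used by the jitter
    surrogate to re-bin pairs without re-enumerating them).
    """
    r = _times(ref)
    t = _times(target)
    if len(r) == 0 or len(t) == 0:
        return np.empty(0), np.empty(0, dtype=np.intp)
    lo = np.searchsorted(t, r - max_lag_s, side="left")
    hi = np.searchsorted(t, r + max_lag_s, side="right")
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return np.empty(0), np.empty(0, dtype=np.intp)
    # flat index of every in-window target spike, per reference spike
    starts = np.cumsum(counts) - counts
    tidx = np.repeat(lo - starts, counts) + np.arange(total)
    diffs = t[tidx] - np.repeat(r, counts)
    return diffs, tidx


def bin_lags(diffs_s: np.ndarray, bin_ms: float, n_half: int) -> np.ndarray:
    """Histogram lag differences (seconds) into ``2*n_half + 1`` half-open
    bins centered on multiples of ``bin_ms``."""
    k = np.floor(diffs_s * 1000.0 / bin_ms + 0.5).astype(np.int64) + n_half
    k = k[(k >= 0) & (k < 2 * n_half + 1)]
    return np.bincount(k, minlength=2 * n_half + 1).astype(float)


def crosscorrelogram(ref, target, bin_ms: float = 0.5, window_ms: float = 50.0) -> Correlogram:
    """Cross-correlogram of two trains on a common clock.

    ``counts[l]`` is the number of (ref, target) spike pairs whose lag
    ``target - ref`` falls in bin *l*.  Empty trains give all-zero counts.
    """
    n_half = _check_bins(bin_ms, window_ms)
    max_lag_s = (n_half + 0.5) * bin_ms / 1000.0
    diffs, _ = pair_lag_diffs(ref, target, max_lag_s)
    counts = bin_lags(diffs, bin_ms, n_half)
    lags = np.arange(-n_half, n_half + 1) * bin_ms
    return Correlogram(lags=lags, counts=counts, bin_ms=bin_ms,
                       n_ref_spikes=len(_times(ref)), kind="cross")


def autocorrelogram(spikes, bin_ms: float = 1.0, window_ms: float = 500.0) -> Correlogram:
    """Autocorrelogram of one train: ordered spike pairs per lag bin,
    self-pairs excluded, zero-lag bin set to 0, symmetric about 0."""
    c = crosscorrelogram(spikes, spikes, bin_ms=bin_ms, window_ms=window_ms)
    counts = c.counts
    counts[len(counts) // 2] = 0.0  # removes exactly the n self-pairs
    return replace(c, counts=counts, kind="auto")


def smooth_correlogram(c: Correlogram, kernel_sd_ms: float) -> Correlogram:
    """Gaussian-kernel smoothing of the counts.

    ``kernel_sd_ms = 0`` is the identity.  Total count is conserved up to
    leakage past the window edges (exact for features away from the edges);
    confidence bands, if any, are smoothed with the same kernel so that
    band comparisons remain consistent.
    """
    if kernel_sd_ms < 0:
        raise ParameterError("kernel_sd_ms must be >= 0")
    if kernel_sd_ms == 0:
        return replace(c, counts=c.counts.copy())
    sigma = kernel_sd_ms / c.bin_ms

    def _sm(x):
        return gaussian_filter1d(np.asarray(x, dtype=float), sigma=sigma,
                                 mode="constant", cval=0.0)

    return replace(
        c,
        counts=_sm(c.counts),
        ci_lower=None if c.ci_lower is None else _sm(c.ci_lower),
        ci_upper=None if c.ci_upper is None else _sm(c.ci_upper),
    )
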