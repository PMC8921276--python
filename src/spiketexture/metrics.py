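"""Spike-train metric layer.

Three primitives drive all downstream analyses:

* the Victor-Purpura spike distance -- the minimum cost of editing one
  spike train into another, where inserting or deleting a spike costs 1 and
  moving a spike by dt seconds costs q*|dt|.  The shift cost q (in 1/s)
  sets the temporal resolution of the metric: q=0 compares spike counts
  only, large q penalizes any timing mismatch.  The nominal resolution of a
  given q is taken as 1000/q ms (so q=500/s corresponds to 2 ms);
* Gaussian-smoothed peri-stimulus time histograms (PSTHs), optionally
  demeaned so correlation-based comparisons carry no overall-rate
  information;
* the maximum of the zero-mean cross-correlation between two demeaned
  PSTHs over a bounded lag range, used as a timing-similarity measure that
  tolerates small phase shifts between repeats.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .data_model import AnalysisWindow, SpikeTrain

__all__ = [
    "VpCost",
    "vp_distance",
    "mean_pairwise_vp",
    "Psth",
    "psth",
    "default_bin_width",
    "max_xcorr",
    "pairwise_max_xcorr",
    "RESOLUTION_GRID_MS",
]

#: Default grid of temporal resolutions (Gaussian kernel SDs) in ms.
RESOLUTION_GRID_MS = (0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0, 500.0)


@dataclass(frozen=True)
class VpCost:
    """Shift-cost parameter of the spike distance, in 1/s."""

    q: float = 500.0

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ValueError("q must be >= 0")

    @property
    def resolution_ms(self) -> float:
        """Nominal temporal resolution 1000/q in ms (inf for q=0)."""
        return np.inf if self.q == 0 else 1000.0 / self.q

    @classmethod
    def from_resolution_ms(cls, ms: float) -> "VpCost":
        if ms <= 0:
            raise ValueError("resolution must be > 0 ms")
        return cls(q=1000.0 / ms)


def vp_distance(a, b, cost: VpCost = VpCost()) -> float:
    """Victor-Purpura distance between two spike trains (times in ms).

    Exact minimum-cost edit value via dynamic programming over insertions
    and deletions (cost 1 each) and shifts (cost q*|dt| with dt in
    seconds).  Accepts SpikeTrain objects or bare time arrays; both trains
    must be expressed in the same (windowed) time base.
    """
    ta = a.times if isinstance(a, SpikeTrain) else np.asarray(a, dtype=float)
    tb = b.times if isinstance(b, SpikeTrain) else np.asarray(b, dtype=float)
    n, m = ta.size, tb.size
    if n == 0 or m == 0:
        return float(n + m)
    if cost.q == 0:
        return float(abs(n - m))
    # shift cost matrix in cost units; times ms -> seconds
    shift = cost.q * np.abs(ta[:, None] - tb[None, :]) / 1000.0
    prev = np.arange(m + 1, dtype=float)  # G[0, :]
    jj = np.arange(m + 1, dtype=float)
    for i in range(1, n + 1):
        cand = np.empty(m + 1)
        cand[0] = i
        # min(delete from a, diagonal match) -- then left-insertions folded in
        cand[1:] = np.minimum(prev[1:] + 1.0, prev[:-1] + shift[i - 1])
        cur = jj + np.minimum.accumulate(cand - jj)
        prev = cur
    return float(prev[m])


def mean_pairwise_vp(trains: Sequence, cost: VpCost = VpCost()) -> float:
    """Mean spike distance over all unordered pairs of trains."""
    if len(trains) < 2:
        raise ValueError("need >= 2 trains for a pairwise mean")
    return float(np.mean([vp_distance(a, b, cost) for a, b in combinations(trains, 2)]))


# ---------------------------------------------------------------------------
# PSTHs
# ---------------------------------------------------------------------------


def default_bin_width(kernel_sd: float) -> float:
    """Default PSTH bin width: half the kernel SD, at most 1 ms, at least 0.1 ms."""
    return max(0.1, min(kernel_sd / 2.0, 1.0))


@dataclass(frozen=True)
class Psth:
    """Smoothed (optionally demeaned) time-varying rate vector in spikes/s.

    ``values`` has length window.duration / bin_width; sample k covers
    [k*bin_width, (k+1)*bin_width) in windowed time.
    """

    values: np.ndarray
    bin_width: float
    kernel_sd: float
    window: AnalysisWindow
    demeaned: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def compatible_with(self, other: "Psth") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.bin_width, other.bin_width)
            and np.isclose(self.kernel_sd, other.kernel_sd)
        )


def bin_counts(times: np.ndarray, duration: float, bin_width: float) -> np.ndarray:
    n_bins = int(round(duration / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(times, bins=edges)
    return counts.astype(float)


def smooth_counts(counts: np.ndarray, kernel_sd: float, bin_width: float) -> np.ndarray:
    """Convolve binned rates with a unit-area Gaussian (truncated at 4 SD,
    reflected boundary mass) and return spikes/s."""
    rate = counts / (bin_width / 1000.0)
    sigma_bins = kernel_sd / bin_width
    return gaussian_filter1d(rate, sigma=sigma_bins, mode="reflect", truncate=4.0)


def psth(
    train,
    kernel_sd: float,
    bin_width: float | None = None,
    demean: bool = True,
    window: AnalysisWindow | None = None,
) -> Psth:
    """Gaussian-smoothed PSTH of a (windowed) spike train.

    ``train`` may be a SpikeTrain or a bare array of windowed times in ms.
    The undemeaned PSTH integrates to the spike count (sum * bin_width /
    1000 == n spikes); an empty train yields an all-zero PSTH.
    """
    if kernel_sd <= 0:
        raise ValueError("kernel_sd must be > 0")
    w = window or AnalysisWindow(start=0.0)
    times = train.times if isinstance(train, SpikeTrain) else np.asarray(train, dtype=float)
    bw = bin_width if bin_width is not None else default_bin_width(kernel_sd)
    values = smooth_counts(bin_counts(times, w.duration, bw), kernel_sd, bw)
    if demean and values.size:
        values = values - values.mean()
    return Psth(values=values, bin_width=bw, kernel_sd=kernel_sd, window=w, demeaned=demean)


# ---------------------------------------------------------------------------
# Lagged zero-mean cross-correlation
# ---------------------------------------------------------------------------

DEFAULT_MAX_LAG_MS = 50.0


def _lagged_products(x: np.ndarray, y: np.ndarray, max_lag_bins: int, mode: str) -> np.ndarray:
    """c[l] = sum_k x[k + l] * y[k] for l in [-L, L].

    ``circular`` wraps indices modulo the window length, so a pure phase
    shift between two otherwise identical signals is exactly cost-free;
    ``linear`` uses zero padding outside the window (MATLAB xcov style).
    """
    n = x.size
    L = min(max_lag_bins, n - 1)
    if mode == "circular":
        r = np.fft.irfft(np.fft.rfft(x) * np.conj(np.fft.rfft(y)), n=n)
        # r[l] = sum_k x[(k + l) % n] * y[k]; gather l in [-L, L]
        return np.concatenate([r[n - L:], r[: L + 1]])
    if mode == "linear":
        full = np.correlate(x, y, mode="full")  # index (len(y)-1) is lag 0
        center = y.size - 1
        return full[center - L: center + L + 1]
    raise ValueError(f"unknown cross-correlation mode {mode!r}")


def max_xcorr(
    p: Psth,
    q: Psth,
    max_lag: float = DEFAULT_MAX_LAG_MS,
    normalized: bool = False,
    mode: str = "circular",
) -> float:
    """Maximum of the zero-mean cross-correlation over lags in [-max_lag, max_lag].

    Both PSTHs must be demeaned and share bin width / kernel SD.  The
    default (unnormalized) form returns max over lags of
    sum(p[k+l]*q[k]) * bin_width; the ``normalized`` mode divides by the
    zero-lag geometric mean of the autocovariances (correlation
    coefficient-like scaling).  The default circular lag convention makes
    the similarity exactly invariant to a pure phase shift within the lag
    bound (the reason for searching over lags); ``mode="linear"`` gives the
    zero-padded form.
    """
    if not (p.demeaned and q.demeaned):
        raise ValueError("max_xcorr requires demeaned PSTHs")
    if not p.compatible_with(q):
        raise ValueError("mismatched PSTH resolutions (bin width / kernel SD / length)")
    if p.values.size == 0 or not (np.any(p.values) and np.any(q.values)):
        return 0.0
    L = int(round(max_lag / p.bin_width))
    c = _lagged_products(p.values, q.values, L, mode)
    best = float(c.max()) * p.bin_width
    if normalized:
        denom = np.sqrt(float(np.dot(p.values, p.values)) * float(np.dot(q.values, q.values)))
        return best / (denom * p.bin_width) if denom > 0 else 0.0
    return best


def pairwise_max_xcorr(
    values: np.ndarray, bin_width: float, max_lag: float = DEFAULT_MAX_LAG_MS
) -> np.ndarray:
    """All-pairs max cross-correlation for a stack of demeaned PSTHs.

    ``values`` is (n_trials, n_bins).  Returns the symmetric (n_trials,
    n_trials) matrix of max-over-lag circular zero-mean cross-correlations,
    computed with one matrix product per lag (BLAS-bound), matching
    :func:`max_xcorr` applied to each pair.
    """
    V = np.asarray(values, dtype=float)
    n, nb = V.shape
    L = min(int(round(max_lag / bin_width)), nb - 1)
    best = V @ V.T  # lag 0
    for lag in range(1, L + 1):
        s = np.roll(V, -lag, axis=1) @ V.T  # (i,j): sum_k V_i[k+lag] V_j[k], circular
        np.maximum(best, s, out=best)
        np.maximum(best, s.T, out=best)  # negative lag: c_ij(-l) = c_ji(l)
    return best * bin_width


def cross_max_xcorr_matrix(
    A: np.ndarray, B: np.ndarray, bin_width: float, max_lag: float = DEFAULT_MAX_LAG_MS
) -> np.ndarray:
    """Max circular cross-correlation between two stacks of demeaned PSTHs.

    Returns the (len(A), len(B)) matrix of max-over-lag values; used when
    test and training trials come from different conditions (e.g. speeds).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape[1] != B.shape[1]:
        raise ValueError("PSTH stacks must share bin count")
    L = min(int(round(max_lag / bin_width)), A.shape[1] - 1)
    best = A @ B.T
    for lag in range(1, L + 1):
        np.maximum(best, np.roll(A, -lag, axis=1) @ B.T, out=best)  # +lag
        np.maximum(best, (np.roll(B, -lag, axis=1) @ A.T).T, out=best)  # -lag
    return best * bin_width
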