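"""Speed warping and within-/cross-speed texture classification.

Texture-evoked temporal spiking patterns dilate and contract with scanning
speed because they are anchored to the spatial structure of the surface.
Multiplying contact-referenced spike times by the scanning speed
re-expresses a response in spikes/mm rather than spikes/ms, so responses
to the same texture at different speeds align in absolute position on the
surface and can be compared directly (cross-speed comparisons are
truncated to the spatial region scanned at every speed during the
analysis window).  Timing classifiers are trained at one speed and tested
at another, either on raw (unwarped) spike times or on warped spatial
positions; rate classifiers are evaluated the same way (warping converts
spikes/s into spikes/mm, which overcompensates the mild speed dependence
of firing rates).

The analysis window's start (default 100 ms after contact) is needed to
absolutize windowed spike times; pass the window the trains were cut with.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import AnalysisWindow, ResponseSet, SpikeTrain
from .decoding import (
    DecodingResult,
    DistanceTable,
    PopulationResult,
    _argmin_with_ties,
    classify_table,
    population_classify,
    rate_distance_table,
    timing_distance_table,
)
from .metrics import bin_counts, cross_max_xcorr_matrix, default_bin_width, smooth_counts

__all__ = [
    "WarpedTrain",
    "warp",
    "unwarp",
    "sd_mm_for",
    "cross_speed_classify",
    "cross_speed_table",
    "cross_speed_population",
    "DEFAULT_MAX_LAG_MM",
]

REFERENCE_SPEED = 80.0  # mm/s

#: Spatial lag bound for warped cross-correlation (25 ms at 80 mm/s).
#: Spike times are absolutized to contact before warping, so responses at
#: different speeds align in absolute position and only small phase noise
#: remains for the lag search to absorb.
DEFAULT_MAX_LAG_MM = 2.0


@dataclass(frozen=True)
class WarpedTrain:
    """A spike train expressed in space: positions (mm) = times x speed/1000."""

    neuron_id: str
    texture_id: str
    repeat_index: int
    speed: float
    positions: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))

    def __len__(self) -> int:
        return int(self.positions.size)


def warp(train: SpikeTrain) -> WarpedTrain:
    """Convert windowed spike times (ms) into spatial positions (mm)."""
    return WarpedTrain(
        train.neuron_id, train.texture_id, train.repeat_index, train.speed,
        train.times * train.speed / 1000.0,
    )


def unwarp(wt: WarpedTrain) -> SpikeTrain:
    """Exact inverse of :func:`warp`."""
    return SpikeTrain(
        wt.neuron_id, wt.texture_id, wt.repeat_index, wt.speed,
        wt.positions / wt.speed * 1000.0,
    )


def sd_mm_for(kernel_sd_ms: float, speed: float = REFERENCE_SPEED) -> float:
    """Spatial kernel SD (mm) equivalent to a temporal SD at a given speed."""
    return kernel_sd_ms * speed / 1000.0


def _common_region(speeds: Sequence[float], window: AnalysisWindow) -> tuple[float, float]:
    """Absolute spatial interval (mm from contact point) scanned at every
    speed during the analysis window."""
    lo = window.start / 1000.0 * max(speeds)
    hi = window.end / 1000.0 * min(speeds)
    if hi <= lo:
        raise ValueError("speeds too disparate: no common scanned region in the window")
    return lo, hi


def _spatial_stack(
    trains: Sequence[SpikeTrain],
    region: tuple[float, float],
    kernel_sd_mm: float,
    bin_width_mm: float | None,
    window: AnalysisWindow,
) -> tuple[np.ndarray, float]:
    """Demeaned spatially binned PSTHs (smoothed spikes/mm) over the common
    absolute region.  Window-referenced spike times are absolutized to
    contact (t + window.start) before warping, so responses at different
    speeds align in absolute position on the surface."""
    lo, hi = region
    bw = (
        bin_width_mm
        if bin_width_mm is not None
        else default_bin_width(kernel_sd_mm / sd_mm_for(1.0)) * sd_mm_for(1.0)
    )
    n_bins = int(round((hi - lo) / bw))
    V = np.empty((len(trains), n_bins))
    for i, tr in enumerate(trains):
        x = (tr.times + window.start) * tr.speed / 1000.0 - lo
        counts, _ = np.histogram(x, bins=np.arange(n_bins + 1) * bw)
        V[i] = smooth_counts(counts.astype(float), kernel_sd_mm, bw)
    return V - V.mean(axis=1, keepdims=True), bw


def _temporal_stack(
    trains: Sequence[SpikeTrain],
    duration_ms: float,
    kernel_sd_ms: float,
    bin_width_ms: float | None,
) -> tuple[np.ndarray, float]:
    bw = bin_width_ms if bin_width_ms is not None else default_bin_width(kernel_sd_ms)
    V = np.stack(
        [
            smooth_counts(bin_counts(t.times, duration_ms, bw), kernel_sd_ms, bw)
            for t in trains
        ]
    )
    return V - V.mean(axis=1, keepdims=True), bw


def _split_by_speed(trains: Sequence[SpikeTrain], speed: float) -> list[SpikeTrain]:
    return [t for t in trains if np.isclose(t.speed, speed)]


def _rate_values(trains: Sequence[SpikeTrain], window: AnalysisWindow, warped: bool):
    if warped:  # spikes per mm of scanned surface
        return np.array([len(t) / (window.duration_s * t.speed) for t in trains])
    return np.array([len(t) / window.duration_s for t in trains])


def _fold_distance_cube(
    train_trials: Sequence[SpikeTrain],
    test_trials: Sequence[SpikeTrain],
    texture_ids: Sequence[str],
    scheme: str,
    warped: bool,
    kernel_sd: float,
    max_lag: float,
    window: AnalysisWindow,
    bin_width: float | None,
) -> np.ndarray:
    """Distances (n_test, n_folds, n_textures); fold f leaves out training
    repeat f.  ``kernel_sd``/``max_lag``/``bin_width`` are in ms (unwarped)
    or mm (warped)."""
    order = {t: i for i, t in enumerate(texture_ids)}
    train_labels = np.array([order[t.texture_id] for t in train_trials])
    n_tex = len(texture_ids)
    fold_reps = sorted({t.repeat_index for t in train_trials})
    n_folds = len(fold_reps)
    train_folds = np.array([fold_reps.index(t.repeat_index) for t in train_trials])

    if scheme == "timing":
        if warped:
            speeds = [t.speed for t in train_trials] + [t.speed for t in test_trials]
            region = _common_region(speeds, window)
            A, bw = _spatial_stack(test_trials, region, kernel_sd, bin_width, window)
            B, _ = _spatial_stack(train_trials, region, kernel_sd, bin_width, window)
        else:
            A, bw = _temporal_stack(test_trials, window.duration, kernel_sd, bin_width)
            B, _ = _temporal_stack(train_trials, window.duration, kernel_sd, bin_width)
        S = cross_max_xcorr_matrix(A, B, bw, max_lag)  # (n_test, n_train)
        D = np.empty((len(test_trials), n_folds, n_tex))
        for f in range(n_folds):
            in_fold = train_folds != f  # train on the other repeats
            for t in range(n_tex):
                cols = in_fold & (train_labels == t)
                D[:, f, t] = -S[:, cols].mean(axis=1)
        return D

    if scheme == "rate":
        r_test = _rate_values(test_trials, window, warped)
        r_train = _rate_values(train_trials, window, warped)
        D = np.empty((len(test_trials), n_folds, n_tex))
        for f in range(n_folds):
            in_fold = train_folds != f
            for t in range(n_tex):
                cols = in_fold & (train_labels == t)
                D[:, f, t] = np.abs(r_test - r_train[cols].mean())
        return D

    raise ValueError(f"unknown scheme {scheme!r}")


def cross_speed_classify(
    trains: Sequence[SpikeTrain],
    train_speed: float,
    test_speed: float,
    scheme: str = "timing",
    warped: bool = False,
    kernel_sd: float = 2.0,
    max_lag: float | None = None,
    window: AnalysisWindow | None = None,
    bin_width: float | None = None,
    rng: int | np.random.Generator = 0,
) -> DecodingResult:
    """Within- or cross-speed nearest-neighbor classification for one neuron.

    Training candidates come from ``train_speed``; test trials from
    ``test_speed``.  Cross-speed, classifiers are trained on each
    4-repetition fold of the training speed and tested on every repetition
    at the test speed (every test repeat x every fold); within speed the
    standard leave-one-out protocol applies.  In warped mode PSTHs are
    built over spatial bins (``kernel_sd``/``max_lag``/``bin_width`` in mm,
    truncated to the shortest common spatial extent); unwarped, over time
    bins (ms).
    """
    w = window or AnalysisWindow()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if max_lag is None:
        max_lag = DEFAULT_MAX_LAG_MM if warped else 50.0
    texture_ids = list(dict.fromkeys(t.texture_id for t in trains))
    train_trials = _split_by_speed(trains, train_speed)
    test_trials = _split_by_speed(trains, test_speed)
    if not train_trials or not test_trials:
        raise ValueError("both speeds must be present in the data")
    order = {t: i for i, t in enumerate(texture_ids)}

    if np.isclose(train_speed, test_speed):  # within-speed LOO control
        labels = np.array([order[t.texture_id] for t in train_trials])
        repeats = np.array([t.repeat_index for t in train_trials])
        if scheme == "timing":
            if warped:
                region = _common_region([train_speed], w)
                V, bw = _spatial_stack(train_trials, region, kernel_sd, bin_width, w)
                from .metrics import pairwise_max_xcorr
                from .decoding import _similarity_to_table

                S = pairwise_max_xcorr(V, bw, max_lag)
                table = _similarity_to_table(
                    S, labels, repeats, texture_ids, train_trials[0].neuron_id, kernel_sd
                )
            else:
                table = timing_distance_table(
                    train_trials, labels, texture_ids, kernel_sd,
                    max_lag=max_lag, bin_width=bin_width, window=w,
                    neuron_id=train_trials[0].neuron_id,
                )
        else:
            table = rate_distance_table(
                _rate_values(train_trials, w, warped), labels, repeats, texture_ids,
                train_trials[0].neuron_id,
            )
        return classify_table(table, rng)

    D = _fold_distance_cube(
        train_trials, test_trials, texture_ids, scheme, warped,
        kernel_sd, max_lag, w, bin_width,
    )
    test_labels = np.array([order[t.texture_id] for t in test_trials])
    n_test, n_folds, n_tex = D.shape
    preds = _argmin_with_ties(D.reshape(n_test * n_folds, n_tex), rng)
    truth = np.repeat(test_labels, n_folds)
    confusion = np.zeros((n_tex, n_tex), dtype=int)
    np.add.at(confusion, (truth, preds), 1)
    return DecodingResult(
        accuracy=float(np.mean(preds == truth)),
        n_textures=n_tex,
        confusion=confusion,
        scheme=f"{scheme}-{'warped' if warped else 'unwarped'}",
        neuron_id=trains[0].neuron_id,
        resolution_ms=kernel_sd if scheme == "timing" else None,
    )


def cross_speed_table(
    trains: Sequence[SpikeTrain],
    train_speed: float,
    test_speed: float,
    scheme: str = "timing",
    warped: bool = False,
    kernel_sd: float = 2.0,
    max_lag: float | None = None,
    window: AnalysisWindow | None = None,
    bin_width: float | None = None,
) -> DistanceTable:
    """Fold-averaged trial x texture distance table for population analyses."""
    w = window or AnalysisWindow()
    if max_lag is None:
        max_lag = DEFAULT_MAX_LAG_MM if warped else 50.0
    texture_ids = list(dict.fromkeys(t.texture_id for t in trains))
    order = {t: i for i, t in enumerate(texture_ids)}
    train_trials = _split_by_speed(trains, train_speed)
    test_trials = _split_by_speed(trains, test_speed)
    D = _fold_distance_cube(
        train_trials, test_trials, texture_ids, scheme, warped,
        kernel_sd, max_lag, w, bin_width,
    ).mean(axis=1)
    labels = np.array([order[t.texture_id] for t in test_trials])
    return DistanceTable(
        D, labels, tuple(texture_ids),
        f"{scheme}-{'warped' if warped else 'unwarped'}",
        trains[0].neuron_id, kernel_sd if scheme == "timing" else None,
    )


def cross_speed_population(
    rate_tables: Sequence[DistanceTable],
    timing_tables: Sequence[DistanceTable],
    scheme: str,
    n_sample: int,
    n_iter: int = 1000,
    seed: int = 0,
) -> PopulationResult:
    """Population cross-speed classification.

    ``scheme`` is "rate-unwarped" (use rate_tables), "timing-warped" (use
    timing_tables), or "combined" (equal-weight average of each neuron's
    z-scored unwarped-rate and warped-timing tables).
    """
    if scheme == "rate-unwarped":
        tables = [t.zscore() for t in rate_tables]
    elif scheme == "timing-warped":
        tables = [t.zscore() for t in timing_tables]
    elif scheme == "combined":
        tables = []
        for r, t in zip(rate_tables, timing_tables, strict=True):
            rz, tz = r.zscore(), t.zscore()
            tables.append(
                replace(rz, values=0.5 * rz.values + 0.5 * tz.values, scheme="combined")
            )
    else:
        raise ValueError(f"unknown population scheme {scheme!r}")
    return population_classify(tables, n_sample, n_iter=n_iter, seed=seed, scheme=scheme)
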