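"""Rate-matched control spike trains.

Two controls bracket the space between a purely rate-coded response and a
perfectly repeatable temporal pattern:

* homogeneous Poisson surrogates, which match a measured firing rate but
  carry no temporal structure at all (Bernoulli draw per 0.1-ms bin with
  P = r*dt); and
* jittered surrogates, which start from one measured trial, perturb every
  spike by Gaussian jitter of known SD, and are then count-matched to the
  measured repeats, so trial-to-trial temporal variability is set
  parametrically by the jitter level.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .data_model import AnalysisWindow, SpikeTrain

__all__ = [
    "JitterLevel",
    "default_jitter_grid",
    "poisson_surrogate",
    "poisson_responses",
    "jittered_surrogates",
    "CountMatchError",
    "reflect_into_window",
]

POISSON_DT_MS = 0.1


class CountMatchError(ValueError):
    """Raised when count matching is impossible under the requested policy."""


@dataclass(frozen=True)
class JitterLevel:
    """Gaussian jitter SD in ms."""

    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("jitter sigma must be >= 0")


def default_jitter_grid(n_levels: int = 12, low: float = 0.1, high: float = 200.0) -> np.ndarray:
    """Log-spaced jitter grid in ms (default 12 levels over 0.1-200 ms)."""
    return np.geomspace(low, high, n_levels)


def poisson_surrogate(
    rate: float,
    w: AnalysisWindow,
    rng: np.random.Generator,
    neuron_id: str = "poisson",
    texture_id: str = "surrogate",
    repeat_index: int = 0,
    speed: float = 80.0,
    dt: float = POISSON_DT_MS,
) -> SpikeTrain:
    """Homogeneous Poisson spike train over the window (windowed time base).

    One Bernoulli draw per ``dt``-ms bin with P = r*dt; at most one spike
    per bin, placed at the bin center.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    p = rate * dt / 1000.0
    if p > 1.0:
        raise ValueError(
            f"rate {rate} spikes/s exceeds 1 spike per {dt}-ms bin (P = {p:.3f} > 1)"
        )
    n_bins = int(round(w.duration / dt))
    hits = rng.random(n_bins) < p
    times = (np.flatnonzero(hits) + 0.5) * dt
    return SpikeTrain(neuron_id, texture_id, repeat_index, speed, times)


def poisson_responses(
    rates: Sequence[float], w: AnalysisWindow, rng: np.random.Generator, **ids
) -> list[SpikeTrain]:
    """One Poisson surrogate per measured rate (repeat i gets rates[i])."""
    return [
        poisson_surrogate(r, w, rng, repeat_index=i, **ids) for i, r in enumerate(rates)
    ]


def reflect_into_window(times: np.ndarray, duration: float) -> np.ndarray:
    """Reflect times at the window edges into [0, duration)."""
    period = 2.0 * duration
    y = np.mod(times, period)
    y = np.where(y > duration, period - y, y)
    # map the measure-zero boundary hit onto the half-open interval
    return np.where(y >= duration, np.nextafter(duration, 0.0), y)


def jittered_surrogates(
    base: SpikeTrain,
    level: JitterLevel | float,
    target_counts: Sequence[int],
    rng: np.random.Generator,
    window: AnalysisWindow | None = None,
    policy: str = "remove",
    edge: str = "reflect",
) -> list[SpikeTrain]:
    """Jittered, count-matched surrogate repeats of one measured trial.

    Each surrogate jitters every spike of ``base`` (windowed time base) by
    Normal(0, sigma), folds spikes that leave the window back in
    (``edge="reflect"``, default) or drops them (``edge="clip"``), then
    removes spikes uniformly at random to reach the target count (default
    ``policy="remove"``; ``policy="add"`` instead inserts uniform spikes
    when the target exceeds the base count).
    """
    sigma = level.sigma if isinstance(level, JitterLevel) else float(level)
    if sigma < 0:
        raise ValueError("jitter sigma must be >= 0")
    if policy not in ("remove", "add"):
        raise ValueError(f"unknown count-match policy {policy!r}")
    if edge not in ("reflect", "clip"):
        raise ValueError(f"unknown edge mode {edge!r}")
    w = window or AnalysisWindow(start=0.0)
    out = []
    for k, target in enumerate(target_counts):
        target = int(target)
        t = base.times + (rng.normal(0.0, sigma, size=len(base)) if sigma > 0 else 0.0)
        if edge == "reflect":
            t = reflect_into_window(t, w.duration)
        else:
            t = t[(t >= 0) & (t < w.duration)]
        if target > t.size:
            if policy == "remove":
                raise CountMatchError(
                    f"target count {target} exceeds base count {t.size}; "
                    "use policy='add' (lowest-count base) for upward matching"
                )
            t = np.concatenate([t, rng.uniform(0.0, w.duration, size=target - t.size)])
        elif target < t.size:
            keep = rng.choice(t.size, size=target, replace=False)
            t = t[keep]
        t = np.unique(np.sort(t))
        out.append(replace(base, repeat_index=k, times=t))
    return out
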