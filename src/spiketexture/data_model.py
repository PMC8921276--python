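"""Core domain types for trial-structured spike-time data.

Conventions used throughout the package: spike times are in milliseconds
relative to texture contact onset (or, after windowing, relative to window
start), scanning speeds in mm/s, firing rates in spikes/s. The standard
analysis epoch is the 500 ms of steady-state response beginning 100 ms
after contact, excluding onset transients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AREAS = ("3b", "1", "2", "unknown")
SUBMODALITIES = ("SA1-like", "RA-like", "PC-like", "unclassified")


class ValidationError(ValueError):
    """A ResponseSet (or file) violates its declared design."""


class IngestError(ValueError):
    """A spike-table file is malformed."""


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open analysis epoch [start, start + duration) in ms after contact."""

    start: float = 100.0
    duration: float = 500.0

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError(f"window duration must be > 0, got {self.duration}")

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def duration_s(self) -> float:
        return self.duration / 1000.0


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times for one neuron x texture x repeat x speed.

    ``times`` must be strictly increasing and finite. Use
    :func:`spike_train_from_raw` to ingest unsorted data with possible
    duplicate event times.
    """

    neuron_id: str
    texture_id: str
    repeat_index: int
    speed: float
    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ValueError("times must be a 1-d array")
        if t.size and not np.all(np.isfinite(t)):
            raise ValueError("spike times must be finite")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("spike times must be strictly increasing (no duplicates)")
        if not self.speed > 0:
            raise ValueError(f"speed must be > 0 mm/s, got {self.speed}")
        if self.repeat_index < 0:
            raise ValueError("repeat_index must be >= 0")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def key(self) -> tuple:
        return (self.neuron_id, self.texture_id, self.repeat_index, float(self.speed))


def spike_train_from_raw(
    neuron_id: str,
    texture_id: str,
    repeat_index: int,
    speed: float,
    times: Iterable[float],
) -> SpikeTrain:
    """Build a SpikeTrain from possibly unsorted times, collapsing duplicates.

    Exactly coincident events (recording artifacts) are collapsed to a single
    spike with a logged warning, since the metric layer requires strict
    ordering.
    """
    t = np.sort(np.asarray(list(times), dtype=float))
    if t.size > 1:
        keep = np.concatenate([[True], np.diff(t) > 0])
        if not keep.all():
            logger.warning(
                "collapsed %d duplicate spike time(s) for neuron %s texture %s repeat %d",
                int((~keep).sum()), neuron_id, texture_id, repeat_index,
            )
            t = t[keep]
    return SpikeTrain(neuron_id, texture_id, repeat_index, speed, t)


def window(train: SpikeTrain, w: AnalysisWindow) -> SpikeTrain:
    """Restrict a train to the half-open window [start, end), re-referencing
    times to the window start."""
    t = train.times
    sel = t[(t >= w.start) & (t < w.end)] - w.start
    return replace(train, times=sel)


@dataclass(frozen=True)
class RateResponse:
    """Firing rate (spikes/s) of one trial over an analysis window."""

    neuron_id: str
    texture_id: str
    repeat_index: int
    speed: float
    rate: float

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")


def spike_rate(train: SpikeTrain, w: AnalysisWindow) -> RateResponse:
    """Firing rate over the window: spike count / window duration in seconds."""
    n = len(window(train, w))
    return RateResponse(
        train.neuron_id, train.texture_id, train.repeat_index, train.speed,
        n / w.duration_s,
    )


@dataclass
class StudyDesign:
    """Declared factorial design: every neuron x texture x repeat x speed cell
    must be present exactly once."""

    n_repeats: int
    speeds: tuple[float, ...]

    def __post_init__(self) -> None:
        self.speeds = tuple(float(s) for s in self.speeds)
        if self.n_repeats < 1 or not self.speeds:
            raise ValueError("design needs >= 1 repeat and >= 1 speed")


@dataclass
class ResponseSet:
    """The full indexed collection of spike trains plus neuron/texture metadata.

    ``neurons``: DataFrame with columns neuron_id, area, submodality.
    ``textures``: DataFrame with columns texture_id, name.
    """

    trains: list[SpikeTrain]
    neurons: pd.DataFrame
    textures: pd.DataFrame
    design: StudyDesign
    provenance: dict = field(default_factory=dict)
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {tr.key: tr for tr in self.trains}

    # -- access -----------------------------------------------------------
    @property
    def neuron_ids(self) -> list[str]:
        return list(self.neurons["neuron_id"])

    @property
    def texture_ids(self) -> list[str]:
        return list(self.textures["texture_id"])

    def get(self, neuron_id: str, texture_id: str, repeat_index: int, speed: float) -> SpikeTrain:
        return self._index[(neuron_id, texture_id, repeat_index, float(speed))]

    def trains_for(
        self,
        neuron_id: str,
        texture_id: str | None = None,
        speed: float | None = None,
    ) -> list[SpikeTrain]:
        """All trains for one neuron, optionally restricted to a texture and/or
        speed, ordered by (texture order in table, repeat)."""
        textures = [texture_id] if texture_id is not None else self.texture_ids
        speeds = [float(speed)] if speed is not None else list(self.design.speeds)
        out = []
        for tex in textures:
            for sp in speeds:
                for rep in range(self.design.n_repeats):
                    out.append(self._index[(neuron_id, tex, rep, sp)])
        return out

    def __iter__(self) -> Iterator[SpikeTrain]:
        return iter(self.trains)

    def __len__(self) -> int:
        return len(self.trains)

    # -- validation -------------------------------------------------------
    def missing_cells(self) -> list[tuple]:
        expected = {
            (n, t, r, s)
            for n in self.neuron_ids
            for t in self.texture_ids
            for r in range(self.design.n_repeats)
            for s in self.design.speeds
        }
        return sorted(expected - set(self._index), key=str)

    def validate(self) -> None:
        """Check design completeness and referential integrity."""
        neurons = set(self.neuron_ids)
        textures = set(self.texture_ids)
        for tr in self.trains:
            if tr.neuron_id not in neurons:
                raise ValidationError(f"train references unknown neuron {tr.neuron_id!r}")
            if tr.texture_id not in textures:
                raise ValidationError(f"train references unknown texture {tr.texture_id!r}")
        if len(self._index) != len(self.trains):
            raise ValidationError("duplicate (neuron, texture, repeat, speed) cells present")
        missing = self.missing_cells()
        if missing:
            shown = ", ".join(map(str, missing[:20]))
            more = "" if len(missing) <= 20 else f" (+{len(missing) - 20} more)"
            raise ValidationError(f"design incomplete; missing cells: {shown}{more}")
        extra = set(self._index) - {
            (n, t, r, s)
            for n in self.neuron_ids
            for t in self.texture_ids
            for r in range(self.design.n_repeats)
            for s in self.design.speeds
        }
        if extra:
            raise ValidationError(f"cells outside declared design: {sorted(extra, key=str)[:20]}")


def neuron_table(
    neuron_ids: Sequence[str],
    areas: Sequence[str] | None = None,
    submodalities: Sequence[str] | None = None,
) -> pd.DataFrame:
    areas = list(areas) if areas is not None else ["unknown"] * len(neuron_ids)
    subs = list(submodalities) if submodalities is not None else ["unclassified"] * len(neuron_ids)
    for a in areas:
        if a not in AREAS:
            raise ValueError(f"unknown area label {a!r}")
    for s in subs:
        if s not in SUBMODALITIES:
            raise ValueError(f"unknown submodality label {s!r}")
    return pd.DataFrame({"neuron_id": list(neuron_ids), "area": areas, "submodality": subs})


def texture_table(texture_ids: Sequence[str], names: Sequence[str] | None = None) -> pd.DataFrame:
    names = list(names) if names is not None else list(texture_ids)
    return pd.DataFrame({"texture_id": list(texture_ids), "name": names})
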