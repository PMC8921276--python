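"""Synthetic texture-evoked spike trains with known ground truth.

The generator emulates the statistical structure that the analyses assume:

* each texture is a spatial modulation profile (band-limited positive
  noise over 0.1-10 cycles/mm), so temporal spiking patterns are anchored
  in space and dilate/contract with scanning speed;
* each neuron holds a per-texture *master* spike pattern drawn once from
  an inhomogeneous point process on that profile; individual trials jitter
  the master spikes by Normal(0, temporal_precision), keep each with
  probability ``pattern_strength``, and top up with homogeneous Poisson
  spikes, so trial-to-trial temporal precision is controlled by a single
  parameter (mirroring the jittered-surrogate logic of the analyses);
* firing rates are texture-tuned: per neuron x texture rate offsets are a
  weighted mix of three afferent-class rate vectors (SA1/RA/PC) plus
  noise, so submodality-profile regression recovery is well posed;
* rates scale with speed as (speed/80)**alpha (alpha = 0.5 by default,
  configurable, 0 for none).

Regeneration from (config, seed) is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    AnalysisWindow,
    ResponseSet,
    SpikeTrain,
    StudyDesign,
    neuron_table,
    texture_table,
)

__all__ = [
    "NeuronSpec",
    "TextureTemplate",
    "GroundTruth",
    "StudyConfig",
    "main_design",
    "speed_design",
    "make_templates",
    "simulate_trial",
    "TrialSimulator",
    "simulate_study",
    "simulate_afferent_rates",
    "PerceptGenerativeSpec",
    "simulate_ratings",
]

AFFERENT_CLASSES = ("SA1", "RA", "PC")
REFERENCE_SPEED = 80.0  # mm/s
#: target pairwise correlation between afferent-class rate vectors
AFFERENT_CLASS_CORR = 0.4


@dataclass(frozen=True)
class NeuronSpec:
    """Generative parameters of one synthetic cortical neuron."""

    neuron_id: str
    base_rate: float  # spikes/s at the reference speed
    rate_tuning_sd: float  # SD of texture-specific mean-rate offsets, spikes/s
    temporal_precision: float  # trial-to-trial spike jitter SD, ms
    pattern_strength: float  # fraction of spikes locked to the master pattern
    submodality_weights: tuple[float, float, float]  # (w_SA1, w_RA, w_PC)
    area: str = "unknown"
    group: str = "unclassified"  # planted submodality group label

    def __post_init__(self) -> None:
        if not self.base_rate > 0:
            raise ValueError("base_rate must be > 0")
        if not self.temporal_precision > 0:
            raise ValueError("temporal_precision must be > 0")
        if not 0.0 <= self.pattern_strength <= 1.0:
            raise ValueError("pattern_strength must be in [0, 1]")
        w = np.asarray(self.submodality_weights, dtype=float)
        if w.min() < 0 or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("submodality weights must be nonnegative and sum to 1")


@dataclass(frozen=True)
class TextureTemplate:
    """Nonnegative spatial modulation profile sampled on a regular grid.

    ``profile[k]`` is the modulation at position k*dx mm; mean ~ 1 so it
    multiplies a neuron's mean rate.
    """

    texture_id: str
    profile: np.ndarray
    dx: float = 0.01  # mm

    def __post_init__(self) -> None:
        p = np.asarray(self.profile, dtype=float)
        object.__setattr__(self, "profile", p)
        if p.min() < 0:
            raise ValueError("template profile must be nonnegative")
        if self.dx > 0.0100001:
            raise ValueError("template grid spacing must be <= 0.01 mm")

    @property
    def length(self) -> float:
        return self.profile.size * self.dx

    def at(self, x: np.ndarray) -> np.ndarray:
        grid = np.arange(self.profile.size) * self.dx
        return np.interp(x, grid, self.profile)


SPATIAL_BAND = (0.1, 10.0)  # cycles/mm


def make_templates(
    n_textures: int,
    seed: int,
    roughness_range: tuple[float, float] = (0.6, 1.4),
    length: float = 80.0,
    dx: float = 0.01,
) -> list[TextureTemplate]:
    """Distinct band-limited positive noise profiles, one per texture.

    Gaussian noise is band-passed to 0.1-10 cycles/mm with a random
    per-texture spectral tilt, then exponentiated (log-normal envelope)
    with a modulation depth drawn from ``roughness_range`` and normalized
    to mean 1.
    """
    if n_textures < 2:
        raise ValueError("need at least 2 textures")
    out = []
    n = int(round(length / dx))
    freqs = np.fft.rfftfreq(n, d=dx)  # cycles/mm
    band = (freqs >= SPATIAL_BAND[0]) & (freqs <= SPATIAL_BAND[1])
    for j in range(n_textures):
        rng = np.random.default_rng([seed, 0, j])
        spec = (rng.normal(size=band.sum()) + 1j * rng.normal(size=band.sum()))
        tilt = rng.uniform(-1.0, 0.0)  # spectral slope: flat to 1/f
        amp = np.where(freqs[band] > 0, freqs[band] ** tilt, 0.0)
        full = np.zeros(freqs.size, dtype=complex)
        full[band] = spec * amp
        g = np.fft.irfft(full, n=n)
        g = (g - g.mean()) / g.std()
        depth = rng.uniform(*roughness_range)
        profile = np.exp(depth * g)
        profile = profile / profile.mean()
        out.append(TextureTemplate(texture_id=f"tex{j:02d}", profile=profile, dx=dx))
    return out


# ---------------------------------------------------------------------------
# Trial simulation
# ---------------------------------------------------------------------------


class TrialSimulator:
    """Per neuron x texture simulator holding the master spike pattern.

    The master pattern lives in spatial coordinates shared by all speeds;
    per-speed patterns are nested thinnings of it (keep probability
    proportional to speed**(alpha-1)), so warped spike trains align across
    speeds while temporal rates scale as (speed/80)**alpha.
    """

    def __init__(
        self,
        neuron: NeuronSpec,
        template: TextureTemplate,
        speeds: Sequence[float],
        seed_key: Sequence[int],
        window: AnalysisWindow = AnalysisWindow(),
        rate_offset: float | None = None,
        speed_exponent: float = 0.5,
    ) -> None:
        self.neuron = neuron
        self.template = template
        self.window = window
        self.speeds = tuple(float(v) for v in speeds)
        self.alpha = speed_exponent
        self._seed_key = list(seed_key)
        rng = np.random.default_rng(self._seed_key)
        if rate_offset is None:
            rate_offset = rng.normal(0.0, neuron.rate_tuning_sd)
        else:
            rng.normal()  # keep the stream aligned whether or not offset is supplied
        self.rate_offset = float(rate_offset)
        self._draw_master(rng)

    def mean_rate(self, speed: float) -> float:
        """Specified mean rate (spikes/s) for this neuron x texture x speed."""
        r = max(0.0, self.neuron.base_rate + self.rate_offset)
        return r * (speed / REFERENCE_SPEED) ** self.alpha

    def _segment(self, speed: float) -> tuple[float, float]:
        return (speed * self.window.start / 1000.0, speed * self.window.end / 1000.0)

    def _draw_master(self, rng: np.random.Generator) -> None:
        w = self.window
        x_lo = min(v * w.start / 1000.0 for v in self.speeds)
        x_hi = max(v * w.end / 1000.0 for v in self.speeds)
        if x_hi > self.template.length + 1e-9:
            raise ValueError(
                f"template length {self.template.length} mm too short for "
                f"speed {max(self.speeds)} mm/s over the window (needs {x_hi} mm)"
            )
        # intensity C * profile(x); C set so the fastest-demand speed needs
        # keep probability exactly 1 over its own segment
        seg_integral = {}
        for v in self.speeds:
            lo, hi = self._segment(v)
            grid = np.arange(self.template.profile.size) * self.template.dx
            mask = (grid >= lo) & (grid < hi)
            seg_integral[v] = float(self.template.profile[mask].sum() * self.template.dx)
        demands = {
            v: (self.mean_rate(v) * w.duration_s) / max(seg_integral[v], 1e-12)
            for v in self.speeds
        }
        C = max(demands.values())
        self._keep_prob = {v: demands[v] / C if C > 0 else 0.0 for v in self.speeds}
        pmax = float(self.template.profile.max())
        n_exp = C * pmax * (x_hi - x_lo)
        n = rng.poisson(n_exp) if n_exp > 0 else 0
        xs = np.sort(rng.uniform(x_lo, x_hi, size=n))
        accept = rng.random(n) < self.template.at(xs) / pmax
        self.master_x = xs[accept]
        self._marks = rng.random(self.master_x.size)  # nested per-speed thinning

    def master_positions(self, speed: float) -> np.ndarray:
        lo, hi = self._segment(speed)
        sel = (self._marks < self._keep_prob[speed]) & (self.master_x >= lo) & (self.master_x < hi)
        return self.master_x[sel]

    def trial(self, speed: float, repeat_index: int) -> SpikeTrain:
        speed = float(speed)
        w = self.window
        rng = np.random.default_rng(
            self._seed_key + [100 + repeat_index, int(round(speed * 1000))]
        )
        ps = self.neuron.pattern_strength
        xs = self.master_positions(speed)
        times = xs / speed * 1000.0 - w.start  # windowed ms
        keep = rng.random(times.size) < ps
        times = times[keep]
        times = times + rng.normal(0.0, self.neuron.temporal_precision, size=times.size)
        topup_rate = (1.0 - ps) * self.mean_rate(speed)
        n_top = rng.poisson(topup_rate * w.duration_s)
        times = np.concatenate([times, rng.uniform(0.0, w.duration, size=n_top)])
        # reflect jittered spikes back into the window, sort, dedupe
        period = 2.0 * w.duration
        y = np.mod(times, period)
        y = np.where(y > w.duration, period - y, y)
        y = y[y < w.duration]
        times = np.unique(y)
        return SpikeTrain(
            self.neuron.neuron_id, self.template.texture_id, repeat_index, speed, times
        )


def simulate_trial(
    neuron: NeuronSpec,
    template: TextureTemplate,
    speed: float,
    w: AnalysisWindow,
    seed: int,
    repeat_index: int = 0,
    speed_exponent: float = 0.5,
) -> SpikeTrain:
    """One synthetic trial (windowed time base).

    The per neuron x texture master pattern and rate offset are derived
    deterministically from ``seed``; repeated calls with different
    ``repeat_index`` give jittered repeats of the same master pattern.
    """
    sim = TrialSimulator(
        neuron, template, [speed], [seed], window=w, speed_exponent=speed_exponent
    )
    return sim.trial(speed, repeat_index)


# ---------------------------------------------------------------------------
# Afferent reference rates
# ---------------------------------------------------------------------------

_AFF_MEAN = {"SA1": 50.0, "RA": 60.0, "PC": 45.0}
_AFF_SD = {"SA1": 15.0, "RA": 18.0, "PC": 12.0}


def _class_z_vectors(n_textures: int, rng: np.random.Generator) -> np.ndarray:
    """Three unit-variance class vectors with pairwise correlation ~0.4.

    For n >= 6 the common and idiosyncratic components are exactly
    orthogonalized (Gram-Schmidt against the constant vector and each
    other), so sample correlations equal the target by construction.
    """
    raw = rng.normal(size=(4, n_textures))
    if n_textures >= 6:
        basis = [np.ones(n_textures) / np.sqrt(n_textures)]
        comps = []
        for v in raw:
            for b in basis:
                v = v - np.dot(v, b) * b
            v = v / np.linalg.norm(v)
            basis.append(v)
            comps.append(v * np.sqrt(n_textures - 1))  # unit sample variance
        common, idio = comps[0], comps[1:]
    else:
        std = lambda v: (v - v.mean()) / v.std(ddof=1)
        common, idio = std(raw[0]), [std(v) for v in raw[1:]]
    rho = AFFERENT_CLASS_CORR
    return np.stack([np.sqrt(rho) * common + np.sqrt(1 - rho) * g for g in idio])


def simulate_afferent_rates(
    templates: Sequence[TextureTemplate] | Sequence[str], seed: int
) -> pd.DataFrame:
    """Mean firing rates of the three afferent classes to a shared texture set.

    Returns a 3 x n_textures DataFrame (rows SA1, RA, PC). Class vectors
    are related but distinct (pairwise correlation ~0.4).
    """
    texture_ids = [
        t.texture_id if isinstance(t, TextureTemplate) else str(t) for t in templates
    ]
    if len(texture_ids) < 3:
        raise ValueError("need >= 3 textures")
    rng = np.random.default_rng([seed, 1])
    Z = _class_z_vectors(len(texture_ids), rng)
    rates = np.stack(
        [
            np.clip(_AFF_MEAN[c] + _AFF_SD[c] * Z[i], 0.0, None)
            for i, c in enumerate(AFFERENT_CLASSES)
        ]
    )
    return pd.DataFrame(rates, index=list(AFFERENT_CLASSES), columns=texture_ids)


# ---------------------------------------------------------------------------
# Study-level simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PerceptGenerativeSpec:
    """Generative coefficients linking neural features to dissimilarity ratings."""

    a_rate: tuple[float, float, float] = (0.3, 0.3, 0.3)  # per (SA1, RA, PC) subpop
    a_timing: tuple[float, float, float] = (0.0, 0.1, 0.8)  # timing informative in PC
    noise_sd: float = 0.25  # in units of the systematic-part SD


@dataclass
class StudyConfig:
    """Design and generative parameters of a synthetic study."""

    name: str = "custom"
    n_neurons: int = 20
    n_textures: int = 10
    n_repeats: int = 5
    speeds: tuple[float, ...] = (80.0,)
    window: AnalysisWindow = field(default_factory=AnalysisWindow)
    base_rate_range: tuple[float, float] = (20.0, 100.0)
    speed_exponent: float = 0.5
    offset_noise_frac: float = 0.15  # fraction of tuning variance not explained by classes
    template_length: float = 80.0
    template_dx: float = 0.01
    roughness_range: tuple[float, float] = (0.6, 1.4)
    percept: PerceptGenerativeSpec = field(default_factory=PerceptGenerativeSpec)

    def to_json(self) -> str:
        d = asdict(self)
        d["window"] = [self.window.start, self.window.duration]
        return json.dumps(d, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def main_design(**overrides) -> StudyConfig:
    """The principal design: 141 neurons x 59 textures x 5 repeats at 80 mm/s."""
    cfg = dict(name="main", n_neurons=141, n_textures=59, n_repeats=5, speeds=(80.0,))
    cfg.update(overrides)
    return StudyConfig(**cfg)


def speed_design(**overrides) -> StudyConfig:
    """The scanning-speed design: 49 neurons x 10 textures x 4 speeds x 5 repeats."""
    cfg = dict(
        name="speed", n_neurons=49, n_textures=10, n_repeats=5,
        speeds=(60.0, 80.0, 100.0, 120.0),
    )
    cfg.update(overrides)
    return StudyConfig(**cfg)


#: planted group proportions, mirroring 12 PC-like / 12 RA-like / 25 SA1-like of 141
GROUP_FRACTIONS = {"PC-like": 12 / 141, "RA-like": 12 / 141, "SA1-like": 25 / 141}

_GROUP_PARAMS: Mapping[str, dict] = {
    # (precision ms, pattern strength, rate tuning SD) ranges per planted group
    "PC-like": dict(precision=(0.5, 2.0), strength=(0.6, 0.9), tuning=(15.0, 25.0)),
    "RA-like": dict(precision=(2.0, 6.0), strength=(0.4, 0.7), tuning=(15.0, 25.0)),
    "SA1-like": dict(precision=(10.0, 30.0), strength=(0.05, 0.2), tuning=(20.0, 30.0)),
    "unclassified": dict(precision=(2.0, 20.0), strength=(0.2, 0.5), tuning=(10.0, 20.0)),
}
_DOMINANT_INDEX = {"SA1-like": 0, "RA-like": 1, "PC-like": 2}
_AREA_FRACTIONS = {"3b": 35 / 141, "1": 81 / 141, "2": 25 / 141}


def composition_for(n_neurons: int) -> list[str]:
    """Planted group label per neuron, proportional to the default composition."""
    counts = {g: int(round(f * n_neurons)) for g, f in GROUP_FRACTIONS.items()}
    labels = []
    for g, c in counts.items():
        labels.extend([g] * c)
    labels.extend(["unclassified"] * max(0, n_neurons - len(labels)))
    return labels[:n_neurons]


def _areas_for(n_neurons: int) -> list[str]:
    counts = {a: int(round(f * n_neurons)) for a, f in _AREA_FRACTIONS.items()}
    labels = []
    for a, c in counts.items():
        labels.extend([a] * c)
    labels.extend(["unknown"] * max(0, n_neurons - len(labels)))
    return labels[:n_neurons]


def _make_neuron(i: int, group: str, area: str, cfg: StudyConfig, seed: int) -> NeuronSpec:
    rng = np.random.default_rng([seed, 2, i])
    p = _GROUP_PARAMS[group]
    precision = float(np.exp(rng.uniform(*np.log(p["precision"]))))
    strength = float(rng.uniform(*p["strength"]))
    tuning = float(rng.uniform(*p["tuning"]))
    base = float(rng.uniform(*cfg.base_rate_range))
    if group in _DOMINANT_INDEX:
        w = np.empty(3)
        dom = rng.uniform(0.90, 0.97)
        split = rng.uniform(0.2, 0.8)
        rest = 1.0 - dom
        others = [rest * split, rest * (1 - split)]
        k = _DOMINANT_INDEX[group]
        w[k] = dom
        w[[j for j in range(3) if j != k]] = others
    else:
        w = rng.dirichlet([4.0, 4.0, 4.0])
    return NeuronSpec(
        neuron_id=f"n{i:03d}",
        base_rate=base,
        rate_tuning_sd=tuning,
        temporal_precision=precision,
        pattern_strength=strength,
        submodality_weights=tuple(float(x) for x in w / w.sum()),
        area=area,
        group=group,
    )


@dataclass
class GroundTruth:
    """Everything needed to score recovery: specs, templates, class rates,
    planted rate offsets, perceptual coefficients, and the seed/config."""

    neuron_specs: list[NeuronSpec]
    templates: list[TextureTemplate]
    afferent_rates: pd.DataFrame  # 3 x n_textures (SA1, RA, PC)
    rate_offsets: pd.DataFrame  # neurons x textures, spikes/s
    percept: PerceptGenerativeSpec
    seed: int
    config: StudyConfig

    def spec_for(self, neuron_id: str) -> NeuronSpec:
        return next(s for s in self.neuron_specs if s.neuron_id == neuron_id)


def simulate_study(config: StudyConfig, seed: int) -> tuple[ResponseSet, GroundTruth]:
    """Generate a complete, validated ResponseSet plus its GroundTruth."""
    cfg = config
    templates = make_templates(
        cfg.n_textures, seed, cfg.roughness_range, cfg.template_length, cfg.template_dx
    )
    afferents = simulate_afferent_rates(templates, seed)
    groups = composition_for(cfg.n_neurons)
    areas = _areas_for(cfg.n_neurons)
    specs = [_make_neuron(i, groups[i], areas[i], cfg, seed) for i in range(cfg.n_neurons)]

    # texture-rate offsets: weights . z-scored class vectors + noise,
    # scaled to each neuron's rate_tuning_sd
    Z = ((afferents.T - afferents.mean(axis=1)) / afferents.std(axis=1, ddof=1)).T.to_numpy()
    R = np.corrcoef(Z)
    nu = cfg.offset_noise_frac
    offsets = np.empty((cfg.n_neurons, cfg.n_textures))
    for i, spec in enumerate(specs):
        w = np.asarray(spec.submodality_weights)
        signal = w @ Z / np.sqrt(max(w @ R @ w, 1e-12))
        eps = np.random.default_rng([seed, 3, i]).normal(size=cfg.n_textures)
        offsets[i] = spec.rate_tuning_sd * (np.sqrt(1 - nu**2) * signal + nu * eps)
    offsets_df = pd.DataFrame(
        offsets, index=[s.neuron_id for s in specs], columns=[t.texture_id for t in templates]
    )

    trains: list[SpikeTrain] = []
    for i, spec in enumerate(specs):
        for j, tpl in enumerate(templates):
            sim = TrialSimulator(
                spec, tpl, cfg.speeds, [seed, 4, i, j], window=cfg.window,
                rate_offset=offsets[i, j], speed_exponent=cfg.speed_exponent,
            )
            for v in cfg.speeds:
                for k in range(cfg.n_repeats):
                    trains.append(sim.trial(v, k))

    rs = ResponseSet(
        trains=trains,
        neurons=neuron_table(
            [s.neuron_id for s in specs],
            areas=[s.area for s in specs],
            submodalities=[s.group for s in specs],
        ),
        textures=texture_table([t.texture_id for t in templates]),
        design=StudyDesign(n_repeats=cfg.n_repeats, speeds=cfg.speeds),
        provenance={"seed": seed, "config_hash": cfg.config_hash, "design": cfg.name},
    )
    rs.validate()
    gt = GroundTruth(
        neuron_specs=specs,
        templates=templates,
        afferent_rates=afferents,
        rate_offsets=offsets_df,
        percept=cfg.percept,
        seed=seed,
        config=cfg,
    )
    return rs, gt


def simulate_ratings(
    predictors: pd.DataFrame,
    percept: PerceptGenerativeSpec,
    seed: int,
) -> pd.Series:
    """Dissimilarity ratings generated linearly from a built predictor table.

    ``predictors`` columns follow the ``rate_<GROUP>`` / ``timing_<GROUP>``
    naming of the perception-link feature builder.  The systematic part is
    the planted linear combination; Gaussian noise of
    ``percept.noise_sd * SD(systematic)`` is added, and the result is
    shifted/scaled to be nonnegative with mean 1 (as normalized ratings).
    """
    coef = {}
    for i, g in enumerate(("SA1-like", "RA-like", "PC-like")):
        coef[f"rate_{g}"] = percept.a_rate[i]
        # timing features are similarities: more similar -> less dissimilar
        coef[f"timing_{g}"] = -percept.a_timing[i]
    y = np.zeros(len(predictors))
    for col in predictors.columns:
        y = y + coef.get(col, 0.0) * predictors[col].to_numpy()
    sd = y.std() if y.std() > 0 else 1.0
    rng = np.random.default_rng([seed, 6])
    y = y + rng.normal(0.0, percept.noise_sd * sd, size=y.size)
    y = y - y.min()
    if y.mean() > 0:
        y = y / y.mean()
    return pd.Series(y, index=predictors.index, name="rating")
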