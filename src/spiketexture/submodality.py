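"""Submodality profiling of cortical neurons.

A neuron's texture firing-rate profile is regressed onto the mean rate
profiles of the three mechanoreceptive afferent classes (SA1, RA, PC)
over a shared texture set; all variables are z-scored across textures and
the ordinary-least-squares fit has no intercept, so the coefficients are
standardized betas.  A neuron is labeled X-like when its standardized
coefficient for class X exceeds the threshold (0.8 by default); neurons
with no coefficient above threshold are unclassified, and the (unexpected)
case of two coefficients above threshold is flagged rather than silently
labeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import AnalysisWindow, ResponseSet, spike_rate

__all__ = ["SubmodalityProfile", "fit_submodality", "SubmodalityModel", "SubmodalityResults"]

CLASSES = ("SA1", "RA", "PC")
DEFAULT_THRESHOLD = 0.8


class CollinearityError(ValueError):
    """Afferent predictors are rank-deficient."""


@dataclass(frozen=True)
class SubmodalityProfile:
    """Standardized regression coefficients and the resulting label."""

    neuron_id: str
    coefficients: tuple[float, float, float]  # (b_SA1, b_RA, b_PC)
    label: str  # "SA1-like" | "RA-like" | "PC-like" | "unclassified"
    threshold: float
    ambiguous: bool = False  # two or more coefficients above threshold

    @property
    def coef_series(self) -> pd.Series:
        return pd.Series(self.coefficients, index=[f"b_{c}" for c in CLASSES])


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant vector")
    return (v - v.mean()) / sd


def fit_submodality(
    neuron_rates: pd.Series,
    afferent_table: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    neuron_id: str = "",
) -> SubmodalityProfile:
    """Regress a neuron's z-scored per-texture mean rates onto z-scored
    afferent class rates (OLS, no intercept).

    ``neuron_rates``: mean rate per texture (index = texture ids).
    ``afferent_table``: 3 x textures (rows SA1, RA, PC) over a shared set.
    """
    shared = [t for t in afferent_table.columns if t in neuron_rates.index]
    if len(shared) < 4:
        raise ValueError("need >= 4 shared textures")
    y = _zscore(neuron_rates.loc[shared].to_numpy(dtype=float))
    X = np.stack([_zscore(afferent_table.loc[c, shared].to_numpy(dtype=float)) for c in CLASSES]).T
    rank = np.linalg.matrix_rank(X)
    if rank < 3:
        corr = np.corrcoef(X.T)
        pairs = [
            f"{CLASSES[i]}~{CLASSES[j]}"
            for i in range(3)
            for j in range(i + 1, 3)
            if abs(corr[i, j]) > 0.999
        ]
        raise CollinearityError(f"rank-deficient afferent predictors ({', '.join(pairs) or 'rank ' + str(rank)})")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    above = np.flatnonzero(beta > threshold)
    if above.size == 1:
        label, ambiguous = f"{CLASSES[above[0]]}-like", False
    elif above.size == 0:
        label, ambiguous = "unclassified", False
    else:
        label, ambiguous = "unclassified", True
    return SubmodalityProfile(
        neuron_id=neuron_id,
        coefficients=tuple(float(b) for b in beta),
        label=label,
        threshold=threshold,
        ambiguous=ambiguous,
    )


@dataclass
class SubmodalityResults:
    profiles: pd.DataFrame  # neuron_id, b_SA1, b_RA, b_PC, label, ambiguous

    def group_counts(self) -> pd.Series:
        return self.profiles["label"].value_counts()

    def summary(self) -> str:
        counts = self.group_counts()
        lines = ["Submodality composition (standardized regression onto afferent rates)"]
        for label in ("SA1-like", "RA-like", "PC-like", "unclassified"):
            lines.append(f"  {label}: {int(counts.get(label, 0))}")
        n_amb = int(self.profiles["ambiguous"].sum())
        if n_amb:
            lines.append(f"  flagged ambiguous (two coefficients above threshold): {n_amb}")
        return "\n".join(lines)


class SubmodalityModel:
    """Profile every neuron of a ResponseSet against an afferent rate table."""

    def __init__(
        self,
        response_set: ResponseSet,
        afferent_table: pd.DataFrame,
        threshold: float = DEFAULT_THRESHOLD,
        speed: float | None = None,
        window: AnalysisWindow | None = None,
    ) -> None:
        self.rs = response_set
        self.afferents = afferent_table
        self.threshold = threshold
        self.speed = speed if speed is not None else response_set.design.speeds[0]
        self.window = window or AnalysisWindow(start=0.0)

    def mean_rates(self, neuron_id: str) -> pd.Series:
        """Per-texture mean firing rate across repeats."""
        vals = {}
        for tid in self.rs.texture_ids:
            reps = self.rs.trains_for(neuron_id, tid, self.speed)
            vals[tid] = float(np.mean([spike_rate(t, self.window).rate for t in reps]))
        return pd.Series(vals)

    def fit(self) -> SubmodalityResults:
        rows = []
        for nid in self.rs.neuron_ids:
            p = fit_submodality(
                self.mean_rates(nid), self.afferents, self.threshold, neuron_id=nid
            )
            rows.append(
                dict(
                    neuron_id=nid, b_SA1=p.coefficients[0], b_RA=p.coefficients[1],
                    b_PC=p.coefficients[2], label=p.label, ambiguous=p.ambiguous,
                )
            )
        return SubmodalityResults(profiles=pd.DataFrame(rows))
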