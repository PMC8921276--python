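"""Predicting perceived texture dissimilarity from neural rate and timing.

For every pair of textures in a dissimilarity-rating study, two families
of neural predictors are built per submodality subpopulation (SA1-like,
RA-like, PC-like):

* rate difference: |difference of trial-averaged firing rates| per cell,
  z-scored across all pairs for that cell, averaged over the subpopulation;
* timing correlation: the max cross-correlation between the pair's
  trial-averaged demeaned PSTHs at the cell's best decoding resolution,
  z-scored across pairs per cell, averaged over the subpopulation (kept as
  a similarity, so its fitted coefficient against dissimilarity is
  expected to be negative).

Ratings are then predicted by leave-one-pair-out cross-validated multiple
regression (OLS with intercept), and models are compared by the mean
squared error of the held-out predictions across all pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import AnalysisWindow, ResponseSet, spike_rate
from .metrics import DEFAULT_MAX_LAG_MS, Psth, bin_counts, default_bin_width, max_xcorr, smooth_counts

logger = logging.getLogger(__name__)

__all__ = [
    "DissimilarityStudy",
    "build_predictors",
    "cv_regression",
    "population_mse_curve",
    "DissimilarityRegression",
    "DissimilarityResults",
    "MODEL_SPECS",
]

SUBPOPS = ("SA1-like", "RA-like", "PC-like")

MODEL_SPECS: Mapping[str, tuple[str, ...]] = {
    "rate3": tuple(f"rate_{g}" for g in SUBPOPS),
    "timing3": tuple(f"timing_{g}" for g in SUBPOPS),
    "full6": tuple(f"rate_{g}" for g in SUBPOPS) + tuple(f"timing_{g}" for g in SUBPOPS),
}


@dataclass
class DissimilarityStudy:
    """Texture pairs and mean normalized dissimilarity ratings.

    ``ratings`` is indexed by (texture_a, texture_b) tuples covering all
    C(n, 2) unordered pairs.
    """

    textures: list[str]
    ratings: pd.Series

    def __post_init__(self) -> None:
        expected = list(combinations(self.textures, 2))
        if list(self.ratings.index) != expected:
            self.ratings = self.ratings.reindex(expected)
        if self.ratings.isna().any():
            missing = [p for p, v in self.ratings.items() if pd.isna(v)]
            raise ValueError(f"missing ratings for pairs: {missing[:10]}")
        if (self.ratings < 0).any():
            raise ValueError("ratings must be >= 0")

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(self.ratings.index)

    def __len__(self) -> int:
        return len(self.ratings)

    @classmethod
    def from_csv(cls, path) -> "DissimilarityStudy":
        df = pd.read_csv(path, dtype={"texture_a": str, "texture_b": str})
        seen: list[str] = []
        for row in df.itertuples(index=False):
            for t in (row.texture_a, row.texture_b):
                if t not in seen:
                    seen.append(t)
        ratings = pd.Series(
            df["rating"].to_numpy(),
            index=[(a, b) for a, b in zip(df["texture_a"], df["texture_b"])],
        )
        return cls(textures=seen, ratings=ratings)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "texture_a": [a for a, _ in self.ratings.index],
                "texture_b": [b for _, b in self.ratings.index],
                "rating": self.ratings.to_numpy(),
            }
        ).to_csv(path, index=False, float_format="%.17g")


def _zscore_pairs(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def build_predictors(
    rs: ResponseSet,
    labels: Mapping[str, str],
    study: DissimilarityStudy,
    resolutions: Mapping[str, float] | float = 5.0,
    max_lag: float = DEFAULT_MAX_LAG_MS,
    window: AnalysisWindow | None = None,
    speed: float | None = None,
) -> pd.DataFrame:
    """Per-pair neural predictor table (one row per texture pair).

    ``labels`` maps neuron_id -> submodality label; ``resolutions`` maps
    neuron_id -> best timing resolution in ms (or one value for all).
    Subpopulations with no labeled neurons are dropped with a warning.
    """
    w = window or AnalysisWindow(start=0.0)
    speed = speed if speed is not None else rs.design.speeds[0]
    missing = [t for t in study.textures if t not in rs.texture_ids]
    if missing:
        raise ValueError(f"study textures absent from responses: {missing}")
    pairs = study.pairs
    cols: dict[str, list[np.ndarray]] = {f"{kind}_{g}": [] for g in SUBPOPS for kind in ("rate", "timing")}
    for nid in rs.neuron_ids:
        g = labels.get(nid, "unclassified")
        if g not in SUBPOPS:
            continue
        res = resolutions[nid] if isinstance(resolutions, Mapping) else float(resolutions)
        bw = default_bin_width(res)
        mean_rate, mean_psth = {}, {}
        for tid in study.textures:
            reps = rs.trains_for(nid, tid, speed)
            mean_rate[tid] = float(np.mean([spike_rate(t, w).rate for t in reps]))
            V = np.stack(
                [smooth_counts(bin_counts(t.times, w.duration, bw), res, bw) for t in reps]
            ).mean(axis=0)
            mean_psth[tid] = Psth(V - V.mean(), bw, res, w, demeaned=True)
        rate_diff = np.array([abs(mean_rate[a] - mean_rate[b]) for a, b in pairs])
        timing_corr = np.array(
            [max_xcorr(mean_psth[a], mean_psth[b], max_lag=max_lag) for a, b in pairs]
        )
        cols[f"rate_{g}"].append(_zscore_pairs(rate_diff))
        cols[f"timing_{g}"].append(_zscore_pairs(timing_corr))
    out = {}
    for name, feats in cols.items():
        if not feats:
            logger.warning("no neurons in subpopulation for feature %s; column dropped", name)
            continue
        out[name] = np.mean(feats, axis=0)
    return pd.DataFrame(out, index=pd.Index(pairs, tupleize_cols=False))


def _loo_ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out OLS predictions via the hat matrix (exact)."""
    n = X.shape[0]
    Xi = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = np.linalg.lstsq(Xi, y, rcond=None)
    if rank < Xi.shape[1]:
        raise ValueError("collinear features; reduce the model")
    G = np.linalg.inv(Xi.T @ Xi)
    H = Xi @ G @ Xi.T
    resid = y - Xi @ beta
    loo_resid = resid / (1.0 - np.diag(H))
    return y - loo_resid, beta


def cv_regression(
    predictors: pd.DataFrame,
    ratings: pd.Series,
    model: str | Sequence[str] = "full6",
) -> tuple[float, pd.Series, pd.Series]:
    """Leave-one-pair-out cross-validated multiple regression.

    Fits OLS (with intercept) on all pairs but one, predicts the held-out
    pair, iterates over every pair, and returns (MSE across pairs,
    per-pair predictions, full-data coefficients including intercept).
    ``model`` is "rate3", "timing3", "full6", or an explicit feature list
    (a single-feature model is allowed).
    """
    features = list(MODEL_SPECS[model]) if isinstance(model, str) else list(model)
    features = [f for f in features if f in predictors.columns]
    if not features:
        raise ValueError("no requested features present in predictor table")
    if len(features) >= len(predictors) - 1:
        raise ValueError("need at least 2 more pairs than features")
    X = predictors[features].to_numpy(dtype=float)
    y = ratings.loc[predictors.index].to_numpy(dtype=float)
    corr = np.corrcoef(X.T) if X.shape[1] > 1 else np.ones((1, 1))
    bad = [
        f"{features[i]}~{features[j]}"
        for i in range(len(features))
        for j in range(i + 1, len(features))
        if abs(corr[i, j]) > 0.9999
    ]
    if bad:
        raise ValueError(f"collinear features: {', '.join(bad)}")
    preds, beta = _loo_ols(X, y)
    mse = float(np.mean((preds - y) ** 2))
    return (
        mse,
        pd.Series(preds, index=predictors.index, name="prediction"),
        pd.Series(beta, index=["intercept"] + features, name="coefficient"),
    )


def population_mse_curve(
    rs: ResponseSet,
    labels: Mapping[str, str],
    study: DissimilarityStudy,
    ratings: pd.Series,
    model: str | Sequence[str] = "full6",
    sample_sizes: Sequence[int] = (1, 2, 5, 10),
    n_iter: int = 20,
    seed: int = 0,
    resolutions: Mapping[str, float] | float = 5.0,
    **predictor_kwargs,
) -> pd.DataFrame:
    """Cross-validated MSE as a function of subpopulation sample size.

    Per iteration, ``n`` cells are sampled (without replacement, capped at
    the subpopulation size) from each submodality subpopulation, features
    are rebuilt from the sample, and the cross-validated regression is
    rerun; a subpopulation sampled at n=0 drops its feature columns.
    """
    by_group: dict[str, list[str]] = {g: [] for g in SUBPOPS}
    for nid in rs.neuron_ids:
        g = labels.get(nid, "unclassified")
        if g in by_group:
            by_group[g].append(nid)
    rng = np.random.default_rng(seed)
    rows = []
    for n in sample_sizes:
        mses = []
        for _ in range(n_iter):
            sub_labels = {}
            for g, members in by_group.items():
                k = min(n, len(members))
                for nid in rng.choice(members, size=k, replace=False):
                    sub_labels[nid] = g
            if not sub_labels:
                continue
            preds = build_predictors(
                rs, sub_labels, study, resolutions=resolutions, **predictor_kwargs
            )
            mse, _, _ = cv_regression(preds, ratings, model=model)
            mses.append(mse)
        rows.append(dict(n_per_subpop=n, mean_mse=float(np.mean(mses)), sd=float(np.std(mses))))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------


@dataclass
class DissimilarityResults:
    mse: float
    predictions: pd.Series
    coefficients: pd.Series
    model: str
    rating_variance: float

    def summary(self) -> str:
        lines = [
            f"Leave-one-pair-out dissimilarity regression ({self.model})",
            f"  pairs: {len(self.predictions)}",
            f"  cross-validated MSE: {self.mse:.4f} "
            f"(rating variance {self.rating_variance:.4f})",
            "  coefficients:",
        ]
        for name, b in self.coefficients.items():
            lines.append(f"    {name}: {b:+.4f}")
        return "\n".join(lines)

    def plot_fit(self, ratings: pd.Series, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(ratings.loc[self.predictions.index], self.predictions, s=12)
        ax.set_xlabel("rated dissimilarity")
        ax.set_ylabel("predicted dissimilarity")
        return ax


class DissimilarityRegression:
    """Cross-validated regression of ratings on neural rate/timing features."""

    def __init__(
        self,
        predictors: pd.DataFrame,
        ratings: pd.Series,
        model: str | Sequence[str] = "full6",
    ) -> None:
        self.predictors = predictors
        self.ratings = ratings
        self.model = model

    def fit(self) -> DissimilarityResults:
        mse, preds, beta = cv_regression(self.predictors, self.ratings, self.model)
        y = self.ratings.loc[self.predictors.index].to_numpy(dtype=float)
        return DissimilarityResults(
            mse=mse,
            predictions=preds,
            coefficients=beta,
            model=self.model if isinstance(self.model, str) else "+".join(self.model),
            rating_variance=float(y.var()),
        )
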