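"""Bootstrap stability selection on top of L1-regularized logistic regression.

The procedure: draw a bootstrap sample of size n; fit the sparse logistic
model over a grid of M regularization parameters; record, per (feature,
lambda) cell, whether the feature had a nonzero weight; repeat N times.  The
relative selection frequency Pi_j^lambda is the fraction of bootstrap fits
that selected feature j at penalty lambda; the *stability score* of a feature
is max over lambda of Pi_j^lambda, and the stable set keeps features whose
score reaches a threshold tau.

Defaults follow the reference configuration N=1000, Lambda={0.005*i,
i=1..60} (M=60), tau=0.5.  Because an absolute lambda grid presumes a fixed
data scale, the default ``grid_mode`` is ``relative_to_lambda_max``: the
literal grid, whose largest entry is 0.30, is rescaled by lambda_max/0.30 so
it spans (0, lambda_max] on any input; ``absolute`` mode reproduces the
literal grid.  Columns are re-standardized inside every bootstrap so each
selection event reflects the resampled data only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cohort import FeatureTable
from .sparse import (EPS_SUPPORT, fit_path, lambda_max, standardize_columns)

__all__ = [
    "StabilityConfig",
    "SelectionProfile",
    "default_lambda_grid",
    "bootstrap_indices",
    "selection_profile",
    "stable_set",
    "top_features",
]

logger = logging.getLogger(__name__)


def default_lambda_grid(m: int = 60, step: float = 0.005) -> np.ndarray:
    """The literal grid {step*i, i=1..m}; largest entry step*m (0.30)."""
    return step * np.arange(1, m + 1)


@dataclass(frozen=True)
class StabilityConfig:
    """Configuration of the bootstrap stability-selection run.

    ``n_bootstrap`` (N) resamples, lambda grid ``lambdas`` (Lambda, length M),
    threshold ``tau``; ``grid_mode`` is ``relative_to_lambda_max`` (default)
    or ``absolute``; ``stratified`` keeps the original class counts in every
    resample (on by default so no resample is single-class).
    """

    n_bootstrap: int = 1000
    lambdas: np.ndarray = field(default_factory=default_lambda_grid)
    tau: float = 0.5
    seed: int = 0
    grid_mode: str = "relative_to_lambda_max"
    min_ratio: float = 0.2
    stratified: bool = True
    tol: float = 1e-8
    max_iter: int = 5000

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, dtype=float)
        object.__setattr__(self, "lambdas", lam)
        if self.n_bootstrap < 1:
            raise ValueError("need at least one bootstrap")
        if lam.size == 0 or (lam <= 0).any():
            raise ValueError("lambda grid must be positive")
        if not (0.0 < self.tau <= 1.0):
            raise ValueError("tau must lie in (0, 1]")
        if self.grid_mode not in ("absolute", "relative_to_lambda_max"):
            raise ValueError(f"unknown grid_mode {self.grid_mode!r}")
        if not (0.0 <= self.min_ratio < 1.0):
            raise ValueError("min_ratio must lie in [0, 1)")

    @property
    def n_lambdas(self) -> int:
        return len(self.lambdas)


@dataclass
class SelectionProfile:
    """Per-(feature, lambda) selection frequencies and derived scores.

    ``frequencies`` is p x M with entries that are exact multiples of 1/N
    (count over N bootstraps); columns follow ``grid`` in increasing lambda
    order.  The stability score of a feature is its row maximum.
    """

    frequencies: np.ndarray
    grid: np.ndarray
    config: StabilityConfig
    feature_names: list[str]
    modality_tags: list[str]
    n_redraws: int = 0
    n_nonconverged: int = 0

    @property
    def stability_scores(self) -> np.ndarray:
        return self.frequencies.max(axis=1)

    def score_of(self, name: str) -> float:
        return float(self.stability_scores[self.feature_names.index(name)])

    def to_frame(self):
        import pandas as pd
        scores = self.stability_scores
        argmax = self.grid[self.frequencies.argmax(axis=1)]
        df = pd.DataFrame({
            "feature": self.feature_names,
            "modality": self.modality_tags,
            "stability_score": scores,
            "argmax_lambda": argmax,
        })
        for k, lam in enumerate(self.grid):
            df[f"pi_lambda={lam:.6g}"] = self.frequencies[:, k]
        return df


def bootstrap_indices(labels: np.ndarray, rng: np.random.Generator,
                      stratified: bool = True,
                      max_redraws: int = 100) -> tuple[np.ndarray, int]:
    """Draw a size-n bootstrap (with replacement) of subject indices.

    Stratified draws resample within each class, so class counts match the
    originals exactly.  A non-stratified draw that happens to contain a
    single class is redrawn; the redraw count is returned alongside.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < 2 or len(np.unique(labels)) < 2:
        raise ValueError("need at least two subjects and both classes")
    if stratified:
        parts = []
        for cls in (-1, 1):
            idx = np.flatnonzero(labels == cls)
            parts.append(rng.choice(idx, size=len(idx), replace=True))
        return np.concatenate(parts), 0
    for redraw in range(max_redraws + 1):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(labels[idx])) == 2:
            if redraw:
                logger.warning("bootstrap redrawn %d time(s) (single class)", redraw)
            return idx, redraw
    raise RuntimeError("could not draw a two-class bootstrap")


def _resolve_grid(cfg: StabilityConfig, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Absolute mode: the literal grid.  Relative mode: the literal grid
    mapped linearly onto (min_ratio*lambda_max, lambda_max].

    The floor keeps the grid out of the saturated regime: on a standardized
    n~p problem, penalties well below lambda_max admit so many features per
    fit that any chance-correlated column is selected in nearly every
    bootstrap and the selection frequency stops discriminating.
    """
    if cfg.grid_mode == "absolute":
        return np.asarray(cfg.lambdas, dtype=float)
    Xs, _, _ = standardize_columns(X)
    lam_max = lambda_max(Xs, y)
    lam = np.asarray(cfg.lambdas, dtype=float)
    frac = lam / float(np.max(lam))               # (0, 1]
    return lam_max * (cfg.min_ratio + (1.0 - cfg.min_ratio) * frac)


def selection_profile(table: FeatureTable, cfg: StabilityConfig) -> SelectionProfile:
    """Run the N-bootstrap selection-frequency computation.

    Requires a complete-case matrix (handle missing values upstream).  The
    per-bootstrap RNG streams are spawned from the config seed, so the result
    is identical regardless of the order bootstraps are executed in.
    Non-converged fits are counted and logged but still contribute their
    returned supports.
    """
    X = np.asarray(table.X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values present; take complete cases first")
    y = table.labels.astype(float)
    grid = _resolve_grid(cfg, X, y)
    order = np.argsort(grid)                      # profile columns: increasing lambda
    p, m = X.shape[1], len(grid)

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_bootstrap)
    counts = np.zeros((p, m), dtype=np.int64)
    n_redraws = 0
    n_nonconverged = 0
    for t in range(cfg.n_bootstrap):
        rng = np.random.default_rng(seeds[t])
        idx, redraws = bootstrap_indices(y, rng, stratified=cfg.stratified)
        n_redraws += redraws
        Xb, _, _ = standardize_columns(X[idx])
        yb = y[idx]
        path = fit_path(Xb, yb, grid, tol=cfg.tol, max_iter=cfg.max_iter,
                        standardize=False)
        bad = sum(not f.converged for f in path.fits)
        if bad:
            n_nonconverged += bad
            logger.warning("bootstrap %d: %d non-converged fit(s)", t, bad)
        # path.lambdas is decreasing; map each fit back to its grid column
        col_of = {lam: k for k, lam in enumerate(np.sort(grid))}
        for lam, fit in zip(path.lambdas, path.fits):
            counts[fit.support, col_of[lam]] += 1

    freq = counts / float(cfg.n_bootstrap)
    return SelectionProfile(
        frequencies=freq,
        grid=np.sort(grid),
        config=cfg,
        feature_names=list(table.feature_names),
        modality_tags=list(table.modality_tags),
        n_redraws=n_redraws,
        n_nonconverged=n_nonconverged,
    )


def stable_set(profile: SelectionProfile, tau: float | None = None) -> list[str]:
    """Features whose stability score reaches tau (config tau by default)."""
    tau = profile.config.tau if tau is None else tau
    if not (0.0 < tau <= 1.0):
        raise ValueError("tau must lie in (0, 1]")
    scores = profile.stability_scores
    return [n for n, s in zip(profile.feature_names, scores) if s >= tau]


def top_features(profile: SelectionProfile, t: int) -> list[str]:
    """The t features with the highest stability scores.

    Ties are broken by mean selection frequency across the grid, then by
    column order in the table — fully deterministic.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    scores = profile.stability_scores
    mean_freq = profile.frequencies.mean(axis=1)
    order = sorted(range(len(scores)),
                   key=lambda j: (-scores[j], -mean_freq[j], j))
    return [profile.feature_names[j] for j in order[:t]]
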