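"""Blocked cross-validation folds and performance statistics.

Model skill is summarised by R², RMSE, and the intercept and slope of an
ordinary-least-squares fit of observations on cross-validated
predictions (so unbiased predictions give intercept ≈ 0 and slope ≈ 1).
RMSE is computed from the raw observation−prediction differences, never
from the fitted line.

Performance is disaggregated into three scopes:

* overall  — all (observation, prediction) pairs;
* spatial  — per-monitor means of observed vs per-monitor means of
  predicted (the between-site, annual-mean skill);
* temporal — deviations of each pair from its monitor's means (the
  within-site, day-to-day skill).

Cross-validation is blocked: every observation of a monitor (or of a
grid cell, for satellite gap-filling) shares one fold, which emulates
predicting at unmonitored locations and prevents leakage of a site's own
series into its predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CVAssignment",
    "PerformanceReport",
    "make_folds",
    "performance_from_pairs",
    "decompose_performance",
    "residual_components",
]


@dataclass(frozen=True)
class CVAssignment:
    """Blocked fold assignment: every block id maps to exactly one fold."""

    kind: str                       # "monitor" or "cell"
    assignment: dict                # block id -> fold in 1..K
    n_folds: int
    seed: int

    def fold_of(self, blocks: Sequence[Hashable]) -> np.ndarray:
        return np.array([self.assignment[b] for b in blocks], dtype=int)

    def blocks_in(self, fold: int) -> list:
        return [b for b, f in self.assignment.items() if f == fold]


@dataclass(frozen=True)
class PerformanceReport:
    """OLS-based skill summary for one scope."""

    scope: str                      # overall | spatial | temporal
    r2: float
    rmse: float                    # μg/m³
    intercept: float               # μg/m³
    slope: float                   # dimensionless
    n: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.r2)

    def as_dict(self) -> dict:
        return {"scope": self.scope, "r2": self.r2, "rmse": self.rmse,
                "intercept": self.intercept, "slope": self.slope, "n": self.n}


def make_folds(blocks: Sequence[Hashable], n_folds: int = 10, seed: int = 0,
               kind: str = "monitor") -> CVAssignment:
    """Randomly split blocks into ``n_folds`` near-equal groups.

    Balancing is by block count; deterministic under ``seed``.
    """
    blocks = list(blocks)
    if len(set(blocks)) != len(blocks):
        raise ValueError("block ids must be unique")
    if len(blocks) < n_folds:
        raise ValueError(f"need at least {n_folds} blocks, got {len(blocks)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(blocks))
    assignment = {blocks[j]: (i % n_folds) + 1 for i, j in enumerate(order)}
    return CVAssignment(kind=kind, assignment=assignment, n_folds=n_folds, seed=seed)


def performance_from_pairs(observed: np.ndarray, predicted: np.ndarray,
                           scope: str = "overall") -> PerformanceReport:
    """Skill of predictions against observations (see module docstring).

    With constant predictions the OLS fit is undefined; the report then
    carries NaN for R²/intercept/slope while RMSE is still computed.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    if obs.size < 2:
        raise ValueError("need at least 2 pairs")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    if np.ptp(pred) == 0.0:
        return PerformanceReport(scope, np.nan, rmse, np.nan, np.nan, obs.size)
    fit = stats.linregress(pred, obs)
    return PerformanceReport(scope, float(fit.rvalue ** 2), rmse,
                             float(fit.intercept), float(fit.slope), obs.size)


def decompose_performance(observed: np.ndarray, predicted: np.ndarray,
                          monitor_ids: Sequence[Hashable],
                          dates: Sequence | None = None,
                          ) -> dict[str, PerformanceReport]:
    """Overall / spatial / temporal skill decomposition.

    Spatial skill compares per-monitor means; temporal skill compares
    deviations of each pair from its monitor's means.  Monitors with a
    single observation contribute to the spatial scope only.
    """
    df = pd.DataFrame({
        "obs": np.asarray(observed, dtype=float),
        "pred": np.asarray(predicted, dtype=float),
        "mon": list(monitor_ids),
    })
    overall = performance_from_pairs(df["obs"], df["pred"], "overall")
    means = df.groupby("mon").agg(obs=("obs", "mean"), pred=("pred", "mean"),
                                  n=("obs", "size"))
    spatial = performance_from_pairs(means["obs"], means["pred"], "spatial")
    multi = df.merge(means, left_on="mon", right_index=True, suffixes=("", "_m"))
    multi = multi[multi["n"] > 1]
    dev_obs = multi["obs"] - multi["obs_m"]
    dev_pred = multi["pred"] - multi["pred_m"]
    if len(multi) < 2 or np.ptp(dev_pred.to_numpy()) == 0.0:
        temporal = PerformanceReport(
            "temporal", np.nan,
            float(np.sqrt(np.mean((dev_obs - dev_pred) ** 2))) if len(multi) else np.nan,
            np.nan, np.nan, len(multi))
    else:
        temporal = performance_from_pairs(dev_obs, dev_pred, "temporal")
    return {"overall": overall, "spatial": spatial, "temporal": temporal}


def residual_components(observed: np.ndarray, predicted: np.ndarray,
                        monitor_ids: Sequence[Hashable]) -> tuple[float, float, float]:
    """Exact variance decomposition of prediction residuals around monitor means.

    Returns (total, between, within) sums of squares with
    total = between + within:

        Σ (o − p)² = Σ_m n_m (ō_m − p̄_m)² + Σ ((o − ō_m) − (p − p̄_m))²
    """
    df = pd.DataFrame({
        "r": np.asarray(observed, dtype=float) - np.asarray(predicted, dtype=float),
        "mon": list(monitor_ids),
    })
    total = float((df["r"] ** 2).sum())
    gm = df.groupby("mon")["r"]
    means = gm.transform("mean")
    counts = gm.size()
    between = float((counts * gm.mean() ** 2).sum())
    within = float(((df["r"] - means) ** 2).sum())
    return total, between, within
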