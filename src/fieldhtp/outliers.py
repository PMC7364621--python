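"""QC step 2: model-based iterative outlier removal and plot means.

Each trait is fit with a fixed-effects least-squares model on the
experimental design factors (default: plot identity, i.e. a one-way
layout whose fitted values are the plot means).  Outliers are judged by
the *studentized deleted residual*

    t_i = e_i / sqrt( MSE_(-i) * (1 - h_ii) ),
    MSE_(-i) = (SSE - e_i^2 / (1 - h_ii)) / (n - p - 1),

the residual scaled by an error estimate computed with observation i
excluded -- evaluated with the leave-one-out shortcut, no refitting.
All observations with |t_i| above the threshold tau are removed
together, the model is refit, and the cycle repeats until a fixed point
(or the iteration cap).  An optional attitude pre-filter drops
observations logged during excessive boom pitch/roll before anything is
fit.

Mixed-model variance components are deliberately not estimated: the
default design-factor model gives exact, dependency-light residual
diagnostics, and the model is configurable where a design needs more
factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

_RCOND = 1e-10


class ModelError(ValueError):
    pass


@dataclass
class ModelSpec:
    """Outlier-model specification for one trait.

    ``factors`` are categorical design factors (columns of the
    observation table); the default single ``plot_id`` factor makes the
    fitted values the plot means.  ``tau`` is the |studentized deleted
    residual| removal threshold; with ``bonferroni=True`` tau is instead
    derived from a Bonferroni-corrected t quantile each iteration.
    """

    response: str = "value"
    factors: list[str] = dc_field(default_factory=lambda: ["plot_id"])
    tau: float = 3.0
    max_iterations: int = 10
    bonferroni: bool = False
    bonferroni_alpha: float = 0.05

    def validate(self) -> None:
        if not self.tau > 0:
            raise ModelError("tau must be > 0")
        if not self.factors:
            raise ModelError("at least one factor is required")
        if self.max_iterations < 1:
            raise ModelError("max_iterations must be >= 1")


@dataclass
class FitResult:
    """A least-squares fit with the quantities QC2 needs."""

    fitted: np.ndarray
    residuals: np.ndarray  # e_i
    leverage: np.ndarray   # h_ii; sums to p
    sse: float
    n: int
    p: int  # rank of the design
    params: np.ndarray
    column_names: list[str]


def _design_matrix(df: pd.DataFrame, factors: list[str]):
    """Cell-means coding for one factor; intercept + treatment coding
    for additional factors.  Aliased columns are handled downstream by
    the rank-revealing SVD."""
    n = len(df)
    first = df[factors[0]].astype(str)
    levels = sorted(first.unique())
    cols = [f"{factors[0]}[{lv}]" for lv in levels]
    X = (first.to_numpy()[:, None] == np.array(levels)[None, :]).astype(float)
    for f in factors[1:]:
        vals = df[f].astype(str)
        lvls = sorted(vals.unique())
        for lv in lvls[1:]:  # drop first level: absorbed by the cell means
            X = np.column_stack([X, (vals == lv).astype(float)])
            cols.append(f"{f}[{lv}]")
    return X, cols


def fit_trait_model(df: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Least-squares fit of the response on the factor design.

    Exposes residuals, leverages, SSE, n, and p (the design rank).
    Rank deficiency drops aliased directions with a warning; n <= p is
    fatal (no residual degrees of freedom).
    """
    spec.validate()
    for f in spec.factors:
        if f not in df.columns:
            raise ModelError(f"factor column {f!r} missing")
    if spec.response not in df.columns:
        raise ModelError(f"response column {spec.response!r} missing")
    y = pd.to_numeric(df[spec.response], errors="coerce").to_numpy(dtype=float)
    keep = np.isfinite(y)
    if not keep.all():
        raise ModelError("response contains non-finite values; filter flags first")
    X, cols = _design_matrix(df, spec.factors)
    n, ncol = X.shape
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > _RCOND * (s[0] if len(s) else 1.0)))
    if rank < ncol:
        warnings.warn(f"rank-deficient design: {ncol - rank} aliased "
                      f"column(s) dropped", stacklevel=2)
    if n <= rank:
        raise ModelError(f"n={n} <= p={rank}: no residual degrees of freedom")
    Ur = U[:, :rank]
    coef_r = (Ur.T @ y) / s[:rank]
    params = Vt[:rank].T @ coef_r  # minimum-norm solution
    fitted = Ur @ (Ur.T @ y)
    resid = y - fitted
    leverage = np.einsum("ij,ij->i", Ur, Ur)
    return FitResult(fitted, resid, np.clip(leverage, 0.0, 1.0),
                     float(resid @ resid), n, rank, params, cols)


def studentized_deleted_residuals(fit: FitResult) -> np.ndarray:
    """t_i per observation from the leave-one-out shortcut.

    NaN where the observation is uninformative (h_ii = 1: it alone
    determines a parameter) or where n - p - 1 <= 0.
    """
    dof = fit.n - fit.p - 1
    one_minus_h = 1.0 - fit.leverage
    with np.errstate(divide="ignore", invalid="ignore"):
        if dof <= 0:
            return np.full(fit.n, np.nan)
        mse_i = (fit.sse - fit.residuals**2 / one_minus_h) / dof
        mse_i = np.where(one_minus_h <= 1e-12, np.nan, np.maximum(mse_i, 0.0))
        t = fit.residuals / np.sqrt(mse_i * one_minus_h)
    return t


def attitude_filter(observations: pd.DataFrame,
                    max_pitch: Optional[float] = None,
                    max_roll: Optional[float] = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Optional pre-filter on boom attitude.

    Removes observations whose paired |pitch| / |roll| exceeds its
    threshold; disabled thresholds (None) pass everything through.
    Returns ``(retained, removed)``.  Missing attitude columns skip the
    filter with a warning (no attitude stream to judge by).
    """
    if max_pitch is None and max_roll is None:
        return observations, observations.iloc[0:0]
    if "pitch" not in observations.columns or "roll" not in observations.columns:
        warnings.warn("no attitude stream on observations; attitude filter "
                      "skipped", stacklevel=2)
        return observations, observations.iloc[0:0]
    bad = np.zeros(len(observations), dtype=bool)
    if max_pitch is not None:
        bad |= observations["pitch"].abs().to_numpy() > max_pitch
    if max_roll is not None:
        bad |= observations["roll"].abs().to_numpy() > max_roll
    return observations[~bad], observations[bad]


def remove_outliers(observations: pd.DataFrame, spec: ModelSpec):
    """Iterative removal: fit, studentize, drop all |t_i| > tau, repeat.

    Stops at a fixed point (no removal) or after ``max_iterations``.
    Returns ``(cleaned, diagnostics, iterations_used)`` where
    diagnostics carries e_i, h_ii, t_i and ``iteration_removed``
    (0 = kept; kept rows show their final-iteration quantities).
    """
    spec.validate()
    obs = observations
    diag = pd.DataFrame(index=obs.index.copy())
    diag["residual"] = np.nan
    diag["leverage"] = np.nan
    diag["t"] = np.nan
    diag["iteration_removed"] = 0
    current = obs
    iterations = 0
    for it in range(1, spec.max_iterations + 1):
        iterations = it
        if len(current) == 0:
            raise ModelError("all observations removed; check tau and the model")
        fit = fit_trait_model(current, spec)
        t = studentized_deleted_residuals(fit)
        diag.loc[current.index, "residual"] = fit.residuals
        diag.loc[current.index, "leverage"] = fit.leverage
        diag.loc[current.index, "t"] = t
        tau = spec.tau
        if spec.bonferroni:
            dof = fit.n - fit.p - 1
            tau = float(stats.t.ppf(1.0 - spec.bonferroni_alpha / (2.0 * fit.n), dof))
        with np.errstate(invalid="ignore"):
            drop = np.abs(t) > tau
        drop = np.where(np.isnan(t), False, drop)
        if not drop.any():
            break
        diag.loc[current.index[drop], "iteration_removed"] = it
        current = current[~drop]
    if len(current) == 0:
        raise ModelError("all observations removed; check tau and the model")
    return current, diag, iterations


def plot_means(observations: pd.DataFrame, value_col: str = "value",
               by: tuple = ("plot_id", "trait"),
               plot_universe: Optional[list] = None) -> pd.DataFrame:
    """Arithmetic mean / SD / n per plot x trait after QC.

    Plots from ``plot_universe`` with no surviving observations are
    reported with n = 0 and missing means (so empty plots are visible,
    not silently absent).
    """
    by = list(by)
    g = observations.groupby(by, sort=True)[value_col]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out.loc[out["n"] == 1, "sd"] = 0.0
    if plot_universe is not None:
        traits_present = (sorted(observations[by[1]].unique())
                          if len(by) > 1 and len(observations) else [])
        want = pd.MultiIndex.from_product(
            [list(plot_universe), traits_present or [""]], names=by)
        have = pd.MultiIndex.from_frame(out[by].astype(object))
        missing = want.difference(have) if traits_present else want
        if len(missing):
            add = pd.DataFrame(index=missing).reset_index()
            add["mean"] = np.nan
            add["sd"] = np.nan
            add["n"] = 0
            out = pd.concat([out, add], ignore_index=True)
            out = out.sort_values(by, kind="stable").reset_index(drop=True)
    return out
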