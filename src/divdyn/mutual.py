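"""Sliding-window mutual prediction and determinism / nonlinearity diagnostics.

A change in an indicator's dynamical rule is detected by training a simplex
forecaster on one sliding window and testing it on every other window: if the
rule changed between two windows, mutual prediction fails (sRMSE >= 1) even
though each window may predict itself well.  The n_w x n_w matrix of
standardized errors (rows = training window, columns = test window) is the
indicator's *mutual prediction matrix*; block structure in it localizes
regime shifts, and its diagonal measures determinism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from divdyn.edm import (
    DEFAULT_E_RANGE,
    DEFAULT_PENALTY_GRID,
    DEFAULT_THETA_GRID,
    estimate_theta,
    optimal_embedding,
    simplex_cross_prediction,
)

logger = logging.getLogger(__name__)


@dataclass
class WindowSet:
    """Contiguous, overlapping, stride-1 sliding windows over a series."""

    n: int
    w: int

    def __post_init__(self) -> None:
        if self.w < 4:
            raise ValueError("window length must be at least 4 for embedding")
        if self.n < self.w:
            raise ValueError(f"series length {self.n} shorter than window {self.w}")

    @property
    def starts(self) -> np.ndarray:
        return np.arange(self.n - self.w + 1)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """(start, end) index pairs, end exclusive."""
        return [(int(s), int(s + self.w)) for s in self.starts]

    def __len__(self) -> int:
        return self.n - self.w + 1


def make_windows(n: int, w: int) -> WindowSet:
    """All ``n - w + 1`` stride-1 windows of length ``w`` over an n-point series."""
    return WindowSet(int(n), int(w))


@dataclass
class MutualPredictionMatrix:
    """Mutual-prediction sRMSE matrix for one indicator.

    ``srmse[i, j]`` is the standardized error of a simplex model trained on
    window i (embedding dimension ``e_star[i]``, chosen by self-prediction)
    forecasting window j; the diagonal holds leave-one-out self-predictions.
    """

    name: str
    srmse: np.ndarray
    e_star: np.ndarray
    windows: WindowSet

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.srmse)

    @property
    def n_windows(self) -> int:
        return len(self.windows)


def _check_no_missing(values: np.ndarray, index) -> None:
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        labels = [index[i] for i in bad] if index is not None else bad.tolist()
        raise ValueError(
            f"series contains missing values at surveys {labels}; "
            "windows may not contain missing values"
        )


def mutual_prediction_matrix(
    series,
    w: int,
    E_range=DEFAULT_E_RANGE,
    tau: int = 1,
    tp: int = 1,
    theiler: int = 0,
    name: str | None = None,
) -> MutualPredictionMatrix:
    """Train on every window, test on every window.

    The training window's embedding dimension is chosen once by maximizing
    its own leave-one-out prediction skill and reused across the whole row.
    Standardization of entry (i, j) uses the population sd of window j's
    observed one-step targets, so each column has the untrained-model
    baseline at exactly 1.  Constant test windows give an undefined (NaN)
    column, logged.
    """
    if isinstance(series, pd.Series):
        index = list(series.index)
        values = series.to_numpy(dtype=float)
        name = name or (str(series.name) if series.name is not None else "series")
    else:
        values = np.asarray(series, dtype=float)
        index = None
        name = name or "series"
    _check_no_missing(values, index)

    windows = make_windows(values.size, w)
    n_w = len(windows)
    slices = [values[s:e] for s, e in windows.pairs]

    e_star = np.empty(n_w, dtype=int)
    for i, x in enumerate(slices):
        e_star[i], _ = optimal_embedding(x, E_range, tau, tp, theiler)

    mat = np.full((n_w, n_w), np.nan)
    constant_cols = set()
    for i, (lib, (lib_start, _)) in enumerate(zip(slices, windows.pairs)):
        for j, (tgt, (tgt_start, _)) in enumerate(zip(slices, windows.pairs)):
            res = simplex_cross_prediction(
                lib,
                tgt,
                int(e_star[i]),
                tau,
                tp,
                lib_offset=lib_start,
                tgt_offset=tgt_start,
                theiler=theiler,
            )
            mat[i, j] = res.srmse
            if not np.isfinite(res.srmse) and j not in constant_cols:
                constant_cols.add(j)
    if constant_cols:
        logger.warning(
            "%s: undefined sRMSE entries in test windows %s (constant targets)",
            name,
            sorted(constant_cols),
        )
    return MutualPredictionMatrix(name, mat, e_star, windows)


def determinism_fraction(matrix: MutualPredictionMatrix) -> float:
    """Proportion of windows whose self-prediction sRMSE is strictly below 1."""
    diag = matrix.diagonal
    if not np.all(np.isfinite(diag)):
        logger.warning(
            "%s: %d undefined diagonal entries counted as failures",
            matrix.name,
            int(np.sum(~np.isfinite(diag))),
        )
    return float(np.sum(diag < 1.0) / diag.size)


def block_contrast(
    matrix: MutualPredictionMatrix, change_index: int, mode: str = "contain"
) -> float:
    """Mean cross-regime minus mean within-regime sRMSE around a change point.

    ``mode="contain"`` assigns a window to a regime only if it lies entirely
    on one side of ``change_index`` (windows straddling the boundary are
    dropped); ``mode="center"`` assigns every window by the side its center
    falls on.  Positive values mean models trained in one regime forecast
    the other regime worse than their own — the signature of a change in the
    dynamical rule.
    """
    pairs = matrix.windows.pairs
    if mode == "contain":
        group = np.array(
            [0 if e <= change_index else (1 if s >= change_index else -1) for s, e in pairs]
        )
    elif mode == "center":
        group = np.array([0 if (s + e) / 2 < change_index else 1 for s, e in pairs])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    in_a, in_b = np.flatnonzero(group == 0), np.flatnonzero(group == 1)
    if in_a.size == 0 or in_b.size == 0:
        raise ValueError("no windows fully on one side of the change point")
    m = matrix.srmse
    within = np.concatenate([m[np.ix_(in_a, in_a)].ravel(), m[np.ix_(in_b, in_b)].ravel()])
    cross = np.concatenate([m[np.ix_(in_a, in_b)].ravel(), m[np.ix_(in_b, in_a)].ravel()])
    return float(np.nanmean(cross) - np.nanmean(within))


def window_size_scan(
    series,
    sizes,
    E_range=DEFAULT_E_RANGE,
    tau: int = 1,
    tp: int = 1,
    theiler: int = 0,
) -> pd.DataFrame:
    """Skill-versus-sensitivity report over candidate window lengths.

    For each feasible size the mean self-prediction sRMSE (skill; smaller is
    better) and the cross-midpoint minus within-half mean sRMSE (sensitivity
    proxy for detecting a mid-series change in dynamics; larger is more
    sensitive) are tabulated.  The table is a report only — no size is
    selected automatically.  Windows are assigned to series halves by their
    centers, so the proxy is defined even when every window straddles the
    midpoint.
    """
    values = (
        series.to_numpy(dtype=float) if isinstance(series, pd.Series) else np.asarray(series, float)
    )
    rows = []
    for w in sizes:
        try:
            mat = mutual_prediction_matrix(values, int(w), E_range, tau, tp, theiler)
            contrast = block_contrast(mat, values.size // 2, mode="center")
        except ValueError as exc:
            logger.warning("window size %s skipped: %s", w, exc)
            continue
        rows.append(
            {
                "w": int(w),
                "n_windows": mat.n_windows,
                "mean_self_srmse": float(np.nanmean(mat.diagonal)),
                "sensitivity": contrast,
            }
        )
    return pd.DataFrame(rows, columns=["w", "n_windows", "mean_self_srmse", "sensitivity"])


def window_thetas(
    series,
    w: int,
    E_range=DEFAULT_E_RANGE,
    theta_grid=DEFAULT_THETA_GRID,
    penalties=DEFAULT_PENALTY_GRID,
    tau: int = 1,
    tp: int = 1,
    theiler: int = 0,
    stride: int = 1,
    selection: str = "1se",
) -> pd.DataFrame:
    """S-map locality theta for each (or every ``stride``-th) sliding window."""
    values = (
        series.to_numpy(dtype=float) if isinstance(series, pd.Series) else np.asarray(series, float)
    )
    _check_no_missing(values, None)
    windows = make_windows(values.size, w)
    rows = []
    for s, e in windows.pairs[::stride]:
        x = values[s:e]
        E, _ = optimal_embedding(x, E_range, tau, tp, theiler)
        res = estimate_theta(
            x, E, theta_grid, penalties, tau=tau, tp=tp, selection=selection
        )
        rows.append({"start": s, "E": E, "theta": res.theta})
    return pd.DataFrame(rows, columns=["start", "E", "theta"])


def nonlinearity_test(
    thetas: dict[str, np.ndarray],
    alpha: float = 0.05,
    method: str = "t",
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simultaneous one-sided tests of "theta = 0 in every window".

    For each indicator the per-window theta estimates are compared against
    the linear-dynamics reference value 0 (a many-to-one, Dunnett-style
    comparison).  ``method="t"`` uses a one-sample one-sided t statistic;
    ``method="signflip"`` replaces the t reference distribution with a
    sign-flip permutation null, offered because the dependence between
    overlapping windows is unknown.  Familywise error across indicators is
    controlled with the Sidak step (exact under independence of the
    indicator-level statistics).

    Degenerate inputs are decided exactly: all thetas zero -> p = 1; all
    equal and positive -> p = 0 (both logged).
    """
    if method not in ("t", "signflip"):
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    names = list(thetas)
    m = len(names)
    rows = []
    for nm in names:
        th = np.asarray(thetas[nm], dtype=float)
        n = th.size
        if n < 5:
            raise ValueError(f"{nm}: need at least 5 windows, got {n}")
        if np.any(th < 0):
            raise ValueError(f"{nm}: theta estimates must be non-negative")
        mean = float(th.mean())
        sd = float(th.std(ddof=1))
        if sd == 0:
            p_raw = 1.0 if mean == 0 else 0.0
            stat = 0.0 if mean == 0 else np.inf
            logger.info("%s: zero variance in theta, exact decision p=%g", nm, p_raw)
        elif method == "t":
            stat = mean / (sd / np.sqrt(n))
            p_raw = float(stats.t.sf(stat, df=n - 1))
        else:
            stat = mean
            flips = rng.choice([-1.0, 1.0], size=(n_perm, n))
            null = (flips * th).mean(axis=1)
            p_raw = float((1 + np.sum(null >= mean)) / (1 + n_perm))
        rows.append({"indicator": nm, "n": n, "mean_theta": mean, "statistic": stat, "p_raw": p_raw})
    out = pd.DataFrame(rows).set_index("indicator")
    out["p_adj"] = 1.0 - (1.0 - out["p_raw"]) ** m
    out["significant"] = out["p_adj"] <= alpha
    return out
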