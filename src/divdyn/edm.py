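"""State-space reconstruction and nonlinear forecasting primitives.

The engine behind the sliding-window analysis: Takens delay embedding of a
scalar window, simplex-projection forecasting (exponentially distance-weighted
average of the E+1 nearest library neighbors' one-step futures), the
standardized forecast error sRMSE = RMSE / sd(observed targets), and the
regularized S-map (locally weighted penalized linear forecasting) whose
locality parameter theta measures state dependence of the dynamics.

Conventions used throughout (configurable where noted):

* time delay tau = 1 and prediction horizon Tp = 1 — the surveys this package
  targets are at a single (monthly) cadence and one-step forecasts are the
  sharpest probe of the local dynamical rule;
* population (1/n) standard deviations, so that predicting the mean of the
  test targets yields sRMSE = 1 exactly, and sRMSE >= 1 marks deterministic
  prediction failure;
* leave-one-out exclusion removes library points that share a time index with
  the target (a Theiler window of ``theiler`` extra neighbors on each side,
  default 0).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet

logger = logging.getLogger(__name__)

#: locality grid for the regularized S-map, spanning the global-linear limit
#: (theta = 0) through strongly state-dependent maps
DEFAULT_THETA_GRID = (0.0, 0.1, 0.3, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0)

#: elastic-net penalty path searched inside each S-map fit
DEFAULT_PENALTY_GRID = (1e-4, 1e-3, 1e-2, 1e-1, 1.0)

#: default embedding-dimension search range (upper end capped by window size)
DEFAULT_E_RANGE = tuple(range(1, 11))


class EmbeddingError(ValueError):
    """Raised when a series is too short for the requested embedding."""


@dataclass
class PredictionResult:
    """Forecasts for one (library, target) window pair."""

    predicted: np.ndarray
    observed: np.ndarray
    rmse: float
    srmse: float  # NaN when the observed targets are constant

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.observed = np.asarray(self.observed, dtype=float)


@dataclass
class NonlinearityResult:
    """Outcome of the S-map locality (theta) grid search on one window."""

    theta: float
    grid: np.ndarray
    errors: np.ndarray  # leave-one-out sRMSE per grid value
    losses: list = field(repr=False, default_factory=list)  # per-target sq. errors


def _pop_sd(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def srmse(pred, obs) -> float:
    """RMSE standardized by the population sd of the observed values.

    sd(obs) is the expected RMSE of an untrained model that always predicts
    the mean of the test data, so a value of 1 means "no better than the
    mean" and values >= 1 flag deterministic prediction failure.  Returns NaN
    (with a log message) when the observed targets are constant.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("pred and obs must be 1-d arrays of equal length")
    if obs.size < 2:
        raise ValueError("need at least two observations")
    sd = _pop_sd(obs)
    if sd == 0:
        logger.info("sRMSE undefined: constant observed targets")
        return float("nan")
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    return rmse / sd


def delay_embed(x, E: int, tau: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Lagged-coordinate embedding of a scalar series.

    Returns ``(points, times)`` where ``points[k] = (x_t, x_{t-tau}, ...,
    x_{t-(E-1)tau})`` and ``times[k] = t`` is the index of the leading
    coordinate.  The number of points is ``len(x) - (E-1)*tau``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if E < 1 or tau < 1:
        raise ValueError("E and tau must be positive integers")
    min_len = (E - 1) * tau + 1
    if x.size < min_len:
        raise EmbeddingError(
            f"series of length {x.size} too short for E={E}, tau={tau}; "
            f"need at least {min_len} points"
        )
    times = np.arange((E - 1) * tau, x.size)
    points = np.column_stack([x[times - j * tau] for j in range(E)])
    return points, times


def _simplex_forecasts(
    lib_points: np.ndarray,
    lib_times: np.ndarray,
    lib_futures: np.ndarray,
    tgt_points: np.ndarray,
    tgt_times: np.ndarray,
    E: int,
    theiler: int = 0,
) -> np.ndarray:
    """Simplex-projection forecasts for each target point.

    Library points whose time index is within ``theiler`` of the target's are
    excluded (this removes the target itself during self-prediction and
    shared points between overlapping windows).  Weights are
    ``exp(-d_k / d_min)``; if the nearest usable neighbor is at distance 0,
    all zero-distance neighbors get weight 1 and the rest weight 0.
    """
    n_neighbors = E + 1
    dist = cdist(tgt_points, lib_points)
    excluded = np.abs(tgt_times[:, None] - lib_times[None, :]) <= theiler
    dist = np.where(excluded, np.inf, dist)

    usable = np.isfinite(dist).sum(axis=1)
    if np.any(usable < n_neighbors):
        bad = int(tgt_times[np.argmin(usable)])
        raise ValueError(
            f"fewer than E+1={n_neighbors} usable neighbors for target at "
            f"time {bad} after exclusion"
        )

    preds = np.empty(len(tgt_points))
    # stable ordering: distance first, then library time, so ties are broken
    # deterministically toward earlier library points
    order = np.lexsort((np.broadcast_to(lib_times, dist.shape), dist), axis=1)
    for i in range(len(tgt_points)):
        idx = order[i, :n_neighbors]
        d = dist[i, idx]
        d_min = d[0]
        if d_min == 0.0:
            zero = dist[i] == 0.0
            preds[i] = lib_futures[zero].mean()
        else:
            w = np.exp(-d / d_min)
            preds[i] = float(np.dot(w, lib_futures[idx]) / w.sum())
    return preds


def _window_library(x: np.ndarray, E: int, tau: int, tp: int):
    """Embedded points of a window that have an in-window Tp-step future."""
    points, times = delay_embed(x, E, tau)
    has_future = times + tp <= x.size - 1
    return points[has_future], times[has_future], x[times[has_future] + tp]


def simplex_self_prediction(
    x, E: int, tau: int = 1, tp: int = 1, theiler: int = 0
) -> PredictionResult:
    """Leave-one-out simplex forecast of a window from itself."""
    x = np.asarray(x, dtype=float)
    points, times, futures = _window_library(x, E, tau, tp)
    if len(points) < E + 2:
        raise EmbeddingError(
            f"window of length {x.size} leaves {len(points)} embedded points "
            f"for E={E}; need at least {E + 2}"
        )
    preds = _simplex_forecasts(points, times, futures, points, times, E, theiler)
    rmse = float(np.sqrt(np.mean((preds - futures) ** 2)))
    return PredictionResult(preds, futures, rmse, srmse(preds, futures))


def simplex_cross_prediction(
    lib_x,
    tgt_x,
    E: int,
    tau: int = 1,
    tp: int = 1,
    lib_offset: int = 0,
    tgt_offset: int = 0,
    theiler: int = 0,
) -> PredictionResult:
    """Simplex forecast of one window's dynamics using another as library.

    ``lib_offset`` and ``tgt_offset`` place the two windows on a common time
    axis; points shared between overlapping windows are excluded from their
    own neighbor sets exactly as in leave-one-out.
    """
    lib_x = np.asarray(lib_x, dtype=float)
    tgt_x = np.asarray(tgt_x, dtype=float)
    lib_points, lib_times, lib_futures = _window_library(lib_x, E, tau, tp)
    tgt_points, tgt_times, tgt_futures = _window_library(tgt_x, E, tau, tp)
    preds = _simplex_forecasts(
        lib_points,
        lib_times + lib_offset,
        lib_futures,
        tgt_points,
        tgt_times + tgt_offset,
        E,
        theiler,
    )
    rmse = float(np.sqrt(np.mean((preds - tgt_futures) ** 2)))
    return PredictionResult(preds, tgt_futures, rmse, srmse(preds, tgt_futures))


def feasible_embeddings(
    n: int, E_range=DEFAULT_E_RANGE, tau: int = 1, tp: int = 1
) -> list[int]:
    """Embedding dimensions whose library keeps at least E+2 points."""
    return [E for E in E_range if n - (E - 1) * tau - tp >= E + 2]


def optimal_embedding(
    x,
    E_range=DEFAULT_E_RANGE,
    tau: int = 1,
    tp: int = 1,
    theiler: int = 0,
) -> tuple[int, dict[int, float]]:
    """Embedding dimension maximizing leave-one-out self-prediction skill.

    Evaluates the self-prediction sRMSE for every feasible E in ``E_range``
    and returns the minimizer (ties broken toward smaller E) together with
    the per-E error map.
    """
    x = np.asarray(x, dtype=float)
    feasible = feasible_embeddings(x.size, E_range, tau, tp)
    if not feasible:
        raise EmbeddingError(
            f"no feasible embedding dimension in {tuple(E_range)} for a "
            f"window of length {x.size}"
        )
    errors: dict[int, float] = {}
    for E in feasible:
        errors[E] = simplex_self_prediction(x, E, tau, tp, theiler).srmse
    finite = {E: e for E, e in errors.items() if np.isfinite(e)}
    if not finite:
        logger.warning("all self-prediction errors undefined; falling back to E=%d", feasible[0])
        return feasible[0], errors
    best = min(finite, key=lambda E: (finite[E], E))
    return best, errors


def _smap_losses(
    x: np.ndarray,
    E: int,
    theta: float,
    penalties,
    l1_ratio: float,
    tau: int,
    tp: int,
) -> tuple[np.ndarray, float]:
    """Per-target squared LOO errors at the best penalty, plus that penalty."""
    points, times, futures = _window_library(x, E, tau, tp)
    m = len(points)
    if m < E + 2:
        raise EmbeddingError("window too short for S-map embedding")

    penalties = [float(p) for p in penalties]
    if any(p < 0 for p in penalties):
        raise ValueError("penalties must be non-negative")
    if any(p == 0 for p in penalties):
        smallest = min(p for p in penalties if p > 0)
        logger.info("zero penalty replaced by smallest positive grid value %g", smallest)
        penalties = [p if p > 0 else smallest for p in penalties]
    penalties = sorted(set(penalties), reverse=True)

    dist = cdist(points, points)
    sq_err = np.zeros((len(penalties), m))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for i in range(m):
            others = np.arange(m) != i
            d = dist[i, others]
            d_bar = d.mean()
            w = np.ones(d.size) if d_bar == 0 else np.exp(-theta * d / d_bar)
            X, y = points[others], futures[others]
            model = ElasticNet(
                alpha=penalties[0],
                l1_ratio=l1_ratio,
                max_iter=5000,
                tol=1e-8,
                warm_start=True,
            )
            for k, lam in enumerate(penalties):
                model.set_params(alpha=lam)
                model.fit(X, y, sample_weight=w)
                pred = float(model.predict(points[i : i + 1])[0])
                sq_err[k, i] = (pred - futures[i]) ** 2
    best = int(np.argmin(sq_err.mean(axis=1)))
    return sq_err[best], penalties[best]


def regularized_smap(
    x,
    E: int,
    theta: float,
    penalties=DEFAULT_PENALTY_GRID,
    l1_ratio: float = 0.5,
    tau: int = 1,
    tp: int = 1,
) -> float:
    """Leave-one-out sRMSE of the regularized S-map at a given locality theta.

    For each target point a linear map is fit on all other embedded points
    with state-space weights ``exp(-theta * d / d_bar)`` (d_bar = mean
    distance to the target) under an elastic-net penalty; the penalty level
    is chosen from ``penalties`` by the same leave-one-out criterion.  The
    window is z-scored before fitting so the penalty grid has a common scale.
    """
    if theta < 0:
        raise ValueError("theta must be non-negative")
    x = np.asarray(x, dtype=float)
    sd = _pop_sd(x)
    if sd == 0:
        raise ValueError("constant window: S-map undefined")
    z = (x - x.mean()) / sd
    losses, _ = _smap_losses(z, E, theta, penalties, l1_ratio, tau, tp)
    _, _, futures = _window_library(z, E, tau, tp)
    sd_f = _pop_sd(futures)
    if sd_f == 0:
        return float("nan")
    return float(np.sqrt(losses.mean()) / sd_f)


def estimate_theta(
    x,
    E: int,
    theta_grid=DEFAULT_THETA_GRID,
    penalties=DEFAULT_PENALTY_GRID,
    l1_ratio: float = 0.5,
    tau: int = 1,
    tp: int = 1,
    selection: str = "1se",
) -> NonlinearityResult:
    """Grid-search the S-map locality theta on one window.

    ``selection="min"`` returns the strict minimizer of the leave-one-out
    error (ties toward theta = 0).  The default ``"1se"`` applies the
    one-standard-error rule familiar from penalized-regression
    cross-validation: the smallest theta whose mean loss is within one
    standard error of the minimum.  S-map error curves are nearly flat in
    theta for linear-stochastic windows, so the strict argmin is dominated
    by selection noise there; the 1-SE rule resolves those near-ties toward
    the linear null and leaves strongly nonlinear windows (whose error drops
    sharply with theta) unaffected.
    """
    grid = np.asarray(sorted(set(float(t) for t in theta_grid)))
    if grid.size == 0 or grid[0] != 0.0:
        raise ValueError("theta grid must include 0")
    x = np.asarray(x, dtype=float)
    sd = _pop_sd(x)
    if sd == 0:
        raise ValueError("constant window: S-map undefined")
    z = (x - x.mean()) / sd
    _, _, futures = _window_library(z, E, tau, tp)
    sd_f = _pop_sd(futures)

    losses = []
    for theta in grid:
        loss, _ = _smap_losses(z, E, theta, penalties, l1_ratio, tau, tp)
        losses.append(loss)
    mse = np.array([loss.mean() for loss in losses])
    errors = np.sqrt(mse) / sd_f if sd_f > 0 else np.full(grid.size, np.nan)

    i_min = int(np.argmin(mse))  # np.argmin takes the first, i.e. smaller theta
    if selection == "min":
        theta_star = float(grid[i_min])
    elif selection == "1se":
        n = losses[i_min].size
        se = float(np.std(losses[i_min], ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        within = np.flatnonzero(mse <= mse[i_min] + se)
        theta_star = float(grid[within[0]])
    else:
        raise ValueError(f"unknown selection rule: {selection!r}")
    return NonlinearityResult(theta_star, grid, errors, losses)
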