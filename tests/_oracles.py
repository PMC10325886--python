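"""Independent brute-force oracles used to cross-check the fast implementations."""

from __future__ import annotations

import math

import numpy as np


def embed_by_hand(x, E, tau=1):
    """Lagged coordinates built with explicit Python loops."""
    x = list(map(float, x))
    points, times = [], []
    for t in range((E - 1) * tau, len(x)):
        points.append([x[t - j * tau] for j in range(E)])
        times.append(t)
    return points, times


def simplex_oracle(lib_points, lib_times, lib_futures, tgt_points, tgt_times, E, theiler=0):
    """Exhaustive neighbor enumeration + independent weighted average.

    Returns (predictions, neighbor_time_sets); the latter lets structural
    tests assert that a target never appears in its own neighbor set.
    """
    preds, neighbor_sets = [], []
    for p, t in zip(tgt_points, tgt_times):
        cand = []
        for q, lt, f in zip(lib_points, lib_times, lib_futures):
            if abs(lt - t) <= theiler:
                continue
            d = math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))
            cand.append((d, lt, f))
        cand.sort(key=lambda c: (c[0], c[1]))
        sel = cand[: E + 1]
        if sel[0][0] == 0.0:
            zeros = [f for d, lt, f in cand if d == 0.0]
            preds.append(sum(zeros) / len(zeros))
            neighbor_sets.append({lt for d, lt, f in cand if d == 0.0})
        else:
            dmin = sel[0][0]
            ws = [math.exp(-d / dmin) for d, lt, f in sel]
            preds.append(sum(w * f for w, (d, lt, f) in zip(ws, sel)) / sum(ws))
            neighbor_sets.append({lt for d, lt, f in sel})
    return np.array(preds), neighbor_sets


def self_prediction_oracle(x, E, tau=1, tp=1, theiler=0):
    """Leave-one-out simplex self-prediction, fully independent code path."""
    points, times = embed_by_hand(x, E, tau)
    usable = [(p, t, float(x[t + tp])) for p, t in zip(points, times) if t + tp < len(x)]
    pts = [p for p, t, f in usable]
    tms = [t for p, t, f in usable]
    futs = [f for p, t, f in usable]
    preds, _ = simplex_oracle(pts, tms, futs, pts, tms, E, theiler)
    obs = np.array(futs)
    rmse = math.sqrt(float(np.mean((preds - obs) ** 2)))
    sd = math.sqrt(float(np.mean((obs - obs.mean()) ** 2)))
    return preds, obs, rmse, (rmse / sd if sd > 0 else float("nan"))


def ar1(n, phi=0.5, sigma=1.0, seed=0, burn=100):
    rng = np.random.default_rng(seed)
    x = 0.0
    out = np.empty(n)
    for t in range(-burn, n):
        x = phi * x + rng.normal(0.0, sigma)
        if t >= 0:
            out[t] = x
    return out


def logistic(n, r=3.8, seed=0, burn=100):
    rng = np.random.default_rng(seed)
    y = float(rng.uniform(0.2, 0.8))
    for _ in range(burn):
        y = r * y * (1 - y)
    out = np.empty(n)
    out[0] = y
    for t in range(1, n):
        out[t] = r * out[t - 1] * (1 - out[t - 1])
    return out
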