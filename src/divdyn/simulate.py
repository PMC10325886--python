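"""Synthetic communities and fixtures with known dynamical ground truth.

Three generators:

* :func:`piecewise_map` — a scalar logistic map whose parameter switches at a
  known index, the minimal series with a planted change in the dynamical rule
  (what the mutual-prediction matrix must reveal as a cross-regime block of
  prediction failures);
* :func:`community_sim` — a multispecies Ricker community with seasonal
  temperature forcing, a low-latitude immigrant pool whose members appear only
  in the warm season (species turnover), and an optional mid-series warming
  shift of the forcing mean (the regime change);
* :func:`archetype_matrices` — stylized mutual-prediction matrices for the
  three responsiveness archetypes (uniformly predictable, two-regime block
  structure, unpredictable/noisy) used to exercise the classifier.

Everything is reproducible from the supplied seed.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def piecewise_map(
    n: int,
    change_index: int,
    r_before: float,
    r_after: float,
    seed: int | None = None,
    x0: float | None = None,
    burn_in: int = 100,
) -> np.ndarray:
    """Logistic map x -> r x (1 - x) with the parameter switching mid-series.

    Points ``0 .. change_index-1`` are generated under ``r_before`` and the
    rest under ``r_after``.  The initial condition is drawn from the seed
    unless ``x0`` is given, and ``burn_in`` iterations under ``r_before``
    are discarded so the series starts on the attractor.
    """
    for name, r in (("r_before", r_before), ("r_after", r_after)):
        if not (0 < r <= 4):
            raise ValueError(f"{name}={r} outside (0, 4]")
    if not (0 < change_index < n):
        raise ValueError(f"change_index must lie strictly inside the series (got {change_index})")
    if x0 is None:
        x0 = float(np.random.default_rng(seed).uniform(0.1, 0.9))
    if not (0 < x0 < 1):
        raise ValueError("x0 must lie in (0, 1)")
    x = x0
    for _ in range(burn_in):
        x = r_before * x * (1 - x)
    out = np.empty(n)
    out[0] = x
    for t in range(1, n):
        r = r_before if t < change_index else r_after
        out[t] = r * out[t - 1] * (1 - out[t - 1])
    return out


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic monitoring community.

    Defaults emulate roughly 7 years of monthly visual-census surveys of a
    temperate coastal fish community: ~90 surveys, tens of species, strong
    seasonality (period 12), a seasonal low-latitude immigrant pool, and a
    warming shift of the forcing mean halfway through the series.
    """

    n_species: int = 40
    n_time: int = 88
    regime_change: int | None = 44  # survey index where the forcing mean shifts
    season_amplitude: float = 2.0  # deg C seasonal temperature swing
    season_period: int = 12
    warming_shift: float = 2.0  # deg C mean shift after the regime change
    interaction_scale: float = 0.15  # strength of interspecific competition
    immigration: float = 0.8  # warm-season immigration of the low-latitude pool
    migrant_fraction: float = 0.5  # share of species from the low-latitude pool
    obs_noise: float = 0.2  # lognormal sd of the observation intensity
    burn_in: int = 36
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "season_amplitude",
            "warming_shift",
            "interaction_scale",
            "immigration",
            "obs_noise",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.migrant_fraction <= 1:
            raise ValueError("migrant_fraction must lie in [0, 1]")
        if self.n_species < 2 or self.n_time < 2:
            raise ValueError("need at least 2 species and 2 time points")
        if self.regime_change is not None and not (0 < self.regime_change < self.n_time):
            raise ValueError("regime_change must lie strictly inside the series")


def _taxonomy(n_species: int, rng) -> pd.DataFrame:
    """Nested genus/family/order labels: ~2 species per genus, 2 genera per
    family, 2 families per order."""
    n_genera = max(2, n_species // 2)
    n_families = max(2, n_genera // 2)
    n_orders = max(2, n_families // 2)
    genus_of_species = rng.integers(0, n_genera, size=n_species)
    family_of_genus = rng.integers(0, n_families, size=n_genera)
    order_of_family = rng.integers(0, n_orders, size=n_families)
    return pd.DataFrame(
        {
            "genus": [f"G{g:03d}" for g in genus_of_species],
            "family": [f"F{family_of_genus[g]:03d}" for g in genus_of_species],
            "order": [f"O{order_of_family[family_of_genus[g]]:03d}" for g in genus_of_species],
        },
        index=pd.Index([f"sp{i:03d}" for i in range(n_species)], name="species"),
    )


def community_sim(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multispecies Ricker community under seasonal, shiftable forcing.

    Latent abundances follow
    ``u_{i,t+1} = u_{i,t} exp(r_i(t) - u_{i,t}/K_i - c_i(t)) + m_i(t)``
    with temperature-dependent growth ``r_i(t) = r0_i + a_i T(t)``, where the
    thermal affinity ``a_i`` increases as the species' latitudinal center of
    distribution (COD) decreases — low-COD species thrive in the warm season
    and crash in winter, re-seeded by seasonal immigration ``m_i(t)``.
    ``c_i(t)`` is weak random interspecific competition.  Observed counts
    are Poisson draws around the jittered latent abundance.

    Returns ``(community, species_table)``: an ``n_time x n_species`` integer
    count table indexed by monthly survey dates, and the per-species
    taxonomy/COD table.
    """
    rng = np.random.default_rng(cfg.seed)
    n_sp, n_t = cfg.n_species, cfg.n_time

    species = _taxonomy(n_sp, rng)
    is_migrant = rng.random(n_sp) < cfg.migrant_fraction
    cod = np.where(
        is_migrant, rng.normal(22.0, 3.0, n_sp), rng.normal(34.0, 2.0, n_sp)
    )
    species["cod_latitude"] = np.round(cod, 2)

    affinity = np.clip((30.0 - cod) / 10.0, -0.6, 1.5)  # warm-lovers: positive
    r0 = np.where(is_migrant, rng.uniform(-0.8, -0.2, n_sp), rng.uniform(0.4, 0.9, n_sp))
    K = np.exp(rng.normal(np.log(25.0), 0.7, n_sp))
    A = (rng.random((n_sp, n_sp)) < 0.15) * rng.uniform(0, 1, (n_sp, n_sp))
    np.fill_diagonal(A, 0.0)

    def temperature(t: int) -> float:
        anomaly = cfg.season_amplitude * np.sin(2 * np.pi * t / cfg.season_period)
        if cfg.regime_change is not None and t >= cfg.regime_change:
            anomaly += cfg.warming_shift
        return float(anomaly)

    u = K * rng.uniform(0.3, 1.0, n_sp)
    latent = np.empty((n_t, n_sp))
    for t in range(-cfg.burn_in, n_t):
        if t >= 0:
            latent[t] = u
        T = temperature(t)
        r = r0 + affinity * T * 0.5
        competition = cfg.interaction_scale * (A @ (u / K))
        growth = np.exp(np.clip(r - u / K - competition, -8.0, 2.0))
        imm = np.where(
            is_migrant,
            cfg.immigration * max(T, 0.0),
            0.02,
        )
        u = u * growth + imm
        if u.sum() <= 1e-9:
            raise RuntimeError(
                "entire community went extinct; increase immigration or "
                "reduce interaction_scale / season_amplitude"
            )

    jitter = np.exp(
        rng.normal(-0.5 * cfg.obs_noise**2, cfg.obs_noise, size=(n_t, n_sp))
    )
    counts = rng.poisson(latent * jitter)

    dates = pd.date_range("2012-01-15", periods=n_t, freq="MS").normalize()
    community = pd.DataFrame(counts, index=dates, columns=species.index)
    community.index.name = "date"

    richness = (community > 0).sum(axis=1)
    if (richness < 2).any():
        raise RuntimeError(
            "a survey has fewer than 2 species; increase immigration or K"
        )
    turnover = float(np.mean((community == 0).any(axis=0)))
    if turnover < 0.10:
        raise RuntimeError(
            f"only {turnover:.0%} of species show turnover; expected >= 10% — "
            "increase seasonality or migrant_fraction"
        )
    community.attrs["config"] = asdict(cfg)
    return community, species


def archetype_matrices(
    kind: str,
    shape: tuple[int, int] = (41, 41),
    noise: float = 0.05,
    seed: int | None = None,
) -> np.ndarray:
    """Stylized mutual-prediction matrix for one responsiveness archetype.

    ``uniform``: predictable everywhere (entries ~0.5); ``block``: two-regime
    structure (within-half ~0.5, cross-half ~1.5); ``noisy``: unpredictable
    (entries ~ Uniform(0.3, 2.0)).  Gaussian jitter of sd ``noise`` is added.
    """
    rng = np.random.default_rng(seed)
    n, m = shape
    if n < 1 or m < 1:
        raise ValueError("invalid shape")
    if kind == "uniform":
        base = np.full(shape, 0.5)
    elif kind == "block":
        base = np.full(shape, 0.5)
        base[: n // 2, m // 2 :] = 1.5
        base[n // 2 :, : m // 2] = 1.5
    elif kind == "noisy":
        base = rng.uniform(0.3, 2.0, size=shape)
    else:
        raise ValueError(f"unknown archetype kind {kind!r}")
    return base + rng.normal(0.0, noise, size=shape)
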