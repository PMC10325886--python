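"""Biodiversity indicators computed per survey from abundance counts.

Ten indicators are supported, in the canonical output order used throughout
the package:

========  =====================================================================
name      definition (sums run over species *present* in the survey)
========  =====================================================================
S         species richness, number of species with n_i > 0
N         total abundance, sum of n_i
p_max     species dominance (Berger–Parker), max_i p_i
D         Simpson's diversity, 1 - sum_i p_i**2
H         Shannon's diversity, -sum_i p_i ln p_i  (natural log)
E_D       Simpson's evenness, D * S / (S - 1)            (undefined for S = 1)
E_H       Shannon's evenness, H / ln S                   (undefined for S = 1)
E_var     Smith–Wilson's evenness,
          1 - (2/pi) * arctan( Var_pop[ln n_i] )  with the 1/S normalization
delta     taxonomic diversity (Warwick–Clarke), abundance-weighted mean
          taxonomic path length between individuals
cCOD      community mean of the standardized latitudinal center of
          distribution, sum_i p_i z(COD_i)
========  =====================================================================

p_i = n_i / N is the proportion of the i-th species among all individuals
observed in the survey.  COD standardization (z-scores with the population
variance) is done once per dataset over the full set of species ever observed,
not survey by survey.  Indicator values that are undefined for a survey
(evenness with S = 1; delta with a single individual) are reported as missing
values (NaN), never as zeros.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical indicator output order
INDICATOR_NAMES = ["S", "N", "p_max", "D", "H", "E_D", "E_H", "E_var", "delta", "cCOD"]

#: taxonomic relatedness weights by finest shared rank
_RANK_WEIGHTS = {"genus": 1.0, "family": 2.0, "order": 3.0, "other": 4.0}


class EmptyCommunityError(ValueError):
    """Raised when a survey contains no individuals at all."""


def _as_counts(a) -> np.ndarray:
    counts = np.asarray(a, dtype=float)
    if counts.ndim != 1:
        raise ValueError("abundance vector must be one-dimensional")
    if np.any(counts < 0) or not np.all(np.isfinite(counts)):
        raise ValueError("abundance counts must be finite and non-negative")
    return counts


def relative_abundances(a) -> np.ndarray:
    """Proportions p_i over *present* species (zero counts dropped).

    Returns an array aligned to the present-species subset, summing to 1.
    Raises :class:`EmptyCommunityError` for an all-zero survey.
    """
    counts = _as_counts(a)
    total = counts.sum()
    if total <= 0:
        raise EmptyCommunityError("empty community: all counts are zero")
    return counts[counts > 0] / total


def alpha_indicators(a) -> dict[str, float]:
    """Richness, abundance, dominance, diversity and evenness for one survey.

    Returns a dict with keys S, N, p_max, D, H, E_D, E_H, E_var.  For a
    single-species survey the evenness ratios E_D and E_H are undefined and
    returned as NaN, while D = H = 0, p_max = 1 and E_var = 1.
    """
    counts = _as_counts(a)
    present = counts[counts > 0]
    if present.size == 0:
        raise EmptyCommunityError("empty community: all counts are zero")
    p = present / present.sum()
    s = present.size
    n_total = present.sum()

    d = 1.0 - np.sum(p**2)
    h = float(-np.sum(p * np.log(p)))
    # ln(n_i) variance with the 1/S normalization (population form)
    log_n = np.log(present)
    var_log = np.mean((log_n - log_n.mean()) ** 2)
    e_var = 1.0 - (2.0 / np.pi) * np.arctan(var_log)

    if s > 1:
        e_d = d * s / (s - 1.0)
        e_h = h / np.log(s)
    else:
        e_d = np.nan
        e_h = np.nan

    return {
        "S": float(s),
        "N": float(n_total),
        "p_max": float(p.max()),
        "D": float(d),
        "H": h,
        "E_D": float(e_d),
        "E_H": float(e_h),
        "E_var": float(e_var),
    }


def _validate_species_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"genus", "family", "order", "cod_latitude"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"species table missing columns: {sorted(missing)}")
    if table.index.has_duplicates:
        dup = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate species identifiers: {dup}")
    for col in ("genus", "family", "order"):
        bad = table.index[table[col].astype(str).str.strip().eq("") | table[col].isna()]
        if len(bad):
            raise ValueError(f"empty {col} label for species: {bad.tolist()}")
    if not np.all(np.isfinite(table["cod_latitude"].to_numpy(dtype=float))):
        raise ValueError("non-finite COD latitude in species table")
    # taxonomic nesting: one genus cannot sit in two families, nor a family
    # in two orders — the finest-shared-rank weights assume this
    for child, parent in (("genus", "family"), ("family", "order")):
        counts = table.groupby(child)[parent].nunique()
        bad = counts[counts > 1]
        if len(bad):
            raise ValueError(
                f"taxonomy not nested: {child} {bad.index.tolist()} spans multiple {parent} labels"
            )
    return table


def _pair_weights(table: pd.DataFrame, species: list) -> np.ndarray:
    """Taxonomic relatedness w_ij: 1 same genus, 2 same family, 3 same order, 4 otherwise."""
    sub = table.loc[species]
    genus = sub["genus"].to_numpy()
    family = sub["family"].to_numpy()
    order = sub["order"].to_numpy()
    w = np.full((len(species), len(species)), _RANK_WEIGHTS["other"])
    w[order[:, None] == order[None, :]] = _RANK_WEIGHTS["order"]
    w[family[:, None] == family[None, :]] = _RANK_WEIGHTS["family"]
    w[genus[:, None] == genus[None, :]] = _RANK_WEIGHTS["genus"]
    np.fill_diagonal(w, 0.0)
    return w


def taxonomic_diversity(a, species_table: pd.DataFrame, species=None) -> float:
    """Warwick–Clarke taxonomic diversity delta for one survey.

    delta = sum_{i<j} w_ij n_i n_j / (sum_{i<j} n_i n_j + sum_i n_i (n_i - 1) / 2)

    The denominator counts all pairs of individuals; the numerator weights
    between-species pairs by the finest shared taxonomic rank.  A survey with
    a single species and a single individual has no pairs at all and delta is
    undefined (NaN).  A single species with several individuals gives 0.
    """
    counts = _as_counts(a)
    if species is None:
        species = list(species_table.index)
    if len(species) != counts.size:
        raise ValueError("abundance vector and species list lengths differ")
    present = counts > 0
    if not present.any():
        raise EmptyCommunityError("empty community: all counts are zero")
    sp = [s for s, keep in zip(species, present) if keep]
    missing = [s for s in sp if s not in species_table.index]
    if missing:
        raise KeyError(f"species missing from species table: {missing}")
    n = counts[present]
    w = _pair_weights(species_table, sp)
    cross = np.outer(n, n)
    iu = np.triu_indices(len(n), k=1)
    numerator = np.sum(w[iu] * cross[iu])
    denominator = np.sum(cross[iu]) + np.sum(n * (n - 1.0) / 2.0)
    if denominator == 0:
        logger.warning("taxonomic diversity undefined: single individual survey")
        return float("nan")
    return float(numerator / denominator)


def standardized_cod(species_table: pd.DataFrame, observed_species) -> pd.Series:
    """Z-scored COD latitude over the full set of species ever observed.

    Standardization uses the population (1/n) variance and is computed once
    per dataset, so the same z-scores apply to every survey.  Raises if all
    observed CODs are identical (degenerate distribution).
    """
    observed = list(observed_species)
    missing = [s for s in observed if s not in species_table.index]
    if missing:
        raise KeyError(f"species missing from species table: {missing}")
    cod = species_table.loc[observed, "cod_latitude"].astype(float)
    sd = float(np.sqrt(np.mean((cod - cod.mean()) ** 2)))
    if sd == 0:
        raise ValueError("degenerate COD distribution: all observed CODs equal")
    return (cod - cod.mean()) / sd


def community_cod(p, z) -> float:
    """Proportion-weighted mean of standardized CODs of present species."""
    p = np.asarray(p, dtype=float)
    z = np.asarray(z, dtype=float)
    if p.shape != z.shape:
        raise ValueError("proportions and z-scores must align")
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("proportions must sum to 1")
    return float(np.dot(p, z))


def indicator_time_series(
    community: pd.DataFrame, species_table: pd.DataFrame
) -> pd.DataFrame:
    """The full 10-indicator panel, one row per survey.

    Parameters
    ----------
    community
        Surveys x species abundance table (non-negative counts), indexed by
        survey date, columns = species identifiers.
    species_table
        Per-species taxonomy (genus/family/order) and COD latitude, indexed by
        species identifier.

    Returns a DataFrame with columns :data:`INDICATOR_NAMES` in order.
    Surveys with an empty community propagate NaN across all indicators with
    a logged warning.
    """
    species_table = _validate_species_table(species_table)
    unknown = [s for s in community.columns if s not in species_table.index]
    if unknown:
        raise KeyError(f"species missing from species table: {unknown}")

    counts = community.to_numpy(dtype=float)
    ever_observed = [
        s for s, tot in zip(community.columns, counts.sum(axis=0)) if tot > 0
    ]
    if len(ever_observed) < 2:
        raise ValueError("need at least two species observed across the dataset")
    z = standardized_cod(species_table, ever_observed)
    z_full = pd.Series(0.0, index=community.columns)
    z_full.loc[ever_observed] = z

    rows = []
    for date, row in zip(community.index, counts):
        if row.sum() <= 0:
            warnings.warn(f"empty community at survey {date}; indicators set to NaN")
            rows.append({name: np.nan for name in INDICATOR_NAMES})
            continue
        rec = alpha_indicators(row)
        rec["delta"] = taxonomic_diversity(row, species_table, list(community.columns))
        present = row > 0
        p = row[present] / row[present].sum()
        rec["cCOD"] = community_cod(p, z_full.to_numpy()[present])
        rows.append(rec)

    result = pd.DataFrame(rows, index=community.index)[INDICATOR_NAMES]
    n_missing = int(result.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("indicator panel has missing values in %d surveys", n_missing)
    return result
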