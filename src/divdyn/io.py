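"""Readers, writers and run configuration.

File formats are plain delimited text (comma by default):

* community table — header row of species identifiers, first column an
  ISO-8601 survey date, cells non-negative integer counts;
* species table — columns ``species, genus, family, order, cod_latitude``;
* indicator panel — one row per survey, ten indicator columns, missing
  values as empty cells;
* mutual-prediction matrix — square table with window start dates as row and
  column headers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from divdyn.edm import DEFAULT_THETA_GRID
from divdyn.indicators import INDICATOR_NAMES


def read_community(path, sep: str = ",") -> pd.DataFrame:
    """Load a surveys x species count table, ordered by survey date.

    Rejects duplicate dates and non-integer or negative cells, naming the
    offending row and column.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    try:
        dates = pd.to_datetime(df.index, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: survey dates must be ISO-8601: {exc}") from exc
    df.index = dates
    df.index.name = "date"
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].strftime("%Y-%m-%d").tolist()
        raise ValueError(f"{path}: duplicate survey dates {dup}")
    for col in df.columns:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric count at row {bad[0].date()}, column {col!r}"
            )
        if (values < 0).any():
            row = df.index[values < 0][0]
            raise ValueError(f"{path}: negative count at row {row.date()}, column {col!r}")
        if not np.allclose(values, np.round(values)):
            row = df.index[values != np.round(values)][0]
            raise ValueError(
                f"{path}: non-integer count at row {row.date()}, column {col!r}"
            )
        df[col] = values.astype(int)
    return df.sort_index()


def write_community(community: pd.DataFrame, path, sep: str = ",") -> None:
    out = community.copy()
    out.index = out.index.strftime("%Y-%m-%d")
    out.index.name = "date"
    out.to_csv(path, sep=sep)


def read_species(path, sep: str = ",") -> pd.DataFrame:
    """Load the per-species taxonomy and COD-latitude table."""
    df = pd.read_csv(path, sep=sep)
    required = ["species", "genus", "family", "order", "cod_latitude"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: species table missing columns {missing}")
    df = df.set_index("species")
    df["cod_latitude"] = pd.to_numeric(df["cod_latitude"], errors="raise")
    return df


def write_species(species: pd.DataFrame, path, sep: str = ",") -> None:
    species.to_csv(path, sep=sep, index_label="species")


def write_indicators(indicators: pd.DataFrame, path, sep: str = ",") -> None:
    out = indicators[INDICATOR_NAMES].copy()
    out.index = pd.to_datetime(out.index).strftime("%Y-%m-%d")
    out.index.name = "date"
    out.to_csv(path, sep=sep, na_rep="")


def read_indicators(path, sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0, parse_dates=True)
    return df


def write_matrix(matrix: np.ndarray, labels, path, sep: str = ",") -> None:
    """Square sRMSE table with window start labels on both axes."""
    labels = [str(x) for x in labels]
    pd.DataFrame(np.asarray(matrix, float), index=labels, columns=labels).to_csv(
        path, sep=sep, index_label="train\\test"
    )


def read_matrix(path, sep: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, index_col=0)


@dataclass
class RunConfig:
    """Resolved settings for one end-to-end analysis run.

    Defaults follow the package's reference analysis: 48-point sliding
    windows, embedding dimensions 1-10, one-step forecasts at lag one,
    SIMPROF at alpha = 0.01 with 999 permutations.
    """

    community_path: str = ""
    species_path: str = ""
    output_dir: str = "results"
    window: int = 48
    e_max: int = 10
    tau: int = 1
    tp: int = 1
    theiler: int = 0
    theta_grid: tuple = DEFAULT_THETA_GRID
    theta_stride: int = 1
    alpha: float = 0.01
    n_perm: int = 999
    seed: int = 0

    @property
    def e_range(self) -> tuple:
        return tuple(range(1, self.e_max + 1))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "theta_grid" in raw:
            raw["theta_grid"] = tuple(float(t) for t in raw["theta_grid"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["theta_grid"] = [float(t) for t in self.theta_grid]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def write_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
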