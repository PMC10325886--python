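"""End-to-end analysis: counts -> indicators -> mutual prediction -> clusters."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from divdyn import cluster, indicators, io, mutual

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An analysis stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc

        return inner

    return wrap


@_stage("read_community")
def _read_community(cfg: io.RunConfig) -> pd.DataFrame:
    return io.read_community(cfg.community_path)


@_stage("read_species")
def _read_species(cfg: io.RunConfig) -> pd.DataFrame:
    return io.read_species(cfg.species_path)


@_stage("indicators")
def _indicators(community, species) -> pd.DataFrame:
    return indicators.indicator_time_series(community, species)


@_stage("window_check")
def _window_check(panel: pd.DataFrame, cfg: io.RunConfig) -> None:
    if len(panel) < cfg.window:
        raise ValueError(
            f"{len(panel)} surveys but window length {cfg.window}; "
            "shorten the window or extend the series"
        )
    bad = panel.index[panel.isna().any(axis=1)]
    if len(bad):
        raise ValueError(
            "indicator series contain missing values at surveys "
            f"{[d.date() for d in bad]}; every sliding window would be "
            "contaminated — drop or impute these surveys before windowing"
        )


@_stage("mutual_prediction")
def _mutual(panel: pd.DataFrame, cfg: io.RunConfig) -> dict[str, mutual.MutualPredictionMatrix]:
    mats = {}
    for name in indicators.INDICATOR_NAMES:
        mats[name] = mutual.mutual_prediction_matrix(
            panel[name], cfg.window, cfg.e_range, cfg.tau, cfg.tp, cfg.theiler, name=name
        )
        logger.info("mutual prediction done for %s", name)
    return mats


@_stage("nonlinearity")
def _nonlinearity(panel: pd.DataFrame, cfg: io.RunConfig):
    thetas = {}
    for name in indicators.INDICATOR_NAMES:
        tab = mutual.window_thetas(
            panel[name],
            cfg.window,
            cfg.e_range,
            cfg.theta_grid,
            tau=cfg.tau,
            tp=cfg.tp,
            theiler=cfg.theiler,
            stride=cfg.theta_stride,
        )
        thetas[name] = tab["theta"].to_numpy()
        logger.info("theta estimation done for %s", name)
    test = mutual.nonlinearity_test(thetas, alpha=0.05, seed=cfg.seed)
    return thetas, test


@_stage("classification")
def _classification(mats, cfg: io.RunConfig) -> cluster.ClassificationResult:
    return cluster.classify_indicators(
        mats, alpha=cfg.alpha, n_perm=cfg.n_perm, seed=cfg.seed
    )


@_stage("write_outputs")
def _write_outputs(outdir: Path, cfg, panel, mats, thetas, nl_test, result) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "matrices").mkdir(exist_ok=True)
    io.write_indicators(panel, outdir / "indicators.csv")
    dates = pd.to_datetime(panel.index)
    for name, mat in mats.items():
        starts = [dates[s].date() for s, _ in mat.windows.pairs]
        io.write_matrix(mat.srmse, starts, outdir / "matrices" / f"{name}.csv")
    nl_test.to_csv(outdir / "nonlinearity.csv")

    names = sorted(mats)
    from scipy.spatial.distance import squareform

    dist = pd.DataFrame(squareform(result.distances), index=names, columns=names)
    dist.to_csv(outdir / "distances.csv", index_label="indicator")
    (outdir / "dendrogram.nwk").write_text(cluster.to_newick(result.linkage, result.names))

    clusters = result.labels.rename("cluster").to_frame()
    clusters.to_csv(outdir / "clusters.csv", index_label="indicator")
    result.node_pvalues.to_csv(outdir / "simprof_nodes.csv", index_label="node")

    summary = {
        "n_surveys": int(len(panel)),
        "n_windows": int(next(iter(mats.values())).n_windows),
        "e_star": {k: mats[k].e_star.tolist() for k in names},
        "determinism_fraction": {
            k: mutual.determinism_fraction(mats[k]) for k in names
        },
        "theta_median": {k: float(np.median(thetas[k])) for k in names},
        "n_clusters": result.n_clusters,
        "seed": cfg.seed,
    }
    io.write_summary(summary, outdir / "summary.json")
    cfg.to_yaml(outdir / "resolved_config.yaml")


def run_pipeline(cfg: io.RunConfig) -> dict:
    """Run the whole analysis and write the artifact bundle to ``cfg.output_dir``.

    Stages: read inputs, compute the 10-indicator panel, verify windows are
    free of missing values, build the per-indicator mutual-prediction
    matrices, estimate per-window S-map nonlinearity and test theta = 0,
    classify indicators (Ward + SIMPROF), and write all artifacts plus the
    resolved configuration.  Any stage failure raises :class:`StageError`
    naming the stage.
    """
    outdir = Path(cfg.output_dir)
    community = _read_community(cfg)
    species = _read_species(cfg)
    panel = _indicators(community, species)
    _window_check(panel, cfg)
    mats = _mutual(panel, cfg)
    thetas, nl_test = _nonlinearity(panel, cfg)
    result = _classification(mats, cfg)
    _write_outputs(outdir, cfg, panel, mats, thetas, nl_test, result)
    logger.info("pipeline complete: %d clusters", result.n_clusters)
    return {
        "panel": panel,
        "matrices": mats,
        "thetas": thetas,
        "nonlinearity": nl_test,
        "classification": result,
    }
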