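# divdyn — dynamics-based characterization of biodiversity indicators

Monitoring programs track community change through summary indicators —
species richness, total abundance, diversity and evenness indices, taxonomic
distinctness, biogeographic composition. Biodiversity is multidimensional,
and different indicators can respond to the same environmental change in
entirely different ways; correlations between their *values* are notoriously
condition dependent. `divdyn` compares indicators by the behavior of their
*dynamics* instead: indicators whose dynamical rules break at the same times,
in the same way, under the same forcing are read as probes of the same
dimension of biodiversity, and can substitute for one another in monitoring.

The package is aimed at community ecologists with a moderately long
(~monthly, ~100-survey) abundance time series who want to know which of
their indicators are redundant and which carry independent signal.

## Method

For a community table of counts (surveys × species) the package computes ten
per-survey indicators: S, N, Berger–Parker dominance p_max, Simpson D,
Shannon H′, Simpson evenness E_D = D·S/(S−1), Shannon evenness H′/ln S,
Smith–Wilson evenness E_var, Warwick–Clarke taxonomic diversity δ, and the
community-weighted mean of standardized latitudinal centers of distribution
(cCOD).

Each indicator series is then analyzed by **sliding-window nonlinear mutual
prediction**. All n − w + 1 stride-1 windows of length w (default 48; 41
windows for an 88-survey series) are delay-embedded (Takens reconstruction,
τ = 1), and a simplex-projection forecaster trained on window i (embedding
dimension E chosen by leave-one-out self-prediction) forecasts one-step
futures in window j. The standardized error

    sRMSE_ij = RMSE_ij / sd_j ,

with sd_j the population sd of window j's targets, equals 1 for the
untrained always-predict-the-mean model, so sRMSE ≥ 1 marks deterministic
prediction failure. The 41 × 41 matrix of sRMSE values is the indicator's
fingerprint of environmental responsiveness: a regime shift appears as
off-diagonal blocks of failures.

Two diagnostics qualify each indicator: **determinism** (fraction of windows
with self-prediction sRMSE < 1) and **nonlinearity** (the locality parameter
θ of a regularized S-map, grid-searched per window with an elastic-net local
fit and tested against θ = 0 across windows with a Dunnett-style simultaneous
one-sided test).

Finally, indicators are **classified** by the Euclidean distances between
their mutual-prediction matrices: Ward (D2) hierarchical clustering, with
the SIMPROF permutation test (α = 0.01) deciding which splits are
statistically real. See `docs/methods.md` for assumptions, parameter
defaults and limitations.

## Worked example

The `analysis/` scripts run the whole study on a synthetic community
(40 species, 88 monthly surveys, seasonal immigration of a low-latitude
species pool, and a +2 °C shift of the forcing mean at survey 44):

```sh
python analysis/01_simulate.py          # writes results/data/
python analysis/02_indicators.py        # writes results/indicators.csv
python analysis/03_mutual_prediction.py # writes results/matrices/
python analysis/04_nonlinearity.py      # writes results/nonlinearity.csv
python analysis/05_classify.py          # writes results/clusters.csv
python analysis/06_window_size_scan.py  # writes results/window_size_scan.csv
```

`01_simulate.py` reports the realism guards of the generator:

```
wrote results/data/community.csv: 88 surveys x 40 species
regime change at survey 44 (+2.0 degC)
species with at least one absence: 85%
per-survey richness: 15-39
```

`03_mutual_prediction.py` prints the determinism summary — here every
indicator predicts itself better than the untrained baseline in all 41
windows (the simulated dynamics are strongly seasonal, hence highly
forecastable):

```
           n_windows  determinism_fraction  median_E
S                 41                   1.0         6
N                 41                   1.0         5
...
cCOD              41                   1.0         2
```

`05_classify.py` groups the ten indicators by responsiveness; on this
realization SIMPROF finds seven significant clusters, with the evenness
pair (E_H, E_var), the diversity pair (D, δ) and the richness-like pair
(S, H) each sharing a cluster:

```
7 significant clusters (alpha=0.01):
  cluster 1: D, delta
  cluster 2: E_D
  cluster 3: E_H, E_var
  cluster 4: H, S
  cluster 5: N
  cluster 6: cCOD
  cluster 7: p_max
```

Indicators in one cluster changed dynamics at the same times — in a
monitoring design, measuring one of them would have captured the same
dimension of community change as the others.

The same pipeline runs end to end on real data with

```sh
divdyn run community.csv species.csv --out results
```

where `community.csv` has one row per ISO-dated survey and one integer
column per species, and `species.csv` lists
`species,genus,family,order,cod_latitude`.

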