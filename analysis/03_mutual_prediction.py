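"""Mutual-prediction matrices (48-point sliding windows) for every indicator.

Writes one 41 x 41 sRMSE matrix per indicator and a determinism summary:
the fraction of windows each indicator predicts itself better than the
untrained-model baseline (self-prediction sRMSE < 1).
"""

import argparse
from pathlib import Path

import pandas as pd

from divdyn import io
from divdyn.mutual import determinism_fraction, mutual_prediction_matrix


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indicators", type=Path, default=Path("results/indicators.csv"))
    ap.add_argument("--window", type=int, default=48)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    panel = io.read_indicators(args.indicators)
    matdir = args.out / "matrices"
    matdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for name in panel.columns:
        mat = mutual_prediction_matrix(panel[name], args.window, name=name)
        starts = [panel.index[s].date() for s, _ in mat.windows.pairs]
        io.write_matrix(mat.srmse, starts, matdir / f"{name}.csv")
        rows.append(
            {
                "indicator": name,
                "n_windows": mat.n_windows,
                "determinism_fraction": determinism_fraction(mat),
                "median_E": int(pd.Series(mat.e_star).median()),
            }
        )
    summary = pd.DataFrame(rows).set_index("indicator")
    summary.to_csv(args.out / "determinism.csv")
    print(summary.round(3).to_string())
    print(f"\nwrote {len(rows)} matrices to {matdir}")


if __name__ == "__main__":
    main()
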