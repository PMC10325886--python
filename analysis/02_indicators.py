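"""Compute the 10-indicator panel from the simulated monitoring data."""

import argparse
from pathlib import Path

from divdyn import io
from divdyn.indicators import indicator_time_series


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    community = io.read_community(args.data / "community.csv")
    species = io.read_species(args.data / "species.csv")
    panel = indicator_time_series(community, species)
    args.out.mkdir(parents=True, exist_ok=True)
    io.write_indicators(panel, args.out / "indicators.csv")

    print(f"wrote {args.out}/indicators.csv ({len(panel)} surveys)")
    print(panel.describe().loc[["min", "mean", "max"]].round(3).to_string())


if __name__ == "__main__":
    main()
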