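"""Window-length trade-off: self-prediction skill vs regime-shift sensitivity.

Short windows localize changes in dynamics sharply but embed fewer points
(worse self-prediction); long windows predict well but smear the change.
This scan tabulates both sides of the trade-off for candidate lengths on the
species-richness series; it reports, it does not choose.
"""

import argparse
from pathlib import Path

from divdyn import io
from divdyn.mutual import window_size_scan


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indicators", type=Path, default=Path("results/indicators.csv"))
    ap.add_argument("--indicator", default="S")
    ap.add_argument("--sizes", type=int, nargs="+", default=[24, 36, 48])
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    panel = io.read_indicators(args.indicators)
    report = window_size_scan(panel[args.indicator], args.sizes)
    args.out.mkdir(parents=True, exist_ok=True)
    report.to_csv(args.out / "window_size_scan.csv", index=False)
    print(report.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
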