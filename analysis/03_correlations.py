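"""Pearson correlations of each color index with the visual wilting score.

On the synthetic field the interesting check is directional: hue,
saturation, GA, GGA, b* and v* should fall as wilting rises, while
intensity, lightness, a*, u* and CSI should climb — the sign pattern
reported for real proximal and aerial peanut imagery.
"""

import argparse
from pathlib import Path

import pandas as pd

import canopywilt as cw

ROOT = Path(__file__).resolve().parents[1]

EXPECTED_SIGNS = {
    "intensity": +1, "hue": -1, "saturation": -1, "lightness": +1,
    "a_star": +1, "b_star": -1, "u_star": +1, "v_star": -1,
    "ga": -1, "gga": -1, "csi": +1,
}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--indices", type=Path, default=ROOT / "results" / "indices.csv")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "correlations.csv")
    args = ap.parse_args()

    table = pd.read_csv(args.indices)
    corr = cw.correlation_table(table, cw.INDEX_COLUMNS)
    report = corr.to_frame()
    report["expected_sign"] = pd.Series(EXPECTED_SIGNS)
    report["sign_matches"] = (report["r"] * report["expected_sign"]) > 0
    report.to_csv(args.out, index_label="index")

    print(report.round(3))
    n_ok = int(report["sign_matches"].sum())
    print(f"{n_ok}/11 correlation signs match the published direction")


if __name__ == "__main__":
    main()
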