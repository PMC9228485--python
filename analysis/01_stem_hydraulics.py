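#!/usr/bin/env python
"""Stem operating point and Reynolds-similarity match to the chip.

From the measured whole-stem quantities — mean axial velocity
U0 = 221.5 µm/s through a total xylem lumen area of 358,292.39 µm², with
kinematic viscosity 8.74e-7 m²/s at 26 °C — this script computes:

* the implied whole-plant volumetric flow Q = U0 * S;
* the per-vessel Reynolds span over the observed hydraulic-diameter
  range 3.8-46 µm;
* the chip operating points (mean velocity, inlet flow rates in mL/h)
  that put the 120 x 240 µm outlet duct at the same Reynolds numbers;
* the laminar velocity-profile shape of that duct (max/mean ratio).

Writes results/stem_hydraulics.json and results/chip_match.csv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from xylemflow import hydraulics as hy

OUT = Path(__file__).resolve().parents[1] / "results"

U0_STEM = 221.5e-6        # m/s
S_XYLEM = 358_292.39e-12  # m²
DH_SPAN = (3.8e-6, 46e-6)  # m


def main() -> None:
    OUT.mkdir(exist_ok=True)
    Q = U0_STEM * S_XYLEM
    re_lo = hy.reynolds(U0_STEM, DH_SPAN[0])
    re_hi = hy.reynolds(U0_STEM, DH_SPAN[1])
    _, _, _, ratio = hy.rect_duct_profile(hy.CHIP_OUTLET, truncation_N=101)

    rows = []
    for target in (re_lo, re_hi, 3.0, 10.0, 47.0):
        for R in (0.25, 0.5, 1.0):
            op = hy.match_chip_operating_point(target, ratio_R=R)
            rows.append({
                "Re": target, "ratio_R": R,
                "U_chip_mm_s": op["U_chip"] * 1e3,
                "Q1_ml_h": op["Q1_ml_h"], "Q2_ml_h": op["Q2_ml_h"],
            })
    match = pd.DataFrame(rows)
    match.to_csv(OUT / "chip_match.csv", index=False)

    summary = {
        "Q_plant_m3_s": Q,
        "Q_plant_ml_h": hy.m3s_to_ml_h(Q),
        "Re_smallest_vessel": re_lo,
        "Re_largest_vessel": re_hi,
        "chip_Dh_um": hy.CHIP_OUTLET.hydraulic_diameter * 1e6,
        "duct_max_over_mean": ratio,
    }
    (OUT / "stem_hydraulics.json").write_text(json.dumps(summary, indent=2) + "\n")

    print(f"whole-plant flow Q = {Q:.3e} m³/s = {hy.m3s_to_ml_h(Q):.4f} mL/h")
    print(f"vessel Reynolds span: {re_lo:.4f} (Dh 3.8 µm) to {re_hi:.4f} (Dh 46 µm)")
    print(f"chip outlet Dh = {hy.CHIP_OUTLET.hydraulic_diameter*1e6:.0f} µm; "
          f"laminar max/mean = {ratio:.3f} (close to 2)")
    print(f"chip operating points written to {OUT / 'chip_match.csv'}")


if __name__ == "__main__":
    main()
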