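#!/usr/bin/env python
"""Central-axis depth-dose comparison and the dual-depth ratio check.

Part 1 — the certified CAX record for the fully circular (CCA) plaque:
per-depth differences between the detector measurement and the
manufacturer reference at the 11 certified depths (both normalised at
2 mm), with summary statistics.  Part 2 — the dual-depth (3 mm / 1 mm)
dose ratios from the film-measured doses, against certification.
Writes results/cax_comparison.csv and results/dual_depth_ratios.csv.
"""

import json
from importlib import resources
from pathlib import Path

import pandas as pd

from plaquefilm.cax_analysis import compare_profiles, dual_depth_ratio

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    data = resources.files("plaquefilm").joinpath("data")
    RESULTS.mkdir(exist_ok=True)

    with data.joinpath("cax_depth_dose_cca.csv").open() as fh:
        table = pd.read_csv(fh)
    measured = table["reference"] + table["difference_pp"] / 100.0
    cmp = compare_profiles(measured, table["reference"])
    table.to_csv(RESULTS / "cax_comparison.csv", index=False)
    print("CAX depth-dose comparison (CCA, normalised at 2 mm):")
    print(table.to_string(index=False))
    worst = table.loc[table["difference_pp"].idxmin(), "depth_mm"]
    print(f"mean |diff| {cmp.mean_abs_pp:.2f} pp, population SD {cmp.sd_abs_pp:.2f} pp; "
          f"largest negative {cmp.min_pp:.2f} pp at {worst:.0f} mm; all within ±2 pp: {cmp.max_abs_pp <= 2.0}")

    films = json.loads(data.joinpath("dual_depth_film_doses.json").read_text())
    rows = []
    for model in ("CCA", "COB", "CIB"):
        rec = films[model]
        measured_pct = dual_depth_ratio(rec["dose_1mm_Gy"], rec["dose_3mm_Gy"])
        rows.append(
            {
                "model": model,
                "dose_1mm_Gy": rec["dose_1mm_Gy"],
                "dose_3mm_Gy": rec["dose_3mm_Gy"],
                "measured_ratio_pct": round(measured_pct, 1),
                "certified_ratio_pct": rec["certified_ratio_pct"],
                "difference_pp": round(measured_pct - rec["certified_ratio_pct"], 1),
            }
        )
    ratios = pd.DataFrame(rows)
    ratios.to_csv(RESULTS / "dual_depth_ratios.csv", index=False)
    print("\ndual-depth dose ratios (3 mm as % of 1 mm):")
    print(ratios.to_string(index=False))
    print(f"wrote {RESULTS/'cax_comparison.csv'} and {RESULTS/'dual_depth_ratios.csv'}")


if __name__ == "__main__":
    main()
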