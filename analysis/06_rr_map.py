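#!/usr/bin/env python
"""Observed/expected relative-risk table of poor QoL by area and year.

Expected counts standardise each area-year cell to the pooled cohort
prevalence, so RR > 1 marks area-years with more poor-QoL patients than
the cohort rate implies. Writes the RR table and a GeoJSON with mean RR
attached per area for external choropleth tools.
"""

import argparse
from pathlib import Path

from spatqol import io, outputs, weights


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    import pandas as pd

    patients, _ = io.read_patients(args.out_dir / "patients.csv")
    scored = pd.read_csv(args.out_dir / "outcomes.csv")
    cohort = patients.drop(columns=["poor_qol"], errors="ignore").merge(
        scored[["patient_id", "poor_qol"]], on="patient_id"
    )
    rr = outputs.rr_table(cohort)
    rr.to_csv(args.out_dir / "rr_table.csv", index=False)

    areas = weights.read_geojson(args.out_dir / "areas.geojson")
    mean_rr = rr.groupby("area_id").rr.mean()
    weights.write_geojson(
        areas, args.out_dir / "rr_map.geojson",
        extra_properties={a: {"mean_rr": float(v)} for a, v in mean_rr.items()},
    )
    print(f"{len(rr)} area-year cells; RR range {rr.rr.min():.2f} to {rr.rr.max():.2f}")
    print(f"calibration: sum observed {rr.observed.sum():.0f} = sum expected {rr.expected.sum():.1f}")


if __name__ == "__main__":
    main()
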