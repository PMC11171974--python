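#!/usr/bin/env python
"""Derive the binary poor-QoL outcome from the five EPIC-26 domain scores.

Quartile-bins each domain over the cohort, sums the quartile codes into
the 5-20 composite, and labels patients below the cohort median composite
as having poor QoL. Writes the outcome table and the exclusion report,
and (because this cohort is synthetic) reports agreement with the
generative labels.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from spatqol import io, scoring


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    patients, _ = io.read_patients(args.out_dir / "patients.csv")
    scored = scoring.derive_outcomes(patients)
    io.write_table(scored.table, args.out_dir / "outcomes.csv")
    with open(args.out_dir / "exclusions.json", "w") as fh:
        json.dump(scored.exclusion_report, fh, indent=2)

    tab = scored.table
    print(f"scored {len(tab)} patients; median composite {scored.thresholds.composite_median:g}")
    print(f"poor QoL: {tab.poor_qol.sum()} ({tab.poor_qol.mean():.2%})")
    if "poor_qol" in patients.columns:
        agree = (tab.poor_qol.to_numpy() == patients.poor_qol.to_numpy()).mean()
        print(f"agreement with generative labels: {agree:.2%}")


if __name__ == "__main__":
    main()
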