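#!/usr/bin/env python
"""SNR-versus-depth profile of the simulated human cohort at 930 nm.

The liver mask of every subject is tiled into 5 mm depth slabs; each slab's
SNR (mean signal over the coupling-medium noise sd) is tabulated together
with the SAT segment, and the per-step / per-cm percentage decreases are
summarised.  Writes results/snr_profiles.csv and results/snr_decreases.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from lipidquant.snr_depth import percent_decrease, snr_profile
from lipidquant.stack_io import read_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rows, decreases = [], {}
    data = read_cohort(args.sim / "human")
    for cohort, subjects in data.items():
        for stack, rois in subjects:
            prof = snr_profile(stack, rois, 930.0, slab_thickness_cm=0.5)
            for seg in prof.segments:
                rows.append((cohort, stack.subject_id, seg.label,
                             seg.centroid_depth_cm, seg.snr_linear,
                             seg.snr_db, seg.n_pixels))
            decreases[stack.subject_id] = percent_decrease(prof)

    table = pd.DataFrame(rows, columns=[
        "cohort", "subject_id", "segment", "centroid_depth_cm",
        "snr_linear", "snr_db", "n_pixels",
    ])
    table.to_csv(args.out / "snr_profiles.csv", index=False,
                 float_format="%.10g")
    (args.out / "snr_decreases.json").write_text(
        json.dumps(decreases, indent=1, sort_keys=True)
    )

    mean_step = sum(d["mean_step_decrease_pct"] for d in decreases.values())
    mean_cm = sum(d["mean_per_cm_decrease_pct"] for d in decreases.values())
    n = len(decreases)
    print(table.groupby("segment")[["centroid_depth_cm", "snr_db"]]
          .mean().round(2).to_string())
    print(f"\nmean liver SNR decrease: {mean_step / n:.1f}% per 5 mm slab, "
          f"{mean_cm / n:.1f}% per cm of depth")


if __name__ == "__main__":
    main()
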