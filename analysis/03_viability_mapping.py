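#!/usr/bin/env python
"""Whole-graft viability mapping of an ejection-streak graft.

Simulates a graft whose streak damage is auto-calibrated to a true
viable-area fraction of 0.73, segments it at the 40-grey-level cutoff, and
attributes detected damage back to the ground-truth footprints.  Outputs:
results/viability_report.json, results/damage_attribution.csv.
"""

import json
from pathlib import Path

from endoquant import benchmarks
from endoquant.viability_map import attribute_damage

SEED = 22
OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    res = benchmarks.streak_graft_benchmark(SEED, target_viable_fraction=0.73)
    rep = res.report
    print(f"true viable fraction {res.true_viable_fraction:.3f}; "
          f"segmentation at cutoff {rep.threshold:.0f} reports "
          f"{100*rep.viable_area_fraction:.1f}% viable "
          f"(Dice vs truth {rep.dice:.3f})")
    table = attribute_damage(rep, res.gt)
    table.to_csv(OUT / "damage_attribution.csv", index=False)
    doc = {
        "true_viable_fraction": res.true_viable_fraction,
        "reported_viable_pct": 100 * rep.viable_area_fraction,
        "threshold": rep.threshold,
        "pixel_sensitivity": rep.sensitivity,
        "pixel_specificity": rep.specificity,
        "dice": rep.dice,
        "leakage_mm2": table.attrs["leakage_mm2"],
    }
    (OUT / "viability_report.json").write_text(json.dumps(doc, indent=2))
    print(f"streak recall: {table.recall.round(3).tolist()}; "
          f"leakage {table.attrs['leakage_mm2']:.4f} mm^2")


if __name__ == "__main__":
    main()
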