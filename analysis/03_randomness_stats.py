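#!/usr/bin/env python
"""Randomness statistics for the simulated cohort, plus the published reproduction.

Reads the cohort outputs of 02_cohort_display.py, reports both χ² forms for
the simulated data (percentage-scale df=1 reproduction form and count-based
df=2 multinomial test), hotspot regions, and the euchromatic fraction; then
reproduces the published percentage-scale statistic from the printed
observed/expected values (16.2%, 9.5%) vs (11.6%, 10.5%).
"""

import json
from pathlib import Path

from tgmap.stats import chisq_paper

RESULTS = Path(__file__).resolve().parent.parent / "results"
COHORT = RESULTS / "cohort"


def main() -> None:
    stats = json.loads((COHORT / "stats.json").read_text())
    out = {
        "simulated_cohort": {
            "chisq_paper": stats["chisq_paper"],
            "chisq_counts": stats["chisq_counts"],
            "hotspots": stats["hotspots"],
            "euchromatic_percent": stats["euchromatic_percent"],
        },
        "published_reproduction": chisq_paper((16.2, 9.5), (11.6, 10.5)).as_dict(),
    }
    with open(RESULTS / "randomness.json", "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
        fh.write("\n")

    sim_p = stats["chisq_paper"]
    sim_c = stats["chisq_counts"]
    print("simulated cohort (uniform insertion, ascertained 105/124):")
    print(f"  percentage-scale χ² = {sim_p['statistic']:.2f} (df=1), p = {sim_p['p_value']:.3f}")
    print(f"  count-based     χ² = {sim_c['statistic']:.2f} (df=2), p = {sim_c['p_value']:.3f}")
    print(f"  hotspot regions detected: {len(stats['hotspots'])}")
    print(f"  euchromatic fraction: {stats['euchromatic_percent']}%")
    rep = out["published_reproduction"]
    print("published-values reproduction (observed 16.2/9.5 vs expected 11.6/10.5):")
    print(f"  χ² = {rep['statistic']:.2f} (df=1), p = {rep['p_value']:.3f} "
          f"-> not significant at p = 0.05")


if __name__ == "__main__":
    main()
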