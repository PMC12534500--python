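#!/usr/bin/env python
"""A priori sample size for the paired crossover contrasts.

Tabulates the required number of pairs for the two-tailed paired t-test
over a grid of effect sizes and power targets (noncentral-t iteration).
The study-design anchor — dz = 0.5, α = 0.05, 1−β = 0.9 — requires
n = 44. Writes results/sample_size.csv.
"""
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

import pandas as pd                          # noqa: E402
from ctbseeg import paired_t_sample_size     # noqa: E402


def main():
    rows = []
    for d in (0.2, 0.3, 0.5, 0.8):
        for power in (0.8, 0.9, 0.95):
            n = paired_t_sample_size(d, alpha=0.05, power=power).n_required
            rows.append({"d": d, "alpha": 0.05, "power": power,
                         "n_required": n})
    df = pd.DataFrame(rows)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    df.to_csv(results / "sample_size.csv", index=False)
    print(df.to_string(index=False))
    anchor = df.query("d == 0.5 and power == 0.9")["n_required"].item()
    print(f"\ndesign anchor (d=0.5, power=0.9): n = {anchor}")


if __name__ == "__main__":
    main()
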