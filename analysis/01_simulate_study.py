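#!/usr/bin/env python
"""Generate the synthetic crossover study used by the downstream drivers.

Writes a scaled-down study (6 subjects, both arms, all six timepoints,
60 s wake recordings, 2-hour nights) under scratch/study/: delimited
recordings, hypnograms, ground truth, manifest and config. The full
defaults (20 subjects, 300 s) are exercised by scripts/acceptance.py;
this size keeps the exploratory drivers fast.
"""
import sys
import time
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from ctbseeg import SimConfig                 # noqa: E402
from ctbseeg.pipeline import simulate_study   # noqa: E402


def main():
    cfg = SimConfig(n_subjects=6, wake_duration=60.0,
                    sleep_duration_minutes=120.0, seed=20260929 % (2**31))
    outdir = ROOT / "scratch" / "study"
    t0 = time.time()
    manifest = simulate_study(cfg, outdir)
    n = len(manifest.rows)
    print(f"wrote {n} recordings ({(manifest.rows['kind'] == 'wake').sum()} "
          f"wake, {(manifest.rows['kind'] == 'sleep').sum()} nights) "
          f"to {outdir} in {time.time() - t0:.0f} s")
    print(f"manifest: {outdir / 'manifest.csv'}")
    print(f"ground truth: {outdir / 'ground_truth.json'}")


if __name__ == "__main__":
    main()
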