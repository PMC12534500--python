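#!/usr/bin/env python
"""Run the full analysis pipeline on the simulated study.

Consumes scratch/study/manifest.csv (see 01_simulate_study.py), writes
every analysis table under scratch/study_out/, and copies the compact
narrative outputs — the summary, the network-property ANOVA, and the
wake→sleep correlations — into results/.

What to look for: the active arm's T1-vs-T6 delta/theta contrasts flag
electrodes across the scalp (the injected +30 % ramp), the sham arm
stays quiet, and the active-arm wake ΔPSD z-scores correlate with
first-cycle NREM power in the effect bands.
"""
import shutil
import sys
import time
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from ctbseeg.pipeline import StudyManifest, run_pipeline  # noqa: E402


def main():
    study = ROOT / "scratch" / "study"
    if not (study / "manifest.csv").exists():
        sys.exit("run analysis/01_simulate_study.py first")
    outdir = ROOT / "scratch" / "study_out"
    manifest = StudyManifest.from_csv(study / "manifest.csv", outdir)
    t0 = time.time()
    out = run_pipeline(manifest)
    print(f"pipeline finished in {time.time() - t0:.0f} s; "
          f"tables in {outdir}")

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    for name in ("summary.json", "network_anova.csv",
                 "wake_sleep_correlation.csv", "sleep_architecture.csv"):
        src = outdir / name
        if src.exists():
            shutil.copy(src, results / name)

    sig = out["summary"]["significant_psd_units"]
    print("\nFDR-significant electrodes per (arm/band/comparison):")
    for key, units in sorted(sig.items()):
        print(f"  {key}: {len(units)} electrodes")
    wsc = out.get("wake_sleep_correlation")
    if wsc is not None and len(wsc):
        print("\nwake ΔPSD (F4, z) vs first-cycle NREM power:")
        print(wsc.to_string(index=False))


if __name__ == "__main__":
    main()
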