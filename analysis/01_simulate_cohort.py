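#!/usr/bin/env python
"""Simulate the study cohort: 7 deaf + 14 hearing participants.

Deaf participants bounce in the two vibrotactile conditions (mask, muff),
hearing participants additionally in the auditory condition; three tempi
(110/115/120 BPM), two 128-beat trials per condition x tempo cell — 336
trials in total. Trial TSVs and stimulus CSVs are bulky and go under
scratch/cohort; the manifest is copied to results/ for the record.

Writes: scratch/cohort/*.tsv, scratch/cohort/manifest.csv,
results/manifest.csv.
"""
import shutil
from pathlib import Path

import beatsync as bs
from beatsync import synth

ROOT = Path(__file__).resolve().parents[1]
SEED = 20260919

def main() -> None:
    out = ROOT / "scratch" / "cohort"
    design = bs.CohortDesign()
    manifest = synth.write_cohort(design, seed=SEED, out_dir=out)
    (ROOT / "results").mkdir(exist_ok=True)
    shutil.copy(out / "manifest.csv", ROOT / "results" / "manifest.csv")
    n_deaf = (manifest["group"] == "deaf").sum()
    n_hear = (manifest["group"] == "hearing").sum()
    print(f"simulated {len(manifest)} trials ({n_deaf} deaf, {n_hear} hearing) -> {out}")
    print("planted phase-noise SD per condition:")
    for (g, c), sd in design.condition_noise_sd.items():
        print(f"  {g:8s} {c:9s} {sd:.2f} rad/sqrt(s)")


if __name__ == "__main__":
    main()
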