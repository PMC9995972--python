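#!/usr/bin/env python
"""Simulate one male and one female subject under the recording protocol.

Writes each subject's recording (CSV + sidecar), epoch schedule (YAML) and
generator ground truth (JSON) under scratch/subjects/<sex>/ — raw signals
are bulky, so they live in scratch/ while later steps write their tables
to results/.  Simulations run at 250 Hz; the protocol covers 5400 s
(basal, saline, drug, five DBS periods, post).
"""

import sys
from pathlib import Path

from oscillonet import pipeline

ROOT = Path(__file__).resolve().parents[1]
FS = 250.0


def main(seed: int = 1):
    for sex in ("male", "female"):
        out = ROOT / "scratch" / "subjects" / sex
        pipeline.cmd_simulate(sex, seed=seed, out_dir=out, fs=FS)
        print(f"{sex}: wrote recording + schedule + ground truth to {out}")
    print("done; run 02_spectral_profiles.py next")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
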