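#!/usr/bin/env python
"""Phase–amplitude coupling with surrogate significance per epoch.

Computes the modulation index for the canonical phase→amplitude pairs
(slow→mid-gamma, delta→beta, low-theta→mid-gamma) over the basal, drug
and final-DBS epochs with 200 circular-shift surrogates, and writes
results/pac_<sex>.csv.  Observed MI values are flagged significant when
they exceed the surrogate mean by two surrogate standard deviations.
"""

from pathlib import Path

from oscillonet import pipeline, recording as rio

ROOT = Path(__file__).resolve().parents[1]
EPOCHS = ("basal", "FG", "DBS5")


def main(seed: int = 1):
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    for sex in ("male", "female"):
        d = ROOT / "scratch" / "subjects" / sex
        rec = rio.load_recording(d / "recording.csv")
        sched = rio.load_schedule(d / "schedule.yaml")
        sub = rio.EpochSchedule([e for e in sched if e[0] in EPOCHS])
        out = pipeline.analyze_subject(rec, sub, include=("pac",), seed=seed)
        out["pac"].to_csv(results / f"pac_{sex}.csv", index=False)
        sig = out["pac"].groupby(["phase_band", "amp_band", "epoch"])["sig"].mean()
        print(f"\nfraction of channels with significant PAC — {sex}")
        print(sig.unstack("epoch").round(2).to_string())
    print("\nwrote PAC tables to results/")


if __name__ == "__main__":
    main()
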