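#!/usr/bin/env python
"""Pairwise coupling: WPLI, PLV and normalized envelope MI per epoch.

Computes epoch-level metrics for all six channel pairs in the slow, delta,
low-theta and beta bands over the basal, drug and final-DBS epochs, and
writes results/connectivity_<sex>.csv.  In the male subject the drug
raises low-theta WPLI across the circuit; the female values stay at their
baseline.
"""

from pathlib import Path

from oscillonet import pipeline, recording as rio

ROOT = Path(__file__).resolve().parents[1]
EPOCHS = ("basal", "FG", "DBS5")


def main():
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    for sex in ("male", "female"):
        d = ROOT / "scratch" / "subjects" / sex
        rec = rio.load_recording(d / "recording.csv")
        sched = rio.load_schedule(d / "schedule.yaml")
        sub = rio.EpochSchedule([e for e in sched if e[0] in EPOCHS])
        out = pipeline.analyze_subject(rec, sub, include=("connectivity",))
        conn = out["connectivity"]
        conn.to_csv(results / f"connectivity_{sex}.csv", index=False)
        lt = conn[conn.band == "low_theta"].pivot(index="pair",
                                                  columns="epoch",
                                                  values="wpli")[list(EPOCHS)]
        print(f"\nlow-theta WPLI — {sex}")
        print(lt.round(3).to_string())
    print("\nwrote connectivity tables to results/")


if __name__ == "__main__":
    main()
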