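"""Shared fixtures: small deterministic signals and the simulated cohorts.

The cohort fixture simulates six subjects per sex under the full protocol
presets at 250 Hz (all analyzed bands sit below the 125 Hz Nyquist) and
runs the spectral and theta stages once per session; several tests read
different contrasts from the same tables.
"""

import numpy as np
import pytest

from oscillonet import pipeline, synth

COHORT_FS = 250.0
COHORT_N = 6


def _build_cohort(sex: str, base_seed: int):
    subjects = []
    preset = synth.protocol_preset(sex)
    for s in range(COHORT_N):
        rec, sched, _ = synth.generate_protocol(preset, fs=COHORT_FS,
                                                seed=base_seed + s)
        subjects.append(pipeline.analyze_subject(rec, sched,
                                                 include=("spectral", "theta")))
    return subjects


@pytest.fixture(scope="session")
def male_cohort():
    return _build_cohort("male", 100)


@pytest.fixture(scope="session")
def female_cohort():
    return _build_cohort("female", 200)


def cohort_values(subjects, channel, epoch, band=None, value="rel_power",
                  stage="spectral"):
    """Per-subject scalar metric for one channel/epoch (cohort vector)."""
    out = []
    for s in subjects:
        df = s[stage]
        sel = df[(df.channel == channel) & (df.epoch == epoch)]
        if band is not None:
            sel = sel[sel.band == band]
        out.append(float(sel[value].mean()))
    return np.array(out)
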