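"""Config-driven orchestration: simulate → analyze → compare.

``cmd_simulate`` writes a synthetic protocol recording (CSV + sidecar),
its epoch schedule (YAML) and the generator ground truth (JSON).
``cmd_analyze`` runs the spectral, theta, connectivity and PAC stages over
the protocol epochs and writes one tidy CSV per stage.  ``cmd_compare``
applies the nonparametric test battery across simulated subjects and
cohorts and writes a results CSV plus a markdown report.

The same functions are the library entry points used by the analysis
drivers and the test-suite; the click CLI in :mod:`oscillonet.cli` is a
thin wrapper.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import pac as pacmod
from . import spectral as spec
from . import stats as gstats
from . import synth, theta
from .recording import (EpochSchedule, Recording, load_recording,
                        load_schedule, save_recording, save_schedule,
                        slice_epoch)

log = logging.getLogger(__name__)

DEFAULT_PAIRS = (("HPCd", "HPCi"), ("HPCd", "HPCv"), ("HPCi", "HPCv"),
                 ("HPCd", "BLA"), ("HPCi", "BLA"), ("HPCv", "BLA"))
DEFAULT_CONN_BANDS = ("slow", "delta", "low_theta", "beta")
DEFAULT_PAC_PAIRS = (("slow", "mid_gamma"), ("delta", "beta"),
                     ("low_theta", "mid_gamma"))


def _representative_span(rec: Recording, start_s, end_s, span_s=300.0):
    lo = max(start_s, end_s - span_s)
    sched = EpochSchedule([("span", lo, end_s)])
    return slice_epoch(rec, sched, "span")


def analyze_subject(rec: Recording, schedule: EpochSchedule,
                    include=("spectral", "theta"), window_s: float = 60.0,
                    representative_s: float = 300.0,
                    pairs=DEFAULT_PAIRS, conn_bands=DEFAULT_CONN_BANDS,
                    pac_pairs=DEFAULT_PAC_PAIRS, n_perm: int = 200,
                    seed: int = 0) -> dict:
    """Run the analysis stages for one subject.

    Returns a dict of tidy DataFrames keyed by stage name.  Theta,
    connectivity and PAC are evaluated on each epoch's representative span
    (its final ``representative_s`` seconds); the spectral timecourse
    covers the full recording and is then summarized per epoch.
    """
    out = {}
    if "spectral" in include:
        tc = spec.band_timecourse(rec, window_s=window_s)
        out["spectral_timecourse"] = tc
        out["spectral"] = spec.epoch_summary(tc, schedule, window_s=window_s,
                                             representative_s=representative_s)
    if "theta" in include:
        rows = []
        for name, a, b in schedule:
            span = _representative_span(rec, a, b, representative_s)
            for ch in rec.channel_labels:
                tfr = theta.cwt_tfr(span.channel(ch), rec.fs)
                segs = theta.detect_theta_segments(tfr)
                total = span.n_samples / span.fs
                widths = [s.width_s for s in segs]
                rows.append({
                    "epoch": name, "channel": ch,
                    "temporal_ratio": float(np.sum(widths)) / total,
                    "mean_width_s": float(np.mean(widths)) if widths else 0.0,
                    "n_segments": len(widths),
                })
        out["theta"] = pd.DataFrame(rows)
    if "connectivity" in include:
        rows = []
        for name, a, b in schedule:
            span = _representative_span(rec, a, b, representative_s)
            for (c1, c2) in pairs:
                x, y = span.channel(c1), span.channel(c2)
                for bname in conn_bands:
                    band = spec.BAND_MAP[bname]
                    wpli = conn.wpli_epoch(x, y, rec.fs, band)
                    ax = conn.band_analytic(x, rec.fs, band)
                    ay = conn.band_analytic(y, rec.fs, band)
                    plv = float(np.nanmean(conn.plv_windowed(ax, ay)))
                    nmi = conn.band_mutual_information(ax, ay)
                    rows.append({"epoch": name, "pair": f"{c1}-{c2}",
                                 "band": bname, "wpli": wpli, "plv": plv,
                                 "nmi": nmi})
        out["connectivity"] = pd.DataFrame(rows)
    if "pac" in include:
        rows = []
        for name, a, b in schedule:
            span = _representative_span(rec, a, b, representative_s)
            for ch in rec.channel_labels:
                x = span.channel(ch)
                for (pb, ab) in pac_pairs:
                    tag = zlib.crc32(f"{name}|{ch}|{pb}|{ab}".encode())
                    res = pacmod.pac_for_bands(
                        x, rec.fs, spec.BAND_MAP[pb], spec.BAND_MAP[ab],
                        n_perm=n_perm,
                        seed=int(np.random.SeedSequence(
                            [seed, tag]).generate_state(1)[0] % (2 ** 31)))
                    rows.append({"epoch": name, "channel": ch,
                                 "phase_band": pb, "amp_band": ab,
                                 "mi": res.mi, "sig": res.significant,
                                 "surr_mean": res.surrogate_mean,
                                 "surr_sd": res.surrogate_sd})
        out["pac"] = pd.DataFrame(rows)
    return out


# ---------------------------------------------------------------------------
# Cohort-level helpers
# ---------------------------------------------------------------------------

def metric_table(summaries, channel, band=None, value="rel_power",
                 stage="spectral") -> gstats.RepeatedMeasuresTable:
    """Subjects × epochs table of one metric from per-subject summaries.

    ``summaries`` is a list of ``analyze_subject`` outputs (one per
    subject); epoch order follows the first subject's table.
    """
    first = summaries[0][stage]
    epochs = list(dict.fromkeys(first["epoch"]))
    rows = []
    for s in summaries:
        df = s[stage]
        sel = df[df["channel"] == channel] if "channel" in df else df
        if band is not None:
            sel = sel[sel["band"] == band]
        vals = [float(sel[sel["epoch"] == e][value].mean()) for e in epochs]
        rows.append(vals)
    return gstats.RepeatedMeasuresTable(np.array(rows),
                                        condition_names=epochs)


def compare_cohorts(cohorts: dict, channel, band=None, value="rel_power",
                    stage="spectral", epoch="FG", m: int | None = None):
    """Within-cohort Friedman (across epochs) and between-cohort
    Mann–Whitney at one epoch, for one channel/band metric."""
    if len(cohorts) < 2:
        raise ValueError("need at least two cohorts to compare")
    tables = {name: metric_table(s, channel, band, value, stage)
              for name, s in cohorts.items()}
    friedman = {name: gstats.friedman_conover(t) for name, t in tables.items()}
    names = list(cohorts)
    cols = {name: t.values[:, t.condition_names.index(epoch)]
            for name, t in tables.items()}
    mw = gstats.mann_whitney_bonferroni(
        [(cols[names[0]], cols[names[1]])], m=m)[0]
    return {"friedman": friedman, "mann_whitney": mw, "tables": tables}


# ---------------------------------------------------------------------------
# File-level commands
# ---------------------------------------------------------------------------

def cmd_simulate(preset_name: str, seed: int, out_dir, fs: float = 1000.0):
    """Simulate one subject under the named protocol preset and write
    recording, schedule and ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    preset = synth.protocol_preset(preset_name)
    rec, schedule, truth = synth.generate_protocol(preset, fs=fs, seed=seed)
    save_recording(rec, out / "recording.csv")
    save_schedule(schedule, out / "schedule.yaml")
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    (out / "config.json").write_text(json.dumps(
        {"preset": preset_name, "seed": seed, "fs": fs}))
    return out


def cmd_analyze(rec_path, schedule_path, out_dir,
                include=("spectral", "theta", "connectivity", "pac"),
                epochs=None, seed: int = 0, n_perm: int = 200):
    """Analyze a recording on disk; one CSV per stage."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec = load_recording(rec_path)
    schedule = load_schedule(schedule_path)
    if epochs:
        schedule = EpochSchedule(
            [e for e in schedule if e[0] in set(epochs)])
    results = analyze_subject(rec, schedule, include=include, seed=seed,
                              n_perm=n_perm)
    for stage, df in results.items():
        df.to_csv(out / f"{stage}.csv", index=False)
    return results


def cmd_compare(subject_dirs_by_cohort: dict, out_dir, channel="HPCd",
                band="low_theta", value="rel_power", epoch="FG"):
    """Compare analyzed subjects across cohorts; write CSV + report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohorts = {}
    for name, dirs in subject_dirs_by_cohort.items():
        if len(dirs) < 2:
            raise ValueError("repeated-measures comparison needs >= 2 subjects")
        cohorts[name] = [
            {"spectral": pd.read_csv(Path(d) / "spectral.csv"),
             "theta": pd.read_csv(Path(d) / "theta.csv")}
            for d in dirs]
    res = compare_cohorts(cohorts, channel, band, value, epoch=epoch)
    lines = [f"# Cohort comparison — {channel} {band} {value}", ""]
    rows = []
    for name, fr in res["friedman"].items():
        lines.append(f"## Friedman across epochs — cohort {name}")
        lines.append(f"chi2 = {fr.statistic:.3f}, df = {fr.df}, "
                     f"p = {fr.p:.4g} {gstats.significance_stars(fr.p)}")
        lines.append("")
        lines.append("Conover post hoc (Holm-adjusted):")
        lines.append(fr.posthoc.to_markdown(index=False))
        lines.append("")
        rows.append({"cohort": name, "test": "friedman",
                     "statistic": fr.statistic, "p": fr.p})
    mw = res["mann_whitney"]
    lines.append(f"## Mann–Whitney between cohorts at epoch {epoch}")
    lines.append(f"U = {mw.statistic:.1f}, p = {mw.p:.4g} "
                 f"{gstats.significance_stars(mw.p)}")
    rows.append({"cohort": "between", "test": "mann-whitney",
                 "statistic": mw.statistic, "p": mw.p})
    pd.DataFrame(rows).to_csv(out / "compare.csv", index=False)
    (out / "report.md").write_text("\n".join(lines))
    return res
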