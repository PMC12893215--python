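"""Reading a serialized cohort directory back into memory."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from melophys.core import ACOUSTIC_CHANNELS, DataError, UniformSeries
from melophys.synthetic import (
    AnnotationSet,
    Cohort,
    ListenerRecord,
    MusicFeatureSet,
    SessionSignals,
    SimConfig,
)


def read_cohort(indir) -> Cohort:
    """Load a cohort written by :func:`melophys.synthetic.write_cohort`."""
    root = Path(indir)
    if not (root / "manifest.json").exists():
        raise DataError(f"{root} does not contain a cohort manifest")
    manifest = json.loads((root / "manifest.json").read_text())
    truth = {}
    if (root / "truth.json").exists():
        truth = json.loads((root / "truth.json").read_text())

    music = {}
    for path in sorted((root / "music").glob("*.csv")):
        perf = path.stem
        piece, version = perf.split("__")
        df = pd.read_csv(path)
        rate = 1.0 / float(df["time_s"].iloc[1] - df["time_s"].iloc[0])
        chans = {
            ch: UniformSeries(ch, df[ch].to_numpy(), rate=rate) for ch in ACOUSTIC_CHANNELS
        }
        cps = [tuple(c) for c in truth.get("changepoints", {}).get(perf, [])]
        music[perf] = MusicFeatureSet(piece, version, chans, cps)

    annotations = {}
    for path in sorted((root / "annotations").glob("*.csv")):
        perf = path.stem
        piece, version = perf.split("__")
        df = pd.read_csv(path)
        events = [(float(t), str(c)) for t, c in zip(df["onset_s"], df["category"])]
        annotations[perf] = AnnotationSet(piece, version, events)

    archetypes = truth.get("archetypes", {})
    listeners = []
    for meta in manifest["listeners"]:
        lid = meta["listener_id"]
        ldir = root / "listeners" / lid
        baseline_rr = pd.read_csv(ldir / "baseline_rr.csv")["rr_s"].to_numpy()
        sessions = {}
        for rr_path in sorted(ldir.glob("*__rr.csv")):
            perf = rr_path.name[: -len("__rr.csv")]
            rr = pd.read_csv(rr_path)["rr_s"].to_numpy()
            resp_df = pd.read_csv(ldir / f"{perf}__resp.csv")
            resp_rate = 1.0 / float(resp_df["time_s"].iloc[1] - resp_df["time_s"].iloc[0])
            resp = UniformSeries("resp_wave", resp_df["resp"].to_numpy(),
                                 rate=resp_rate, units="a.u.")
            bp = pd.read_csv(ldir / f"{perf}__bp.csv")
            sessions[perf] = SessionSignals(
                rr=rr, resp_wave=resp, resp_truth_intervals=np.empty(0),
                resp_truth_peaks=np.empty(0),
                sys=bp["sys_mmHg"].to_numpy(), dia=bp["dia_mmHg"].to_numpy(),
                duration=music[perf].duration if perf in music else float(np.sum(rr)),
            )
        demographics = {k: meta[k] for k in ("age", "gender", "musician", "prefers_classical")
                        if k in meta}
        listeners.append(ListenerRecord(
            lid, archetypes.get(lid, "balanced"), baseline_rr, sessions,
            demographics, list(meta["playlist"])))

    config = SimConfig(
        n_pieces=manifest.get("n_pieces", max(1, len(music))),
        versions={k: tuple(v) for k, v in manifest.get("versions", {}).items()},
        n_listeners=max(len(listeners), 3),
        playlist_length=max(len(listeners[0].playlist), 2) if listeners else 2,
        seed=manifest.get("seed", 0),
    )
    return Cohort(config, music, annotations, listeners, truth)
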