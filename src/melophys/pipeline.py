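"""End-to-end pipeline driver and configuration.

Stages: simulate (or load) a cohort, preprocess physiology, stratify by
baseline autonomic state, detect consensus change points in musical and
physiological channels, build Gaussian-kernel event-density matrices,
run CCA per stratum (all listeners and each autonomic cluster), render
connectivity graphs, run the event-locked difference analysis, and fit
the individual-effects models. Every stage seed is derived from one
master seed via a counter scheme, so identical configs give identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from melophys import baseline as bl
from melophys import cca as cc
from melophys import changepoints as cp
from melophys import events as ev
from melophys import gkf
from melophys import graph as cg
from melophys import individual as ind
from melophys import preprocess as pp
from melophys import synthetic as syn
from melophys.core import ACOUSTIC_CHANNELS, PHYSIO_CHANNELS


@dataclass
class PipelineConfig:
    seed: int = 0
    sim: dict = field(default_factory=dict)             # SimConfig overrides
    grid_resolutions: tuple = (5.0, 1.0)
    grid_penalty_factors: tuple = cp.DEFAULT_PENALTY_FACTORS
    consensus: float = cp.DEFAULT_CONSENSUS
    min_spacing_s: float = cp.DEFAULT_MIN_SPACING_S
    tolerance_s: float = cp.DEFAULT_TOLERANCE_S
    sigma_s: float = gkf.DEFAULT_SIGMA_S
    display_threshold: float = cg.DISPLAY_THRESHOLD
    alpha: float = 0.05
    windows_s: tuple = ev.SENSITIVITY_WINDOWS_S
    n_surrogates: int = 100
    n_permutations: int = 199

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "little")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        cfg = cls(**{k: v for k, v in raw.items() if k in known})
        for name in ("grid_resolutions", "grid_penalty_factors", "windows_s"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for name in ("grid_resolutions", "grid_penalty_factors", "windows_s"):
            d[name] = list(d[name])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def detector_grid(self):
        return cp.default_grid(self.grid_resolutions, self.grid_penalty_factors)

    def sim_config(self) -> syn.SimConfig:
        return syn.SimConfig(seed=self.stage_seed("simulate"), **self.sim)


@dataclass
class PipelineResult:
    cohort: syn.Cohort
    channels: dict           # (listener_id, perf_id) -> {channel: UniformSeries}
    profiles: pd.DataFrame   # listener, archetype, pns, sns, cluster, elevated_bp
    music_cps: dict          # perf_id -> {channel: ChangePointSet (directioned)}
    events_by_category: dict # perf_id -> {category: [onsets]}
    inputs_by_stratum: dict  # stratum -> CCAInputs
    cca_by_stratum: dict     # stratum -> CCAResult
    graphs: dict             # stratum -> ConnectivityGraph
    event_tables: dict       # window -> DataFrame
    similarity: pd.DataFrame
    gam_report: object


def preprocess_cohort(cohort) -> dict:
    channels = {}
    for rec in cohort.listeners:
        for perf, session in rec.sessions.items():
            channels[(rec.listener_id, perf)] = pp.process_session(session)
    return channels


def baseline_profiles(cohort, seed: int) -> pd.DataFrame:
    summaries = [bl.hrv_summary(rec.baseline_rr) for rec in cohort.listeners]
    idx = bl.pns_sns_indices(summaries)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labels, info = bl.cluster_autonomic(idx, seed=seed)
    rows = []
    for rec, (pns, sns), label in zip(cohort.listeners, idx, labels):
        sess = next(iter(rec.sessions.values()))
        rows.append(dict(
            listener_id=rec.listener_id, archetype=rec.archetype,
            pns=float(pns), sns=float(sns), cluster=int(label),
            elevated_bp=bl.elevated_bp(float(np.mean(sess.sys)), float(np.mean(sess.dia))),
            sys=float(np.mean(sess.sys)), dia=float(np.mean(sess.dia)),
            **rec.demographics,
        ))
    return pd.DataFrame(rows)


def detect_music_changepoints(cohort, config: PipelineConfig) -> dict:
    grid = config.detector_grid()
    out = {}
    for perf, music in cohort.music.items():
        per_channel = {}
        for ch in ACOUSTIC_CHANNELS:
            cps = cp.ensemble_detect(
                music.channels[ch], grid, config.consensus,
                config.min_spacing_s, config.tolerance_s)
            per_channel[ch] = cp.directionize(music.channels[ch], cps)
        out[perf] = per_channel
    return out


def build_event_categories(music_cps: dict, annotations: dict) -> dict:
    """perf -> {category: [onsets]} over the 17 event categories."""
    out = {}
    for perf, per_channel in music_cps.items():
        cats = {}
        for ch, cps in per_channel.items():
            for onset, label in zip(cps.onsets, cps.categories):
                cats.setdefault(label, []).append(float(onset))
        for onset, category in annotations[perf].events:
            cats.setdefault(category, []).append(float(onset))
        out[perf] = {k: sorted(v) for k, v in cats.items()}
    return out


def physio_gkf_sources(cohort, channels, config: PipelineConfig, listener_ids=None) -> dict:
    """(perf, physio channel) -> listener-averaged GKF series.

    Change points are detected per listener and channel, turned into
    unit-peak Gaussian series, and averaged across the listeners of the
    stratum who heard the performance.
    """
    grid_cfg = config.detector_grid()
    per_listener = {}
    for (lid, perf), chans in channels.items():
        if listener_ids is not None and lid not in listener_ids:
            continue
        for ch in PHYSIO_CHANNELS:
            series = chans[ch]
            cps = cp.ensemble_detect(series, grid_cfg, config.consensus,
                                     config.min_spacing_s, config.tolerance_s)
            g = gkf.gkf(cps.onsets, config.sigma_s, series.times, label=ch)
            per_listener.setdefault((perf, ch), []).append(g.series)
    out = {}
    for (perf, ch), series_list in per_listener.items():
        mean = gkf.average_listeners(series_list)
        out[(perf, ch)] = gkf.GKFSeries(ch, mean, config.sigma_s)
    return out


def music_gkf_sources(cohort, music_cps: dict, config: PipelineConfig) -> dict:
    out = {}
    for perf, music in cohort.music.items():
        grid = next(iter(music.channels.values())).times
        for ch in ACOUSTIC_CHANNELS:
            out[(perf, ch)] = gkf.gkf(music_cps[perf][ch].onsets, config.sigma_s, grid, label=ch)
        by_cat = {}
        for onset, category in cohort.annotations[perf].events:
            by_cat.setdefault(category, []).append(onset)
        for category in gkf.MUSIC_COLUMNS[len(ACOUSTIC_CHANNELS):]:
            out[(perf, category)] = gkf.gkf(by_cat.get(category, []), config.sigma_s, grid, label=category)
    return out


def musical_rows(cohort, music_cps: dict, config: PipelineConfig) -> list:
    rows = []
    for perf, music in cohort.music.items():
        onsets = gkf.musical_onsets(
            music_cps[perf],
            cohort.annotations[perf].events,
            config.min_spacing_s,
        )
        # clamp merged onsets into the sampled support
        end = music.duration
        rows.extend((music.piece_id, music.version_id, float(np.clip(t, 0, end))) for t in onsets)
    return rows


def run_pipeline(config: PipelineConfig, outdir=None, cohort=None) -> PipelineResult:
    if cohort is None:
        cohort = syn.generate_cohort(config.sim_config())
    channels = preprocess_cohort(cohort)
    profiles = baseline_profiles(cohort, config.stage_seed("baseline"))
    music_cps = detect_music_changepoints(cohort, config)
    events_by_category = build_event_categories(music_cps, cohort.annotations)

    x_sources = music_gkf_sources(cohort, music_cps, config)
    rows = musical_rows(cohort, music_cps, config)

    strata = {"all": None}
    for c in sorted(profiles["cluster"].unique()):
        strata[f"cluster_{c}"] = set(profiles.loc[profiles["cluster"] == c, "listener_id"])

    inputs_by_stratum = {}
    cca_by_stratum = {}
    graphs = {}
    for name, members in strata.items():
        y_sources = physio_gkf_sources(cohort, channels, config, members)
        covered = [r for r in rows if any(k[0] == f"{r[0]}__{r[1]}" for k in y_sources)]
        if not covered:
            continue
        inputs = gkf.assemble(x_sources, y_sources, covered)
        inputs_by_stratum[name] = inputs
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = cc.fit_cca(inputs.x, inputs.y)
            cc.surrogate_selection(
                inputs.x, inputs.y, config.n_surrogates,
                config.stage_seed(f"surrogate:{name}"), config.alpha, result=res)
            cc.permutation_pvalues(
                inputs.x, inputs.y, config.n_permutations,
                config.stage_seed(f"permutation:{name}"), result=res)
        cca_by_stratum[name] = res
        xl, yl = cc.loadings(res)
        retained = res.retained if res.retained is not None and res.retained.any() else None
        graphs[name] = cg.build_graph(xl, yl, retained, config.display_threshold)

    sessions = [
        (lid, perf, chans) for (lid, perf), chans in channels.items()
    ]
    event_tables = ev.run_event_response(
        sessions, events_by_category, config.windows_s, config.alpha,
        seed=config.stage_seed("events"))

    similarity, gam_report = individual_effects(
        cohort, channels, config, x_sources, rows, cca_by_stratum.get("all"), profiles)

    result = PipelineResult(
        cohort, channels, profiles, music_cps, events_by_category,
        inputs_by_stratum, cca_by_stratum, graphs, event_tables,
        similarity, gam_report)
    if outdir is not None:
        write_results(result, config, outdir)
    return result


def full_loading_vector(result, variate: int) -> np.ndarray:
    """Concatenated (music + physiology) loadings on the full column
    universe; columns dropped during the fit contribute zeros."""
    vec = np.zeros(len(gkf.MUSIC_COLUMNS) + len(PHYSIO_CHANNELS))
    for j, col in enumerate(gkf.MUSIC_COLUMNS):
        if col in result.x_columns:
            vec[j] = result.x_loadings[result.x_columns.index(col), variate]
    off = len(gkf.MUSIC_COLUMNS)
    for j, col in enumerate(PHYSIO_CHANNELS):
        if col in result.y_columns:
            vec[off + j] = result.y_loadings[result.y_columns.index(col), variate]
    return vec


def _subject_vector(inputs, variate: int):
    n = len(inputs.x)
    if n < ind.MIN_SUBJECT_ROWS:
        return None, f"only {n} rows (< {ind.MIN_SUBJECT_ROWS})"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = cc.fit_cca(inputs.x, inputs.y)
    if variate >= res.k:
        return None, f"variate {variate + 1} not available (k = {res.k})"
    return full_loading_vector(res, variate), None


def individual_effects(cohort, channels, config, x_sources, rows, group_result, profiles):
    if group_result is None:
        return pd.DataFrame(), None
    retained = group_result.retained
    variate = int(np.argmax(retained)) if retained is not None and retained.any() else 0
    group_vec = full_loading_vector(group_result, variate)

    sim_rows = []
    for rec in cohort.listeners:
        heard = set(rec.playlist)
        own_rows = [r for r in rows if f"{r[0]}__{r[1]}" in heard]
        if not own_rows:
            sim_rows.append(dict(listener_id=rec.listener_id, similarity=np.nan,
                                 skipped="no rows"))
            continue
        y_sources = physio_gkf_sources(
            cohort, {k: v for k, v in channels.items() if k[0] == rec.listener_id},
            config)
        inputs = gkf.assemble(x_sources, y_sources, own_rows)
        vec, reason = _subject_vector(inputs, variate)
        if vec is None:
            sim_rows.append(dict(listener_id=rec.listener_id, similarity=np.nan,
                                 skipped=reason, n_rows=len(own_rows)))
            continue
        sim_rows.append(dict(
            listener_id=rec.listener_id,
            similarity=ind.cosine_similarity(vec, group_vec),
            skipped="", n_rows=len(own_rows)))
    sim = pd.DataFrame(sim_rows).merge(profiles, on="listener_id")

    fitted = sim[np.isfinite(sim["similarity"])]
    report = None
    if len(fitted) >= 10:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = ind.fit_gam(fitted)
    return sim, report


def write_results(result: PipelineResult, config: PipelineConfig, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    syn.write_cohort(result.cohort, out / "cohort")
    result.profiles.to_csv(out / "profiles.csv", index=False)

    cps_rows = []
    for perf, per_channel in sorted(result.music_cps.items()):
        for ch, cps in per_channel.items():
            for onset, prob, cat in zip(cps.onsets, cps.probabilities, cps.categories):
                cps_rows.append(dict(performance=perf, channel=ch, onset_s=float(onset),
                                     probability=float(prob), category=cat))
    pd.DataFrame(cps_rows).to_csv(out / "changepoints.csv", index=False)

    for name, inputs in result.inputs_by_stratum.items():
        gkf.write_inputs(inputs, out / "matrices" / name)
    for name, res in result.cca_by_stratum.items():
        (out / "cca").mkdir(exist_ok=True)
        (out / "cca" / f"{name}.json").write_text(json.dumps(cc.to_json_dict(res), indent=1))
    for name, graph in result.graphs.items():
        (out / "graphs").mkdir(exist_ok=True)
        cg.save_graph(graph, out / "graphs" / f"{name}.json")
        cg.render(graph, out / "graphs" / f"{name}.svg")
    (out / "events").mkdir(exist_ok=True)
    for w, table in result.event_tables.items():
        table.to_csv(out / "events" / f"window_{w:g}s.csv", index=False)
        ev.render_arrows(table, out / "events" / f"window_{w:g}s.png")
    result.similarity.to_csv(out / "similarity.csv", index=False)
    if result.gam_report is not None:
        (out / "gam_report.json").write_text(json.dumps(result.gam_report.to_dict(), indent=1))

    manifest = dict(
        config_hash=config.config_hash(),
        seed=config.seed,
        stage_seeds={s: config.stage_seed(s) for s in
                     ("simulate", "baseline", "events")},
        outputs=sorted(str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()),
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
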