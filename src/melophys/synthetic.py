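"""Synthetic cohort generator with known ground truth.

Emulates the four inputs the analysis pipeline consumes — per-piece musical
feature series, annotation event lists, per-listener physiological
recordings, and a cohort manifest — with planted change points, planted
event-locked physiological responses whose sign can depend on the
listener's baseline autonomic archetype, and three baseline archetypes.

Stated simplifications (documented, deliberate):

* RR sequences are built directly (mean + respiratory sinus arrhythmia +
  a slow oscillation + AR(1) noise) rather than through an
  integral-pulse-frequency-modulation model.
* Event responses are causal transients with configurable latency, rise
  and decay; the shape is a saturating-rise/exponential-decay kernel
  normalized to unit peak.
* Altered versions of a piece are global gain/tempo rescalings of the
  original's channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from melophys.core import (
    ACOUSTIC_CHANNELS,
    ANNOTATION_CATEGORIES,
    GRID_RATE_HZ,
    ConfigError,
    UniformSeries,
    common_grid,
)

ARCHETYPES = ("pns_dominant", "balanced", "sns_dominant")

#: Baseline physiology per archetype: mean RR (s), RSA amplitude (s),
#: slow-oscillation amplitude (s), AR(1) noise sd (s), SYS/DIA means (mmHg).
ARCHETYPE_PARAMS = {
    "pns_dominant": dict(mean_rr=1.05, rsa_amp=0.050, lf_amp=0.030, ar_sd=0.020, sys=115.0, dia=72.0),
    "balanced": dict(mean_rr=0.85, rsa_amp=0.030, lf_amp=0.025, ar_sd=0.015, sys=122.0, dia=78.0),
    "sns_dominant": dict(mean_rr=0.68, rsa_amp=0.012, lf_amp=0.015, ar_sd=0.006, sys=135.0, dia=88.0),
}

#: Resting levels for the acoustic feature channels.
MUSIC_BASE_LEVELS = {
    "tempo": 100.0,        # bpm
    "loudness": 20.0,      # sones
    "spectral_centroid": 1500.0,  # Hz
    "mfcc": 0.0,           # a.u.
    "diameter": 1.0,       # a.u.
}

#: Default mean-shift magnitude per channel (channel units).
MUSIC_SHIFT = {
    "tempo": 15.0,
    "loudness": 6.0,
    "spectral_centroid": 300.0,
    "mfcc": 1.5,
    "diameter": 0.4,
}

#: Default white-noise sd per channel (channel units).
MUSIC_NOISE_SD = {
    "tempo": 3.0,
    "loudness": 1.2,
    "spectral_centroid": 60.0,
    "mfcc": 0.3,
    "diameter": 0.08,
}

#: Version alterations: (loudness gain, tempo factor).
DEFAULT_VERSIONS = {"V1": (1.0, 1.0), "V2": (1.25, 1.1)}


@dataclass(frozen=True)
class Coupling:
    """One planted music-event -> physiology response link.

    ``category`` is either a retained annotation category (e.g.
    ``"Novel Melody"``) or an acoustic channel with a direction suffix
    (``"tempo_up"``, ``"loudness_down"``). ``channel`` is one of the raw
    physiological channels the generator can perturb: ``rr`` (s, added to
    RR intervals), ``resp`` (s, added to respiratory intervals), ``sys``
    or ``dia`` (mmHg, added beatwise). ``sign_map`` multiplies the
    amplitude per archetype (default +1 everywhere).
    """

    category: str
    channel: str
    amplitude: float
    latency_s: float = 1.0
    rise_s: float = 1.5
    decay_s: float = 4.0
    sign_map: dict = field(default_factory=dict)

    def sign(self, archetype: str) -> float:
        return float(self.sign_map.get(archetype, 1.0))


@dataclass
class SimConfig:
    n_pieces: int = 4
    piece_duration_s: float = 180.0
    n_listeners: int = 12
    playlist_length: int = 9
    archetype_mix: tuple = (0.2, 0.6, 0.2)  # pns, balanced, sns
    couplings: tuple = ()
    annotation_counts: dict = field(default_factory=lambda: {c: 2 for c in ANNOTATION_CATEGORIES})
    cp_per_channel: int = 3
    music_noise_sd: dict = field(default_factory=dict)
    music_shift: dict = field(default_factory=dict)
    versions: dict = field(default_factory=lambda: dict(DEFAULT_VERSIONS))
    event_window_s: float = 10.0
    baseline_duration_s: float = 320.0
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.piece_duration_s <= 0:
            raise ConfigError("piece_duration_s must be > 0")
        if self.n_pieces < 1 or self.n_listeners < 1:
            raise ConfigError("need at least one piece and one listener")
        if abs(sum(self.archetype_mix) - 1.0) > 1e-9:
            raise ConfigError("archetype_mix proportions must sum to 1")
        if any(p < 0 for p in self.archetype_mix):
            raise ConfigError("archetype_mix proportions must be non-negative")
        n_perf = self.n_pieces * len(self.versions)
        if self.playlist_length > n_perf:
            raise ConfigError(
                f"playlist_length {self.playlist_length} exceeds available performances {n_perf}"
            )
        if self.playlist_length < 2:
            raise ConfigError("playlist_length must be >= 2 (first/last are versions of one piece)")
        if len(self.versions) < 2:
            raise ConfigError("need >= 2 versions per piece for the first/last playlist rule")
        for sd in self.music_noise_sd.values():
            if sd < 0:
                raise ConfigError("noise sd must be >= 0")
        for cat, cnt in self.annotation_counts.items():
            if cnt < 0:
                raise ConfigError(f"annotation count for {cat!r} must be >= 0")

    def noise_sd(self, channel: str) -> float:
        return self.music_noise_sd.get(channel, MUSIC_NOISE_SD[channel])

    def shift(self, channel: str) -> float:
        return self.music_shift.get(channel, MUSIC_SHIFT[channel])


@dataclass
class MusicFeatureSet:
    piece_id: str
    version_id: str
    channels: dict            # channel -> UniformSeries
    truth_changepoints: list  # (time_s, channel, direction "up"/"down")

    @property
    def performance_id(self) -> str:
        return f"{self.piece_id}__{self.version_id}"

    @property
    def duration(self) -> float:
        return next(iter(self.channels.values())).duration


@dataclass
class AnnotationSet:
    piece_id: str
    version_id: str
    events: list  # (onset_s, category), strictly increasing onsets

    @property
    def performance_id(self) -> str:
        return f"{self.piece_id}__{self.version_id}"


@dataclass
class SessionSignals:
    """Raw physiological signals for one listener x performance."""

    rr: np.ndarray                 # beat-wise RR intervals (s)
    resp_wave: UniformSeries       # respiration waveform (a.u., 10 Hz)
    resp_truth_intervals: np.ndarray  # ground-truth respiratory intervals (s)
    resp_truth_peaks: np.ndarray      # ground-truth breath peak times (s)
    sys: np.ndarray                # beat-wise systolic BP (mmHg)
    dia: np.ndarray                # beat-wise diastolic BP (mmHg)
    duration: float


@dataclass
class ListenerRecord:
    listener_id: str
    archetype: str
    baseline_rr: np.ndarray
    sessions: dict   # performance_id -> SessionSignals
    demographics: dict
    playlist: list   # ordered performance ids


@dataclass
class Cohort:
    config: SimConfig
    music: dict        # performance_id -> MusicFeatureSet
    annotations: dict  # performance_id -> AnnotationSet
    listeners: list
    truth: dict        # ground-truth ledger


def _rng(seed: int, *stream) -> np.random.Generator:
    return np.random.default_rng([seed, *stream])


def _piece_index(piece_id: str) -> int:
    return int(piece_id.rsplit("_", 1)[-1])


def piece_name(i: int) -> str:
    return f"piece_{i:02d}"


# ---------------------------------------------------------------------------
# music


def _plant_changepoints(rng, duration: float, k: int, min_gap: float = 20.0):
    """k change-point times with pairwise gaps >= min_gap, away from edges."""
    if k == 0:
        return np.empty(0)
    edge = 15.0
    span = duration - 2 * edge - (k - 1) * min_gap
    if span <= 0:
        raise ConfigError(f"cannot place {k} change points {min_gap} s apart in {duration} s")
    u = np.sort(rng.uniform(0, span, size=k))
    return edge + u + min_gap * np.arange(k)


def generate_music(config: SimConfig, piece_id: str, version_id: str = "V1") -> MusicFeatureSet:
    """Piecewise-constant mean processes plus white noise per acoustic channel.

    Deterministic given ``config.seed`` and the piece id; versions other
    than V1 are gain/tempo rescalings of V1 (same underlying draws).
    """
    if version_id not in config.versions:
        raise ConfigError(f"unknown version {version_id!r}")
    gain, tempo_factor = config.versions[version_id]
    duration = config.piece_duration_s / tempo_factor
    grid = common_grid(duration)
    rng = _rng(config.seed, 1, _piece_index(piece_id))

    channels = {}
    truth = []
    for channel in ACOUSTIC_CHANNELS:
        # draws are shared across versions: same rng stream, onsets rescaled
        cps_v1 = _plant_changepoints(rng, config.piece_duration_s, config.cp_per_channel)
        signs = rng.choice([-1.0, 1.0], size=len(cps_v1))
        noise = rng.standard_normal(len(grid)) * config.noise_sd(channel)

        level = MUSIC_BASE_LEVELS[channel]
        if channel == "loudness":
            level = level * gain
        if channel == "tempo":
            level = level * tempo_factor
        mean = np.full(len(grid), level)
        cps = cps_v1 / tempo_factor
        for t_cp, s in zip(cps, signs):
            shift = s * config.shift(channel)
            if channel == "loudness":
                shift *= gain
            if channel == "tempo":
                shift *= tempo_factor
            mean[grid >= t_cp] += shift
            truth.append((float(t_cp), channel, "up" if s > 0 else "down"))
        channels[channel] = UniformSeries(channel, mean + noise, rate=GRID_RATE_HZ)
    truth.sort()
    return MusicFeatureSet(piece_id, version_id, channels, truth)


def generate_annotations(config: SimConfig, piece_id: str, version_id: str = "V1") -> AnnotationSet:
    """Annotation events with all pairwise gaps >= 2 x event window length."""
    counts = {c: int(n) for c, n in config.annotation_counts.items() if n > 0}
    bad = set(counts) - set(ANNOTATION_CATEGORIES)
    if bad:
        raise ConfigError(f"unknown annotation categories: {sorted(bad)}")
    _, tempo_factor = config.versions[version_id]
    duration = config.piece_duration_s / tempo_factor
    total = sum(counts.values())
    if total == 0:
        return AnnotationSet(piece_id, version_id, [])
    gap = 2.0 * config.event_window_s / tempo_factor
    edge = config.event_window_s / tempo_factor
    span = duration - 2 * edge - (total - 1) * gap
    if span <= 0:
        raise ConfigError(
            f"cannot place {total} events with gap {gap:.1f} s in a {duration:.0f} s piece"
        )
    rng = _rng(config.seed, 2, _piece_index(piece_id))
    u = np.sort(rng.uniform(0, span, size=total))
    onsets = edge + u + gap * np.arange(total)
    labels = np.repeat(list(counts.keys()), list(counts.values()))
    rng.shuffle(labels)
    return AnnotationSet(piece_id, version_id, [(float(t), str(c)) for t, c in zip(onsets, labels)])


# ---------------------------------------------------------------------------
# physiology


def response_kernel(t: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Causal transient, unit peak: (1 - exp(-t/rise)) * exp(-t/decay) for t > 0."""
    t = np.asarray(t, dtype=float)
    raw = np.where(t > 0, (1.0 - np.exp(-np.maximum(t, 0) / rise_s)) * np.exp(-np.maximum(t, 0) / decay_s), 0.0)
    # peak of the analytic form
    t_pk = rise_s * np.log(1.0 + decay_s / rise_s)
    peak = (1.0 - np.exp(-t_pk / rise_s)) * np.exp(-t_pk / decay_s)
    return raw / peak


def _coupling_events(config, archetype, music, annotations):
    """Per raw channel: list of (onset, signed amplitude, latency, rise, decay)."""
    by_channel = {}
    for c in config.couplings:
        if c.channel not in ("rr", "resp", "sys", "dia"):
            raise ConfigError(f"coupling channel {c.channel!r} not generatable")
        onsets = []
        if c.category in ANNOTATION_CATEGORIES:
            onsets = [t for t, cat in annotations.events if cat == c.category]
        else:
            chan, _, direction = c.category.rpartition("_")
            if chan not in ACOUSTIC_CHANNELS or direction not in ("up", "down"):
                raise ConfigError(f"unknown coupling category {c.category!r}")
            onsets = [t for t, ch, d in music.truth_changepoints if ch == chan and d == direction]
        amp = c.amplitude * c.sign(archetype)
        for t in onsets:
            by_channel.setdefault(c.channel, []).append((t, amp, c.latency_s, c.rise_s, c.decay_s))
    return by_channel


def _event_response(t, events):
    """Summed transient responses at times t for a list of planted events."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    for onset, amp, latency, rise, decay in events:
        out += amp * response_kernel(t - onset - latency, rise, decay)
    return out


def _session_physio(rng, params, duration, events_by_channel):
    """Generate one session's raw signals for a listener archetype."""
    resp_rate = 10.0  # waveform sample rate, Hz
    tg = np.arange(int(duration * resp_rate) + 1) / resp_rate

    # respiratory interval process: base 4 s + slow drift + planted responses
    phi = rng.uniform(0, 2 * np.pi)
    interval = 4.0 + 0.3 * np.sin(2 * np.pi * 0.01 * tg + phi)
    interval += _event_response(tg, events_by_channel.get("resp", ()))
    interval = np.clip(interval, 1.5, 10.0)
    freq = 1.0 / interval
    phase = 2 * np.pi * np.concatenate([[0.0], np.cumsum((freq[1:] + freq[:-1]) / 2) / resp_rate])
    wave = np.sin(phase) + 0.02 * rng.standard_normal(len(tg))
    resp_wave = UniformSeries("resp_wave", wave, rate=resp_rate, units="a.u.")

    # ground-truth respiratory intervals from peak times (phase = pi/2 + 2*pi*k)
    k_max = int((phase[-1] - np.pi / 2) / (2 * np.pi))
    peak_phases = np.pi / 2 + 2 * np.pi * np.arange(k_max + 1)
    peak_phases = peak_phases[(peak_phases > phase[0]) & (peak_phases < phase[-1])]
    peak_times = np.interp(peak_phases, phase, tg)
    resp_truth = np.diff(peak_times)

    # RR sequence: mean + RSA at instantaneous respiratory phase + slow osc + AR(1)
    rr_events = events_by_channel.get("rr", ())
    phi_lf = rng.uniform(0, 2 * np.pi)
    rho = 0.3
    rr_list = []
    t, ar = 0.0, 0.0
    while t < duration:
        ar = rho * ar + params["ar_sd"] * np.sqrt(1 - rho ** 2) * rng.standard_normal()
        ph = np.interp(t, tg, phase)
        rr = (
            params["mean_rr"]
            + params["rsa_amp"] * np.sin(ph)
            + params["lf_amp"] * np.sin(2 * np.pi * 0.1 * t + phi_lf)
            + ar
            + float(_event_response(t, rr_events)[0])
        )
        rr = float(np.clip(rr, 0.31, 1.99))
        rr_list.append(rr)
        t += rr
    rr = np.asarray(rr_list)

    beat_times = np.concatenate([[0.0], np.cumsum(rr)[:-1]])
    n_beats = len(rr)
    sys_bp = params["sys"] + 2.0 * rng.standard_normal(n_beats)
    dia_bp = params["dia"] + 1.5 * rng.standard_normal(n_beats)
    sys_bp += _event_response(beat_times, events_by_channel.get("sys", ()))
    dia_bp += _event_response(beat_times, events_by_channel.get("dia", ()))
    dia_bp = np.minimum(dia_bp, sys_bp - 5.0)  # enforce PP > 0

    return SessionSignals(rr, resp_wave, resp_truth, peak_times, sys_bp, dia_bp, duration)


def generate_listener(
    config: SimConfig,
    archetype: str,
    performances: dict,
    annotations: dict,
    playlist: list,
    listener_id: str = "listener_000",
) -> ListenerRecord:
    """One listener: archetype-specific baseline plus session signals per
    performance in the playlist, with planted event-locked responses."""
    if archetype not in ARCHETYPES:
        raise ConfigError(f"unknown archetype {archetype!r}")
    params = ARCHETYPE_PARAMS[archetype]
    idx = int(listener_id.rsplit("_", 1)[-1])
    rng = _rng(config.seed, 3, idx)

    base = _session_physio(rng, params, config.baseline_duration_s, {})
    baseline_rr = base.rr

    sessions = {}
    for perf_id in playlist:
        music = performances[perf_id]
        ann = annotations[perf_id]
        events = _coupling_events(config, archetype, music, ann)
        sessions[perf_id] = _session_physio(rng, params, music.duration, events)

    demographics = dict(
        age=int(rng.integers(21, 80)),
        gender=str(rng.choice(["F", "M"])),
        musician=bool(rng.random() < 0.4),
        prefers_classical=bool(rng.random() < 0.5),
    )
    return ListenerRecord(listener_id, archetype, baseline_rr, sessions, demographics, list(playlist))


# ---------------------------------------------------------------------------
# cohort


def archetype_counts(mix, n: int) -> list:
    """Largest-remainder apportionment of n listeners over the three archetypes."""
    raw = np.asarray(mix) * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def _make_playlist(config: SimConfig, rng) -> list:
    """Ordered performance ids; first and last are versions of one piece."""
    version_ids = list(config.versions.keys())
    pieces = [piece_name(i) for i in range(config.n_pieces)]
    anchor = pieces[int(rng.integers(config.n_pieces))]
    v1, v2 = rng.choice(version_ids, size=2, replace=False)
    first, last = f"{anchor}__{v1}", f"{anchor}__{v2}"
    pool = [
        f"{p}__{v}" for p in pieces for v in version_ids
        if f"{p}__{v}" not in (first, last)
    ]
    middle = [str(p) for p in rng.choice(pool, size=config.playlist_length - 2, replace=False)]
    return [first, *middle, last]


def generate_cohort(config: SimConfig) -> Cohort:
    """Full synthetic cohort plus a ground-truth ledger."""
    if config.n_listeners < 3:
        raise ConfigError("need >= 3 listeners for 3 archetypes")
    pieces = [piece_name(i) for i in range(config.n_pieces)]
    music, annotations = {}, {}
    for p in pieces:
        for v in config.versions:
            m = generate_music(config, p, v)
            music[m.performance_id] = m
            a = generate_annotations(config, p, v)
            annotations[a.performance_id] = a

    counts = archetype_counts(config.archetype_mix, config.n_listeners)
    arch_list = [a for a, c in zip(ARCHETYPES, counts) for _ in range(c)]
    rng = _rng(config.seed, 4)
    rng.shuffle(arch_list)

    listeners = []
    for i, arch in enumerate(arch_list):
        lid = f"listener_{i:03d}"
        playlist = _make_playlist(config, _rng(config.seed, 5, i))
        listeners.append(generate_listener(config, arch, music, annotations, playlist, lid))

    # guarantee coverage: round-robin any unheard performance onto listeners
    heard = {p for rec in listeners for p in rec.playlist}
    missing = [p for p in music if p not in heard]
    for j, perf in enumerate(missing):
        rec = listeners[j % len(listeners)]
        m = music[perf]
        events = _coupling_events(config, rec.archetype, m, annotations[perf])
        srng = _rng(config.seed, 6, j)
        rec.sessions[perf] = _session_physio(srng, ARCHETYPE_PARAMS[rec.archetype], m.duration, events)
        rec.playlist.insert(1, perf)

    truth = dict(
        changepoints={pid: m.truth_changepoints for pid, m in music.items()},
        annotations={pid: a.events for pid, a in annotations.items()},
        archetypes={rec.listener_id: rec.archetype for rec in listeners},
        couplings=[
            dict(category=c.category, channel=c.channel, amplitude=c.amplitude,
                 latency_s=c.latency_s, rise_s=c.rise_s, decay_s=c.decay_s,
                 sign_map=dict(c.sign_map))
            for c in config.couplings
        ],
    )
    return Cohort(config, music, annotations, listeners, truth)


# ---------------------------------------------------------------------------
# serialization


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write the cohort as plain-text tables plus JSON manifest and truth ledger."""
    from pathlib import Path

    import pandas as pd

    out = Path(outdir)
    (out / "music").mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(exist_ok=True)
    (out / "listeners").mkdir(exist_ok=True)

    for pid, m in sorted(cohort.music.items()):
        grid = next(iter(m.channels.values())).times
        df = pd.DataFrame({"time_s": grid})
        for ch in ACOUSTIC_CHANNELS:
            df[ch] = m.channels[ch].values
        df.to_csv(out / "music" / f"{pid}.csv", index=False, float_format="%.6f")

    for pid, a in sorted(cohort.annotations.items()):
        pd.DataFrame(a.events, columns=["onset_s", "category"]).to_csv(
            out / "annotations" / f"{pid}.csv", index=False, float_format="%.6f"
        )

    for rec in cohort.listeners:
        ldir = out / "listeners" / rec.listener_id
        ldir.mkdir(exist_ok=True)
        pd.DataFrame({"rr_s": rec.baseline_rr}).to_csv(
            ldir / "baseline_rr.csv", index=False, float_format="%.6f"
        )
        for perf, s in sorted(rec.sessions.items()):
            pd.DataFrame({"rr_s": s.rr}).to_csv(
                ldir / f"{perf}__rr.csv", index=False, float_format="%.6f")
            pd.DataFrame(
                {"time_s": s.resp_wave.times, "resp": s.resp_wave.values}
            ).to_csv(ldir / f"{perf}__resp.csv", index=False, float_format="%.6f")
            pd.DataFrame({"sys_mmHg": s.sys, "dia_mmHg": s.dia}).to_csv(
                ldir / f"{perf}__bp.csv", index=False, float_format="%.6f")

    manifest = dict(
        n_pieces=cohort.config.n_pieces,
        versions={k: list(v) for k, v in cohort.config.versions.items()},
        seed=cohort.config.seed,
        listeners=[
            dict(listener_id=r.listener_id, playlist=r.playlist, **r.demographics)
            for r in cohort.listeners
        ],
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (out / "truth.json").write_text(json.dumps(cohort.truth, indent=1, sort_keys=True))
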