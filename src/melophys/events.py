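"""Event-locked physiological response analysis.

For each musical change-point category (7 annotation categories plus
5 acoustic channels split into increase/decrease, 17 in total) and each
of the 9 physiological channels, the mean physiological level in the
10-s window after each event is compared with the 10-s window before,
with a paired t-test or Wilcoxon signed-rank test depending on the
normality of the differences, Bonferroni correction across all 153
combinations, and sensitivity window lengths of 8 and 12 s.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from melophys.core import ACOUSTIC_CHANNELS, ANNOTATION_CATEGORIES, PHYSIO_CHANNELS, UniformSeries

DEFAULT_WINDOW_S = 10.0
SENSITIVITY_WINDOWS_S = (8.0, 10.0, 12.0)
ALPHA = 0.05
NORMALITY_ALPHA = 0.05
BOOTSTRAP_RESAMPLES = 1000

#: The 17 event categories: directioned acoustic channels + annotations.
EVENT_CATEGORIES = tuple(
    f"{ch}_{d}" for ch in ACOUSTIC_CHANNELS for d in ("up", "down")
) + tuple(ANNOTATION_CATEGORIES)


def bonferroni_alpha(alpha: float = ALPHA, m: int | None = None) -> float:
    """Per-comparison threshold alpha / m (m defaults to 17 x 9 = 153)."""
    if m is None:
        m = len(EVENT_CATEGORIES) * len(PHYSIO_CHANNELS)
    return alpha / m


def window_diff(series: UniformSeries, onset: float, window_s: float = DEFAULT_WINDOW_S):
    """mean(onset, onset + w] - mean[onset - w, onset), or None if the
    windows do not fully fit within the recording (event skipped)."""
    if onset - window_s < series.start or onset + window_s > series.end:
        return None
    t = series.times
    pre = series.values[(t >= onset - window_s) & (t < onset)]
    post = series.values[(t > onset) & (t <= onset + window_s)]
    return float(np.mean(post) - np.mean(pre))


def category_test(diffs):
    """Two-sided paired test on event differences.

    Shapiro-Wilk at alpha 0.05 gates the choice: normal differences use
    a one-sample t-test on the differences (equivalent to the paired
    t-test), otherwise a Wilcoxon signed-rank test. Returns
    ``(statistic, p, label)``; ``label`` is ``"degenerate"`` for
    all-zero differences.
    """
    diffs = np.asarray(diffs, dtype=float)
    if len(diffs) < 5:
        raise ValueError("need >= 5 paired differences")
    if np.all(diffs == 0):
        return 0.0, 1.0, "degenerate"
    _, p_norm = stats.shapiro(diffs)
    if p_norm >= NORMALITY_ALPHA:
        stat, p = stats.ttest_1samp(diffs, 0.0)
        return float(stat), float(p), "paired-t"
    res = stats.wilcoxon(diffs, alternative="two-sided")
    # signed statistic for direction reporting
    sign = np.sign(np.median(diffs[diffs != 0])) if np.any(diffs != 0) else 0.0
    return float(sign * res.statistic), float(res.pvalue), "wilcoxon"


def _ci95(diffs, normal: bool, seed: int = 0):
    diffs = np.asarray(diffs, dtype=float)
    m = float(np.mean(diffs))
    if normal:
        sem = stats.sem(diffs)
        if sem == 0:
            return m, m
        lo, hi = stats.t.interval(0.95, len(diffs) - 1, loc=m, scale=sem)
        return float(lo), float(hi)
    rng = np.random.default_rng(seed)
    boots = rng.choice(diffs, size=(BOOTSTRAP_RESAMPLES, len(diffs)), replace=True).mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(lo), float(hi)


def collect_diffs(sessions, events_by_category, window_s: float = DEFAULT_WINDOW_S):
    """Per-(participant, event) window differences for every cell.

    ``sessions``: list of (listener_id, performance_id, {channel: UniformSeries}).
    ``events_by_category``: performance_id -> {category: [onset_s, ...]}.
    Returns ``{(category, channel): (diff list, n skipped)}``.
    """
    cells = {(c, ch): ([], 0) for c in EVENT_CATEGORIES for ch in PHYSIO_CHANNELS}
    for listener_id, perf, channels in sessions:
        cat_events = events_by_category.get(perf, {})
        for category, onsets in cat_events.items():
            if category not in EVENT_CATEGORIES:
                continue
            for ch in PHYSIO_CHANNELS:
                series = channels[ch]
                diffs, skipped = cells[(category, ch)]
                for onset in onsets:
                    d = window_diff(series, onset, window_s)
                    if d is None:
                        skipped += 1
                    else:
                        diffs.append(d)
                cells[(category, ch)] = (diffs, skipped)
    return cells


def run_event_response(sessions, events_by_category,
                       windows_s=SENSITIVITY_WINDOWS_S, alpha: float = ALPHA,
                       seed: int = 0) -> dict:
    """Full difference analysis; one table per window length.

    The Bonferroni family size is the full 17 x 9 = 153 grid regardless
    of how many cells have enough events, matching the family the
    correction is defined over.
    """
    m = len(EVENT_CATEGORIES) * len(PHYSIO_CHANNELS)
    thr = bonferroni_alpha(alpha, m)
    tables = {}
    for w in windows_s:
        cells = collect_diffs(sessions, events_by_category, w)
        rows = []
        for (category, ch), (diffs, skipped) in sorted(cells.items()):
            row = dict(category=category, signal=ch, window_s=w,
                       n_pairs=len(diffs), n_skipped=skipped)
            if len(diffs) >= 5:
                stat, p, label = category_test(diffs)
                lo, hi = _ci95(diffs, label == "paired-t", seed)
                tier = ("significant" if p < thr
                        else "trend" if p < alpha else "none")
                row.update(mean_diff=float(np.mean(diffs)), ci_lo=lo, ci_hi=hi,
                           statistic=stat, p=p, test=label, tier=tier)
            else:
                row.update(mean_diff=np.nan, ci_lo=np.nan, ci_hi=np.nan,
                           statistic=np.nan, p=np.nan, test="insufficient", tier="none")
            rows.append(row)
        tables[w] = pd.DataFrame(rows)
    return tables


def render_arrows(table: pd.DataFrame, path) -> None:
    """Arrow-diagram figure: two arrows = Bonferroni-significant,
    one arrow = trend (p < 0.05), blank = none; direction from the sign
    of the mean difference."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cats = list(dict.fromkeys(table["category"]))
    sigs = list(dict.fromkeys(table["signal"]))
    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(sigs), 1 + 0.35 * len(cats)))
    for i, cat in enumerate(cats):
        for j, sig in enumerate(sigs):
            row = table[(table["category"] == cat) & (table["signal"] == sig)].iloc[0]
            if row["tier"] == "none" or not np.isfinite(row["mean_diff"]):
                continue
            arrow = "↑" if row["mean_diff"] > 0 else "↓"
            txt = arrow * (2 if row["tier"] == "significant" else 1)
            ax.text(j, len(cats) - 1 - i, txt, ha="center", va="center", fontsize=10,
                    color="firebrick" if row["mean_diff"] > 0 else "navy")
    ax.set_xticks(range(len(sigs)), sigs, rotation=45, ha="right", fontsize=8)
    ax.set_yticks(range(len(cats)), list(reversed(cats)), fontsize=8)
    ax.set_xlim(-0.5, len(sigs) - 0.5)
    ax.set_ylim(-0.5, len(cats) - 0.5)
    ax.set_title(f"event-locked responses (window {table['window_s'].iloc[0]:g} s)", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
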