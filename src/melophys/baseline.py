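"""Baseline HRV summaries, PNS/SNS composite indices, and k-means stratification."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from melophys.core import DataError

#: Histogram bin width (s) for the Baevsky stress index mode/AMo.
BAEVSKY_BIN_S = 0.050

#: Cluster labels, ordered by descending mean(PNS - SNS).
CLUSTER_NAMES = {1: "pns_dominant", 2: "balanced", 3: "sns_dominant"}


@dataclass(frozen=True)
class HRVSummary:
    mean_rr: float    # s
    mean_hr: float    # bpm
    rmssd: float      # ms
    sdnn: float       # ms
    sd1: float        # ms
    sd2: float        # ms
    sd1nu: float      # % of SD1+SD2
    sd2nu: float      # % of SD1+SD2
    baevsky_si: float # dimensionless
    degenerate: bool = False


def hrv_summary(rr, min_beats: int = 120) -> HRVSummary:
    """Time-domain and Poincaré HRV summary of a baseline RR sequence.

    RMSSD is the root mean square of successive differences; SD1/SD2 are
    the Poincaré plot axes (SD1 = sd(successive diffs)/sqrt(2),
    SD2 = sqrt(2*SDNN^2 - SD1^2)); SD1nu/SD2nu are their shares of
    SD1+SD2 in percent. The Baevsky stress index is
    AMo% / (2 * Mo * MxDMn) with a 50 ms RR histogram (Mo the modal bin
    centre in s, AMo its percentage share, MxDMn the RR range in s).
    """
    rr = np.asarray(rr, dtype=float)
    if len(rr) < min_beats:
        raise DataError(f"need >= {min_beats} baseline beats, got {len(rr)}")
    mean_rr = float(np.mean(rr))
    diffs = np.diff(rr)
    sdnn = float(np.std(rr, ddof=1)) * 1e3
    rmssd = float(np.sqrt(np.mean(diffs**2))) * 1e3
    degenerate = np.ptp(rr) == 0.0
    if degenerate:
        sd1 = sd2 = 0.0
        sd1nu = sd2nu = float("nan")
        si = float("inf")
    else:
        sd1 = float(np.std(diffs, ddof=1) / np.sqrt(2)) * 1e3
        sd2 = float(np.sqrt(max(2 * (sdnn**2) - sd1**2, 0.0)))
        sd1nu = 100.0 * sd1 / (sd1 + sd2)
        sd2nu = 100.0 * sd2 / (sd1 + sd2)
        edges = np.arange(np.min(rr), np.max(rr) + 2 * BAEVSKY_BIN_S, BAEVSKY_BIN_S)
        hist, edges = np.histogram(rr, bins=edges)
        k = int(np.argmax(hist))
        mo = float((edges[k] + edges[k + 1]) / 2)
        amo = 100.0 * hist[k] / len(rr)
        mxdmn = float(np.ptp(rr))
        si = amo / (2.0 * mo * mxdmn)
    return HRVSummary(
        mean_rr=mean_rr, mean_hr=60.0 / mean_rr, rmssd=rmssd, sdnn=sdnn,
        sd1=sd1, sd2=sd2, sd1nu=sd1nu, sd2nu=sd2nu, baevsky_si=float(si),
        degenerate=degenerate,
    )


def _zscores(values) -> np.ndarray:
    """Cohort z-scores; a zero-variance constituent is dropped (all zeros)."""
    values = np.asarray(values, dtype=float)
    sd = np.std(values, ddof=1) if len(values) > 1 else 0.0
    if sd == 0.0 or not np.isfinite(sd):
        warnings.warn("zero-variance constituent dropped from index", stacklevel=3)
        return np.zeros_like(values)
    return (values - np.mean(values)) / sd


def pns_sns_indices(summaries) -> np.ndarray:
    """Cohort-standardized composite indices, shape (n, 2) = (PNS, SNS).

    PNS averages z-scores of (mean RR, RMSSD, SD1nu); SNS averages
    z-scores of (mean HR, Baevsky SI, SD2nu). Indices are standardized
    within the cohort, not against external population norms, so their
    absolute scale differs from normative software output while
    preserving ordering.
    """
    if len(summaries) < 3:
        raise DataError("need >= 3 listeners to standardize indices")
    pns = np.mean(
        [_zscores([s.mean_rr for s in summaries]),
         _zscores([s.rmssd for s in summaries]),
         _zscores([s.sd1nu for s in summaries])], axis=0)
    sns = np.mean(
        [_zscores([s.mean_hr for s in summaries]),
         _zscores([s.baevsky_si for s in summaries]),
         _zscores([s.sd2nu for s in summaries])], axis=0)
    return np.column_stack([pns, sns])


def cluster_autonomic(indices, seed: int = 0, n_clusters: int = 3, n_init: int = 25):
    """K-means stratification into autonomic clusters 1..3.

    Labels are relabelled by descending cluster mean of (PNS - SNS), so
    cluster 1 is parasympathetic-dominant and cluster 3
    sympathetic-dominant irrespective of k-means initialization.
    Returns ``(labels, info)``; ``info['low_separation']`` flags a
    silhouette score below 0.5 (k-means on a single isotropic blob
    scores ~0.35, well-separated archetype blobs score > 0.9).
    """
    indices = np.asarray(indices, dtype=float)
    if len(indices) < n_clusters:
        raise DataError(f"need >= {n_clusters} listeners to form {n_clusters} clusters")
    km = KMeans(n_clusters=n_clusters, n_init=n_init, random_state=seed)
    raw = km.fit_predict(indices)
    balance = np.array([
        np.mean(indices[raw == c, 0] - indices[raw == c, 1]) for c in range(n_clusters)
    ])
    order = np.argsort(-balance)  # descending PNS - SNS
    relabel = {int(old): new + 1 for new, old in enumerate(order)}
    labels = np.array([relabel[int(c)] for c in raw])
    sil = float(silhouette_score(indices, raw)) if len(set(raw)) > 1 else -1.0
    info = {"silhouette": sil, "low_separation": sil < 0.5}
    if info["low_separation"]:
        warnings.warn(f"low cluster separation (silhouette {sil:.2f})", stacklevel=2)
    return labels, info


def elevated_bp(mean_sys: float, mean_dia: float) -> bool:
    """Resting blood pressure elevation rule: SYS > 140 or DIA > 90 mmHg."""
    return mean_sys > 140.0 or mean_dia > 90.0
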