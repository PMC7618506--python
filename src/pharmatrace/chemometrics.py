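"""DART-MS spectrum preprocessing and discriminant feature selection.

The chain is: blank-strip background subtraction -> per-measurement
relative-intensity normalization (base peak = 100 %) -> aggregation of
peaks closer than 1 m/z -> cross-measurement alignment into a feature
matrix at 15 mmu tolerance -> univariate pre-selection (ANOVA between the
extreme-mean tablet groups on abundant features) or two-class Fisher-ratio
ranking of the most discriminant masses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import SpectrumSet

__all__ = [
    "FeatureMatrix",
    "subtract_background",
    "normalize_relative",
    "aggregate_masses",
    "align_features",
    "anova_select",
    "fisher_ratio_select",
]


@dataclass
class FeatureMatrix:
    """Measurement x feature relative-intensity matrix.

    Columns are consensus m/z values (Daltons, floats); ``meta`` maps each
    measurement to its tablet and group.
    """

    intensities: pd.DataFrame  # measurements x features (columns: float m/z)
    meta: pd.DataFrame  # index measurement_id; columns tablet_id, group

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.meta.index):
            raise ValueError("feature matrix and meta must share measurement index")

    @property
    def features(self) -> list[float]:
        return list(self.intensities.columns)

    def groups(self) -> pd.Series:
        return self.meta["group"]


def _peak_frame(spectra: SpectrumSet) -> pd.DataFrame:
    return spectra.peaks.copy()


def subtract_background(
    spectra: SpectrumSet, blanks: SpectrumSet, mz_tol: float = 0.015
) -> SpectrumSet:
    """Subtract the mean blank intensity from matching sample peaks.

    A sample peak is matched to the nearest blank consensus mass within
    ``mz_tol``; the blank's mean intensity (over blank measurements) is
    subtracted and peaks that drop to zero or below are removed.
    """
    if mz_tol <= 0:
        raise ValueError("mz_tol must be > 0")
    bl = _peak_frame(blanks)
    if len(bl) == 0 or bl["measurement_id"].nunique() == 0:
        raise ValueError("at least one blank measurement is required")
    n_blank = bl["measurement_id"].nunique()
    # consensus blank masses: cluster blank peaks within mz_tol, mean intensity
    blank_agg = _cluster_peaks(bl[["mz", "intensity"]].to_numpy(), mz_tol)
    blank_mz = blank_agg[:, 0]
    blank_mean = blank_agg[:, 2] / n_blank  # summed intensity / #blank measurements

    df = _peak_frame(spectra)
    if len(df) == 0:
        return SpectrumSet(df)
    mz = df["mz"].to_numpy(float)
    pos = np.searchsorted(blank_mz, mz)
    best = np.full(len(mz), -1)
    best_d = np.full(len(mz), np.inf)
    for cand in (np.clip(pos - 1, 0, len(blank_mz) - 1), np.clip(pos, 0, len(blank_mz) - 1)):
        d = np.abs(blank_mz[cand] - mz)
        better = d < best_d
        best[better] = cand[better]
        best_d[better] = d[better]
    matched = best_d <= mz_tol
    new_int = df["intensity"].to_numpy(float).copy()
    new_int[matched] -= blank_mean[best[matched]]
    df = df.assign(intensity=new_int)
    df = df[df["intensity"] > 0].reset_index(drop=True)
    return SpectrumSet(df)


def normalize_relative(spectra: SpectrumSet) -> SpectrumSet:
    """Scale each measurement so its base peak has relative intensity 100."""
    df = _peak_frame(spectra)
    if len(df) == 0:
        raise ValueError("empty spectrum set")
    out = []
    for mid, grp in df.groupby("measurement_id", sort=False):
        top = grp["intensity"].max()
        if top <= 0:
            raise ValueError(f"measurement {mid!r} has no positive peak")
        g = grp.copy()
        g["intensity"] = 100.0 * g["intensity"] / top
        out.append(g)
    return SpectrumSet(pd.concat(out, ignore_index=True))


def _cluster_peaks(mz_int: np.ndarray, window: float, linkage: str = "gap") -> np.ndarray:
    """Cluster (mz, [extra...], intensity-last?) rows along m/z.

    Input columns: mz, intensity[, ...].  Returns array of
    (weighted-mean mz, n_peaks, summed intensity) per cluster, mz ascending.
    ``linkage='gap'`` merges consecutive peaks whose gap is < window
    (single linkage); ``linkage='centroid'`` starts a new cluster when a
    peak is further than window from the running intensity-weighted
    centroid (greedy, used for cross-measurement alignment).
    """
    if len(mz_int) == 0:
        return np.zeros((0, 3))
    order = np.argsort(mz_int[:, 0], kind="stable")
    mz = mz_int[order, 0]
    inten = mz_int[order, 1]
    clusters = []
    start = 0
    if linkage == "gap":
        for i in range(1, len(mz) + 1):
            if i == len(mz) or mz[i] - mz[i - 1] >= window:
                clusters.append((start, i))
                start = i
    else:  # centroid
        centroid = mz[0]
        wsum = inten[0] if inten[0] > 0 else 1e-30
        msum = centroid * wsum
        for i in range(1, len(mz) + 1):
            if i == len(mz) or abs(mz[i] - msum / wsum) > window:
                clusters.append((start, i))
                if i < len(mz):
                    start = i
                    wsum = inten[i] if inten[i] > 0 else 1e-30
                    msum = mz[i] * wsum
            else:
                w = inten[i] if inten[i] > 0 else 1e-30
                wsum += w
                msum += mz[i] * w
    out = np.zeros((len(clusters), 3))
    for k, (a, b) in enumerate(clusters):
        w = inten[a:b]
        tot = w.sum()
        if tot > 0:
            out[k, 0] = (mz[a:b] * w).sum() / tot
        else:
            out[k, 0] = mz[a:b].mean()
        out[k, 1] = b - a
        out[k, 2] = tot
    return out


def aggregate_masses(spectra: SpectrumSet, window: float = 1.0) -> SpectrumSet:
    """Merge peaks within a measurement differing by less than ``window`` m/z.

    Single-linkage along the mass axis: consecutive peaks with gap < window
    join one cluster.  The merged peak carries the summed intensity and the
    intensity-weighted mean m/z, so total intensity is conserved.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    df = _peak_frame(spectra)
    out = []
    for (mid,), grp in df.groupby(["measurement_id"], sort=False):
        agg = _cluster_peaks(grp[["mz", "intensity"]].to_numpy(float), window, linkage="gap")
        first = grp.iloc[0]
        out.append(
            pd.DataFrame(
                {
                    "measurement_id": mid,
                    "tablet_id": first["tablet_id"],
                    "group": first["group"],
                    "mz": agg[:, 0],
                    "intensity": agg[:, 2],
                    "blank": bool(first["blank"]),
                }
            )
        )
    if not out:
        return SpectrumSet(df)
    return SpectrumSet(pd.concat(out, ignore_index=True))


def align_features(spectra: SpectrumSet, mz_tol: float = 0.015) -> FeatureMatrix:
    """Align peaks across measurements into a measurement x feature matrix.

    All peaks are pooled, sorted by m/z and greedily clustered: a peak joins
    the current feature while it stays within ``mz_tol`` of the running
    intensity-weighted centroid, otherwise it opens a new feature.  Every
    peak maps to exactly one feature; absent features get intensity 0.
    """
    if mz_tol <= 0:
        raise ValueError("mz_tol must be > 0")
    df = _peak_frame(spectra)
    if len(df) == 0:
        raise ValueError("empty spectrum set")
    order = np.argsort(df["mz"].to_numpy(float), kind="stable")
    df = df.iloc[order].reset_index(drop=True)
    mz = df["mz"].to_numpy(float)
    inten = df["intensity"].to_numpy(float)
    labels = np.zeros(len(df), dtype=int)
    centroids = []
    wsum = inten[0] if inten[0] > 0 else 1e-30
    msum = mz[0] * wsum
    cur = 0
    for i in range(1, len(df)):
        if abs(mz[i] - msum / wsum) > mz_tol:
            centroids.append(msum / wsum)
            cur += 1
            wsum = inten[i] if inten[i] > 0 else 1e-30
            msum = mz[i] * wsum
        else:
            w = inten[i] if inten[i] > 0 else 1e-30
            wsum += w
            msum += mz[i] * w
        labels[i] = cur
    centroids.append(msum / wsum)

    mids = list(dict.fromkeys(df["measurement_id"]))
    mat = pd.DataFrame(0.0, index=mids, columns=np.round(centroids, 6))
    for (mid, lab), grp in df.groupby(["measurement_id", labels]):
        mat.loc[mid, np.round(centroids[lab], 6)] += grp["intensity"].sum()
    meta = (
        df.drop_duplicates("measurement_id")
        .set_index("measurement_id")[["tablet_id", "group"]]
        .loc[mids]
    )
    return FeatureMatrix(intensities=mat, meta=meta)


def anova_select(
    features: FeatureMatrix,
    groups=None,
    alpha: float = 0.05,
    min_intensity: float = 10.0,
) -> list[float]:
    """Pre-select abundant group-differential features.

    Candidates are features whose maximum group-mean relative intensity
    exceeds ``min_intensity`` (percent).  For each candidate a one-way ANOVA
    compares the two tablet groups with the largest and smallest mean
    intensity; the feature is kept when p < ``alpha``.  Groups with a single
    measurement are excluded from the extremes with a warning.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not 0 <= min_intensity <= 100:
        raise ValueError("min_intensity must lie in [0, 100]")
    if groups is None:
        groups = features.groups()
    groups = pd.Series(np.asarray(groups), index=features.intensities.index)
    if groups.nunique() < 2:
        raise ValueError("need >= 2 groups")
    sizes = groups.value_counts()
    small = list(sizes.index[sizes < 2])
    if small:
        warnings.warn(f"group(s) with one measurement excluded from extremes: {small}",
                      stacklevel=2)
    usable = [g for g in sizes.index if g not in small]
    if len(usable) < 2:
        raise ValueError("fewer than 2 testable groups")
    gm = features.intensities.groupby(groups).mean()
    selected = []
    for feat in features.intensities.columns:
        col_means = gm[feat]
        if col_means.max() <= min_intensity:
            continue
        mu = col_means.loc[usable]
        g_hi, g_lo = mu.idxmax(), mu.idxmin()
        if g_hi == g_lo:
            continue
        a = features.intensities.loc[groups == g_hi, feat]
        b = features.intensities.loc[groups == g_lo, feat]
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            continue  # flat between the extreme groups
        _, p = stats.f_oneway(a, b)
        if p < alpha:
            selected.append(feat)
    return selected


def fisher_ratio_select(
    features: FeatureMatrix,
    two_class_labels,
    k: int = 95,
    min_fold: float = 1.0,
) -> list[float]:
    """Rank features by the two-class Fisher ratio and return the top ``k``.

    FR = (mean_A - mean_B)^2 / (var_A + var_B) with a variance floor of
    1e-12; eligibility requires fold change > ``min_fold``, where fold
    change is max/min of the class means after offsetting both by one
    intensity unit (so all-zero classes are well defined).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = pd.Series(np.asarray(two_class_labels), index=features.intensities.index)
    classes = list(pd.unique(labels))
    if len(classes) != 2:
        raise ValueError(f"exactly 2 classes required, got {classes}")
    a = features.intensities[labels == classes[0]]
    b = features.intensities[labels == classes[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("a class has no measurements")
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    var_a = a.var(axis=0, ddof=1) if len(a) > 1 else pd.Series(0.0, index=mean_a.index)
    var_b = b.var(axis=0, ddof=1) if len(b) > 1 else pd.Series(0.0, index=mean_b.index)
    fr = (mean_a - mean_b) ** 2 / np.maximum(var_a + var_b, 1e-12)
    off_a, off_b = mean_a + 1.0, mean_b + 1.0
    fold = np.maximum(off_a, off_b) / np.minimum(off_a, off_b)
    eligible = fr.index[fold > min_fold]
    ranked = fr.loc[eligible].sort_values(ascending=False, kind="stable")
    return list(ranked.index[:k])
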