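"""Extracted-ion chromatograms, peak picking and feature extraction.

The first step of the screen extracts a narrow ion trace of the
characteristic backbone fragment from the all-ions chromatogram; peaks in
that trace mark compounds that contain the drug core.  Feature extraction
collapses connected (rt, dt, m/z) signal regions to apex features and
applies the standard screening filters: minimum ion intensity, retention
time window and maximum charge state (inferred from isotopologue spacing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from .chem import ISOTOPE_SPACING
from .iodata import Feature, FrameTable

__all__ = [
    "EIC",
    "ChromPeak",
    "DriftSpectrum",
    "extract_eic",
    "detect_chrom_peaks",
    "drift_spectrum",
    "detect_features",
]


@dataclass
class EIC:
    """Extracted-ion chromatogram: summed intensity vs retention time."""

    target_mz: float
    tol_ppm: float
    rt: np.ndarray
    intensity: np.ndarray

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())


@dataclass
class ChromPeak:
    """One chromatographic peak with apex, bounds, height and area."""

    rt_apex: float
    rt_start: float
    rt_end: float
    height: float
    area: float


@dataclass
class DriftSpectrum:
    """Summed intensity vs drift time over a retention-time window."""

    rt_window: Tuple[float, float]
    dt: np.ndarray
    intensity: np.ndarray


def extract_eic(frames: FrameTable, target_mz: float, tol_ppm: float = 20.0) -> EIC:
    """Sum intensities of records within ``tol_ppm`` of ``target_mz`` per rt.

    Every distinct retention time of the input contributes a point; times
    with no in-window record contribute zero, so co-acquired traces share a
    common axis.  An empty frame table yields an empty (not erroneous) EIC.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    df = frames.df
    if df.empty:
        return EIC(target_mz, tol_ppm, np.array([]), np.array([]))
    rts = np.unique(df["rt_min"].to_numpy())
    window = tol_ppm * 1e-6 * target_mz
    mask = np.abs(df["mz"].to_numpy() - target_mz) <= window
    sums = (
        df.loc[mask].groupby("rt_min")["intensity"].sum()
        if mask.any()
        else None
    )
    intensity = np.zeros_like(rts, dtype=float)
    if sums is not None:
        idx = np.searchsorted(rts, sums.index.to_numpy())
        intensity[idx] = sums.to_numpy()
    return EIC(target_mz, tol_ppm, rts, intensity)


def _moving_minimum(y: np.ndarray, window: int) -> np.ndarray:
    half = max(1, window // 2)
    out = np.empty_like(y)
    for i in range(len(y)):
        out[i] = y[max(0, i - half) : i + half + 1].min()
    return out


def detect_chrom_peaks(
    eic: EIC,
    min_height: float,
    min_points: int = 3,
    baseline: str = "zero",
    baseline_window: int = 51,
) -> List[ChromPeak]:
    """Pick chromatographic peaks above ``min_height`` in an ion trace.

    A peak is a local maximum with at least ``min_points`` contiguous
    above-baseline samples; its bounds are the surrounding minima (or the
    edge of the above-baseline run).  The baseline is zero by default; a
    moving-minimum baseline is available for noisy traces.
    """
    if min_height <= 0:
        raise ValueError("min_height must be positive")
    if min_points < 3:
        raise ValueError("min_points must be >= 3")
    if len(eic.rt) == 0:
        return []
    y = eic.intensity.astype(float)
    if baseline == "moving_min":
        y = y - _moving_minimum(y, baseline_window)
    elif baseline != "zero":
        raise ValueError(f"unknown baseline mode {baseline!r}")
    apex_idx, _ = find_peaks(y, height=min_height)
    peaks: List[ChromPeak] = []
    above = y > 0
    for idx in apex_idx:
        # expand to the surrounding minima within the above-baseline run
        left = idx
        while left > 0 and above[left - 1] and y[left - 1] <= y[left]:
            left -= 1
        right = idx
        while right < len(y) - 1 and above[right + 1] and y[right + 1] <= y[right]:
            right += 1
        if np.count_nonzero(above[left : right + 1]) < min_points:
            continue
        area = float(np.trapezoid(y[left : right + 1], eic.rt[left : right + 1]))
        peaks.append(
            ChromPeak(
                rt_apex=float(eic.rt[idx]),
                rt_start=float(eic.rt[left]),
                rt_end=float(eic.rt[right]),
                height=float(y[idx]),
                area=area,
            )
        )
    peaks.sort(key=lambda p: p.rt_apex)
    return peaks


def drift_spectrum(
    frames: FrameTable,
    rt_window: Tuple[float, float],
    mz_window: Optional[Tuple[float, float]] = None,
) -> DriftSpectrum:
    """Sum intensities per drift-time bin over a retention-time window."""
    lo, hi = rt_window
    if hi < lo:
        raise ValueError("rt_window must be ordered (lo, hi)")
    df = frames.df
    mask = (df["rt_min"] >= lo) & (df["rt_min"] <= hi)
    if mz_window is not None:
        mask &= (df["mz"] >= mz_window[0]) & (df["mz"] <= mz_window[1])
    sub = df.loc[mask]
    if sub.empty:
        return DriftSpectrum(rt_window, np.array([]), np.array([]))
    sums = sub.groupby("dt_ms")["intensity"].sum()
    return DriftSpectrum(rt_window, sums.index.to_numpy(), sums.to_numpy())


def _split_on_gaps(values: np.ndarray, order: np.ndarray, gap) -> List[np.ndarray]:
    """Split pre-sorted indices wherever consecutive values differ by > gap."""
    if len(order) == 0:
        return []
    sorted_vals = values[order]
    gaps = np.diff(sorted_vals)
    if callable(gap):
        breaks = np.nonzero(gaps > gap(sorted_vals[:-1]))[0]
    else:
        breaks = np.nonzero(gaps > gap)[0]
    return np.split(order, breaks + 1)


def _cluster_records(
    rt: np.ndarray,
    dt: np.ndarray,
    mz: np.ndarray,
    mz_tol_ppm: float,
    dt_gap_ms: float,
    rt_gap_min: float,
) -> List[np.ndarray]:
    """Connected (mz, dt, rt) regions by successive gap splitting."""
    clusters: List[np.ndarray] = []
    order = np.argsort(mz, kind="mergesort")
    for mz_group in _split_on_gaps(mz, order, lambda v: mz_tol_ppm * 1e-6 * v):
        dt_order = mz_group[np.argsort(dt[mz_group], kind="mergesort")]
        for dt_group in _split_on_gaps(dt, dt_order, dt_gap_ms):
            rt_order = dt_group[np.argsort(rt[dt_group], kind="mergesort")]
            clusters.extend(_split_on_gaps(rt, rt_order, rt_gap_min))
    return clusters


def _infer_charges(
    features: List[Feature],
    max_probe_charge: int,
    mz_tol: float = 0.005,
    rt_tol: float = 0.06,
    dt_tol: float = 0.2,
) -> None:
    """Assign charges from isotopologue spacing (13C spacing / z).

    For each feature the list is searched for a weaker companion at
    ``mz + spacing/z`` co-located in rt and dt; the largest matching z wins.
    Features without isotopologues keep charge 1 (all singly protonated in
    positive-mode screening).
    """
    mzs = np.array([f.mz for f in features])
    order = np.argsort(mzs)
    sorted_mzs = mzs[order]
    for i, feat in enumerate(features):
        for z in range(max_probe_charge, 0, -1):
            target = feat.mz + ISOTOPE_SPACING / z
            j0 = np.searchsorted(sorted_mzs, target - mz_tol)
            j1 = np.searchsorted(sorted_mzs, target + mz_tol)
            for j in order[j0:j1]:
                other = features[j]
                if other is feat:
                    continue
                if (
                    abs(other.rt_apex - feat.rt_apex) <= rt_tol
                    and abs(other.dt_apex - feat.dt_apex) <= dt_tol
                    and other.intensity < feat.intensity
                ):
                    feat.charge = z
                    other.charge = z
                    break
            if feat.charge == z and z > 1:
                break


def detect_features(
    frames: FrameTable,
    min_intensity: float = 100.0,
    rt_range: Tuple[float, float] = (2.0, 10.0),
    max_charge: int = 3,
    mz_tol_ppm: float = 20.0,
    dt_gap_ms: float = 0.3,
    rt_gap_min: float = 0.05,
) -> List[Feature]:
    """Collapse connected signal regions to apex features and filter them.

    Records are clustered by m/z (ppm gap), then drift time, then contiguous
    retention time; each cluster becomes one feature with intensity-weighted
    m/z and drift time centroids, the rt of its most intense record as apex,
    and that record's intensity as feature intensity.  Features below
    ``min_intensity``, outside ``rt_range``, or with inferred charge above
    ``max_charge`` are removed.
    """
    if min_intensity <= 0 or max_charge < 1:
        raise ValueError("thresholds must be positive")
    df = frames.df
    if df.empty:
        return []
    rt = df["rt_min"].to_numpy()
    dt = df["dt_ms"].to_numpy()
    mz = df["mz"].to_numpy()
    inten = df["intensity"].to_numpy()
    features: List[Feature] = []
    for cluster in _cluster_records(rt, dt, mz, mz_tol_ppm, dt_gap_ms, rt_gap_min):
        w = inten[cluster]
        total = w.sum()
        if total <= 0:
            continue
        apex = cluster[np.argmax(w)]
        features.append(
            Feature(
                rt_apex=float(rt[apex]),
                dt_apex=float(np.average(dt[cluster], weights=w)),
                mz=float(np.average(mz[cluster], weights=w)),
                intensity=float(w.max()),
            )
        )
    _infer_charges(features, max_probe_charge=max_charge + 1)
    lo, hi = rt_range
    kept = [
        f
        for f in features
        if f.intensity >= min_intensity and lo <= f.rt_apex <= hi and f.charge <= max_charge
    ]
    kept.sort(key=lambda f: (f.mz, f.rt_apex))
    return kept
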