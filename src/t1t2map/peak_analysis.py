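"""Detection and quantification of relaxation reservoirs on a spectrum map.

Local maxima above a relative threshold are merged when closer than a
minimum cell separation (the larger apex wins), every above-threshold cell
is assigned to an apex by steepest ascent, and each region is summarized
by a peak coordinate in (log T1, log T2).  The default coordinate is the
apex refined by parabolic sub-cell interpolation in log space, which is
robust to the shoulder skew that neighbouring reservoirs imprint on
amplitude-weighted centroids; full-region and half-max centroids remain
available as alternatives.

The R/S/T labelling follows the blood-microenvironment convention: R is
the dominant slow (bulk-water) component with the largest T2, T the
fastest (protein-bound) component with the smallest T2, S the
intermediate hydration layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .core_model import a_ratio
from .laplace_inversion import SpectrumMap

__all__ = [
    "Peak",
    "PeakReport",
    "detect_peaks",
    "tail_extent",
    "classify_peaks_rst",
]


@dataclass(frozen=True)
class Peak:
    """One detected relaxation reservoir."""

    t1_ms: float
    t2_ms: float
    a_ratio: float
    volume: float
    apex_intensity: float
    n_cells: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("peak volume must be positive")
        if abs(self.a_ratio - self.t1_ms / self.t2_ms) > 1e-9 * self.a_ratio:
            raise ValueError("a_ratio inconsistent with centroid coordinates")


@dataclass(frozen=True)
class PeakReport:
    """Peaks (descending volume) plus tail metrics of one spectrum."""

    peaks: tuple[Peak, ...]
    tail_extent_decades: float
    diagonal_min_aratio: float | None

    def by_label(self, label: str) -> Peak | None:
        for p in self.peaks:
            if p.label == label:
                return p
        return None


def _local_maxima(F: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    mx = ndimage.maximum_filter(F, size=3, mode="constant", cval=-np.inf)
    cand = np.argwhere((F == mx) & (F > threshold))
    # descending intensity; ties broken by grid position for determinism
    return sorted(map(tuple, cand), key=lambda pq: (-F[pq], pq))


def _merge_apexes(apexes: list[tuple[int, int]], F: np.ndarray,
                  min_sep: int) -> list[tuple[int, int]]:
    kept: list[tuple[int, int]] = []
    for a in apexes:  # already sorted by descending intensity
        if all(max(abs(a[0] - b[0]), abs(a[1] - b[1])) >= min_sep
               for b in kept):
            kept.append(a)
    return kept


def _segment(F: np.ndarray, apexes: list[tuple[int, int]],
             threshold: float) -> np.ndarray:
    """Assign above-threshold cells to apexes by steepest ascent.

    Returns an integer label array (-1 = unassigned/below threshold).
    """
    n1, n2 = F.shape
    labels = -np.ones(F.shape, dtype=int)
    apex_index = {a: i for i, a in enumerate(apexes)}
    for a, i in apex_index.items():
        labels[a] = i

    def climb(p: int, q: int) -> int:
        path: list[tuple[int, int]] = []
        while True:
            if labels[p, q] >= 0:
                lab = labels[p, q]
                break
            if (p, q) in apex_index:
                lab = apex_index[(p, q)]
                break
            path.append((p, q))
            window = F[max(p - 1, 0):p + 2, max(q - 1, 0):q + 2]
            dp, dq = np.unravel_index(int(np.argmax(window)), window.shape)
            np_, nq = max(p - 1, 0) + dp, max(q - 1, 0) + dq
            if F[np_, nq] <= F[p, q]:
                # local max that was merged away: attach to nearest apex
                lab = min(
                    range(len(apexes)),
                    key=lambda i: ((apexes[i][0] - p) ** 2
                                   + (apexes[i][1] - q) ** 2),
                )
                break
            p, q = np_, nq
        for c in path:
            labels[c] = lab
        return lab

    for p in range(n1):
        for q in range(n2):
            if F[p, q] > threshold and labels[p, q] < 0:
                climb(p, q)
    return labels


def _refined_apex_log(F: np.ndarray, p: int, q: int,
                      lg1: np.ndarray, lg2: np.ndarray) -> tuple[float, float]:
    """Parabolic sub-cell refinement of an apex in log coordinates."""
    x1, x2 = lg1[p], lg2[q]
    if 0 < p < F.shape[0] - 1:
        a, b, c = F[p - 1, q], F[p, q], F[p + 1, q]
        den = a - 2 * b + c
        if den < 0:
            x1 += 0.5 * (a - c) / den * (lg1[1] - lg1[0])
    if 0 < q < F.shape[1] - 1:
        a, b, c = F[p, q - 1], F[p, q], F[p, q + 1]
        den = a - 2 * b + c
        if den < 0:
            x2 += 0.5 * (a - c) / den * (lg2[1] - lg2[0])
    return x1, x2


def detect_peaks(spectrum: SpectrumMap, rel_threshold: float = 0.02,
                 min_separation_cells: int = 3, min_region_cells: int = 2,
                 centroid: str = "apex",
                 min_a_ratio: float = 0.5) -> PeakReport:
    """Detect relaxation reservoirs on a spectrum map.

    Parameters
    ----------
    spectrum
        Non-negative T1-T2 map.
    rel_threshold
        Intensity floor as a fraction of the global maximum (default 0.02:
        keeps small protein-bound peaks, suppresses inversion ripple).
    min_separation_cells
        Apexes closer than this (Chebyshev distance) merge into the larger.
    min_region_cells
        Regions smaller than this are dropped as inversion artifacts.
    min_a_ratio
        Peaks with T1/T2 below this are dropped: relaxation physics
        requires T1 >= T2, so regions far below the log-log diagonal are
        inversion artifacts (0.5 leaves margin for blur around genuine
        diagonal peaks).
    centroid
        ``"apex"`` (default): apex position with parabolic sub-cell
        refinement; ``"halfmax"``: amplitude-weighted centroid over region
        cells >= 0.5 x region apex, blended with the refined apex;
        ``"region"``: centroid over all region cells.
    """
    if not 0 < rel_threshold <= 1:
        raise ValueError("rel_threshold must be in (0, 1]")
    if centroid not in ("halfmax", "region", "apex"):
        raise ValueError(f"unknown centroid mode {centroid!r}")
    F = spectrum.intensity
    if not np.any(F > 0):
        return PeakReport(peaks=(), tail_extent_decades=0.0,
                          diagonal_min_aratio=None)
    threshold = rel_threshold * float(F.max())
    # rel_threshold == 1 keeps exactly the global maximum
    if rel_threshold == 1.0:
        threshold = float(F.max()) * (1 - 1e-12)
    apexes = _merge_apexes(_local_maxima(F, threshold), F,
                           min_separation_cells)
    labels = _segment(F, apexes, threshold)
    lg1 = np.log10(spectrum.grid.t1_grid_ms)
    lg2 = np.log10(spectrum.grid.t2_grid_ms)
    peaks: list[Peak] = []
    for i, (p, q) in enumerate(apexes):
        cells = np.argwhere(labels == i)
        if len(cells) < min_region_cells:
            continue
        volume = float(F[cells[:, 0], cells[:, 1]].sum())
        apex_val = float(F[p, q])
        if centroid == "apex":
            x1, x2 = _refined_apex_log(F, p, q, lg1, lg2)
        else:
            if centroid == "halfmax":
                keep = F[cells[:, 0], cells[:, 1]] >= 0.5 * apex_val
                sel = cells[keep]
            else:
                sel = cells
            w = F[sel[:, 0], sel[:, 1]]
            x1 = float(np.sum(w * lg1[sel[:, 0]]) / w.sum())
            x2 = float(np.sum(w * lg2[sel[:, 1]]) / w.sum())
            if centroid == "halfmax":
                # blend with the refined apex: half-max cells centre the
                # blob, the parabola recovers the sub-cell apex offset
                a1r, a2r = _refined_apex_log(F, p, q, lg1, lg2)
                x1 = 0.5 * (x1 + a1r)
                x2 = 0.5 * (x2 + a2r)
        t1_ms, t2_ms = 10.0 ** x1, 10.0 ** x2
        if t1_ms / t2_ms < min_a_ratio:
            continue
        peaks.append(Peak(
            t1_ms=t1_ms, t2_ms=t2_ms, a_ratio=a_ratio(t1_ms, t2_ms),
            volume=volume, apex_intensity=apex_val, n_cells=int(len(cells)),
        ))
    peaks.sort(key=lambda pk: (-pk.volume, -pk.t2_ms))
    extent = tail_extent(spectrum, rel_threshold=rel_threshold)
    min_ar = min((p.a_ratio for p in peaks), default=None)
    return PeakReport(peaks=tuple(peaks), tail_extent_decades=extent,
                      diagonal_min_aratio=min_ar)


def tail_extent(spectrum: SpectrumMap,
                t2_window_ms: tuple[float, float] = (0.3, 3.0),
                rel_threshold: float = 0.02) -> float:
    """T1 span (decades) of the protein-bound band.

    Within the T2 window (default 0.3-3 ms, the protein-bound band),
    returns ``log10(T1_hi / T1_lo)`` over the contiguous run of T1 rows
    exceeding ``rel_threshold`` x the band maximum that contains the band
    maximum itself (the tail is a connected stretch originating at the
    T-peak; disconnected ripple or grid-edge artifacts do not count).
    An oxidized sample stretches across more than a decade (the
    paramagnetic relaxation tail); an oxygenated one stays compact.
    """
    lo, hi = t2_window_ms
    if lo >= hi:
        raise ValueError("t2 window must be increasing")
    t2 = spectrum.grid.t2_grid_ms
    cols = np.where((t2 >= lo) & (t2 <= hi))[0]
    if cols.size == 0:
        return 0.0
    F = spectrum.intensity
    band = F[:, cols]
    row_max = band.max(axis=1)
    if float(row_max.max()) <= 0:
        return 0.0
    # Anchor on rows whose intensity is concentrated inside the window:
    # rows dominated by the shoulder of a higher-T2 reservoir (their
    # full-row maximum lies outside the window) must not set the scale.
    row_argmax = F.argmax(axis=1)
    concentrated = ((row_max > 0)
                    & (row_argmax >= cols[0]) & (row_argmax <= cols[-1]))
    anchored = row_max.copy()
    if np.any(concentrated):
        anchored[~concentrated] = 0.0
    apex_row = int(np.argmax(anchored))
    bmax = float(row_max[apex_row])
    above = row_max > rel_threshold * bmax
    row_lo = apex_row
    while row_lo > 0 and above[row_lo - 1]:
        row_lo -= 1
    row_hi = apex_row
    while row_hi < len(above) - 1 and above[row_hi + 1]:
        row_hi += 1
    if row_hi == row_lo:
        return 0.0
    t1 = spectrum.grid.t1_grid_ms
    return float(math.log10(t1[row_hi] / t1[row_lo]))


def classify_peaks_rst(report: PeakReport) -> PeakReport:
    """Label peaks as R (bulk water), S (hydration layer), T (protein-bound).

    R is the largest-volume peak among those with the largest T2 (ties on
    volume break toward larger T2); T has the smallest T2 of the rest; any
    remaining peak of the top three is S.  With fewer than three peaks the
    available labels are assigned in the same order and extra peaks stay
    unlabelled.
    """
    if not report.peaks:
        raise ValueError("cannot label an empty peak report")
    order = sorted(report.peaks, key=lambda p: (-p.volume, -p.t2_ms))
    r_peak = order[0]
    rest = [p for p in order if p is not r_peak]
    t_peak = min(rest, key=lambda p: (p.t2_ms, -p.volume)) if rest else None
    s_peak = None
    middle = [p for p in rest if p is not t_peak]
    if middle:
        s_peak = max(middle, key=lambda p: (p.volume, p.t2_ms))
    labelled = []
    for p in report.peaks:
        if p is r_peak:
            labelled.append(replace(p, label="R"))
        elif t_peak is not None and p is t_peak:
            labelled.append(replace(p, label="T"))
        elif s_peak is not None and p is s_peak:
            labelled.append(replace(p, label="S"))
        else:
            labelled.append(p)
    return PeakReport(peaks=tuple(labelled),
                      tail_extent_decades=report.tail_extent_decades,
                      diagonal_min_aratio=report.diagonal_min_aratio)
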