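"""Region-restricted PCA and second-derivative peak detection/assignment.

PCA is computed on column-mean-centered data by singular value
decomposition, with the sign of each component fixed so the channel of
maximum absolute loading is positive. Peak detection finds local minima of
second-derivative spectra (absorption bands are minima there), refines each
position by three-point parabolic interpolation, and assigns positions
against the published collagen / chondroitin-4-sulfate band table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    DataError,
    ParameterError,
    RegionError,
    Spectrum,
    SpectrumSet,
    WavenumberAxis,
    crop_region,
)


# --------------------------------------------------------------------------- #
# reference band table (second-derivative peak assignments)
# --------------------------------------------------------------------------- #

#: Published band assignments for pure collagen type I and C-4-S second
#: derivative spectra. 1060 and 1031 cm^-1 carry their ambiguous dual
#: readings verbatim rather than a resolved choice.
REFERENCE_ASSIGNMENTS: tuple[tuple[float, str], ...] = (
    (1660.0, "Amide I in collagen type I"),
    (1554.0, "Amide II in collagen type I"),
    (1456.0, "CH2 asymmetric bending vibration in collagen type I"),
    (1376.0, "CH3 symmetric bending vibration of GAGs"),
    (1338.0, "CH2 side chain vibration of collagen type I"),
    (1286.0, "Collagen amide III with CH2 wagging (glycine backbone, proline)"),
    (1236.0, "Collagen amide III (C-N stretch, N-H bend, CH2 wag)"),
    (1228.0, "O-SO3- asymmetric stretching vibration in GAGs"),
    (1204.0, "Collagen amide III with CH2 wagging (glycine backbone, proline)"),
    (1161.0, "C-O stretching vibration of carbohydrate residues"),
    (1134.0, "C-O-S asymmetric stretching of GAGs"),
    (1082.0, "C-O stretching of carbohydrate residues in collagen and PGs"),
    (1072.0, "Sugar ring of GAGs"),
    (1060.0, "C-O stretching of carbohydrate residues in collagen and PGs / "
             "SO3- symmetric stretching of sulfated GAGs"),
    (1031.0, "C-O stretching of carbohydrate residues in collagen and PGs"),
    (989.0, "Not assigned (GAG marker)"),
    (924.0, "Sulfate-carrying proteoglycan aggrecan"),
)

#: The three second-derivative minima treated as reliable GAG indicators.
GAG_MARKERS: tuple[float, ...] = (1134.0, 989.0, 924.0)

#: Detection windows around each GAG marker, in cm^-1.
GAG_MARKER_WINDOWS: dict[float, tuple[float, float]] = {
    1134.0: (1120.0, 1150.0),
    989.0: (974.0, 1004.0),
    924.0: (910.0, 940.0),
}


# --------------------------------------------------------------------------- #
# PCA
# --------------------------------------------------------------------------- #

@dataclass
class PCAResult:
    """Scores, loadings and explained variance of a region-restricted PCA."""

    scores: np.ndarray               # n_spectra x k
    loadings: np.ndarray             # k x n_channels
    explained_variance_pct: np.ndarray
    region: tuple[float, float]
    centering: np.ndarray            # channel means
    axis: WavenumberAxis
    ids: pd.Index

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=self.ids,
            columns=[f"PC{i + 1}" for i in range(self.scores.shape[1])],
        )


def pca_fit(sset: SpectrumSet, region: tuple[float, float] | None = None,
            k: int = 2) -> PCAResult:
    """Column-mean-centered PCA (via SVD) of the region-restricted spectra.

    Deterministic: the sign of each component is fixed by making the channel
    of maximum absolute loading positive. ``explained_variance_pct`` is each
    component's share of the total centered variance, in percent.
    """
    if sset.n < 2:
        raise DataError(f"PCA needs at least 2 spectra, got {sset.n}")
    work = crop_region(sset, *region) if region is not None else sset
    kmax = min(work.n - 1, work.axis.n)
    if not 1 <= k <= kmax:
        raise ParameterError(f"k={k} outside valid range [1, {kmax}]")

    mean = work.matrix.mean(axis=0)
    X = work.matrix - mean
    total = float(np.sum(X**2))
    if total <= 0.0:
        raise DataError("zero-variance data: PCA is degenerate")

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: max |loading| channel positive, per component
    for i in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]

    scores = (U * s)[:, :k]
    loadings = Vt[:k]
    pct = 100.0 * (s[:k] ** 2) / total
    region_out = (work.axis.lo, work.axis.hi) if region is None else tuple(region)
    return PCAResult(scores, loadings, pct, region_out, mean, work.axis,
                     work.labels.index)


# --------------------------------------------------------------------------- #
# peak detection
# --------------------------------------------------------------------------- #

def _refine_parabolic(nu: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through the three channels around index ``i``.

    Returns (position, value); falls back to the grid point at region edges
    or where the three points are (numerically) collinear.
    """
    if i == 0 or i == len(y) - 1:
        return float(nu[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if abs(denom) < 1e-300:
        return float(nu[i]), float(y1)
    h = nu[i + 1] - nu[i]  # signed step (negative on a descending axis)
    delta = 0.5 * (y0 - y2) / denom
    pos = float(nu[i] + delta * h)
    val = float(y1 - 0.25 * (y0 - y2) * delta)
    return pos, val


def detect_minima(s: Spectrum, region: tuple[float, float] | None = None,
                  prominence_frac: float = 0.05) -> pd.DataFrame:
    """Local minima of a second-derivative spectrum, deepest first.

    Keeps interior local minima whose depth exceeds ``prominence_frac``
    times the deepest value in the region, each refined to sub-grid
    precision by parabolic interpolation. Returns a DataFrame with columns
    ``wavenumber``, ``depth`` and ``assignment`` (filled by
    :func:`assign_peaks`).
    """
    work = crop_region(s, *region) if region is not None else s
    nu, y = work.axis.values, work.intensity
    ymin = float(y.min())
    if ymin >= 0.0:
        return pd.DataFrame(columns=["wavenumber", "depth", "assignment"])
    floor = -prominence_frac * abs(ymin)

    interior = np.flatnonzero((y[1:-1] < y[:-2]) & (y[1:-1] < y[2:])) + 1
    rows = []
    for i in interior:
        if y[i] >= floor:
            continue
        pos, val = _refine_parabolic(nu, y, int(i))
        rows.append({"wavenumber": pos, "depth": val, "assignment": None})
    out = pd.DataFrame(rows, columns=["wavenumber", "depth", "assignment"])
    return out.sort_values("depth", ignore_index=True)


def assign_peaks(peaks: pd.DataFrame,
                 reference: tuple[tuple[float, str], ...] = REFERENCE_ASSIGNMENTS,
                 tol: float = 4.0) -> pd.DataFrame:
    """Label detected minima with the nearest reference band within ``tol`` cm^-1.

    Nearest reference wins; an exact distance tie goes to the lower
    wavenumber. Minima with no reference within ``tol`` are labelled
    ``"unassigned"``.
    """
    if not tol > 0:
        raise ParameterError(f"assignment tolerance must be > 0, got {tol}")
    ref = sorted(reference)  # ascending wavenumber: ties resolve to the lower
    out = peaks.copy()
    labels = []
    for w in out["wavenumber"]:
        best, best_d = "unassigned", tol
        for rw, name in ref:
            d = abs(w - rw)
            if d < best_d or (d == best_d and best == "unassigned"):
                best, best_d = name, d
        labels.append(best)
    out["assignment"] = labels
    return out


def deepest_minimum(s: Spectrum, region: tuple[float, float],
                    prominence_frac: float = 0.05) -> float:
    """Refined position of the deepest second-derivative minimum in a window."""
    peaks = detect_minima(s, region=region, prominence_frac=prominence_frac)
    if peaks.empty:
        raise DataError(f"no minima found in region {region}")
    return float(peaks["wavenumber"].iloc[0])


# --------------------------------------------------------------------------- #
# GAG marker scan
# --------------------------------------------------------------------------- #

@dataclass
class GagScanReport:
    """Per-mixture GAG-marker detection and the detection threshold fraction."""

    table: pd.DataFrame                 # index: mixture id; columns per marker + all_detected
    min_detected_fraction: float | None  # smallest C-4-S fraction fully detected


def gag_marker_scan(mixtures: SpectrumSet,
                    prominence_frac: float = 0.05,
                    tol: float = 4.0,
                    depth_floor_frac: float = 0.01) -> GagScanReport:
    """Scan preprocessed mixture spectra for the three GAG marker minima.

    For each mixture (labels must carry a ``c4s_fraction`` column) the three
    marker windows are searched with :func:`detect_minima` +
    :func:`assign_peaks`. A marker counts as detected only if its refined
    position lands within ``tol`` of the marker wavenumber *and* its depth
    exceeds ``depth_floor_frac`` of the spectrum's deepest minimum over the
    full valid region -- the absolute floor rejects numerically flat windows
    (e.g. pure collagen near 1134 cm^-1) that a purely window-relative
    threshold would admit.
    """
    if mixtures.n == 0:
        raise DataError("no mixture spectra supplied")
    if "c4s_fraction" not in mixtures.labels.columns:
        raise DataError("mixture labels must carry a 'c4s_fraction' column")

    records = []
    for rid in mixtures.ids:
        s = mixtures.spectrum(rid)
        global_floor = depth_floor_frac * abs(float(s.intensity.min()))
        rec = {"c4s_fraction": float(mixtures.labels.loc[rid, "c4s_fraction"])}
        for marker in GAG_MARKERS:
            lo, hi = GAG_MARKER_WINDOWS[marker]
            try:
                peaks = detect_minima(s, region=(lo, hi),
                                      prominence_frac=prominence_frac)
            except RegionError:
                peaks = pd.DataFrame(columns=["wavenumber", "depth", "assignment"])
            hit = False
            for _, row in peaks.iterrows():
                if (abs(row["wavenumber"] - marker) <= tol
                        and row["depth"] < -global_floor):
                    hit = True
                    break
            rec[f"detected_{int(marker)}"] = hit
        rec["all_detected"] = all(rec[f"detected_{int(m)}"] for m in GAG_MARKERS)
        records.append(rec)

    table = pd.DataFrame(records, index=mixtures.labels.index)
    detected = table.loc[table["all_detected"], "c4s_fraction"]
    min_frac = float(detected.min()) if len(detected) else None
    return GagScanReport(table, min_frac)
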