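"""Core data model and file I/O for FTIR spectra, spectral sets and hyperspectral cubes.

The package-wide conventions live here:

* The canonical wavenumber axis is **strictly decreasing** (FTIR plotting
  convention, high wavenumber on the left).  All readers normalize to it, so
  downstream code never has to branch on orientation.
* Spectra that are combined (stacked into a set, fitted against a reference)
  must share one axis object-for-object or value-for-value; there is no
  silent interpolation between mismatched grids.
* The exchange format for spectral matrices is wide delimited text
  (``id,meta_*...,<wavenumbers>``); hyperspectral cubes use ENVI
  (text header + raw binary).
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd


# --------------------------------------------------------------------------- #
# errors
# --------------------------------------------------------------------------- #

class FtirError(Exception):
    """Base class for all errors raised by this package."""


class AxisError(FtirError):
    """Wavenumber axis is malformed (non-monotonic, duplicated, off-range)."""


class ParseError(FtirError):
    """A text input could not be parsed; the message names the offending cell."""


class FormatError(FtirError):
    """A binary/structured file does not match its declared layout."""


class RegionError(FtirError):
    """A requested wavenumber region does not overlap the data axis."""


class GridError(FtirError):
    """The axis is not uniformly spaced where an operation requires it."""


class ParameterError(FtirError):
    """An operation parameter is out of its valid range."""


class DataError(FtirError):
    """Input data are empty or degenerate for the requested operation."""


# --------------------------------------------------------------------------- #
# axis
# --------------------------------------------------------------------------- #

#: Nominal span of the instrument grid in cm^-1.
AXIS_MIN, AXIS_MAX = 750.0, 4000.0


@dataclass(frozen=True)
class WavenumberAxis:
    """A strictly decreasing wavenumber grid in cm^-1.

    Parameters
    ----------
    values
        Wavenumbers, strictly decreasing. Expected to lie within
        [750, 4000] cm^-1 unless ``extended`` is set.
    nominal_step
        The nominal grid spacing in cm^-1 (4 by default, matching a
        4 cm^-1 spectral resolution).
    extended
        Allow values outside the nominal [750, 4000] range.
    """

    values: np.ndarray
    nominal_step: float = 4.0
    extended: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise AxisError("axis must be a 1-D array with at least 2 channels")
        if not np.all(np.isfinite(v)):
            raise AxisError("axis contains non-finite values")
        if not np.all(np.diff(v) < 0):
            raise AxisError("axis must be strictly decreasing")
        if not self.extended and (v[0] > AXIS_MAX + 1e-9 or v[-1] < AXIS_MIN - 1e-9):
            raise AxisError(
                f"axis [{v[-1]:g}, {v[0]:g}] outside nominal [{AXIS_MIN:g}, {AXIS_MAX:g}] "
                "(pass extended=True to allow)"
            )
        object.__setattr__(self, "values", v)
        v.setflags(write=False)

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def lo(self) -> float:
        return float(self.values[-1])

    @property
    def hi(self) -> float:
        return float(self.values[0])

    @property
    def step(self) -> float:
        """Median absolute channel spacing in cm^-1."""
        return float(np.median(-np.diff(self.values)))

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        d = -np.diff(self.values)
        return bool(np.all(np.abs(d - d[0]) <= rtol * abs(d[0])))

    def normalized(self) -> np.ndarray:
        """Axis mapped affinely onto [-1, 1] (descending: +1 at the high end)."""
        v = self.values
        return (2.0 * v - (v[0] + v[-1])) / (v[0] - v[-1])

    def region_slice(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of channels with lo <= nu <= hi (inclusive both ends)."""
        if not lo < hi:
            raise RegionError(f"region bounds must satisfy lo < hi, got ({lo}, {hi})")
        mask = (self.values >= lo - 1e-9) & (self.values <= hi + 1e-9)
        if not mask.any():
            raise RegionError(
                f"region [{lo:g}, {hi:g}] does not overlap axis "
                f"[{self.lo:g}, {self.hi:g}]"
            )
        return mask

    def index_nearest(self, wavenumber: float) -> int:
        return int(np.argmin(np.abs(self.values - wavenumber)))

    def same_grid(self, other: "WavenumberAxis", rtol: float = 1e-9) -> bool:
        return self.n == other.n and bool(
            np.allclose(self.values, other.values, rtol=rtol, atol=0.0)
        )

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n


def default_axis(lo: float = AXIS_MIN, hi: float = AXIS_MAX, step: float = 4.0) -> WavenumberAxis:
    """The instrument grid: descending from ``hi`` in steps of ``step``.

    The grid is anchored at the high end (4000 cm^-1 by default), so the
    lowest channel is the last grid point >= ``lo`` (752 cm^-1 for the
    default 4000-750 span at 4 cm^-1).
    """
    n = int(np.floor((hi - lo) / step)) + 1
    return WavenumberAxis(hi - step * np.arange(n), nominal_step=step)


def fingerprint_axis(step: float = 4.0) -> WavenumberAxis:
    """The 1800-750 cm^-1 fingerprint-region grid used for imaging."""
    return default_axis(lo=AXIS_MIN, hi=1800.0, step=step)


def _check_same_axis(a: WavenumberAxis, b: WavenumberAxis) -> None:
    if not a.same_grid(b):
        raise AxisError("operands are on different wavenumber grids; resampling is not supported")


# --------------------------------------------------------------------------- #
# spectra
# --------------------------------------------------------------------------- #

@dataclass
class Spectrum:
    """A single absorbance (or derivative) spectrum on a shared axis."""

    axis: WavenumberAxis
    intensity: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        y = np.asarray(self.intensity, dtype=float)
        if y.shape != (self.axis.n,):
            raise DataError(
                f"intensity length {y.size} != axis length {self.axis.n}"
            )
        if not np.all(np.isfinite(y)):
            raise DataError("spectrum intensity contains non-finite values")
        self.intensity = y


@dataclass
class SpectrumSet:
    """A labelled stack of spectra sharing one wavenumber axis.

    ``labels`` is a DataFrame indexed by unique row identifiers; typical
    columns are ``group`` (LS/HS/pure/mixture), ``tissue``
    (muscle/connective/unknown) and any generator bookkeeping such as
    ``c4s_fraction`` or pixel coordinates.
    """

    axis: WavenumberAxis
    matrix: np.ndarray
    labels: pd.DataFrame
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != self.axis.n:
            raise DataError(
                f"matrix shape {m.shape} incompatible with axis length {self.axis.n}"
            )
        if not np.all(np.isfinite(m)):
            raise DataError("spectrum matrix contains non-finite values")
        if len(self.labels) != m.shape[0]:
            raise DataError("labels row count does not match matrix")
        if self.labels.index.has_duplicates:
            dup = self.labels.index[self.labels.index.duplicated()][0]
            raise DataError(f"duplicated row identifier: {dup!r}")
        self.matrix = m

    @property
    def n(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def ids(self) -> list:
        return list(self.labels.index)

    def spectrum(self, row_id) -> Spectrum:
        i = self.labels.index.get_loc(row_id)
        return Spectrum(self.axis, self.matrix[i].copy(),
                        meta=dict(self.labels.loc[row_id].dropna()))

    def subset(self, mask) -> "SpectrumSet":
        mask = np.asarray(mask)
        return SpectrumSet(self.axis, self.matrix[mask].copy(),
                           self.labels.iloc[np.flatnonzero(mask)].copy(),
                           meta=dict(self.meta))

    @classmethod
    def from_spectra(cls, spectra: list[Spectrum], ids: list | None = None,
                     labels: pd.DataFrame | None = None) -> "SpectrumSet":
        if not spectra:
            raise DataError("cannot build a SpectrumSet from zero spectra")
        axis = spectra[0].axis
        for s in spectra[1:]:
            _check_same_axis(axis, s.axis)
        m = np.stack([s.intensity for s in spectra])
        if labels is None:
            if ids is None:
                ids = [f"s{i}" for i in range(len(spectra))]
            labels = pd.DataFrame(index=pd.Index(ids, name="id"))
        return cls(axis, m, labels)


@dataclass
class HyperCube:
    """A hyperspectral image: rows x cols x channels absorbance."""

    axis: WavenumberAxis
    cube: np.ndarray
    pixel_size: float = 6.25
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.cube, dtype=float)
        if c.ndim != 3 or c.shape[2] != self.axis.n:
            raise DataError(f"cube shape {c.shape} incompatible with axis length {self.axis.n}")
        if c.shape[0] < 1 or c.shape[1] < 1:
            raise DataError("cube must have at least one pixel")
        if not np.all(np.isfinite(c)):
            raise DataError("cube contains non-finite values")
        if not self.pixel_size > 0:
            raise ParameterError("pixel_size must be positive")
        self.cube = c

    @property
    def shape(self) -> tuple[int, int]:
        return (int(self.cube.shape[0]), int(self.cube.shape[1]))

    def flatten(self) -> SpectrumSet:
        """Pixels as rows, with ``row``/``col`` coordinates in the labels."""
        r, c, p = self.cube.shape
        rows, cols = np.meshgrid(np.arange(r), np.arange(c), indexing="ij")
        labels = pd.DataFrame(
            {"row": rows.ravel(), "col": cols.ravel()},
            index=pd.Index([f"px_{i}_{j}" for i, j in zip(rows.ravel(), cols.ravel())],
                           name="id"),
        )
        out = SpectrumSet(self.axis, self.cube.reshape(r * c, p).copy(), labels)
        out.meta["image_shape"] = (r, c)
        out.meta["pixel_size"] = self.pixel_size
        return out

    def with_data(self, axis: WavenumberAxis, cube: np.ndarray) -> "HyperCube":
        return HyperCube(axis, cube, pixel_size=self.pixel_size, meta=dict(self.meta))


# --------------------------------------------------------------------------- #
# wide-CSV I/O
# --------------------------------------------------------------------------- #

_NUM_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _is_wavenumber_col(name: str) -> bool:
    return bool(_NUM_RE.match(name.strip()))


def read_spectrum_matrix(path: str | os.PathLike) -> SpectrumSet:
    """Read a wide delimited-text spectral matrix.

    Layout: header ``id,<meta_*...>,<wavenumbers>``; one spectrum per row.
    Metadata columns are prefixed ``meta_``; every other non-``id`` column
    name must parse as a wavenumber. The returned axis is sorted to
    descending order with intensities reordered consistently.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")
    raw_wn = [h for h in header if h != "id" and not h.startswith("meta_")]
    numeric_wn = [h for h in raw_wn if _is_wavenumber_col(h)]
    if len(numeric_wn) == len(raw_wn) and len({float(h) for h in numeric_wn}) != len(numeric_wn):
        raise AxisError(f"{path}: duplicated wavenumber in header")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "id" not in df.columns:
        raise ParseError(f"{path}: missing required 'id' column")
    meta_cols = [c for c in df.columns if c.startswith("meta_")]
    wn_cols = [c for c in df.columns if c not in meta_cols and c != "id"]
    bad = [c for c in wn_cols if not _is_wavenumber_col(c)]
    if bad:
        raise ParseError(f"{path}: non-numeric wavenumber column header {bad[0]!r}")
    if not wn_cols:
        raise ParseError(f"{path}: no wavenumber columns found")

    wns = np.array([float(c) for c in wn_cols])
    if np.unique(wns).size != wns.size:
        raise AxisError(f"{path}: duplicated wavenumber in header")
    order = np.argsort(wns)[::-1]

    n = len(df)
    matrix = np.empty((n, wns.size), dtype=float)
    for j, c in enumerate(wn_cols):
        col = pd.to_numeric(df[c], errors="coerce")
        if n and col.isna().any():
            i = int(col.isna().idxmax())
            raise ParseError(
                f"{path}: non-numeric intensity {df[c].iloc[i]!r} "
                f"at row id={df['id'].iloc[i]!r}, column {c!r}"
            )
        matrix[:, j] = col.to_numpy()

    labels = df[meta_cols].copy()
    labels.columns = [c[len("meta_"):] for c in meta_cols]
    # restore numeric dtypes where the whole column parses
    for c in labels.columns:
        num = pd.to_numeric(labels[c], errors="coerce")
        if not num.isna().any():
            labels[c] = num
    labels.index = pd.Index(df["id"], name="id")

    axis = WavenumberAxis(wns[order], extended=True)
    if AXIS_MIN <= axis.lo and axis.hi <= AXIS_MAX:
        axis = WavenumberAxis(wns[order])
    return SpectrumSet(axis, matrix[:, order], labels)


def write_spectrum_matrix(sset: SpectrumSet, path: str | os.PathLike) -> Path:
    """Write a SpectrumSet as wide CSV; round-trips losslessly via repr floats."""
    path = Path(path)
    cols: dict[str, Any] = {"id": sset.ids}
    for c in sset.labels.columns:
        cols[f"meta_{c}"] = sset.labels[c].to_numpy()
    for j, wn in enumerate(sset.axis.values):
        cols[format(wn, ".10g")] = sset.matrix[:, j]
    df = pd.DataFrame(cols)
    try:
        df.to_csv(path, index=False, float_format="%.17g")
    except OSError as exc:
        raise FtirError(f"cannot write {path}: {exc}") from exc
    return path


# --------------------------------------------------------------------------- #
# ENVI cube I/O (minimal header + raw binary, float64 payload)
# --------------------------------------------------------------------------- #

_ENVI_DTYPES = {4: np.float32, 5: np.float64}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def _parse_envi_header(text: str) -> dict[str, str]:
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError("not an ENVI header (missing 'ENVI' magic)")
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    # collapse {...} blocks onto one logical line
    body = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), body)
    for line in body.splitlines():
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def read_cube(path: str | os.PathLike) -> HyperCube:
    """Read an ENVI cube (``<path>`` raw binary + ``<path>.hdr`` header).

    Supports bil/bip/bsq interleaves; the ``wavelength`` field (cm^-1) is
    required and the band axis is reordered to descending wavenumber.
    """
    path = Path(path)
    hdr_path = path.with_suffix(path.suffix + ".hdr")
    if not hdr_path.exists():
        raise FormatError(f"missing ENVI header {hdr_path}")
    fields = _parse_envi_header(hdr_path.read_text())

    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        interleave = fields["interleave"].lower()
        dtype_code = int(fields.get("data type", "5"))
    except KeyError as exc:
        raise FormatError(f"{hdr_path}: missing required field {exc}") from exc
    if interleave not in ("bil", "bip", "bsq"):
        raise FormatError(f"{hdr_path}: unsupported interleave {interleave!r}")
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"{hdr_path}: unsupported data type code {dtype_code}")
    if "wavelength" not in fields:
        raise FormatError(f"{hdr_path}: missing wavelength list")
    wl_text = fields["wavelength"].strip()
    if not (wl_text.startswith("{") and wl_text.endswith("}")):
        raise FormatError(f"{hdr_path}: malformed wavelength list")
    wns = np.array([float(t) for t in wl_text[1:-1].split(",") if t.strip()])
    if wns.size != bands:
        raise FormatError(f"{hdr_path}: wavelength count {wns.size} != bands {bands}")

    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    expected = samples * lines * bands * dtype.itemsize
    raw = path.read_bytes()
    if len(raw) != expected:
        raise FormatError(
            f"{path}: payload size {len(raw)} != expected {expected} bytes"
        )
    data = np.frombuffer(raw, dtype=dtype)
    if interleave == "bsq":       # (bands, lines, samples)
        cube = data.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":     # (lines, bands, samples)
        cube = data.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:                         # bip: (lines, samples, bands)
        cube = data.reshape(lines, samples, bands)
    cube = np.ascontiguousarray(cube, dtype=float)

    order = np.argsort(wns)[::-1]
    axis_vals = wns[order]
    extended = not (AXIS_MIN <= axis_vals[-1] and axis_vals[0] <= AXIS_MAX)
    axis = WavenumberAxis(axis_vals, extended=extended)
    pixel_size = float(fields.get("pixel size", "6.25").strip("{} ").split(",")[0])
    return HyperCube(axis, cube[:, :, order], pixel_size=pixel_size)


def write_cube(cube: HyperCube, path: str | os.PathLike,
               interleave: str = "bsq") -> Path:
    """Write a HyperCube as ENVI raw binary + ``.hdr`` header (float64)."""
    if interleave not in ("bil", "bip", "bsq"):
        raise ParameterError(f"unsupported interleave {interleave!r}")
    path = Path(path)
    data = cube.cube.astype(np.float64)
    lines, samples, bands = data.shape
    if interleave == "bsq":
        payload = data.transpose(2, 0, 1)
    elif interleave == "bil":
        payload = data.transpose(0, 2, 1)
    else:
        payload = data
    try:
        path.write_bytes(np.ascontiguousarray(payload).tobytes())
    except OSError as exc:
        raise FtirError(f"cannot write {path}: {exc}") from exc
    wl = ", ".join(format(w, ".10g") for w in cube.axis.values)
    hdr = (
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "data type = 5\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"pixel size = {{{cube.pixel_size:.10g}, {cube.pixel_size:.10g}}}\n"
        f"wavelength = {{{wl}}}\n"
    )
    path.with_suffix(path.suffix + ".hdr").write_text(hdr)
    return path


# --------------------------------------------------------------------------- #
# region cropping
# --------------------------------------------------------------------------- #

def crop_region(x: Spectrum | SpectrumSet | HyperCube, lo: float, hi: float):
    """Restrict ``x`` to channels with lo <= nu <= hi (inclusive both ends).

    Returns the same kind as the input; the axis stays descending. Raises
    :class:`RegionError` if the region does not overlap the axis.
    """
    mask = x.axis.region_slice(lo, hi)
    new_axis = WavenumberAxis(x.axis.values[mask],
                              nominal_step=x.axis.nominal_step,
                              extended=x.axis.extended)
    if isinstance(x, Spectrum):
        return Spectrum(new_axis, x.intensity[mask].copy(), meta=dict(x.meta))
    if isinstance(x, SpectrumSet):
        return SpectrumSet(new_axis, x.matrix[:, mask].copy(), x.labels.copy(),
                           meta=dict(x.meta))
    if isinstance(x, HyperCube):
        return HyperCube(new_axis, x.cube[:, :, mask].copy(),
                         pixel_size=x.pixel_size, meta=dict(x.meta))
    raise TypeError(f"cannot crop object of type {type(x).__name__}")
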