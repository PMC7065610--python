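"""Savitzky-Golay differentiation and basic EMSC correction.

The standard preprocessing chain for second-derivative FTIR work:

1. crop to the analysis region;
2. Savitzky-Golay second derivative (9-point window, 2nd-order polynomial),
   computed per cm^-1^2 so absorption bands become minima;
3. basic extended multiplicative signal correction (EMSC) against the
   dataset-mean reference, with a quadratic polynomial baseline model:
   each spectrum z is decomposed by ordinary least squares as

       z(nu) = a + d1*nt + d2*nt^2 + b*m(nu) + e(nu),

   where m is the reference, nt the wavenumber mapped onto [-1, 1], and the
   corrected spectrum is (z - a - d1*nt - d2*nt^2) / b.

Edge policy: channels where the full SG window does not fit are dropped
from the output axis rather than padded, so no fabricated derivative value
ever enters downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .core import (
    DataError,
    GridError,
    HyperCube,
    ParameterError,
    Spectrum,
    SpectrumSet,
    WavenumberAxis,
    _check_same_axis,
    crop_region,
)


class DesignError(DataError):
    """The EMSC design matrix is rank-deficient (reference collinear with baseline)."""


class CorrectionError(DataError):
    """A fitted multiplicative coefficient is too small to divide by."""


# --------------------------------------------------------------------------- #
# Savitzky-Golay derivative
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class SGParams:
    """Savitzky-Golay filter parameters (window in channels, both orders)."""

    window: int = 9
    polyorder: int = 2
    deriv: int = 2

    def __post_init__(self) -> None:
        if self.window % 2 != 1:
            raise ParameterError(f"SG window must be odd, got {self.window}")
        if not self.window > self.polyorder >= self.deriv >= 0:
            raise ParameterError(
                f"require window > polyorder >= deriv >= 0, got "
                f"({self.window}, {self.polyorder}, {self.deriv})"
            )

    @property
    def half(self) -> int:
        return self.window // 2


def _trimmed_axis(axis: WavenumberAxis, half: int) -> WavenumberAxis:
    return WavenumberAxis(axis.values[half:-half] if half else axis.values,
                          nominal_step=axis.nominal_step, extended=axis.extended)


def _sg_matrix(matrix: np.ndarray, axis: WavenumberAxis, p: SGParams) -> np.ndarray:
    if not axis.is_uniform(rtol=1e-6):
        raise GridError("SG differentiation requires a uniformly spaced axis")
    if p.window > axis.n:
        raise ParameterError(
            f"SG window {p.window} exceeds axis length {axis.n}")
    step = axis.step
    # data are stored in descending nu; derivative w.r.t. nu flips sign per order
    sign = (-1.0) ** p.deriv
    out = savgol_filter(matrix, p.window, p.polyorder, deriv=p.deriv,
                        delta=step, axis=-1, mode="interp")
    out = sign * out
    h = p.half
    return out[..., h:-h] if h else out


def sg_second_derivative(x: Spectrum | SpectrumSet | HyperCube,
                         p: SGParams = SGParams()):
    """SG derivative of order ``p.deriv`` in wavenumber units (per cm^-1^deriv).

    Returns the same kind as the input, on the axis trimmed by half a window
    at each end (the edge channels where the centered window does not fit).
    For positive absorption bands and ``deriv=2``, band positions appear as
    minima of the output.
    """
    if isinstance(x, Spectrum):
        y = _sg_matrix(x.intensity[None, :], x.axis, p)[0]
        return Spectrum(_trimmed_axis(x.axis, p.half), y, meta=dict(x.meta))
    if isinstance(x, SpectrumSet):
        m = _sg_matrix(x.matrix, x.axis, p)
        return SpectrumSet(_trimmed_axis(x.axis, p.half), m, x.labels.copy(),
                           meta=dict(x.meta))
    if isinstance(x, HyperCube):
        c = _sg_matrix(x.cube, x.axis, p)
        return HyperCube(_trimmed_axis(x.axis, p.half), c,
                         pixel_size=x.pixel_size, meta=dict(x.meta))
    raise TypeError(f"cannot differentiate object of type {type(x).__name__}")


# --------------------------------------------------------------------------- #
# EMSC
# --------------------------------------------------------------------------- #

B_MIN_DEFAULT = 1e-8


@dataclass
class EMSCModel:
    """Fitted basic-EMSC decomposition for one dataset.

    ``coefficients`` is indexed by spectrum id with columns
    ``a, d1, d2, b, residual_rms``.
    """

    reference: Spectrum
    coefficients: pd.DataFrame
    b_min: float = B_MIN_DEFAULT

    @property
    def axis(self) -> WavenumberAxis:
        return self.reference.axis


def build_reference(sset: SpectrumSet) -> Spectrum:
    """EMSC reference: the channel-wise mean spectrum of the dataset."""
    if sset.n == 0:
        raise DataError("cannot build a reference from an empty set")
    return Spectrum(sset.axis, sset.matrix.mean(axis=0),
                    meta={"role": "emsc_reference", "n_spectra": sset.n})


def _emsc_design(axis: WavenumberAxis, reference: Spectrum) -> np.ndarray:
    nt = axis.normalized()
    return np.column_stack([np.ones(axis.n), nt, nt**2, reference.intensity])


def emsc_fit(sset: SpectrumSet, reference: Spectrum,
             b_min: float = B_MIN_DEFAULT) -> EMSCModel:
    """Ordinary-least-squares basic EMSC fit of every spectrum in the set.

    Raises :class:`DesignError` if the reference is (numerically) collinear
    with the polynomial baseline terms, and :class:`CorrectionError` naming
    the first spectrum whose |b| falls below ``b_min``.
    """
    _check_same_axis(sset.axis, reference.axis)
    D = _emsc_design(sset.axis, reference)
    # guard: reference must carry signal beyond the quadratic baseline
    poly = D[:, :3]
    proj, *_ = np.linalg.lstsq(poly, reference.intensity, rcond=None)
    resid = reference.intensity - poly @ proj
    if np.sqrt(np.mean(resid**2)) < 1e-10:
        raise DesignError(
            "EMSC reference is collinear with the polynomial baseline terms")

    beta, *_ = np.linalg.lstsq(D, sset.matrix.T, rcond=None)  # 4 x n
    resid = sset.matrix.T - D @ beta
    rms = np.sqrt(np.mean(resid**2, axis=0))
    coeffs = pd.DataFrame(
        {"a": beta[0], "d1": beta[1], "d2": beta[2], "b": beta[3],
         "residual_rms": rms},
        index=sset.labels.index,
    )
    small = coeffs.index[np.abs(coeffs["b"].to_numpy()) < b_min]
    if len(small):
        raise CorrectionError(
            f"multiplicative coefficient |b| < {b_min:g} for spectrum "
            f"{small[0]!r}; correction would be unstable")
    return EMSCModel(reference, coeffs, b_min=b_min)


def emsc_correct(sset: SpectrumSet, model: EMSCModel) -> SpectrumSet:
    """Remove the fitted baseline and divide out the multiplicative factor."""
    _check_same_axis(sset.axis, model.axis)
    if not sset.labels.index.equals(model.coefficients.index):
        raise DataError("EMSC model was fitted on a different set of spectra")
    nt = sset.axis.normalized()
    co = model.coefficients
    baseline = (co["a"].to_numpy()[:, None]
                + co["d1"].to_numpy()[:, None] * nt
                + co["d2"].to_numpy()[:, None] * nt**2)
    corrected = (sset.matrix - baseline) / co["b"].to_numpy()[:, None]
    return SpectrumSet(sset.axis, corrected, sset.labels.copy(), meta=dict(sset.meta))


def emsc(sset: SpectrumSet, reference: Spectrum | None = None,
         b_min: float = B_MIN_DEFAULT) -> tuple[SpectrumSet, EMSCModel]:
    """Fit-and-correct convenience wrapper (reference defaults to the set mean)."""
    ref = reference if reference is not None else build_reference(sset)
    model = emsc_fit(sset, ref, b_min=b_min)
    return emsc_correct(sset, model), model


# --------------------------------------------------------------------------- #
# pipeline
# --------------------------------------------------------------------------- #

PipelineOrder = Literal["derivative-first", "emsc-first"]


@dataclass
class PipelineResult:
    """Preprocessed data plus the EMSC model and a provenance record."""

    data: SpectrumSet | HyperCube
    emsc_model: EMSCModel
    provenance: dict


def preprocess_pipeline(
    x: SpectrumSet | HyperCube,
    p: SGParams = SGParams(),
    region: tuple[float, float] | None = None,
    reference: Spectrum | None = None,
    order: PipelineOrder = "derivative-first",
    b_min: float = B_MIN_DEFAULT,
) -> PipelineResult:
    """The full preprocessing chain: crop -> SG derivative -> EMSC.

    The default stage order applies EMSC to the second-derivative spectra
    with the dataset mean as reference; ``order="emsc-first"`` is exposed
    for sensitivity checks. Cubes are flattened to pixel rows for the EMSC
    stage and reshaped back afterwards. Deterministic.
    """
    is_cube = isinstance(x, HyperCube)
    work: SpectrumSet | HyperCube = x
    if region is not None:
        work = crop_region(work, *region)

    def _emsc_stage(obj, ref):
        if isinstance(obj, HyperCube):
            flat = obj.flatten()
            corrected, model = emsc(flat, reference=ref, b_min=b_min)
            r, c = obj.shape
            cube = corrected.matrix.reshape(r, c, obj.axis.n)
            return obj.with_data(obj.axis, cube), model
        return (*emsc(obj, reference=ref, b_min=b_min),)

    if order == "derivative-first":
        work = sg_second_derivative(work, p)
        work, model = _emsc_stage(work, reference)
    elif order == "emsc-first":
        work, model = _emsc_stage(work, reference)
        work = sg_second_derivative(work, p)
    else:
        raise ParameterError(f"unknown pipeline order {order!r}")

    provenance = {
        "stages": (["crop"] if region is not None else [])
        + (["sg_second_derivative", "emsc"] if order == "derivative-first"
           else ["emsc", "sg_second_derivative"]),
        "region": list(region) if region is not None else None,
        "sg": {"window": p.window, "polyorder": p.polyorder, "deriv": p.deriv},
        "order": order,
        "reference": "dataset-mean" if reference is None else "supplied",
        "input_kind": "cube" if is_cube else "set",
    }
    return PipelineResult(work, model, provenance)
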