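"""Synthetic FTIR data with the statistical structure the analysis assumes.

Pure-component spectra are sums of Gaussian bands whose centers follow the
published second-derivative band assignments for collagen type I and
chondroitin-4-sulfate (C-4-S); relative amplitudes are package defaults
chosen so that collagen's strongest band sits in the amide I region
(1585-1720 cm^-1) and C-4-S's strongest band sits in the carbohydrate
region (1140-985 cm^-1). Mixtures follow Beer-Lambert linearity. Measured
spectra are degraded by a lognormal multiplicative factor, a random
quadratic baseline and iid Gaussian noise -- exactly the distortion family
that basic EMSC is built to remove.

Tissue images are Voronoi tessellations of muscle-fiber cells separated by
connective-tissue seams; a ground-truth label map and per-pixel collagen
fraction map are always emitted alongside the cube.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    DataError,
    HyperCube,
    ParameterError,
    Spectrum,
    SpectrumSet,
    WavenumberAxis,
    default_axis,
)


class ModelError(DataError):
    """A band model is invalid on the requested axis."""


class CompositionError(DataError):
    """Mixture fractions are negative or do not sum to one."""


class GeometryError(DataError):
    """Tissue-image geometry parameters are inconsistent."""


# --------------------------------------------------------------------------- #
# band models
# --------------------------------------------------------------------------- #

_FWHM_DEFAULT = 16.0  # cm^-1: four grid steps on the 4 cm^-1 grid


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band: center (cm^-1), FWHM (cm^-1), amplitude."""

    center: float
    fwhm: float = _FWHM_DEFAULT
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not self.fwhm > 0:
            raise ModelError(f"band at {self.center}: fwhm must be > 0")
        if not self.amplitude > 0:
            raise ModelError(f"band at {self.center}: amplitude must be > 0")


@dataclass(frozen=True)
class BandModel:
    """A named component as a list of Gaussian bands."""

    component: str
    bands: tuple[Band, ...]

    def validate_on(self, axis: WavenumberAxis) -> None:
        for b in self.bands:
            if not (axis.lo <= b.center <= axis.hi):
                raise ModelError(
                    f"{self.component}: band center {b.center} cm^-1 outside "
                    f"axis [{axis.lo:g}, {axis.hi:g}]"
                )
            if b.fwhm < 2 * axis.nominal_step:
                raise ModelError(
                    f"{self.component}: band at {b.center} has fwhm {b.fwhm} "
                    f"< 2 x grid step {axis.nominal_step}; unresolvable"
                )

    @property
    def centers(self) -> np.ndarray:
        return np.array([b.center for b in self.bands])


def collagen_model() -> BandModel:
    """Collagen type I: amide I/II dominant, amide III triplet, carbohydrate C-O."""
    amps = {
        1660: 1.00,   # amide I, C=O stretch (strongest)
        1554: 0.80,   # amide II
        1456: 0.45,   # CH2 asymmetric bend
        1338: 0.35,   # CH2 side-chain
        1286: 0.30,   # amide III / CH2 wag
        1236: 0.35,   # amide III
        1204: 0.25,   # amide III / CH2 wag
        1082: 0.30,   # C-O carbohydrate residues
        1060: 0.28,   # C-O carbohydrate residues / SO3- ambiguity
        1031: 0.32,   # C-O carbohydrate residues
    }
    return BandModel("collagen_I", tuple(Band(c, amplitude=a) for c, a in amps.items()))


def c4s_model() -> BandModel:
    """Chondroitin-4-sulfate: strongest band in the 1140-985 carbohydrate region.

    The 1060 cm^-1 band is carried at near-negligible amplitude: it appears
    in the assignment table with a dual collagen/sulfate reading but is not
    a distinct feature of the pure C-4-S spectrum; here it merges into the
    1072/1031 cluster and never forms its own minimum.
    """
    amps = {
        1376: 0.35,   # CH3 symmetric bend of GAGs
        1228: 0.55,   # O-SO3- asymmetric stretch
        1161: 0.40,   # C-O carbohydrate residues
        1134: 0.60,   # C-O-S asymmetric stretch (GAG marker)
        1072: 0.55,   # sugar ring
        1060: 0.05,   # see docstring
        1031: 0.75,   # C-O carbohydrate residues (strongest)
        989: 0.50,    # unassigned GAG marker
        924: 0.40,    # sulfated proteoglycan (aggrecan) marker
    }
    return BandModel("C4S", tuple(Band(c, amplitude=a) for c, a in amps.items()))


def muscle_model() -> BandModel:
    """Synthetic muscle-fiber component (acknowledged invention).

    Real muscle-fiber FTIR spectra are not characterized by the source
    band-assignment table; this amide-dominated model -- lacking the
    collagen amide III triplet (1338/1286/1236) and all GAG bands -- exists
    so segmentation has a contrast to work with.
    """
    amps = {
        1652: 1.00,   # amide I (myofibrillar proteins)
        1548: 0.70,   # amide II
        1456: 0.40,   # CH2 bend
        1400: 0.30,   # COO- symmetric stretch
        1304: 0.12,   # amide III, weak
        1080: 0.10,   # weak carbohydrate/phosphate background
    }
    return BandModel("muscle", tuple(Band(c, amplitude=a) for c, a in amps.items()))


def _models() -> dict[str, BandModel]:
    return {"collagen_I": collagen_model(), "C4S": c4s_model(), "muscle": muscle_model()}


# --------------------------------------------------------------------------- #
# clean generation
# --------------------------------------------------------------------------- #

_FOUR_LN2 = 4.0 * np.log(2.0)


def generate_pure_spectrum(model: BandModel, axis: WavenumberAxis) -> Spectrum:
    """Clean pure-component spectrum: sum of Gaussian bands on the grid."""
    model.validate_on(axis)
    nu = axis.values
    y = np.zeros(axis.n)
    for b in model.bands:
        y += b.amplitude * np.exp(-_FOUR_LN2 * (nu - b.center) ** 2 / b.fwhm**2)
    return Spectrum(axis, y, meta={"component": model.component})


def generate_mixture_spectrum(
    fractions: Mapping[str, float],
    axis: WavenumberAxis,
    models: Mapping[str, BandModel] | None = None,
) -> Spectrum:
    """Beer-Lambert linear mixture of pure components by mass fraction."""
    models = dict(models) if models is not None else _models()
    fr = dict(fractions)
    if any(f < 0 for f in fr.values()):
        raise CompositionError(f"negative fraction in {fr}")
    total = sum(fr.values())
    if abs(total - 1.0) > 1e-9:
        raise CompositionError(f"fractions sum to {total!r}, expected 1")
    y = np.zeros(axis.n)
    for name, f in fr.items():
        if name not in models:
            raise ModelError(f"unknown component {name!r}")
        if f == 0.0:
            continue
        y += f * generate_pure_spectrum(models[name], axis).intensity
    return Spectrum(axis, y, meta={"fractions": dict(fr)})


def connective_spectrum(f_coll: float, axis: WavenumberAxis,
                        models: Mapping[str, BandModel] | None = None) -> Spectrum:
    """Connective tissue as a collagen/C-4-S binary mixture."""
    if not 0.0 <= f_coll <= 1.0:
        raise CompositionError(f"collagen fraction {f_coll} outside [0, 1]")
    return generate_mixture_spectrum(
        {"collagen_I": f_coll, "C4S": 1.0 - f_coll}, axis, models=models
    )


# --------------------------------------------------------------------------- #
# degradations
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class DegradationSpec:
    """Measurement distortions applied to a clean spectrum.

    The degraded spectrum is ``b*s(nu) + a + d1*nt + d2*nt**2 + eps(nu)``
    where ``b = exp(N(0, mult_scale_sd))``, the polynomial coefficients are
    iid ``N(0, baseline_coeff_sd[k])``, ``eps`` is iid ``N(0, noise_sd)``
    per channel, and ``nt`` is the wavenumber mapped affinely onto [-1, 1].
    Zero sds reproduce the clean spectrum exactly.
    """

    mult_scale_sd: float = 0.0
    baseline_coeff_sd: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        sds = (self.mult_scale_sd, *self.baseline_coeff_sd, self.noise_sd)
        if any(s < 0 for s in sds):
            raise ParameterError("degradation sds must be >= 0")

    @property
    def is_null(self) -> bool:
        return (self.mult_scale_sd == 0.0 and self.noise_sd == 0.0
                and all(s == 0.0 for s in self.baseline_coeff_sd))


#: Realistic measurement conditions for replicate tissue spectra: ~0.5% of
#: the amide I amplitude in additive noise, a +-20% (1 sd, lognormal)
#: thickness/scatter factor and a gentle quadratic baseline.
DEFAULT_DEGRADATION = DegradationSpec(
    mult_scale_sd=0.2,
    baseline_coeff_sd=(0.10, 0.05, 0.02),
    noise_sd=0.005,
)


def apply_degradations(s: Spectrum, d: DegradationSpec,
                       rng: np.random.Generator) -> Spectrum:
    """One random realization of the degradation model for one spectrum."""
    nt = s.axis.normalized()
    b = float(np.exp(rng.normal(0.0, d.mult_scale_sd))) if d.mult_scale_sd > 0 else 1.0
    coeffs = [rng.normal(0.0, sd) if sd > 0 else 0.0 for sd in d.baseline_coeff_sd]
    y = b * s.intensity + coeffs[0] + coeffs[1] * nt + coeffs[2] * nt**2
    if d.noise_sd > 0:
        y = y + rng.normal(0.0, d.noise_sd, size=s.axis.n)
    meta = dict(s.meta)
    meta.update({"b": b, "a": coeffs[0], "d1": coeffs[1], "d2": coeffs[2]})
    return Spectrum(s.axis, y, meta=meta)


# --------------------------------------------------------------------------- #
# replicate diet groups
# --------------------------------------------------------------------------- #

#: Default diet-group connective compositions. The high-starch (HS) group has
#: relatively more collagen; the low-starch (LS) group carries ~40% more
#: GAGs (C-4-S fraction 0.10 vs 0.07).
DEFAULT_GROUP_PARAMS: dict[str, float] = {"LS": 0.90, "HS": 0.93}


def generate_group_set(
    n_per_group: int,
    group_params: Mapping[str, float] | None = None,
    degradation: DegradationSpec = DEFAULT_DEGRADATION,
    axis: WavenumberAxis | None = None,
    models: Mapping[str, BandModel] | None = None,
    seed: int | None = None,
) -> SpectrumSet:
    """Replicate connective-tissue spectra for the LS and HS diet groups.

    Each replicate is the group's clean connective mixture pushed through
    one independent degradation draw. Reproducible under a fixed seed; the
    per-replicate random streams are spawned independently so adding
    replicates never perturbs earlier draws.
    """
    if n_per_group < 2:
        raise DataError(f"need n_per_group >= 2 replicates, got {n_per_group}")
    gp = dict(group_params) if group_params is not None else dict(DEFAULT_GROUP_PARAMS)
    if set(gp) != {"LS", "HS"}:
        raise ParameterError(f"group_params must have exactly keys LS and HS, got {set(gp)}")
    if not gp["HS"] > gp["LS"]:
        raise ParameterError(
            f"HS collagen fraction ({gp['HS']}) must exceed LS ({gp['LS']})"
        )
    axis = axis if axis is not None else default_axis()
    if seed is None:
        seed = degradation.seed
    streams = np.random.SeedSequence(seed).spawn(2 * n_per_group)

    rows, ids, recs = [], [], []
    k = 0
    for group in ("LS", "HS"):
        clean = connective_spectrum(gp[group], axis, models=models)
        for r in range(n_per_group):
            rng = np.random.default_rng(streams[k]); k += 1
            spec = apply_degradations(clean, degradation, rng)
            rows.append(spec.intensity)
            ids.append(f"{group}_{r}")
            recs.append({
                "group": group, "tissue": "connective",
                "collagen_fraction": gp[group], "c4s_fraction": 1.0 - gp[group],
                "b": spec.meta["b"], "a": spec.meta["a"],
                "d1": spec.meta["d1"], "d2": spec.meta["d2"],
            })
    labels = pd.DataFrame(recs, index=pd.Index(ids, name="id"))
    return SpectrumSet(axis, np.stack(rows), labels,
                       meta={"seed": seed, "group_params": gp})


# --------------------------------------------------------------------------- #
# tissue images
# --------------------------------------------------------------------------- #

MUSCLE, CONNECTIVE = 0, 1
LABEL_NAMES = {MUSCLE: "muscle", CONNECTIVE: "connective"}


@dataclass(frozen=True)
class TissueImageSpec:
    """Geometry, composition and degradation of one synthetic tissue image."""

    rows: int = 64
    cols: int = 64
    n_fiber_seeds: int = 6
    seam_width: float = 2.0
    connective_composition: float = 0.90  # collagen mass fraction of seams
    group: str = "LS"
    degradation: DegradationSpec = field(default_factory=DegradationSpec)
    composition_jitter_sd: float = 0.05   # per-pixel sd of the collagen fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.connective_composition <= 1.0:
            raise CompositionError(
                f"collagen fraction {self.connective_composition} outside [0, 1]")
        if self.seam_width < 1:
            raise GeometryError("seam_width must be >= 1 pixel")
        if self.n_fiber_seeds < 1:
            raise GeometryError("need at least one fiber seed")
        if self.seam_width >= min(self.rows, self.cols):
            raise GeometryError(
                f"seam_width {self.seam_width} >= min image dimension "
                f"{min(self.rows, self.cols)}")
        if self.composition_jitter_sd < 0:
            raise ParameterError("composition_jitter_sd must be >= 0")


@dataclass
class TissueImage:
    """A generated cube plus its ground truth.

    ``truth_labels`` is rows x cols of {MUSCLE, CONNECTIVE};
    ``collagen_fraction`` is the per-pixel collagen mass fraction on
    connective pixels and NaN on muscle pixels.
    """

    cube: HyperCube
    truth_labels: np.ndarray
    collagen_fraction: np.ndarray
    spec: TissueImageSpec


def _voronoi_labels(spec: TissueImageSpec, rng: np.random.Generator) -> np.ndarray:
    """Fiber cells = Voronoi regions of random seeds; seams between cells.

    A pixel is connective if the gap between its distances to the two
    nearest seeds is at most ``seam_width`` (an approximately
    seam_width-wide band around each Voronoi edge). With a single seed the
    whole image is muscle.
    """
    pts = np.column_stack([
        rng.uniform(0, spec.rows, size=spec.n_fiber_seeds),
        rng.uniform(0, spec.cols, size=spec.n_fiber_seeds),
    ])
    rr, cc = np.meshgrid(np.arange(spec.rows) + 0.5,
                         np.arange(spec.cols) + 0.5, indexing="ij")
    d = np.sqrt((rr[..., None] - pts[:, 0]) ** 2 + (cc[..., None] - pts[:, 1]) ** 2)
    if spec.n_fiber_seeds == 1:
        return np.full((spec.rows, spec.cols), MUSCLE, dtype=int)
    d.sort(axis=-1)
    seam = (d[..., 1] - d[..., 0]) <= spec.seam_width
    return np.where(seam, CONNECTIVE, MUSCLE)


def generate_tissue_image(
    spec: TissueImageSpec,
    axis: WavenumberAxis | None = None,
    models: Mapping[str, BandModel] | None = None,
) -> TissueImage:
    """Generate one hyperspectral tissue image with ground truth.

    Muscle pixels draw the synthetic muscle spectrum; connective pixels draw
    the collagen/C-4-S mixture at a per-pixel collagen fraction jittered
    around ``connective_composition``. Every pixel is degraded independently.
    Deterministic under ``spec.seed``.
    """
    from .core import fingerprint_axis  # default imaging grid

    axis = axis if axis is not None else fingerprint_axis()
    models = dict(models) if models is not None else _models()
    root = np.random.SeedSequence(spec.seed)
    geom_ss, comp_ss, degr_ss = root.spawn(3)

    labels = _voronoi_labels(spec, np.random.default_rng(geom_ss))
    n_px = spec.rows * spec.cols

    # per-pixel collagen fraction on connective pixels
    comp_rng = np.random.default_rng(comp_ss)
    frac = np.full((spec.rows, spec.cols), np.nan)
    conn = labels == CONNECTIVE
    jitter = comp_rng.normal(0.0, spec.composition_jitter_sd, size=int(conn.sum())) \
        if spec.composition_jitter_sd > 0 else np.zeros(int(conn.sum()))
    frac[conn] = np.clip(spec.connective_composition + jitter, 0.0, 1.0)

    muscle = generate_pure_spectrum(models["muscle"], axis).intensity
    coll = generate_pure_spectrum(models["collagen_I"], axis).intensity
    c4s = generate_pure_spectrum(models["C4S"], axis).intensity

    cube = np.empty((spec.rows, spec.cols, axis.n))
    cube[~conn] = muscle
    f = frac[conn][:, None]
    cube[conn] = f * coll + (1.0 - f) * c4s

    d = spec.degradation
    if not d.is_null:
        # one independent stream per pixel: adding pixels never perturbs earlier draws
        px_streams = degr_ss.spawn(n_px)
        flat = cube.reshape(n_px, axis.n)
        nt = axis.normalized()
        for i in range(n_px):
            rng = np.random.default_rng(px_streams[i])
            b = float(np.exp(rng.normal(0.0, d.mult_scale_sd))) if d.mult_scale_sd > 0 else 1.0
            coeffs = [rng.normal(0.0, sd) if sd > 0 else 0.0 for sd in d.baseline_coeff_sd]
            y = b * flat[i] + coeffs[0] + coeffs[1] * nt + coeffs[2] * nt**2
            if d.noise_sd > 0:
                y += rng.normal(0.0, d.noise_sd, size=axis.n)
            flat[i] = y

    hc = HyperCube(axis, cube, meta={"group": spec.group, "seed": spec.seed,
                                     "sample_id": f"synthetic_{spec.group}_{spec.seed}"})
    return TissueImage(hc, labels, frac, spec)
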