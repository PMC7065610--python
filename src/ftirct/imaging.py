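"""Tissue segmentation and pure-component correlation mapping of FTIR images.

Pixels of a preprocessed hyperspectral cube are labelled muscle or
connective tissue by cosine similarity to the mean spectra of user-selected
patches; muscle pixels are then discarded (they would bias any
quantification toward the dominant tissue class), and each remaining
connective pixel is scored by its Pearson correlation to the preprocessed
pure-component spectra of collagen type I and chondroitin-4-sulfate.
Diet groups are compared by superimposing the histograms of their
correlation images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    DataError,
    HyperCube,
    ParameterError,
    Spectrum,
    SpectrumSet,
    _check_same_axis,
    crop_region,
)
from .synth import CONNECTIVE, MUSCLE


class SimilarityError(DataError):
    """A vector with (near-)zero norm was passed to cosine similarity."""


class PatchError(DataError):
    """A patch selection is out of bounds, overlapping, or empty."""


# --------------------------------------------------------------------------- #
# cosine similarity
# --------------------------------------------------------------------------- #

NORM_EPS = 1e-12


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u.v / (|u||v|), in [-1, 1]; raises on (near-)zero vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ParameterError("cosine similarity needs two equal-length vectors")
    nu_, nv_ = np.linalg.norm(u), np.linalg.norm(v)
    if nu_ < NORM_EPS or nv_ < NORM_EPS:
        raise SimilarityError("cannot compute cosine similarity of a zero vector")
    return float(np.clip(u @ v / (nu_ * nv_), -1.0, 1.0))


# --------------------------------------------------------------------------- #
# patches and segmentation
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class Patch:
    """A rectangular pixel region: top-left (row, col), height, width."""

    row: int
    col: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise PatchError(f"patch {self} must be at least 1x1")
        if self.row < 0 or self.col < 0:
            raise PatchError(f"patch {self} has negative origin")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        r, c = shape
        if self.row + self.height > r or self.col + self.width > c:
            raise PatchError(f"patch {self} exceeds image bounds {shape}")
        m = np.zeros(shape, dtype=bool)
        m[self.row:self.row + self.height, self.col:self.col + self.width] = True
        return m


@dataclass(frozen=True)
class PatchSelection:
    """Manually selected patches per tissue class."""

    muscle: tuple[Patch, ...]
    connective: tuple[Patch, ...]

    def __post_init__(self) -> None:
        if not self.muscle or not self.connective:
            raise PatchError("need at least one patch per tissue class")

    def validate_on(self, shape: tuple[int, int]) -> None:
        m = np.zeros(shape, dtype=bool)
        for p in self.muscle:
            m |= p.mask(shape)
        c = np.zeros(shape, dtype=bool)
        for p in self.connective:
            c |= p.mask(shape)
        if (m & c).any():
            raise PatchError("muscle and connective patches overlap")


def patches_from_truth(truth_labels: np.ndarray, n_per_class: int = 2,
                       size: int = 2, seed: int = 0) -> PatchSelection:
    """Draw small patches from a ground-truth label map (synthetic benchmarks).

    Oracle-assisted: stands in for the manual patch selection a spectroscopist
    would do on a real image. Each patch is a ``size`` x ``size`` square fully
    inside one class.
    """
    rng = np.random.default_rng(seed)
    out: dict[int, list[Patch]] = {MUSCLE: [], CONNECTIVE: []}
    rmax, cmax = truth_labels.shape
    for cls in (MUSCLE, CONNECTIVE):
        candidates = []
        for r in range(rmax - size + 1):
            for c in range(cmax - size + 1):
                if (truth_labels[r:r + size, c:c + size] == cls).all():
                    candidates.append((r, c))
        if len(candidates) < n_per_class:
            raise PatchError(
                f"cannot place {n_per_class} {size}x{size} patches in class {cls}")
        for idx in rng.choice(len(candidates), size=n_per_class, replace=False):
            r, c = candidates[int(idx)]
            out[cls].append(Patch(r, c, size, size))
    return PatchSelection(muscle=tuple(out[MUSCLE]), connective=tuple(out[CONNECTIVE]))


@dataclass
class SegmentationMap:
    """Per-pixel tissue labels and the similarity margin behind each call."""

    labels: np.ndarray   # rows x cols of {MUSCLE, CONNECTIVE}
    margin: np.ndarray   # winning score minus losing score, >= 0

    def accuracy(self, truth: np.ndarray) -> float:
        if truth.shape != self.labels.shape:
            raise DataError("truth map shape does not match segmentation")
        return float(np.mean(self.labels == truth))

    @property
    def n_connective(self) -> int:
        return int(np.sum(self.labels == CONNECTIVE))


def segment_tissue(cube: HyperCube, patches: PatchSelection) -> SegmentationMap:
    """Label each pixel by the class of its most cosine-similar patch mean.

    The class score is the *maximum* cosine similarity over that class's
    patch-mean spectra (robust to one unrepresentative patch). An exact tie
    labels the pixel muscle, so ambiguous pixels are discarded rather than
    quantified downstream. Deterministic.
    """
    shape = cube.shape
    patches.validate_on(shape)

    def patch_means(plist: tuple[Patch, ...]) -> np.ndarray:
        means = []
        for p in plist:
            block = cube.cube[p.row:p.row + p.height, p.col:p.col + p.width, :]
            mean = block.reshape(-1, cube.axis.n).mean(axis=0)
            if np.linalg.norm(mean) < NORM_EPS:
                raise PatchError(f"patch {p} has a zero mean spectrum")
            means.append(mean)
        return np.stack(means)

    flat = cube.cube.reshape(-1, cube.axis.n)
    norms = np.linalg.norm(flat, axis=1)
    if np.any(norms < NORM_EPS):
        raise SimilarityError("image contains zero-norm pixel spectra")
    unit = flat / norms[:, None]

    def class_score(means: np.ndarray) -> np.ndarray:
        mu = means / np.linalg.norm(means, axis=1)[:, None]
        return (unit @ mu.T).max(axis=1)

    s_mus = class_score(patch_means(patches.muscle))
    s_con = class_score(patch_means(patches.connective))
    labels = np.where(s_con > s_mus, CONNECTIVE, MUSCLE).reshape(shape)
    margin = np.abs(s_con - s_mus).reshape(shape)
    return SegmentationMap(labels=labels, margin=margin)


def discard_muscle(cube: HyperCube, seg: SegmentationMap) -> SpectrumSet:
    """Keep only connective-labelled pixel spectra (coordinates in the labels)."""
    if seg.labels.shape != cube.shape:
        raise DataError("segmentation shape does not match cube")
    conn = seg.labels == CONNECTIVE
    if not conn.any():
        raise DataError("segmentation contains no connective pixels")
    rr, cc = np.nonzero(conn)
    matrix = cube.cube[rr, cc, :]
    labels = pd.DataFrame(
        {"row": rr, "col": cc, "tissue": "connective"},
        index=pd.Index([f"px_{r}_{c}" for r, c in zip(rr, cc)], name="id"),
    )
    out = SpectrumSet(cube.axis, matrix, labels, meta=dict(cube.meta))
    out.meta["image_shape"] = cube.shape
    return out


# --------------------------------------------------------------------------- #
# correlation images
# --------------------------------------------------------------------------- #

@dataclass
class CorrelationImage:
    """Per-pixel Pearson correlation to one pure-component spectrum.

    ``values`` is NaN outside the connective mask and on masked (constant)
    pixels; ``mask`` is True exactly where a correlation is defined.
    """

    values: np.ndarray
    mask: np.ndarray
    component: str
    region: tuple[float, float]
    n_masked_constant: int = 0

    @property
    def defined(self) -> np.ndarray:
        return self.values[self.mask]


def correlate_to_component(connective: SpectrumSet, pure: Spectrum,
                           region: tuple[float, float] | None = None,
                           component: str | None = None) -> CorrelationImage:
    """Pearson correlation of each connective pixel to a pure spectrum.

    Pearson is affine-invariant, so the map responds to spectral *shape*,
    not intensity. Constant pixel spectra over the region are masked and
    counted rather than erroring. Pixels are reassembled into image
    coordinates using the ``row``/``col`` labels and ``image_shape`` meta
    attached by :func:`discard_muscle`.
    """
    _check_same_axis(connective.axis, pure.axis)
    if "image_shape" not in connective.meta:
        raise DataError("connective set lacks image_shape meta; "
                        "was it produced by discard_muscle?")
    shape = tuple(connective.meta["image_shape"])

    work_set = crop_region(connective, *region) if region is not None else connective
    work_pure = crop_region(pure, *region) if region is not None else pure
    region_out = (work_set.axis.lo, work_set.axis.hi)

    X = work_set.matrix - work_set.matrix.mean(axis=1, keepdims=True)
    y = work_pure.intensity - work_pure.intensity.mean()
    ynorm = np.linalg.norm(y)
    if ynorm < NORM_EPS:
        raise DataError("pure-component spectrum is constant over the region")
    xnorm = np.linalg.norm(X, axis=1)
    constant = xnorm < NORM_EPS

    r = np.full(work_set.n, np.nan)
    ok = ~constant
    r[ok] = np.clip((X[ok] @ y) / (xnorm[ok] * ynorm), -1.0, 1.0)

    values = np.full(shape, np.nan)
    mask = np.zeros(shape, dtype=bool)
    rows = work_set.labels["row"].to_numpy(dtype=int)
    cols = work_set.labels["col"].to_numpy(dtype=int)
    values[rows[ok], cols[ok]] = r[ok]
    mask[rows[ok], cols[ok]] = True
    name = component or (pure.meta.get("component") if pure.meta else None) or "component"
    return CorrelationImage(values, mask, name, region_out,
                            n_masked_constant=int(constant.sum()))


# --------------------------------------------------------------------------- #
# group comparison
# --------------------------------------------------------------------------- #

@dataclass
class HistogramComparison:
    """Superimposed LS/HS histograms of one component's correlation values."""

    bin_edges: np.ndarray
    counts: dict[str, np.ndarray]
    n_pixels: dict[str, int]
    mean: dict[str, float]
    median: dict[str, float]
    mean_difference: float  # HS - LS
    component: str

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {g: {"n_pixels": self.n_pixels[g], "mean": self.mean[g],
                 "median": self.median[g]} for g in ("LS", "HS")}
        ).T


def compare_groups(images: dict[str, CorrelationImage],
                   bins: int = 50) -> HistogramComparison:
    """Shared-bin histograms over [-1, 1] plus mean/median per diet group.

    ``images`` must map exactly the group names LS and HS to correlation
    images of the same component. The signed mean difference is HS - LS.
    """
    if set(images) != {"LS", "HS"}:
        raise ParameterError(f"expected exactly groups LS and HS, got {set(images)}")
    if bins < 1:
        raise ParameterError("bins must be >= 1")
    comps = {im.component for im in images.values()}
    if len(comps) > 1:
        raise DataError(f"images are for different components: {comps}")
    edges = np.linspace(-1.0, 1.0, bins + 1)
    counts, n_pixels, mean, median = {}, {}, {}, {}
    for g, im in images.items():
        vals = im.defined
        if vals.size == 0:
            raise DataError(f"group {g}: correlation image has no defined pixels")
        counts[g], _ = np.histogram(vals, bins=edges)
        n_pixels[g] = int(vals.size)
        mean[g] = float(vals.mean())
        median[g] = float(np.median(vals))
    return HistogramComparison(
        bin_edges=edges, counts=counts, n_pixels=n_pixels, mean=mean,
        median=median, mean_difference=mean["HS"] - mean["LS"],
        component=comps.pop(),
    )
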