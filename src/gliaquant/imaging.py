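"""Calibrated image containers and the primitive operators of the pipeline.

Everything downstream (plaque burden, neuritic-damage ratios, microglial
coverage) is a short composition of the operators in this module:
z-projection, histogram thresholding (Otsu between-class variance and Kapur
maximum entropy), binarization, connected-component particle analysis with a
physical-area cut-off, micrometer-calibrated morphological dilation, binary
mask algebra, and polygonal region-of-interest restriction.

Conventions, fixed so results are bit-reproducible:

* foreground is strictly greater than the threshold (``intensity > t``);
* threshold ties are broken toward the smallest candidate;
* histograms use equal-width bins over the observed range (256 by default);
* particle analysis uses 8-connectivity in 2-D;
* dilation is Euclidean, in-plane, applied independently per z-plane;
* ROI membership tests the pixel *center* against the polygon, with pixels
  whose center lies exactly on an edge counting as inside.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import measure

__all__ = [
    "ChannelRole",
    "CalibratedStack",
    "BinaryMask",
    "LabeledMask",
    "RegionOfInterest",
    "Histogram",
    "ThresholdResult",
    "DegenerateThresholdWarning",
    "intensity_histogram",
    "max_project",
    "sum_project",
    "otsu_threshold",
    "maxentropy_threshold",
    "binarize",
    "label_particles",
    "dilate_physical",
    "mask_and",
    "mask_subtract",
    "restrict_to_roi",
]


class ChannelRole(str, enum.Enum):
    """Which biological stain a channel carries."""

    PLAQUE_6E10 = "plaque_6e10"
    PLAQUE_MEX04 = "plaque_mex04"
    MICROGLIA = "microglia"
    LAMP1 = "lamp1"
    CD68 = "cd68"
    TAU_TOTAL = "tau_total"
    TAU_PHOSPHO = "tau_phospho"


class DegenerateThresholdWarning(UserWarning):
    """A histogram had fewer than two populated bins; foreground is empty."""


@dataclass
class CalibratedStack:
    """A (z, y, x) fluorescence stack with isotropic in-plane calibration.

    Parameters
    ----------
    voxels : ndarray
        Non-negative finite intensities, shape ``(z, y, x)``.
    pixel_size_um : float
        Physical edge length of one pixel in micrometers, > 0.
    channel_role : ChannelRole
        The stain this channel carries.
    """

    voxels: np.ndarray
    pixel_size_um: float
    channel_role: ChannelRole

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a (z, y, x) array, got ndim={self.voxels.ndim}")
        if any(s < 1 for s in self.voxels.shape):
            raise ValueError(f"all extents must be >= 1, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("intensities must be finite")
        if np.any(self.voxels < 0):
            raise ValueError("intensities must be non-negative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        self.channel_role = ChannelRole(self.channel_role)

    @property
    def n_planes(self) -> int:
        return self.voxels.shape[0]


@dataclass
class BinaryMask:
    """A boolean foreground mask carrying the source calibration."""

    bits: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")

    def area_um2(self) -> float:
        """Total foreground area (summed over planes for 3-D masks)."""
        return float(self.bits.sum()) * self.pixel_size_um**2


@dataclass
class LabeledMask:
    """Connected components surviving a physical-area cut-off.

    ``labels`` uses 0 for background and consecutive ids 1..K for retained
    components; ``areas_um2[k-1]`` is the physical area of component k.
    ``removed_mask`` holds the foreground pixels of components that fell
    below the cut-off, so retained | removed reconstructs the input.
    """

    labels: np.ndarray
    areas_um2: np.ndarray
    pixel_size_um: float
    removed_mask: np.ndarray

    @property
    def n_components(self) -> int:
        return int(len(self.areas_um2))

    def retained_mask(self) -> BinaryMask:
        return BinaryMask(self.labels > 0, self.pixel_size_um)


@dataclass
class RegionOfInterest:
    """A simple polygon (vertices as (y, x) pixel coordinates) naming an
    anatomical region such as the subiculum or CA1."""

    polygon: list[tuple[float, float]]
    name: str = "roi"
    _shape: Polygon = field(init=False, repr=False)

    def __post_init__(self) -> None:
        verts = [(float(y), float(x)) for y, x in self.polygon]
        if len(verts) < 3:
            raise ValueError("a region of interest needs at least 3 vertices")
        self.polygon = verts
        shp = Polygon([(x, y) for y, x in verts])  # shapely wants (x, y)
        if not shp.is_valid and shp.area > 0:
            raise ValueError(f"polygon for ROI {self.name!r} is self-intersecting")
        self._shape = shp

    def rasterize(self, shape_yx: tuple[int, int]) -> np.ndarray:
        """Boolean membership mask: pixel centers covered by the polygon.

        Raises ``ValueError`` if any vertex lies outside the image bounds.
        """
        ny, nx = shape_yx
        ys = np.array([v[0] for v in self.polygon])
        xs = np.array([v[1] for v in self.polygon])
        if ys.min() < -0.5 or xs.min() < -0.5 or ys.max() > ny - 0.5 or xs.max() > nx - 0.5:
            raise ValueError(
                f"ROI {self.name!r} extends outside the image bounds ({ny} x {nx})"
            )
        yy, xx = np.mgrid[0:ny, 0:nx]
        pts = shapely.points(xx.ravel().astype(float), yy.ravel().astype(float))
        inside = shapely.covers(self._shape, pts)  # boundary-inclusive
        return inside.reshape(ny, nx)


@dataclass
class Histogram:
    """Equal-width intensity histogram, the carrier for threshold search."""

    counts: np.ndarray
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        if self.counts.ndim != 1 or self.bin_edges.ndim != 1:
            raise ValueError("counts and bin_edges must be 1-D")
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("bin_edges must have len(counts) + 1 entries")
        if np.any(self.counts < 0):
            raise ValueError("histogram counts must be non-negative")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class ThresholdResult:
    """A threshold intensity plus a degeneracy flag.

    ``degenerate`` is True when the histogram had fewer than two populated
    bins, in which case ``threshold`` is the populated bin's upper edge and
    binarization yields an empty foreground. Blank control sections must not
    abort a batch run, so this is a warning condition, not an error.
    """

    threshold: float
    degenerate: bool = False


def intensity_histogram(values: np.ndarray, n_bins: int = 256) -> Histogram:
    """Histogram intensities into equal-width bins over the observed range.

    A constant input yields a single-bin histogram of unit width so the
    degenerate-threshold path is well defined.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("cannot histogram an empty pixel set")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        counts = np.array([values.size], dtype=np.int64)
        return Histogram(counts, np.array([lo, lo + 1.0]))
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    return Histogram(counts, edges)


def max_project(stack: CalibratedStack) -> np.ndarray:
    """Maximum z-projection of a stack."""
    return stack.voxels.max(axis=0)


def sum_project(stack: CalibratedStack) -> np.ndarray:
    """Sum z-projection, accumulated in float64 so wide stacks cannot overflow."""
    return stack.voxels.sum(axis=0, dtype=np.float64)


def _split_candidates(hist: Histogram) -> np.ndarray:
    """Indices k such that background = bins 0..k, foreground = bins k+1.."""
    return np.arange(hist.n_bins - 1)


def otsu_threshold(hist: Histogram) -> ThresholdResult:
    """Between-class-variance (Otsu) threshold on a histogram.

    Returns the bin edge ``t`` maximizing sigma^2_B(t) = w0 w1 (mu0 - mu1)^2
    over all splits, foreground being intensity > t, ties broken toward the
    smallest t. Histograms with fewer than two populated bins return a
    degenerate result (see :class:`ThresholdResult`).
    """
    populated = np.flatnonzero(hist.counts)
    if len(populated) < 2:
        return _degenerate_result(hist, populated)
    p = hist.counts / hist.counts.sum()
    c = hist.centers()
    w0 = np.cumsum(p)[:-1]  # background weight for split k
    w1 = 1.0 - w0
    m = np.cumsum(p * c)
    mu_total = m[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m[:-1] / w0
        mu1 = (mu_total - m[:-1]) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    k = int(np.argmax(sigma_b))  # argmax takes the first (smallest) maximizer
    return ThresholdResult(float(hist.bin_edges[k + 1]), False)


def maxentropy_threshold(hist: Histogram) -> ThresholdResult:
    """Kapur maximum-entropy threshold on a histogram.

    Maximizes the sum of Shannon entropies of the renormalized background
    and foreground histograms; same foreground convention, tie-break and
    degeneracy handling as :func:`otsu_threshold`.
    """
    populated = np.flatnonzero(hist.counts)
    if len(populated) < 2:
        return _degenerate_result(hist, populated)
    p = hist.counts / hist.counts.sum()
    plogp = np.zeros_like(p)
    nz = p > 0
    plogp[nz] = p[nz] * np.log(p[nz])
    cw = np.cumsum(p)
    cs = np.cumsum(plogp)
    w0 = cw[:-1]
    w1 = 1.0 - w0
    s_total = cs[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        h0 = np.log(w0) - cs[:-1] / w0
        h1 = np.log(w1) - (s_total - cs[:-1]) / w1
        crit = h0 + h1
    crit = np.where((w0 > 0) & (w1 > 0), crit, -np.inf)
    k = int(np.argmax(crit))
    return ThresholdResult(float(hist.bin_edges[k + 1]), False)


def _degenerate_result(hist: Histogram, populated: np.ndarray) -> ThresholdResult:
    idx = int(populated[0]) if len(populated) else hist.n_bins - 1
    t = float(hist.bin_edges[idx + 1])
    warnings.warn(
        "histogram has fewer than two populated bins; threshold is degenerate "
        "and the foreground is empty",
        DegenerateThresholdWarning,
        stacklevel=3,
    )
    return ThresholdResult(t, True)


def binarize(image: np.ndarray, t: float, pixel_size_um: float) -> BinaryMask:
    """Foreground mask of pixels strictly above the threshold."""
    return BinaryMask(np.asarray(image) > t, pixel_size_um)


def label_particles(mask: BinaryMask, min_area_um2: float = 0.0) -> LabeledMask:
    """Connected-component particle analysis with a physical-area cut-off.

    8-connected components (2-D) whose area in um^2 falls below
    ``min_area_um2`` are dropped and the survivors renumbered 1..K in scan
    order. The dropped pixels are preserved in ``removed_mask`` so the
    operation conserves foreground.
    """
    bits = mask.bits
    if bits.ndim != 2:
        raise ValueError("label_particles expects a 2-D mask (projection or plane)")
    lab, n = measure.label(bits, connectivity=2, return_num=True)
    px_area = mask.pixel_size_um**2
    if n == 0:
        return LabeledMask(
            labels=np.zeros_like(lab),
            areas_um2=np.empty(0),
            pixel_size_um=mask.pixel_size_um,
            removed_mask=np.zeros_like(bits),
        )
    counts = np.bincount(lab.ravel(), minlength=n + 1)[1:]
    areas = counts * px_area
    keep = areas >= min_area_um2
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[1:][keep] = np.arange(1, keep.sum() + 1)
    new_labels = remap[lab]
    removed = bits & (new_labels == 0)
    return LabeledMask(
        labels=new_labels,
        areas_um2=areas[keep],
        pixel_size_um=mask.pixel_size_um,
        removed_mask=removed,
    )


def dilate_physical(mask: BinaryMask, radius_um: float) -> BinaryMask:
    """Euclidean dilation by a physical radius, per z-plane.

    A pixel is foreground in the output iff the in-plane Euclidean distance
    (in um, center to center) to the nearest input foreground pixel is at
    most ``radius_um``. The input is always a subset of the output and
    radius 0 is the identity.
    """
    if radius_um < 0:
        raise ValueError("radius_um must be >= 0")
    bits = mask.bits
    if radius_um == 0 or not bits.any():
        return BinaryMask(bits.copy(), mask.pixel_size_um)
    planes = bits[None] if bits.ndim == 2 else bits
    out = np.empty_like(planes)
    s = (mask.pixel_size_um, mask.pixel_size_um)
    for i, plane in enumerate(planes):
        if not plane.any():
            out[i] = False
            continue
        dist = ndimage.distance_transform_edt(~plane, sampling=s)
        out[i] = dist <= radius_um
    return BinaryMask(out[0] if bits.ndim == 2 else out, mask.pixel_size_um)


def _check_compatible(a: BinaryMask, b: BinaryMask) -> None:
    if a.bits.shape != b.bits.shape:
        raise ValueError(f"mask shapes differ: {a.bits.shape} vs {b.bits.shape}")
    if a.pixel_size_um != b.pixel_size_um:
        raise ValueError("mask calibrations differ")


def mask_and(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Pixelwise intersection (the 'multiply binarized images' operation)."""
    _check_compatible(a, b)
    return BinaryMask(a.bits & b.bits, a.pixel_size_um)


def mask_subtract(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Pixels of ``a`` not in ``b`` (image subtraction of binary masks)."""
    _check_compatible(a, b)
    return BinaryMask(a.bits & ~b.bits, a.pixel_size_um)


def restrict_to_roi(
    array: np.ndarray, roi: RegionOfInterest
) -> tuple[np.ndarray, int]:
    """Zero out pixels outside the ROI polygon; return (restricted, roi_px).

    Works on 2-D images/masks and on 3-D stacks (the polygon is applied to
    every plane). The returned pixel count is the per-plane ROI area used as
    the denominator of area-fraction metrics. A sliver polygon covering no
    pixel centers yields an empty result with roi_px = 0.
    """
    array = np.asarray(array)
    shape_yx = array.shape[-2:]
    member = roi.rasterize(shape_yx)
    restricted = np.where(member, array, np.zeros((), dtype=array.dtype))
    return restricted, int(member.sum())
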