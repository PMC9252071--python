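"""Region-restricted pathology readouts of plaque, neurite and microglia stains.

Each public function composes the primitives in :mod:`gliaquant.imaging`
with fixed parameters into one of the study readouts:

* plaque burden (area fraction, count, mean size) from an amyloid channel;
* the dense-core / total amyloid ratio (Methoxy-X04 vs 6E10);
* plaque-associated dystrophic-neurite load (non-microglial LAMP1 inside a
  25 um plaque halo, normalized to plaque area);
* microglial coverage and plaque-associated microglia (5 um halo);
* CD68-positive fraction of the microglial mask (activation proxy);
* background-subtracted homeostatic-marker intensity (P2RY12-style);
* phospho/total tau area-fraction ratios.

Thresholds are computed per region of interest: the histogram is built from
ROI pixels only (pooled over z for stack metrics) and the resulting single
threshold is applied plane-wise. Undefined ratios (zero denominator) are
reported as NaN with a reason flag, never as 0, so they cannot bias group
means downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import (
    BinaryMask,
    CalibratedStack,
    RegionOfInterest,
    ThresholdResult,
    binarize,
    dilate_physical,
    intensity_histogram,
    label_particles,
    mask_and,
    mask_subtract,
    max_project,
    maxentropy_threshold,
    otsu_threshold,
    restrict_to_roi,
    sum_project,
)

__all__ = [
    "PlaqueParams",
    "MetricValue",
    "MetricReport",
    "plaque_burden",
    "mex04_ratio",
    "neuritic_damage_ratio",
    "microglia_coverage",
    "plaque_associated_microglia",
    "cd68_in_microglia",
    "background_subtracted_intensity",
    "tau_epitope_ratio",
]

N_BINS = 256


@dataclass(frozen=True)
class PlaqueParams:
    """Fixed physical parameters of the plaque readouts.

    min_plaque_area_um2
        Particle-analysis cut-off below which a thresholded object does not
        count as a plaque (default 50 um^2).
    neurite_halo_um
        Dilation radius around detected plaques that defines the peri-plaque
        tissue searched for dystrophic (LAMP1+) neurites (default 25 um).
    microglia_assoc_halo_um
        Dilation radius defining plaque-associated microglia (default 5 um).
    """

    min_plaque_area_um2: float = 50.0
    neurite_halo_um: float = 25.0
    microglia_assoc_halo_um: float = 5.0

    def __post_init__(self) -> None:
        if min(self.min_plaque_area_um2, self.neurite_halo_um, self.microglia_assoc_halo_um) <= 0:
            raise ValueError("all plaque parameters must be > 0")


@dataclass
class MetricValue:
    """One named scalar metric with its degeneracy/missingness flag."""

    name: str
    value: float  # NaN when undefined
    flag: str = ""  # "", "degenerate_threshold", "zero_denominator", ...


@dataclass
class MetricReport:
    """Long-format accumulator: one row per (image, region, metric)."""

    rows: list[dict] = field(default_factory=list)

    def add(self, image_id: str, region: str, metrics: list[MetricValue]) -> None:
        for m in metrics:
            self.rows.append(
                {
                    "image": image_id,
                    "region": region,
                    "metric": m.name,
                    "value": m.value,
                    "flag": m.flag,
                }
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["image", "region", "metric", "value", "flag"])


def _roi_threshold(
    pixels: np.ndarray, method: str
) -> ThresholdResult:
    hist = intensity_histogram(pixels, N_BINS)
    if method == "otsu":
        return otsu_threshold(hist)
    if method == "maxentropy":
        return maxentropy_threshold(hist)
    raise ValueError(f"unknown threshold method {method!r}")


def _threshold_projection(
    image: np.ndarray,
    roi: RegionOfInterest,
    pixel_size_um: float,
    method: str = "otsu",
) -> tuple[BinaryMask, int, ThresholdResult]:
    """Threshold a 2-D image on its ROI histogram; return the ROI-restricted
    foreground mask, the ROI pixel count and the threshold result."""
    member = roi.rasterize(image.shape)
    roi_px = int(member.sum())
    if roi_px == 0:
        return BinaryMask(np.zeros_like(member), pixel_size_um), 0, ThresholdResult(0.0, True)
    res = _roi_threshold(image[member], method)
    fg = binarize(image, res.threshold, pixel_size_um)
    if res.degenerate:
        fg = BinaryMask(np.zeros_like(member), pixel_size_um)
    fg.bits &= member
    return fg, roi_px, res


def _threshold_stack(
    stack: CalibratedStack,
    roi: RegionOfInterest,
    method: str = "otsu",
) -> tuple[BinaryMask, int, ThresholdResult]:
    """One threshold from the pooled ROI histogram of all planes, applied
    plane-wise; mask is ROI-restricted in every plane."""
    member = roi.rasterize(stack.voxels.shape[1:])
    roi_px = int(member.sum())
    if roi_px == 0:
        empty = np.zeros_like(stack.voxels, dtype=bool)
        return BinaryMask(empty, stack.pixel_size_um), 0, ThresholdResult(0.0, True)
    res = _roi_threshold(stack.voxels[:, member], method)
    if res.degenerate:
        bits = np.zeros_like(stack.voxels, dtype=bool)
    else:
        bits = (stack.voxels > res.threshold) & member[None]
    return BinaryMask(bits, stack.pixel_size_um), roi_px, res


def plaque_burden(
    plaque_stack: CalibratedStack,
    roi: RegionOfInterest,
    params: PlaqueParams = PlaqueParams(),
) -> list[MetricValue]:
    """Plaque area fraction, count and mean size within the ROI.

    The amyloid channel is max-projected, Otsu-thresholded on the ROI
    histogram, and binarized. The area fraction counts *all* suprathreshold
    ROI pixels; the count and the mean size come from particle analysis with
    the physical cut-off, so sub-cut-off specks contribute to area fraction
    but not to plaque number or size.
    """
    proj = max_project(plaque_stack)
    fg, roi_px, res = _threshold_projection(proj, roi, plaque_stack.pixel_size_um)
    if res.degenerate or roi_px == 0:
        flag = "degenerate_threshold"
        return [
            MetricValue("plaque_area_fraction", 0.0, flag),
            MetricValue("plaque_count", 0.0, flag),
            MetricValue("plaque_mean_size_um2", 0.0, flag),
        ]
    frac = float(fg.bits.sum()) / roi_px
    labeled = label_particles(fg, params.min_plaque_area_um2)
    count = labeled.n_components
    mean_size = float(labeled.areas_um2.mean()) if count else 0.0
    return [
        MetricValue("plaque_area_fraction", frac),
        MetricValue("plaque_count", float(count)),
        MetricValue("plaque_mean_size_um2", mean_size, "" if count else "no_particles"),
    ]


def mex04_ratio(
    mex04_stack: CalibratedStack,
    e6e10_stack: CalibratedStack,
    roi: RegionOfInterest,
) -> list[MetricValue]:
    """Dense-core amyloid fraction (Methoxy-X04, max-entropy threshold) and
    its ratio to total amyloid (6E10, Otsu threshold)."""
    if mex04_stack.voxels.shape != e6e10_stack.voxels.shape:
        raise ValueError("MeX04 and 6E10 stacks must share shape")
    mex_fg, roi_px, mex_res = _threshold_projection(
        max_project(mex04_stack), roi, mex04_stack.pixel_size_um, "maxentropy"
    )
    e_fg, _, e_res = _threshold_projection(
        max_project(e6e10_stack), roi, e6e10_stack.pixel_size_um, "otsu"
    )
    flag = "degenerate_threshold" if (mex_res.degenerate or e_res.degenerate) else ""
    mex_px = int(mex_fg.bits.sum())
    e_px = int(e_fg.bits.sum())
    frac = mex_px / roi_px if roi_px else 0.0
    out = [MetricValue("mex04_area_fraction", frac, flag)]
    if e_px == 0:
        out.append(MetricValue("mex04_over_6e10", float("nan"), flag or "zero_denominator"))
    else:
        out.append(MetricValue("mex04_over_6e10", mex_px / e_px, flag))
    return out


def _filtered_plaque_planes(
    plaque_mask: BinaryMask, min_area_um2: float
) -> BinaryMask:
    """Per-plane particle filtering of a 3-D plaque mask."""
    planes = [
        label_particles(BinaryMask(p, plaque_mask.pixel_size_um), min_area_um2).labels > 0
        for p in plaque_mask.bits
    ]
    return BinaryMask(np.stack(planes), plaque_mask.pixel_size_um)


def neuritic_damage_ratio(
    plaque_stack: CalibratedStack,
    lamp1_stack: CalibratedStack,
    microglia_stack: CalibratedStack,
    roi: RegionOfInterest,
    params: PlaqueParams = PlaqueParams(),
    denominator: str = "filtered",
) -> MetricValue:
    """Ratio of plaque-associated non-microglial LAMP1 to plaque area.

    Per z-plane: the amyloid channel is thresholded and binarized, detected
    particles (>= cut-off) are dilated by ``neurite_halo_um`` to capture the
    surrounding tissue; LAMP1 overlapping the microglial mask is subtracted
    out (lysosomal LAMP1 inside microglia is not neuritic damage); the
    remaining LAMP1 inside the dilated halo is summed over planes and
    divided by the non-dilated plaque pixel count.

    ``denominator`` selects whether the plaque pixel count uses the
    particle-filtered mask (default, consistent with the dilation source) or
    all suprathreshold pixels (``"all"``).
    """
    if not (
        plaque_stack.voxels.shape == lamp1_stack.voxels.shape == microglia_stack.voxels.shape
    ):
        raise ValueError("all three stacks must share shape")
    if denominator not in ("filtered", "all"):
        raise ValueError("denominator must be 'filtered' or 'all'")
    plaque_fg, _, p_res = _threshold_stack(plaque_stack, roi)
    lamp1_fg, _, _ = _threshold_stack(lamp1_stack, roi)
    mg_fg, _, _ = _threshold_stack(microglia_stack, roi)
    if p_res.degenerate:
        return MetricValue("lamp1_per_plaque", float("nan"), "degenerate_threshold")
    plaques = _filtered_plaque_planes(plaque_fg, params.min_plaque_area_um2)
    halo = dilate_physical(plaques, params.neurite_halo_um)
    non_mg_lamp1 = mask_subtract(lamp1_fg, mg_fg)
    numerator = int(mask_and(non_mg_lamp1, halo).bits.sum())
    denom_mask = plaques if denominator == "filtered" else plaque_fg
    denom = int(denom_mask.bits.sum())
    if denom == 0:
        return MetricValue("lamp1_per_plaque", float("nan"), "zero_denominator")
    return MetricValue("lamp1_per_plaque", numerator / denom)


def microglia_coverage(
    microglia_stack: CalibratedStack, roi: RegionOfInterest
) -> MetricValue:
    """Fraction of the ROI volume occupied by thresholded microglial signal."""
    fg, roi_px, res = _threshold_stack(microglia_stack, roi)
    if res.degenerate or roi_px == 0:
        return MetricValue("microglia_coverage", 0.0, "degenerate_threshold")
    frac = float(fg.bits.sum()) / (roi_px * microglia_stack.n_planes)
    return MetricValue("microglia_coverage", frac)


def plaque_associated_microglia(
    plaque_stack: CalibratedStack,
    microglia_stack: CalibratedStack,
    roi: RegionOfInterest,
    params: PlaqueParams = PlaqueParams(),
) -> MetricValue:
    """Fraction of microglial pixels lying within 5 um of thresholded plaque
    (microglial recruitment to plaques), summed over z-planes."""
    if plaque_stack.voxels.shape != microglia_stack.voxels.shape:
        raise ValueError("stacks must share shape")
    plaque_fg, _, p_res = _threshold_stack(plaque_stack, roi)
    mg_fg, _, m_res = _threshold_stack(microglia_stack, roi)
    mg_px = int(mg_fg.bits.sum())
    if m_res.degenerate or mg_px == 0:
        return MetricValue("plaque_associated_microglia", float("nan"), "zero_denominator")
    if p_res.degenerate:
        return MetricValue("plaque_associated_microglia", 0.0, "degenerate_threshold")
    halo = dilate_physical(plaque_fg, params.microglia_assoc_halo_um)
    overlap = int(mask_and(mg_fg, halo).bits.sum())
    return MetricValue("plaque_associated_microglia", overlap / mg_px)


def cd68_in_microglia(
    cd68_stack: CalibratedStack,
    microglia_stack: CalibratedStack,
    roi: RegionOfInterest,
) -> MetricValue:
    """Fraction of the microglial mask positive for CD68 (activation proxy)."""
    if cd68_stack.voxels.shape != microglia_stack.voxels.shape:
        raise ValueError("stacks must share shape")
    cd68_fg, _, c_res = _threshold_stack(cd68_stack, roi)
    mg_fg, _, m_res = _threshold_stack(microglia_stack, roi)
    mg_px = int(mg_fg.bits.sum())
    if m_res.degenerate or mg_px == 0:
        return MetricValue("cd68_in_microglia", float("nan"), "zero_denominator")
    if c_res.degenerate:
        return MetricValue("cd68_in_microglia", 0.0, "degenerate_threshold")
    overlap = int(mask_and(cd68_fg, mg_fg).bits.sum())
    return MetricValue("cd68_in_microglia", overlap / mg_px)


def background_subtracted_intensity(
    stack: CalibratedStack,
    roi: RegionOfInterest,
    suprathreshold_only: bool = True,
) -> MetricValue:
    """Mean background-subtracted marker intensity on the z-sum projection.

    The projection is Otsu-thresholded on the ROI histogram; the mean of the
    sub-threshold (marker-negative) ROI pixels defines the background level,
    which is subtracted from the projection (clipped at zero). The reported
    value is the mean over suprathreshold ROI pixels by default, or over the
    whole ROI when ``suprathreshold_only`` is False.
    """
    proj = sum_project(stack)
    member = roi.rasterize(proj.shape)
    roi_px = int(member.sum())
    if roi_px == 0:
        return MetricValue("marker_intensity", 0.0, "empty_roi")
    res = _roi_threshold(proj[member], "otsu")
    if res.degenerate:
        return MetricValue("marker_intensity", 0.0, "degenerate_threshold")
    below = member & ~(proj > res.threshold)
    background = float(proj[below].mean()) if below.any() else 0.0
    corrected = np.maximum(proj - background, 0.0)
    sel = (member & (proj > res.threshold)) if suprathreshold_only else member
    if not sel.any():
        return MetricValue("marker_intensity", 0.0, "empty_foreground")
    return MetricValue("marker_intensity", float(corrected[sel].mean()))


def tau_epitope_ratio(
    phospho_stack: CalibratedStack,
    total_tau_stack: CalibratedStack,
    roi: RegionOfInterest,
) -> list[MetricValue]:
    """Phospho-tau and total-tau area fractions and their ratio.

    Both channels are max-projected, Otsu-thresholded per ROI and binarized;
    no particle-size cut-off applies. The ratio normalizes each phospho
    epitope's area fraction to the total-tau area fraction.
    """
    if phospho_stack.voxels.shape != total_tau_stack.voxels.shape:
        raise ValueError("stacks must share shape")
    p_fg, roi_px, p_res = _threshold_projection(
        max_project(phospho_stack), roi, phospho_stack.pixel_size_um
    )
    t_fg, _, t_res = _threshold_projection(
        max_project(total_tau_stack), roi, total_tau_stack.pixel_size_um
    )
    flag = "degenerate_threshold" if (p_res.degenerate or t_res.degenerate) else ""
    p_frac = float(p_fg.bits.sum()) / roi_px if roi_px else 0.0
    t_frac = float(t_fg.bits.sum()) / roi_px if roi_px else 0.0
    out = [
        MetricValue("phospho_tau_area_fraction", p_frac, flag),
        MetricValue("total_tau_area_fraction", t_frac, flag),
    ]
    if t_frac == 0:
        out.append(MetricValue("phospho_over_total_tau", float("nan"), flag or "zero_denominator"))
    else:
        out.append(MetricValue("phospho_over_total_tau", p_frac / t_frac, flag))
    return out
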