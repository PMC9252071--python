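"""Seeded synthetic data: fluorescence scenes and count matrices with truth.

The image generator renders the channel geometry the pathology metrics
assume: amyloid plaques as bright compact disks with dimmer diffuse halos on
a noisy background, microglial blobs overlapping plaque margins, LAMP1
annuli concentric with plaques and partly overlapping microglia, and CD68
puncta inside microglia. Noise is additive Gaussian (clipped at zero), a
reasonable desk-scale stand-in for confocal shot noise at these intensities.
Geometry is constant across z-planes; noise varies per plane.

The matrix generator draws negative-binomial counts with designated
mitochondrial and ribosomal genes and plants three kinds of low-quality
cells (low-feature, high-count, high-mito) plus fold-change marker genes,
with truth labels exported for oracle tests.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import CalibratedStack, ChannelRole
from .scrna import CountMatrix

__all__ = [
    "PlaqueSpec",
    "SceneSpec",
    "GroundTruth",
    "render_scene",
    "random_scene_spec",
    "MatrixSpec",
    "MatrixTruth",
    "sample_matrix",
]


# ---------------------------------------------------------------------------
# imaging scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlaqueSpec:
    """One plaque: a bright core disk plus a dimmer diffuse halo ring."""

    center_yx: tuple[float, float]
    core_radius_um: float
    halo_radius_um: float  # outer radius of the diffuse halo
    core_intensity: float
    halo_intensity: float


@dataclass
class SceneSpec:
    """Deterministic description of a multi-channel synthetic scene.

    Default intensities put the plaque core five noise standard deviations
    above the background mean (SNR 5), with halos one SD above background.
    """

    shape: tuple[int, int, int] = (3, 256, 256)
    pixel_size_um: float = 1.0
    plaques: list[PlaqueSpec] = field(default_factory=list)
    n_microglia: int = 8
    microglia_radius_um: float = 10.0
    microglia_intensity: float = 60.0
    lamp1_inner_factor: float = 1.1  # annulus radii relative to core radius
    lamp1_outer_factor: float = 1.8
    lamp1_intensity: float = 60.0
    cd68_puncta_per_cell: int = 4
    cd68_radius_um: float = 1.5
    cd68_intensity: float = 60.0
    background_mean: float = 20.0
    noise_sd: float = 8.0
    seed: int = 0


@dataclass
class GroundTruth:
    """Noiseless geometric truth of a rendered scene.

    Masks are 2-D (geometry is constant over z). ``plaque_core_areas_um2``
    lists every planted core's area from the rasterized geometry;
    ``n_plaques_above`` counts cores at or above ``min_area_um2``.
    """

    plaque_core_mask: np.ndarray
    plaque_halo_mask: np.ndarray
    microglia_mask: np.ndarray
    lamp1_mask: np.ndarray
    cd68_mask: np.ndarray
    plaque_core_areas_um2: list[float]
    plaque_centers: list[tuple[float, float]]
    pixel_size_um: float

    def area_fraction(self) -> float:
        return float(self.plaque_core_mask.mean())

    def n_plaques_above(self, min_area_um2: float) -> int:
        return sum(a >= min_area_um2 for a in self.plaque_core_areas_um2)


def _disk(shape_yx: tuple[int, int], center: tuple[float, float], radius_px: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape_yx[0], 0 : shape_yx[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px**2


def render_scene(spec: SceneSpec) -> tuple[dict[ChannelRole, CalibratedStack], GroundTruth]:
    """Render the channel stacks of a scene plus its geometric ground truth.

    The same noiseless geometry underlies every z-plane; independent
    Gaussian noise is added per voxel. Raises ``ValueError`` when an object
    extends outside the image.
    """
    nz, ny, nx = spec.shape
    px = spec.pixel_size_um
    rng = np.random.default_rng(spec.seed)

    core = np.zeros((ny, nx), dtype=bool)
    halo = np.zeros((ny, nx), dtype=bool)
    lamp1 = np.zeros((ny, nx), dtype=bool)
    areas, centers = [], []
    for p in spec.plaques:
        cy, cx = p.center_yx
        r_out = max(p.halo_radius_um, p.core_radius_um * spec.lamp1_outer_factor) / px
        if cy - r_out < -0.5 or cx - r_out < -0.5 or cy + r_out > ny - 0.5 or cx + r_out > nx - 0.5:
            raise ValueError(f"plaque at {p.center_yx} extends outside the image")
        d_core = _disk((ny, nx), (cy, cx), p.core_radius_um / px)
        d_halo = _disk((ny, nx), (cy, cx), p.halo_radius_um / px) & ~d_core
        core |= d_core
        halo |= d_halo
        inner = _disk((ny, nx), (cy, cx), p.core_radius_um * spec.lamp1_inner_factor / px)
        outer = _disk((ny, nx), (cy, cx), p.core_radius_um * spec.lamp1_outer_factor / px)
        lamp1 |= outer & ~inner
        areas.append(float(d_core.sum()) * px**2)
        centers.append((cy, cx))

    # microglial blobs: half near plaque margins (recruitment), half free
    microglia = np.zeros((ny, nx), dtype=bool)
    r_mg = spec.microglia_radius_um / px
    mg_centers = []
    for i in range(spec.n_microglia):
        if centers and i % 2 == 0:
            cy, cx = centers[i // 2 % len(centers)]
            ang = rng.uniform(0, 2 * np.pi)
            rad = spec.plaques[i // 2 % len(centers)].core_radius_um / px + 0.5 * r_mg
            my, mx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
        else:
            my = rng.uniform(r_mg, ny - 1 - r_mg)
            mx = rng.uniform(r_mg, nx - 1 - r_mg)
        my = float(np.clip(my, r_mg, ny - 1 - r_mg))
        mx = float(np.clip(mx, r_mg, nx - 1 - r_mg))
        microglia |= _disk((ny, nx), (my, mx), r_mg)
        mg_centers.append((my, mx))

    cd68 = np.zeros((ny, nx), dtype=bool)
    r_cd = spec.cd68_radius_um / px
    for my, mx in mg_centers:
        for _ in range(spec.cd68_puncta_per_cell):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, 0.7 * r_mg)
            cd68 |= _disk((ny, nx), (my + rad * np.sin(ang), mx + rad * np.cos(ang)), r_cd)
    cd68 &= microglia  # puncta live inside microglia

    def render(mask_vals: list[tuple[np.ndarray, float]], role: ChannelRole) -> CalibratedStack:
        base = np.full((ny, nx), spec.background_mean)
        for m, v in mask_vals:
            base[m] = v
        vox = base[None] + rng.normal(0.0, spec.noise_sd, size=(nz, ny, nx))
        return CalibratedStack(np.clip(vox, 0, None), px, role)

    plaque_levels = [(halo, spec.plaques[0].halo_intensity if spec.plaques else 0.0)]
    # per-plaque core intensity (halos share the first plaque's level for simplicity)
    base_core = np.full((ny, nx), spec.background_mean)
    base_core[halo] = spec.plaques[0].halo_intensity if spec.plaques else spec.background_mean
    for p in spec.plaques:
        d = _disk((ny, nx), p.center_yx, p.core_radius_um / px)
        base_core[d] = p.core_intensity
    vox = base_core[None] + rng.normal(0.0, spec.noise_sd, size=(nz, ny, nx))
    plaque_stack = CalibratedStack(np.clip(vox, 0, None), px, ChannelRole.PLAQUE_6E10)

    mex_stack_src = rng.normal(0.0, spec.noise_sd, size=(nz, ny, nx))
    mex_base = np.full((ny, nx), spec.background_mean)
    for p in spec.plaques:  # dense cores only: MeX04 labels fibrillar amyloid
        d = _disk((ny, nx), p.center_yx, 0.7 * p.core_radius_um / px)
        mex_base[d] = p.core_intensity
    mex_stack = CalibratedStack(np.clip(mex_base[None] + mex_stack_src, 0, None), px,
                                ChannelRole.PLAQUE_MEX04)

    channels = {
        ChannelRole.PLAQUE_6E10: plaque_stack,
        ChannelRole.PLAQUE_MEX04: mex_stack,
        ChannelRole.MICROGLIA: render([(microglia, spec.microglia_intensity)], ChannelRole.MICROGLIA),
        ChannelRole.LAMP1: render([(lamp1, spec.lamp1_intensity)], ChannelRole.LAMP1),
        ChannelRole.CD68: render([(cd68, spec.cd68_intensity)], ChannelRole.CD68),
    }
    truth = GroundTruth(
        plaque_core_mask=core,
        plaque_halo_mask=halo,
        microglia_mask=microglia,
        lamp1_mask=lamp1,
        cd68_mask=cd68,
        plaque_core_areas_um2=areas,
        plaque_centers=centers,
        pixel_size_um=px,
    )
    return channels, truth


def random_scene_spec(
    seed: int,
    n_plaques: int = 5,
    n_small: int = 3,
    shape: tuple[int, int, int] = (3, 256, 256),
    pixel_size_um: float = 1.0,
    snr: float = 5.0,
    small_radius_um: float = 3.0,
) -> SceneSpec:
    """A randomized scene with ``n_plaques`` large plaques (cores well above
    the 50 um^2 particle cut-off) and ``n_small`` bright sub-cut-off specks,
    placed without overlap. SNR is (core - background) / noise SD."""
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    background, noise_sd = 20.0, 8.0
    core_i = background + snr * noise_sd
    plaques: list[PlaqueSpec] = []
    placed: list[tuple[float, float, float]] = []
    margin = 40.0 / pixel_size_um

    def place(radius_um: float) -> tuple[float, float]:
        r = radius_um / pixel_size_um
        for _ in range(10_000):
            cy = rng.uniform(margin, ny - 1 - margin)
            cx = rng.uniform(margin, nx - 1 - margin)
            if all((cy - y) ** 2 + (cx - x) ** 2 > (r + rr + 8) ** 2 for y, x, rr in placed):
                placed.append((cy, cx, r))
                return cy, cx
        raise RuntimeError("could not place all objects without overlap")

    for _ in range(n_plaques):
        r = rng.uniform(9.0, 14.0)
        cy, cx = place(2.0 * r)
        plaques.append(PlaqueSpec((cy, cx), r, 1.8 * r, core_i, background + noise_sd))
    for _ in range(n_small):
        cy, cx = place(2.0 * small_radius_um)
        plaques.append(
            PlaqueSpec((cy, cx), small_radius_um, 1.5 * small_radius_um, core_i,
                       background + noise_sd)
        )
    return SceneSpec(
        shape=shape,
        pixel_size_um=pixel_size_um,
        plaques=plaques,
        background_mean=background,
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

@dataclass
class MatrixSpec:
    """Negative-binomial count matrix with planted QC failures and markers.

    Gene means are log-uniform on [mean_lo, mean_hi]; the NB dispersion
    parameter ``theta`` gives variance mu + mu^2/theta. Marker genes have
    their mean multiplied by ``marker_fold`` in group B. Planted bad cells:
    low-feature cells express ~120 genes at one count each; high-count cells
    are scaled by ``high_count_factor``; high-mito cells have mitochondrial
    counts boosted to roughly twice the QC ceiling.
    """

    n_genes: int = 500
    n_cells_per_group: tuple[int, int] = (150, 150)
    mean_lo: float = 1.0
    mean_hi: float = 10.0
    theta: float = 10.0
    n_mito: int = 10
    n_ribo: int = 20
    mito_share: float = 0.02  # expected mito fraction in healthy cells
    n_low_feature: int = 0
    n_high_count: int = 0
    n_high_mito: int = 0
    low_feature_genes: int = 120
    high_count_factor: float = 6.0
    high_mito_fraction: float = 0.10
    marker_genes: int = 0
    marker_fold: float = 4.0
    group_names: tuple[str, str] = ("control", "repopulated")
    seed: int = 0


@dataclass
class MatrixTruth:
    """Truth labels: planted bad cells per criterion and marker gene names."""

    low_feature_cells: list[str]
    high_count_cells: list[str]
    high_mito_cells: list[str]
    marker_gene_names: list[str]

    def bad_cells(self) -> set[str]:
        return set(self.low_feature_cells) | set(self.high_count_cells) | set(self.high_mito_cells)

    def to_frame(self) -> pd.DataFrame:
        rows = [("low_feature", c) for c in self.low_feature_cells]
        rows += [("high_count", c) for c in self.high_count_cells]
        rows += [("high_mito", c) for c in self.high_mito_cells]
        rows += [("marker_gene", g) for g in self.marker_gene_names]
        return pd.DataFrame(rows, columns=["kind", "id"])


def sample_matrix(spec: MatrixSpec) -> tuple[CountMatrix, MatrixTruth]:
    """Draw a genes x cells count matrix per the spec; deterministic in seed."""
    rng = np.random.default_rng(spec.seed)
    n_genes = spec.n_genes
    n_a, n_b = spec.n_cells_per_group
    n_cells = n_a + n_b
    if spec.n_mito + spec.n_ribo + spec.marker_genes > n_genes:
        raise ValueError("designated gene classes exceed n_genes")

    symbols = np.array([f"Gene{i:04d}" for i in range(n_genes)], dtype=object)
    mito_idx = np.arange(spec.n_mito)
    ribo_idx = np.arange(spec.n_mito, spec.n_mito + spec.n_ribo)
    symbols[mito_idx] = [f"mt-Gene{i}" for i in range(spec.n_mito)]
    half = spec.n_ribo // 2
    symbols[ribo_idx[:half]] = [f"Rps{i}" for i in range(half)]
    symbols[ribo_idx[half:]] = [f"Rpl{i}" for i in range(spec.n_ribo - half)]

    means = np.exp(rng.uniform(np.log(spec.mean_lo), np.log(spec.mean_hi), size=n_genes))
    if spec.n_mito:
        # scale mito means so the expected mito fraction matches mito_share
        other = means[spec.n_mito:].sum()
        means[mito_idx] = spec.mito_share * other / (1 - spec.mito_share) / spec.n_mito

    marker_idx = np.array([], dtype=int)
    if spec.marker_genes:
        candidates = np.arange(spec.n_mito + spec.n_ribo, n_genes)
        marker_idx = rng.choice(candidates, size=spec.marker_genes, replace=False)

    mu = np.tile(means[:, None], (1, n_cells))
    mu[np.ix_(marker_idx, np.arange(n_a, n_cells))] *= spec.marker_fold
    p = spec.theta / (spec.theta + mu)
    counts = rng.negative_binomial(spec.theta, p)

    cell_ids = np.array(
        [f"{spec.group_names[0]}_{i:04d}" for i in range(n_a)]
        + [f"{spec.group_names[1]}_{i:04d}" for i in range(n_b)],
        dtype=object,
    )
    groups = np.array([spec.group_names[0]] * n_a + [spec.group_names[1]] * n_b, dtype=object)

    n_planted = spec.n_low_feature + spec.n_high_count + spec.n_high_mito
    if n_planted > n_cells:
        raise ValueError("more planted bad cells than cells")
    planted = rng.choice(n_cells, size=n_planted, replace=False)
    lf = planted[: spec.n_low_feature]
    hc = planted[spec.n_low_feature : spec.n_low_feature + spec.n_high_count]
    hm = planted[spec.n_low_feature + spec.n_high_count :]

    non_mito = np.setdiff1d(np.arange(n_genes), mito_idx)
    for c in lf:
        counts[:, c] = 0
        expressed = rng.choice(non_mito, size=spec.low_feature_genes, replace=False)
        counts[expressed, c] = 1
    for c in hc:
        counts[:, c] = counts[:, c] * spec.high_count_factor
    for c in hm:
        total_other = counts[non_mito, c].sum()
        target = spec.high_mito_fraction
        mito_total = int(np.ceil(target / (1 - target) * total_other)) + spec.n_mito
        per_gene = np.full(spec.n_mito, mito_total // spec.n_mito)
        per_gene[: mito_total % spec.n_mito] += 1
        counts[mito_idx, c] = per_gene

    matrix = CountMatrix(
        counts=counts.astype(np.int64),
        gene_symbols=symbols,
        cell_ids=cell_ids,
        cell_group=groups,
    )
    truth = MatrixTruth(
        low_feature_cells=[str(cell_ids[c]) for c in lf],
        high_count_cells=[str(cell_ids[c]) for c in hc],
        high_mito_cells=[str(cell_ids[c]) for c in hm],
        marker_gene_names=[str(symbols[g]) for g in np.sort(marker_idx)],
    )
    return matrix, truth
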