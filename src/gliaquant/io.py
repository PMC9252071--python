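"""File-format plumbing: TIFF stacks, ROI polygons, count matrices.

Pixel size always comes from the run configuration, never from TIFF
metadata, so that a single calibration governs an entire batch.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import io as scipy_io
from scipy import sparse

from .imaging import BinaryMask, CalibratedStack, ChannelRole, RegionOfInterest
from .scrna import CountMatrix

__all__ = [
    "load_stack",
    "save_stack",
    "save_mask_tiff",
    "load_rois",
    "save_rois",
    "load_count_matrix",
    "save_count_matrix",
]


def load_stack(path: str | Path, pixel_size_um: float, channel_role: str | ChannelRole) -> CalibratedStack:
    """Read a (multi-page) TIFF as a calibrated stack; 2-D files become
    single-plane stacks."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 2-D or 3-D TIFF, got ndim={arr.ndim}")
    return CalibratedStack(arr.astype(np.float64), pixel_size_um, ChannelRole(channel_role))


def save_stack(stack: CalibratedStack, path: str | Path) -> None:
    tifffile.imwrite(str(path), stack.voxels.astype(np.float32))


def save_mask_tiff(mask: BinaryMask, path: str | Path) -> None:
    """Export a mask as 8-bit 0/255 TIFF for visual audit."""
    tifffile.imwrite(str(path), (mask.bits.astype(np.uint8) * 255))


def load_rois(path: str | Path) -> dict[str, RegionOfInterest]:
    """ROI polygons from JSON: {"name": [[y, x], ...], ...}."""
    with open(path) as fh:
        data = json.load(fh)
    return {name: RegionOfInterest([(y, x) for y, x in verts], name)
            for name, verts in data.items()}


def save_rois(rois: dict[str, RegionOfInterest], path: str | Path) -> None:
    data = {name: [[y, x] for y, x in roi.polygon] for name, roi in rois.items()}
    with open(path, "w") as fh:
        json.dump(data, fh)


def load_count_matrix(
    counts_path: str | Path, labels_path: str | Path | None = None
) -> CountMatrix:
    """Load a genes x cells matrix.

    ``counts_path`` is either a directory holding sparse triplet files
    (matrix.mtx, genes.tsv, barcodes.tsv) or a dense CSV with gene symbols
    as the index and cell ids as columns. ``labels_path`` is an optional CSV
    with columns cell_id, group[, cluster].
    """
    counts_path = Path(counts_path)
    if counts_path.is_dir():
        mat = scipy_io.mmread(str(counts_path / "matrix.mtx")).tocsr().astype(np.int64)
        genes = pd.read_csv(counts_path / "genes.tsv", sep="\t", header=None)[0].to_numpy(object)
        cells = pd.read_csv(counts_path / "barcodes.tsv", sep="\t", header=None)[0].to_numpy(object)
    else:
        df = pd.read_csv(counts_path, index_col=0)
        mat = df.to_numpy(dtype=np.int64)
        genes = df.index.to_numpy(object)
        cells = df.columns.to_numpy(object)
    group = cluster = None
    if labels_path is not None:
        labels = pd.read_csv(labels_path).set_index("cell_id").reindex(cells)
        if labels["group"].isna().any():
            missing = [str(c) for c in labels.index[labels["group"].isna()][:5]]
            raise ValueError(f"labels file missing entries for cells such as {missing}")
        group = labels["group"].to_numpy(object)
        if "cluster" in labels.columns:
            cluster = labels["cluster"].to_numpy(object)
    return CountMatrix(mat, genes, cells, cell_group=group, cell_cluster=cluster)


def save_count_matrix(matrix: CountMatrix, out_dir: str | Path) -> None:
    """Write sparse triplet files plus a labels CSV when labels exist."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = matrix.counts if sparse.issparse(matrix.counts) else sparse.coo_matrix(matrix.counts)
    scipy_io.mmwrite(str(out / "matrix.mtx"), counts, field="integer")
    pd.Series(matrix.gene_symbols).to_csv(out / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(matrix.cell_ids).to_csv(out / "barcodes.tsv", sep="\t", header=False, index=False)
    if matrix.cell_group is not None:
        labels = pd.DataFrame({"cell_id": matrix.cell_ids, "group": matrix.cell_group})
        if matrix.cell_cluster is not None:
            labels["cluster"] = matrix.cell_cluster
        labels.to_csv(out / "labels.csv", index=False)
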