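"""Readers and writers for the standard on-disk formats.

Images travel as TIFF (planes ordered C, H, W with channel names in the image
description), spot data as Matrix Market plus sibling row/column name files or
as a single TSV, coordinates as TSV, and label maps as lossless integer TIFF
with a JSON sidecar recording the background sentinel.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import tifffile

from .datatypes import MultiplexImage, SpotDataset, TissueMask

__all__ = [
    "read_multichannel_image",
    "write_multichannel_image",
    "read_spot_dataset",
    "write_spot_dataset",
    "write_label_image",
    "read_label_image",
    "write_mask",
    "read_mask",
]

_BACKGROUND = -1


def write_multichannel_image(image: MultiplexImage, path: str | Path) -> Path:
    """Write a multichannel image as a C-plane TIFF with JSON metadata."""
    path = Path(path)
    meta = {
        "channels": image.channels,
        "resolution_um_per_px": image.resolution_um_per_px,
        "slide_id": image.slide_id,
    }
    planes = np.moveaxis(image.pixels, 2, 0)
    tifffile.imwrite(path, planes, description=json.dumps(meta),
                     photometric="minisblack")
    return path


def read_multichannel_image(path: str | Path,
                            channel_names: list[str] | None = None,
                            ) -> MultiplexImage:
    """Read a TIFF with C planes (or an H x W x C page) into a MultiplexImage.

    ``channel_names`` overrides any names stored in the file; its length must
    match the plane count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].description
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise ValueError(f"cannot interpret TIFF of shape {arr.shape} as multichannel image")
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"non-numeric TIFF data of dtype {arr.dtype}")
    # stored as (C, H, W); a stray (H, W, C) array with few trailing planes is
    # also accepted when names pin down C
    pixels = np.moveaxis(arr, 0, 2)
    n_planes = pixels.shape[2]
    if channel_names is not None:
        if len(channel_names) != n_planes:
            raise ValueError(
                f"{len(channel_names)} channel names provided for {n_planes} planes"
            )
        channels = list(channel_names)
    elif isinstance(meta.get("channels"), list) and len(meta["channels"]) == n_planes:
        channels = [str(c) for c in meta["channels"]]
    else:
        channels = [f"ch{i}" for i in range(n_planes)]
    return MultiplexImage(
        pixels=pixels,
        channels=channels,
        resolution_um_per_px=float(meta.get("resolution_um_per_px", 1.0)),
        slide_id=str(meta.get("slide_id", path.stem)),
    )


def write_spot_dataset(dataset: SpotDataset, matrix_path: str | Path,
                       coords_path: str | Path) -> tuple[Path, Path]:
    """Write spots-by-genes matrix (.mtx or .tsv) plus a coordinate table.

    Matrix Market output gains two sibling files ``<stem>.rows.txt`` (spot
    ids) and ``<stem>.cols.txt`` (gene names).
    """
    matrix_path, coords_path = Path(matrix_path), Path(coords_path)
    genes = dataset.gene_names or [f"g{i}" for i in range(dataset.n_genes)]
    if matrix_path.suffix == ".mtx":
        scipy.io.mmwrite(matrix_path, scipy.sparse.csr_matrix(dataset.matrix))
        matrix_path.with_suffix(".rows.txt").write_text("\n".join(dataset.spot_ids) + "\n")
        matrix_path.with_suffix(".cols.txt").write_text("\n".join(genes) + "\n")
    else:
        df = pd.DataFrame(dataset.matrix, index=dataset.spot_ids, columns=genes)
        df.to_csv(matrix_path, sep="\t", index_label="spot_id")
    coords = pd.DataFrame({
        "spot_id": dataset.spot_ids,
        "array_row": dataset.array_row,
        "array_col": dataset.array_col,
        "slide_id": dataset.slide_id,
        "batch": dataset.batch,
    })
    coords.to_csv(coords_path, sep="\t", index=False)
    return matrix_path, coords_path


def read_spot_dataset(matrix_path: str | Path, coords_path: str | Path) -> SpotDataset:
    """Read a spot dataset, aligning matrix rows to the coordinate table.

    Row order of the returned dataset follows the coordinate table; every
    spot_id in the table must be present in the matrix.
    """
    matrix_path, coords_path = Path(matrix_path), Path(coords_path)
    if matrix_path.suffix == ".mtx":
        mat = np.asarray(scipy.io.mmread(matrix_path).todense(), dtype=float)
        spot_ids = matrix_path.with_suffix(".rows.txt").read_text().split()
        genes = matrix_path.with_suffix(".cols.txt").read_text().split()
    else:
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        mat = df.to_numpy(dtype=float)
        spot_ids = [str(i) for i in df.index]
        genes = [str(c) for c in df.columns]
    coords = pd.read_csv(coords_path, sep="\t")
    missing = set(coords["spot_id"].astype(str)) - set(spot_ids)
    if missing:
        raise ValueError(f"spot ids in coordinates absent from matrix: {sorted(missing)}")
    order = [spot_ids.index(s) for s in coords["spot_id"].astype(str)]
    slide_id = str(coords["slide_id"].iloc[0]) if "slide_id" in coords else matrix_path.stem
    batch = str(coords["batch"].iloc[0]) if "batch" in coords else "batch0"
    return SpotDataset(
        matrix=mat[order],
        spot_ids=list(coords["spot_id"].astype(str)),
        array_row=coords["array_row"].to_numpy(),
        array_col=coords["array_col"].to_numpy(),
        slide_id=slide_id,
        batch=batch,
        gene_names=genes,
    )


def write_label_image(labels: np.ndarray, path: str | Path) -> Path:
    """Write an integer label map losslessly as TIFF.

    Background is ``-1``; it is serialized as the maximum value of the chosen
    unsigned dtype, recorded in a JSON sidecar ``<path>.json`` so the file
    round-trips exactly through :func:`read_label_image`.
    """
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise TypeError(f"labels must be an integer array, got dtype {labels.dtype}")
    if labels.min() < _BACKGROUND:
        raise ValueError("labels must be >= -1")
    path = Path(path)
    dtype = np.uint16 if labels.max() < np.iinfo(np.uint16).max else np.uint32
    sentinel = int(np.iinfo(dtype).max)
    out = labels.astype(np.int64)
    out[out == _BACKGROUND] = sentinel
    tifffile.imwrite(path, out.astype(dtype))
    sidecar = {"background_value": sentinel, "dtype": np.dtype(dtype).name,
               "n_domains": int(labels.max() + 1)}
    Path(str(path) + ".json").write_text(json.dumps(sidecar))
    return path


def read_label_image(path: str | Path) -> np.ndarray:
    """Read a label map written by :func:`write_label_image` (background -1)."""
    path = Path(path)
    arr = tifffile.imread(path).astype(np.int64)
    sidecar_path = Path(str(path) + ".json")
    if sidecar_path.exists():
        sentinel = json.loads(sidecar_path.read_text())["background_value"]
    else:
        sentinel = int(np.iinfo(np.uint16).max)
    arr[arr == sentinel] = _BACKGROUND
    return arr


def write_mask(mask: TissueMask, path: str | Path) -> Path:
    """Write a tissue mask as an 8-bit TIFF (255 = foreground)."""
    path = Path(path)
    tifffile.imwrite(path, (mask.mask.astype(np.uint8) * 255),
                     description=json.dumps({"slide_id": mask.slide_id}))
    return path


def read_mask(path: str | Path) -> TissueMask:
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].description
    slide_id = Path(path).stem
    if desc:
        try:
            slide_id = json.loads(desc).get("slide_id", slide_id)
        except (json.JSONDecodeError, TypeError):
            pass
    return TissueMask(mask=arr > 0, slide_id=slide_id)
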