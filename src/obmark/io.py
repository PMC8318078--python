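"""Readers and writers for the formats the pipeline consumes and emits.

Expression matrices travel as MatrixMarket (.mtx) plus genes.tsv /
barcodes.tsv triplets, or as loom (HDF5 with a central ``/matrix`` dataset
and row/column attribute groups).  Histology scenes are CSVs of pixel
coordinates with a JSON sidecar holding the micrometers-per-pixel scale;
masks are PNG/TIFF; traces are CSV with a JSON timing sidecar.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


@dataclass
class ExpressionMatrix:
    """Genes x cells integer count matrix with identifiers."""

    counts: np.ndarray  # (n_genes, n_cells), non-negative ints
    gene_names: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (genes x cells)")
        if self.counts.shape != (self.gene_names.size, self.cell_ids.size):
            raise ValueError(
                f"shape {self.counts.shape} inconsistent with "
                f"{self.gene_names.size} genes / {self.cell_ids.size} cells"
            )
        if len(set(self.gene_names)) != self.gene_names.size:
            raise ValueError("gene names must be unique")
        if len(set(self.cell_ids)) != self.cell_ids.size:
            raise ValueError("cell ids must be unique")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


def write_mtx(matrix: ExpressionMatrix, outdir: str | Path) -> Path:
    """Write counts as matrix.mtx + genes.tsv + barcodes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.coo_matrix(matrix.counts))
    pd.Series(matrix.gene_names).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(matrix.cell_ids).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    return outdir


def read_mtx(path: str | Path) -> ExpressionMatrix:
    """Read a matrix.mtx + genes.tsv + barcodes.tsv triplet directory."""
    path = Path(path)
    mtx = path / "matrix.mtx" if path.is_dir() else path
    counts = np.asarray(spio.mmread(mtx).todense()).astype(np.int64)
    genes = pd.read_csv(mtx.parent / "genes.tsv", sep="\t", header=None)[0].to_numpy(dtype=object)
    cells = pd.read_csv(mtx.parent / "barcodes.tsv", sep="\t", header=None)[0].to_numpy(dtype=object)
    if counts.shape == (cells.size, genes.size) and genes.size != cells.size:
        counts = counts.T  # stored cells x genes; normalize orientation
    return ExpressionMatrix(counts=counts, gene_names=genes, cell_ids=cells)


_LOOM_GENE_ATTRS = ("Gene", "gene_names", "GeneName", "var_names")
_LOOM_CELL_ATTRS = ("CellID", "cell_ids", "obs_names")


def write_loom(matrix: ExpressionMatrix, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("matrix", data=matrix.counts)
        f.create_dataset("row_attrs/Gene", data=np.asarray(matrix.gene_names, dtype="S"))
        f.create_dataset("col_attrs/CellID", data=np.asarray(matrix.cell_ids, dtype="S"))
    return path


def read_loom(path: str | Path) -> ExpressionMatrix:
    """Read a loom file (genes as rows, per the format convention)."""
    with h5py.File(path, "r") as f:
        if "matrix" not in f:
            raise ValueError(f"{path}: not a loom file (no /matrix dataset)")
        counts = np.asarray(f["matrix"]).astype(np.int64)
        genes = _read_attr(f, "row_attrs", _LOOM_GENE_ATTRS, path)
        cells = _read_attr(f, "col_attrs", _LOOM_CELL_ATTRS, path)
    if counts.shape != (genes.size, cells.size):
        if counts.shape == (cells.size, genes.size):
            counts = counts.T
        else:
            raise ValueError(f"{path}: matrix shape does not match attribute lengths")
    return ExpressionMatrix(counts=counts, gene_names=genes, cell_ids=cells)


def _read_attr(f: h5py.File, group: str, candidates, path) -> np.ndarray:
    if group not in f:
        raise ValueError(f"{path}: missing /{group}")
    grp = f[group]
    for name in candidates:
        if name in grp:
            vals = np.asarray(grp[name])
            if vals.dtype.kind in "SO":
                vals = np.array([v.decode() if isinstance(v, bytes) else v for v in vals], dtype=object)
            return vals
    raise ValueError(f"{path}: no recognized name attribute in /{group} (tried {candidates})")


def read_matrix(path: str | Path) -> ExpressionMatrix:
    """Auto-detect loom vs MatrixMarket-triplet input."""
    path = Path(path)
    if path.is_dir() or path.suffix == ".mtx":
        return read_mtx(path)
    if path.suffix == ".loom" or h5py.is_hdf5(path):
        return read_loom(path)
    raise ValueError(f"{path}: unrecognized matrix format (expected .loom or .mtx)")


# ---------------------------------------------------------------------------
# histology scene IO


def write_scene(scene, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, arr in (
        ("mcl_boundary", scene.mcl_boundary),
        ("gl_boundary", scene.gl_boundary),
        ("somata", scene.somata),
    ):
        if arr is not None:
            pd.DataFrame(np.atleast_2d(arr), columns=["x", "y"]).to_csv(
                outdir / f"{name}.csv", index=False
            )
    (outdir / "scale.json").write_text(
        json.dumps({"um_per_px": scene.scale_um_per_px})
    )
    if scene.dendrite_mask is not None:
        import imageio.v3 as iio

        iio.imwrite(outdir / "dendrite_mask.png", scene.dendrite_mask.astype(np.uint8) * 255)
    return outdir


def read_scene(indir: str | Path):
    from .histology import LaminarScene

    indir = Path(indir)
    sidecar = indir / "scale.json"
    if not sidecar.exists():
        raise FileNotFoundError(f"missing scale sidecar {sidecar}")
    scale = json.loads(sidecar.read_text())["um_per_px"]

    def load(name, required=True):
        p = indir / f"{name}.csv"
        if not p.exists():
            if required:
                raise FileNotFoundError(p)
            return None
        try:
            df = pd.read_csv(p)
            return df[["x", "y"]].to_numpy(dtype=float)
        except (KeyError, ValueError) as e:
            raise ValueError(f"malformed boundary CSV {p}: {e}") from e

    mask = None
    mask_path = indir / "dendrite_mask.png"
    if mask_path.exists():
        import imageio.v3 as iio

        mask = iio.imread(mask_path) > 0

    somata = load("somata", required=False)
    if somata is None:
        somata = np.empty((0, 2))
    return LaminarScene(
        mcl_boundary=load("mcl_boundary"),
        gl_boundary=load("gl_boundary"),
        somata=somata,
        dendrite_mask=mask,
        scale_um_per_px=scale,
    )


# ---------------------------------------------------------------------------
# trace IO


def write_traces(traces, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_cells, n_odors, n_trials, n_frames = traces.f.shape
    flat = traces.f.reshape(n_cells * n_odors * n_trials, n_frames)
    idx = pd.MultiIndex.from_product(
        [range(n_cells), range(n_odors), range(n_trials)], names=["cell", "odor", "trial"]
    )
    pd.DataFrame(flat, index=idx).to_csv(outdir / "traces.csv")
    (outdir / "timing.json").write_text(
        json.dumps(
            {
                "frame_rate": traces.frame_rate,
                "onset_frame": traces.onset_frame,
                "n_cells": n_cells,
                "n_odors": n_odors,
                "n_trials": n_trials,
            }
        )
    )
    return outdir


def read_traces(indir: str | Path):
    from .simulate import TraceSet

    indir = Path(indir)
    timing = json.loads((indir / "timing.json").read_text())
    df = pd.read_csv(indir / "traces.csv", index_col=[0, 1, 2])
    f = df.to_numpy().reshape(
        timing["n_cells"], timing["n_odors"], timing["n_trials"], -1
    )
    return TraceSet(f=f, frame_rate=timing["frame_rate"], onset_frame=timing["onset_frame"])


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
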