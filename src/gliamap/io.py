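"""Readers and writers for the package's plain-text interchange formats.

Counts travel as MatrixMarket triplets (1-based, integer field) with
``genes.csv``/``cells.csv`` sidecars, or as a long CSV
(cell_id,gene,count[,x,y,fov,region]). Tables are comma-delimited UTF-8 CSV
with a header row; geometry is JSON. Coordinates are µm, image convention.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse

OBS_COLUMNS = ("x", "y", "fov", "region")


def write_counts(adata: ad.AnnData, outdir: str | Path, stem: str = "counts") -> None:
    """Write counts.mtx + genes.csv + cells.csv into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    coo = sparse.coo_matrix(np.asarray(X, dtype=np.int64))
    sio.mmwrite(outdir / f"{stem}.mtx", coo, field="integer")
    pd.DataFrame({"gene": list(adata.var_names)}).to_csv(
        outdir / "genes.csv", index=False
    )
    cells = pd.DataFrame({"cell_id": list(adata.obs_names)})
    for col in OBS_COLUMNS:
        if col in adata.obs.columns:
            cells[col] = adata.obs[col].to_numpy()
    cells.to_csv(outdir / "cells.csv", index=False)


def _read_counts_mtx(path: Path) -> ad.AnnData:
    X = sio.mmread(path)
    dense = np.asarray(X.todense() if sparse.issparse(X) else X)
    if not np.allclose(dense, np.round(dense)):
        raise ValueError("non-integer counts in MTX")
    dense = dense.astype(np.int64)
    genes = pd.read_csv(path.parent / "genes.csv")["gene"].tolist()
    cells = pd.read_csv(path.parent / "cells.csv")
    if len(genes) != dense.shape[1] or len(cells) != dense.shape[0]:
        raise ValueError("sidecar dimensions do not match matrix")
    obs = cells.set_index("cell_id")
    obs.index.name = None
    return ad.AnnData(X=dense, obs=obs, var=pd.DataFrame(index=pd.Index(genes)))


def _read_counts_long(path: Path) -> ad.AnnData:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError("empty counts file")
    required = {"cell_id", "gene", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"long CSV needs columns {sorted(required)}")
    if not np.allclose(df["count"], np.round(df["count"])):
        raise ValueError("non-integer counts in long CSV")
    dup = df.duplicated(subset=["cell_id", "gene"]).any()
    if dup:
        warnings.warn("duplicate (cell, gene) entries summed", stacklevel=2)
    extra = [c for c in OBS_COLUMNS if c in df.columns]
    obs = df.groupby("cell_id", sort=True)[extra].first() if extra else None
    wide = (
        df.groupby(["cell_id", "gene"], sort=True)["count"].sum().unstack(fill_value=0)
    )
    obs = obs.loc[wide.index] if obs is not None else pd.DataFrame(index=wide.index)
    obs.index.name = None
    var = pd.DataFrame(index=pd.Index(wide.columns.tolist()))
    return ad.AnnData(X=wide.to_numpy(dtype=np.int64), obs=obs, var=var)


def read_counts(path: str | Path) -> ad.AnnData:
    """Read an expression matrix from MTX-with-sidecars or long CSV.

    Both dialects yield the identical matrix; integer counts are enforced and
    duplicate long-CSV entries are summed with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError("empty file")
    if path.suffix == ".mtx":
        return _read_counts_mtx(path)
    return _read_counts_long(path)


def write_tables(outdir: str | Path, **tables: pd.DataFrame) -> list[Path]:
    """Write keyword-named DataFrames as <name>.csv; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths.append(p)
    return paths


DATA_DICTIONARY = """\
# Data dictionary

All coordinates are micrometres, origin top-left, y increasing downward.
CSV files are comma-delimited UTF-8 with a header row; MTX is 1-based.

cells.csv      cell_id, mouse, group, region, cx, cy, polygon ("x y;x y;..."),
               area (µm²), intdens_<CH> (integrated density, a.u.),
               bg_<CH> (mean local background, a.u./µm²)
tracts.csv     mouse, tract_id, region, angle_deg (axial, [0,180)),
               x1, y1, x2, y2
scene.json     region polygons, fimbria midline and ventricle-edge polylines,
               µm-per-unit scale
truth.csv      planted per-cell ground truth (tests only)
counts.mtx     cells × genes raw integer counts (MatrixMarket triplet)
genes.csv      gene (panel order = matrix columns)
cells.csv      cell_id, x, y, fov, region (matrix row order)
morphometrics.csv  one row per cell: feret_length, feret_angle, area,
               perimeter, circularity, nearest_tract, tract_distance,
               angle_offset, tccf_<CH>, tccf_<CH>_negative, norm_<CH>
"""


def write_data_dictionary(outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = outdir / "DATA_DICTIONARY.md"
    p.write_text(DATA_DICTIONARY, encoding="utf-8")
    return p


__all__ = [
    "read_counts", "write_counts", "write_tables", "write_data_dictionary",
]
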