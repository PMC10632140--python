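"""Reading and writing the pipeline's on-disk formats.

Expression travels as MatrixMarket (genes x cells) plus gene/cell TSVs,
signatures as GMT text, punctum fields as multi-channel TIFF with a YAML
sidecar carrying pixel size and channel roles, and traces as two-column CSV.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import sparse
from scipy.io import mmread, mmwrite

from .expression import ExpressionMatrix, Signature
from .imaging import PunctaField
from .traces import FluorTrace

__all__ = [
    "write_expression",
    "read_expression",
    "read_dense_expression",
    "read_gmt",
    "write_gmt",
    "write_puncta_field",
    "read_puncta_field",
    "write_trace",
    "read_trace",
]


def write_expression(matrix: ExpressionMatrix, outdir: str | Path) -> None:
    """Write matrix.mtx (genes x cells), genes.tsv and cells.tsv to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(outdir / "matrix.mtx"), sparse.csr_matrix(matrix.values))
    pd.Series(matrix.gene_ids, name="gene_id").to_csv(
        outdir / "genes.tsv", sep="\t", index=False
    )
    meta = matrix.cell_meta.copy()
    meta.insert(0, "cell_id", matrix.cell_ids)
    meta.to_csv(outdir / "cells.tsv", sep="\t", index=False)


def read_expression(indir: str | Path, is_log: bool = False) -> ExpressionMatrix:
    """Read an expression directory written by :func:`write_expression`."""
    indir = Path(indir)
    values = np.asarray(mmread(str(indir / "matrix.mtx")).todense())
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")["gene_id"]
    cells = pd.read_csv(indir / "cells.tsv", sep="\t")
    meta = cells.set_index("cell_id")
    return ExpressionMatrix(
        values=values,
        gene_ids=pd.Index(genes),
        cell_ids=meta.index,
        cell_meta=meta,
        is_log=is_log,
    )


def read_dense_expression(path: str | Path, is_log: bool = False) -> ExpressionMatrix:
    """Read a dense TSV matrix (genes as rows, cells as columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        values=df.to_numpy(float),
        gene_ids=df.index,
        cell_ids=pd.Index(df.columns),
        is_log=is_log,
    )


def read_gmt(path: str | Path) -> list:
    """Read signatures from GMT text (name, description, genes...)."""
    sigs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sigs.append(Signature(name=parts[0], genes=tuple(parts[2:])))
    return sigs


def write_gmt(signatures, path: str | Path) -> None:
    lines = ["\t".join([s.name, s.name] + list(s.genes)) for s in signatures]
    Path(path).write_text("\n".join(lines) + "\n")


def write_puncta_field(field: PunctaField, path: str | Path) -> None:
    """Write a two-channel TIFF plus a YAML sidecar (<path>.meta.yaml)."""
    path = Path(path)
    tifffile.imwrite(path, field.image.astype(np.float32))
    sidecar = {
        "pixel_size_um": float(field.pixel_size_um),
        "channel_roles": {k: int(v) for k, v in field.channel_roles.items()},
    }
    Path(str(path) + ".meta.yaml").write_text(yaml.safe_dump(sidecar))


def read_puncta_field(
    path: str | Path,
    pixel_size_um: float | None = None,
    channel_roles: Mapping[str, int] | None = None,
) -> PunctaField:
    """Read a two-channel TIFF; metadata from arguments or the YAML sidecar."""
    path = Path(path)
    image = np.asarray(tifffile.imread(path), dtype=float)
    sidecar_path = Path(str(path) + ".meta.yaml")
    if sidecar_path.exists():
        sidecar = yaml.safe_load(sidecar_path.read_text())
        pixel_size_um = pixel_size_um or sidecar.get("pixel_size_um")
        channel_roles = channel_roles or sidecar.get("channel_roles")
    if pixel_size_um is None:
        raise ValueError("pixel_size_um not given and no sidecar found")
    return PunctaField(
        image=image,
        pixel_size_um=pixel_size_um,
        channel_roles=channel_roles or {"pre": 0, "post": 1},
    )


def write_trace(trace: FluorTrace, path: str | Path) -> None:
    """Write a trace as CSV with time_s and F columns."""
    pd.DataFrame({"time_s": trace.time_s, "F": trace.samples}).to_csv(
        path, index=False
    )


def read_trace(
    path: str | Path,
    baseline_window: tuple | None = None,
    background: float = 0.0,
    fs: float | None = None,
) -> FluorTrace:
    """Read a CSV trace; the sampling rate comes from time_s unless given."""
    df = pd.read_csv(path)
    if fs is None:
        dt = np.diff(df["time_s"].to_numpy(float))
        if len(dt) == 0 or not np.allclose(dt, dt[0]):
            raise ValueError("time_s must be evenly sampled to infer fs")
        fs = 1.0 / dt[0]
    return FluorTrace(
        samples=df["F"].to_numpy(float),
        fs=fs,
        baseline_window=baseline_window,
        background=background,
    )
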