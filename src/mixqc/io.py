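"""Readers and writers: 10x-style MatrixMarket directories, metrics and
decision tables (TSV), fitted-model JSON, and the per-run log.

All tables are plain delimited text and every writer's output is
re-readable by the matching reader; the model JSON round-trips the fit
bit-exactly (JSON serialises Python floats via repr, which is lossless).
"""

from __future__ import annotations

import gzip
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .mixture import MixtureFit
from .qc_metrics import QC_COLUMNS, CountMatrix

__all__ = [
    "read_10x_mtx",
    "write_10x_mtx",
    "read_metrics_table",
    "write_metrics_table",
    "read_decisions_table",
    "write_decisions_table",
    "save_model",
    "load_model",
    "write_outputs",
]


def _find(directory: Path, stems: list[str]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = directory / (stem + suffix)
            if p.exists():
                return p
    raise FileNotFoundError(
        f"none of {stems} (optionally .gz) found in {directory}"
    )


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_id_file(path: Path) -> pd.DataFrame:
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", header=None, dtype=str)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing fields")
    return df


def read_10x_mtx(directory: str | Path, transpose: bool = False) -> CountMatrix:
    """Read a 10x-convention MatrixMarket directory.

    Expects ``matrix.mtx[.gz]`` (rows = genes, columns = cells; pass
    ``transpose=True`` for the opposite orientation), a features file
    (``features.tsv`` or ``genes.tsv``, 1-3 tab-separated columns: id,
    optional symbol, optional type) and ``barcodes.tsv``.  Symbols, when
    present, are preferred for mitochondrial matching.  Non-integer
    matrix values are truncated toward zero with a warning.
    """
    directory = Path(directory)
    mtx_path = _find(directory, ["matrix.mtx"])
    feat_path = _find(directory, ["features.tsv", "genes.tsv"])
    bc_path = _find(directory, ["barcodes.tsv"])

    with _open_text(mtx_path) as fh:
        mat = scipy_io.mmread(fh)
    mat = sparse.csc_matrix(mat)
    if transpose:
        mat = mat.T.tocsc()
    if mat.nnz and not np.allclose(mat.data, np.rint(mat.data)):
        warnings.warn(
            f"{mtx_path}: non-integer values truncated toward zero",
            UserWarning,
            stacklevel=2,
        )
        mat.data = np.trunc(mat.data)
        mat.eliminate_zeros()
    mat = mat.astype(np.int64)

    feats = _read_id_file(feat_path)
    barcodes = _read_id_file(bc_path)
    if len(feats) != mat.shape[0]:
        raise ValueError(
            f"{feat_path}: {len(feats)} rows but matrix has {mat.shape[0]} genes"
        )
    if len(barcodes) != mat.shape[1]:
        raise ValueError(
            f"{bc_path}: {len(barcodes)} rows but matrix has {mat.shape[1]} cells"
        )
    gene_ids = feats.iloc[:, 0].tolist()
    symbols = feats.iloc[:, 1].tolist() if feats.shape[1] >= 2 else None
    return CountMatrix(
        values=mat,
        gene_ids=gene_ids,
        cell_ids=barcodes.iloc[:, 0].tolist(),
        gene_symbols=symbols,
    )


def write_10x_mtx(m: CountMatrix, directory: str | Path) -> None:
    """Write a CountMatrix as an uncompressed 10x-style directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy_io.mmwrite(directory / "matrix.mtx", m.values.tocoo(), field="integer")
    symbols = m.gene_symbols if m.gene_symbols is not None else m.gene_ids
    pd.DataFrame({"id": m.gene_ids, "symbol": symbols}).to_csv(
        directory / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(m.cell_ids).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )


_DEFAULT_COLMAP = {
    "cell_id": "cell_id",
    "detected_genes": "detected_genes",
    "pct_mito": "pct_mito",
    "total_counts": "total_counts",
}


def read_metrics_table(
    path: str | Path, column_map: dict[str, str] | None = None, sep: str = "\t"
) -> pd.DataFrame:
    """Read a per-cell metrics table from a delimited file.

    ``column_map`` maps the canonical names (cell_id, detected_genes,
    pct_mito, optionally total_counts) to the file's column headers.
    pct_mito values outside [0, 100] are fatal, reported with row index.
    """
    path = Path(path)
    cmap = dict(_DEFAULT_COLMAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for canon in ("cell_id", "detected_genes", "pct_mito"):
        if cmap[canon] not in df.columns:
            raise ValueError(f"{path}: required column {cmap[canon]!r} missing")
    out = pd.DataFrame(
        {
            "cell_id": df[cmap["cell_id"]].astype(str),
            "detected_genes": df[cmap["detected_genes"]].astype(np.int64),
            "pct_mito": df[cmap["pct_mito"]].astype(float),
        }
    )
    if cmap["total_counts"] in df.columns:
        out["total_counts"] = df[cmap["total_counts"]].astype(np.int64)
    else:
        out["total_counts"] = -1  # unknown; prefilter on totals not possible
    if "true_state" in df.columns:
        out["true_state"] = df["true_state"].astype(str)
    bad = out.index[(out["pct_mito"] < 0) | (out["pct_mito"] > 100)]
    if len(bad):
        raise ValueError(
            f"{path}: pct_mito outside [0, 100] at row(s) {bad.tolist()[:5]}"
        )
    out["zero_total_flag"] = out["total_counts"] == 0
    return out[QC_COLUMNS + (["true_state"] if "true_state" in out.columns else [])]


def write_metrics_table(cells: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    cols = [c for c in QC_COLUMNS + ["true_state"] if c in cells.columns]
    cells[cols].to_csv(path, sep=sep, index=False)


def write_decisions_table(decisions: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write keep/remove verdicts; gamma is left empty for non-model filters."""
    decisions.to_csv(path, sep=sep, index=False)


def read_decisions_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    df["keep"] = df["keep"].astype(bool)
    return df


def save_model(fit: MixtureFit, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=1) + "\n")


def load_model(path: str | Path) -> MixtureFit:
    return MixtureFit.from_dict(json.loads(Path(path).read_text()))


def write_outputs(
    decisions: pd.DataFrame,
    fit: MixtureFit | None,
    metrics: pd.DataFrame,
    outdir: str | Path,
    run_params: dict | None = None,
) -> dict[str, Path]:
    """Write the full result set for one run.

    Produces ``decisions.tsv``, ``metrics.tsv``, ``model.json`` (when a
    fit is given) and ``run_log.json`` summarising parameters and
    per-reason verdict counts.  Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["decisions"] = outdir / "decisions.tsv"
    write_decisions_table(decisions, paths["decisions"])
    paths["metrics"] = outdir / "metrics.tsv"
    write_metrics_table(metrics, paths["metrics"])
    if fit is not None:
        paths["model"] = outdir / "model.json"
        save_model(fit, paths["model"])

    reason_counts = decisions["reason"].value_counts().to_dict()
    log = {
        "params": run_params or {},
        "n_cells": int(len(decisions)),
        "n_kept": int(decisions["keep"].sum()),
        "n_removed": int((~decisions["keep"]).sum()),
        "reason_counts": {k: int(v) for k, v in sorted(reason_counts.items())},
    }
    if fit is not None:
        log["model"] = {
            "weights": [float(w) for w in fit.weights],
            "intercepts": [float(p.coefficients[0]) for p in fit.components],
            "compromised_index": int(fit.compromised_index),
            "converged": bool(fit.converged),
            "n_iter": int(fit.n_iter),
        }
    paths["log"] = outdir / "run_log.json"
    paths["log"].write_text(json.dumps(log, indent=1) + "\n")
    return paths
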