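"""Readers and writers for the standard on-disk formats.

10x triplet layout (matrix.mtx + features.tsv + barcodes.tsv, gzip
tolerated), cell-metadata CSV, spaceranger-style tissue_positions CSV,
GMT gene sets, pixel tables, ligand-receptor CSVs and the synthetic-truth
JSON.
"""

from __future__ import annotations

import gzip
import json
import warnings
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


def _open_maybe_gz(path: Path):
    if path.exists():
        return open(path, "rb")
    gz = path.with_name(path.name + ".gz")
    if gz.exists():
        return gzip.open(gz, "rb")
    raise FileNotFoundError(path)


def write_10x_mtx(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write counts in the 10x triplet layout (genes as matrix rows)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    mat = sparse.csc_matrix(X.T if sparse.issparse(X) else np.asarray(X).T)
    spio.mmwrite(outdir / "matrix.mtx", mat, field="integer")
    pd.DataFrame(
        {"gene_id": adata.var_names, "gene_name": adata.var_names,
         "feature_type": "Gene Expression"}
    ).to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )


def read_10x_mtx(indir: str | Path) -> ad.AnnData:
    """Read a 10x triplet directory into AnnData (cells x genes)."""
    indir = Path(indir)
    with _open_maybe_gz(indir / "matrix.mtx") as fh:
        mat = spio.mmread(fh)
    if (sparse.issparse(mat) and (mat.data < 0).any()) or (
        not sparse.issparse(mat) and (np.asarray(mat) < 0).any()
    ):
        raise ValueError("count matrix contains negative entries")
    with _open_maybe_gz(indir / "features.tsv") as fh:
        features = pd.read_csv(fh, sep="\t", header=None)
    with _open_maybe_gz(indir / "barcodes.tsv") as fh:
        barcodes = pd.read_csv(fh, sep="\t", header=None)
    gene_names = features.iloc[:, 1] if features.shape[1] > 1 else features.iloc[:, 0]
    X = sparse.csr_matrix(mat.T).astype(np.int32)
    return ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(barcodes.iloc[:, 0].astype(str), name="barcode")),
        var=pd.DataFrame(index=pd.Index(gene_names.astype(str), name="gene")),
    )


def write_cell_meta(adata: ad.AnnData, path: str | Path) -> None:
    meta = adata.obs[["sample_id", "condition"]].copy()
    meta.index.name = "barcode"
    meta.to_csv(path)


def read_cell_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, index_col=0)
    required = {"sample_id", "condition"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"cell metadata missing columns: {sorted(missing)}")
    return meta


def write_tissue_positions(adata: ad.AnnData, path: str | Path) -> None:
    """Spaceranger-style tissue_positions CSV (55 um spots at 100 px pitch)."""
    df = pd.DataFrame(
        {
            "barcode": adata.obs_names,
            "in_tissue": 1,
            "array_row": adata.obs["array_row"].to_numpy(),
            "array_col": adata.obs["array_col"].to_numpy(),
            "pxl_row_in_fullres": adata.obs["array_row"].to_numpy() * 100,
            "pxl_col_in_fullres": adata.obs["array_col"].to_numpy() * 100,
        }
    )
    df.to_csv(path, index=False)


def read_tissue_positions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"barcode", "array_row", "array_col"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tissue positions missing columns: {sorted(missing)}")
    df = df.set_index("barcode")
    if "in_tissue" in df.columns:
        df = df[df["in_tissue"] == 1]
    return df[["array_row", "array_col"]].astype(int)


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT gene sets; duplicate genes within a set are dropped."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {ln}: fewer than 3 fields")
            name, genes = parts[0], [g for g in parts[2:] if g]
            uniq = list(dict.fromkeys(genes))
            if len(uniq) < len(genes):
                warnings.warn(f"GMT set {name!r}: duplicate genes deduplicated")
            out[name] = uniq
    return out


def write_pixel_table(px: pd.DataFrame, path: str | Path) -> None:
    px.to_csv(path, index=False)


def read_pixel_table(path: str | Path) -> pd.DataFrame:
    px = pd.read_csv(path)
    required = {"x_um", "y_um", "gene", "count"}
    missing = required - set(px.columns)
    if missing:
        raise ValueError(f"pixel table missing columns: {sorted(missing)}")
    if (px["count"] <= 0).any():
        raise ValueError("pixel counts must be positive")
    if not np.isfinite(px[["x_um", "y_um"]].to_numpy()).all():
        raise ValueError("pixel coordinates must be finite")
    return px


def read_lr_csv(path: str | Path) -> pd.DataFrame:
    db = pd.read_csv(path)
    required = {"pair_id", "ligand_members", "receptor_members"}
    missing = required - set(db.columns)
    if missing:
        raise ValueError(f"ligand-receptor table missing columns: {sorted(missing)}")
    return db


def write_truth_json(truth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_json_dict(), fh)
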