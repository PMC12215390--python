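"""Readers and writers for the pipeline's on-disk formats.

All writers are byte-deterministic for identical inputs: gzip streams carry
no filename and a zeroed mtime, YAML keys are sorted, and tables are written
with a fixed float representation. Formats:

* read observations — gzip TSV, columns ``barcode, umi, gene_id, pos, ref,
  obs, qual`` (one row per covered position per read);
* per-UMI summaries — gzip TSV with content (A/C/G/T) and the 12
  substitution-type counts, compatible with per-UMI counts CSVs from
  nucleotide-conversion pipelines;
* per-cell ``rates.csv`` — barcode plus the 12 rates, missing rates as
  empty fields;
* expression layers — MatrixMarket ``.mtx`` per layer with ``barcodes.tsv``
  / ``features.tsv`` sidecars.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml
from scipy import sparse
from scipy.io import mmread, mmwrite

from .quantify import SUB_TYPES

__all__ = [
    "write_reads",
    "read_reads",
    "write_summaries",
    "read_summaries",
    "read_dynast_counts",
    "write_rates_csv",
    "write_table",
    "write_layers",
    "read_layers",
    "write_yaml",
    "read_yaml",
]

READ_COLUMNS = ["barcode", "umi", "gene_id", "pos", "ref", "obs", "qual"]
SUMMARY_COLUMNS = ["barcode", "umi", "gene_id", "A", "C", "G", "T", *SUB_TYPES]
_LAYER_NAMES = ["total", "labeled", "unlabeled", "estimated_new", "estimated_old"]


def _write_text(text: str, path: Path) -> None:
    path = Path(path)
    if path.suffix == ".gz":
        buf = _io.BytesIO()
        # filename='' and mtime=0 keep the gzip header byte-stable
        with gzip.GzipFile(filename="", mode="wb", fileobj=buf, mtime=0) as fh:
            fh.write(text.encode())
        path.write_bytes(buf.getvalue())
    else:
        path.write_text(text)


def write_table(df: pd.DataFrame, path: Path, float_format: str = "%.10g") -> None:
    sep = "," if str(path).replace(".gz", "").endswith(".csv") else "\t"
    _write_text(df.to_csv(sep=sep, index=False, float_format=float_format), Path(path))


def write_reads(reads: pd.DataFrame, path) -> None:
    write_table(reads[READ_COLUMNS], Path(path))


def read_reads(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "barcode": "category",
            "umi": "category",
            "gene_id": "category",
            "pos": np.int32,
            "ref": "category",
            "obs": "category",
            "qual": np.int16,
        },
    )
    return df[READ_COLUMNS]


def write_summaries(summaries: pd.DataFrame, path) -> None:
    write_table(summaries[SUMMARY_COLUMNS], Path(path))


def read_summaries(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"barcode": "category", "umi": "category", "gene_id": "category"},
    )
    return df[SUMMARY_COLUMNS]


def read_dynast_counts(path) -> pd.DataFrame:
    """Adapter for dynast-style per-UMI counts CSV.

    Expected columns: ``barcode, GX, A, C, G, T`` plus the 12 substitution
    types. The source carries no explicit UMI identifier (one row per UMI);
    a synthetic row-index UMI is added so downstream grouping works.
    """
    df = pd.read_csv(path)
    missing = {"barcode", "GX", *"ACGT", *SUB_TYPES} - set(df.columns)
    if missing:
        raise ValueError(f"counts CSV missing columns: {sorted(missing)}")
    out = df.rename(columns={"GX": "gene_id"}).copy()
    out["umi"] = [f"row{i:09d}" for i in range(len(out))]
    return out[SUMMARY_COLUMNS]


def write_rates_csv(profiles: pd.DataFrame, path) -> None:
    """Per-cell rates table; NaN rates serialize as empty fields."""
    out = profiles.reset_index().rename(columns={"index": "barcode"})
    cols = ["barcode", *SUB_TYPES]
    write_table(out[cols], Path(path))


def write_yaml(obj: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_layers(adata: ad.AnnData, outdir) -> None:
    """Serialize expression layers as MatrixMarket + sidecars.

    Each layer goes to ``layer_<name>.mtx`` (genes x cells, matching the
    ``features.tsv`` / ``barcodes.tsv`` sidecars). Estimated layers of
    unsupported genes are NaN in memory; the sparse export stores zeros for
    them and ``features.tsv``'s ``estimated_supported`` column records which
    rows are meaningful.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "barcodes.tsv").write_text("\n".join(adata.obs_names) + "\n")
    feat = pd.DataFrame(
        {
            "gene_id": adata.var_names,
            "estimated_supported": adata.var["estimated_supported"].astype(int),
            "pi": adata.var["pi"],
        }
    )
    write_table(feat, outdir / "features.tsv")
    for name in _LAYER_NAMES:
        mat = np.nan_to_num(np.asarray(adata.layers[name]), nan=0.0).T
        buf = _io.BytesIO()
        mmwrite(buf, sparse.coo_matrix(mat))
        (outdir / f"layer_{name}.mtx").write_bytes(buf.getvalue())
    write_yaml(
        {k: v for k, v in adata.uns.get("fit", {}).items()}, outdir / "fit.yaml"
    )


def read_layers(indir) -> ad.AnnData:
    indir = Path(indir)
    barcodes = (indir / "barcodes.tsv").read_text().splitlines()
    feat = pd.read_csv(indir / "features.tsv", sep="\t")
    layers = {}
    for name in _LAYER_NAMES:
        mat = np.asarray(mmread(indir / f"layer_{name}.mtx").todense()).T
        layers[name] = mat.astype(float)
    supported = feat["estimated_supported"].to_numpy(dtype=bool)
    for name in ("estimated_new", "estimated_old"):
        layers[name][:, ~supported] = np.nan
    adata = ad.AnnData(
        X=layers["total"].copy(),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(
            {
                "estimated_supported": supported,
                "pi": feat["pi"].to_numpy(),
                "n_umis": layers["total"].sum(axis=0),
            },
            index=pd.Index(feat["gene_id"], name="gene_id"),
        ),
    )
    for name, mat in layers.items():
        adata.layers[name] = mat
    fit_path = indir / "fit.yaml"
    if fit_path.exists():
        adata.uns["fit"] = read_yaml(fit_path)
    return adata
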