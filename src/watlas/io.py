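"""Readers and writers for the pipeline's on-disk formats.

Expression matrices travel as Matrix Market sparse triplets with sidecar
``features.tsv`` / ``barcodes.tsv`` files (the 10x-style layout) or as dense
TSV; annotations and score/trait tables as CSV; ground truth and report
objects as JSON.  Real-data gene-universe intersection is handled here, not
in the generators.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


def write_mtx(expr: pd.DataFrame, outdir: str | Path) -> Path:
    """Write a genes x observations matrix as matrix.mtx + features/barcodes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(expr.to_numpy()))
    expr.index.to_series().to_csv(outdir / "features.tsv", sep="\t",
                                  header=False, index=False)
    pd.Series(expr.columns).to_csv(outdir / "barcodes.tsv", sep="\t",
                                   header=False, index=False)
    return outdir


def read_mtx(indir: str | Path) -> pd.DataFrame:
    indir = Path(indir)
    mat = spio.mmread(indir / "matrix.mtx").toarray()
    genes = pd.read_csv(indir / "features.tsv", sep="\t",
                        header=None)[0].astype(str)
    cells = pd.read_csv(indir / "barcodes.tsv", sep="\t",
                        header=None)[0].astype(str)
    return pd.DataFrame(mat, index=genes, columns=cells)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x observations matrix: MTX directory or dense TSV/CSV."""
    path = Path(path)
    if path.is_dir():
        return read_mtx(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    expr.to_csv(path, sep="\t")
    return path


def read_annotation(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_annotation(ann: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ann.to_csv(path)
    return path


def read_embedding_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def intersect_genes(*frames: pd.DataFrame) -> list[pd.DataFrame]:
    """Restrict several genes x obs frames to their common gene universe."""
    common = frames[0].index
    for f in frames[1:]:
        common = common.intersection(f.index)
    return [f.loc[common] for f in frames]


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)
    return path


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def truth_to_json(truth) -> dict:
    """Serialize a GroundTruth to plain JSON-compatible structures."""
    out: dict = {}
    if truth.celltype_of_observation is not None:
        out["celltype_of_observation"] = \
            truth.celltype_of_observation.to_dict()
    if truth.marker_genes_of_type:
        out["marker_genes_of_type"] = truth.marker_genes_of_type
    if truth.true_proportions is not None:
        out["true_proportions"] = {
            "index": list(truth.true_proportions.index),
            "columns": list(truth.true_proportions.columns),
            "values": truth.true_proportions.to_numpy().tolist(),
        }
    if truth.planted_colocalized_pairs:
        out["planted_colocalized_pairs"] = [
            list(p) for p in truth.planted_colocalized_pairs]
    if truth.planted_discordant_genes:
        out["planted_discordant_genes"] = truth.planted_discordant_genes
    if truth.planted_peak_timepoint:
        out["planted_peak_timepoint"] = truth.planted_peak_timepoint
    return out
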