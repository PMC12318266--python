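"""Reading and writing the pipeline's on-disk formats.

Count matrices travel as a CellRanger-style triple — ``matrix.mtx`` (genes x
nuclei, Matrix Market), ``features.tsv`` (gene ID, mito flag) and
``barcodes.tsv`` (nucleus ID, genotype). Marker sets, spot tables, vein
outlines and radial profiles are plain TSV/CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from shapely.geometry import Polygon

from .simulate import VeinOutline

__all__ = [
    "MarkerSets",
    "write_counts",
    "read_counts",
    "read_marker_sets",
    "write_marker_sets",
    "write_veins",
    "read_veins",
]


@dataclass
class MarkerSets:
    """Pericentral and periportal marker gene lists."""

    pericentral: list[str]
    periportal: list[str]

    def __post_init__(self) -> None:
        if not self.pericentral or not self.periportal:
            raise ValueError("both marker sets must be non-empty")


def write_counts(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write an AnnData (nuclei x genes) as matrix.mtx + features/barcodes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    mat = sp.csr_matrix(X) if not sp.issparse(X) else X
    scipy.io.mmwrite(outdir / "matrix.mtx", mat.T.astype(np.int64))
    mito = adata.var["mito"] if "mito" in adata.var else pd.Series(False, index=adata.var_names)
    pd.DataFrame({"gene": adata.var_names, "mito": mito.astype(int).values}).to_csv(
        outdir / "features.tsv", sep="\t", header=False, index=False)
    genotype = (adata.obs["genotype"].astype(str)
                if "genotype" in adata.obs else pd.Series("NA", index=adata.obs_names))
    pd.DataFrame({"barcode": adata.obs_names, "genotype": genotype.values}).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False)


def read_counts(indir: str | Path) -> ad.AnnData:
    """Read a matrix.mtx + features.tsv + barcodes.tsv triple into AnnData."""
    indir = Path(indir)
    mat = scipy.io.mmread(indir / "matrix.mtx").tocsr().T  # -> nuclei x genes
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None,
                           names=["gene", "mito"])
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None,
                           names=["barcode", "genotype"])
    if features["gene"].duplicated().any():
        raise ValueError("duplicate gene IDs in features.tsv")
    if barcodes["barcode"].duplicated().any():
        raise ValueError("duplicate nucleus IDs in barcodes.tsv")
    adata = ad.AnnData(
        X=np.asarray(mat.todense(), dtype=np.int64),
        obs=pd.DataFrame({"genotype": barcodes["genotype"].values},
                         index=barcodes["barcode"].astype(str)),
        var=pd.DataFrame({"mito": features["mito"].astype(bool).values},
                         index=features["gene"].astype(str)),
    )
    return adata


def write_marker_sets(markers: MarkerSets, path: str | Path) -> None:
    rows = [(g, "pericentral") for g in markers.pericentral]
    rows += [(g, "periportal") for g in markers.periportal]
    pd.DataFrame(rows, columns=["gene", "set"]).to_csv(path, sep="\t", index=False)


def read_marker_sets(path: str | Path) -> MarkerSets:
    """Read a two-column TSV (gene, set) with set in {pericentral, periportal}."""
    df = pd.read_csv(path, sep="\t")
    bad = set(df["set"]) - {"pericentral", "periportal"}
    if bad:
        raise ValueError(f"unknown marker set labels: {sorted(bad)}")
    return MarkerSets(
        pericentral=df.loc[df["set"] == "pericentral", "gene"].tolist(),
        periportal=df.loc[df["set"] == "periportal", "gene"].tolist(),
    )


def write_veins(veins: list[VeinOutline], path: str | Path, image: str = "img000") -> None:
    rows = []
    for v in veins:
        xs, ys = v.polygon.exterior.coords.xy
        for i, (x, y) in enumerate(zip(xs, ys)):
            rows.append({"image": image, "type": v.kind, "vertex": i, "x": x, "y": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_veins(path: str | Path) -> dict[str, dict[str, VeinOutline]]:
    """Read vein outlines CSV -> {image: {'central': ..., 'portal': ...}}."""
    df = pd.read_csv(path)
    out: dict[str, dict[str, VeinOutline]] = {}
    for (image, kind), sub in df.groupby(["image", "type"], sort=True):
        sub = sub.sort_values("vertex")
        poly = Polygon(zip(sub["x"], sub["y"]))
        out.setdefault(str(image), {})[str(kind)] = VeinOutline(poly, str(kind))
    return out


def write_truth(truth_dict: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth_dict, fh, indent=1, default=str)
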