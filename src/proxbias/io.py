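"""Readers and writers for the plain-text formats the pipeline speaks.

Coordinate convention: everything is 1-based inclusive once inside the
package. BED-style inputs (0-based half-open) are converted here, at the
boundary, and nowhere else.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

from .benchmark import AnnotationSet
from .genome import LOCUS_COLUMNS
from .maps import GeneVectors, SimilarityMap, WellFeatures
from .truncation import ExpressionCounts

_ARM_COL = "__arm__"
_DISPLAY_COL = "__display__"


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Gene loci from a headered TSV (1-based) or BED6 (0-based, converted).

    The TSV form has columns ``gene_id, symbol, chrom, start, end, strand``.
    A file without a ``gene_id`` header is treated as BED6
    (chrom, start, end, name, score, strand) with name as the gene id.
    """
    path = Path(path)
    head = pd.read_csv(path, sep="\t", nrows=1)
    if "gene_id" in head.columns:
        return pd.read_csv(path, sep="\t")[LOCUS_COLUMNS]
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"])
    return pd.DataFrame({
        "gene_id": bed["name"],
        "symbol": bed["name"],
        "chrom": bed["chrom"],
        "start": bed["start"] + 1,  # 0-based half-open -> 1-based inclusive
        "end": bed["end"],
        "strand": bed["strand"],
    })


def read_cytoband(path: str | Path) -> pd.DataFrame:
    """Arm definitions from a UCSC cytoBand TSV.

    Arms are derived as p = chromosome start to the acen band start and
    q = acen band end to the chromosome end (0-based half-open input
    converted to 1-based inclusive). Chromosomes without an acen band are
    skipped.
    """
    bands = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "band", "stain"], comment="#")
    rows = []
    for chrom, sub in bands.groupby("chrom", sort=False):
        acen = sub[sub["stain"] == "acen"]
        if acen.empty:
            continue
        cen_start, cen_end = int(acen["start"].min()), int(acen["end"].max())
        chrom_end = int(sub["end"].max())
        if cen_start > 0:
            rows.append((chrom, "p", 1, cen_start))
        rows.append((chrom, "q", cen_end + 1, chrom_end))
    return pd.DataFrame(rows, columns=["chrom", "arm", "arm_start", "arm_end"])


def read_arm_table(path: str | Path) -> pd.DataFrame:
    """Arm definitions from a headered TSV (chrom, arm, arm_start, arm_end[, acrocentric])."""
    return pd.read_csv(path, sep="\t")


def hg38_arms() -> pd.DataFrame:
    """Bundled approximate hg38 arm definitions.

    Derived from a cytoBand-format summary with approximate chromosome
    lengths and centromere spans; the arm topology (22 autosomes + X/Y,
    acrocentric 13/14/15/21/22 p arms) is exact, individual boundary
    coordinates are approximate to ~1 Mb.
    """
    ref = importlib.resources.files("proxbias.data") / "hg38_cytoband_approx.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_cytoband(path)


def read_annotation_pairs(path: str | Path, name: str | None = None) -> AnnotationSet:
    """Two-column TSV of annotated gene-id pairs."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["gene_a", "gene_b"], dtype=str)
    return AnnotationSet(name or Path(path).stem,
                         list(df.itertuples(index=False, name=None)))


def read_well_features(path: str | Path) -> WellFeatures:
    """Well features from CSV/TSV/Parquet with leading metadata columns."""
    path = Path(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path, sep="\t" if path.suffix == ".tsv" else ",")
    df["gene_id"] = df["gene_id"].fillna("")
    return WellFeatures.from_frame(df)


def write_well_features(wells: WellFeatures, path: str | Path) -> None:
    path = Path(path)
    df = wells.to_frame()
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, sep="\t" if path.suffix == ".tsv" else ",", index=False)


def read_gene_vectors(path: str | Path) -> GeneVectors:
    path = Path(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path, sep="\t" if path.suffix == ".tsv" else ",",
                         index_col=0)
    if df.index.name != "gene_id" and "gene_id" in df.columns:
        df = df.set_index("gene_id")
    return GeneVectors(df)


def write_gene_vectors(vectors: GeneVectors, path: str | Path) -> None:
    path = Path(path)
    df = vectors.vectors.rename_axis("gene_id")
    if path.suffix == ".parquet":
        df.to_parquet(path)
    else:
        df.to_csv(path, sep="\t" if path.suffix == ".tsv" else ",")


def write_map(smap: SimilarityMap, path: str | Path) -> None:
    """Similarity map to Parquet (arm labels and display flag embedded)."""
    df = smap.to_frame()
    df.columns = df.columns.astype(str)
    df.insert(0, _ARM_COL, smap.arms if smap.arms is not None else np.nan)
    df.insert(0, _DISPLAY_COL, bool(smap.display_only))
    df.rename_axis("gene_id").to_parquet(Path(path))


def read_map(path: str | Path) -> SimilarityMap:
    df = pd.read_parquet(Path(path))
    display = bool(df.pop(_DISPLAY_COL).iloc[0])
    arms = df.pop(_ARM_COL)
    arms = None if arms.isna().all() else arms
    return SimilarityMap(df.index, df.to_numpy(float), arms, display)


def read_expression_counts(
    path: str | Path,
    perturbation_column: str = "perturbation",
    control_labels: tuple[str, ...] = ("control", "non-targeting"),
) -> ExpressionCounts:
    """Expression counts from H5AD, MTX-triplet directory, or dense TSV.

    H5AD: cells x genes with the perturbation label in ``obs``. MTX
    directory: ``matrix.mtx`` (cells x genes), ``genes.tsv``,
    ``barcodes.tsv`` (barcode<TAB>perturbation). Dense TSV: one row per
    cell, a ``perturbation`` column, remaining columns are genes.
    """
    path = Path(path)
    if path.suffix == ".h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        X = adata.X
        if hasattr(X, "toarray"):
            X = X.toarray()
        obs = pd.DataFrame(
            {"perturbation": adata.obs[perturbation_column].astype(str).to_numpy()})
        return ExpressionCounts(np.asarray(X), obs, pd.Index(adata.var_names),
                                control_labels)
    if path.is_dir():
        from scipy.io import mmread

        X = np.asarray(mmread(path / "matrix.mtx").todense())
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0]
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None,
                               names=["barcode", "perturbation"])
        return ExpressionCounts(X, barcodes[["perturbation"]],
                                pd.Index(genes), control_labels)
    df = pd.read_csv(path, sep="\t")
    obs = df[[perturbation_column]].rename(
        columns={perturbation_column: "perturbation"})
    counts = df.drop(columns=[perturbation_column])
    return ExpressionCounts(counts.to_numpy(), obs, pd.Index(counts.columns),
                            control_labels)


def write_expression_counts(counts: ExpressionCounts, path: str | Path) -> None:
    """Dense TSV with a leading perturbation column."""
    df = pd.DataFrame(counts.counts, columns=counts.var_names)
    df.insert(0, "perturbation", counts.obs["perturbation"].to_numpy())
    df.to_csv(Path(path), sep="\t", index=False)
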