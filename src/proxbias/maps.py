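"""From replicate-level feature data to gene-level cosine similarity maps.

A phenomics screen measures each guide in many wells; wells are centered on
in-batch perturbation controls, scaled by the control feature spread
("typical variance" normalization), averaged to guides and then to genes
with equal guide weighting. The gene x gene cosine matrix of those vectors
is the object every proximity-bias statistic consumes.

A rank-based Gaussianization (mean 0, sd 0.2) is provided for display
parity across maps; it is flagged so statistics refuse it by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.decomposition import PCA

from .genome import GeneArmIndex

META_COLUMNS = ["guide_id", "gene_id", "batch", "control_flag"]


@dataclass
class WellFeatures:
    """Well/sample-level feature matrix with perturbation metadata.

    ``meta`` has one row per well with columns ``guide_id, gene_id, batch,
    control_flag`` (controls have a true flag and an empty gene id);
    ``X`` is the aligned numeric feature matrix.
    """

    meta: pd.DataFrame
    X: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"well metadata missing columns: {missing}")
        self.X = np.asarray(self.X, dtype=float)
        if len(self.meta) != self.X.shape[0]:
            raise ValueError("metadata and feature matrix row counts differ")
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains non-finite values")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "WellFeatures":
        features = [c for c in df.columns if c not in META_COLUMNS]
        return cls(df[META_COLUMNS].reset_index(drop=True),
                   df[features].to_numpy(float), list(features))

    def to_frame(self) -> pd.DataFrame:
        features = pd.DataFrame(self.X, columns=self.feature_names)
        return pd.concat([self.meta.reset_index(drop=True), features], axis=1)


@dataclass
class GeneVectors:
    """Gene-level feature vectors with replicate provenance."""

    vectors: pd.DataFrame  # genes x features
    provenance: pd.DataFrame | None = None  # n_guides, n_wells per gene

    def __post_init__(self) -> None:
        if self.vectors.index.duplicated().any():
            raise ValueError("duplicate gene rows")
        if not np.isfinite(self.vectors.to_numpy()).all():
            raise ValueError("gene vectors contain non-finite values")

    @property
    def genes(self) -> pd.Index:
        return self.vectors.index


@dataclass
class SimilarityMap:
    """Symmetric gene x gene cosine similarity matrix.

    ``arms`` carries the arm key per gene when a :class:`GeneArmIndex` was
    attached (NaN for unassigned genes). ``display_only`` marks maps that
    went through the display normalization; statistics reject those unless
    explicitly overridden.
    """

    genes: pd.Index
    values: np.ndarray
    arms: pd.Series | None = None
    display_only: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genes)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match gene list")
        if self.arms is not None:
            self.arms = self.arms.reindex(self.genes)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def off_diagonal(self) -> np.ndarray:
        """Upper-triangle (unordered pair) values in row-major order."""
        iu = np.triu_indices(self.n_genes, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.genes)

    def with_arms(self, index: GeneArmIndex) -> "SimilarityMap":
        arms = index.arm_of.reindex(self.genes)
        return SimilarityMap(self.genes, self.values, arms, self.display_only)


def aggregate_to_gene(
    wells: WellFeatures,
    center_on_controls: bool = True,
    scale_strategy: str = "control_std",
) -> GeneVectors:
    """Normalize wells against in-batch controls and aggregate to genes.

    Per batch, the control mean is subtracted feature-wise and features are
    divided by the pooled control standard deviation (``scale_strategy=
    "control_std"``, the default; ``"none"`` skips scaling). Wells are then
    averaged within guide and guides within gene, so genes with unequal
    replicate counts weight each guide equally.
    """
    if scale_strategy not in ("control_std", "none"):
        raise ValueError(f"unknown scale_strategy {scale_strategy!r}")
    meta, X = wells.meta, wells.X.copy()
    if center_on_controls:
        for batch, rows in meta.groupby("batch").groups.items():
            rows = np.asarray(rows)
            ctrl = rows[meta.loc[rows, "control_flag"].to_numpy(bool)]
            if len(ctrl) == 0:
                raise ValueError(f"batch {batch!r} has no control wells")
            mu = X[ctrl].mean(axis=0)
            X[rows] -= mu
            if scale_strategy == "control_std":
                sd = X[ctrl].std(axis=0, ddof=1) if len(ctrl) > 1 else np.ones(X.shape[1])
                zero = sd == 0
                if zero.any():
                    warnings.warn(
                        f"{zero.sum()} zero-variance control features in batch "
                        f"{batch!r}; scale set to 1"
                    )
                    sd = np.where(zero, 1.0, sd)
                X[rows] /= sd
    pert = ~meta["control_flag"].to_numpy(bool)
    df = pd.DataFrame(X[pert])
    df["gene_id"] = meta.loc[pert, "gene_id"].to_numpy()
    df["guide_id"] = meta.loc[pert, "guide_id"].to_numpy()
    n_wells = df.groupby("gene_id").size()
    guide_means = df.groupby(["gene_id", "guide_id"], sort=True).mean()
    gene_means = guide_means.groupby(level="gene_id").mean()
    gene_means.columns = wells.feature_names
    n_guides = guide_means.groupby(level="gene_id").size()
    provenance = pd.DataFrame({"n_guides": n_guides, "n_wells": n_wells})
    return GeneVectors(gene_means, provenance)


def pca_reduce(
    features: pd.DataFrame, variance_cutoff: float = 0.98
) -> pd.DataFrame:
    """Project onto the fewest leading PCs reaching the variance cutoff."""
    if not 0 < variance_cutoff <= 1:
        raise ValueError("variance_cutoff must be in (0, 1]")
    X = np.asarray(features, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns for PCA")
    pca = PCA(n_components=None)
    scores = pca.fit_transform(X)
    evr = np.cumsum(pca.explained_variance_ratio_)
    if variance_cutoff == 1.0:
        k = int((pca.explained_variance_ > 1e-12).sum())
    else:
        k = int(np.searchsorted(evr, variance_cutoff) + 1)
    k = max(k, 1)
    cols = [f"PC{i + 1}" for i in range(k)]
    index = features.index if isinstance(features, pd.DataFrame) else None
    return pd.DataFrame(scores[:, :k], index=index, columns=cols)


def cosine_map(
    vectors: GeneVectors | pd.DataFrame, index: GeneArmIndex | None = None
) -> SimilarityMap:
    """Cosine similarity between gene vectors (symmetric, unit diagonal)."""
    df = vectors.vectors if isinstance(vectors, GeneVectors) else vectors
    X = df.to_numpy(float)
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0
    if zero.any():
        raise ValueError(
            f"all-zero gene vectors: {list(df.index[zero][:10])}"
        )
    U = X / norms[:, None]
    S = U @ U.T
    S = np.clip((S + S.T) / 2, -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    arms = index.arm_of.reindex(df.index) if index is not None else None
    return SimilarityMap(df.index, S, arms)


def quantile_normalize_display(
    smap: SimilarityMap, sigma: float = 0.2
) -> SimilarityMap:
    """Rank-match off-diagonal similarities to N(0, sigma^2) for display.

    Ties take average ranks, so tied inputs map to identical outputs; the
    inverse normal CDF is evaluated at ``(rank - 0.5) / n``. Rank order is
    preserved exactly and the diagonal is untouched. The result is flagged
    ``display_only``.
    """
    vals = smap.off_diagonal()
    if np.unique(vals).size < 2:
        raise ValueError("cannot quantile-normalize a constant map")
    ranks = rankdata(vals, method="average")
    z = norm.ppf((ranks - 0.5) / len(vals)) * sigma
    out = np.zeros_like(smap.values)
    iu = np.triu_indices(smap.n_genes, k=1)
    out[iu] = z
    out = out + out.T
    np.fill_diagonal(out, np.diag(smap.values))
    return SimilarityMap(smap.genes, out, smap.arms, display_only=True)
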