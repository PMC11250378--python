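"""Genes, chromosome arms and coordinate conventions.

Every downstream statistic needs to know which chromosome arm a gene sits
on, how far along the arm it is (centromere -> telomere), and which genomic
direction a cut extends from a gene. This module owns those conventions:

* coordinates are 1-based inclusive once ingested (BED input is converted
  at the reader in :mod:`proxbias.io`);
* a gene is assigned to an arm by its *start* coordinate, matching the
  cut-site semantics of a guide targeting the transcript;
* relative position is ``(rank - 1) / (n_arm - 1)`` with 0 at the
  centromere-proximal end and 1 at the telomere-proximal end of the arm.

The short (p) arms of the acrocentric chromosomes carry essentially no
unique genes and are flagged so that arm-level statistics can exclude
them; the human autosomal universe then has 39 arms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Human chromosomes whose p arm is acrocentric (satellite/stalk only).
ACROCENTRIC_CHROMS = frozenset({"chr13", "chr14", "chr15", "chr21", "chr22"})
SEX_CHROMS = frozenset({"chrX", "chrY"})

LOCUS_COLUMNS = ["gene_id", "symbol", "chrom", "start", "end", "strand"]
ARM_COLUMNS = ["chrom", "arm", "arm_start", "arm_end", "acrocentric"]


def validate_loci(loci: pd.DataFrame) -> pd.DataFrame:
    """Check GeneLocus invariants and return a normalized copy."""
    missing = [c for c in LOCUS_COLUMNS if c not in loci.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    loci = loci[LOCUS_COLUMNS].copy()
    if loci["gene_id"].duplicated().any():
        dupes = loci.loc[loci["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids: {dupes[:5]}")
    bad = loci["start"] >= loci["end"]
    if bad.any():
        raise ValueError(
            f"{bad.sum()} loci with start >= end, e.g. "
            f"{loci.loc[bad, 'gene_id'].iloc[0]}"
        )
    if not loci["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    return loci


@dataclass
class GeneArmIndex:
    """Genes mapped to chromosome arms with within-arm position.

    Attributes
    ----------
    genes
        One row per assigned gene, indexed by ``gene_id``; columns
        ``chrom, start, end, strand, arm`` (e.g. ``"chr1p"``),
        ``within_arm_rank`` (dense 1..n by coordinate) and ``rel_pos``.
    arms
        One row per arm, indexed by arm key; columns ``chrom, arm,
        arm_start, arm_end, acrocentric, autosomal, n_genes``.
    excluded
        Genes that could not be assigned, with a ``reason`` column.
    n_gap_assigned
        Genes whose representative point fell in the centromere gap and
        were attached to the nearer arm boundary.
    """

    genes: pd.DataFrame
    arms: pd.DataFrame
    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene_id", "reason"])
    )
    n_gap_assigned: int = 0

    @property
    def arm_of(self) -> pd.Series:
        return self.genes["arm"]

    @property
    def rel_pos(self) -> pd.Series:
        return self.genes["rel_pos"]

    def genes_on_arm(self, arm: str) -> pd.Index:
        return self.genes.index[self.genes["arm"] == arm]

    def default_arm_universe(
        self, include_acrocentric: bool = False, include_sex: bool = False
    ) -> list[str]:
        """Arms entering arm-level statistics by default."""
        arms = self.arms
        keep = pd.Series(True, index=arms.index)
        if not include_acrocentric:
            keep &= ~(arms["acrocentric"] & (arms["arm"] == "p"))
        if not include_sex:
            keep &= arms["autosomal"]
        return list(arms.index[keep])

    def arm_codes(self, genes: pd.Index, universe: list[str] | None = None) -> np.ndarray:
        """Integer arm code per gene (-1: unassigned or outside universe)."""
        arm = self.genes["arm"].reindex(genes)
        if universe is None:
            universe = self.default_arm_universe()
        lookup = {a: i for i, a in enumerate(universe)}
        return np.array([lookup.get(a, -1) for a in arm.fillna("")], dtype=np.int64)


def build_arms(arms: pd.DataFrame, acrocentric: set[str] | None = None) -> pd.DataFrame:
    """Normalize an ArmDefinition table and check its invariants."""
    missing = [c for c in ARM_COLUMNS if c not in arms.columns and c != "acrocentric"]
    if missing:
        raise ValueError(f"arm table missing columns: {missing}")
    arms = arms.copy()
    if "acrocentric" not in arms.columns:
        acro = ACROCENTRIC_CHROMS if acrocentric is None else acrocentric
        arms["acrocentric"] = arms["chrom"].isin(acro)
    arms["autosomal"] = ~arms["chrom"].isin(SEX_CHROMS)
    arms.index = pd.Index(arms["chrom"] + arms["arm"], name="arm_key")
    for chrom, sub in arms.groupby("chrom"):
        if set(sub["arm"]) != {"p", "q"}:
            continue
        p = sub[sub["arm"] == "p"].iloc[0]
        q = sub[sub["arm"] == "q"].iloc[0]
        if not p["arm_end"] <= q["arm_start"]:
            raise ValueError(f"{chrom}: p arm span must precede q arm span")
    return arms


def assign_arms(
    loci: pd.DataFrame,
    arms: pd.DataFrame,
    max_gap_distance: int = 1_000_000,
) -> GeneArmIndex:
    """Assign each gene to a chromosome arm by its start coordinate.

    Genes whose start falls in the centromere gap (or just beyond an arm
    terminus) are attached to the nearest arm boundary when within
    ``max_gap_distance`` (1 Mb), else excluded. Genes on chromosomes with
    no arm definition are excluded. Conservation holds:
    ``len(assigned) + len(excluded) == len(loci)``.
    """
    loci = validate_loci(loci)
    arms = build_arms(arms)
    records, excluded = [], []
    n_gap = 0
    by_chrom = {c: sub for c, sub in arms.groupby("chrom")}
    for row in loci.itertuples(index=False):
        sub = by_chrom.get(row.chrom)
        if sub is None:
            excluded.append((row.gene_id, "no arm definitions for chromosome"))
            continue
        pos = row.start
        inside = sub[(sub["arm_start"] <= pos) & (pos <= sub["arm_end"])]
        if len(inside):
            records.append((row.gene_id, row.chrom, row.start, row.end, row.strand,
                            inside.index[0]))
            continue
        # distance to the nearest arm boundary
        dist = np.minimum(np.abs(sub["arm_start"] - pos), np.abs(sub["arm_end"] - pos))
        nearest = dist.idxmin()
        if dist.min() <= max_gap_distance:
            n_gap += 1
            records.append((row.gene_id, row.chrom, row.start, row.end, row.strand,
                            nearest))
        else:
            excluded.append((row.gene_id, "outside arm spans beyond max_gap_distance"))
    genes = pd.DataFrame(
        records, columns=["gene_id", "chrom", "start", "end", "strand", "arm"]
    ).set_index("gene_id")
    arms = arms.copy()
    arms["n_genes"] = genes["arm"].value_counts().reindex(arms.index).fillna(0).astype(int)
    index = GeneArmIndex(
        genes=genes,
        arms=arms,
        excluded=pd.DataFrame(excluded, columns=["gene_id", "reason"]),
        n_gap_assigned=n_gap,
    )
    relative_positions(index)
    return index


def relative_positions(index: GeneArmIndex) -> pd.Series:
    """Within-arm dense ranks and centromere->telomere relative positions.

    Ranks order genes by start coordinate (ties broken by gene id for
    reproducibility). ``rel_pos`` runs 0 at the centromere-proximal gene to
    1 at the telomere-proximal gene: increasing coordinate on q arms,
    decreasing on p arms. Single-gene arms get ``rel_pos`` 0.
    """
    genes = index.genes
    ranks = np.zeros(len(genes), dtype=int)
    rel = np.zeros(len(genes), dtype=float)
    for arm_key, sub in genes.groupby("arm", sort=False):
        order = sub.assign(_gid=sub.index).sort_values(["start", "_gid"])
        pos = genes.index.get_indexer(order.index)
        n = len(order)
        ranks[pos] = np.arange(1, n + 1)
        if n == 1:
            warnings.warn(f"arm {arm_key} has a single scored gene; rel_pos 0")
            rel[pos] = 0.0
            continue
        frac = np.arange(n) / (n - 1)
        if index.arms.loc[arm_key, "arm"] == "p":
            frac = frac[::-1]  # telomere is at low coordinates on p arms
        rel[pos] = frac
    genes["within_arm_rank"] = ranks
    genes["rel_pos"] = rel
    return genes["rel_pos"]


def genomic_direction(gene_id: str, side: str, index: GeneArmIndex) -> str:
    """Label the genomic direction of a gene's 3' or 5' side.

    On a ``+`` strand gene the 3' side points toward increasing coordinate;
    on a ``-`` strand gene, decreasing. That coordinate direction is
    *telomeric* on a q arm when increasing and on a p arm when decreasing,
    *centromeric* otherwise.
    """
    if side not in ("3prime", "5prime"):
        raise ValueError(f"side must be '3prime' or '5prime', got {side!r}")
    if gene_id not in index.genes.index:
        raise KeyError(f"gene {gene_id!r} not in arm index")
    row = index.genes.loc[gene_id]
    strand = row["strand"]
    if strand not in ("+", "-"):
        raise ValueError(f"gene {gene_id!r} has no usable strand: {strand!r}")
    increasing = (side == "3prime") == (strand == "+")
    q_arm = index.arms.loc[row["arm"], "arm"] == "q"
    return "telomeric" if increasing == q_arm else "centromeric"


def coordinate_step(gene_id: str, side: str, index: GeneArmIndex) -> int:
    """+1 if the side points toward increasing coordinate, else -1."""
    if side not in ("3prime", "5prime"):
        raise ValueError(f"side must be '3prime' or '5prime', got {side!r}")
    strand = index.genes.loc[gene_id, "strand"]
    return 1 if (side == "3prime") == (strand == "+") else -1
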