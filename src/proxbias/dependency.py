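"""Proximity bias in pooled CRISPR dependency screens.

A gene's dependency profile across cell lines is treated as its feature
vector: rows are mean-centered over the chosen line subset and related by
cosine, giving a similarity map the Brunner-Munzel machinery consumes
unchanged. On top of that sit the screen-specific analyses:

* CNV-clean arm pairs -- restrict to lines with <1% of an arm's genes
  outside copy number (1.75, 2.25), intersect per pair, and show the bias
  survives without copy-number variation;
* genotype-stratified bootstrap bias -- compare WT vs LOF/AMP line sets
  for a gene (optionally within a TP53 background) via repeated
  20-line map constructions;
* the spurious-dependency screen -- unexpressed genes centromeric of a
  subtype driver that look differentially essential purely through
  truncation spillover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind
from statsmodels.stats.multitest import multipletests

from ._util import check_seed
from .genome import GeneArmIndex
from .maps import SimilarityMap, cosine_map
from .proximity import BootstrapConfig, bm_exact, bm_montecarlo


@dataclass
class DependencyPanel:
    """Gene x cell-line dependency scores with per-line genomic context.

    All matrices are genes x lines and share keys; ``lineage`` maps each
    line to its subtype/lineage label.
    """

    dependency: pd.DataFrame
    copy_number: pd.DataFrame
    damaging: pd.DataFrame  # bool: nonsense/frameshift mutation
    tpm: pd.DataFrame
    lineage: pd.Series

    def __post_init__(self) -> None:
        genes, lines = self.dependency.index, self.dependency.columns
        for name in ("copy_number", "damaging", "tpm"):
            m = getattr(self, name)
            if not (m.index.equals(genes) and m.columns.equals(lines)):
                raise ValueError(f"{name} keys do not match dependency matrix")
        if not self.lineage.index.equals(lines):
            raise ValueError("lineage index does not match cell lines")
        if (self.copy_number.to_numpy() < 0).any():
            raise ValueError("copy numbers must be >= 0")

    @property
    def genes(self) -> pd.Index:
        return self.dependency.index

    @property
    def lines(self) -> pd.Index:
        return self.dependency.columns


@dataclass
class StratifiedBiasResult:
    """Bootstrap bias comparison between WT and mutant line sets."""

    gene: str
    condition: str  # LOF or AMP
    background: str
    wt_probabilities: np.ndarray = field(repr=False)
    mutant_probabilities: np.ndarray = field(repr=False)
    mean_difference: float = np.nan
    p_value: float = np.nan
    p_adj: float | None = None
    n_wt_lines: int = 0
    n_mutant_lines: int = 0


def build_dependency_map(
    panel: DependencyPanel,
    line_subset: list[str] | pd.Index | None = None,
    index: GeneArmIndex | None = None,
) -> SimilarityMap:
    """Row mean-centered cosine map over a cell-line subset.

    Centering removes each gene's constant essentiality offset so cosine
    reflects the co-variation of dependencies, not shared essentiality.
    Genes with zero variance over the subset are excluded.
    """
    lines = panel.lines if line_subset is None else pd.Index(line_subset)
    if len(lines) < 2:
        raise ValueError("need at least 2 cell lines")
    X = panel.dependency[lines]
    centered = X.sub(X.mean(axis=1), axis=0)
    keep = centered.std(axis=1) > 0
    if not keep.all():
        centered = centered[keep]
    return cosine_map(centered, index)


def cnv_clean_lines(
    panel: DependencyPanel,
    arm: str,
    index: GeneArmIndex,
    cn_window: tuple[float, float] = (1.75, 2.25),
    max_frac_out: float = 0.01,
) -> pd.Index:
    """Lines with <1% of the arm's genes outside the copy-number window."""
    genes = index.genes_on_arm(arm).intersection(panel.genes)
    if len(genes) == 0:
        raise ValueError(f"no copy-number data for genes on arm {arm}")
    cn = panel.copy_number.loc[genes]
    frac_out = ((cn < cn_window[0]) | (cn > cn_window[1])).mean(axis=0)
    return panel.lines[frac_out < max_frac_out]


def arm_pair_universe(index: GeneArmIndex) -> list[tuple[str, str]]:
    """Unordered pairs of autosomal, non-acrocentric arms."""
    return list(combinations(index.default_arm_universe(), 2))


def arm_pair_bias(
    panel: DependencyPanel,
    index: GeneArmIndex,
    cn_window: tuple[float, float] = (1.75, 2.25),
    max_frac_out: float = 0.01,
    min_lines: int = 20,
) -> pd.DataFrame:
    """Arm-level bias for every CNV-clean arm pair (two values per pair).

    For each unordered pair {A, B}: intersect the CNV-clean line sets of A
    and B, build a map restricted to genes on the two arms, and emit the
    exact BM probability of A-within vs A-B-between pairs and of B-within
    vs between. 39 clean autosomal arms give 741 pairs / 1,482 values.
    """
    clean = {arm: cnv_clean_lines(panel, arm, index, cn_window, max_frac_out)
             for arm in index.default_arm_universe()}
    rows = []
    for a, b in arm_pair_universe(index):
        lines = clean[a].intersection(clean[b])
        if len(lines) < min_lines:
            rows.append((a, b, a, np.nan, len(lines), "skipped"))
            rows.append((a, b, b, np.nan, len(lines), "skipped"))
            continue
        genes = index.genes_on_arm(a).union(index.genes_on_arm(b))
        genes = genes.intersection(panel.genes)
        sub = DependencyPanel(
            panel.dependency.loc[genes], panel.copy_number.loc[genes],
            panel.damaging.loc[genes], panel.tpm.loc[genes], panel.lineage)
        smap = build_dependency_map(sub, list(lines), index)
        arm_of = index.arm_of.reindex(smap.genes)
        codes = (arm_of == b).astype(int).to_numpy()
        iu, ju = np.triu_indices(smap.n_genes, k=1)
        vals = smap.values[iu, ju]
        within_a = (codes[iu] == 0) & (codes[ju] == 0)
        within_b = (codes[iu] == 1) & (codes[ju] == 1)
        between = codes[iu] != codes[ju]
        for arm_label, within in ((a, within_a), (b, within_b)):
            res = bm_exact(vals[within], vals[between], level="arm_pair",
                           label=f"{arm_label}|{a}-{b}")
            rows.append((a, b, arm_label, res.probability, len(lines), "tested"))
    return pd.DataFrame(
        rows, columns=["arm_a", "arm_b", "within_arm", "probability",
                       "n_lines", "status"])


def genotype_split(
    panel: DependencyPanel,
    gene: str,
    mode: str,
    background_gene: str | None = None,
    background_mode: str | None = None,
) -> tuple[pd.Index, pd.Index]:
    """(WT, mutant) cell-line sets for a gene under LOF or AMP.

    LOF: copy number <= 1.5. AMP: copy number >= 2.5 and no damaging
    (nonsense/frameshift) mutation. WT: lines in neither set and without
    a damaging mutation (a damaging mutation is functional LOF whatever
    the copy number, so such lines belong in no comparison group other
    than LOF-by-mutation analyses). When a background is given (e.g. TP53 WT or TP53 partial LOF, copy number
    <= 1.5), lines are restricted to it first.
    """
    if mode not in ("LOF", "AMP"):
        raise ValueError("mode must be 'LOF' or 'AMP'")
    lines = panel.lines
    if background_gene is not None:
        bg_cn = panel.copy_number.loc[background_gene]
        if background_mode == "LOF":
            lines = lines[bg_cn.loc[lines] <= 1.5]
        elif background_mode == "WT":
            bg_dam = panel.damaging.loc[background_gene]
            lines = lines[(bg_cn.loc[lines] > 1.5) & ~bg_dam.loc[lines]]
        else:
            raise ValueError("background_mode must be 'WT' or 'LOF'")
    cn = panel.copy_number.loc[gene, lines]
    dam = panel.damaging.loc[gene, lines].astype(bool)
    lof = lines[cn <= 1.5]
    amp = lines[(cn >= 2.5) & ~dam]
    mutant = lof if mode == "LOF" else amp
    wt = lines[(cn > 1.5) & (cn < 2.5) & ~dam]
    return wt, mutant


def stratified_bootstrap_bias(
    panel: DependencyPanel,
    gene: str,
    mode: str,
    index: GeneArmIndex,
    background_gene: str | None = None,
    background_mode: str | None = None,
    lines_per_sample: int = 20,
    s_trials: int = 4,
    cfg: BootstrapConfig | None = None,
    min_lines: int = 25,
    seed: int | np.random.Generator | None = None,
) -> StratifiedBiasResult:
    """Bootstrap genome-bias difference between WT and mutant line sets.

    Each of ``s_trials`` bootstraps samples ``lines_per_sample`` lines per
    condition, builds a map and computes the Monte-Carlo BM probability.
    Conditions with fewer than ``min_lines`` lines are skipped (raises).
    The reported difference is mean(mutant) - mean(WT) with a Welch t-test
    over the bootstrap values.
    """
    rng = check_seed(seed)
    cfg = cfg or BootstrapConfig(n_pairs=500, t_trials=200, seed=rng)
    wt, mutant = genotype_split(panel, gene, mode, background_gene, background_mode)
    if len(wt) < min_lines or len(mutant) < min_lines:
        raise ValueError(
            f"{gene} {mode}: condition below min_lines={min_lines} "
            f"(WT {len(wt)}, mutant {len(mutant)})")

    def boot(lines: pd.Index) -> np.ndarray:
        vals = np.empty(s_trials)
        for s in range(s_trials):
            sample = rng.choice(lines.to_numpy(), lines_per_sample, replace=False)
            smap = build_dependency_map(panel, list(sample), index)
            vals[s] = bm_montecarlo(smap, index, cfg).probability
        return vals

    wt_probs = boot(wt)
    mut_probs = boot(mutant)
    if s_trials > 1:
        t_res = ttest_ind(mut_probs, wt_probs, equal_var=False)
        p = float(t_res.pvalue)
    else:
        p = np.nan
    return StratifiedBiasResult(
        gene, mode, f"{background_gene}:{background_mode}" if background_gene else "all",
        wt_probs, mut_probs, float(mut_probs.mean() - wt_probs.mean()), p,
        n_wt_lines=len(wt), n_mutant_lines=len(mutant))


def spurious_dependency_screen(
    panel: DependencyPanel,
    subtype: str,
    driver_list: dict[str, str] | list[str],
    index: GeneArmIndex,
    tpm_max: float = 0.3,
    cn_window: tuple[float, float] = (1.75, 2.25),
    alpha: float = 0.01,
    min_subtype_lines: int = 3,
) -> pd.DataFrame:
    """Unexpressed genes centromeric of a driver with spurious dependency.

    Per gene, lines are restricted to copy number inside ``cn_window`` at
    that gene, and a Welch t-test compares subtype vs other lines;
    Benjamini-Hochberg correction runs across genes. A gene is flagged
    when adjusted p < alpha, mean subtype TPM < ``tpm_max`` and the gene
    lies centromeric of a listed driver on the same arm.
    """
    drivers = list(driver_list.values()) if isinstance(driver_list, dict) else list(driver_list)
    in_subtype = panel.lineage == subtype
    rel = index.rel_pos
    arm_of = index.arm_of
    rows = []
    for gene in panel.genes:
        cn = panel.copy_number.loc[gene]
        clean = (cn >= cn_window[0]) & (cn <= cn_window[1])
        sub = clean & in_subtype
        rest = clean & ~in_subtype
        if sub.sum() < min_subtype_lines or rest.sum() < 2:
            continue
        dep_sub = panel.dependency.loc[gene, sub[sub].index]
        dep_rest = panel.dependency.loc[gene, rest[rest].index]
        if dep_sub.std() == 0 and dep_rest.std() == 0:
            continue
        t_res = ttest_ind(dep_sub, dep_rest, equal_var=False)
        tpm_sub = float(panel.tpm.loc[gene, sub[sub].index].mean())
        centromeric_of = ""
        if gene in arm_of.index:
            for d in drivers:
                if (d in arm_of.index and d != gene
                        and arm_of[d] == arm_of[gene]
                        and rel[gene] < rel[d]):
                    centromeric_of = d
                    break
        rows.append((gene, float(t_res.statistic), float(t_res.pvalue),
                     tpm_sub, centromeric_of,
                     float(dep_sub.mean() - dep_rest.mean())))
    out = pd.DataFrame(
        rows, columns=["gene_id", "t_stat", "p_value", "subtype_tpm",
                       "centromeric_of_driver", "dependency_difference"]
    ).set_index("gene_id")
    if len(out) == 0:
        out["p_adj"] = []
        out["flagged"] = []
        return out
    out["p_adj"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["flagged"] = (
        (out["p_adj"] < alpha)
        & (out["subtype_tpm"] < tpm_max)
        & (out["centromeric_of_driver"] != "")
        & (out["dependency_difference"] < 0)  # more essential in the subtype
    )
    return out
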