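"""Seeded generators for every input the pipeline consumes.

The generators encode the truncation mechanism the analysis is built to
detect: an unrepaired Cas9 cut occasionally detaches the chromosome-arm
fragment telomeric of the target, so a perturbed population is a mixture
of clean knockouts and cells/wells that additionally lost every gene out
to the telomere. Three data modalities are produced:

* phenomics wells -- gene loss-of-function effect vectors from a sparse
  Gaussian dictionary, truncation contamination summing the effects of
  the key genes telomeric of the cut, control wells, and ground truth
  (key genes, related pairs, truncated wells, unexpressed genes);
* expression counts -- negative-binomial counts with dosage loss of the
  telomeric genes in an affected subpopulation of each target's cells;
* dependency panels -- base essentiality, subtype driver effects, a
  truncation-spillover term that transfers part of a driver's effect to
  genes centromeric of it, arm-scale CNV events, damaging mutations and
  TPM with designated unexpressed genes.

Every generator is deterministic under its seed and emits its ground
truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import check_seed
from .genome import GeneArmIndex, assign_arms
from .maps import WellFeatures
from .truncation import ExpressionCounts
from .dependency import DependencyPanel


@dataclass
class TruncationModel:
    """Parameters of the truncation mixture.

    ``rho`` is the per-well truncation probability in phenomics;
    ``affected_fraction`` the per-cell analog in expression data;
    ``dosage`` the expression multiplier for lost genes. Key genes (those
    with a nonzero LOF phenotype) cover ``key_gene_density`` of expressed
    genes; their effect vectors are nonzero on ``effect_density`` of
    features with scale ``effect_scale``. ``interstitial_prob`` routes
    that share of truncations to an interstitial deletion (cut to a
    random interior breakpoint) instead of running to the telomere.
    """

    rho: float = 0.1
    affected_fraction: float = 0.1
    dosage: float = 0.5
    noise_sd: float = 1.0
    key_gene_density: float = 0.2
    effect_density: float = 0.25
    effect_scale: float = 0.4
    interstitial_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in ("rho", "affected_fraction", "interstitial_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 < self.dosage <= 1:
            raise ValueError("dosage must be in (0, 1]")


@dataclass
class SimGenome:
    """A toy genome with its arm index and unexpressed-gene labels."""

    loci: pd.DataFrame
    arms: pd.DataFrame
    index: GeneArmIndex
    unexpressed: set[str] = field(default_factory=set)


def make_genome(
    n_chrom: int = 4,
    genes_per_arm: int = 200,
    seed: int | np.random.Generator | None = 0,
    arm_length: int = 50_000_000,
    centromere_gap: int = 3_000_000,
    gene_span: int = 20_000,
    unexpressed_frac: float = 0.4,
) -> SimGenome:
    """Deterministic toy genome: both arms per chromosome, even spacing.

    Strands are random; per arm, ``unexpressed_frac`` of genes are labeled
    unexpressed (no phenotype when knocked out), mirroring the roughly
    half of the genome a single cell type does not transcribe.
    """
    if n_chrom < 1 or genes_per_arm < 2:
        raise ValueError("need n_chrom >= 1 and genes_per_arm >= 2")
    rng = check_seed(seed)
    spacing = arm_length // (genes_per_arm + 1)
    loci_rows, arm_rows = [], []
    unexpressed: set[str] = set()
    gid = 0
    for c in range(1, n_chrom + 1):
        chrom = f"chr{c}"
        p_span = (1, arm_length)
        q_span = (arm_length + centromere_gap + 1, 2 * arm_length + centromere_gap)
        arm_rows.append((chrom, "p", *p_span, False))
        arm_rows.append((chrom, "q", *q_span, False))
        for arm_key, (lo, _hi) in (("p", p_span), ("q", q_span)):
            starts = lo + spacing * (1 + np.arange(genes_per_arm))
            for s in starts:
                gid += 1
                strand = "+" if rng.random() < 0.5 else "-"
                loci_rows.append((f"g{gid:05d}", f"G{gid}", chrom,
                                  int(s), int(s) + gene_span, strand))
            ids = [r[0] for r in loci_rows[-genes_per_arm:]]
            n_un = int(round(unexpressed_frac * genes_per_arm))
            unexpressed.update(rng.choice(ids, n_un, replace=False))
    loci = pd.DataFrame(
        loci_rows, columns=["gene_id", "symbol", "chrom", "start", "end", "strand"])
    arms = pd.DataFrame(
        arm_rows, columns=["chrom", "arm", "arm_start", "arm_end", "acrocentric"])
    index = assign_arms(loci, arms)
    return SimGenome(loci, arms, index, unexpressed)


@dataclass
class PhenomicsTruth:
    """Ground truth emitted with simulated phenomics wells."""

    key_genes: list[str]
    effects: pd.DataFrame  # key genes x features
    related_pairs: list[tuple[str, str]]
    truncated_wells: np.ndarray
    unexpressed: set[str]


def _telomeric_order(index: GeneArmIndex) -> dict[str, list[str]]:
    """Genes per arm ordered centromere -> telomere."""
    out = {}
    for arm in index.arms.index:
        sub = index.genes[index.genes["arm"] == arm]
        out[arm] = list(sub.sort_values("rel_pos").index)
    return out


def simulate_phenomics(
    genome: SimGenome,
    model: TruncationModel | None = None,
    n_guides: int = 4,
    n_wells: int = 6,
    n_features: int = 128,
    n_control_wells: int = 96,
    n_batches: int = 2,
    n_related_pairs: int = 20,
    seed: int | np.random.Generator | None = 0,
) -> tuple[WellFeatures, PhenomicsTruth]:
    """Phenomics wells under the truncation mixture model.

    Each well targeting gene g carries g's LOF effect plus, with
    probability ``rho``, the summed effects of the key genes telomeric of
    g on g's arm (the truncation), plus Gaussian noise. Controls are noise
    only. ``n_related_pairs`` pairs of key genes on different chromosomes
    share an effect vector, providing ground-truth relationships for
    recall benchmarking.
    """
    model = model or TruncationModel()
    rng = check_seed(seed)
    idx = genome.index
    genes = list(idx.genes.index)
    n_genes = len(genes)
    gpos = {g: i for i, g in enumerate(genes)}
    expressed = [g for g in genes if g not in genome.unexpressed]
    n_key = int(round(model.key_gene_density * n_genes))
    key_genes = sorted(rng.choice(expressed, min(n_key, len(expressed)),
                                  replace=False))
    # sparse Gaussian effect dictionary
    eff = np.zeros((n_genes, n_features))
    kpos = np.array([gpos[g] for g in key_genes])
    mask = rng.random((len(kpos), n_features)) < model.effect_density
    eff[kpos] = rng.normal(0, model.effect_scale, (len(kpos), n_features)) * mask
    # related pairs: key genes on different chromosomes share an effect
    chrom_of = idx.genes["chrom"]
    related: list[tuple[str, str]] = []
    pool = list(key_genes)
    rng.shuffle(pool)
    while pool and len(related) < n_related_pairs:
        a = pool.pop()
        partner = next((g for g in pool if chrom_of[g] != chrom_of[a]), None)
        if partner is None:
            break
        pool.remove(partner)
        eff[gpos[partner]] = eff[gpos[a]]
        related.append((a, partner))
    # truncation contamination: sum of key effects strictly telomeric of g
    trunc = np.zeros_like(eff)
    arm_orders = _telomeric_order(idx)
    for order in arm_orders.values():
        rows = [gpos[g] for g in order]
        tail = np.cumsum(eff[rows][::-1], axis=0)[::-1]
        trunc[rows[:-1]] = tail[1:]
    # wells
    n_pert = n_genes * n_guides * n_wells
    gene_idx = np.repeat(np.arange(n_genes), n_guides * n_wells)
    guide_no = np.tile(np.repeat(np.arange(n_guides), n_wells), n_genes)
    truncated = rng.random(n_pert) < model.rho
    X = eff[gene_idx].copy()
    if model.interstitial_prob > 0:
        interstitial = truncated & (rng.random(n_pert) < model.interstitial_prob)
        full = truncated & ~interstitial
        X[full] += trunc[gene_idx[full]]
        for w in np.where(interstitial)[0]:
            g = genes[gene_idx[w]]
            order = arm_orders[idx.arm_of[g]]
            k = order.index(g)
            stop = rng.integers(k + 1, len(order) + 1)
            lost = [gpos[h] for h in order[k + 1: stop]]
            X[w] += eff[lost].sum(axis=0)
    else:
        X[truncated] += trunc[gene_idx[truncated]]
    X += rng.normal(0, model.noise_sd, X.shape)
    ctrl = rng.normal(0, model.noise_sd, (n_control_wells, n_features))
    meta = pd.DataFrame({
        "guide_id": [f"{genes[g]}_sg{k + 1}" for g, k in zip(gene_idx, guide_no)],
        "gene_id": [genes[g] for g in gene_idx],
        "batch": [f"b{i % n_batches}" for i in range(n_pert)],
        "control_flag": False,
    })
    ctrl_meta = pd.DataFrame({
        "guide_id": [f"ctrl_{i}" for i in range(n_control_wells)],
        "gene_id": "",
        "batch": [f"b{i % n_batches}" for i in range(n_control_wells)],
        "control_flag": True,
    })
    wells = WellFeatures(
        pd.concat([meta, ctrl_meta], ignore_index=True),
        np.vstack([X, ctrl]),
        [f"f{i}" for i in range(n_features)],
    )
    truth = PhenomicsTruth(
        list(key_genes),
        pd.DataFrame(eff[kpos], index=pd.Index(key_genes, name="gene_id")),
        related, truncated, set(genome.unexpressed))
    return wells, truth


@dataclass
class ExpressionTruth:
    """Ground truth emitted with simulated expression counts."""

    affected: np.ndarray  # bool per cell
    lost_genes: dict[str, list[str]]  # target -> genes at reduced dosage
    targets: list[str]
    base_means: pd.Series


def simulate_expression(
    genome: SimGenome,
    targets: list[str] | int = 20,
    model: TruncationModel | None = None,
    n_cells_per_target: int = 200,
    n_control_cells: int = 200,
    nb_dispersion: float = 0.01,
    mean_log: tuple[float, float] = (2.5, 0.8),
    min_telomeric_genes: int = 160,
    seed: int | np.random.Generator | None = 0,
) -> tuple[ExpressionCounts, ExpressionTruth]:
    """Negative-binomial counts with telomeric dosage loss.

    For each target, an ``affected_fraction`` subset of its cells has the
    target and every gene telomeric of it on the same arm scaled by
    ``dosage``. When ``targets`` is an integer, that many targets are
    drawn among genes with at least ``min_telomeric_genes`` telomeric
    neighbors (so the planted loss spans a full calling window), spread
    round-robin across arms the way a genome-wide screen spreads its
    targets. Counts are Gamma-Poisson with variance
    ``mu + nb_dispersion * mu^2``; the default depth/dispersion profile
    emulates deeply sequenced plate-based cells.
    """
    model = model or TruncationModel()
    rng = check_seed(seed)
    idx = genome.index
    genes = list(idx.genes.index)
    gpos = {g: i for i, g in enumerate(genes)}
    arm_orders = _telomeric_order(idx)
    tel_count = {}
    for order in arm_orders.values():
        for k, g in enumerate(order):
            tel_count[g] = len(order) - k - 1
    if isinstance(targets, int):
        n_targets = targets
        per_arm = {
            arm: [g for g in order if tel_count[g] >= min_telomeric_genes]
            for arm, order in arm_orders.items()}
        per_arm = {a: v for a, v in per_arm.items() if v}
        if sum(len(v) for v in per_arm.values()) < n_targets:
            raise ValueError(
                f"not enough genes with >= {min_telomeric_genes} "
                "telomeric neighbors")
        chosen: list[str] = []
        arms_cycle = sorted(per_arm)
        while len(chosen) < n_targets:
            for arm in arms_cycle:
                pool = per_arm[arm]
                if pool and len(chosen) < n_targets:
                    pick = pool.pop(rng.integers(len(pool)))
                    chosen.append(pick)
        targets = sorted(chosen)
    else:
        missing = [t for t in targets if t not in gpos]
        if missing:
            raise ValueError(f"targets not in genome: {missing[:5]}")
    base = np.exp(rng.normal(mean_log[0], mean_log[1], len(genes)))
    lost_genes: dict[str, list[str]] = {}
    for t in targets:
        order = arm_orders[idx.arm_of[t]]
        k = order.index(t)
        lost_genes[t] = order[k:]  # target + telomeric genes
    n_cells = len(targets) * n_cells_per_target + n_control_cells
    labels = np.array(
        [t for t in targets for _ in range(n_cells_per_target)]
        + ["control"] * n_control_cells)
    affected = np.zeros(n_cells, dtype=bool)
    mu = np.tile(base, (n_cells, 1))
    for ti, t in enumerate(targets):
        rows = np.arange(ti * n_cells_per_target, (ti + 1) * n_cells_per_target)
        hit = rows[rng.random(len(rows)) < model.affected_fraction]
        affected[hit] = True
        cols = [gpos[g] for g in lost_genes[t]]
        mu[np.ix_(hit, cols)] *= model.dosage
    if nb_dispersion > 0:
        shape = 1.0 / nb_dispersion
        lam = rng.gamma(shape, mu / shape)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(np.int32)
    obs = pd.DataFrame({"perturbation": labels})
    ec = ExpressionCounts(counts, obs, pd.Index(genes, name="gene_id"))
    truth = ExpressionTruth(affected, lost_genes, list(targets),
                            pd.Series(base, index=genes))
    return ec, truth


@dataclass
class DependencyTruth:
    """Ground truth emitted with simulated dependency panels."""

    drivers: dict[str, str]  # subtype -> driver gene
    spurious_genes: dict[str, list[str]]  # subtype -> unexpressed centromeric genes
    mediator: str | None
    mediator_lof_lines: list[str]
    unexpressed: set[str]


def simulate_dependency(
    genome: SimGenome,
    n_lines: int = 120,
    subtypes: tuple[str, ...] = ("subtypeA", "subtypeB", "other"),
    subtype_probs: tuple[float, ...] = (0.2, 0.2, 0.6),
    drivers: dict[str, str] | None = None,
    driver_effect: float = -1.0,
    truncation_spillover: float = 0.3,
    cnv_rate: float = 0.1,
    mediator: str | None = None,
    mediator_lof_frac: float = 0.3,
    mediator_spillover_multiplier: float = 2.0,
    noise_sd: float = 0.3,
    damaging_rate: float = 0.01,
    seed: int | np.random.Generator | None = 0,
) -> tuple[DependencyPanel, DependencyTruth]:
    """Dependency panel with planted drivers and truncation spillover.

    Dependency = base essentiality + subtype driver effect + spillover +
    noise. The spillover term has two parts, both consequences of cutting:
    (a) a nested random arm walk shared by lines (key-gene loss effects
    telomeric of each gene), which produces arm-scale proximity bias even
    in CNV-clean lines; and (b) a transfer of each driver's effect to the
    genes centromeric of it on the same arm, which creates the spurious
    subtype dependencies the screen looks for. Copy-number events are
    arm-scale (whole-arm gain/loss per line at ``cnv_rate``). A mediator
    gene, when given, doubles the spillover in its planted LOF lines.
    """
    rng = check_seed(seed)
    idx = genome.index
    genes = list(idx.genes.index)
    n_genes = len(genes)
    gpos = {g: i for i, g in enumerate(genes)}
    lines = [f"line{i:03d}" for i in range(n_lines)]
    lineage = pd.Series(
        rng.choice(subtypes, n_lines, p=subtype_probs), index=lines)
    arm_orders = _telomeric_order(idx)
    expressed = [g for g in genes if g not in genome.unexpressed]
    if drivers is None:
        drivers = {}
        named = [s for s in subtypes if s != "other"]
        # drivers sit mid-arm among expressed genes so both centromeric
        # neighbors and telomeric room exist
        for s, arm in zip(named, list(arm_orders)):
            order = arm_orders[arm]
            candidates = [g for g in order[len(order) // 3: 2 * len(order) // 3]
                          if g in expressed]
            drivers[s] = candidates[len(candidates) // 2]
    dep = rng.normal(0, noise_sd, (n_genes, n_lines))
    dep += rng.normal(-0.2, 0.2, (n_genes, 1))  # per-gene base essentiality
    # (b) driver effects and centromeric spillover
    spurious: dict[str, list[str]] = {}
    for s, d in drivers.items():
        cols = (lineage == s).to_numpy()
        dep[gpos[d], cols] += driver_effect
        order = arm_orders[idx.arm_of[d]]
        k = order.index(d)
        centromeric = order[:k]
        for g in centromeric:
            dep[gpos[g], cols] += truncation_spillover * driver_effect
        spurious[s] = [g for g in centromeric if g in genome.unexpressed]
    # mediator LOF lines get amplified spillover
    mediator_lines: list[str] = []
    if mediator is not None:
        if mediator not in gpos:
            raise ValueError(f"mediator {mediator!r} not in genome")
        n_lof = int(round(mediator_lof_frac * n_lines))
        mediator_lines = list(rng.choice(lines, n_lof, replace=False))
    spill_scale = np.ones(n_lines)
    if mediator_lines:
        spill_scale[[lines.index(l) for l in mediator_lines]] = (
            mediator_spillover_multiplier)
    # (a) nested arm walk: shared proximal-loss phenotype across lines
    if truncation_spillover > 0:
        for order in arm_orders.values():
            rows = [gpos[g] for g in order]
            z = rng.normal(0, 1, (len(rows), n_lines))
            tail = np.cumsum(z[::-1], axis=0)[::-1]
            contrib = np.zeros_like(z)
            contrib[:-1] = tail[1:] / np.sqrt(np.maximum(
                np.arange(len(rows) - 1, 0, -1), 1))[:, None]
            dep[rows] += truncation_spillover * contrib * spill_scale[None, :]
    # copy number: arm-scale events
    cn = np.full((n_genes, n_lines), 2.0)
    for order in arm_orders.values():
        rows = [gpos[g] for g in order]
        events = rng.random(n_lines) < cnv_rate
        sign = rng.choice([-1.0, 1.0], n_lines)
        cn[np.ix_(rows, np.where(events)[0])] += sign[events]
    if mediator_lines:
        cn[gpos[mediator], [lines.index(l) for l in mediator_lines]] = 1.0
    damaging = rng.random((n_genes, n_lines)) < damaging_rate
    tpm = np.exp(rng.normal(2.0, 1.0, (n_genes, n_lines)))
    un_rows = [gpos[g] for g in genome.unexpressed]
    tpm[un_rows] = rng.uniform(0, 0.2, (len(un_rows), n_lines))
    gi = pd.Index(genes, name="gene_id")
    li = pd.Index(lines, name="cell_line")
    panel = DependencyPanel(
        pd.DataFrame(dep, index=gi, columns=li),
        pd.DataFrame(cn, index=gi, columns=li),
        pd.DataFrame(damaging, index=gi, columns=li),
        pd.DataFrame(tpm, index=gi, columns=li),
        lineage.rename_axis("cell_line"),
    )
    truth = DependencyTruth(drivers, spurious, mediator, mediator_lines,
                            set(genome.unexpressed))
    return panel, truth
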