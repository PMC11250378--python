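"""Recall of annotated gene-gene relationships from a similarity map.

A map "predicts" a relationship for the most extreme similarities: the top
and bottom ``tail_frac`` of off-diagonal pairs (5% + 5% by default). Recall
is the fraction of annotation pairs, restricted to genes present in the
map, that land in that predicted set; annotations spread randomly through
the similarity distribution give a baseline of ``2 * tail_frac`` (0.1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from ._util import condensed_index
from .genome import GeneArmIndex
from .maps import SimilarityMap


@dataclass
class AnnotationSet:
    """Named set of unordered annotated gene-id pairs (no self-pairs)."""

    name: str
    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen = set()
        clean = []
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-pair {a!r} in annotation set {self.name!r}")
            key = (a, b) if a <= b else (b, a)
            if key not in seen:
                seen.add(key)
                clean.append(key)
        self.pairs = clean

    def __len__(self) -> int:
        return len(self.pairs)


def _predicted_mask(smap: SimilarityMap, tail_frac: float) -> np.ndarray:
    """Boolean mask over condensed pairs: in the extreme 2*tail_frac set.

    Tail selection is by rank with ties broken by the stable row-major pair
    order; the predicted count is exactly ``ceil(2 * tail_frac * n_pairs)``
    (split as evenly as the ceilings allow between the two tails).
    """
    if not 0 < tail_frac <= 0.5:
        raise ValueError("tail_frac must be in (0, 0.5]")
    vals = smap.off_diagonal()
    n_pairs = len(vals)
    k_total = int(np.ceil(2 * tail_frac * n_pairs))
    k_top = int(np.ceil(tail_frac * n_pairs))
    k_bot = k_total - k_top
    order = np.argsort(vals, kind="stable")
    mask = np.zeros(n_pairs, dtype=bool)
    if k_bot:
        mask[order[:k_bot]] = True
    mask[order[n_pairs - k_top:]] = True
    return mask


def _in_map_pair_indices(
    smap: SimilarityMap, ann: AnnotationSet
) -> np.ndarray:
    pos = {g: i for i, g in enumerate(smap.genes)}
    idx = [(pos[a], pos[b]) for a, b in ann.pairs if a in pos and b in pos]
    if not idx:
        return np.empty((0,), dtype=np.int64)
    ij = np.asarray(idx, dtype=np.int64)
    return condensed_index(ij[:, 0], ij[:, 1], smap.n_genes)


def recall_known(
    smap: SimilarityMap, ann: AnnotationSet, tail_frac: float = 0.05
) -> float:
    """Fraction of in-map annotation pairs among the predicted extremes."""
    cond = _in_map_pair_indices(smap, ann)
    if len(cond) == 0:
        raise ValueError(
            f"no pairs of {ann.name!r} have both genes in the map"
        )
    return float(_predicted_mask(smap, tail_frac)[cond].mean())


def stratified_recall(
    smap: SimilarityMap,
    ann: AnnotationSet,
    index: GeneArmIndex,
    tail_frac: float = 0.05,
) -> pd.DataFrame:
    """Recall separately for within-arm and between-arm annotation pairs."""
    cond = _in_map_pair_indices(smap, ann)
    if len(cond) == 0:
        raise ValueError(f"no pairs of {ann.name!r} have both genes in the map")
    pos = {g: i for i, g in enumerate(smap.genes)}
    arm = index.arm_of.reindex(smap.genes)
    in_map = [(a, b) for a, b in ann.pairs if a in pos and b in pos]
    same = np.array([
        pd.notna(arm.iloc[pos[a]]) and arm.iloc[pos[a]] == arm.iloc[pos[b]]
        for a, b in in_map
    ])
    predicted = _predicted_mask(smap, tail_frac)[cond]
    rows = []
    for label, sel in (("within_arm", same), ("between_arm", ~same)):
        if sel.any():
            rows.append((label, float(predicted[sel].mean()), int(sel.sum())))
        else:
            rows.append((label, np.nan, 0))
    rows.append(("overall", float(predicted.mean()), len(in_map)))
    return pd.DataFrame(rows, columns=["stratum", "recall", "n_pairs"]).set_index("stratum")


def intra_arm_enrichment(
    rel_a: AnnotationSet, rel_b: AnnotationSet, index: GeneArmIndex
) -> tuple[float, float, pd.DataFrame]:
    """Fisher test of same-arm pair enrichment between two relation sets.

    Builds the 2x2 table (set a vs set b) x (intra-arm vs inter-arm pair)
    over pairs whose genes both have arm assignments, and returns
    (odds ratio, two-sided p, table). Degenerate margins yield an odds
    ratio of 0 or inf.
    """
    arm = index.arm_of

    def counts(ann: AnnotationSet) -> tuple[int, int]:
        intra = inter = 0
        for a, b in ann.pairs:
            if a in arm.index and b in arm.index:
                if arm[a] == arm[b]:
                    intra += 1
                else:
                    inter += 1
        return intra, inter

    a_intra, a_inter = counts(rel_a)
    b_intra, b_inter = counts(rel_b)
    if (a_intra + a_inter) == 0 or (b_intra + b_inter) == 0:
        raise ValueError("both annotation sets must have arm-resolvable pairs")
    table = pd.DataFrame(
        [[a_intra, a_inter], [b_intra, b_inter]],
        index=[rel_a.name, rel_b.name], columns=["intra_arm", "inter_arm"],
    )
    odds, p = fisher_exact(table.to_numpy(), alternative="two-sided")
    return float(odds), float(p), table
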