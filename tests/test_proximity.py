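import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import brunnermunzel

from proxbias.maps import SimilarityMap
from proxbias.proximity import (BootstrapConfig, arm_bias_scan, bm_exact,
                                bm_montecarlo, gene_bias_scan, genome_bias,
                                position_trend)

from conftest import random_map


def brute_force_probability(x, y):
    """Independent oracle: P(X>Y) + 0.5 P(X=Y) by enumeration."""
    x, y = np.asarray(x), np.asarray(y)
    wins = (x[:, None] > y[None, :]).sum()
    ties = (x[:, None] == y[None, :]).sum()
    return (wins + 0.5 * ties) / (len(x) * len(y))


class TestBmExact:
    def test_complete_separation(self):
        assert bm_exact([0.9, 0.8], [0.1, 0.2]).probability == 1.0

    def test_singleton_between_two(self):
        # brute force: P(0.3>0.1)=1, P(0.3>0.5)=0 -> 0.5
        assert bm_exact([0.3], [0.1, 0.5]).probability == pytest.approx(0.5)

    def test_single_tie_contributes_half(self):
        res = bm_exact([0.5], [0.5])
        assert res.probability == pytest.approx(0.5)

    def test_identical_values_probability_half_p_one(self):
        res = bm_exact([1.0, 1.0, 1.0], [1.0, 1.0])
        assert res.probability == 0.5
        assert res.p_value == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bm_exact([], [1.0])

    @given(st.data())
    @settings(max_examples=150, deadline=None)
    def test_matches_brute_force_oracle(self, data):
        vals = st.floats(-1, 1, allow_nan=False)
        x = data.draw(st.lists(vals, min_size=1, max_size=50))
        y = data.draw(st.lists(vals, min_size=1, max_size=50))
        assert bm_exact(x, y).probability == pytest.approx(
            brute_force_probability(x, y), abs=1e-12)

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_complementarity(self, data):
        vals = st.floats(-1, 1, allow_nan=False)
        x = data.draw(st.lists(vals, min_size=1, max_size=30))
        y = data.draw(st.lists(vals, min_size=1, max_size=30))
        assert bm_exact(x, y).probability + bm_exact(y, x).probability == \
            pytest.approx(1.0)

    def test_monotone_transform_invariance(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=25)
        a = bm_exact(x, y)
        b = bm_exact(np.exp(3 * x), np.exp(3 * y))
        assert a.probability == pytest.approx(b.probability)
        assert a.p_value == pytest.approx(b.p_value)

    def test_p_value_cross_checked_against_scipy(self, rng):
        for _ in range(20):
            x = rng.normal(0.3, 1, size=rng.integers(5, 40))
            y = rng.normal(0, 1, size=rng.integers(5, 40))
            ours = bm_exact(x, y)
            ref = brunnermunzel(x, y, alternative="greater",
                                distribution="t")
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)


class TestGenomeBias:
    def test_null_map_near_half(self, toy_index):
        vals = [genome_bias(random_map(20, seed=s, index=toy_index),
                            toy_index).probability for s in range(30)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.02)

    def test_perfect_arm_structure_gives_one(self, toy_index):
        smap = random_map(20, seed=1, index=toy_index)
        codes = pd.factorize(smap.arms)[0]
        S = np.where(codes[:, None] == codes[None, :], 0.9, 0.1)
        np.fill_diagonal(S, 1.0)
        smap = SimilarityMap(smap.genes, S, smap.arms)
        assert genome_bias(smap, toy_index).probability == 1.0

    def test_swapping_roles_complements(self, toy_index):
        smap = random_map(20, seed=2, index=toy_index)
        res = genome_bias(smap, toy_index)
        # swap by negating similarities reverses every strict comparison
        flipped = SimilarityMap(smap.genes, -smap.values, smap.arms)
        res2 = genome_bias(flipped, toy_index)
        assert res.probability + res2.probability == pytest.approx(1.0)

    def test_no_arm_annotation_rejected(self):
        smap = random_map(10, seed=3)
        with pytest.raises(Exception):
            genome_bias(smap, None)


class TestArmScan:
    def test_min_pair_rule_counts(self):
        # one arm with 7 genes (21 pairs, tested), one with 6 (15, skipped)
        arms = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "arm": ["p", "q"],
            "arm_start": [1, 200], "arm_end": [150, 400],
            "acrocentric": [False, False]})
        rows = [(f"p{i}", f"p{i}", "chr1", 2 + i, 4 + i, "+") for i in range(7)]
        rows += [(f"q{i}", f"q{i}", "chr1", 210 + i, 212 + i, "+")
                 for i in range(6)]
        # second chromosome so inter-arm pairs exist for both arms
        arms2 = pd.concat([arms, pd.DataFrame({
            "chrom": ["chr2", "chr2"], "arm": ["p", "q"],
            "arm_start": [1, 200], "arm_end": [150, 400],
            "acrocentric": [False, False]})], ignore_index=True)
        rows += [(f"x{i}", f"x{i}", "chr2", 2 + i, 4 + i, "+")
                 for i in range(8)]
        from proxbias.genome import assign_arms
        loci = pd.DataFrame(
            rows, columns=["gene_id", "symbol", "chrom", "start", "end",
                           "strand"])
        index = assign_arms(loci, arms2)
        smap = random_map(21, seed=4)
        smap = SimilarityMap(pd.Index([r[0] for r in rows]),
                             smap.values, index.arm_of.reindex(
                                 [r[0] for r in rows]))
        out = arm_bias_scan(smap, index)
        assert out.loc["chr1p", "status"] == "tested"
        assert out.loc["chr1p", "n_intra"] == 21
        assert out.loc["chr1q", "status"] == "skipped"

    def test_null_type_one_error_controlled(self):
        from proxbias.maps import cosine_map
        from proxbias.simulate import make_genome
        genome = make_genome(4, 12, seed=0)
        rng = np.random.default_rng(0)
        n_sig = n_tested = 0
        for _ in range(15):
            df = pd.DataFrame(rng.normal(size=(96, 64)),
                              index=genome.index.genes.index)
            out = arm_bias_scan(cosine_map(df, genome.index), genome.index)
            tested = out[out["status"] == "tested"]
            n_tested += len(tested)
            n_sig += int((tested["p_adj"] < 0.05).sum())
        assert n_tested == 15 * 8
        # pairs within a map share gene vectors, so deep-tail p-values are
        # mildly optimistic; a handful of hits across 120 corrected null
        # tests is the expected regime (a biased map lights up all arms)
        assert n_sig <= 5

    def test_gene_scan_matches_manual_slices(self, toy_index):
        smap = random_map(20, seed=8, index=toy_index)
        out = gene_bias_scan(smap, toy_index)
        codes = pd.factorize(smap.arms)[0]
        i = 3
        same = (codes == codes[i])
        same[i] = False
        other = ~same & (np.arange(20) != i)
        manual = bm_exact(smap.values[i, same], smap.values[i, other])
        gene = smap.genes[i]
        assert out.loc[gene, "probability"] == pytest.approx(
            manual.probability)


class TestPositionTrend:
    def test_decreasing_probabilities_give_rho_minus_one(self, toy_index):
        genes = toy_index.genes_on_arm("chr1q")
        df = pd.DataFrame({
            "arm": "chr1q",
            "probability": 1 - toy_index.rel_pos.reindex(genes) * 0.4,
        }, index=genes)
        out = position_trend(df, toy_index, min_genes=5)
        assert out.loc["chr1q", "rho"] == pytest.approx(-1.0)

    def test_constant_probabilities_skipped(self, toy_index):
        genes = toy_index.genes_on_arm("chr1q")
        df = pd.DataFrame({"arm": "chr1q", "probability": 0.6}, index=genes)
        out = position_trend(df, toy_index, min_genes=5)
        assert out.loc["chr1q", "status"] == "constant values"

    def test_too_few_genes_skipped(self, toy_index):
        genes = toy_index.genes_on_arm("chr1q")[:3]
        df = pd.DataFrame({
            "arm": "chr1q",
            "probability": [0.5, 0.6, 0.7]}, index=genes)
        out = position_trend(df, toy_index)
        assert out.loc["chr1q", "status"] == "too few genes"


class TestMonteCarlo:
    def test_seed_reproducibility(self, toy_index):
        smap = random_map(20, seed=9, index=toy_index)
        cfg = lambda: BootstrapConfig(n_pairs=40, t_trials=20, seed=5)
        a = bm_montecarlo(smap, toy_index, cfg())
        b = bm_montecarlo(smap, toy_index, cfg())
        assert a.probability == b.probability
        assert np.array_equal(a.trial_values, b.trial_values)

    def test_agrees_with_exact_within_mc_error(self, toy_index):
        smap = random_map(20, seed=10, index=toy_index)
        exact = genome_bias(smap, toy_index).probability
        mc = bm_montecarlo(smap, toy_index,
                           BootstrapConfig(n_pairs=30, t_trials=100, seed=1))
        se = mc.trial_values.std(ddof=1) / np.sqrt(len(mc.trial_values))
        assert abs(mc.probability - exact) <= 3 * max(se, 1e-6)

    def test_insufficient_pairs_suggests_exact(self, toy_index):
        smap = random_map(20, seed=11, index=toy_index)
        with pytest.raises(ValueError, match="exact"):
            bm_montecarlo(smap, toy_index,
                          BootstrapConfig(n_pairs=10 ** 6, t_trials=2))
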