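import numpy as np
import pandas as pd
import pytest

from proxbias.dependency import (arm_pair_bias, arm_pair_universe,
                                 build_dependency_map, cnv_clean_lines,
                                 genotype_split, spurious_dependency_screen,
                                 stratified_bootstrap_bias)
from proxbias.correction import correct_arm_means, select_unexpressed
from proxbias.maps import GeneVectors
from proxbias.proximity import BootstrapConfig
from proxbias.simulate import make_genome, simulate_dependency


@pytest.fixture(scope="module")
def dep_setup():
    genome = make_genome(4, 30, seed=31)
    panel, truth = simulate_dependency(genome, n_lines=100,
                                       truncation_spillover=0.4, seed=31)
    return genome, panel, truth


@pytest.fixture(scope="module")
def clean_setup():
    genome = make_genome(4, 30, seed=32)
    panel, truth = simulate_dependency(genome, n_lines=100,
                                       truncation_spillover=0.0,
                                       cnv_rate=0.0, seed=32)
    return genome, panel, truth


class TestBuildDependencyMap:
    def test_identical_centered_profiles_have_unit_similarity(self, dep_setup):
        genome, panel, _ = dep_setup
        dep = panel.dependency.copy()
        dep.iloc[1] = dep.iloc[0] + 3.0  # same profile, constant offset
        panel2 = type(panel)(dep, panel.copy_number, panel.damaging,
                             panel.tpm, panel.lineage)
        smap = build_dependency_map(panel2, index=genome.index)
        assert smap.values[0, 1] == pytest.approx(1.0)

    def test_constant_offset_leaves_map_unchanged(self, dep_setup):
        genome, panel, _ = dep_setup
        a = build_dependency_map(panel, index=genome.index)
        dep = panel.dependency.copy()
        dep.iloc[5] += 7.5
        panel2 = type(panel)(dep, panel.copy_number, panel.damaging,
                             panel.tpm, panel.lineage)
        b = build_dependency_map(panel2, index=genome.index)
        assert np.allclose(a.values, b.values)

    def test_spillover_creates_proximity_bias(self, dep_setup, clean_setup):
        from proxbias.proximity import genome_bias
        genome, panel, _ = dep_setup
        biased = genome_bias(build_dependency_map(panel, index=genome.index),
                             genome.index)
        genome0, panel0, _ = clean_setup
        null = genome_bias(build_dependency_map(panel0, index=genome0.index),
                           genome0.index)
        assert biased.probability > 0.6
        assert null.probability == pytest.approx(0.5, abs=0.03)


class TestCnvCleanLines:
    def _panel(self, genome, cn):
        genes = genome.index.genes.index
        lines = cn.columns
        zeros = pd.DataFrame(0.0, index=genes, columns=lines)
        return type("P", (), {})() or None

    def test_diploid_retained_arm_loss_excluded(self, clean_setup):
        genome, panel, _ = clean_setup
        arm = genome.index.arms.index[0]
        cn = panel.copy_number.copy()
        line = cn.columns[0]
        cn.loc[genome.index.genes_on_arm(arm), line] = 1.0
        panel2 = type(panel)(panel.dependency, cn, panel.damaging,
                             panel.tpm, panel.lineage)
        kept = cnv_clean_lines(panel2, arm, genome.index)
        assert line not in kept
        assert cn.columns[1] in kept

    def test_threshold_arithmetic(self, clean_setup):
        genome, panel, _ = clean_setup
        arm = genome.index.arms.index[1]
        genes = genome.index.genes_on_arm(arm)  # 30 genes -> 1% rule
        cn = panel.copy_number.copy()
        cn.loc[genes[:0], :] = 2.0
        line = cn.columns[2]
        # 0/30 outside -> retained; 1/30 = 3.3% -> excluded
        assert line in cnv_clean_lines(panel, arm, genome.index)
        cn.loc[genes[0], line] = 3.0
        panel2 = type(panel)(panel.dependency, cn, panel.damaging,
                             panel.tpm, panel.lineage)
        assert line not in cnv_clean_lines(panel2, arm, genome.index)


class TestArmPairs:
    def test_universe_counts(self, dep_setup):
        genome, _, _ = dep_setup
        pairs = arm_pair_universe(genome.index)
        assert len(pairs) == 8 * 7 // 2

    def test_clean_pairs_unbiased_spillover_raises_values(self, clean_setup,
                                                          dep_setup):
        genome0, panel0, _ = clean_setup
        out0 = arm_pair_bias(panel0, genome0.index)
        tested0 = out0[out0["status"] == "tested"]
        assert len(tested0) == 56  # 28 pairs x 2 orientations
        assert tested0["probability"].mean() == pytest.approx(0.5, abs=0.03)
        genome, panel, _ = dep_setup
        out = arm_pair_bias(panel, genome.index)
        tested = out[out["status"] == "tested"]
        assert tested["probability"].mean() > 0.6

    def test_insufficient_lines_skipped(self, clean_setup):
        genome, panel, _ = clean_setup
        out = arm_pair_bias(panel, genome.index, min_lines=10 ** 4)
        assert (out["status"] == "skipped").all()


class TestGenotypeSplit:
    def _panel_with(self, clean_setup, gene, cn_vals, damaging=None):
        genome, panel, _ = clean_setup
        cn = panel.copy_number.copy()
        cn.loc[gene, :] = cn_vals
        dam = panel.damaging.copy()
        dam.loc[gene, :] = False
        if damaging is not None:
            dam.loc[gene, damaging] = True
        return genome, type(panel)(panel.dependency, cn, dam, panel.tpm,
                                   panel.lineage)

    def test_boundary_and_mode_rules(self, clean_setup):
        gene = clean_setup[1].genes[0]
        lines = clean_setup[1].lines
        cn_vals = np.full(len(lines), 2.0)
        cn_vals[0] = 1.5   # inclusive LOF boundary
        cn_vals[1] = 3.0   # AMP
        cn_vals[2] = 3.0   # AMP but damaging -> excluded
        genome, panel = self._panel_with(clean_setup, gene, cn_vals,
                                         damaging=[lines[2]])
        wt_lof, lof = genotype_split(panel, gene, "LOF")
        wt_amp, amp = genotype_split(panel, gene, "AMP")
        assert list(lof) == [lines[0]]
        assert list(amp) == [lines[1]]
        assert lines[2] not in set(amp) | set(wt_amp)
        # CN 2.0 lines are WT in both modes; sets are disjoint
        assert lines[3] in set(wt_lof) and lines[3] in set(wt_amp)
        assert not set(lof) & set(wt_lof)

    def test_background_restriction(self, clean_setup):
        genome, panel, _ = clean_setup
        bg_gene, gene = panel.genes[10], panel.genes[11]
        cn = panel.copy_number.copy()
        cn.loc[bg_gene, :] = 2.0
        cn.loc[bg_gene, panel.lines[:40]] = 1.0  # TP53-like LOF background
        cn.loc[gene, :] = 2.0
        cn.loc[gene, panel.lines[:20]] = 1.0
        panel2 = type(panel)(panel.dependency, cn, panel.damaging,
                             panel.tpm, panel.lineage)
        wt, mut = genotype_split(panel2, gene, "LOF",
                                 background_gene=bg_gene,
                                 background_mode="LOF")
        assert set(mut) == set(panel.lines[:20])
        assert set(wt) <= set(panel.lines[:40])


class TestStratifiedBootstrap:
    def test_identical_conditions_give_null_difference(self, clean_setup):
        genome, panel, _ = clean_setup
        gene = panel.genes[0]
        cn = panel.copy_number.copy()
        cn.loc[gene, :] = 2.0
        cn.loc[gene, panel.lines[:50]] = 1.0
        panel2 = type(panel)(panel.dependency, cn, panel.damaging,
                             panel.tpm, panel.lineage)
        cfg = BootstrapConfig(n_pairs=200, t_trials=30, seed=1)
        res = stratified_bootstrap_bias(panel2, gene, "LOF", genome.index,
                                        s_trials=4, cfg=cfg, seed=1)
        assert abs(res.mean_difference) < 0.05
        assert res.p_value > 0.001

    def test_seed_reproducibility(self, clean_setup):
        genome, panel, _ = clean_setup
        gene = panel.genes[0]
        cn = panel.copy_number.copy()
        cn.loc[gene, :] = 2.0
        cn.loc[gene, panel.lines[:40]] = 1.0
        panel2 = type(panel)(panel.dependency, cn, panel.damaging,
                             panel.tpm, panel.lineage)
        def run():
            return stratified_bootstrap_bias(
                panel2, gene, "LOF", genome.index, s_trials=3,
                cfg=BootstrapConfig(n_pairs=150, t_trials=20, seed=2), seed=2)
        a, b = run(), run()
        assert np.array_equal(a.wt_probabilities, b.wt_probabilities)
        assert a.mean_difference == b.mean_difference

    def test_planted_mediator_detected(self):
        genome = make_genome(4, 30, seed=33)
        mediator = list(genome.index.genes.index)[5]
        panel, truth = simulate_dependency(
            genome, n_lines=140, truncation_spillover=0.25,
            mediator=mediator, mediator_lof_frac=0.45,
            mediator_spillover_multiplier=3.0, cnv_rate=0.0, seed=33)
        res = stratified_bootstrap_bias(
            panel, mediator, "LOF", genome.index, s_trials=8,
            cfg=BootstrapConfig(n_pairs=300, t_trials=40, seed=3), seed=3)
        assert res.mean_difference > 0.02
        assert res.p_value < 0.05

    def test_min_lines_guard(self, clean_setup):
        genome, panel, _ = clean_setup
        gene = panel.genes[1]  # CN ~2 everywhere -> empty LOF set
        with pytest.raises(ValueError, match="min_lines"):
            stratified_bootstrap_bias(panel, gene, "LOF", genome.index)


class TestSpuriousScreen:
    def test_planted_unexpressed_centromeric_genes_flagged(self):
        genome = make_genome(4, 30, seed=34)
        panel, truth = simulate_dependency(
            genome, n_lines=160, truncation_spillover=0.5, cnv_rate=0.05,
            seed=34)
        subtype = next(iter(truth.drivers))
        out = spurious_dependency_screen(
            panel, subtype, list(truth.drivers.values()), genome.index)
        flagged = set(out.index[out["flagged"]])
        planted = set(truth.spurious_genes[subtype])
        assert flagged & planted
        assert all(out.loc[g, "subtype_tpm"] < 0.3 for g in flagged)

    def test_no_spillover_flags_nothing(self):
        genome = make_genome(4, 30, seed=35)
        panel, truth = simulate_dependency(
            genome, n_lines=160, truncation_spillover=0.0, driver_effect=0.0,
            cnv_rate=0.05, seed=35)
        subtype = next(iter(truth.drivers))
        out = spurious_dependency_screen(
            panel, subtype, list(truth.drivers.values()), genome.index)
        assert int(out["flagged"].sum()) == 0

    def test_arm_correction_reduces_flags(self):
        genome = make_genome(4, 30, seed=36)
        panel, truth = simulate_dependency(
            genome, n_lines=160, truncation_spillover=0.5, cnv_rate=0.0,
            seed=36)
        subtype = next(iter(truth.drivers))
        drivers = list(truth.drivers.values())
        before = spurious_dependency_screen(panel, subtype, drivers,
                                            genome.index)
        z = pd.Series(0.0, index=genome.index.genes.index)
        z[sorted(truth.unexpressed)] = -10.0
        by_arm, _ = select_unexpressed(z, genome.index)
        corrected, _ = correct_arm_means(
            GeneVectors(panel.dependency), by_arm, genome.index)
        panel2 = type(panel)(corrected.vectors, panel.copy_number,
                             panel.damaging, panel.tpm, panel.lineage)
        after = spurious_dependency_screen(panel2, subtype, drivers,
                                           genome.index)
        assert int(after["flagged"].sum()) < int(before["flagged"].sum())
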