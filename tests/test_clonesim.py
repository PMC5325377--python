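"""Generator: structure, determinism, infinite-sites and VAF consistency."""

import numpy as np
import pandas as pd
import pytest

from clonelines import (SimConfig, build_profiles, detect_bimodality,
                        four_gamete_conflicts, random_germline,
                        simulate_bulk_vafs, simulate_clonal_tree,
                        simulate_ig_colonies, simulate_marker_intensities,
                        simulate_omics, simulate_single_cell_clones,
                        sort_and_regrow, true_vafs)
from clonelines.genotypes import MISSING, PRESENT


def test_config_validation_rejects_bad_simplex_and_counts():
    with pytest.raises(ValueError):
        SimConfig(n_lineages=2, lineage_props=(0.6, 0.6),
                  stages_per_lineage=0)
    with pytest.raises(ValueError):
        SimConfig(n_lineages=0)
    with pytest.raises(ValueError):
        SimConfig(dropout_rate=1.5, n_lineages=3)


def test_tree_structure_matches_config():
    # three lineages, the second with a two-stage chain
    cfg = SimConfig(n_lineages=3, n_trunk_mut=2, muts_per_lineage=1,
                    stages_per_lineage=(0, 2, 0), muts_per_stage=1,
                    lineage_props=None)
    tree = simulate_clonal_tree(cfg)
    assert tree.n_lineages == 3
    assert len(tree.trunk_mutations) == 2
    chain = tree.subtree_nodes("L2")
    assert len(chain) == 3  # branch node + 2 stages
    # mutation sets on distinct edges are disjoint and cover everything
    all_muts = [m for n in tree.nodes if n != tree.root
                for m in tree.edge_mutations.get(n, ())]
    assert len(all_muts) == len(set(all_muts)) == len(tree.mutations)


def test_degenerate_tree_single_lineage_no_mutations():
    cfg = SimConfig(n_lineages=1, n_trunk_mut=0, muts_per_lineage=0,
                    stages_per_lineage=0, lineage_props=(1.0,))
    tree = simulate_clonal_tree(cfg)
    assert tree.mutations == frozenset()
    assert tree.n_lineages == 1


def test_same_seed_gives_identical_outputs():
    cfg = SimConfig(seed=42, dropout_rate=0.2)
    t1, t2 = simulate_clonal_tree(cfg), simulate_clonal_tree(cfg)
    assert t1.to_newick() == t2.to_newick()
    m1, l1 = simulate_single_cell_clones(t1, cfg)
    m2, l2 = simulate_single_cell_clones(t2, cfg)
    assert np.array_equal(m1.calls, m2.calls)
    pd.testing.assert_frame_equal(l1, l2)


def test_clone_genotype_equals_root_path_and_trunk_universal(hg3):
    tree, cfg, matrix, labels = hg3
    assert np.all(matrix.column("CAV1_T46I") == PRESENT)  # trunk in all 60
    for _, row in labels.iterrows():
        expected = tree.path_mutations(row["node"])
        assert matrix.genotype_of(row["clone_id"]) == expected


def test_dropout_free_matrix_has_zero_four_gamete_conflicts(hg3):
    _, _, matrix, _ = hg3
    assert four_gamete_conflicts(matrix).n_conflicts == 0


def test_full_dropout_masks_every_call():
    cfg = SimConfig(dropout_rate=1.0, n_clones=10)
    tree = simulate_clonal_tree(cfg)
    matrix, _ = simulate_single_cell_clones(tree, cfg)
    assert np.all(matrix.calls == MISSING)


def test_zero_clones_yields_empty_matrix():
    cfg = SimConfig(n_clones=0)
    matrix, labels = simulate_single_cell_clones(simulate_clonal_tree(cfg),
                                                 cfg)
    assert matrix.n_clones == 0 and labels.empty


# -- IG colonies -----------------------------------------------------------

def test_single_lineage_colonies_identical_at_two_percent():
    # 5 shared substitutions over 250 nt = 2.0% in every colony
    cfg = SimConfig(n_lineages=1, lineage_props=(1.0,),
                    stages_per_lineage=0, pcr_error_rate=0.0, seed=5)
    tree = simulate_clonal_tree(cfg)
    germ = random_germline(250, seed=5)
    colonies, _ = simulate_ig_colonies(tree, germ, 8, shared_mut=5,
                                       specific_mut_per_lineage=0,
                                       config=cfg)
    seqs = {seq for _, seq in colonies.colonies}
    assert len(seqs) == 1
    levels = [p.mutation_level for p in build_profiles(colonies)]
    assert levels == pytest.approx([2.0] * 8)


def test_no_mutations_colonies_equal_germline():
    cfg = SimConfig(n_lineages=1, lineage_props=(1.0,), stages_per_lineage=0)
    tree = simulate_clonal_tree(cfg)
    germ = random_germline(200, seed=1)
    colonies, _ = simulate_ig_colonies(tree, germ, 3, 0, 0, cfg)
    assert all(seq == germ for _, seq in colonies.colonies)


def test_requested_mutations_exceeding_length_rejected():
    cfg = SimConfig(n_lineages=2, lineage_props=(0.5, 0.5),
                    stages_per_lineage=0)
    tree = simulate_clonal_tree(cfg)
    with pytest.raises(ValueError):
        simulate_ig_colonies(tree, random_germline(120), 5,
                             shared_mut=100, specific_mut_per_lineage=50,
                             config=cfg)


def test_lineage_specific_substitutions_shared_within_lineage():
    cfg = SimConfig(n_lineages=2, lineage_props=(0.6, 0.4),
                    stages_per_lineage=0, seed=7)
    tree = simulate_clonal_tree(cfg)
    colonies, truth = simulate_ig_colonies(tree, random_germline(300, 7),
                                           20, 3, 2, cfg)
    profiles = {p.colony_id: p.substitutions
                for p in build_profiles(colonies)}
    for lid in truth["lineage_id"].unique():
        members = truth.loc[truth["lineage_id"] == lid, "colony_id"]
        sigs = {profiles[c] for c in members}
        assert len(sigs) == 1  # no PCR errors: identical within lineage


# -- bulk VAFs -------------------------------------------------------------

def test_true_vafs_trunk_half_and_private_quarter():
    cfg = SimConfig(n_lineages=2, n_trunk_mut=1, muts_per_lineage=1,
                    stages_per_lineage=0, lineage_props=(0.5, 0.5))
    tree = simulate_clonal_tree(cfg)
    vafs = true_vafs(tree, cfg.props)
    assert vafs["trunk_m0"] == 0.5            # carried by all, heterozygous
    assert vafs["L1_m0"] == pytest.approx(0.25)  # 0.5 lineage / 2


def test_observed_vaf_converges_to_truth_at_high_depth():
    cfg = SimConfig(seed=3)
    tree = simulate_clonal_tree(cfg)
    df = simulate_bulk_vafs(tree, cfg.props, depth=100_000, seed=3)
    obs = df["alt_count"] / df["depth"]
    assert np.allclose(obs, df["true_vaf"], atol=0.01)


def test_bulk_vaf_depth_validation():
    cfg = SimConfig()
    with pytest.raises(ValueError):
        simulate_bulk_vafs(simulate_clonal_tree(cfg), cfg.props, depth=0)


# -- marker intensities ----------------------------------------------------

def test_zero_positive_fraction_is_unimodal():
    df = simulate_marker_intensities("subclone", 1000,
                                     positive_fraction=0.0, seed=2)
    assert df["state"].sum() == 0
    assert detect_bimodality(df["log_intensity"]).verdict == "unimodal"


def test_subclone_sort_stays_pure_after_regrowth():
    rg = sort_and_regrow("subclone", n_cells=1000, steps=14, seed=4)
    final = rg[rg["step"] == 14]
    assert final["state"].mean() == 1.0  # heritable state never switches


def test_activation_relaxes_to_markov_stationary_fraction():
    # f_k = pi + (1 - pi) * (1 - s)^k starting from a pure positive sort
    s, pi, steps = 0.2, 0.3, 14
    expected = pi + (1 - pi) * (1 - s) ** steps
    fracs = []
    for seed in range(30):
        rg = sort_and_regrow("activation", n_cells=500, steps=steps,
                             switch_prob=s, positive_fraction=pi, seed=seed)
        fracs.append(rg[rg["step"] == steps]["state"].mean())
    mc_se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
    assert abs(np.mean(fracs) - expected) < 3 * mc_se + 1e-3


def test_activation_without_switching_equals_subclone_model():
    a = sort_and_regrow("activation", n_cells=300, steps=10,
                        switch_prob=0.0, seed=6)
    assert a[a["step"] == 10]["state"].mean() == 1.0


# -- omics -----------------------------------------------------------------

def test_omics_effect_zero_has_no_lineage_structure(hg3):
    tree, _, _, labels = hg3
    expr, _, truth = simulate_omics(tree, labels.head(12), effect_size=0.0,
                                    seed=8)
    sig = [g for genes in truth["signature_genes"].values() for g in genes]
    lab = labels.head(12).set_index("clone_id")["lineage_id"]
    for gene in sig[:5]:
        means = expr[gene].groupby(lab).mean()
        assert means.max() - means.min() < 2.0  # noise-scale only


def test_omics_epigene_beta_inversely_tracks_expression(hg3):
    tree, _, _, labels = hg3
    expr, beta, truth = simulate_omics(tree, labels.head(20),
                                       effect_size=4.0, seed=9)
    for gene in truth["epigenes"]:
        r = np.corrcoef(beta[gene], expr[gene])[0, 1]
        assert r < -0.7
        assert beta[gene].between(0, 1).all()


def test_omics_rejects_too_many_signature_genes(hg3):
    tree, _, _, labels = hg3
    with pytest.raises(ValueError):
        simulate_omics(tree, labels, n_genes=10,
                       n_signature_genes_per_lineage=10)
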