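import numpy as np
import pandas as pd
import pytest

from mseqith.ccf_clustering import MutationCluster, classify_clonality
from mseqith.phylogeny_parallel import (
    build_clone_tree,
    detect_parallel_evolution,
    enumerate_admissible_trees,
    time_driver_events,
    tree_satisfies_constraints,
)


def make_clusters(ccf_rows, n_mut=10):
    clusters = []
    for i, ccf in enumerate(ccf_rows):
        ccf = np.asarray(ccf, dtype=float)
        clusters.append(
            MutationCluster(
                cluster_id=i,
                members=[f"c{i}_m{j}" for j in range(n_mut)],
                ccf=ccf,
                clonality=classify_clonality(ccf),
            )
        )
    return clusters


def test_single_cluster_tree():
    trees = build_clone_tree(make_clusters([[1.0, 1.0]]))
    assert len(trees) == 1
    t = trees[0]
    assert t.root == 0 and t.nodes == [0]
    assert t.to_newick() == "0;"


def test_no_trunk_error():
    with pytest.raises(ValueError, match="no trunk"):
        build_clone_tree(make_clusters([[0.5, 0.5], [0.3, 0.1]]))


def test_greedy_matches_exhaustive_on_example():
    """Clusters (1,1), (0.6,0.0), (0.3,0.0): every greedy tree must appear in
    the brute-force admissible set."""
    clusters = make_clusters([[1.0, 1.0], [0.6, 0.0], [0.3, 0.0]])
    greedy = build_clone_tree(clusters)
    admissible = enumerate_admissible_trees(clusters)
    admissible_parents = {tuple(sorted(t.parent.items())) for t in admissible}
    for t in greedy:
        assert tuple(sorted(t.parent.items())) in admissible_parents
        assert tree_satisfies_constraints(t)


def test_sibling_structure_recovered():
    """Trunk plus three mutually exclusive subclones: all three attach to the
    trunk (region-disjoint CCFs forbid chains)."""
    clusters = make_clusters(
        [[1.0, 1.0, 1.0], [0.8, 0.0, 0.0], [0.0, 0.7, 0.0], [0.0, 0.0, 0.9]]
    )
    trees = build_clone_tree(clusters)
    assert len(trees) == 1
    t = trees[0]
    assert sorted(t.children(t.root)) == [1, 2, 3]


def test_chain_forced_by_sum_rule():
    # 0.6 + 0.5 > 1: the two subclones cannot be siblings under the trunk
    clusters = make_clusters([[1.0], [0.6], [0.5]])
    trees = build_clone_tree(clusters)
    for t in trees:
        assert t.parent[2] == 1  # nested chain
        assert tree_satisfies_constraints(t)


def test_unattachable_cluster_raises_naming_constraint():
    # subclone exceeds the trunk in region 2 beyond tolerance
    clusters = make_clusters([[1.0, 0.2], [0.5, 0.9]])
    with pytest.raises(ValueError, match="region"):
        build_clone_tree(clusters)


def test_ambiguous_attachment_returns_all_admissible():
    # region-disjoint intermediates at equal depth; a tiny cluster fits
    # under either within tolerance -> both trees reported
    clusters = make_clusters([[1.0, 1.0], [0.4, 0.0], [0.0, 0.4], [0.03, 0.03]])
    trees = build_clone_tree(clusters)
    assert len(trees) >= 2
    admissible = enumerate_admissible_trees(clusters)
    admissible_parents = {tuple(sorted(t.parent.items())) for t in admissible}
    for t in trees:
        assert tuple(sorted(t.parent.items())) in admissible_parents


def test_greedy_in_admissible_set_random_instances():
    from mseqith.synthetic_data import simulate_clone_tree

    checked = 0
    for seed in range(30):
        truth = simulate_clone_tree(int(np.random.default_rng(seed).integers(2, 6)), seed)
        regions = truth.regions()
        clusters = make_clusters(
            [[truth.clone_ccf[(r, c)] for r in regions] for c in truth.nodes]
        )
        if not any(cl.clonality == "clonal" for cl in clusters):
            continue
        greedy = build_clone_tree(clusters)
        admissible = enumerate_admissible_trees(clusters)
        admissible_parents = {tuple(sorted(t.parent.items())) for t in admissible}
        for t in greedy:
            assert tuple(sorted(t.parent.items())) in admissible_parents
            assert tree_satisfies_constraints(t)
        checked += 1
    assert checked >= 20


# -- parallel evolution --------------------------------------------------------


def _variant_row(mid, gene, effect="missense", pos=1):
    return {
        "mutation_id": mid, "chrom": "3", "pos": pos, "ref": "C", "alt": "T",
        "gene": gene, "effect": effect,
    }


def test_no_event_for_same_clone_variants():
    clusters = make_clusters([[1.0, 1.0]])
    tree = build_clone_tree(clusters)[0]
    variants = pd.DataFrame([_variant_row("m1", "CTNNB1", pos=1),
                             _variant_row("m2", "CTNNB1", pos=2)])
    events = detect_parallel_evolution(variants, {"m1": 0, "m2": 0}, tree)
    assert events == []


def test_three_sibling_variants_one_event():
    clusters = make_clusters(
        [[1.0, 1.0, 1.0], [0.8, 0.0, 0.0], [0.0, 0.7, 0.0], [0.0, 0.0, 0.9]]
    )
    tree = build_clone_tree(clusters)[0]
    variants = pd.DataFrame([_variant_row(f"m{i}", "CTNNB1", pos=i) for i in (1, 2, 3)])
    events = detect_parallel_evolution(
        variants, {"m1": 1, "m2": 2, "m3": 3}, tree
    )
    genes = [e.gene for e in events]
    assert "CTNNB1" in genes
    ev = next(e for e in events if e.gene == "CTNNB1")
    assert len(ev.variants) == 3
    assert sorted(ev.clone_ids) == [1, 2, 3]


def test_ancestral_pair_not_an_event():
    clusters = make_clusters([[1.0], [0.6], [0.3]])
    tree = build_clone_tree(clusters)[0]  # chain 0 -> 1 -> 2
    variants = pd.DataFrame([_variant_row("m1", "CTNNB1", pos=1),
                             _variant_row("m2", "CTNNB1", pos=2)])
    events = detect_parallel_evolution(variants, {"m1": 1, "m2": 2}, tree)
    assert events == []


def test_silent_variants_ignored():
    clusters = make_clusters([[1.0, 1.0], [0.5, 0.0], [0.0, 0.5]])
    tree = build_clone_tree(clusters)[0]
    variants = pd.DataFrame(
        [_variant_row("m1", "CTNNB1", effect="silent", pos=1),
         _variant_row("m2", "CTNNB1", effect="silent", pos=2)]
    )
    assert detect_parallel_evolution(variants, {"m1": 1, "m2": 2}, tree) == []


def test_pathway_scope_detects_cross_gene_convergence():
    clusters = make_clusters([[1.0, 1.0], [0.5, 0.0], [0.0, 0.5]])
    tree = build_clone_tree(clusters)[0]
    variants = pd.DataFrame([_variant_row("m1", "APC", pos=1),
                             _variant_row("m2", "RNF43", pos=2)])
    events = detect_parallel_evolution(
        variants, {"m1": 1, "m2": 2}, tree,
        gene_sets={"wnt_pathway": ["CTNNB1", "APC", "RNF43"]},
    )
    assert [e.gene for e in events] == ["wnt_pathway"]


# -- driver timing -------------------------------------------------------------


def test_time_driver_events_fractions():
    snv = pd.DataFrame(
        [{"patient_id": f"P{i}", "gene": "PTEN",
          "clonality": "clonal" if i < 3 else "subclonal"} for i in range(5)]
    )
    out = time_driver_events(["PTEN", "TP53"], snv)
    assert list(out["gene"]) == ["PTEN"]  # TP53 has no events -> omitted
    assert out.iloc[0]["fraction_clonal"] == pytest.approx(0.6)


def test_time_driver_events_mixes_snv_and_scna():
    snv = pd.DataFrame([{"patient_id": "P1", "gene": "TP53", "clonality": "clonal"}])
    scna = pd.DataFrame([{"patient_id": "P2", "gene": "TP53", "status": "heterogeneous"}])
    out = time_driver_events(["TP53"], snv, scna)
    assert out.iloc[0]["n_events"] == 2
    assert out.iloc[0]["fraction_clonal"] == pytest.approx(0.5)


def test_single_truncal_event_fraction_one():
    snv = pd.DataFrame([{"patient_id": "P1", "gene": "SPOP", "clonality": "clonal"}])
    out = time_driver_events(["SPOP"], snv)
    assert out.iloc[0]["fraction_clonal"] == 1.0
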