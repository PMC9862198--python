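import math

import numpy as np
import pytest

from flafam.models import SpeciesMeta
from flafam.phylo import (
    TreeNode,
    assign_groups,
    bipartitions,
    bootstrap,
    expansion_stats,
    leaf_path_lengths,
    midpoint_root,
    neighbor_joining,
    nj_from_alignment,
    p_distance,
    poisson_distance,
    summarize_family_sizes,
)
from flafam.synthetic import random_additive_tree, simulate_clade_alignment


# ------------------------------------------------------------ distances

def test_p_distance_hand_counts():
    assert p_distance("ACDE", "ACDE") == 0.0
    assert p_distance("AC-D", "AD-D") == pytest.approx(1 / 3)
    assert p_distance("AXCD", "AACD") == 0.0  # X sites excluded


def test_p_distance_empty_overlap_errors():
    with pytest.raises(ValueError):
        p_distance("--", "AA")


def test_poisson_distance_closed_form_and_monotone():
    assert poisson_distance(0.0) == 0.0
    assert poisson_distance(0.5) == pytest.approx(math.log(2))
    ps = np.linspace(0, 0.9, 50)
    ds = [poisson_distance(p) for p in ps]
    assert all(b > a for a, b in zip(ds, ds[1:]))
    with pytest.raises(ValueError):
        poisson_distance(1.0)


# ------------------------------------------------------------------- NJ

def test_nj_three_taxa_closed_form():
    D = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
    tree = neighbor_joining(D, ["a", "b", "c"])
    lengths = {c.name: l for c, l in tree.children}
    assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
    assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
    assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)


def test_nj_recovers_random_additive_trees():
    for seed in range(40):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        labels, D, true_tree = random_additive_tree(n, rng)
        nj = neighbor_joining(D, labels)
        assert bipartitions(nj) == bipartitions(true_tree)
        got = leaf_path_lengths(nj)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    assert got[(a, b)] == pytest.approx(D[i, j], abs=1e-9)


def test_nj_taxon_order_invariance():
    rng = np.random.default_rng(5)
    labels, D, _ = random_additive_tree(6, rng)
    t1 = neighbor_joining(D, labels)
    perm = rng.permutation(len(labels))
    D2 = D[np.ix_(perm, perm)]
    labels2 = [labels[i] for i in perm]
    t2 = neighbor_joining(D2, labels2)
    assert bipartitions(t1) == bipartitions(t2)


def test_nj_agrees_with_dendropy_on_additive_matrix():
    dendropy = pytest.importorskip("dendropy")
    rng = np.random.default_rng(9)
    labels, D, _ = random_additive_tree(7, rng)
    nj = neighbor_joining(D, labels)
    csv = "," + ",".join(labels) + "\n"
    for i, a in enumerate(labels):
        csv += a + "," + ",".join(f"{D[i, j]:.8f}" for j in range(len(labels))) + "\n"
    import io as _io

    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        src=_io.StringIO(csv), delimiter=","
    )
    ref = pdm.nj_tree()
    ref_bps = set()
    ref.encode_bipartitions()
    all_taxa = frozenset(labels)
    for edge in ref.preorder_edge_iter():
        bp = edge.bipartition
        side = frozenset(t.label for t in bp.leafset_taxa(ref.taxon_namespace))
        other = all_taxa - side
        if 2 <= len(side) <= len(labels) - 2:
            canon = side if (len(side), sorted(side)) <= (len(other), sorted(other)) else other
            ref_bps.add(canon)
    assert bipartitions(nj) == ref_bps


def test_nj_rejects_asymmetric_matrix():
    D = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
    with pytest.raises(ValueError):
        neighbor_joining(D, ["a", "b", "c"])


# ------------------------------------------------------------ bootstrap

def test_bootstrap_b1_supports_binary():
    ids, rows, _ = simulate_clade_alignment(3, n_per_clade=3, length=60)
    tree = bootstrap(ids, rows, B=1, seed=0)
    sup = [n for n in _internal_supports(tree)]
    assert sup and all(s in (0.0, 100.0) for s in sup)


def _internal_supports(tree):
    out = []

    def visit(node):
        if node.is_leaf:
            return
        if node.support is not None:
            out.append(node.support)
        for c, _ in node.children:
            visit(c)

    visit(tree)
    return out


def test_bootstrap_same_seed_identical():
    ids, rows, _ = simulate_clade_alignment(4, n_per_clade=3, length=80)
    t1 = bootstrap(ids, rows, B=25, seed=11)
    t2 = bootstrap(ids, rows, B=25, seed=11)
    assert t1.newick() == t2.newick()


def test_bootstrap_strong_clade_high_support():
    ids, rows, clade = simulate_clade_alignment(7)
    tree = bootstrap(ids, rows, B=100, seed=5)
    support = _support_of_bipartition(tree, ids, clade)
    assert support is not None and support >= 95.0


def _support_of_bipartition(tree, ids, target):
    whole = frozenset(ids)
    found = []

    def visit(node):
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(visit(c) for c, _ in node.children))
        if below == target or whole - below == target:
            found.append(node.support)
        return below

    for c, _ in tree.children:
        visit(c)
    return found[0] if found else None


# ----------------------------------------------------- group assignment

def _clade_tree():
    """Four well-separated clades, each holding its anchors plus members."""
    def clade(names, stem=1.0):
        node = TreeNode(
            children=[(TreeNode(name=n), 0.1) for n in names]
        )
        return node

    groups = {
        "I": ["AtFLA11", "AtFLA12", "w1", "w2"],
        "II": ["AtFLA1", "x1"],
        "III": ["AtFLA16", "y1"],
        "IV": ["AtFLA3", "z1"],
    }
    root = TreeNode(children=[(clade(m), 1.0) for m in groups.values()])
    return root, groups


def test_assign_groups_planted_clades():
    tree, groups = _clade_tree()
    got = assign_groups(tree).groups
    for g, members in groups.items():
        for leaf in members:
            assert got[leaf] == g, leaf


def test_assign_groups_anchor_only_tree():
    anchors = ["AtFLA11", "AtFLA12", "AtFLA1", "AtFLA16", "AtFLA3"]
    root = TreeNode(children=[(TreeNode(name=a), 1.0) for a in anchors])
    got = assign_groups(root).groups
    assert got == {
        "AtFLA11": "I", "AtFLA12": "I", "AtFLA1": "II",
        "AtFLA16": "III", "AtFLA3": "IV",
    }


def test_assign_groups_missing_anchor_errors():
    root = TreeNode(children=[(TreeNode(name="AtFLA11"), 1.0),
                              (TreeNode(name="x"), 1.0),
                              (TreeNode(name="y"), 1.0)])
    with pytest.raises(ValueError, match="missing"):
        assign_groups(root)


def test_midpoint_root_preserves_leaf_distances():
    rng = np.random.default_rng(3)
    labels, D, tree = random_additive_tree(6, rng)
    rooted = midpoint_root(tree)
    got = leaf_path_lengths(rooted)
    want = leaf_path_lengths(tree)
    for k, v in want.items():
        assert got[k] == pytest.approx(v, abs=1e-9)


# ------------------------------------------------------ expansion stats

def _meta(sid, habit, total=10000):
    return SpeciesMeta(sid, habit, total, sid[:3].title())


def test_expansion_stats_three_species_hand_computed():
    from flafam.phylo import GroupAssignment

    assignment = GroupAssignment(
        groups={
            "a1": "I", "a2": "I", "a3": "II", "a4": "III",
            "b1": "I", "b2": "II",
            "c1": "IV", "c2": "I", "c3": "I", "c4": "I",
        },
        anchor_map={},
    )
    metas = [_meta("spa", "woody", 20000), _meta("spb", "woody", 10000),
             _meta("spc", "herbaceous", 40000)]
    l2s = {k: "sp" + k[0] for k in assignment.groups}
    stats = expansion_stats(assignment, metas, l2s)
    assert stats.per_species["spa"]["n_fla"] == 4
    assert stats.per_species["spa"]["prop_of_family"] == pytest.approx(0.5)
    assert stats.per_species["spa"]["prop_of_genome"] == pytest.approx(2 / 20000)
    assert stats.per_species["spc"]["prop_of_family"] == pytest.approx(0.75)
    assert stats.habit_means_family_pct["woody"] == pytest.approx(50.0)
    assert stats.habit_means_family_pct["herbaceous"] == pytest.approx(75.0)
    # one herbaceous species only: p undefined, means still reported
    assert stats.p_value is None


def test_expansion_identical_proportions_t0_p1():
    from flafam.phylo import GroupAssignment

    groups = {}
    l2s = {}
    metas = []
    for si, habit in enumerate(["woody", "woody", "herbaceous", "herbaceous"]):
        sid = f"s{si}"
        metas.append(_meta(sid, habit))
        for gi in range(4):
            leaf = f"{sid}_g{gi}"
            groups[leaf] = "I" if gi < 2 else "II"
            l2s[leaf] = sid
    stats = expansion_stats(GroupAssignment(groups, {}), metas, l2s)
    assert stats.t_statistic == 0.0 and stats.p_value == 1.0


def test_expansion_monte_carlo_detects_woody_enrichment():
    hits = 0
    n_seeds = 100
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        from flafam.phylo import GroupAssignment

        groups, l2s, metas = {}, {}, []
        for si in range(10):
            habit = "woody" if si < 5 else "herbaceous"
            p = 0.50 if habit == "woody" else 0.33
            sid = f"s{si}"
            metas.append(_meta(sid, habit))
            # per-species tree membership sized (power analysis) so the
            # planted 50% vs 33% effect is reliably detectable at n=5+5
            n_genes = 80
            k = rng.binomial(n_genes, p)
            for gi in range(n_genes):
                leaf = f"{sid}_g{gi}"
                groups[leaf] = "I" if gi < k else "II"
                l2s[leaf] = sid
        stats = expansion_stats(GroupAssignment(groups, {}), metas, l2s)
        if (
            stats.habit_means_family_pct["woody"] > stats.habit_means_family_pct["herbaceous"]
            and stats.p_value is not None
            and stats.p_value < 0.05
        ):
            hits += 1
    assert hits >= 0.9 * n_seeds


def test_summarize_family_sizes_fold_ratios():
    table = summarize_family_sizes({"pop": 40, "wil": 46, "ath": 21}, "ath")
    assert table["pop"]["fold_vs_reference"] == 1.9
    assert table["wil"]["fold_vs_reference"] == 2.2
    assert table["ath"]["fold_vs_reference"] == 1.0
    with pytest.raises(ValueError):
        summarize_family_sizes({"a": 5, "r": 0}, "r")
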