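"""Distance phylogenetics for protein families.

Distances are Poisson-corrected p-distances with pairwise deletion
(columns with '-' or 'X' in either row are dropped per pair), trees
are built with the Saitou–Nei neighbor-joining algorithm, and branch
supports come from column bootstrap. Group I–IV labels are assigned
from anchor sequences (the Arabidopsis FLAs that define each clade in
multi-species FLA phylogenies), and woody/herbaceous expansion of
Group I is summarized per species with a Welch t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .models import SpeciesMeta

# Anchor sequences defining each phylogenetic group in FLA trees.
DEFAULT_ANCHOR_MAP = {
    "AtFLA11": "I",
    "AtFLA12": "I",
    "AtFLA1": "II",
    "AtFLA16": "III",
    "AtFLA3": "IV",
}
GROUP_ORDER = ("I", "II", "III", "IV")


# ------------------------------------------------------------ distances

def p_distance(row_i: str, row_j: str) -> float:
    """Proportion of differing sites under pairwise deletion.

    Sites where either row has '-' or 'X' are excluded; an empty
    overlap is an error.
    """
    if len(row_i) != len(row_j):
        raise ValueError("alignment rows differ in length")
    valid = mismatch = 0
    for a, b in zip(row_i, row_j):
        if a in "-X" or b in "-X":
            continue
        valid += 1
        if a != b:
            mismatch += 1
    if valid == 0:
        raise ValueError("no shared non-gap sites between rows")
    return mismatch / valid


def poisson_distance(p: float) -> float:
    """Poisson-corrected distance d = -ln(1 - p)."""
    if not (0.0 <= p < 1.0):
        raise ValueError(f"p-distance must be in [0, 1), got {p}")
    return -math.log1p(-p)


def distance_matrix(rows: list[str]) -> np.ndarray:
    n = len(rows)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = poisson_distance(p_distance(rows[i], rows[j]))
    return D


# ----------------------------------------------------------------- tree

@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def newick(self, with_support: bool = True) -> str:
        def fmt(node: TreeNode, length: float | None) -> str:
            if node.is_leaf:
                core = node.name
            else:
                inner = ",".join(fmt(c, l) for c, l in node.children)
                label = ""
                if with_support and node.support is not None:
                    label = f"{node.support:g}"
                core = f"({inner}){label}"
            return core if length is None else f"{core}:{length:.6f}"

        return fmt(self, None) + ";"


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalized to its smaller side."""
    all_leaves = frozenset(tree.leaf_names())

    def canon(side: frozenset[str]) -> frozenset[str]:
        other = all_leaves - side
        if (len(side), sorted(side)) <= (len(other), sorted(other)):
            return side
        return other

    out: set[frozenset[str]] = set()

    def visit(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(visit(c) for c, _ in node.children))
        if 2 <= len(below) <= len(all_leaves) - 2:
            out.add(canon(below))
        return below

    for c, _ in tree.children:
        visit(c)
    return out


# ------------------------------------------------------------------- NJ

def neighbor_joining(D: np.ndarray, labels: list[str]) -> TreeNode:
    """Saitou–Nei neighbor joining.

    Requires a symmetric matrix with zero diagonal and n >= 3 taxa.
    Q-criterion ties break on the smallest (row, column) index pair in
    the current join order; negative branch lengths are clamped to 0.
    The result is an unrooted tree represented with a trifurcating
    root node.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix / label size mismatch")
    if not np.allclose(D, D.T, atol=1e-10) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if n < 3:
        raise ValueError("need at least 3 taxa")

    nodes = [TreeNode(name=l) for l in labels]
    D = D.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest Q; ties -> smallest (row, column) pair
        flat = np.argmin(Q)
        i_loc, j_loc = divmod(flat, m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        d_ij = sub[i_loc, j_loc]
        li = 0.5 * d_ij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = d_ij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        gi, gj = active[i_loc], active[j_loc]
        new = TreeNode(children=[(nodes[gi], li), (nodes[gj], lj)])
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (sub[i_loc, :] + sub[j_loc, :] - d_ij)
        D = np.pad(D, ((0, 1), (0, 1)))
        gnew = D.shape[0] - 1
        for loc, g in enumerate(active):
            D[gnew, g] = D[g, gnew] = new_row[loc]
        D[gnew, gnew] = 0.0
        nodes.append(new)
        active = [g for g in active if g not in (gi, gj)] + [gnew]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    return TreeNode(
        children=[
            (nodes[a], max(la, 0.0)),
            (nodes[b], max(lb, 0.0)),
            (nodes[c], max(lc, 0.0)),
        ]
    )


def nj_from_alignment(ids: list[str], rows: list[str]) -> TreeNode:
    return neighbor_joining(distance_matrix(rows), ids)


def bootstrap(
    ids: list[str], rows: list[str], B: int, seed: int, tree: TreeNode | None = None
) -> TreeNode:
    """Column-bootstrap supports on the NJ tree of an alignment.

    Resamples alignment columns with replacement B times, rebuilds the
    NJ tree per replicate, and annotates each internal edge of the
    original tree with the percentage of replicates containing its
    bipartition. Deterministic given the seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if tree is None:
        tree = nj_from_alignment(ids, rows)
    L = len(rows[0])
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in bipartitions(tree)}
    arr = np.array([list(r) for r in rows])
    for _ in range(B):
        cols = rng.integers(0, L, size=L)
        boot_rows = ["".join(row) for row in arr[:, cols]]
        bt = nj_from_alignment(ids, boot_rows)
        for bp in bipartitions(bt):
            if bp in counts:
                counts[bp] += 1

    all_leaves = frozenset(ids)

    def canon(side: frozenset[str]) -> frozenset[str]:
        other = all_leaves - side
        if (len(side), sorted(side)) <= (len(other), sorted(other)):
            return side
        return other

    def annotate(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(annotate(c) for c, _ in node.children))
        if 2 <= len(below) <= len(all_leaves) - 2:
            node.support = 100.0 * counts[canon(below)] / B
        return below

    for c, _ in tree.children:
        annotate(c)
    return tree


# ------------------------------------------------------ midpoint rooting

def _adjacency(tree: TreeNode):
    """Undirected adjacency over node ids, plus the id -> node map."""
    adj: dict[int, list[tuple[int, float]]] = {}
    nodes: dict[int, TreeNode] = {}

    def visit(node: TreeNode) -> None:
        nodes[id(node)] = node
        adj.setdefault(id(node), [])
        for c, l in node.children:
            adj[id(node)].append((id(c), l))
            adj.setdefault(id(c), []).append((id(node), l))
            visit(c)

    visit(tree)
    return adj, nodes


def leaf_path_lengths(tree: TreeNode) -> dict[tuple[str, str], float]:
    """Path length between every pair of leaves."""
    adj, nodes = _adjacency(tree)
    leaves = {nid: n.name for nid, n in nodes.items() if n.is_leaf}
    out: dict[tuple[str, str], float] = {}
    for src, src_name in leaves.items():
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, l in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + l
                    stack.append(v)
        for nid, name in leaves.items():
            if name != src_name:
                out[(src_name, name)] = dist[nid]
    return out


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root the tree at the midpoint of the longest leaf-to-leaf path."""
    adj, nodes = _adjacency(tree)
    leaf_ids = sorted(
        (nid for nid, n in nodes.items() if n.is_leaf), key=lambda i: nodes[i].name
    )

    def paths_from(src: int) -> dict[int, tuple[float, list[int]]]:
        best: dict[int, tuple[float, list[int]]] = {src: (0.0, [src])}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, l in adj[u]:
                if v not in best:
                    best[v] = (best[u][0] + l, best[u][1] + [v])
                    stack.append(v)
        return best

    # longest leaf pair; deterministic tie-break on leaf names
    best_pair = None
    for src in leaf_ids:
        reach = paths_from(src)
        for dst in leaf_ids:
            if dst == src:
                continue
            d, path = reach[dst]
            key = (-d, nodes[src].name, nodes[dst].name)
            if best_pair is None or key < best_pair[0]:
                best_pair = (key, d, path)
    _, total, path = best_pair
    half = total / 2.0

    # find the edge on the path containing the midpoint
    cum = 0.0
    edge = (path[0], path[1])
    offset = 0.0
    for u, v in zip(path, path[1:]):
        l = next(l for w, l in adj[u] if w == v)
        if cum + l >= half - 1e-12:
            edge = (u, v)
            offset = half - cum
            break
        cum += l

    u, v = edge
    l_uv = next(l for w, l in adj[u] if w == v)
    root_id = -1
    adj[u] = [(w, l) for w, l in adj[u] if w != v] + [(root_id, offset)]
    adj[v] = [(w, l) for w, l in adj[v] if w != u] + [(root_id, l_uv - offset)]
    adj[root_id] = [(u, offset), (v, l_uv - offset)]

    def build(nid: int, parent: int) -> TreeNode:
        if nid >= 0 and nodes[nid].is_leaf:
            return nodes[nid]
        node = TreeNode(support=nodes[nid].support if nid >= 0 else None)
        for w, l in adj[nid]:
            if w != parent:
                node.children.append((build(w, nid), l))
        return node

    return build(root_id, None)


# ------------------------------------------------------ group assignment

@dataclass
class GroupAssignment:
    groups: dict[str, str]  # leaf -> group
    anchor_map: dict[str, str]


def assign_groups(
    tree: TreeNode, anchor_map: dict[str, str] | None = None
) -> GroupAssignment:
    """Assign each leaf to a group from anchor leaves.

    The tree is midpoint-rooted; each group's clade is the MRCA of its
    anchors. A leaf under exactly one group clade takes that group; a
    leaf under several takes the group of the smallest enclosing
    clade; a leaf under none takes the group of its nearest anchor by
    path length (ties break toward the lower group number).
    """
    anchor_map = dict(anchor_map or DEFAULT_ANCHOR_MAP)
    leaves = set(tree.leaf_names())
    missing = [a for a in anchor_map if a not in leaves]
    if missing:
        raise ValueError(f"anchor leaves missing from tree: {missing}")

    rooted = midpoint_root(tree)

    # clade (leaf set) of the MRCA of each group's anchors
    group_anchors: dict[str, set[str]] = {}
    for a, g in anchor_map.items():
        group_anchors.setdefault(g, set()).add(a)

    clades: list[set[str]] = []

    def collect(node: TreeNode) -> set[str]:
        if node.is_leaf:
            s = {node.name}
        else:
            s = set()
            for c, _ in node.children:
                s |= collect(c)
        clades.append(s)
        return s

    collect(rooted)

    group_clades: dict[str, set[str]] = {}
    for g, anchors in group_anchors.items():
        containing = [c for c in clades if anchors <= c]
        group_clades[g] = min(containing, key=len)

    dists = leaf_path_lengths(tree)
    groups: dict[str, str] = {}
    rank = {g: i for i, g in enumerate(GROUP_ORDER)}
    for leaf in sorted(leaves):
        covering = [g for g in GROUP_ORDER if g in group_clades and leaf in group_clades[g]]
        if len(covering) == 1:
            groups[leaf] = covering[0]
        elif covering:
            groups[leaf] = min(covering, key=lambda g: (len(group_clades[g]), rank[g]))
        else:
            best = min(
                anchor_map,
                key=lambda a: (dists[(leaf, a)], rank[anchor_map[a]]),
            )
            groups[leaf] = anchor_map[best]
    return GroupAssignment(groups, anchor_map)


# ------------------------------------------------------ expansion stats

@dataclass
class ExpansionStats:
    per_species: dict[str, dict]
    habit_means_family_pct: dict[str, float]
    habit_means_genome_pct: dict[str, float]
    t_statistic: float | None
    p_value: float | None
    focal_group: str = "I"


def expansion_stats(
    assignment: GroupAssignment,
    species_meta: list[SpeciesMeta],
    leaf_to_species: dict[str, str],
    focal_group: str = "I",
    exclude_anchors: bool = True,
) -> ExpansionStats:
    """Per-species group composition and woody/herbaceous comparison.

    For each species: FLA count, per-group counts, the focal group's
    share of the family, and its share of the whole genome. Habit
    classes are compared with a two-sided Welch t-test on the
    per-species family proportions; with fewer than two species in
    either habit the p-value is undefined but means are still
    reported.
    """
    meta = {m.species_id: m for m in species_meta}
    per: dict[str, dict] = {
        m.species_id: {"n_fla": 0, "n_group": {g: 0 for g in GROUP_ORDER}}
        for m in species_meta
    }
    for leaf, group in assignment.groups.items():
        if exclude_anchors and leaf in assignment.anchor_map:
            continue
        sp = leaf_to_species.get(leaf)
        if sp is None:
            raise KeyError(f"leaf {leaf} not mapped to a species")
        per[sp]["n_fla"] += 1
        per[sp]["n_group"][group] += 1
    for sp, d in per.items():
        n = d["n_fla"]
        d["prop_of_family"] = d["n_group"][focal_group] / n if n else float("nan")
        d["prop_of_genome"] = d["n_group"][focal_group] / meta[sp].genome_gene_total

    by_habit: dict[str, list[str]] = {"woody": [], "herbaceous": []}
    for m in species_meta:
        by_habit[m.habit].append(m.species_id)
    fam_means = {}
    gen_means = {}
    for habit, sps in by_habit.items():
        props = [per[s]["prop_of_family"] for s in sps]
        gens = [per[s]["prop_of_genome"] for s in sps]
        fam_means[habit] = 100.0 * float(np.mean(props)) if props else float("nan")
        gen_means[habit] = 100.0 * float(np.mean(gens)) if gens else float("nan")

    woody = [per[s]["prop_of_family"] for s in by_habit["woody"]]
    herb = [per[s]["prop_of_family"] for s in by_habit["herbaceous"]]
    if len(woody) >= 2 and len(herb) >= 2:
        if np.var(woody) == 0 and np.var(herb) == 0:
            if np.mean(woody) == np.mean(herb):
                t, p = 0.0, 1.0
            else:
                t, p = math.inf if np.mean(woody) > np.mean(herb) else -math.inf, 0.0
        else:
            t, p = stats.ttest_ind(woody, herb, equal_var=False)
            t, p = float(t), float(p)
    else:
        t = p = None
    return ExpansionStats(per, fam_means, gen_means, t, p, focal_group)


def summarize_family_sizes(
    counts_by_species: dict[str, int], reference_species: str
) -> dict[str, dict]:
    """Family sizes with fold ratios against a reference species.

    Ratio = n_species / n_reference, rounded to one decimal.
    """
    if reference_species not in counts_by_species:
        raise KeyError(f"unknown reference species {reference_species}")
    ref = counts_by_species[reference_species]
    if ref <= 0:
        raise ValueError("reference species count must be positive")
    return {
        sp: {"n_fla": n, "fold_vs_reference": round(n / ref, 1)}
        for sp, n in counts_by_species.items()
    }
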