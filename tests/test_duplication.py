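import itertools

import numpy as np
import pytest

from flafam.align import global_align
from flafam.duplication import (
    chain_collinear_blocks,
    classify_duplications,
    detect_tandem,
    find_anchors,
    find_orthologs,
)
from flafam.models import GeneModel
from flafam.synthetic import _background


def _gene(gid, chrom, start, end):
    return GeneModel(gid, chrom, start, end, "+", [(start, end)])


# ------------------------------------------------------------ alignment

def test_identity_identical_and_hand_case():
    assert global_align("MKTV", "MKTV").identity_pct == 100.0
    assert global_align("AAAA", "AAAC").identity_pct == 75.0


def test_alignment_score_symmetric():
    rng = np.random.default_rng(0)
    a, b = _background(rng, 60), _background(rng, 70)
    assert global_align(a, b).score == global_align(b, a).score


def test_identity_shorter_denominator_switch():
    res = global_align("MKTVAA", "MKTV", identity_denominator="shorter")
    assert res.identity_pct == 100.0


# --------------------------------------------------------------- tandem

def _mutate(seq, n, rng):
    seq = list(seq)
    for pos in rng.choice(len(seq), size=n, replace=False):
        choices = [a for a in "ACDEFGHIKLMNQRSTVWY" if a != seq[pos]]
        seq[int(pos)] = choices[int(rng.integers(len(choices)))]
    return "".join(seq)


def test_tandem_triplet_from_published_coordinates():
    """Three paralogs within 100 kb on one chromosome at ~98% identity
    form a single 3-member cluster (the classic willow chr19 triplet)."""
    rng = np.random.default_rng(1)
    base = _background(rng, 249, start_met=True)
    variant = _mutate(base, 5, rng)  # 244/249 = 97.99% identity
    genes = [
        _gene("SsuFLA43", "chr19", 16_018_464, 16_019_599),
        _gene("SsuFLA44", "chr19", 16_037_704, 16_038_793),
        _gene("SsuFLA45", "chr19", 16_041_720, 16_042_511),
    ]
    prots = {"SsuFLA43": base, "SsuFLA44": variant, "SsuFLA45": base}
    assert global_align(base, variant).identity_pct == pytest.approx(97.99, abs=0.01)
    clusters = detect_tandem(genes, prots)
    assert len(clusters) == 1
    assert clusters[0].members == ["SsuFLA43", "SsuFLA44", "SsuFLA45"]


def test_tandem_far_apart_not_clustered():
    rng = np.random.default_rng(2)
    base = _background(rng, 200, start_met=True)
    genes = [_gene("g1", "chr1", 1000, 2000), _gene("g2", "chr1", 152_001, 153_000)]
    assert detect_tandem(genes, {"g1": base, "g2": base}) == []


def test_tandem_low_identity_not_clustered():
    rng = np.random.default_rng(3)
    base = _background(rng, 200, start_met=True)
    other = _mutate(base, 80, rng)  # 60% identity
    genes = [_gene("g1", "chr1", 1000, 2000), _gene("g2", "chr1", 10_000, 11_000)]
    assert detect_tandem(genes, {"g1": base, "g2": other}) == []


def test_tandem_translation_invariance_and_order():
    rng = np.random.default_rng(4)
    base = _background(rng, 200, start_met=True)
    genes = [_gene("g1", "chr1", 1000, 2000), _gene("g2", "chr1", 10_000, 11_000)]
    prots = {"g1": base, "g2": base}
    c1 = detect_tandem(genes, prots)
    shift = [_gene(g.gene_id, g.chromosome, g.start + 5_000_000, g.end + 5_000_000)
             for g in genes]
    c2 = detect_tandem(shift, prots)
    c3 = detect_tandem(genes[::-1], prots)
    assert [c.members for c in c1] == [c.members for c in c2] == [c.members for c in c3]
    assert c1[0].members == ["g1", "g2"]


def test_tandem_planted_truth_exact(genome_pair):
    _, _, genome_b, truth = genome_pair
    fla = [g for g in genome_b.gene_models if truth.fla_labels[g.gene_id]]
    prots = {p.protein_id: p.sequence for p in genome_b.proteins
             if truth.fla_labels[p.protein_id]}
    clusters = detect_tandem(fla, prots)
    got = sorted(tuple(c.members) for c in clusters)
    want = sorted(tuple(r["members"]) for r in truth.tandem_clusters)
    assert got == want
    planted_negatives = {m for r in truth.tandem_negatives for m in r["members"]}
    clustered = {m for c in clusters for m in c.members}
    assert not (planted_negatives & clustered)


# -------------------------------------------------------------- anchors

def test_anchors_identical_singletons():
    rng = np.random.default_rng(5)
    seq = _background(rng, 150, start_met=True)
    ga = [_gene("a1", "chr1", 100, 1000)]
    gb = [_gene("b1", "chr1", 100, 1000)]
    assert find_anchors(ga, {"a1": seq}, gb, {"b1": seq}) == [("a1", "b1")]


def test_anchors_unrelated_proteins_empty():
    rng = np.random.default_rng(6)
    ga = [_gene("a1", "chr1", 100, 1000)]
    gb = [_gene("b1", "chr1", 100, 1000)]
    a, b = _background(rng, 150, True), _background(rng, 150, True)
    assert find_anchors(ga, {"a1": a}, gb, {"b1": b}) == []


def test_anchors_planted_block_all_found(genome_pair):
    _, genome_a, genome_b, truth = genome_pair
    fla_a = [g for g in genome_a.gene_models if truth.fla_labels[g.gene_id]]
    fla_b = [g for g in genome_b.gene_models if truth.fla_labels[g.gene_id]]
    pa = {g.gene_id: genome_a.protein_dict()[g.gene_id] for g in fla_a}
    pb = {g.gene_id: genome_b.protein_dict()[g.gene_id] for g in fla_b}
    anchors = find_anchors(fla_a, pa, fla_b, pb)
    planted = [b for b in truth.blocks if b["kind"] == "inter"][0]["anchors"]
    assert set(planted) <= set(anchors)


# ------------------------------------------------------------- chaining

def _rank_genes(chrom, ids):
    return [_gene(g, chrom, 1000 * (i + 1), 1000 * (i + 1) + 500) for i, g in enumerate(ids)]


def test_chain_simple_inverted_and_threshold():
    ids_a = [f"a{i}" for i in range(8)]
    ids_b = [f"b{i}" for i in range(8)]
    ga = _rank_genes("chr1", ids_a)
    gb = _rank_genes("chr2", ids_b)
    anchors = list(zip(ids_a, ids_b))
    blocks = chain_collinear_blocks(anchors, ga, gb)
    assert len(blocks) == 1
    assert blocks[0].orientation == "same" and len(blocks[0].anchors) == 8

    inv = list(zip(ids_a, ids_b[::-1]))
    blocks = chain_collinear_blocks(inv, ga, gb)
    assert len(blocks) == 1 and blocks[0].orientation == "inverted"

    short = anchors[:4]
    assert chain_collinear_blocks(short, ga, gb) == []


def _brute_force_best_chain(items, max_gap=25):
    """Exhaustive longest collinear subset (same orientation)."""
    best = 0
    n = len(items)
    items = sorted(items)
    for mask in range(1, 1 << n):
        sel = [items[i] for i in range(n) if mask >> i & 1]
        ok = all(
            1 <= b[0] - a[0] <= max_gap and 1 <= b[1] - a[1] <= max_gap
            for a, b in zip(sel, sel[1:])
        )
        if ok:
            best = max(best, len(sel))
    return best


def test_chain_dp_matches_exhaustive_oracle():
    rng = np.random.default_rng(7)
    for _ in range(15):
        n = int(rng.integers(5, 12))
        # distinct ranks in each genome so ordinal rank = sampled value
        ra = rng.choice(30, size=n, replace=False)
        rb = rng.choice(30, size=n, replace=False)
        ga = [_gene(f"a{i}", "chr1", 1000 * (int(ra[i]) + 1), 1000 * (int(ra[i]) + 1) + 10)
              for i in range(n)]
        gb = [_gene(f"b{i}", "chr2", 1000 * (int(rb[i]) + 1), 1000 * (int(rb[i]) + 1) + 10)
              for i in range(n)]
        anchors = [(f"a{i}", f"b{i}") for i in range(n)]
        blocks = chain_collinear_blocks(anchors, ga, gb, min_anchors=1)
        got = max(
            (len(b.anchors) for b in blocks if b.orientation == "same"), default=0
        )
        rank_a = {v: r for r, v in enumerate(sorted(int(x) for x in ra))}
        rank_b = {v: r for r, v in enumerate(sorted(int(x) for x in rb))}
        rank_items = [(rank_a[int(ra[i])], rank_b[int(rb[i])]) for i in range(n)]
        want = _brute_force_best_chain(rank_items)
        assert got == want


def test_planted_blocks_recovered_exactly(genome_pair):
    _, genome_a, genome_b, truth = genome_pair
    fla_a = [g for g in genome_a.gene_models if truth.fla_labels[g.gene_id]]
    fla_b = [g for g in genome_b.gene_models if truth.fla_labels[g.gene_id]]
    pa = {g.gene_id: genome_a.protein_dict()[g.gene_id] for g in fla_a}
    pb = {g.gene_id: genome_b.protein_dict()[g.gene_id] for g in fla_b}
    anchors = find_anchors(fla_a, pa, fla_b, pb)
    blocks = chain_collinear_blocks(anchors, fla_a, fla_b, "A", "B")
    planted = [b for b in truth.blocks if b["kind"] == "inter"]
    assert len(blocks) == len(planted)
    assert sorted(tuple(b.anchors) for b in blocks) == sorted(
        tuple(p["anchors"]) for p in planted
    )


# ------------------------------------------- duplication classification

def test_classify_duplication_precedence_and_labels():
    genes = [_gene(f"g{i}", "chr1", 10_000 * i + 1000, 10_000 * i + 2000) for i in range(8)]
    from flafam.duplication import CollinearBlock, TandemCluster

    clusters = [TandemCluster("chr1", ["g0", "g1"])]
    blocks = [CollinearBlock("A", "A", "chr1", "chr2",
                             [("g0", "g2"), ("g1", "g3"), ("g4", "g5")], "same")]
    anchors = [("g0", "g2"), ("g1", "g3"), ("g4", "g5"), ("g6", "g7")]
    calls = classify_duplications(genes, anchors, blocks, clusters)
    assert calls.labels["g0"] == "tandem"          # tandem wins over segmental
    assert calls.labels["g2"] == "segmental"
    assert calls.labels["g4"] == calls.labels["g5"] == "segmental"
    assert calls.labels["g6"] == "dispersed"       # anchored but no block
    assert ("g0", "g2") in calls.segmental_pairs   # pair genes not in one cluster


def test_classify_no_anchors_all_singletons():
    genes = [_gene("g1", "chr1", 100, 200), _gene("g2", "chr2", 100, 200)]
    calls = classify_duplications(genes, [], [], [])
    assert set(calls.labels.values()) == {"singleton"}


def test_segmental_pairs_planted_truth(genome_pair):
    _, genome_a, _, truth = genome_pair
    fla = [g for g in genome_a.gene_models if truth.fla_labels[g.gene_id]]
    prots = {g.gene_id: genome_a.protein_dict()[g.gene_id] for g in fla}
    anchors = find_anchors(fla, prots, fla, prots, same_genome=True)
    blocks = chain_collinear_blocks(anchors, fla, fla, "A", "A")
    clusters = detect_tandem(fla, prots)
    calls = classify_duplications(fla, anchors, blocks, clusters)
    want = sorted(tuple(sorted(p)) for p in truth.segmental_pairs["A"])
    got = sorted(tuple(sorted(p)) for p in calls.segmental_pairs)
    assert got == want


# ------------------------------------------------------------ orthologs

def test_orthologs_from_blocks_and_candidates(genome_pair):
    _, genome_a, genome_b, truth = genome_pair
    fla_a = [g for g in genome_a.gene_models if truth.fla_labels[g.gene_id]]
    fla_b = [g for g in genome_b.gene_models if truth.fla_labels[g.gene_id]]
    pa = {g.gene_id: genome_a.protein_dict()[g.gene_id] for g in fla_a}
    pb = {g.gene_id: genome_b.protein_dict()[g.gene_id] for g in fla_b}
    anchors = find_anchors(fla_a, pa, fla_b, pb)
    blocks = chain_collinear_blocks(anchors, fla_a, fla_b, "A", "B")
    ortho, candidates = find_orthologs(blocks, anchors, pa, pb)
    assert sorted(ortho) == sorted(truth.ortholog_pairs)
    assert candidates == truth.nonsyntenic_pairs


def test_orthologs_empty_blocks():
    assert find_orthologs([]) == ([], [])
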