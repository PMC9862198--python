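"""Tandem duplication, collinear blocks, segmental duplicates, orthologs.

Tandem duplicates follow the two classic criteria: members lie within
100 kb of each other on one chromosome (gap measured between gene
spans) and their proteins align at > 70% identity. Collinearity is a
simplified MCScanX-style procedure: anchor pairs from reciprocal
top-scoring global alignments, then longest-chain dynamic programming
over gene ranks per chromosome pair and orientation, keeping chains
of at least five anchors with rank gaps of at most 25.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import AlignmentResult, align_score, global_align
from .models import GeneModel, ProteinRecord, chrom_sort_key

TANDEM_MAX_GAP_BP = 100_000
TANDEM_MIN_IDENTITY = 70.0


@dataclass
class TandemCluster:
    chromosome: str
    members: list[str]  # gene ids ordered by start


@dataclass
class CollinearBlock:
    genome_a: str
    genome_b: str
    chrom_a: str
    chrom_b: str
    anchors: list[tuple[str, str]]  # ordered gene-id pairs
    orientation: str  # same | inverted


@dataclass
class DuplicationCalls:
    labels: dict[str, str]  # gene -> tandem | segmental | dispersed | singleton
    segmental_pairs: list[tuple[str, str]]
    tandem_clusters: list[TandemCluster]


def _gap_bp(upstream: GeneModel, downstream: GeneModel) -> int:
    """Span gap: start of the downstream gene minus end of the upstream."""
    return downstream.start - upstream.end


def detect_tandem(
    gene_models: list[GeneModel],
    proteins: dict[str, str],
    max_gap_bp: int = TANDEM_MAX_GAP_BP,
    min_identity: float = TANDEM_MIN_IDENTITY,
    identity_denominator: str = "alignment",
) -> list[TandemCluster]:
    """Tandem clusters as connected components of the two-criteria graph.

    Edge (g, h): same chromosome, span gap <= max_gap_bp, protein
    identity > min_identity. Components of size >= 2 are clusters;
    members are ordered by start. Unplaced contigs participate like
    chromosomes.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        if g.gene_id not in proteins:
            raise KeyError(f"no protein sequence for gene {g.gene_id}")
        by_chrom.setdefault(g.chromosome, []).append(g)

    parent: dict[str, str] = {g.gene_id: g.gene_id for g in gene_models}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for chrom, genes in by_chrom.items():
        genes.sort(key=lambda g: g.start)
        for i, gi in enumerate(genes):
            for gj in genes[i + 1:]:
                if _gap_bp(gi, gj) > max_gap_bp:
                    break
                res = global_align(
                    proteins[gi.gene_id], proteins[gj.gene_id],
                    gi.gene_id, gj.gene_id,
                    identity_denominator=identity_denominator,
                )
                if res.identity_pct > min_identity:
                    union(gi.gene_id, gj.gene_id)

    comp: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        comp.setdefault(find(g.gene_id), []).append(g)
    clusters = []
    for members in comp.values():
        if len(members) < 2:
            continue
        members.sort(key=lambda g: g.start)
        clusters.append(TandemCluster(members[0].chromosome, [g.gene_id for g in members]))
    clusters.sort(key=lambda c: (chrom_sort_key(c.chromosome), c.members))
    return clusters


# -------------------------------------------------------------- anchors

def find_anchors(
    genes_a: list[GeneModel],
    proteins_a: dict[str, str],
    genes_b: list[GeneModel],
    proteins_b: dict[str, str],
    top_n: int = 5,
    min_identity: float = 40.0,
    min_length_ratio: float = 0.5,
    same_genome: bool = False,
) -> list[tuple[str, str]]:
    """Candidate homologous gene pairs by global-alignment ranking.

    For each gene, its top-`top_n` partners by alignment score among
    partners passing the length-ratio filter; a pair is kept when it
    appears in either direction and its identity is >= min_identity.
    Self-pairs are excluded for intra-genome searches.
    """
    ids_a = [g.gene_id for g in genes_a]
    ids_b = [g.gene_id for g in genes_b]
    candidates: set[tuple[str, str]] = set()

    def top_partners(src_ids, src_prot, dst_ids, dst_prot, flip: bool):
        for a in src_ids:
            pa = src_prot[a]
            scored = []
            for b in dst_ids:
                if same_genome and a == b:
                    continue
                pb = dst_prot[b]
                ratio = min(len(pa), len(pb)) / max(len(pa), len(pb))
                if ratio < min_length_ratio:
                    continue
                scored.append((align_score(pa, pb), b))
            scored.sort(key=lambda t: (-t[0], t[1]))
            for _, b in scored[:top_n]:
                if same_genome:
                    candidates.add((min(a, b), max(a, b)))
                else:
                    candidates.add((b, a) if flip else (a, b))

    top_partners(ids_a, proteins_a, ids_b, proteins_b, flip=False)
    if not same_genome:
        top_partners(ids_b, proteins_b, ids_a, proteins_a, flip=True)

    anchors = []
    for a, b in sorted(candidates):
        res = global_align(proteins_a[a], (proteins_a if same_genome else proteins_b)[b], a, b)
        if res.identity_pct >= min_identity:
            anchors.append((a, b))
    return anchors


# ------------------------------------------------------------- chaining

def _ranks(genes: list[GeneModel]) -> dict[str, tuple[str, int]]:
    """gene id -> (chromosome, ordinal rank by start within chromosome)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    out = {}
    for chrom, gs in by_chrom.items():
        gs.sort(key=lambda g: g.start)
        for i, g in enumerate(gs):
            out[g.gene_id] = (chrom, i)
    return out


def chain_collinear_blocks(
    anchors: list[tuple[str, str]],
    gene_models_a: list[GeneModel],
    gene_models_b: list[GeneModel],
    genome_a: str = "A",
    genome_b: str = "B",
    min_anchors: int = 5,
    max_rank_gap: int = 25,
) -> list[CollinearBlock]:
    """Longest-chain DP over anchor gene ranks, per chromosome pair.

    A chain extends an anchor when both rank gaps are within
    [1, max_rank_gap]; for inverted chains the second genome's ranks
    decrease. Chains with >= min_anchors anchors become blocks; each
    anchor joins at most one block, best-scoring chain first.
    """
    ranks_a = _ranks(gene_models_a)
    ranks_b = _ranks(gene_models_b)
    groups: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    for a, b in anchors:
        if a not in ranks_a or b not in ranks_b:
            raise KeyError(f"anchor gene without gene model: {(a, b)}")
        ca, ra = ranks_a[a]
        cb, rb = ranks_b[b]
        groups.setdefault((ca, cb), []).append((ra, rb, a, b))

    blocks: list[CollinearBlock] = []
    used: set[tuple[str, str]] = set()

    def best_chain(items, orientation: str):
        items = sorted(items)
        n = len(items)
        score = [1] * n
        prev = [-1] * n
        for i in range(n):
            for j in range(i):
                da = items[i][0] - items[j][0]
                db = items[i][1] - items[j][1]
                if orientation == "inverted":
                    db = -db
                if 1 <= da <= max_rank_gap and 1 <= db <= max_rank_gap:
                    if score[j] + 1 > score[i]:
                        score[i] = score[j] + 1
                        prev[i] = j
        if not score:
            return []
        end = max(range(n), key=lambda i: (score[i], -items[i][0]))
        chain = []
        while end != -1:
            chain.append(items[end])
            end = prev[end]
        return chain[::-1]

    for (ca, cb), items in sorted(groups.items()):
        for orientation in ("same", "inverted"):
            while True:
                avail = [it for it in items if (it[2], it[3]) not in used]
                chain = best_chain(avail, orientation)
                if len(chain) < min_anchors:
                    break
                pairs = [(a, b) for _, _, a, b in chain]
                used.update(pairs)
                blocks.append(
                    CollinearBlock(genome_a, genome_b, ca, cb, pairs, orientation)
                )
    blocks.sort(key=lambda b: (chrom_sort_key(b.chrom_a), chrom_sort_key(b.chrom_b), b.anchors))
    return blocks


# ----------------------------------------------------- classification

def classify_duplications(
    gene_models: list[GeneModel],
    anchors: list[tuple[str, str]],
    blocks: list[CollinearBlock],
    tandem_clusters: list[TandemCluster],
) -> DuplicationCalls:
    """Per-gene duplication labels for one genome.

    Tandem wins over segmental. Segmental pairs are anchor pairs
    inside intra-genome blocks whose two genes are not members of one
    tandem cluster. Genes with any anchor but no label are dispersed;
    the rest are singletons.
    """
    in_tandem: dict[str, int] = {}
    for ci, c in enumerate(tandem_clusters):
        for g in c.members:
            in_tandem[g] = ci
    segmental_pairs = []
    segmental_genes: set[str] = set()
    for blk in blocks:
        for a, b in blk.anchors:
            same_cluster = (
                a in in_tandem and b in in_tandem and in_tandem[a] == in_tandem[b]
            )
            if not same_cluster:
                segmental_pairs.append((a, b))
                segmental_genes.update((a, b))
    anchored = {g for pair in anchors for g in pair}
    labels = {}
    for g in gene_models:
        gid = g.gene_id
        if gid in in_tandem:
            labels[gid] = "tandem"
        elif gid in segmental_genes:
            labels[gid] = "segmental"
        elif gid in anchored:
            labels[gid] = "dispersed"
        else:
            labels[gid] = "singleton"
    return DuplicationCalls(labels, sorted(set(segmental_pairs)), tandem_clusters)


def find_orthologs(
    inter_genome_blocks: list[CollinearBlock],
    anchors: list[tuple[str, str]] | None = None,
    proteins_a: dict[str, str] | None = None,
    proteins_b: dict[str, str] | None = None,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Ortholog pairs from inter-genome blocks.

    Returns (syntenic ortholog pairs, non-syntenic candidate pairs).
    Syntenic orthologs are anchor pairs inside blocks. When anchors
    and both proteomes are given, reciprocal-best anchor pairs whose
    genes are in no block are reported as non-syntenic candidates —
    homologs that moved to different genomic positions.
    """
    ortho = sorted({p for blk in inter_genome_blocks for p in blk.anchors})
    in_block = {g for pair in ortho for g in pair}
    candidates: list[tuple[str, str]] = []
    if anchors and proteins_a and proteins_b:
        best_a: dict[str, tuple[float, str]] = {}
        best_b: dict[str, tuple[float, str]] = {}
        for a, b in anchors:
            s = align_score(proteins_a[a], proteins_b[b])
            if a not in best_a or s > best_a[a][0]:
                best_a[a] = (s, b)
            if b not in best_b or s > best_b[b][0]:
                best_b[b] = (s, a)
        for a, (_, b) in sorted(best_a.items()):
            if best_b.get(b, (0, None))[1] == a and a not in in_block and b not in in_block:
                candidates.append((a, b))
    return ortho, candidates


# ---------------------------------------------------------------- TSV

def write_tandem_clusters(clusters: list[TandemCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tchromosome\tn_members\tmembers\n")
        for i, c in enumerate(clusters, 1):
            fh.write(f"{i}\t{c.chromosome}\t{len(c.members)}\t{';'.join(c.members)}\n")


def write_blocks(blocks: list[CollinearBlock], path) -> None:
    with open(path, "w") as fh:
        fh.write("block_id\tgenome_a\tgenome_b\tchrom_a\tchrom_b\torientation\tn_anchors\tanchors\n")
        for i, b in enumerate(blocks, 1):
            anchors = ";".join(f"{x},{y}" for x, y in b.anchors)
            fh.write(
                f"{i}\t{b.genome_a}\t{b.genome_b}\t{b.chrom_a}\t{b.chrom_b}\t"
                f"{b.orientation}\t{len(b.anchors)}\t{anchors}\n"
            )


def write_duplication_labels(calls: DuplicationCalls, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlabel\n")
        for g in sorted(calls.labels):
            fh.write(f"{g}\t{calls.labels[g]}\n")


def write_pairs(pairs: list[tuple[str, str]], path, header: str = "gene_a\tgene_b") -> None:
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")
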