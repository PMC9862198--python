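"""End-to-end orchestration over one simulated or real genome pair.

Thin glue used by the command-line interface and the determinism
checks: simulate (or load) two genomes, classify, call duplications
and orthologs, estimate Ka/Ks for every called pair, build the NJ
tree of the FLA proteins, and write every stage's TSV outputs into
one directory with deterministic ordering.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

from . import classify as fc
from . import duplication as dup
from . import io as fio
from . import kaks as fk
from . import phylo as fp
from . import structure_expression as fs
from .synthetic import SimulationConfig, generate_ct_table, generate_genome_pair, write_truth


def run_pipeline(config: SimulationConfig, outdir: str | Path) -> dict:
    """simulate -> classify -> duplications -> kaks -> phylo, all to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome_a, genome_b, truth = generate_genome_pair(config)
    genome_a.write(outdir)
    genome_b.write(outdir)
    write_truth(truth, outdir / "truth")
    ct_rows = generate_ct_table(config.ct_design, config.seed + 1)
    fio.write_ct_table(ct_rows, outdir / "ct.tsv")

    summary: dict = {}
    fla_sets: dict[str, list[str]] = {}
    for tag, genome in (("A", genome_a), ("B", genome_b)):
        sid = genome.meta.species_id
        annotations = fc.classify_proteins(genome.proteins, genome.domain_hits)
        fc.assign_names(annotations, genome.gene_models, genome.meta)
        fc.write_annotations(annotations, outdir / f"{sid}.annotations.tsv")
        fla_ids = sorted(a.protein_id for a in annotations if a.is_fla)
        fla_sets[tag] = fla_ids
        summary[f"n_fla_{tag}"] = len(fla_ids)

        models = [g for g in genome.gene_models if g.gene_id in set(fla_ids)]
        prots = {i: genome.protein_dict()[i] for i in fla_ids}
        clusters = dup.detect_tandem(models, prots)
        dup.write_tandem_clusters(clusters, outdir / f"{sid}.tandem.tsv")
        anchors = dup.find_anchors(models, prots, models, prots, same_genome=True)
        blocks = dup.chain_collinear_blocks(anchors, models, models, sid, sid)
        dup.write_blocks(blocks, outdir / f"{sid}.blocks.tsv")
        calls = dup.classify_duplications(models, anchors, blocks, clusters)
        dup.write_duplication_labels(calls, outdir / f"{sid}.duplication_labels.tsv")
        dup.write_pairs(calls.segmental_pairs, outdir / f"{sid}.segmental_pairs.tsv")
        results = fk.kaks_for_pairs(genome.cds, prots, calls.segmental_pairs)
        fk.write_kaks(results, outdir / f"{sid}.kaks.tsv")
        dist = fs.intron_stats(models)
        fs.write_intron_stats(dist, outdir / f"{sid}.intron_stats.tsv")
        summary[f"n_tandem_clusters_{tag}"] = len(clusters)
        summary[f"n_segmental_pairs_{tag}"] = len(calls.segmental_pairs)

    # inter-genome orthologs
    models_a = [g for g in genome_a.gene_models if g.gene_id in set(fla_sets["A"])]
    models_b = [g for g in genome_b.gene_models if g.gene_id in set(fla_sets["B"])]
    prots_a = {i: genome_a.protein_dict()[i] for i in fla_sets["A"]}
    prots_b = {i: genome_b.protein_dict()[i] for i in fla_sets["B"]}
    anchors_ab = dup.find_anchors(models_a, prots_a, models_b, prots_b)
    blocks_ab = dup.chain_collinear_blocks(
        anchors_ab, models_a, models_b,
        genome_a.meta.species_id, genome_b.meta.species_id,
    )
    dup.write_blocks(blocks_ab, outdir / "inter_genome.blocks.tsv")
    ortho, nonsyn = dup.find_orthologs(blocks_ab, anchors_ab, prots_a, prots_b)
    dup.write_pairs(ortho, outdir / "ortholog_pairs.tsv")
    dup.write_pairs(nonsyn, outdir / "nonsyntenic_candidates.tsv")
    cds_all = {**genome_a.cds, **genome_b.cds}
    prots_all = {**prots_a, **prots_b}
    fk.write_kaks(
        fk.kaks_for_pairs(cds_all, prots_all, ortho + nonsyn),
        outdir / "ortholog.kaks.tsv",
    )
    summary["n_ortholog_pairs"] = len(ortho)
    summary["n_nonsyntenic_candidates"] = len(nonsyn)

    # NJ tree of all FLA proteins from both genomes. Families are
    # indel-free so rows are gap-padded to equal length; pairs from
    # unrelated families can approach saturation, so p is capped just
    # below 1 before Poisson correction (saturated distances are
    # effectively "maximally distant", as MEGA flags them).
    import numpy as np

    ids = fla_sets["A"] + fla_sets["B"]
    seqs = [prots_all[i] for i in ids]
    width = max(len(s) for s in seqs)
    rows = [s.ljust(width, "-") for s in seqs]
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = min(fp.p_distance(rows[i], rows[j]), 0.95)
            D[i, j] = D[j, i] = fp.poisson_distance(p)
    tree = fp.neighbor_joining(D, ids)
    (outdir / "fla_nj.nwk").write_text(tree.newick() + "\n")

    # expression
    expr = fs.compare_tissues(ct_rows, config.ct_design.tissues[0])
    fs.write_expression(expr, outdir / "expression.tsv")
    return summary


def hash_outputs(outdir: str | Path) -> dict[str, str]:
    """SHA256 of every file under outdir, keyed by relative path."""
    outdir = Path(outdir)
    out = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file():
            out[str(p.relative_to(outdir))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out
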