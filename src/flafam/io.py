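"""Readers and writers for the formats the pipeline touches.

FASTA goes through Biopython's SeqIO. GFF3 is restricted to the
three-level gene/mRNA/exon dialect used throughout (one primary mRNA
per gene; when several are present, the one with the longest summed
exon length is primary), and the reader is the exact inverse of the
writer on that dialect. HMMER ``--domtblout`` tables are parsed
positionally, as that format requires. SignalP 5.0 short-format and
big-PI result files are accepted as overrides for the built-in
signal-peptide and GPI heuristics.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import DomainHit, GeneModel, ProteinRecord, SpeciesMeta, CtRow

FAS_ACCESSION = "PF02469"
DEFAULT_DOMAIN_EVALUE = 1e-5


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein or CDS FASTA into records, preserving order.

    Sequence letters are uppercased. Duplicate identifiers and empty
    files are errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA identifier: {rec.id}")
        seen.add(rec.id)
        fields = rec.description.split()
        gene_id = fields[1] if len(fields) > 1 else None
        records.append(ProteinRecord(rec.id, str(rec.seq), gene_id))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    seqs = []
    for r in records:
        desc = r.gene_id if r.gene_id else ""
        seqs.append(SeqRecord(Seq(r.sequence), id=r.protein_id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ---------------------------------------------------------------- GFF3

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from a gene/mRNA/exon GFF3 file.

    Coordinates stay 1-based inclusive. When a gene carries several
    mRNAs the one with the longest summed exon length becomes the
    primary isoform. An exon outside its gene span is an error.
    """
    genes: dict[str, GeneModel] = {}
    gene_order: list[str] = []
    mrna_to_gene: dict[str, str] = {}
    mrna_exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            start_i, end_i = int(start), int(end)
            if ftype == "gene":
                gid = attr["ID"]
                genes[gid] = GeneModel(gid, chrom, start_i, end_i, strand, [])
                gene_order.append(gid)
            elif ftype == "mRNA":
                mrna_to_gene[attr["ID"]] = attr["Parent"]
                mrna_exons[attr["ID"]] = []
            elif ftype == "exon":
                parent = attr["Parent"]
                if parent not in mrna_exons:
                    raise ValueError(f"{path}:{lineno}: exon with unknown mRNA parent")
                mrna_exons[parent].append((start_i, end_i))
    out: list[GeneModel] = []
    best_exons: dict[str, list[tuple[int, int]]] = {}
    for mrna_id, exons in mrna_exons.items():
        gid = mrna_to_gene[mrna_id]
        total = sum(e - s + 1 for s, e in exons)
        prev = best_exons.get(gid)
        if prev is None or total > sum(e - s + 1 for s, e in prev):
            best_exons[gid] = sorted(exons)
    for gid in gene_order:
        g = genes[gid]
        exons = best_exons.get(gid, [])
        # GeneModel validation raises on exons outside the gene span
        out.append(GeneModel(gid, g.chromosome, g.start, g.end, g.strand, exons))
    return out


def write_gff3(models: Iterable[GeneModel], path: str | Path, source: str = "flafam") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            fh.write(
                f"{g.chromosome}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chromosome}\t{source}\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chromosome}\t{source}\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.exon{i};Parent={mrna}\n"
                )


# ------------------------------------------------------------ domtblout

def read_domtblout(
    path: str | Path, evalue_threshold: float = DEFAULT_DOMAIN_EVALUE
) -> list[DomainHit]:
    """Parse HMMER ``--domtblout`` rows into domain hits.

    Keeps hits with independent (i-Evalue) at or below the threshold.
    Malformed rows raise with their line number.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 22:
                raise ValueError(f"{path}:{lineno}: truncated domtblout row")
            try:
                hit = DomainHit(
                    protein_id=parts[0],
                    domain_accession=parts[4],
                    env_start=int(parts[19]),
                    env_end=int(parts[20]),
                    independent_evalue=float(parts[12]),
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if hit.independent_evalue <= evalue_threshold:
                hits.append(hit)
    return hits


def write_domtblout(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in domtblout column layout (unused columns filled in)."""
    with open(path, "w") as fh:
        fh.write("# target_name t_acc tlen query_name q_acc qlen E-value score bias "
                 "# of c-Evalue i-Evalue score bias hmm_from hmm_to ali_from ali_to "
                 "env_from env_to acc description\n")
        for h in hits:
            length = h.env_end + 10
            fh.write(
                f"{h.protein_id} - {length} FAS1 {h.domain_accession} 130 "
                f"{h.independent_evalue:.2g} 100.0 0.1 1 1 "
                f"{h.independent_evalue:.2g} {h.independent_evalue:.2g} 100.0 0.1 "
                f"1 130 {h.env_start} {h.env_end} {h.env_start} {h.env_end} 0.99 -\n"
            )


# ------------------------------------------------- SignalP / big-PI overrides

def read_signalp(path: str | Path) -> dict[str, int | None]:
    """Parse SignalP 5.0 short-format output.

    Returns protein id -> cleavage position (last residue of the
    signal peptide) for predicted SP(Sec/SPI) proteins, or None for
    proteins predicted OTHER (an explicit negative override).
    """
    out: dict[str, int | None] = {}
    cs_re = re.compile(r"CS pos:\s*(\d+)-(\d+)")
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                parts = line.split()
            pid, prediction = parts[0], parts[1]
            if prediction.startswith("SP"):
                m = cs_re.search(line)
                out[pid] = int(m.group(1)) if m else None
            else:
                out[pid] = None
    return out


def read_bigpi(path: str | Path) -> dict[str, int | None]:
    """Parse big-PI result text for omega-site positions.

    Accepts per-protein blocks introduced by ``>identifier`` or
    single-line entries; a line containing ``omega site`` (in any
    case) followed by an integer gives the omega position. A protein
    mentioned without an omega-site line is an explicit negative.
    """
    out: dict[str, int | None] = {}
    current: str | None = None
    omega_re = re.compile(r"omega[ _-]?site[^0-9]*(\d+)", re.IGNORECASE)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
                out.setdefault(current, None)
                continue
            m = omega_re.search(line)
            if m:
                pid = current if current else line.split()[0]
                out[pid] = int(m.group(1))
            elif current is None and line and not line.startswith("#"):
                first = line.split()[0]
                out.setdefault(first, None)
    return out


# ----------------------------------------------------------------- TSV

def read_species_meta(path: str | Path) -> list[SpeciesMeta]:
    """Read a species metadata TSV: species_id habit genome_gene_total name_prefix."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            out.append(
                SpeciesMeta(
                    species_id=p[idx["species_id"]],
                    habit=p[idx["habit"]],
                    genome_gene_total=int(p[idx["genome_gene_total"]]),
                    name_prefix=p[idx["name_prefix"]],
                )
            )
    return out


def read_ct_table(path: str | Path) -> list[CtRow]:
    """Read a Ct TSV: gene_id tissue_id replicate ct_target ct_reference."""
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            rows.append(
                CtRow(
                    gene_id=p[idx["gene_id"]],
                    tissue_id=p[idx["tissue_id"]],
                    replicate_index=int(p[idx["replicate"]]),
                    ct_target=float(p[idx["ct_target"]]),
                    ct_reference=float(p[idx["ct_reference"]]),
                )
            )
    return rows


def write_ct_table(rows: Iterable[CtRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\ttissue_id\treplicate\tct_target\tct_reference\n")
        for r in rows:
            fh.write(
                f"{r.gene_id}\t{r.tissue_id}\t{r.replicate_index}\t"
                f"{r.ct_target:.4f}\t{r.ct_reference:.4f}\n"
            )
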