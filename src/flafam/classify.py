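"""FLA protein classification.

A fasciclin-like arabinogalactan protein (FLA) carries at least one
fasciclin (FAS, Pfam PF02469) domain together with arabinogalactan
(AGP) glycomodules — clusters of Pro residues preceded by small
residues that mark O-glycosylation. The classifier here mirrors the
screening done in gene-family surveys: detect the N-terminal signal
peptide and the C-terminal GPI-anchor omega segment, mask those plus
the FAS domain envelopes, scan the remaining mature sequence for
glycomodules, and call a protein FLA when it has at least one FAS
domain and at least one unmasked glycomodule. Neither a signal
peptide nor a GPI anchor is required for membership (real families
include members lacking either).

Signal peptides and GPI anchors are normally predicted with SignalP
and big-PI; those tools' result files are accepted as overrides and
take precedence, while documented rule-based heuristics serve as the
offline default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .models import DomainHit, GeneModel, ProteinRecord, Region, SpeciesMeta, chrom_sort_key

HYDROPHOBIC = set("ACFILMVW")
SP_SMALL = set("AGSCT")          # allowed at cleavage positions -1 and -3
GPI_HYDROPHOBIC = set("AFILMVW")
GPI_OMEGA = set("SGANDC")        # small residues accepted at the omega site
AG_X = set("ASTVG")              # X of the X-Pro glycomodule dipeptide


@dataclass
class FLAAnnotation:
    protein_id: str
    regions: list[Region] = field(default_factory=list)
    is_fla: bool = False
    pI: float | None = None
    Mw: float | None = None
    assigned_name: str | None = None


# ------------------------------------------------------- signal peptide

def scan_signal_peptide(
    sequence: str,
    min_core: int = 7,
    search_window: int = 30,
    cleavage_limit: int = 35,
) -> Region | None:
    """Rule-based N-terminal signal-peptide detection.

    Looks within the first `search_window` residues for a hydrophobic
    core: a stretch of >= `min_core` residues from {A,C,F,I,L,M,V,W}
    allowing at most one interruption. The cleavage position c is then
    the first position >= core_end + 2 (searched up to
    `cleavage_limit`) with small residues {A,G,S,C,T} at both c and
    c-2 — the classic (-3,-1) small-residue rule. Returns region
    (1, c), or None when no core or no cleavage site exists.
    Sequences shorter than 15 residues return None.
    """
    n = len(sequence)
    if n < 15:
        return None
    core_end = None
    for i in range(min(search_window, n)):
        hydro = 0
        interruptions = 0
        last_hydro = None
        j = i
        while j < min(search_window, n):
            if sequence[j] in HYDROPHOBIC:
                hydro += 1
                last_hydro = j
            else:
                interruptions += 1
                if interruptions > 1:
                    break
            j += 1
        if last_hydro is not None and hydro >= min_core:
            span = last_hydro - i + 1
            if span >= min_core:
                core_end = last_hydro + 1  # 1-based
                break
    if core_end is None:
        return None
    for c in range(core_end + 2, min(cleavage_limit, n) + 1):
        if sequence[c - 1] in SP_SMALL and sequence[c - 3] in SP_SMALL:
            return Region("signal_peptide", 1, c)
    return None


# ------------------------------------------------------------ GPI tail

def scan_gpi_segment(
    sequence: str,
    min_tail_run: int = 8,
    tail_window: int = 12,
    omega_offset: tuple[int, int] = (8, 12),
) -> Region | None:
    """Rule-based C-terminal GPI omega-segment detection.

    Requires a hydrophobic run of >= `min_tail_run` residues from
    {A,F,I,L,M,V,W} starting within the final `tail_window` residues,
    and an omega candidate from {S,G,A,N,D,C} located 8–12 residues
    upstream of the run start. Returns region (omega, end) or None.
    """
    n = len(sequence)
    if n < 25:
        return None
    lo, hi = omega_offset
    window_start = n - tail_window  # 0-based index of first position in window
    run_start = None
    i = window_start
    while i < n:
        if sequence[i] in GPI_HYDROPHOBIC:
            j = i
            while j < n and sequence[j] in GPI_HYDROPHOBIC:
                j += 1
            if j - i >= min_tail_run:
                run_start = i  # 0-based
                break
            i = j
        else:
            i += 1
    if run_start is None:
        return None
    for d in range(lo, hi + 1):
        pos = run_start - d  # 0-based omega candidate
        if pos >= 0 and sequence[pos] in GPI_OMEGA:
            return Region("gpi_omega_segment", pos + 1, n)
    return None


# -------------------------------------------------------- glycomodules

def scan_agp_glycomodules(
    sequence: str,
    masked_regions: list[Region] | None = None,
    min_dipeptides: int = 3,
    max_spacing: int = 10,
) -> list[Region]:
    """Find AGP glycomodules outside masked regions.

    An AG dipeptide is X-P with X in {A,S,T,V,G}. A glycomodule is a
    maximal chain of >= `min_dipeptides` dipeptides whose consecutive
    start positions are <= `max_spacing` residues apart, measured in
    original coordinates; dipeptides overlapping a masked region are
    ignored. Regions span the first dipeptide start to the last
    dipeptide end.
    """
    masked = masked_regions or []
    starts = []
    for i in range(len(sequence) - 1):
        if sequence[i] in AG_X and sequence[i + 1] == "P":
            pos = i + 1  # 1-based dipeptide start
            dip = Region("glycomodule", pos, pos + 1)
            if any(dip.overlaps(m) for m in masked):
                continue
            starts.append(pos)
    regions: list[Region] = []
    chain: list[int] = []
    for pos in starts:
        if chain and pos - chain[-1] > max_spacing:
            if len(chain) >= min_dipeptides:
                regions.append(Region("glycomodule", chain[0], chain[-1] + 1))
            chain = []
        chain.append(pos)
    if len(chain) >= min_dipeptides:
        regions.append(Region("glycomodule", chain[0], chain[-1] + 1))
    return regions


# -------------------------------------------------------------- pI / Mw

# Bjellqvist pKa set; N-terminal pKa is residue-specific with 7.5 default.
PKA_CTERM = 3.55
PKA_NTERM_DEFAULT = 7.5
PKA_NTERM = {"A": 7.59, "E": 7.7, "M": 7.0, "P": 8.36, "S": 6.93, "T": 6.82, "V": 7.44}
PKA_NEGATIVE = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PKA_POSITIVE = {"H": 5.98, "K": 10.0, "R": 12.0}

# ExPASy average residue masses (Da); X uses a documented generic 110.0.
RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
    "X": 110.0,
}
WATER_MASS = 18.01524


def net_charge(sequence: str, ph: float) -> float:
    """Net protein charge at a given pH under the documented pKa table."""
    def pos(pka: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (ph - pka))

    def neg(pka: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pka - ph))

    charge = pos(PKA_NTERM.get(sequence[0], PKA_NTERM_DEFAULT)) + neg(PKA_CTERM)
    for aa in sequence:
        if aa in PKA_POSITIVE:
            charge += pos(PKA_POSITIVE[aa])
        elif aa in PKA_NEGATIVE:
            charge += neg(PKA_NEGATIVE[aa])
    return charge


def compute_pi(sequence: str, tol: float = 1e-4) -> float:
    """Isoelectric point by bisection of the net-charge function on [0, 14]."""
    if not sequence:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    while hi - lo > 1e-7:
        mid = (lo + hi) / 2.0
        q = net_charge(sequence, mid)
        if abs(q) < tol:
            break
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def compute_mw(sequence: str) -> float:
    """Average molecular weight: residue masses plus one water."""
    if not sequence:
        raise ValueError("empty sequence")
    return sum(RESIDUE_MASS[aa] for aa in sequence) + WATER_MASS


# ------------------------------------------------------- classification

def merge_regions(regions: list[Region], kind: str) -> list[Region]:
    """Union of overlapping regions of one kind (FAS hits may overlap)."""
    spans = sorted((r.start, r.end) for r in regions)
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return [Region(kind, s, e) for s, e in merged]


def classify_fla(
    protein: ProteinRecord,
    domain_hits: list[DomainHit],
    sp_override: int | None | str = "auto",
    gpi_override: int | None | str = "auto",
    min_dipeptides: int = 3,
    max_spacing: int = 10,
) -> FLAAnnotation:
    """Classify one protein from its sequence and FAS domain hits.

    sp_override / gpi_override: "auto" runs the heuristic; an integer
    is an externally predicted cleavage / omega position (SignalP or
    big-PI); None is an explicit negative override.
    """
    seq = protein.sequence
    n = len(seq)

    if sp_override == "auto":
        sp = scan_signal_peptide(seq)
    elif sp_override is None:
        sp = None
    else:
        sp = Region("signal_peptide", 1, min(int(sp_override), n))

    if gpi_override == "auto":
        gpi = scan_gpi_segment(seq)
    elif gpi_override is None:
        gpi = None
    else:
        gpi = Region("gpi_omega_segment", min(int(gpi_override), n), n)

    fas = merge_regions(
        [
            Region("fas_domain", h.env_start, min(h.env_end, n))
            for h in domain_hits
            if h.protein_id == protein.protein_id
        ],
        "fas_domain",
    )
    masked = ([sp] if sp else []) + fas + ([gpi] if gpi else [])
    glyco = scan_agp_glycomodules(seq, masked, min_dipeptides, max_spacing)
    regions = sorted(masked + glyco, key=lambda r: (r.start, r.end, r.kind))
    return FLAAnnotation(
        protein_id=protein.protein_id,
        regions=regions,
        is_fla=bool(fas) and bool(glyco),
        pI=compute_pi(seq),
        Mw=compute_mw(seq),
    )


def classify_proteins(
    proteins: list[ProteinRecord],
    domain_hits: list[DomainHit],
    signalp: dict[str, int | None] | None = None,
    bigpi: dict[str, int | None] | None = None,
    **kwargs,
) -> list[FLAAnnotation]:
    """Classify a set of proteins; override dicts win over heuristics."""
    hits_by_protein: dict[str, list[DomainHit]] = {}
    for h in domain_hits:
        hits_by_protein.setdefault(h.protein_id, []).append(h)
    out = []
    for p in proteins:
        sp = signalp.get(p.protein_id, "auto") if signalp else "auto"
        gpi = bigpi.get(p.protein_id, "auto") if bigpi else "auto"
        out.append(
            classify_fla(
                p, hits_by_protein.get(p.protein_id, []), sp_override=sp,
                gpi_override=gpi, **kwargs,
            )
        )
    return out


def assign_names(
    annotations: list[FLAAnnotation],
    gene_models: list[GeneModel],
    species_meta: SpeciesMeta,
    protein_to_gene: dict[str, str] | None = None,
) -> list[FLAAnnotation]:
    """Name FLA-positive proteins by chromosomal order.

    Genes are sorted by (chromosome natural order, start); names are
    prefix + "FLA" + 1..n. Numbered chromosomes precede unplaced
    contigs. Input order does not affect the result.
    """
    models = {g.gene_id: g for g in gene_models}
    positives = [a for a in annotations if a.is_fla]

    def gene_of(a: FLAAnnotation) -> GeneModel:
        gid = (protein_to_gene or {}).get(a.protein_id, a.protein_id)
        if gid not in models:
            raise KeyError(f"no gene model for FLA protein {a.protein_id}")
        return models[gid]

    positives.sort(
        key=lambda a: (chrom_sort_key(gene_of(a).chromosome), gene_of(a).start)
    )
    for i, a in enumerate(positives, 1):
        a.assigned_name = f"{species_meta.name_prefix}FLA{i}"
    return annotations


def write_annotations(annotations: list[FLAAnnotation], path) -> None:
    """One row per protein: verdict, regions as start-end:kind, pI, Mw, name."""
    with open(path, "w") as fh:
        fh.write("protein_id\tis_fla\tregions\tpI\tMw\tassigned_name\n")
        for a in annotations:
            regions = ";".join(f"{r.start}-{r.end}:{r.kind}" for r in a.regions)
            fh.write(
                f"{a.protein_id}\t{int(a.is_fla)}\t{regions}\t"
                f"{a.pI:.2f}\t{a.Mw:.2f}\t{a.assigned_name or '.'}\n"
            )
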