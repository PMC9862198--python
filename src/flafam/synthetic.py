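"""Synthetic genome pairs with planted FLA biology and full ground truth.

The generator emulates the data shapes a comparative FLA gene-family
study consumes: two related multi-chromosome "genomes" with protein +
CDS FASTA, GFF3 gene models and FAS-domain hit tables, containing
planted FLA genes (signal peptide, fasciclin domain(s), AGP
glycomodules, GPI omega segment — each constructed to satisfy the
classifier's detection rules exactly), tandem arrays obeying or
violating the two tandem criteria, intra- and inter-genome collinear
blocks, codon-level divergence with controlled synonymous and
nonsynonymous counts, and replicate qPCR Ct tables with known fold
changes. Every planted structure is recorded in truth tables so each
pipeline stage can be validated against exact expectations.

Background sequence contains no proline (so no accidental AGP
glycomodules) and caps hydrophobic runs at three residues (so no
accidental signal-peptide cores or GPI tails); planted features are
therefore the only ones the detectors can find. Families are
substitution-only (indel-free), so the identity alignment of family
members is exact and pairwise alignments are gapless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as fio
from .classify import AG_X, HYDROPHOBIC
from .kaks import CODON_TO_AA, STOP_CODONS, codon_sites, split_codons
from .models import CtRow, DomainHit, GeneModel, ProteinRecord, Region, SpeciesMeta

# background amino-acid frequencies (no proline: see module docstring)
_BG_AA = "ACDEFGHIKLMNQRSTVWY"
_BG_FREQ = np.array(
    [0.090, 0.015, 0.055, 0.065, 0.042, 0.075, 0.022, 0.058, 0.060, 0.095,
     0.024, 0.045, 0.040, 0.055, 0.070, 0.056, 0.071, 0.012, 0.050]
)
_BG_FREQ = _BG_FREQ / _BG_FREQ.sum()
_POLAR = [a for a in _BG_AA if a not in HYDROPHOBIC]
_POLAR_FREQ = np.array([_BG_FREQ[_BG_AA.index(a)] for a in _POLAR])
_POLAR_FREQ = _POLAR_FREQ / _POLAR_FREQ.sum()

_SP_HYDRO = "LVFIAM"
_GPI_RUN = "LVFIAMW"
_GPI_SPACER = "QKERHT"
_SAFE_MUT = "QKERHDNY"  # replacement residues that cannot create new motifs

_CODONS_FOR_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    _CODONS_FOR_AA.setdefault(_aa, []).append(_codon)


# ---------------------------------------------------------------- config

@dataclass
class TandemSpec:
    genome: str          # "A" or "B"
    chromosome: str
    array_size: int
    gap_bp: int
    identity_pct: float
    positive: bool       # True: satisfies both criteria

    def __post_init__(self) -> None:
        if not (0 < self.identity_pct <= 100):
            raise ValueError("identity_pct must be in (0, 100]")
        if self.positive and self.gap_bp > 100_000:
            raise ValueError("planted-positive arrays need gap_bp <= 100000")


@dataclass
class BlockSpec:
    chrom_a: str
    chrom_b: str
    n_anchors: int


@dataclass
class IntraBlockSpec:
    genome: str
    chrom_x: str
    chrom_y: str
    n_anchors: int


@dataclass
class CtDesign:
    tissues: list[str]
    fold_changes: dict[str, dict[str, float]]  # gene -> tissue -> fold
    ct_noise_sd: float = 0.2
    n_replicates: int = 3
    baseline_dct: float = 3.0
    ct_reference: float = 17.5

    def __post_init__(self) -> None:
        for gene, folds in self.fold_changes.items():
            for tissue, f in folds.items():
                if f <= 0:
                    raise ValueError(f"fold change must be > 0 ({gene}/{tissue})")


def _default_tandem_specs() -> list[TandemSpec]:
    return [
        TandemSpec("B", "chr1", 3, 20_000, 92.0, True),
        TandemSpec("B", "chr2", 2, 30_000, 90.0, True),
        TandemSpec("B", "chr3", 2, 150_000, 92.0, False),  # violates the 100 kb rule
        TandemSpec("B", "chr1", 2, 20_000, 60.0, False),   # violates the >70% rule
    ]


def _default_blocks() -> list[BlockSpec]:
    return [BlockSpec("chr1", "chr1", 8)]


def _default_intra_blocks() -> list[IntraBlockSpec]:
    return [
        IntraBlockSpec("A", "chr2", "chr3", 5),
        IntraBlockSpec("B", "chr2", "chr3", 5),
    ]


def _default_ct_design() -> CtDesign:
    tissues = ["S1", "S2", "S3", "S4", "S5"]
    return CtDesign(
        tissues=tissues,
        fold_changes={
            "q1": {"S1": 1.0, "S2": 2.0, "S3": 4.0, "S4": 8.0, "S5": 4.0},
            "q2": {"S1": 1.0, "S2": 1.0, "S3": 2.0, "S4": 4.0, "S5": 8.0},
        },
    )


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 3
    genes_per_chromosome: int = 24
    tandem_specs: list[TandemSpec] = field(default_factory=_default_tandem_specs)
    block_specs: list[BlockSpec] = field(default_factory=_default_blocks)
    intra_block_specs: list[IntraBlockSpec] = field(default_factory=_default_intra_blocks)
    n_nonsyntenic_orthologs: int = 1
    n_isolated_fla: int = 2
    divergence: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"ortholog": (0.05, 0.20), "segmental": (0.03, 0.15)}
    )
    sp_rate: float = 0.85
    gpi_rate: float = 0.72
    intergenic_bp: tuple[int, int] = (4_000, 30_000)
    ct_design: CtDesign = field(default_factory=_default_ct_design)
    species_a: SpeciesMeta = field(
        default_factory=lambda: SpeciesMeta("genomeA", "woody", 30_000, "Gva")
    )
    species_b: SpeciesMeta = field(
        default_factory=lambda: SpeciesMeta("genomeB", "woody", 32_000, "Gvb")
    )

    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "tandem_specs" in d:
            d["tandem_specs"] = [TandemSpec(**t) for t in d["tandem_specs"]]
        if "block_specs" in d:
            d["block_specs"] = [BlockSpec(**b) for b in d["block_specs"]]
        if "intra_block_specs" in d:
            d["intra_block_specs"] = [IntraBlockSpec(**b) for b in d["intra_block_specs"]]
        if "ct_design" in d:
            d["ct_design"] = CtDesign(**d["ct_design"])
        if "species_a" in d:
            d["species_a"] = SpeciesMeta(**d["species_a"])
        if "species_b" in d:
            d["species_b"] = SpeciesMeta(**d["species_b"])
        if "divergence" in d:
            d["divergence"] = {k: tuple(v) for k, v in d["divergence"].items()}
        if "intergenic_bp" in d:
            d["intergenic_bp"] = tuple(d["intergenic_bp"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        def clean(o):
            if isinstance(o, dict):
                return {k: clean(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [clean(v) for v in o]
            return o

        with open(path, "w") as fh:
            yaml.safe_dump(clean(asdict(self)), fh, sort_keys=False)


# ---------------------------------------------------- sequence building

def _background(rng: np.random.Generator, n: int, start_met: bool = False) -> str:
    """Background residues; hydrophobic runs are capped at three."""
    out: list[str] = []
    if start_met and n > 0:
        out.append("M")
    while len(out) < n:
        if len(out) >= 3 and all(c in HYDROPHOBIC for c in out[-3:]):
            out.append(str(rng.choice(list(_POLAR), p=_POLAR_FREQ)))
        else:
            out.append(str(rng.choice(list(_BG_AA), p=_BG_FREQ)))
    return "".join(out[:n])


def _signal_peptide(rng: np.random.Generator) -> str:
    """14-residue signal peptide built to the detector's rule (cleaves at 14)."""
    core = "".join(rng.choice(list(_SP_HYDRO)) for _ in range(8))
    return "MKT" + core + "SQA"


def _gpi_tail(rng: np.random.Generator) -> str:
    """omega + 8-residue spacer + 8-residue hydrophobic tail (17 residues)."""
    omega = str(rng.choice(list("SGND")))
    spacer = "".join(rng.choice(list(_GPI_SPACER)) for _ in range(8))
    run = "".join(rng.choice(list(_GPI_RUN)) for _ in range(8))
    return omega + spacer + run


def _glycomodule(rng: np.random.Generator, n_dipeptides: int) -> str:
    return "".join(str(rng.choice(list(AG_X))) + "P" for _ in range(n_dipeptides))


@dataclass
class FlaTemplate:
    sequence: str
    regions: list[Region]
    mutable: list[int]  # 0-based positions free to change without breaking detection


def _make_fla(
    rng: np.random.Generator,
    with_sp: bool,
    n_domains: int,
    n_glyco: int,
    with_gpi: bool,
    linker_range: tuple[int, int] = (14, 22),
    fas_range: tuple[int, int] = (110, 130),
) -> FlaTemplate:
    segs: list[tuple[str | None, str, bool]] = []  # (kind, text, mutable)

    def linker(first: bool = False) -> None:
        n = int(rng.integers(*linker_range))
        segs.append((None, _background(rng, n, start_met=first), True))

    if with_sp:
        segs.append(("signal_peptide", _signal_peptide(rng), False))
        linker()
    else:
        linker(first=True)

    features: list[str] = []
    for i in range(max(n_glyco, n_domains)):
        if i < n_glyco:
            features.append("glycomodule")
        if i < n_domains:
            features.append("fas_domain")
    for kind in features:
        if kind == "glycomodule":
            segs.append(("glycomodule", _glycomodule(rng, int(rng.integers(3, 6))), False))
        else:
            n = int(rng.integers(*fas_range))
            segs.append(("fas_domain", _background(rng, n), True))
        linker()
    if with_gpi:
        segs.append(("gpi_omega_segment", _gpi_tail(rng), False))

    seq_parts: list[str] = []
    regions: list[Region] = []
    mutable: list[int] = []
    pos = 0
    for kind, text, is_mutable in segs:
        if kind is not None:
            regions.append(Region(kind, pos + 1, pos + len(text)))
        if is_mutable:
            mutable.extend(range(pos, pos + len(text)))
        seq_parts.append(text)
        pos += len(text)
    return FlaTemplate("".join(seq_parts), regions, mutable)


def generate_fla_protein(
    seed: int | np.random.Generator,
    with_sp: bool = True,
    n_domains: int = 1,
    n_glyco: int = 2,
    with_gpi: bool = True,
    require_fla: bool = True,
) -> tuple[str, list[Region]]:
    """One synthetic FLA-like protein and its planted feature regions.

    With require_fla (the default) the protein must be classifiable
    as FLA, so n_domains >= 1 and n_glyco >= 1 are enforced; decoys
    are generated with require_fla=False. Deterministic given seed.
    """
    if require_fla and (n_domains < 1 or n_glyco < 1):
        raise ValueError("an FLA-positive protein needs n_domains >= 1 and n_glyco >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = _make_fla(rng, with_sp, n_domains, n_glyco, with_gpi)
    return t.sequence, t.regions


# -------------------------------------------------------- CDS evolution

def backtranslate_protein(protein: str, rng: np.random.Generator) -> str:
    """CDS for a protein with codons drawn uniformly among synonyms."""
    return "".join(str(rng.choice(_CODONS_FOR_AA[aa])) for aa in protein)


def evolve_cds(
    cds: str,
    target_ka: float,
    target_ks: float,
    seed: int | np.random.Generator,
) -> tuple[str, dict[str, int]]:
    """Diverge a CDS to NG86-scale Ka and Ks targets.

    Converts the targets to p-distances (inverting the Jukes–Cantor
    correction), turns them into synonymous and nonsynonymous change
    quotas against the sequence's NG86 site counts, and applies
    accepted random single-base codon changes (at most one change per
    base position, never creating a stop) until both quotas are met.
    Targets implying saturation (p >= 0.74) are an error. Returns the
    diverged CDS and the realized change counts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codons = split_codons(cds)
    ps_t = 0.75 * (1.0 - math.exp(-4.0 * target_ks / 3.0))
    pn_t = 0.75 * (1.0 - math.exp(-4.0 * target_ka / 3.0))
    if ps_t >= 0.74 or pn_t >= 0.74:
        raise ValueError("divergence target beyond saturation (p >= 0.74)")
    S = sum(codon_sites(c)[0] for c in codons)
    N = sum(codon_sites(c)[1] for c in codons)
    want_s = int(round(ps_t * S))
    want_n = int(round(pn_t * N))

    seq = list("".join(codons))
    touched: set[int] = set()
    done_s = done_n = 0
    max_iter = 500 * len(seq) + 1000
    it = 0
    while (done_s < want_s or done_n < want_n) and it < max_iter:
        it += 1
        pos = int(rng.integers(len(seq)))
        if pos in touched:
            continue
        new_base = "ACGT"[int(rng.integers(4))]
        if new_base == seq[pos]:
            continue
        ci = pos // 3
        cur = "".join(seq[3 * ci:3 * ci + 3])
        nxt = cur[:pos % 3] + new_base + cur[pos % 3 + 1:]
        if nxt in STOP_CODONS:
            continue
        syn = CODON_TO_AA[nxt] == CODON_TO_AA[cur]
        if syn and done_s < want_s:
            done_s += 1
        elif not syn and done_n < want_n:
            done_n += 1
        else:
            continue
        seq[pos] = new_base
        touched.add(pos)
    if done_s < want_s or done_n < want_n:
        raise RuntimeError("could not reach divergence targets")
    return "".join(seq), {"synonymous": done_s, "nonsynonymous": done_n}


def _diverge_member(
    protein: str,
    cds: str,
    mutable: list[int],
    n_aa: int,
    n_syn: int,
    rng: np.random.Generator,
) -> tuple[str, str, dict[str, int]]:
    """Derive a family member with exact substitution counts.

    Applies n_aa nonsynonymous single-base codon changes confined to
    mutable protein positions (replacement residues from a safe set
    that cannot create glycomodule, signal-peptide or GPI motifs) and
    n_syn synonymous single-base changes anywhere, at most one change
    per codon, so planted feature detection and percent identity are
    exact by construction.
    """
    codons = split_codons(cds)
    if n_aa > len(mutable):
        raise ValueError(f"cannot place {n_aa} residue changes in {len(mutable)} mutable positions")
    prot = list(protein)
    touched: set[int] = set()

    order = list(rng.permutation(np.array(sorted(mutable))))
    applied = 0
    realized_n = 0
    for pos in order:
        if applied >= n_aa:
            break
        pos = int(pos)
        cur = codons[pos]
        options = []
        for bp in range(3):
            for b in "ACGT":
                if b == cur[bp]:
                    continue
                alt = cur[:bp] + b + cur[bp + 1:]
                if alt in STOP_CODONS:
                    continue
                aa = CODON_TO_AA[alt]
                if aa != CODON_TO_AA[cur] and aa in _SAFE_MUT:
                    options.append(alt)
        if not options:
            continue
        alt = str(options[int(rng.integers(len(options)))])
        codons[pos] = alt
        prot[pos] = CODON_TO_AA[alt]
        touched.add(pos)
        applied += 1
        realized_n += 1
    if applied < n_aa:
        raise RuntimeError("not enough mutable codons with safe nonsynonymous neighbors")

    syn_candidates = [
        i for i in range(len(codons))
        if i not in touched
        and any(
            codons[i][:bp] + b + codons[i][bp + 1:] not in STOP_CODONS
            and CODON_TO_AA.get(codons[i][:bp] + b + codons[i][bp + 1:]) == CODON_TO_AA[codons[i]]
            for bp in range(3)
            for b in "ACGT"
            if b != codons[i][bp]
        )
    ]
    if n_syn > len(syn_candidates):
        raise ValueError("not enough codons for requested synonymous changes")
    chosen = rng.choice(np.array(syn_candidates), size=n_syn, replace=False) if n_syn else []
    realized_s = 0
    for pos in sorted(int(p) for p in np.atleast_1d(chosen)):
        cur = codons[pos]
        opts = [
            cur[:bp] + b + cur[bp + 1:]
            for bp in range(3)
            for b in "ACGT"
            if b != cur[bp]
            and cur[:bp] + b + cur[bp + 1:] not in STOP_CODONS
            and CODON_TO_AA[cur[:bp] + b + cur[bp + 1:]] == CODON_TO_AA[cur]
        ]
        codons[pos] = str(opts[int(rng.integers(len(opts)))])
        realized_s += 1
    return "".join(prot), "".join(codons), {"synonymous": realized_s, "nonsynonymous": realized_n}


def _counts_for_targets(cds: str, target_ka: float, target_ks: float) -> tuple[int, int]:
    codons = split_codons(cds)
    S = sum(codon_sites(c)[0] for c in codons)
    N = sum(codon_sites(c)[1] for c in codons)
    ps_t = 0.75 * (1.0 - math.exp(-4.0 * target_ks / 3.0))
    pn_t = 0.75 * (1.0 - math.exp(-4.0 * target_ka / 3.0))
    return int(round(pn_t * N)), int(round(ps_t * S))  # (n_aa, n_syn)


# ------------------------------------------------------------ truth

@dataclass
class TruthTables:
    fla_labels: dict[str, bool] = field(default_factory=dict)  # gene -> is FLA
    fla_regions: dict[str, list[Region]] = field(default_factory=dict)
    tandem_clusters: list[dict] = field(default_factory=list)   # planted positives
    tandem_negatives: list[dict] = field(default_factory=list)
    blocks: list[dict] = field(default_factory=list)            # inter + intra
    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)
    nonsyntenic_pairs: list[tuple[str, str]] = field(default_factory=list)
    segmental_pairs: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    pair_substitutions: dict[tuple[str, str], dict[str, int]] = field(default_factory=dict)
    expression_folds: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass
class SyntheticGenome:
    meta: SpeciesMeta
    gene_models: list[GeneModel]
    proteins: list[ProteinRecord]
    cds: dict[str, str]
    domain_hits: list[DomainHit]

    def protein_dict(self) -> dict[str, str]:
        return {p.protein_id: p.sequence for p in self.proteins}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sid = self.meta.species_id
        fio.write_fasta(self.proteins, outdir / f"{sid}.proteins.faa")
        cds_records = [
            ProteinRecord(p.protein_id, self.cds[p.protein_id], p.gene_id)
            for p in self.proteins
        ]
        fio.write_fasta(cds_records, outdir / f"{sid}.cds.fna")
        fio.write_gff3(self.gene_models, outdir / f"{sid}.gff3")
        fio.write_domtblout(self.domain_hits, outdir / f"{sid}.domtblout")


# ----------------------------------------------------- genome assembly

class _Slots:
    """First-fit allocator of consecutive gene slots per chromosome."""

    def __init__(self, chroms: list[str], per_chrom: int) -> None:
        self.slots: dict[str, list] = {c: [None] * per_chrom for c in chroms}

    def take_range(self, chrom: str, k: int) -> int:
        free_run = 0
        slots = self.slots[chrom]
        for i, s in enumerate(slots):
            free_run = free_run + 1 if s is None else 0
            if free_run == k:
                start = i - k + 1
                for j in range(start, i + 1):
                    slots[j] = "reserved"
                return start
        raise ValueError(f"no room for {k} consecutive genes on {chrom}")

    def place(self, chrom: str, start: int, items: list) -> None:
        for j, item in enumerate(items):
            self.slots[chrom][start + j] = item


@dataclass
class _Planted:
    """One gene to be materialized: either background or an FLA member."""
    gene_id: str
    protein: str | None = None      # None -> background gene
    cds: str | None = None
    regions: list[Region] = field(default_factory=list)
    is_fla: bool = False
    tandem_gap_after: int | None = None  # planted gap to the next gene


def _fla_member_flags(rng: np.random.Generator, cfg: SimulationConfig) -> tuple[bool, bool]:
    return (
        bool(rng.random() < cfg.sp_rate),
        bool(rng.random() < cfg.gpi_rate),
    )


def generate_genome_pair(
    config: SimulationConfig,
) -> tuple[SyntheticGenome, SyntheticGenome, TruthTables]:
    """Build the paired synthetic genomes and their truth tables."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    truth = TruthTables()
    chroms = cfg.chromosomes()
    slots = {"A": _Slots(chroms, cfg.genes_per_chromosome),
             "B": _Slots(chroms, cfg.genes_per_chromosome)}
    metas = {"A": cfg.species_a, "B": cfg.species_b}
    counters = {"A": 0, "B": 0}

    def new_gene_id(genome: str) -> str:
        counters[genome] += 1
        return f"{metas[genome].species_id}_g{counters[genome]:03d}"

    def fla_planted(genome: str, template: FlaTemplate, cds: str) -> _Planted:
        gid = new_gene_id(genome)
        truth.fla_labels[gid] = True
        truth.fla_regions[gid] = list(template.regions)
        return _Planted(gid, template.sequence, cds, list(template.regions), True)

    def new_family(rng: np.random.Generator) -> tuple[FlaTemplate, str]:
        with_sp, with_gpi = _fla_member_flags(rng, cfg)
        t = _make_fla(rng, with_sp, 1, int(rng.integers(1, 3)), with_gpi)
        cds = backtranslate_protein(t.sequence, rng)
        return t, cds

    # ---- inter-genome collinear blocks (ortholog anchors)
    ka, ks = cfg.divergence["ortholog"]
    for spec in cfg.block_specs:
        members_a: list[_Planted] = []
        members_b: list[_Planted] = []
        anchor_pairs: list[tuple[str, str]] = []
        for _ in range(spec.n_anchors):
            t, cds = new_family(rng)
            pa = fla_planted("A", t, cds)
            n_aa, n_syn = _counts_for_targets(cds, ka, ks)
            prot_b, cds_b, realized = _diverge_member(
                t.sequence, cds, t.mutable, n_aa, n_syn, rng
            )
            tb = FlaTemplate(prot_b, t.regions, t.mutable)
            pb = fla_planted("B", tb, cds_b)
            members_a.append(pa)
            members_b.append(pb)
            anchor_pairs.append((pa.gene_id, pb.gene_id))
            truth.pair_substitutions[(pa.gene_id, pb.gene_id)] = realized
        sa = slots["A"].take_range(spec.chrom_a, spec.n_anchors)
        sb = slots["B"].take_range(spec.chrom_b, spec.n_anchors)
        slots["A"].place(spec.chrom_a, sa, members_a)
        slots["B"].place(spec.chrom_b, sb, members_b)
        truth.blocks.append(
            {"kind": "inter", "genome": "A+B", "chrom_a": spec.chrom_a,
             "chrom_b": spec.chrom_b, "anchors": anchor_pairs}
        )
        truth.ortholog_pairs.extend(anchor_pairs)

    # ---- intra-genome blocks (segmental duplicates)
    ka, ks = cfg.divergence["segmental"]
    for spec in cfg.intra_block_specs:
        first: list[_Planted] = []
        second: list[_Planted] = []
        anchor_pairs = []
        for _ in range(spec.n_anchors):
            t, cds = new_family(rng)
            p1 = fla_planted(spec.genome, t, cds)
            n_aa, n_syn = _counts_for_targets(cds, ka, ks)
            prot2, cds2, realized = _diverge_member(t.sequence, cds, t.mutable, n_aa, n_syn, rng)
            p2 = fla_planted(spec.genome, FlaTemplate(prot2, t.regions, t.mutable), cds2)
            first.append(p1)
            second.append(p2)
            pair = (p1.gene_id, p2.gene_id)
            anchor_pairs.append(pair)
            truth.pair_substitutions[pair] = realized
        sx = slots[spec.genome].take_range(spec.chrom_x, spec.n_anchors)
        sy = slots[spec.genome].take_range(spec.chrom_y, spec.n_anchors)
        slots[spec.genome].place(spec.chrom_x, sx, first)
        slots[spec.genome].place(spec.chrom_y, sy, second)
        truth.blocks.append(
            {"kind": "intra", "genome": spec.genome, "chrom_a": spec.chrom_x,
             "chrom_b": spec.chrom_y, "anchors": anchor_pairs}
        )
        truth.segmental_pairs.setdefault(spec.genome, []).extend(anchor_pairs)

    # ---- tandem arrays (positives and engineered negatives)
    for spec in cfg.tandem_specs:
        t, cds = new_family(rng)
        n_aa = int(round((1.0 - spec.identity_pct / 100.0) * len(t.sequence)))
        members = [fla_planted(spec.genome, t, cds)]
        for _ in range(spec.array_size - 1):
            prot2, cds2, realized = _diverge_member(t.sequence, cds, t.mutable, n_aa, 0, rng)
            members.append(fla_planted(spec.genome, FlaTemplate(prot2, t.regions, t.mutable), cds2))
        for m in members[:-1]:
            m.tandem_gap_after = spec.gap_bp
        start = slots[spec.genome].take_range(spec.chromosome, spec.array_size)
        slots[spec.genome].place(spec.chromosome, start, members)
        record = {
            "genome": spec.genome,
            "chromosome": spec.chromosome,
            "members": [m.gene_id for m in members],
            "gap_bp": spec.gap_bp,
            "identity_pct": spec.identity_pct,
        }
        if spec.positive:
            truth.tandem_clusters.append(record)
        else:
            record["violates"] = "spacing" if spec.gap_bp > 100_000 else "identity"
            truth.tandem_negatives.append(record)

    # ---- non-syntenic ortholog candidates (reciprocal best, no block)
    # their chromosome pair must differ from every inter-genome block's
    # pair so the single anchor cannot be absorbed into a planted chain
    block_pairs = {(b.chrom_a, b.chrom_b) for b in cfg.block_specs}
    free_pairs = [
        (ca, cb) for ca in chroms for cb in chroms
        if ca != cb and (ca, cb) not in block_pairs
    ]
    for k in range(cfg.n_nonsyntenic_orthologs):
        t, cds = new_family(rng)
        pa = fla_planted("A", t, cds)
        n_aa, n_syn = _counts_for_targets(cds, *cfg.divergence["ortholog"])
        prot_b, cds_b, realized = _diverge_member(t.sequence, cds, t.mutable, n_aa, n_syn, rng)
        pb = fla_planted("B", FlaTemplate(prot_b, t.regions, t.mutable), cds_b)
        ca, cb = free_pairs[k % len(free_pairs)]
        slots["A"].place(ca, slots["A"].take_range(ca, 1), [pa])
        slots["B"].place(cb, slots["B"].take_range(cb, 1), [pb])
        truth.nonsyntenic_pairs.append((pa.gene_id, pb.gene_id))
        truth.pair_substitutions[(pa.gene_id, pb.gene_id)] = realized

    # ---- isolated FLA genes without any homolog
    for genome in ("A", "B"):
        for _ in range(cfg.n_isolated_fla):
            t, cds = new_family(rng)
            p = fla_planted(genome, t, cds)
            c = chroms[int(rng.integers(len(chroms)))]
            slots[genome].place(c, slots[genome].take_range(c, 1), [p])

    # ---- background genes fill remaining slots
    for genome in ("A", "B"):
        for chrom in chroms:
            col = slots[genome].slots[chrom]
            for i, s in enumerate(col):
                if s is None:
                    gid = new_gene_id(genome)
                    prot = _background(rng, int(rng.integers(150, 400)), start_met=True)
                    col[i] = _Planted(gid, prot, backtranslate_protein(prot, rng))
                    truth.fla_labels[gid] = False

    # ---- materialize coordinates, exon structures, records
    genomes: dict[str, SyntheticGenome] = {}
    for genome in ("A", "B"):
        models: list[GeneModel] = []
        proteins: list[ProteinRecord] = []
        cds_map: dict[str, str] = {}
        hits: list[DomainHit] = []
        for chrom in chroms:
            pos = int(rng.integers(10_000, 30_000))
            for planted in slots[genome].slots[chrom]:
                cds_len = len(planted.cds)
                r = rng.random()
                n_introns = 0 if r < 0.51 else 1 if r < 0.86 else 2 if r < 0.98 else 3
                cuts = sorted(rng.choice(np.arange(30, cds_len - 30), size=n_introns,
                                         replace=False)) if n_introns else []
                exon_lens = np.diff([0, *[int(c) for c in cuts], cds_len])
                exons = []
                start = pos
                cursor = pos
                for k, el in enumerate(exon_lens):
                    exons.append((cursor, cursor + int(el) - 1))
                    cursor += int(el)
                    if k < n_introns:
                        cursor += int(rng.integers(80, 500))
                end = exons[-1][1]
                strand = "+" if rng.random() < 0.5 else "-"
                models.append(GeneModel(planted.gene_id, chrom, start, end, strand, exons))
                proteins.append(ProteinRecord(planted.gene_id, planted.protein, planted.gene_id))
                cds_map[planted.gene_id] = planted.cds
                for reg in planted.regions:
                    if reg.kind == "fas_domain":
                        hits.append(
                            DomainHit(planted.gene_id, "PF02469", reg.start, reg.end, 1e-20)
                        )
                gap = (
                    planted.tandem_gap_after
                    if planted.tandem_gap_after is not None
                    else int(rng.integers(*cfg.intergenic_bp))
                )
                pos = end + gap
        genomes[genome] = SyntheticGenome(metas[genome], models, proteins, cds_map, hits)

    # ---- expression truth
    truth.expression_folds = {
        g: dict(folds) for g, folds in cfg.ct_design.fold_changes.items()
    }
    return genomes["A"], genomes["B"], truth


# --------------------------------------------------------------- qPCR

def generate_ct_table(
    design: CtDesign, seed: int | np.random.Generator
) -> list[CtRow]:
    """Replicate Ct rows with planted fold changes.

    ct_target = ct_reference + baseline - log2(fold) + N(0, noise_sd)
    per replicate; the first tissue of the design is the calibrator
    (fold 1 by convention).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows: list[CtRow] = []
    for gene in sorted(design.fold_changes):
        folds = design.fold_changes[gene]
        for tissue in design.tissues:
            fold = folds.get(tissue, 1.0)
            for rep in range(1, design.n_replicates + 1):
                noise = rng.normal(0.0, design.ct_noise_sd) if design.ct_noise_sd > 0 else 0.0
                ct_t = design.ct_reference + design.baseline_dct - math.log2(fold) + noise
                rows.append(CtRow(gene, tissue, rep, ct_t, design.ct_reference))
    return rows


# ------------------------------------------------- classifier test set

def generate_protein_set(
    seed: int,
    n_total: int = 200,
    n_fla: int = 60,
    sp_rate: float = 0.85,
    gpi_rate: float = 0.72,
) -> tuple[list[ProteinRecord], list[DomainHit], dict[str, bool]]:
    """A labelled protein set for classifier validation.

    n_fla planted positives; negatives split between FAS-domain decoys
    lacking glycomodules, glycomodule-bearing proteins lacking a FAS
    domain (no hit emitted), and plain background proteins.
    """
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    hits: list[DomainHit] = []
    labels: dict[str, bool] = {}
    for i in range(n_total):
        pid = f"prot{i + 1:04d}"
        if i < n_fla:
            t = _make_fla(
                rng,
                with_sp=bool(rng.random() < sp_rate),
                n_domains=int(rng.integers(1, 3)),
                n_glyco=int(rng.integers(1, 4)),
                with_gpi=bool(rng.random() < gpi_rate),
            )
            seq = t.sequence
            for reg in t.regions:
                if reg.kind == "fas_domain":
                    hits.append(DomainHit(pid, "PF02469", reg.start, reg.end, 1e-20))
            labels[pid] = True
        else:
            kind = (i - n_fla) % 3
            if kind == 0:  # FAS domain but no glycomodule
                t = _make_fla(rng, with_sp=True, n_domains=1, n_glyco=0,
                              with_gpi=bool(rng.random() < 0.5))
                seq = t.sequence
                for reg in t.regions:
                    if reg.kind == "fas_domain":
                        hits.append(DomainHit(pid, "PF02469", reg.start, reg.end, 1e-20))
            elif kind == 1:  # glycomodules but no FAS hit
                t = _make_fla(rng, with_sp=bool(rng.random() < 0.5), n_domains=1,
                              n_glyco=int(rng.integers(1, 3)), with_gpi=False)
                seq = t.sequence  # FAS-like segment present but no hit emitted
            else:
                seq = _background(rng, int(rng.integers(150, 400)), start_met=True)
            labels[pid] = False
        records.append(ProteinRecord(pid, seq))
    return records, hits, labels


# ------------------------------------------------ random additive trees

def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """A random binary tree and its exact additive distance matrix.

    Returns (labels, distance matrix, tree) where the tree is a
    phylo.TreeNode with strictly positive branch lengths.
    """
    from .phylo import TreeNode, leaf_path_lengths

    labels = [f"t{i + 1}" for i in range(n_taxa)]
    nodes = [TreeNode(name=l) for l in labels]
    pool = list(nodes)
    while len(pool) > 3:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        a, b = pool[i], pool[j]
        la, lb = rng.uniform(0.05, 0.6, size=2)
        parent = TreeNode(children=[(a, float(la)), (b, float(lb))])
        pool = [p for p in pool if p not in (a, b)] + [parent]
    root = TreeNode(
        children=[(p, float(rng.uniform(0.05, 0.6))) for p in pool]
    )
    dists = leaf_path_lengths(root)
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                D[i, j] = dists[(labels[i], labels[j])]
    return labels, D, root


def simulate_clade_alignment(
    seed: int,
    n_per_clade: int = 5,
    length: int = 200,
    between_divergence: float = 0.4,
    within_mutations: int = 2,
) -> tuple[list[str], list[str], frozenset]:
    """Two well-separated clades for bootstrap validation.

    Returns (ids, rows, separating bipartition as a frozenset of the
    first clade's ids).
    """
    rng = np.random.default_rng(seed)
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    base1 = [str(rng.choice(alphabet)) for _ in range(length)]
    base2 = list(base1)
    n_mut = int(round(between_divergence * length))
    for pos in rng.choice(length, size=n_mut, replace=False):
        choices = [a for a in alphabet if a != base2[pos]]
        base2[int(pos)] = str(choices[int(rng.integers(len(choices)))])
    ids: list[str] = []
    rows: list[str] = []
    for clade, base in (("x", base1), ("y", base2)):
        for i in range(n_per_clade):
            leaf = list(base)
            for pos in rng.choice(length, size=within_mutations, replace=False):
                choices = [a for a in alphabet if a != leaf[pos]]
                leaf[int(pos)] = str(choices[int(rng.integers(len(choices)))])
            ids.append(f"{clade}{i + 1}")
            rows.append("".join(leaf))
    clade1 = frozenset(i for i in ids if i.startswith("x"))
    return ids, rows, clade1


# ----------------------------------------------------- truth-table I/O

def write_truth(truth: TruthTables, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "fla_labels.tsv", "w") as fh:
        fh.write("gene_id\tis_fla\tregions\n")
        for gid in sorted(truth.fla_labels):
            regions = ";".join(
                f"{r.start}-{r.end}:{r.kind}" for r in truth.fla_regions.get(gid, [])
            )
            fh.write(f"{gid}\t{int(truth.fla_labels[gid])}\t{regions}\n")
    with open(outdir / "tandem.tsv", "w") as fh:
        fh.write("genome\tchromosome\tpositive\tviolates\tgap_bp\tidentity_pct\tmembers\n")
        for rec in truth.tandem_clusters + truth.tandem_negatives:
            fh.write(
                f"{rec['genome']}\t{rec['chromosome']}\t{int('violates' not in rec)}\t"
                f"{rec.get('violates', '.')}\t{rec['gap_bp']}\t{rec['identity_pct']}\t"
                f"{';'.join(rec['members'])}\n"
            )
    with open(outdir / "blocks.tsv", "w") as fh:
        fh.write("kind\tgenome\tchrom_a\tchrom_b\tanchors\n")
        for b in truth.blocks:
            anchors = ";".join(f"{x},{y}" for x, y in b["anchors"])
            fh.write(f"{b['kind']}\t{b['genome']}\t{b['chrom_a']}\t{b['chrom_b']}\t{anchors}\n")
    with open(outdir / "pairs.tsv", "w") as fh:
        fh.write("gene_a\tgene_b\trelation\tn_synonymous\tn_nonsynonymous\n")
        rel = {}
        for p in truth.ortholog_pairs:
            rel[p] = "ortholog"
        for p in truth.nonsyntenic_pairs:
            rel[p] = "nonsyntenic_ortholog"
        for pairs in truth.segmental_pairs.values():
            for p in pairs:
                rel[p] = "segmental"
        for pair, counts in sorted(truth.pair_substitutions.items()):
            fh.write(
                f"{pair[0]}\t{pair[1]}\t{rel.get(pair, 'other')}\t"
                f"{counts['synonymous']}\t{counts['nonsynonymous']}\n"
            )
    with open(outdir / "expression_folds.tsv", "w") as fh:
        fh.write("gene_id\ttissue_id\tfold\n")
        for g in sorted(truth.expression_folds):
            for t in sorted(truth.expression_folds[g]):
                fh.write(f"{g}\t{t}\t{truth.expression_folds[g][t]}\n")
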