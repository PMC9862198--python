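"""Domain types shared across the pipeline.

All genomic and protein coordinates are 1-based and inclusive at both
ends, matching GFF3 and HMMER conventions; nothing in the package
silently converts to half-open intervals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")

_CHROM_RE = re.compile(r"^(?:chr|Chr|CHR)?(\d+)$")


def chrom_sort_key(name: str) -> tuple[int, int, str]:
    """Natural ordering for chromosome names.

    Numbered chromosomes ("chr2" < "chr10") come first; unplaced
    contigs or scaffolds sort after all chromosomes, lexicographically.
    """
    m = _CHROM_RE.match(name)
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, name)


@dataclass(frozen=True)
class Region:
    """A feature interval on a protein, 1-based inclusive."""

    kind: str  # signal_peptide | fas_domain | gpi_omega_segment | glycomodule
    start: int
    end: int

    KINDS = ("signal_peptide", "fas_domain", "gpi_omega_segment", "glycomodule")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown region kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad region bounds {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Region") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class GeneModel:
    """Genomic location and exon structure of one gene (GFF3 semantics)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"{self.gene_id}: invalid span {self.start}-{self.end}")
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon {s}-{e} reversed")
            if s < self.start or e > self.end:
                raise ValueError(
                    f"{self.gene_id}: exon {s}-{e} outside gene span "
                    f"{self.start}-{self.end}"
                )
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = e

    @property
    def n_introns(self) -> int:
        return max(len(self.exons) - 1, 0)


@dataclass
class ProteinRecord:
    protein_id: str
    sequence: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValueError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - VALID_AA
        if bad:
            raise ValueError(f"{self.protein_id}: invalid residues {sorted(bad)}")


@dataclass
class DomainHit:
    """One domain envelope from an HMMER domtblout row."""

    protein_id: str
    domain_accession: str
    env_start: int
    env_end: int
    independent_evalue: float

    def __post_init__(self) -> None:
        if not (1 <= self.env_start <= self.env_end):
            raise ValueError(
                f"{self.protein_id}: bad envelope {self.env_start}-{self.env_end}"
            )


@dataclass
class SpeciesMeta:
    species_id: str
    habit: str  # woody | herbaceous
    genome_gene_total: int
    name_prefix: str

    def __post_init__(self) -> None:
        if self.habit not in ("woody", "herbaceous"):
            raise ValueError(f"habit must be woody/herbaceous, got {self.habit!r}")
        if self.genome_gene_total <= 0:
            raise ValueError("genome_gene_total must be positive")


@dataclass
class CtRow:
    """One qPCR measurement: target and reference Ct for one replicate."""

    gene_id: str
    tissue_id: str
    replicate_index: int
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_reference):
            if not (v == v and v > 0 and v != float("inf")):
                raise ValueError(
                    f"{self.gene_id}/{self.tissue_id}: Ct must be finite and > 0"
                )
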