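"""Nei–Gojobori (1986) Ka/Ks estimation.

Counts synonymous (S) and nonsynonymous (N) sites per codon under the
standard genetic code, averages synonymous/nonsynonymous difference
counts over all mutational pathways between codon pairs (excluding
pathways through stop codons), and applies the Jukes–Cantor
correction d = -(3/4) ln(1 - 4p/3) to the proportions ps = Sd/S and
pn = Nd/N. Pairs with Ka/Ks < 1 are called purifying, > 1 positive,
= 1 (to 1e-9) neutral; when Ks = 0 the ratio is undefined — the
situation of recently duplicated, fully identical paralogs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
CODON_TO_AA = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)
SENSE_CODONS = sorted(CODON_TO_AA)


@dataclass
class KaKsResult:
    id_a: str
    id_b: str
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ks: float | None
    Ka: float | None
    ratio: float | None
    selection_class: str  # purifying | neutral | positive | undefined
    saturated: bool = False
    stop_paths_used: bool = False
    method: str = "NG86"


def _check_sense(codon: str) -> str:
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} not allowed")
    if codon not in CODON_TO_AA:
        raise ValueError(f"not a valid codon: {codon!r}")
    return codon


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts (s, n) with s + n = 3.

    At each codon position the synonymous fraction is the share of the
    three single-base changes that preserve the amino acid; changes to
    stop codons count as nonsynonymous.
    """
    codon = _check_sense(codon)
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in STOP_CODONS and CODON_TO_AA[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def codon_differences(codon_a: str, codon_b: str) -> tuple[float, float, bool]:
    """Pathway-averaged synonymous/nonsynonymous difference counts.

    For k differing positions, all k! orderings of single-base steps
    are enumerated; each step is scored synonymous when the amino acid
    is unchanged. Pathways passing through a stop codon are excluded;
    if every pathway is blocked, all pathways are used with equal
    weight and the flag in the third slot is set.
    """
    a, b = _check_sense(codon_a), _check_sense(codon_b)
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    k = len(diff_pos)
    if k == 0:
        return 0.0, 0.0, False

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        cur = a
        sd = nd = 0.0
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                if not allow_stops:
                    return None
                # a stop intermediate scores as nonsynonymous
                nd += 1.0
                cur = nxt
                continue
            cur_aa = CODON_TO_AA.get(cur)
            if cur_aa is not None and CODON_TO_AA[nxt] == cur_aa:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    paths = [p for p in (walk(o, False) for o in permutations(diff_pos)) if p is not None]
    used_stops = False
    if not paths:
        used_stops = True
        paths = [walk(o, True) for o in permutations(diff_pos)]
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd, used_stops


def _jc_correct(p: float) -> float | None:
    """Jukes–Cantor distance; None when saturated (p >= 0.75)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class CodonAlignment:
    id_a: str
    id_b: str
    codons_a: list[str]
    codons_b: list[str]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon sequences differ in length")
        for c in self.codons_a + self.codons_b:
            _check_sense(c)


def split_codons(cds: str, label: str = "cds") -> list[str]:
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3:
        raise ValueError(f"{label}: length {len(cds)} not divisible by 3")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    # a trailing stop codon is tolerated and dropped
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    for i, c in enumerate(codons):
        if c in STOP_CODONS:
            raise ValueError(f"{label}: internal stop codon at codon {i + 1}")
    return codons


def backtranslate(
    aligned_a: str, aligned_b: str, cds_a: str, cds_b: str,
    id_a: str = "a", id_b: str = "b",
) -> CodonAlignment:
    """Thread CDS codons under an aligned protein pair.

    Alignment columns where either protein row has a gap are removed
    (complete deletion). CDS length must be three times the ungapped
    protein length (a trailing stop codon is tolerated).
    """
    codons_a = split_codons(cds_a, id_a)
    codons_b = split_codons(cds_b, id_b)
    for label, row, codons in ((id_a, aligned_a, codons_a), (id_b, aligned_b, codons_b)):
        n_res = sum(1 for ch in row if ch != "-")
        if n_res != len(codons):
            raise ValueError(
                f"{label}: {len(codons)} codons do not match {n_res} aligned residues"
            )
    out_a: list[str] = []
    out_b: list[str] = []
    ia = ib = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca != "-" and cb != "-":
            out_a.append(codons_a[ia])
            out_b.append(codons_b[ib])
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    return CodonAlignment(id_a, id_b, out_a, out_b)


def estimate_kaks(alignment: CodonAlignment) -> KaKsResult:
    """NG86 Ka/Ks with Jukes–Cantor correction on a codon alignment."""
    if not alignment.codons_a:
        raise ValueError("empty codon alignment")
    s_a = n_a = s_b = n_b = 0.0
    sd = nd = 0.0
    stop_flag = False
    for ca, cb in zip(alignment.codons_a, alignment.codons_b):
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        s_a += sa
        n_a += na
        s_b += sb
        n_b += nb
        d_s, d_n, flag = codon_differences(ca, cb)
        sd += d_s
        nd += d_n
        stop_flag = stop_flag or flag
    S = (s_a + s_b) / 2.0
    N = (n_a + n_b) / 2.0
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ks = _jc_correct(ps)
    ka = _jc_correct(pn)
    saturated = ks is None or ka is None
    if ks is not None and ks > 0 and ka is not None:
        ratio = ka / ks
        if abs(ratio - 1.0) < 1e-9:
            sel = "neutral"
        elif ratio < 1.0:
            sel = "purifying"
        else:
            sel = "positive"
    else:
        ratio = None
        sel = "undefined"
    return KaKsResult(
        alignment.id_a, alignment.id_b, S, N, sd, nd, ps, pn, ks, ka,
        ratio, sel, saturated=saturated, stop_paths_used=stop_flag,
    )


def kaks_for_pairs(
    cds_by_id: dict[str, str],
    protein_by_id: dict[str, str],
    pairs: list[tuple[str, str]],
    align_fn=None,
) -> list[KaKsResult]:
    """Estimate Ka/Ks for a list of gene pairs.

    Proteins are globally aligned (or, when an `align_fn` is given,
    with that callable returning two gapped rows) and the alignment is
    backtranslated onto the CDS.
    """
    from .align import _aligner

    results = []
    for a, b in pairs:
        pa, pb = protein_by_id[a], protein_by_id[b]
        if align_fn is not None:
            row_a, row_b = align_fn(pa, pb)
        elif pa == pb:
            row_a, row_b = pa, pb
        else:
            aln = _aligner(10.0, 0.5).align(pa, pb)[0]
            row_a, row_b = str(aln[0]), str(aln[1])
        ca = backtranslate(row_a, row_b, cds_by_id[a], cds_by_id[b], a, b)
        results.append(estimate_kaks(ca))
    return results


def write_kaks(results: list[KaKsResult], path) -> None:
    def fmt(v):
        return "NA" if v is None else f"{v:.6f}"

    with open(path, "w") as fh:
        fh.write("pair_a\tpair_b\tS\tN\tSd\tNd\tKa\tKs\tratio\tselection\tmethod\n")
        for r in results:
            fh.write(
                f"{r.id_a}\t{r.id_b}\t{r.S:.2f}\t{r.N:.2f}\t{r.Sd:.4f}\t{r.Nd:.4f}\t"
                f"{fmt(r.Ka)}\t{fmt(r.Ks)}\t{fmt(r.ratio)}\t{r.selection_class}\t{r.method}\n"
            )
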