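"""Gene-structure summaries and qPCR relative expression.

Intron counts come straight from exon structure (introns = exons - 1)
and are binned into the classes 0 / 1 / 2 / >2 commonly reported for
gene families. Relative expression uses the 2^-ddCt method on
replicate Ct tables (target gene normalized against a reference gene
within each replicate, then against a calibrator tissue), with
replicate SD on the fold scale and pooled-variance two-sided Student
t-tests between tissues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .models import CtRow, GeneModel

INTRON_CLASSES = ("0", "1", "2", ">2")


@dataclass
class IntronDistribution:
    counts: dict[str, int]
    total: int
    percentages: dict[str, float]


def intron_stats(gene_models: list[GeneModel]) -> IntronDistribution:
    """Distribution of intron counts over gene models.

    Percentages are 100 * count / total, rounded to 2 decimals.
    """
    if not gene_models:
        raise ValueError("no gene models")
    counts = {c: 0 for c in INTRON_CLASSES}
    for g in gene_models:
        n = g.n_introns
        key = str(n) if n <= 2 else ">2"
        counts[key] += 1
    total = len(gene_models)
    pct = {c: round(100.0 * counts[c] / total, 2) for c in INTRON_CLASSES}
    return IntronDistribution(counts, total, pct)


# ---------------------------------------------------------- 2^-ddCt

@dataclass
class TissueExpression:
    gene_id: str
    tissue_id: str
    fold: float
    sd: float
    n_replicates: int
    flagged: bool = False  # fewer than 2 replicates


@dataclass
class ExpressionResult:
    per_tissue: list[TissueExpression]
    comparisons: list[dict] = field(default_factory=list)
    calibrator: str = ""


def relative_expression(
    ct_rows: list[CtRow], calibrator_tissue: str
) -> ExpressionResult:
    """2^-ddCt relative expression per (gene, tissue) against a calibrator.

    Per replicate dCt = ct_target - ct_reference; ddCt is the tissue
    mean dCt minus the calibrator mean dCt; fold = 2^-ddCt. The SD is
    taken over per-replicate folds 2^-(dCt_i - mean dCt(calibrator)).
    Genes missing the calibrator tissue are an error; tissues with a
    single replicate are computed but flagged.
    """
    dct: dict[tuple[str, str], list[float]] = {}
    for r in ct_rows:
        dct.setdefault((r.gene_id, r.tissue_id), []).append(r.ct_target - r.ct_reference)
    genes = sorted({g for g, _ in dct})
    tissues = sorted({t for _, t in dct})
    if calibrator_tissue not in tissues:
        raise ValueError(f"calibrator tissue {calibrator_tissue!r} not in table")
    out: list[TissueExpression] = []
    for g in genes:
        if (g, calibrator_tissue) not in dct:
            raise ValueError(f"gene {g} has no calibrator tissue {calibrator_tissue!r}")
        cal_mean = float(np.mean(dct[(g, calibrator_tissue)]))
        for t in tissues:
            if (g, t) not in dct:
                continue
            reps = dct[(g, t)]
            folds = [2.0 ** (-(d - cal_mean)) for d in reps]
            out.append(
                TissueExpression(
                    gene_id=g,
                    tissue_id=t,
                    fold=2.0 ** (-(float(np.mean(reps)) - cal_mean)),
                    sd=float(np.std(folds, ddof=1)) if len(folds) > 1 else 0.0,
                    n_replicates=len(reps),
                    flagged=len(reps) < 2,
                )
            )
    return ExpressionResult(out, [], calibrator_tissue)


def two_sided_ttest(group_a, group_b) -> tuple[float, float]:
    """Pooled-variance two-sided Student's t-test.

    Degenerate zero-variance input: equal means give (0, 1); unequal
    means give an infinite statistic and p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    diff = a.mean() - b.mean()
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), 0.0
    t = diff / math.sqrt(pooled * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), na + nb - 2)
    return float(t), float(p)


def compare_tissues(
    ct_rows: list[CtRow],
    calibrator_tissue: str,
    alpha: float = 0.01,
) -> ExpressionResult:
    """Relative expression plus per-gene t-tests of each tissue vs calibrator.

    Significance at p < alpha is annotated with "**" (the convention
    used for qPCR bar plots).
    """
    res = relative_expression(ct_rows, calibrator_tissue)
    dct: dict[tuple[str, str], list[float]] = {}
    for r in ct_rows:
        dct.setdefault((r.gene_id, r.tissue_id), []).append(r.ct_target - r.ct_reference)
    for te in res.per_tissue:
        if te.tissue_id == calibrator_tissue:
            continue
        a = dct[(te.gene_id, te.tissue_id)]
        b = dct[(te.gene_id, calibrator_tissue)]
        if len(a) < 2 or len(b) < 2:
            continue
        t, p = two_sided_ttest(a, b)
        res.comparisons.append(
            {
                "gene_id": te.gene_id,
                "tissue_id": te.tissue_id,
                "vs": calibrator_tissue,
                "t": t,
                "p": p,
                "significant": "**" if p < alpha else "",
            }
        )
    return res


def write_expression(result: ExpressionResult, path) -> None:
    sig = {
        (c["gene_id"], c["tissue_id"]): c for c in result.comparisons
    }
    with open(path, "w") as fh:
        fh.write("gene_id\ttissue_id\tfold\tsd\tn_replicates\tt\tp\tsignificance\n")
        for te in result.per_tissue:
            c = sig.get((te.gene_id, te.tissue_id))
            t = f"{c['t']:.4f}" if c else "NA"
            p = f"{c['p']:.6g}" if c else "NA"
            s = c["significant"] if c else ""
            fh.write(
                f"{te.gene_id}\t{te.tissue_id}\t{te.fold:.4f}\t{te.sd:.4f}\t"
                f"{te.n_replicates}\t{t}\t{p}\t{s}\n"
            )


def write_intron_stats(dist: IntronDistribution, path) -> None:
    with open(path, "w") as fh:
        fh.write("intron_class\tcount\tpercentage\n")
        for c in INTRON_CLASSES:
            fh.write(f"{c}\t{dist.counts[c]}\t{dist.percentages[c]:.2f}\n")
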