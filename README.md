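# flafam

Comparative genomics of **fasciclin-like arabinogalactan protein (FLA)
gene families** — the AGP subclass that carries one or more fasciclin
(FAS, Pfam PF02469) cell-adhesion domains alongside arabinogalactan
O-glycosylation modules. FLAs are of particular interest in woody
plants, where the family's Group I branch expands and tracks secondary
growth (wood formation). `flafam` implements the complete desk
workflow such a study runs after gene prediction, as a tested,
deterministic Python library and CLI:

- **Classification** (`flafam.classify`): detect the N-terminal signal
  peptide and C-terminal GPI-anchor ω segment with documented
  rule-based heuristics (SignalP-5.0 / big-PI result files accepted as
  overrides), mask them together with the FAS domain envelopes from an
  HMMER `domtblout`, scan the mature sequence for AGP glycomodules
  (≥3 `[ASTVG]P` dipeptides clustered within 10 residues), and call a
  protein FLA when it has ≥1 FAS domain plus ≥1 unmasked glycomodule.
  Isoelectric points (Bjellqvist pKa set, bisection) and average
  molecular weights are computed, and members are named
  `<prefix>FLA1..n` in chromosomal order.
- **Duplication & synteny** (`flafam.duplication`): tandem clusters by
  the two classic criteria (members within 100 kb on one chromosome,
  protein identity > 70% by global Needleman–Wunsch alignment with
  BLOSUM62), anchor discovery by reciprocal top-scoring alignments,
  MCScanX-style collinear-block chaining (≥5 anchors, rank gaps ≤ 25),
  segmental-duplicate labeling and syntenic/non-syntenic ortholog
  calling.
- **Ka/Ks** (`flafam.kaks`): Nei–Gojobori (1986) counting from
  scratch — per-codon synonymous/nonsynonymous site fractions,
  pathway-averaged difference counts excluding stop-codon
  intermediates, Jukes–Cantor correction
  `d = -(3/4) ln(1 - 4p/3)` — with purifying/neutral/positive calls.
- **Phylogenetics** (`flafam.phylo`): Poisson-corrected p-distances
  with pairwise deletion, Saitou–Nei neighbor joining, column
  bootstrap, anchor-based Group I–IV assignment, and woody versus
  herbaceous Group-I expansion statistics (Welch t-test).
- **Structure & expression** (`flafam.structure_expression`):
  intron-count distributions and 2^−ΔΔCt qPCR quantification with
  replicate SDs and two-sided Student t-tests.
- **Synthetic data** (`flafam.synthetic`): a generator that plants all
  of the above — FLA genes built to the detectors' rules, tandem
  arrays and engineered near-miss negatives, collinear blocks,
  codon-level divergence with controlled substitution counts,
  replicate Ct tables with known folds — and emits exact truth tables,
  so every stage is validated end to end.

## Worked example

```bash
flafam simulate --seed 7 --out run/
```

simulates a pair of three-chromosome genomes (72 genes each), runs
classification, duplication/synteny, Ka/Ks, the NJ tree and expression
on them, and prints:

```json
{
  "n_fla_A": 21,
  "n_tandem_clusters_A": 0,
  "n_segmental_pairs_A": 5,
  "n_fla_B": 30,
  "n_tandem_clusters_B": 2,
  "n_segmental_pairs_B": 5,
  "n_ortholog_pairs": 8,
  "n_nonsyntenic_candidates": 1
}
```

Genome A carries 21 planted FLA genes and genome B 30; the two planted
tandem arrays in genome B are found (and the two engineered negatives —
one array spaced beyond 100 kb, one pair below 70% identity — are
rejected); the 8-anchor inter-genome block yields 8 syntenic ortholog
pairs plus 1 reciprocal-best pair outside any block; each genome's
planted 5-anchor intra-genome block yields 5 segmental pairs. The
`run/` directory holds every stage's TSV output, the truth tables, the
Newick tree, and `*.kaks.tsv` files in which all diverged pairs are
called `purifying` (Ka/Ks ≪ 1), e.g.

```
pair_a          pair_b          S       N       Sd      Nd      Ka        Ks        ratio     selection  method
genomeB_g009    genomeB_g010    120.83  488.17  17.0000 14.0000 0.029241  0.155809  0.187675  purifying  NG86
```

Individual stages run standalone on real files, e.g.

```bash
flafam classify --proteins sp.faa --gff sp.gff3 --domains sp.domtblout \
    --prefix Ssu --out annotations.tsv
flafam kaks --cds sp.cds.fna --proteins sp.faa --pairs pairs.tsv --out kaks.tsv
flafam phylo --alignment aln.faa -B 1000 --seed 1 --out tree/
flafam expression --ct ct.tsv --calibrator S1 --out expression.tsv
```

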