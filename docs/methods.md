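# Methods

This note documents the models, rules and numerical choices behind
`flafam`, what the synthetic data does and does not emulate, and the
design decisions taken where the underlying procedures are commonly
left unstated in gene-family surveys.

## FLA classification

A protein is called FLA when it carries **≥1 fasciclin (FAS, PF02469)
domain** and **≥1 AGP glycomodule outside all masked regions**. The
masked regions are the signal peptide, the FAS envelopes (overlapping
hits merged by union), and the GPI ω segment — the parts removed
before glycosylation-site screening, since glycomodules inside them
are not O-glycosylated in the mature, anchored protein. Neither a
signal peptide nor a GPI anchor is required for membership: real
families include members lacking either (typically only ~70–85% of
members carry them), so requiring them would discard true FLAs.

**Signal peptide (heuristic default).** Within residues 1–30, the
first stretch of ≥7 residues from {A,C,F,I,L,M,V,W} allowing at most
one interruption is the hydrophobic core (h-region). The cleavage
position `c` is the first position ≥ core_end + 2, searched up to
position 35, with small residues {A,G,S,C,T} at both `c` and `c−2` —
the classic (−3,−1) rule. The region is (1, c); no core or no
cleavage site means no signal peptide; sequences shorter than 15
return none. Neural predictors (SignalP) are deliberately not
reimplemented; their short-format output overrides the heuristic,
including explicit negatives.

**GPI ω segment (heuristic default).** A hydrophobic run of ≥8
residues from {A,F,I,L,M,V,W} starting within the final 12 residues,
plus an ω candidate from {S,G,A,N,D,C} located 8–12 residues upstream
of the run start (small-residue ω, flexible spacer, hydrophobic
tail). The region spans ω to the C terminus. big-PI output files
override.

**Glycomodules.** An AG dipeptide is `X-P` with X ∈ {A,S,T,V,G};
a glycomodule is a maximal chain of ≥3 dipeptides whose start
positions are ≤10 residues apart. All three thresholds are
configurable; the defaults follow standard AGP glycomodule
conventions since surveys rarely state an explicit rule. Proline is
used directly as the glycosylation residue — no hydroxyproline
inference.

**pI and Mw.** pI is the root of the net-charge function under the
Bjellqvist pKa set (C-term 3.55; D 4.05, E 4.45, C 9.0, Y 10.0;
H 5.98, K 10.0, R 12.0; residue-specific N-terminal values with 7.5
default), found by bisection on [0, 14] to |charge| < 1e−4. The
charge function is strictly decreasing in pH, so bisection is exact
up to tolerance; tests verify agreement with a 0.001-step grid scan
to ±0.01 pH. Mw sums ExPASy average residue masses plus one water
(18.01524 Da); the unknown residue X contributes a generic 110.0 Da.

**Naming.** FLA genes are sorted by chromosome (natural order:
chr2 < chr10; unplaced contigs after all chromosomes,
lexicographically) then start, and numbered `<prefix>FLA1..n`.

## Tandem and segmental duplication, orthologs

Tandem clusters are connected components of the graph with an edge
between two genes when they share a chromosome, the span gap
(start of the downstream gene minus end of the upstream) is ≤100 kb,
and their proteins align at >70% identity. The "100 kb range" wording
in the literature is ambiguous between start-to-start and span gap;
span gap is the default here and is configurable. Identity is
identical columns over all alignment columns including gaps (the
EMBOSS-needle convention), from global Needleman–Wunsch alignment
with BLOSUM62 and affine gaps (open 10, extend 0.5); a
shorter-sequence denominator is available as a switch.

Anchors are gene pairs ranked by global alignment score: each gene's
top-5 partners passing a length-ratio ≥ 0.5 filter, kept if found in
either direction with identity ≥ 40%. Collinear blocks are longest
chains (dynamic programming) of anchors per chromosome pair and
orientation, extending when both rank gaps lie in [1, 25], emitting
chains of ≥5 anchors, each anchor used once (best chain first). The
min-anchor and rank-gap defaults are MCScanX's, since the tool is the
de-facto standard and its parameters are rarely reported. Intra-genome
block anchors outside a shared tandem cluster are segmental pairs;
tandem labels take precedence over segmental; anchored genes without
a label are "dispersed", the rest "singleton". Inter-genome block
anchors are syntenic orthologs; reciprocal-best anchors outside any
block are reported separately as non-syntenic candidate orthologs
(homologs that moved).

## NG86 Ka/Ks

Sites: for each codon position, the synonymous fraction is the share
of the three single-base changes that preserve the amino acid,
counting changes to stops as nonsynonymous; s + n = 3 per codon.
Differences: for k differing positions, all k! single-step pathways
are enumerated; pathways through stop codons are excluded (if all are
blocked, all are used with equal weight and the result is flagged).
S and N are the averages of the two sequences' site totals;
ps = Sd/S and pn = Nd/N are Jukes–Cantor corrected,
d = −(3/4)·ln(1 − 4p/3); p ≥ 0.75 makes that distance undefined and
flags the pair as saturated. Ka/Ks < 1 is purifying, > 1 positive,
= 1 (tolerance 1e−9) neutral; Ks = 0 (e.g. fully identical recent
duplicates) leaves the ratio undefined. NG86 was chosen as the single
implemented estimator (the popular calculators offer many, and
published studies rarely state which was used); the method id is
recorded in every output row. Gapped protein-alignment columns are
dropped entirely before backtranslation (complete deletion), which is
exact for the indel-free synthetic families.

## Phylogenetics

Distances are Poisson-corrected, d = −ln(1 − p), on p-distances with
pairwise deletion; sites with `-` or `X` in either row are excluded
(whether standard tools exclude `X` under pairwise deletion is
undocumented; it is excluded here). Neighbor joining follows
Saitou–Nei with the Q criterion; ties break on the smallest
(row, column) pair in the current matrix and negative branch lengths
clamp to 0. On additive matrices the recovery is exact (verified
against random 4–8-taxon trees and cross-checked against dendropy's
NJ). Bootstrap resamples alignment columns with replacement, rebuilds
the tree, and reports the percentage of replicates containing each
internal bipartition; the default is B = 1000 (tests use B = 200 with
a fixed seed for speed).

Group I–IV assignment midpoint-roots the tree (the rooting used in
published FLA trees is unstated) and takes each group's clade as the
MRCA of its anchor leaves (Group I ← AtFLA11/AtFLA12, II ← AtFLA1,
III ← AtFLA16, IV ← AtFLA3). A leaf under exactly one group clade
takes that group; under several, the smallest enclosing clade wins;
under none, the nearest anchor by path length decides, ties toward
the lower group number. Expansion statistics compare per-species
Group-I proportions (of the family, and of the whole genome via the
species' total gene count) between woody and herbaceous species with
a two-sided Welch t-test — chosen because the habit classes are small
and their variances need not match; the Student pooled test is used
only for qPCR replicates, where that test is the field's stated
convention. Family-size summaries report each species' count and its
fold ratio against a designated reference species, rounded to one
decimal.

## Gene structure and expression

Intron count is exon count − 1 from the primary isoform (the mRNA
with the longest summed exon length when several exist); the
distribution is binned 0 / 1 / 2 / >2 with percentages rounded to two
decimals. Relative expression is 2^−ΔΔCt: per replicate
ΔCt = Ct_target − Ct_reference; ΔΔCt is the tissue mean ΔCt minus the
calibrator-tissue mean; the SD is taken over per-replicate folds
2^−(ΔCt_i − mean ΔCt_calibrator), i.e. on the fold scale that error
bars are drawn on. Replicates are paired within ΔCt rather than
averaging Ct first (the choice matters only for the SD). Tissue
contrasts use a pooled-variance two-sided Student t-test on ΔCt
values, annotated `**` at p < 0.01; zero pooled variance returns
t = 0, p = 1 for equal means and a flagged p → 0 otherwise. No
amplification-efficiency correction and no multiple-testing
correction are applied.

## Synthetic data: what it emulates, and what it does not

The generator builds two related genomes at desk scale — by default 3
chromosomes × 24 genes each — with planted FLA genes, one 8-anchor
inter-genome collinear block (the orthologs), one 5-anchor
intra-genome block per genome (the segmental duplicates), two tandem
arrays (sizes 3 and 2, gaps ≤30 kb, identity ~90%) plus two
engineered negatives violating exactly one criterion each (one array
spaced at 150 kb, one pair at 60% identity), one reciprocal-best
ortholog pair outside any block, and isolated singletons. Ortholog
and segmental divergence defaults are (Ka, Ks) = (0.05, 0.20) and
(0.03, 0.15) — young, purifying-selected duplicates. 85% of FLA genes
carry a signal peptide and 72% a GPI anchor, matching the fractions
reported for real families; intron counts are drawn at roughly
51/35/12/2% for 0/1/2/3 introns.

Three constructions make the truth tables exact rather than
approximate. Background sequence contains no proline, so the only AG
dipeptides are the planted ones; hydrophobic runs are capped at three
residues, so no accidental signal-peptide core or GPI tail can arise;
and family divergence applies at most one base change per codon, with
nonsynonymous replacements confined to non-feature positions and
drawn from residues that cannot create any detector motif. Planted
features therefore satisfy the detectors' rules by construction, and
percent identity and substitution counts are exact.

Consequences for interpretation: perfect sensitivity/specificity on
synthetic data demonstrates that the implementation applies its rules
exactly, not that the rules match SignalP/big-PI on real proteins
(those tools' outputs should be supplied as overrides for real
analyses). Families are substitution-only (no indels), so the
identity alignment is valid and alignment construction is outside the
package's scope; real data needs an external aligner. CDS are
generated without stop codons; real chromosome sequence, UTRs,
rearrangements beyond the planted blocks, and assembly artifacts are
not modeled.

The codon-divergence engine (`evolve_cds`) converts Ka/Ks targets to
p-distances by inverting the Jukes–Cantor correction, forms change
quotas against the sequence's NG86 site counts, and accepts random
single-base, non-stop codon changes (one per base position) until the
quotas are met; targets at p ≥ 0.74 are rejected as saturated. This
proposal–acceptance scheme targets NG86-scale proportions directly —
simpler than a continuous-time codon model and sufficient for
estimator validation; repeated-hit effects bias recovered Ks
downward by only ~3–4% at Ks = 0.25.

The qPCR generator writes Ct_target = Ct_reference + baseline −
log2(fold) + N(0, sd) per replicate (3 replicates, baseline ΔCt 3.0,
reference Ct 17.5, noise 0.2 cycles by default), so planted folds are
recovered exactly at zero noise and within sampling error otherwise.

For the woody/herbaceous expansion Monte-Carlo, per-species Group-I
memberships are binomial draws at 50% (woody) versus 33%
(herbaceous) over 80 genes per species across 5 + 5 species — the
family size per species was fixed by a power analysis so that the
planted effect is detectable (power > 95%) at this species count.

## Determinism and numerics

Every stochastic component takes an explicit seed
(`numpy.random.default_rng`); outputs are written in sorted order
with fixed float formatting, so identical config + seed reproduces
every file byte for byte. In the end-to-end pipeline the NJ stage
runs over all FLA proteins from both genomes with rows gap-padded to
equal length; pairs from unrelated families can approach p-distance
saturation, so p is capped at 0.95 before Poisson correction there
(saturated distances are "maximally distant", analogous to distance
tools flagging inestimable pairs). Alignment scores are cached
(symmetric pairs share one entry). Bisection for pI stops at
|charge| < 1e−4 or a 1e−7 pH interval.

## Known limitations

- The signal-peptide and GPI heuristics are transparent rules, not
  trained predictors; on real proteomes they will disagree with
  SignalP/big-PI for borderline sequences. Overrides exist for
  exactly this reason.
- NG86 is the only Ka/Ks estimator; no ML (GY94) or YN00 variants,
  and no sliding windows.
- NJ only; no ML/Bayesian inference, no model selection, no tree
  visualization.
- Tandem clusters use transitive chaining, so published "pair" counts
  map to clusters of size ≥2 here; both views are derivable from the
  output.
- The collinearity chaining is a simplified MCScanX: no e-value
  weighted scoring, no gap-extension penalties in the chain score.
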