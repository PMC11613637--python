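# Methods

This note documents the models and procedures implemented in `panfam`, the
parameters that matter, the numerical choices, and what the synthetic-data
tests do and do not demonstrate.

## Family scanning

Candidate family members are found by optimal local alignment (Gotoh
affine-gap dynamic programming; the fill is numba-compiled, traceback prefers
diagonal over vertical over horizontal moves so results are deterministic).
Scoring is BLOSUM62 with gap open 11 / extend 1 — the standard protein-search
defaults. A proteome entry is a candidate when its best alignment to any seed
query reaches identity ≥ 0.40 over aligned columns and covers ≥ 0.50 of the
query. These thresholds are deliberately loose: membership is decided by the
domain check, and the alignment scan only pre-selects homologs, so its
thresholds need to be permissive rather than precise.

The domain check slides a log₂-odds PSSM (uniform 1/20 background,
pseudocount 0.5) over the protein; the domain is present when some window of
the full profile length scores at or above the profile threshold. The
threshold is calibrated from the seed alignment itself: one quarter of the
way from the highest score of 1,000 shuffled consensus sequences up to the
lowest-scoring seed sequence. Every seed passes, every shuffle fails, and the
margin leaves room for members that have drifted somewhat beyond the seed
variants. The bundled AP2-like seed alignment is **synthetic**
(`data/ap2_seed.synthetic.faa`): a 61-residue consensus with YRG/RAYD-like
blocks and eight mutated variants. It is self-consistent for the scanning
contract (consensus passes, shuffles fail) but is not a curated database
alignment; to scan real proteomes, replace it with a seed alignment of real
domain sequences — the profile builder and TSV format are agnostic.

Accepted members are named `<cultivar>_<FAM><k>` by chromosomal order:
chromosomes sort by trailing integer ("Chr13" → 13, non-numeric names after
numeric ones, lexicographically), then start coordinate, ties broken by end
then gene id. Renaming is idempotent.

## Protein properties

All five calculators follow the classical server definitions. Molecular
weight sums average-isotope residue masses plus one water (18.01524 Da).
The isoelectric point solves net charge = 0 by bisection on pH ∈ [0, 14] to
|charge| < 1e-4 (the charge is strictly decreasing in pH, so bisection always
converges; ~40 iterations reach the tolerance). The pKa set is Bjellqvist's —
the set used by the web tool the family tables of this kind are produced with
— including its residue-specific N- and C-terminal pKas. A consequence worth
knowing: pI is *not* purely a composition function; swapping a terminal
residue into the interior can shift it. The instability index uses the
Guruprasad DIWV dipeptide table, the aliphatic index Ikai's coefficients
(1, 2.9, 3.9 on mole percents of A, V, I+L), GRAVY the Kyte–Doolittle scale.
The DIWV and hydropathy tables are imported from Biopython's published data;
the summation logic is independent and is cross-checked against Biopython's
calculators in the tests. Residue X is excluded from pI/AI/GRAVY and
contributes the mean residue mass to MW, with a logged warning.

## Pan-gene classification

Cross-cultivar ortho-groups are built from reciprocal best hits on
Smith–Waterman score (ties broken by identity, then id), clustered by
single-linkage connected components. The one-member-per-cultivar invariant is
enforced at link time: an edge that would merge two components already
sharing a cultivar is skipped (edges are processed in input order; with clean
RBH input no such conflict arises). Groups are numbered by the median
chromosomal rank of their members so shared groups carry stable family-wide
numbers. Classification is purely by presence count: all *n* cultivars →
core; exactly 1 → unique; otherwise dispensable. In the degenerate
single-cultivar case every group is unique by definition.

RBH plus single-linkage is a declared stand-in for an unspecified published
matching procedure; it is the simplest method consistent with a reported
core/dispensable/unique partition, and it makes no use of gene identifiers
(the five cultivars' annotations use four different nomenclatures, so
cross-cultivar identity must come from sequence, not ids).

## Duplicate pairs, Ka/Ks, dating

Within a cultivar, every unordered member pair is tested against the 70/70
rule on a global (Needleman–Wunsch) protein alignment: *coverage* = aligned
(non-gap) columns / longer protein length, *similarity* = identity over
aligned columns. Global alignment is used because the rule speaks of
whole-gene coverage. A retained pair is *tandem* when both genes share a
chromosome and the gap between nearest gene ends is ≤ 100 kb (inclusive);
everything else is *segmental* — no synteny-block requirement, matching the
binary reporting convention of family studies. The 100-kb default
accommodates every pair in the published duplication table (max observed
adjacent gap ≈ 53 kb) while excluding all cross-chromosome pairs; it is
configurable.

Ka/Ks is Nei–Gojobori 1986. Synonymous sites per codon are the per-position
fractions of the three alternative bases giving a synonymous non-stop codon;
changes to stop codons count as nonsynonymous sites, so sites total exactly
3 per codon. Observed differences in multi-difference codons are averaged
with equal weight over all minimal substitution pathways, excluding pathways
through stop codons (if all are blocked, the average falls back to all
pathways). Both proportions get the Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 is reported as saturated (NaN) rather than
extrapolated. The implementation agrees to machine precision with
Biopython's independent NG86 and with a brute-force pathway-enumeration
oracle in the tests. Codon alignments are obtained by back-translating the
protein alignment; columns with a gap or an ambiguous base are dropped.

Duplication age is T = Ks / (2λ) · 10⁻⁶ Mya with λ = 1.5×10⁻⁸
substitutions·site⁻¹·year⁻¹ by default (configurable). Output tables round
Ka/Ks and age to two decimals, Ka and Ks to four; full precision stays on
the in-memory objects.

## Promoter scanning

The promoter is the ≤ 2,000 bp upstream of the gene start, strand-aware
(minus-strand promoters are reverse-complemented so position 1 is the 5'
end); truncation at a chromosome boundary is logged, a gene starting at
base 1 yields an empty promoter. The element dictionary is an editable TSV of
IUPAC consensi, one documented variant per element name, in five categories
(light, hormone, stress, development, other). Element databases host several
variants per name; which variant is counted is a data decision, not code, so
absolute hit counts are comparable only under a fixed dictionary. Scanning
reports every match position on both strands (overlaps included);
minus-strand hits are reported at their leftmost plus-strand position,
making the reverse-complement symmetry exact and testable.

## Expression

FPKM[g,s] = counts · 10⁹ / (length · total). The response classifier is
descriptive, not inferential: with ε = 0.01 FPKM, a contrast is *induced*
when log₂((treat+ε)/(ctrl+ε)) ≥ 1 and the treatment mean is ≥ 1 FPKM,
*repressed* symmetrically, *not_expressed* when both means sit below 1 FPKM.
There is deliberately no dispersion model or p-value — the upstream studies
report descriptive FPKM heatmaps, and pretending to more statistical
strength than the data supports would be dishonest scope creep.

## Synthetic pan-genomes

The generator emulates the study structure: five cultivars; 15 ortho-groups
(8 core, 5 dispensable absent from the second cultivar, 2 unique to the
fourth); two isolated core genes on Chr1, a five-gene core tandem cluster on
Chr2, and an isolated core gene, the five-gene dispensable cluster and the
two-gene unique cluster on Chr3. Adjacent cluster genes sit 12–25 kb apart
(gaps drawn so that even first-to-last cluster pairs stay under the 100-kb
tandem cutoff); isolated genes 35 kb apart. Each gene carries a 2-kb promoter
seeded with four randomly chosen dictionary elements at recorded offsets,
placed on a 70/30 mix of plus/minus strands. Decoys are codon-shuffled copies
of the family ancestor: same composition, no homology, no domain. Eight
decoys per cultivar stress the scan's specificity.

Sequence evolution is codon-wise with uniform proposals over positions and
alternative bases; stops are rejected; a proposal is accepted with
probability min(1, 1/ω) if synonymous and min(1, ω) if nonsynonymous, which
keeps the nonsynonymous/synonymous rate ratio at ω for ω > 1 as well.
Evolution halts when the realized NG86 Ks against the ancestor first reaches
the target (incremental per-codon bookkeeping makes this O(1) per accepted
substitution); the overshoot is bounded by one substitution's worth of
divergence. There is no transition/transversion bias and no indel process.

Divergence defaults are anchored to the regime the method is used in:
paralog groups diverge at pairwise Ks ≈ 0.1 (the published duplicate pairs
span Ks 0.01–0.15) with ω = 0.5; orthologs of one species' cultivars are
nearly identical (pairwise Ks ≈ 0.01) and evolve under purifying selection
(ω = 0.1) — same-species coding divergence is strongly constrained, and this
also guarantees the generative premise that orthologs are closer than
paralogs, without which a planted "ortho-group" would not be a meaningful
truth label. Protein length is 210 codons with the 61-residue domain
embedded after a 40-residue N-flank.

Read counts are negative binomial with mean = planned FPKM · length ·
library / 10⁹ and size 10 (CV ≈ 33 % at high expression), three replicates
per condition, 20 M fragments per library, planned fold changes drawn from
{4, 1, 0.25} — exactly at the classifier's log₂ decision boundary, so
recovery is asserted at ≥ 95 % per class, not 100 %.

What passing these tests shows: the pipeline's logic — scanning, grouping,
classification, counting, dating — is correct against known truth. What it
does not show: performance on real annotations (fragmented gene models,
alternative transcripts, pseudogenes), real domain variation (the profile is
built from a synthetic seed), indel-rich alignments, or real RNA-seq biases.

## Problem sizes

The default simulation uses 62 family genes + 40 decoys across five
3-chromosome genomes (~0.2 Mb per chromosome), chosen so a full pipeline run
takes a few seconds while every structural feature of the study design
(presence pattern, tandem clusters, promoters, counts) is present. The
dN/dS recovery study uses 500-codon pairs, 50 replicates per ratio at target
Ks 0.1 — the mid-range of the published duplicate-pair Ks values.

## Known limitations

- NG86 with equal-weight pathway averaging underestimates ω above 1: at a
  true ratio of 2.0 the median estimate plateaus near 1.7–1.8 regardless of
  divergence depth (stop-mutation rejection makes the realized estimand
  ≈ 0.94 ω, and pathway averaging misattributes nonsynonymous differences in
  multi-difference codons). This is the estimator's documented behavior, not
  an implementation defect — the implementation matches an independent NG86
  to machine precision. Ratios ≤ 1 (the purifying regime in which the method
  is routinely applied) recover well.
- The 70/70 rule with a permissive family ancestor means *all* member pairs
  within a cultivar can pass, including cross-chromosome ones labeled
  segmental; real studies prune by unstated similarity criteria.
- Ortho-grouping assumes at most one member per cultivar per group; lineage-
  specific duplications inside a group would be split greedily.
- The cis-element dictionary's hit counts depend entirely on the chosen
  consensus variants; they are comparable across genes within a run, not
  across dictionaries.
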