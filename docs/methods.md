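# Methods

This note documents the models, conventions and design choices behind
`oryzacompat`, in the spirit of a statistical-software methods appendix.

## Allele typing

Each locus is described by a `LocusDefinition`: diagnostic polymorphisms
(SNPs or indels) addressed by 1-based alignment columns in a package-defined
amplicon frame, deletion signatures, and a map from diagnostic-state vectors
to allele-type labels. Published diagnostic symbols (C282A, C877T, A434G,
the *SaF* C→T at 287, the fifth-intron G→T of *SaM*) are coding-sequence
positions from the original cloning studies; they are kept as annotations
(`cds_symbol`) while the operational coordinates live in the amplicon frame,
because amplicon-relative offsets are what an aligned resequencing panel
actually exposes. All intervals are 1-based and end-exclusive, which makes
the *SaFX* span arithmetic exact: 22,379,815 − 22,371,187 = 8,628 bp.

Classification is a pure function with a strict precedence order: deletion
signatures beat SNP states (an *s5* allele with the 136-bp gap is *s5-n*
regardless of its SNPs; any allele on the *SaFX* background is *SaFX* or
*SaM±X*, never a plain SNP type). An `N` at a required diagnostic produces
a `missing` call rather than a guess, unless the remaining diagnostics are
already decisive. Contradictory evidence — the two *s5* SNPs disagreeing
(a putative recombinant), or both primer sets of the complementary *SaFX*
assay succeeding — is surfaced as a conflict, never silently resolved.

Orientation convention: for *DPL2*, *SaM* and *SaF* the literature fixes
which nucleotide state is japonica-like (the derived G of A434G, the
truncating T, and the T of the C→T transition respectively). For the two
*s5* SNPs the published symbols do not state which state belongs to which
subspecies; this package adopts the convention that the derived (alt)
states A and T mark *s5-i*. The choice is symmetric — swapping it relabels
i↔j consistently everywhere — and is configurable through the locus config.

Haplotype enumeration collapses identical aligned strings (gaps count as
characters, so a 1-bp indel separates haplotypes). The reference sequence
(the Nipponbare convention) is haplotype 1; remaining ids are assigned by
descending count, ties broken by first appearance in input order (the
source convention for tie-breaking is not documented anywhere, so input
order was chosen as the reproducible rule).

## Panels and frequency tables

Wild (*O. rufipogon*/*O. nivara*) accessions are outcrossing and carry two
alleles per locus; all other groups are haploid inbred lines except rare
heterozygotes, which contribute both alleles to the denominators. Missing
calls shrink the denominator ("alleles sampled") instead of counting as a
type. Percentages are integers by round-half-up; the exact float is also
reported, because published tables of this kind round inconsistently
(5/8 appears in print as both 62.5% and 63, and 37.5% as 37). At *s5* the
wide-compatibility allele is displayed inside the indica-type row, with a
separate "wc" percentage computed among indica-type alleles only.

## Diversity statistics

Gap handling follows the DnaSP convention: any column containing a gap or
ambiguous base is excluded from S, from θ_W's site denominator and from the
complete-deletion statistics. π defaults to pairwise deletion (each pair
compared over its own clean sites; switchable to complete deletion).
θ_W = S/(a1·L) with a1 = Σ_{i<n} 1/i. Tajima's D uses the standard
variance constants and the complete-deletion π so that its numerator and S
are computed on the same sites; D is undefined (rendered "n/a") when n < 4
— the threshold the source tables use — or S = 0. θ_W and π are per-site;
per-locus values follow by multiplying by the gap-free length. Indel events
are contiguous gap runs identified by their exact (start, end) span, so a
deletion shared by many sequences is one event.

Clark haplotype-subtraction phasing resolves homozygotes first, then
iteratively subtracts known haplotypes from heterozygotes, adding each
inferred complement to the known set. Heterozygotes are processed in input
order; order-dependence is inherent to the algorithm and documented rather
than hidden. With no homozygote seed the method abstains (all records
flagged unresolved) — it never guesses.

All three statistics are verified against an independent brute-force oracle
(column frequency-spectrum formulation) to 1e-9 on 200 random alignments in
the test suite; this is the validation route for machinery whose published
per-locus values would require the original deposited sequences.

## Genealogies

K2P distances use the closed form d = −½ln(1−2P−Q) − ¼ln(1−2Q) over
pairwise gap-deleted sites (complete deletion switchable); out-of-domain
log arguments raise a saturation error rather than returning a clamped
number. Neighbor joining is the standard Saitou–Nei agglomeration with two
documented conventions the literature leaves open: Q-criterion ties break
to the lowest label-index pair, and negative branch lengths are clamped to
zero with the length transferred to the sister branch. On additive
matrices the recovered path lengths reproduce the input distances to
1e-9 (tested exhaustively for all three four-taxon topologies), and the
splits match scikit-bio's independent NJ implementation on random matrices.
Bootstrap supports resample alignment columns with replacement (default
B = 500), report per-edge bipartition percentages, skip saturated
replicates with an adjusted denominator, and hide values below 50 when
rendering Newick — all fully deterministic under a fixed seed.

## The sterility model

Per-system rules are pure predicates over F1 diploid genotypes:

* **Sa**: semi-sterile (viable pollen fraction 1 − 0.5) iff functionally
  heterozygous *SaM* and ≥1 functional *SaF+*. The X-background alleles
  are modeled as complete nulls for both genes — the hypothesis the
  crossing data support, since a *SaM+X/SaM−//SaF+/SaFX* hybrid shows no
  pollen deficit — with a conservative `x_mode="unknown"` that abstains
  instead. The 0.5 effect size ("usually about 50%") is configurable.
* **s5**: fertility reduction 0.46 iff the genotype is exactly
  *s5-i*/*s5-j*; any *s5-n* restores compatibility.
* **DPL**: gametes enumerated under independent assortment (the loci are
  on chromosomes 1 and 6); viable fraction = 1 − freq(*K−* & *N−*
  gametes). Verified against exhaustive gamete enumeration for all nine
  two-locus diploid classes.

Heterozygous parents are handled by enumerating parental gamete
combinations and averaging each system's viable fraction over the
equifrequent F1s. The combined relative fertility is the **product** of
per-system fractions. This is a modeling assumption, not an empirical
claim: male-side (Sa, DPL) and female-side (s5) effects act on different
gametophytes and the loci segregate independently, but how pollen
semi-sterility and embryo-sac abortion quantitatively compose into seed
set has not been measured; per-system fractions are therefore always
reported alongside the product. Penetrance variation among crosses
(reported historically from 5 to 95%) is acknowledged but not modeled.
The population barrier matrix averages the combined fertility over all
individual × individual crosses between two groups.

## Pollen statistics

Pollen quality is the mean over three fields of view of
100 × nonviable/(viable + nonviable); quantity is the mean of three
hemacytometer counts times a chamber conversion factor (a config input —
the chamber's 0.5-mm depth alone does not fix the factor). Genotype
summaries take the mean over per-individual averages but the standard
deviation over all raw measurements (n−1), matching the arithmetic of the
published summary tables (e.g. individuals averaging 8.0 and 3.2 give a
genotype mean of 5.6). Group comparisons default to Welch's t-test (the
source says only "t-test"); the Student variant is provided, and both
per-individual-average and raw-triplicate input modes are possible since
the original granularity is not stated.

## Synthetic data

The generator emulates a diagnostic-amplicon resequencing panel: per
group×locus allele-type counts, neutral SNP variation placed only at
non-diagnostic columns (so truth labels cannot be corrupted), the s5
deletion and DPL1 insertion as gap runs, SaFX as whole-amplicon absence
plus complementary-primer assay rows, whole-locus amplification failure as
the missing-data mechanism, and optional exact targets for segregating
sites (met within ±10%; diagnostic columns that segregate count toward the
target) and haplotype numbers (met exactly by carving allele-type cohorts
into subgroups with private marker columns; neutral mutations are then
applied at haplo-group granularity to preserve the count). Everything is
byte-deterministic under the spec seed, with per-locus seed streams.

What it does **not** emulate: coalescent genealogies, recombination,
mutation-rate heterogeneity, or linkage between loci. Passing round-trip
and frequency tests on this generator demonstrates that the analysis
machinery is correct, not that real panels are free of alignment error,
base-calling noise or sampling artifacts. Alignments are generated
per-locus independently, so cross-locus genotype coherence (e.g. matching
*SaM+X* and *SaFX* counts on the same accessions) is the spec author's
responsibility.

## Problem sizes and numerical choices

Default validation sizes — 200 random alignments (n ≤ 8, L ≤ 50) for the
oracle comparison, 500 alleles per locus for typing recovery, B = 100
bootstrap replicates and 200 simulation replicates for the power check —
were chosen as the smallest panels at which the properties are sharp
(oracle agreement at 1e-9, recovery at exactly 100%, support and power
saturating well above their thresholds). Percentages use round-half-up
(never banker's rounding); undefined statistics are explicit `None`/"n/a",
never 0; conflicting evidence is always surfaced in the output rather than
resolved by a tie-break.

## Known limitations

* The published per-locus diversity values and tree figures cannot be
  reproduced without the deposited GenBank sequences; the package
  validates the machinery by oracle and property tests instead.
* Group membership is taken from the metadata (prior population-structure
  work), never inferred from genotype.
* F2+ segregation, transmission-ratio distortion and quantitative fitness
  beyond the stated effect sizes are out of scope.
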