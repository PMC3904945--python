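# oryzacompat

Analysis toolkit for the cloned hybrid-incompatibility loci of Asian rice
(*Oryza sativa*) and its relatives: allele typing, population frequency
tables, diversity statistics, haplotype genealogies, and prediction of
cross (in)compatibility between cultivated, weedy and wild rice.

## The problem

Crosses between the *indica* and *japonica* subspecies of cultivated rice
are partially sterile. Three Bateson–Dobzhansky–Muller (BDM) sterility
systems, comprising four cloned loci, explain much of this barrier:

* **s5** (chromosome 6, embryo sac): the *s5-i*/*s5-j* heterodimer aborts
  embryo sacs, reducing spikelet fertility by 46%. A 136-bp deletion
  (*s5-n*) is a non-functional wide-compatibility allele.
* **DPL1/DPL2** (chromosomes 1 and 6, pollen): duplicate genes; a gamete
  carrying non-functional alleles at both (*DPL1-K−* via a 517-bp insertion,
  *DPL2-N−* via the SNP A434G) is non-viable.
* **Sa = SaM + SaF** (chromosome 1, pollen): an F1 heterozygous for
  functional *SaM+*/*SaM−* that also carries *SaF+* selectively aborts the
  *SaM−*-bearing microspores (~50% pollen semi-sterility). An 8,628-bp
  deletion (*SaFX*) removes *SaF* entirely plus the first four exons of
  *SaM*, producing the null alleles *SaFX* and *SaM+X*/*SaM−X* that escape
  the interaction.

US rice fields host conspecific weedy ("red") rice of *indica*/*aus*
ancestry growing beside a *japonica* crop, so these loci determine whether
crop–weed gene flow is genetically blocked. This package implements the
full analysis chain for such panels: diagnostic-polymorphism allele
classification (including the complementary-primer assay for *SaFX*),
Table-style allele-type frequency and two-locus genotype tables, per-group
diversity statistics (S, π, θ_W, Tajima's D, haplotype and indel counts),
Clark haplotype-subtraction phasing, neighbor-joining haplotype trees under
the Kimura-2-parameter model with bootstrap supports, pollen viability and
quantity statistics, and a sterility model that predicts the expected
relative fertility of any genotype pair and their F1. A fully seeded
synthetic-data module generates aligned haplotype panels with ground truth
for every record.

## Worked example

Predict the outcome of a typical *indica* × *japonica* cross:

```
oryzacompat predict-cross \
    --parent-a "s5-i;DPL1-K-;DPL2-K+;SaM+/SaF+" \
    --parent-b "s5-j;DPL1-N+;DPL2-K+;SaM-/SaF-"
```

prints (abbreviated):

```json
{
 "systems": [
  {"system": "Sa",  "verdict": "semi-sterile", "viable_fraction": 0.5},
  {"system": "s5",  "verdict": "semi-sterile", "viable_fraction": 0.54},
  {"system": "DPL", "verdict": "compatible",   "viable_fraction": 1.0}
 ],
 "combined_fertility": 0.27
}
```

The F1 is a functional *SaM* heterozygote carrying *SaF+* (50% viable
pollen), an *s5-i*/*s5-j* heterodimer (46% spikelet-fertility reduction),
and — because both parents carry functional *DPL2-K+* — no dead *DPL*
gamete class. The combined relative fertility 0.27 is the product of the
per-system fractions. Replacing the *Sa* alleles with the deletion-carrier
genotype of straw-hull weedy rice (`SaM+X/SaFX`) and *s5* with `s5-n`
returns `combined_fertility: 1.0`: the wide-compatibility alleles nearly
fixed in US weed groups remove every predicted postzygotic barrier to
hybridization with the local *japonica* crop.

The same library surface is scriptable in Python (`import oryzacompat`),
and `oryzacompat run-all` executes the whole pipeline (typing → tables →
diversity → trees → barrier matrix → pollen statistics) from FASTA
alignments, a metadata TSV and an amplification-call TSV, writing a
reproducible report bundle whose files embed the run seed and input
checksums. `oryzacompat simulate` generates complete synthetic panels with
truth tables.

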