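# Methods

## Overview

`pagesim` simulates a closed livestock nucleus population improving a
single additive quantitative trait, and quantifies what germline genome
editing of selected sires (promotion of alleles by genome editing,
PAGE) adds on top of truncation selection on true breeding values
(genomic selection with perfect accuracy, "GS only").  The pipeline has
four stages: coalescent founder haplotypes, trait architecture, a
multi-generation gene-drop with selection, and (in future generations)
germline editing.  All reported statistics are computed per generation
and replicate and summarised over replicates.

## Founder haplotypes

Each chromosome is simulated independently with msprime.  Default
genome: 10 chromosomes, each 100 cM and 10⁸ bp (uniform 1 cM/Mb map),
per-site mutation rate 2.5 × 10⁻⁸, biallelic mutations.  The effective
population size is a piecewise-linear function of time anchored at
(0, 100), (10³, 1256), (10⁴, 4350), (10⁵, 43,500) generations ago and
constant beyond the oldest anchor.  msprime expresses demography as
piecewise-constant epochs, so the linear ramps are discretised into
~160 geometrically spaced epochs evaluated at their midpoints; the
discretisation error on segregating-site counts is well under the
replicate-to-replicate spread.  The SMC' approximation is used by
default (`model="smc_prime"`) because it is linear in sequence length
at chromosome scale; the exact Hudson coalescent is available via
`model=None` and agrees on site counts within Monte-Carlo error (the
test suite checks the small-sample Watterson expectation
`E[S] = 4 N_e μ L Σ 1/i` against the simulator).

1000 haplotypes are sampled (as 500 diploids).  A full-scale run yields
≈ 0.5 M segregating sites across the genome.  Haplotypes can also be
imported/exported as plain text (one 0/1 row per haplotype plus a
positions file per chromosome); monomorphic columns are dropped on
import with a logged count.

## Trait architecture

10,000 QTN are sampled uniformly without replacement from the
segregating founder sites, 1000 per chromosome.  Allele-substitution
effects are i.i.d. `N(0, (1/√10,000)²)`; exact zeros are re-drawn so
every QTN has a favourable allele (the allele whose extra copy raises
TBV — allele 1 when α > 0, else allele 0).  TBV uses the allele-1
dosage coding throughout; relabelling alleles while flipping the sign
of α shifts all TBVs by a constant and changes no selection decision
(property-tested).

## Breeding program

Generations are discrete and non-overlapping, 1000 individuals each
(exactly 500 male / 500 female; the sex-label vector is a random
permutation of a fixed half/half split).  The base population at
generation −20 draws, independently per chromosome and with replacement,
two founder haplotypes per individual; genomes are then tracked at QTN
loci only.  Tracking only QTN is exact for every reported statistic
because selection, editing and all metrics depend on QTN genotypes
alone; the inter-QTN linkage that matters (hitchhiking, Bulmer effect)
is preserved through the genetic-map positions of the QTN.

Each generation the 25 highest-TBV males and all 500 females are
selected (ties broken by ascending id).  Every dam produces exactly two
offspring by a single sire; dams are assigned to sires uniformly at
random subject to exact quotas (20 dams, hence 40 offspring, per sire),
honouring equal sire contributions.  Meiosis is the Haldane model: per
chromosome, a Poisson(length in Morgans) number of crossovers at
uniform genetic-map positions, starting strand fair, no interference
and no obligate chiasma.  The batched kernel is vectorised over
gametes; the recombination fraction between loci d Morgans apart
recovers (1 − e^(−2d))/2 in the tests.

After 20 selection steps (generation 0), the editability mask is frozen:
only QTN segregating among the 1000 generation-0 individuals may ever
be edited, so edited and unedited branches compete on identical
standing variation.  The 20 largest-|α| QTN within that set form the
fixed "top-20" panel whose frequency and genic variance are tracked.

## PAGE

In future generations 1–20, after selection on (pre-edit) TBV and
before mating, a strategy subset of the 25 sires is edited: all 25
(A25se), top 10 (T10se), bottom 10 (B10se) or top 5 (T5se), each for
0–100 QTN.  Within a sire, candidate QTN are the editable ones at which
he carries at least one unfavourable allele, ranked by |α| descending
(ties by ascending QTN index); an edit sets both alleles to the
favourable variant (the exclusion of sires "already homozygous
favourable" from candidacy implies heterozygotes are edited, and
homozygous-favourable is the end state consistent with that rule).
Editing is assumed perfectly precise with 100% success and no
off-target changes; edited alleles transmit through meiosis like any
other.  Editing consumes no random numbers, which makes a zero-edit
PAGE branch bitwise identical to GS only (tested) and keeps all
branches of a replicate in random-stream lockstep.

## Metrics

- **Cumulative response**: (mean TBV − reference mean) / σ, where σ is
  the population (divide-by-n) TBV standard deviation of generation
  −20 — the base generation is a complete population, not a sample.
  The reference mean is generation −20 for the whole-program view and
  generation 0 for the future-phase view; the unit is σ(−20) in both
  cases, so the two series differ only by an offset.
- **Genic variance**: Σ 2 p_i (1 − p_i) α_i², invariant to allele
  relabelling; computed for all QTN and the top-20 panel.
- **Favourable-allele frequency**: mean over all 10,000 QTN, over the
  generation-0-segregating set, and over the top-20 panel.
- **Edited-QTN (QTNe) accounting**: a QTN counts as edited in a
  generation if edited in ≥1 sire; the ledger tracks per-generation
  distinct sets, pairwise overlaps, the cumulative union over
  generations 1–20, and the union's share of generation-0 genic
  variance at generation-0 frequencies (loci fixed at generation 0
  contribute zero to both numerator and denominator).
- **Inbreeding**: Wright's F with generation −20 founders unrelated and
  non-inbred.  During a run F comes from a generation-layered kinship
  recursion (the full kinship matrix of each generation is derived from
  its parents' matrix; F of an offspring is the kinship of its
  parents), which is exact for non-overlapping generations and agrees
  with the tabular method to rounding error (tested).  A general
  memoised pedigree recursion is provided for arbitrary pedigrees and
  is validated against a brute-force tabular oracle.

Replicate summaries report means with t-based 95% confidence intervals
(mean ± t₀.₉₇₅,ₙ₋₁ · SE); relative response is formed per replicate as
the ratio of paired branches and then averaged.

## Seeding and pairing

A master seed spawns one `SeedSequence` per replicate; each replicate
spawns independent streams for founders, trait, base population,
historical phase, and a single future-phase stream that every scenario
branch restarts identically from the shared generation-0 state.  This
paired design removes founder and historical noise from
between-scenario contrasts and means adding a scenario never perturbs
another's randomness.  Replicates are embarrassingly parallel
(`--threads`), with results independent of worker count.

## Problem sizes and runtime

Defaults reproduce the study design: 10 replicates configured, 1000
individuals, 10,000 QTN, 41 generations.  The acceptance script runs
three replicates of the four headline branches (GS only, A25se at 20
and 1 edits/sire, T5se at 100 edits/sire), about 3–4 minutes per
replicate on one CPU (founders ≈ 2.5 min, the four 20-generation
branches ≈ 1 min).  The test suite's full-scale check uses one
replicate with bands widened to single-replicate spread.

## Design choices where the design was open

- Base-population haplotype assignment is with replacement,
  independently per chromosome (1000 haplotypes cannot supply 2000
  gametes otherwise).
- Dam→sire allocation is random with exact quotas; both offspring of a
  dam are full sibs.  See limitations for the consequences.
- α = 0 is re-drawn; dosage coding is allele-1 counts with signed
  effects; the favourable orientation is derived, never stored.
- Crossover count may be zero (no obligate chiasma).
- Confidence intervals are t-based over replicates (an empirical
  quantile construction is not meaningful at 3–10 replicates).
- Mean favourable frequency "over all QTN" uses all 10,000 QTN in every
  generation; the generation-0-segregating subset is reported
  separately once defined.

## Limitations

- **Pedigree inbreeding is mating-design sensitive and runs low.**
  With random equal-quota dam allocation the realised ΔF is
  ≈ 0.005/generation (mean F ≈ 0.20 at generation 20 for GS only,
  ≈ 0.36 for T5se/100).  Published values for this breeding design
  (0.44 and 0.65) imply ΔF ≈ 0.014, which our experiments reproduce
  only under strongly assortative (rank-nested) dam allocation — a
  policy that, however, overshoots the response ratios.  The realised
  inbreeding level therefore depends heavily on an allocation policy
  that the design leaves open; the response ratios, allele-frequency
  dynamics and QTNe accounting are robust to it, and the *relative*
  inbreeding penalty of concentrating edits on few sires (the
  super-grandsire effect) appears under every policy tested.
- Selection acts on TBV (perfect accuracy); there are no phenotypes,
  no residual variance and no estimation error, so absolute responses
  are upper bounds relative to practice.
- The trait is strictly additive: no dominance, epistasis, pleiotropy
  or genotype–environment interaction.
- Editing is deterministic and perfect; the molecular biology of
  editing (efficiency, off-target rates, embryo logistics) is out of
  scope.
- Synthetic founders are neutral-coalescent haplotypes; real livestock
  genomes carry selection footprints, variable recombination and
  mutation landscapes, and structural variation that the generator does
  not emulate, so passing tests demonstrate internal consistency of the
  model, not calibration to any real population.
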