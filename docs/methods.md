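# Methods

## Sampling scheme and site classes

All calculations assume one unphased diploid genome per taxon, i.e. four
haploid lineages `a1, a2` (taxon A) and `b1, b2` (taxon B).  Because phase
is unknown and no outgroup polarises alleles, only the folded pattern of a
biallelic site is observable.  Every branch of the genealogy maps to a
mutation class by the set of sampled lineages it subtends: singletons and
their complementary triples give `kA`/`kB` (heterozygous in one taxon),
mixed pairs `{a_i, b_j}` give `kAB` (heterozygous in both), and the
same-taxon pairs `{a1,a2}`/`{b1,b2}` give `kAABB` (alternate homozygotes).
The 14 proper subsets of the sample partition into these classes with
multiplicities 4/4/4/2.  Sites with more than two alleles carry no folded
two-allele pattern; they are excluded from the counts but still occupy
their slot in a block's 150-site span (an infinite-sites model has no
natural place for them, and they are vanishingly rare at these mutation
rates; this is configurable).

## Demographic models and conventions

An ancestral panmictic population of effective size `N_anc` splits at time
`T` (in units of `2 N_anc` generations, backwards from the present) into
descendants A and B.  Four nested model classes: `Div` (nothing else),
`IM` (+ unidirectional migration), `Div2` (+ one-sided instantaneous size
change), `IM2` (both).  Parameters and units:

| parameter | meaning | units / scale | default bounds |
|---|---|---|---|
| `theta` | ancestral per-site mutation rate `4 N_anc mu` | per site | 1e-5 – 0.05 |
| `T` | split time | `2 N_anc` generations | 0.01 – 100 |
| `M` | migration `4 N_anc m`, forward donor→recipient | migrants/generation | 0 – 2 |
| `size_factor` | `N_target / N_anc` for one descendant | ratio | 0.05 – 20 |

Conventions that the code fixes (the source material leaves them implicit):

* **Backward migration rate.**  `M = 4 N_anc m` forward from donor to
  recipient means that, backwards in time, each lineage currently in the
  recipient population jumps to the donor at rate `M/2` per `2 N_anc`
  generations.  This convention reproduces the published expected-frequency
  tables for the subspecies comparison (where immigration inflates the
  recipient's heterozygosity to ≈1.3 θ at `M = 0.032`, `T = 12`).
* **θ is ancestral.**  Descendant sizes are `factor × N_anc` on exactly one
  side and `N_anc` on the other; coalescence rates before `T` are
  `1/factor` and `1` per pair respectively, and `1` after `T`.
* One published parameter row (the hybridizing-pair IM₂ fit: θ = 0.00154,
  factor 1.36 on A, M = 0.015 B→A, T = 19.8) does **not** reproduce its
  printed expected frequencies under any assignment we tried of these two
  conventions; its implied ancestral θ is ≈0.0011.  That row's reporting
  convention is ambiguous and it is therefore not used as a numerical
  reference; the other two pairs' rows reproduce to well under 1%.

## Expected branch lengths

`expected_branch_lengths` computes `E[t_c]`, the expected total branch
length in class `c`, exactly.  The lineage configuration (a partition of
the sample with a population tag per block) evolves as a finite-state
Markov chain (≤ ~30 states).  Over `[0, T)` the occupation time of every
state is `p0^T ∫_0^T e^{Qs} ds`, evaluated with one matrix exponential of
the augmented block matrix `[[Q, I], [0, 0]]`; after `T` the panmictic
chain's occupation times come from a linear solve with the fundamental
matrix.  `E[t_c]` is the reward `Σ_state occupancy × (#class-c lineages)`.
Per-site class frequencies are `E[k_c] = (θ/2) E[t_c]`, with the invariant
complement `1 − Σ_c E[k_c]`; this linearisation requires `Σ E[k_c] < 1`
and the code refuses θ values that violate it.

Checks with closed forms: at `T = 0` the sample is exchangeable and
`E[t] = (4/3, 4/3, 2/3, 1/3)` (total 11/3); the heterozygosity identity
`(θ/2)(E[t_A] + E[t_AB]) = θ E[pair coalescence time]` holds for every
model; `Div = IM(M=0) = Div2(factor=1)` bit-exactly.

## Block pattern probabilities

For a non-recombining block of `n` sites, mutations of class `c` fall on
class-`c` branches as a Poisson process with intensity `λ = n θ/2` per
unit branch length.  `p(k)` is computed on the configuration chain
augmented with a per-class mutation counter capped at the requested `k_c`:
mutation events beyond a cap leave the tracked space (they can never
return, so every retained entry stays exact, not a truncation
approximation).  Phase `[0, T)` uses uniformisation of the sparse
augmented generator (Poisson-weighted powers of `I + Q/Λ`, tail cut at
1e-13); the ancestral phase needs no time limit, so the absorption
distribution is obtained by a forward pass over the jump chain in
topological order (counts only grow, lineages only merge), summing each
partition's geometric series of mutation self-transitions to machine
precision.  One pass yields the whole table `P[k′ ≤ k]`, so the bSFS
log-likelihood of a dataset costs one pass at the componentwise maximum of
the observed `k` regardless of the number of blocks.

Marginal probabilities with some classes pinned to zero (used by the
excess-block tests) set `λ = 0` for the unpinned classes, which integrates
their counts out exactly.

The panmictic invariant-block probability has the closed form
`(6/(6+4λ))(3/(3+3λ))(1/(1+2λ))`; the implementation matches it to 1e-10,
and matches the independent Gillespie simulator within Monte-Carlo error
across histories spanning the fitted parameter ranges.

## Likelihoods and fitting

* **SFS mode** fits the five-category multinomial (four classes plus
  invariant) of all-site category counts.  The four average frequencies
  support at most three free parameters, so `IM2` is not fittable here.
  The one-variable-site-per-block subsampling described for uncertainty
  estimation cannot identify θ on its own (it discards the invariant
  scale), so point estimates use the all-site counts and the subsampling
  is used inside the bootstrap.
* **bSFS mode** maximises `Σ_blocks ln p(k)` over four-gamete-compatible
  blocks (violators — blocks with both a shared heterozygous site and a
  fixed difference, the only phase-free two-site incompatibility — are
  excluded and counted).  Blocks are treated as unlinked replicates; at
  one block per orthogroup and a genetic map of thousands of cM this is
  the intended regime.

Optimisation is bounded Nelder-Mead in transformed coordinates (log10 for
`theta`, `T`, `size_factor`; linear for `M`), multi-start: one
moment-based start (θ from the geometric mean of the two heterozygosities,
`T` from the fixed-difference excess, size factor from the heterozygosity
ratio) plus log-uniform draws over the bounds, 10 starts by default.
Callers can supply extra starts, e.g. the optimum of a nested model; the
parameter-recovery experiments start `IM2` from the fitted `Div2` optimum
with `M = 1e-3`, which also guarantees the nesting inequality
`lnL(IM2) ≥ lnL(Div2)` up to optimizer tolerance.  An IM-type fit whose
`M̂` lands below 1e-4 is flagged as a boundary collapse onto the
strict-divergence model, and estimates at a bound are flagged rather than
silently reported (an effectively infinite `T̂` shows up as `T` at its
upper bound).

### Bootstrap

The 95% CIs for SFS fits use a block bootstrap: each replicate resamples
blocks with replacement, represents every resampled block by one uniformly
drawn variable site weighted by the block's variable-site count (blocks
without variable sites contribute only invariants), refits, and the CI is
the point estimate ± 1.96 SD across replicates.  The weighting keeps
replicate counts unbiased on the per-site scale while the block resampling
captures the dominant, between-block genealogical variance; the extra
within-block draw makes the intervals mildly conservative.

### Absolute conversions

`N_anc = θ/(4μ)` diploids; `t = T × 2 N_anc × g` years; mean waiting time
between effective immigrants `g/M` years; expected introgressed fraction
of the recipient genome `1 − e^{−MT}`.  Defaults `μ = 9.15×10⁻⁹` per site
per generation (a fourfold-degenerate-site rate from related
archaeobatrachian frogs) and `g = 3` years are configuration, not
estimates.

### Excess-block tests

Whether the observed number of blocks lacking a class (e.g. no fixed
differences, or fully invariant) exceeds a fitted model's prediction is
assessed with a one-sided upper-tail binomial test,
`P(X ≥ observed | n_blocks, p_model)`, with `p_model` from the pinned
marginal above.  Sidedness is a design choice: the scientific question is
about an excess.

## Synthetic data

`simulate_block_table` draws independent `k` vectors from the Gillespie
simulator — the inference input, at the study's scale (defaults: θ =
0.00154, `T` = 19.8, `M` = 0.015 B→A, factor 1.36 on A, 1,479 blocks of
150 sites).  `simulate_fixture` fabricates the upstream files: per-taxon
CDS/peptide FASTA with ~30% fourfold-degenerate codons in ~1,560 bp
contigs, VCFs with planted heterozygous SNPs realising per-orthogroup `k`
draws, droppable indel and alternate-homozygote records, planted paralog
pairs (5% uniform divergence), sub-gene paralogs (an internal ~120 nt
tract at ~55% identity), splice-isoform prefixes, cluster files over an
inflation grid with planted filtering violations, and ground-truth tables
for everything planted.  Fixture genealogies reuse the same simulator as
the verification oracle, so the pipeline and the math core share one
ground truth.

What the fixture does *not* emulate: real assembly artefacts (chimeras,
fragmented ORFs), alignment error (cross-taxon peptides are built
identical, so back-translation is exact and gap handling is exercised by
dedicated unit tests instead), mutation-rate heterogeneity across blocks,
within-block recombination, and allele-specific expression.  Passing the
round-trip therefore certifies the bookkeeping and the inference chain,
not robustness to upstream noise.

## Paralog screening parameters

The sub-gene paralog detector uses a sliding window of 100 comparable
(both-ungapped) columns, step 1; windows below 0.85 identity merge into
tracts; tracts touching an alignment terminus are excluded from the mean
identity (structural variation near ends), internal tracts of ≥ 60 columns
flag sub-gene paralogy regardless of the mean, and a remaining mean below
0.98 flags ordinary paralogy.  The 0.98 global threshold is the published
rule; the window/tract constants are this package's defaults (exon-scale
tracts, cutoffs bracketing the global rule) and are configurable.
Inflation-robustness means the non-backbone membership of a cluster is
reproduced exactly at every alternate inflation value (default grid 0.5,
1.0, 1.5, 2.0, 3.0, 5.0); backbone (outgroup proteome) contigs are ignored
in the comparison because their attachment is volatile under inflation
changes.

## Problem sizes used by the test suite

The suite verifies Monte-Carlo agreement with 10⁵ simulated blocks per
history on a six-history grid; parameter recovery uses 20 synthetic
datasets of 1,479 blocks (bSFS fits with the nested-start strategy and a
capped function-evaluation budget, which the recovery margins show is
ample); bootstrap calibration uses reduced replicate counts (B = 20–25 on
400-block datasets).  These sizes were chosen to exercise the study-scale
regime while keeping the full suite in the tens of minutes on one core.

## Known limitations

* Migration is unidirectional per fitted variant; bidirectional flow is
  represented only by comparing the two directions' fits.
* One diploid per taxon: no within-population frequency information, so
  recent growth/decline and fine-scale size history are out of reach.
* The bSFS assumes no recombination within blocks and a constant mutation
  rate across blocks; transcriptome blocks spanning long genomic regions
  violate this in real data and bias `M` and `N_e` downwards.
* The per-site linearisation of the invariant class requires small θ
  (enforced); it is exact only to first order in θ.
* `pattern_probability` cost grows with the product of requested counts;
  extremely mutation-dense blocks (far outside the fitted regime) would
  need larger boxes.
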