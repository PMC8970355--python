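# Methods

This note documents the models behind `matloci`, the parameter choices
that matter, what the synthetic-data generator does and does not emulate,
and the numerical conventions. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The simulator

### Neutral loci

A neutral locus is generated under a two-population Kingman coalescent.
Time is measured in units of 2N generations and each pair of lineages
coalesces at rate 1 per unit. Within each species, lineages coalesce
independently until the split time `T_split`; surviving lineages then
enter a single ancestral population (same size, so the population-size
ratio f = 1 throughout) and coalesce to the root. Mutations are placed on
each branch as Poisson(θ/2 × branch length), hit a uniform site, and
substitute a uniform different base. Expectations under this model:
E[π] = θ/L per site, E[d_xy] = (θ/L)(T_split + 1), so π/d_xy ≈
1/(T_split+1) for neutral genes.

The infinite-sites assumption is deliberately violated — L is finite and
sites can be hit repeatedly — so the downstream statistics see the same
homoplasy they would in real data. Consequences: realized d_xy saturates
below the Poisson expectation at high divergence, and Jukes–Cantor
corrections in the dS/dN machinery are exercised.

In codon mode the root sequence is drawn from the 61 sense codons of the
standard genetic code and every proposed change is filtered: synonymous
changes are always kept, nonsynonymous changes are kept with probability
ω, and changes creating stop codons are always discarded (thinning, not
rate rescaling — simple, and exactly reproducible).

### Balanced loci

Long-term balancing selection is emulated structurally rather than by
simulating selection coefficients: k founder sequences are derived from a
common ancestor by Binomial(L, `d_bal`) substitutions each, every strain
of *both* species draws a lineage uniformly at random, and within-lineage
variation is added by a neutral single-population coalescent with
`theta_within`, ignoring species labels. This reproduces the target
signatures directly — π ≈ d_xy, F_ST ≈ 0, positive Tajima's D (lineages
behave as intermediate-frequency super-alleles), loss of reciprocal
monophyly, and protein-level divergence between lineages far below the
86 % AAI threshold while within-lineage identity stays far above it.

The emitted genealogy is a star of within-lineage subtrees with stem
lengths proportional to `d_bal` (scale factor 50 per unit of `d_bal`).
This is an approximation, not a structured coalescent: only its topology
(which strains share a lineage) is meaningful downstream.

Balanced loci default to ω = 1 in codon mode: balancing selection on
mating specificity *maintains* amino-acid divergence between allelic
classes, so founder substitutions are not purified.

### Default study conditions

Chosen once, used by the test suite and the acceptance script:

| parameter | default | meaning |
|---|---|---|
| `n_a`, `n_b` | 10 | strains sampled per species |
| `theta` | 5 per locus | 4Nμ·L; θ_site = 0.01 at L = 500 |
| `T_split` | 5 | species split, units of 2N generations |
| `L` | 500 nt (300 in codon mode) | locus length |
| `k` | 2–5 | balanced allelic lineages |
| `d_bal` | 0.3 | per-site founder divergence |
| `theta_within` | 0.5 | within-lineage diversity |
| `omega` | 1.0 | nonsynonymous retention probability |

`d_bal` = 0.3 puts between-lineage protein identity far below 86 % (about
two thirds of codons carry at least one nucleotide change, most of them
amino-acid-changing), while `theta_within` = 0.5 over a 300 nt gene keeps
within-lineage identity near 100 % — a wide, realistic separation matching
mating-gene allelic classes, which diverge by tens of percent at the
protein level while classes themselves stay nearly invariant. Lineage
frequencies are uniform by default (no allele-frequency spectrum for
mating alleles is available to calibrate against); a `lineage_freqs`
hook exists.

### The pheromone-region fixture

`plant_pheromone_fixture` builds a ~50 kb contig containing two STE3
placeholder features, two true precursor ORFs (one canonical CaaX, one
CpaX on the reverse strand) and four decoys each violating exactly one
scanner filter (90 bp, 210 bp, no motif, 14 kb from any STE3). The
background sequence is generated base by base so that it never completes
an ATG or CAT triplet — i.e. no start codon on either strand outside the
planted ORFs — and the planted ORFs use a codon table chosen so their
interiors contain no secondary start codons either. The construction is
verified against the scanner itself at build time; the accepted set must
equal the planted truth.

## Per-gene statistics

**Missing data.** Two policies, by the nature of the statistic:
segregating sites S and the mean pairwise difference count k̂ that enter
Tajima's D use *complete deletion* (a column containing any gap or
ambiguity in any selected strain is dropped), so numerator and denominator
of D are computed on the same column set. π and d_xy are *pair*
properties and use pairwise deletion. `N` (DNA) and `X` (protein) count
as missing; the only gap character is `-`.

**F_ST** is Hudson's estimator, 1 − ((π_A+π_B)/2)/d_xy, undefined (null)
when d_xy = 0, and reported as computed — negative values are meaningful
(within-diversity exceeding between-divergence) and are not clamped.
π/d_xy is reported per species, two values per gene.

**Tajima's D** follows the 1989 constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁,
e₂); D is null at S = 0 and a warning is issued for n < 4 where the
variance terms are unstable.

**dS/dN** uses Nei–Gojobori (1986) with equal-weight pathway averaging
and Jukes–Cantor correction (d = −¾ ln(1 − 4p/3), null at p ≥ ¾) — a
self-contained estimator that an exhaustive neighbour-enumeration oracle
can check exactly, rather than the ts/tv- and codon-frequency-aware
yn00 model. Conventions: per-codon synonymous sites are the fraction of
single-base neighbours that are synonymous, with changes to stop codons
counted as nonsynonymous so sites always total 3 per codon; multi-step
codon differences are averaged over all orderings of single steps, paths
through stop codons excluded with weights renormalised; codon pairs whose
every path is blocked are skipped with a warning; codons containing gaps
or N are skipped pairwise. Gene-level values are medians over all
within-species and between-species sequence pairs. For balanced loci the
within/between dS ratio sits near 1 (lineages are shared), for neutral
loci well below 1 — the trans-species polymorphism diagnostic.

## The multilocus HKA test

The classical 1987 method-of-moments fit with f = 1. Inputs per locus:
focal-species sample size nᵢ, segregating sites Sᵢ on complete-deletion
columns (over focal *and* sister strains, so polymorphism and divergence
are surveyed on identical sites, L_pol = L_div), and divergence Dᵢ in
difference-count units. The moment equations

    Sᵢ + Dᵢ = θᵢ (L_pol,i·a(nᵢ) + L_div,i·(T+1)),   a(n) = Σ_{j<n} 1/j

are closed by solving Σᵢ Dᵢ = Σᵢ θ̂ᵢ(T)·L_div,i·(T+1) for T̂ by bisection
on the strictly monotone residual (tolerance 1e-10, T̂ clamped to 0 when
the residual is non-positive at zero). Expectations and variances are the
classical ones — Var[S] = E[S] + (θL)²·Σ1/j², Var[D] = E[D] + (θL)² — and
the per-locus partial is the locus's additive contribution to X²
(df = L−1, chi-square upper tail).

**Divergence observation.** D is, by default, the difference count of one
deterministic cross-species pair (the first strain of each species):
exactly the quantity whose sampling variance the classical Var[D]
describes. Averaging D over all cross pairs is available
(`divergence="mean"`) but shrinks the sampling variance below the model's
Var[D] (measured 26 vs 40 at T = 2 and 45 vs 55 at T = 5 under the default
conditions), which makes an already-approximate test distinctly more
conservative; the single-pair observation is therefore the default.

**Known limitation — test size.** Even with the matched observation, the
chi-square approximation under-rejects at desk-scale counts: with 10 loci,
n = 10 and E[S] ≈ 14 the measured size at nominal α = 0.05 is ≈ 0.015–0.02
(the test is valid — size below nominal — just conservative). The cure
would be a coalescent-simulation null, which is out of scope here.

**Known limitation — partial attribution.** For an extreme locus both the
deviation S − E[S] and the model standard deviation scale with θ̂L, so the
partial's z-scores saturate (≈ 4 under the default conditions) while the
maximum over many neutral loci can exceed that by chance; with few loci
the extreme locus additionally drags T̂ toward itself. Partials therefore
rank candidate loci noisily in small panels, even though the *global* X²
retains good power (measured rejection 0.60 for 9-neutral+1-balanced
panels against a 0.02–0.03 neutral calibration). In genome-scale panels
(hundreds of background genes) the partial column is used as one voice
among several in the outlier scan, not as a standalone detector.

## Allelic classes, trees, monophyly

AAI between two aligned proteins is 100 × (identical non-gap positions) /
(positions where at least one sequence is non-gap); gap-vs-residue is a
mismatch, gap-vs-gap columns are excluded. Classes are single-linkage
clusters of the AAI ≥ τ graph (τ = 86.0; allelic classes are described in
the field by identity *above* 86 %, leaving the boundary case open, so
the inclusive convention is fixed here and documented); single linkage
matches the
chain-within-clade structure of allelic classes and admits an exact
connected-components oracle. Average linkage (UPGMA cut at 100 − τ) is
available for exploration. Class labels are canonical — decreasing size,
ties by lexicographically smallest member — so output is invariant to
input order.

Neighbor joining (Saitou–Nei) runs on d = (100 − AAI)/100 with Q-matrix
ties broken by the smallest index pair, making the tree deterministic;
negative branch-length estimates are reported as computed. A class is
*clade-concordant* when its strain set or that set's complement is a
split of the unrooted tree (i.e. the class is a clade under some
rooting). Reciprocal monophyly is tested after rooting on a named
outgroup (species tips must form a clade); without an outgroup the
unrooted split criterion is used — this is the form applied to simulated
genealogies, which have no outgroup.

Where tree and AAI classification conflict, the conflict is reported
(per-class concordance flags), not adjudicated.

## Mating types and compatibility

A *complex class* is the joint (HD1, HD2) pair label, compared as a
tuple — so strains differing only at bHD1 carry distinct beta complexes
(flagged in output; whether that suffices in vivo is untested). Predicted
type counts are free-combinatorial products (#alpha × #beta, #STE3.2 ×
#STE3.4, and their product), the field's convention, although HD pairs
within a complex are physically linked and do not recombine freely —
observed distinct tuples are reported alongside the products.

Compatibility: a cross is compatible iff (alpha differs OR beta differs)
AND (STE3.2 differs OR STE3.4 differs), where "differs" requires both
values present and unequal; verdicts hinging on a missing component are
`indeterminate`, and a definite "all components equal" on either locus is
`incompatible` regardless of missing data elsewhere (self-crosses are
incompatible, not errors). The predicate is symmetric by construction.
Genotypically compatible *inter-species* crosses carry a cautionary note:
pre-zygotic barriers make genotypic compatibility necessary but not
sufficient across species.

Parental unfolding collects the distinct classes per gene among sibling
monokaryons of one specimen: more than two classes contradicts a single
dikaryotic parent and is an error; exactly two per MATA and MATB
component marks the unfolding complete; identical siblings leave it
incomplete.

## Pheromone scanner

ORFs (ATG→stop, both strands, nested starts reported independently) are
kept when their length *including the stop codon* is within [100, 200] bp,
inclusive. The last four residues of the peptide are the motif: C at
position 1 and aliphatic {A, V, L, I} at positions 2–3 is CaaX; a polar
position 2 (default set {T}, the observed variant; {S,T,N,Q} available)
with aliphatic position 3 is CpaX. The maturation site is the rightmost
ER or DR dipeptide strictly upstream of the motif cysteine, and the
mature peptide runs from the residue after that R through the cysteine
inclusive (the alternative boundary including the E/D is behind a flag);
mature lengths outside [8, 15] are accepted with a warning, since the
canonical product is only approximately 10–11 residues. Distance to the
nearest STE3 feature is the gap between intervals (0 when overlapping),
with acceptance within `max_dist_bp` = 5000 — no exact figure for "close
proximity" exists, and 5 kb spans the internal gaps of a ~30 kb MATB
region while excluding unlinked ORFs; it is configurable. Output is
sorted by (contig, start, strand).

## Outlier scan

Per statistic (π/d_xy and Tajima's D per species, within-species dS per
species, partial HKA — all "high"; F_ST "low"), the tail threshold is the
floor((1−q)·m)-th smallest of the m non-null values and genes strictly
beyond it are flagged, so the flag set is the top ceil(q·m) values and
ties at the threshold are never flagged (with 200 genes and q = 0.01,
exactly the top 2). dN is reported but not flagged by default. The
percentile background is *all* genes, mating genes included (deviation is
measured against the genome, and the handful of mating genes barely moves
a genome-wide quantile); a background-only option exists. A gene flagged
in at least `min_flags` (default 2) statistics is a candidate.

## Numerical conventions and problem sizes

- All randomness flows through `numpy.random.default_rng`; every
  simulation function takes an explicit seed and identical seeds give
  byte-identical outputs. Panel generation derives per-gene seeds as
  master + gene index.
- Coordinates are 1-based inclusive in every file format and 0-based
  half-open internally; conversion is confined to the I/O module.
- HKA bisection: tolerance 1e-10, 200 steps, bracket doubling from 1.
- The test suite and acceptance script size their simulations for
  laptop-scale runs: 500 replicates for HKA calibration, 200 × 20 loci
  for parameter recovery, 100 balanced loci for allelic-class recovery
  and the trans-species signature, and a 104-gene panel (100 neutral + 4
  balanced) for the end-to-end scan. These sizes give Monte-Carlo
  standard errors comfortably inside the asserted margins for every
  property except the HKA calibration band, whose lower edge the
  conservative chi-square genuinely undercuts (see above).

## What the generator does not emulate

No recombination within loci (real mating regions show both suppressed
recombination and occasional exchange), no migration or
population structure within species, no intersterility groups, no gene
loss/duplication events (bHD1 loss and xHD2 duplications are handled at
the genotype level, not simulated), no selection coefficients beyond
ω-thinning, no alignment error, assembly gaps or annotation noise, and
uniform allele frequencies rather than the unknown real spectrum of
mating alleles. Passing tests therefore demonstrate that the statistics,
clustering, census and scanner recover planted structure of the assumed
form — they do not certify performance on misaligned, recombinant or
structured real data.
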