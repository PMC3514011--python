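# Methods

This note documents the statistical machinery of `thermoclade`: the models
and conventions each stage uses, the defaults and why they were chosen, what
the synthetic-data generators do and do not emulate, and known limitations.

## Sequence handling and haplotypes

All sequence statistics operate on an `AlignedSeqSet`: equal-length,
upper-cased nucleotide sequences with unique labels.  Alignment columns are
0-based and windows are half-open `[start, end)`, which keeps window
arithmetic unambiguous (`end - start` is the window length).  Gaps are
treated as ambiguity symbols throughout: COI is protein-coding and indels
are not expected, so a gap in an alignment of COI fragments is missing
data, not a character state.

Haplotype collapsing defaults to the `mask` policy: any column containing
an ambiguity code, `N` or gap in *any* record is excluded set-wide before
identity comparison.  This matches the behaviour of the haplotype
collapsers commonly used in barcoding pipelines and guarantees that two
records differing only at an unreadable position are not split into
artificial haplotypes.  A `strict` policy (any ambiguity is an error,
offending columns listed) is available for auditing clean datasets.
Haplotypes are numbered `H1, H2, ...` in descending frequency with ties
broken by first occurrence, so output is deterministic.

Strand orientation is assumed correct on input; no reverse-complement
detection is attempted.

## Distances

`k2p_distance` implements the Kimura two-parameter distance

    d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q)

with P and Q the transition and transversion fractions over
pairwise-complete sites.  Ambiguous sites are deleted *pairwise* rather
than set-wide — pairwise deletion maximises the usable signal per pair and
is the convention of standard distance software; it is deliberately
different from the set-wide masking used for haplotype identity, and both
choices are fixed so results are reproducible.  When `1 - 2P - Q <= 0` or
`1 - 2Q <= 0` the distance is undefined (saturation) and the pair is named
in the error; there are no silent NaNs.

Net divergence between clades X and Y is

    d_net = d_between - (d_within,X + d_within,Y) / 2,

the usual correction for ancestral polymorphism.  A singleton group
contributes within-group divergence 0 (the mean over zero pairs is
otherwise undefined); this is the convention needed to report net
divergence for clades represented by a single sequence.  Distances are
stored as proportions; the CLI prints percentages with one decimal.

## Diversity indices and Tajima's D

For one population sample the package reports n, K (haplotypes), S
(segregating sites), S/n, nucleotide diversity π (mean pairwise proportion
of differing sites) with a dispersion estimate (standard deviation of the
per-pair proportions), and Tajima's D.  S, π and D are computed over the
columns that are unambiguous in every record (complete deletion), keeping
the three statistics consistent with each other and with masked collapsing.

Tajima's D uses the standard constants a1, a2, b1, b2, c1, c2, e1, e2
computed from n, with π̂ the mean pairwise *count* of differences:

    D = (π̂ - S/a1) / sqrt(e1 S + e2 S (S - 1)).

Significance is judged against a simulated null: neutral Kingman
genealogies for the observed n with exactly the observed S mutations
dropped onto branches in proportion to branch length (fixed-S
conditioning).  Fixed-S conditioning removes the nuisance parameter θ and
matches the convention of the classic simulation tools; a θ-conditioned
mode could be added but is not needed for the fixed-S tests here.
P-values use the add-one rule p = (1 + #{D_sim ≥ D_obs}) / (m + 1), so a
Monte-Carlo p of exactly 0 is never reported, and ties count toward both
tails (hence p_upper + p_lower ≥ 1).  Fewer than 100 replicates is
rejected as unstable.

## AMOVA

AMOVA partitions squared-distance variance using Excoffier-style sums of
squares, SS = Σ d²/(2N) within the relevant index sets.  The two-level
design (populations nested in groups) yields variance components σ²_a
(among groups), σ²_b (among populations within groups) and σ²_c (within
populations) via the standard unbalanced-design coefficients, and

    Φ_CT = σ²_a/σ²_tot,  Φ_SC = σ²_b/(σ²_b+σ²_c),  Φ_ST = (σ²_a+σ²_b)/σ²_tot.

Negative variance components are retained and reported as-is — truncating
them to zero would hide exactly the spatially-dispersed-but-locally-
structured signatures this analysis is meant to reveal (a strongly negative
Φ_CT is a legitimate, interpretable outcome).

Permutation schemes follow the hierarchy: individuals among all
populations for Φ_ST, individuals among populations within their group for
Φ_SC, and whole populations among groups for Φ_CT; 5 000 permutations by
default, add-one p-values.  The default distance is the K2P matrix
(nucleotide-level variation); a haplotype-frequency-only AMOVA is obtained
by supplying a 0/1 distance matrix instead, since the statistic is defined
on any squared-distance matrix.

`pairwise_phi_st` runs the one-level design on every pair of populations.

## Median-joining networks

Haplotype networks are built by the median-joining procedure: start from
the ε-relaxed minimum spanning network (MSN) on Hamming distances — with
ε = 0 the MSN contains every minimum spanning tree, i.e. all tied
alternative connections — then iteratively consider triplets with at least
two MSN links and their columnwise consensus (median) vectors.  Columns
where all three states differ branch into one candidate per observed state
(quasi-medians, capped at 3⁴ candidates per triplet).  In each round the
candidate medians of minimal connection cost are added as a batch, but only
if the batch strictly reduces the minimum-spanning cost of the node set;
this guarantees the total network cost never increases and the procedure
terminates.  Median vectors left with fewer than three neighbours are
pruned iteratively.  ε defaults to 0 (strict MJ), matching typical
published usage.  Tie-breaking is lexicographic by (steps, node order), so
output is invariant to input order.

Character states are restricted to A/C/G/T; ambiguous columns must be
masked upstream (the haplotype collapser's default already does this).

### Statistical-parsimony connection limit

Edges are flagged confident when their mutational steps do not exceed a
connection limit computed from the analysed window length — never
hard-coded, so 489- and 388-site windows get their own limits.  The limit
is the largest j for which the parsimony probability exceeds the chosen
confidence (0.95 by default).  The probability model is a finite-sites
computation in the spirit of statistical parsimony: the observed proportion
of differences p = j/m is corrected to a per-site expected hit count
λ = -(3/4) ln(1 - 4p/3) (Jukes-Cantor); per-site hits are Poisson(λ); and
parsimony requires every differing site to carry exactly one hit and every
identical site none, giving

    P_j = [λe^{-λ} / ((3/4)(1-e^{-4λ/3}))]^j · [e^{-λ} / (1/4 + (3/4)e^{-4λ/3})]^{m-j}.

P_0 = 1 and P_j decreases monotonically in j.  Beyond the saturation point
of the correction (p ≥ 3/4) the divergence is evaluated just inside the
domain so the probability stays finite and the limit degrades gracefully to
the window length as the required confidence approaches zero.  For a
489-site window at 95 % the limit is 7 steps — slightly conservative
relative to older heuristics, which is the safer direction for flagging
tentative long connections.  A fixed step threshold can be imposed directly
through `flag_edges` for users who prefer a hard rule.

## SST analysis

The weighted median SST of a clade is the median of the multiset in which
each occurrence row contributes `count` copies of its SST; even-sized
multisets take the mean of the two middle values.  The bootstrap CI
resamples 20 units with replacement for 1 000 replicates and reports the
2.5/97.5 percentiles of the replicate medians.  The default resampling unit
is the colony (rows expanded by count); a site-level unit (one value per
row) is provided because "resampling populations of individuals" is
ambiguous between the two readings.

Spatial distances are Euclidean on raw decimal degrees (latitude,
longitude) — deliberately not great-circle, matching the convention of the
analysis this package reproduces; a haversine mode exists but is off by
default.  SST distance is |SST_i - SST_j|; clade occurrence enters as 0/1
presence/absence indicator dissimilarity (pairwise tests) or as a
multi-clade mismatch distance, 0 iff two units share a phylogroup
(all-groups test).

The partial Mantel statistic vectorises the strict lower triangles,
rank-transforms them (mean ranks for ties; ranking linearises monotone
relationships between dissimilarities), and computes the first-order
partial correlation of A and B given C.  Significance comes from 10 000
simultaneous row/column permutations of A, one-sided (greater) by default,
with the add-one rule.  Because permuting A only rearranges the same
multiset of triangle entries, the rank transform commutes with the
permutation and is applied once.

The default analysis unit is one colony.  Colony units weight sites by
sampling effort and match the reported per-clade sample sizes; the
site-unit mode is provided as a sensitivity check.  Units from the same
site are mutually at distance zero in C, which the rank transform handles
by mean ranks.

## Zooid morphometrics

Zooid and orifice areas use the ellipse approximation (π/4)·L·W; zooids
are approximately elliptical and, since the ANCOVA operates on log10 areas,
any fixed shape factor shifts intercepts only — a rectangle (L·W) mode is
provided to make that explicit.  The data model stores the four recorded
dimensions (zooid length and maximum width, orifice length and width).

The ANCOVA fits log10(orifice area) ~ log10(zooid area) + group, testing
the group term by nested-model sum-of-squares F against the
covariate-only model, and slope heterogeneity by adding the interaction.
A Levene test of residual variance across groups is reported as the
homogeneity-of-variance diagnostic.  The zooid-length cline is an ordinary
least-squares regression of length on SST at colony level (site-mean
aggregation is left to the caller), reporting slope, intercept, R² and the
slope t-test p.

## Synthetic data

The generators produce data with the statistical structure the pipeline
assumes, so every stage can be tested end-to-end without downloads.  All
are pure functions of (config, seed).

**Sequences.**  Clade ancestors sit on a star topology, each at
`net_divergence_target`/2 expected substitutions per site from a common
random root — a star suffices because only pairwise net divergences are
targeted.  Within each clade a Kingman coalescent genealogy is simulated
(hand-written; the `msprime` package is reserved for use as an independent
oracle in the tests) and sequences evolve site-independently under the K2P
transition matrix (exact matrix exponential) with transition/transversion
rate ratio κ = 2.  Defaults: 2 clades, target 0.15 substitutions/site
(mid-range for deep COI splits of order 12–24 %), θ = 5 per locus over 500
sites (π ≈ 0.01, shallow within-clade variation), 20 sequences per clade.
A target that would saturate the K2P formula is rejected up front.

**Occurrence.**  15 sites span 10–27 °C with latitude decreasing toward
warm sites; each clade's colony count per site is
Binomial(`colonies_per_site` = 20, p) with the Gaussian niche occupancy
p = exp(-(SST - centre)²/2w²); zero-count rows are dropped.  Binomial
rather than Poisson keeps counts bounded by sampling effort, mirroring
fixed-effort dock surveys.  Default niche centres 12 and 18 °C with width
2.5 °C give overlapping but separable thermal envelopes like those seen
across the real SST gradient.

**Zooids.**  Length is linear in SST (base 1.1 mm, slope -0.02 mm/°C,
Gaussian noise σ = 0.05 mm, truncated positive), consistent with zooids
roughly 25 % longer at the cold end of a ~7 °C gradient; widths and
orifice dimensions scale allometrically with multiplicative log-normal
noise, with an optional per-clade log-area offset for programming group
differences.

What the generators do *not* emulate: recombination-free but
selection-free evolution only (no codon structure, so simulated "COI" has
no reading frame), no migration or temporal invasion dynamics, no spatial
autocorrelation of occupancy beyond the SST gradient itself, and no
measurement error structure in morphometrics beyond i.i.d. noise.  Passing
recovery tests therefore demonstrates the estimators' correctness and
calibration under the assumed models, not robustness to real-data
violations of them.

## Numerical choices and degenerate inputs

- Permutation and bootstrap p-values always use the add-one rule; minimum
  replicate counts (100) are enforced.
- All randomised procedures take explicit seeds and are reproducible
  bit-for-bit; the CLI records the seed in every run manifest.
- Saturated K2P pairs, zero-variance Mantel matrices, degenerate AMOVA
  designs (single group, all-zero distances, no within-population
  replication), constant regressors and non-positive zooid dimensions all
  raise typed errors naming the offending object rather than propagating
  NaNs.
- Defaults follow the study conventions: 5 000 permutations for AMOVA and
  the Tajima null, 10 000 for Mantel tests, 1 000 bootstrap replicates of
  size 20, 95 % network confidence.

## Known limitations

- The AMOVA permutation schemes assume exchangeability of individuals
  (Φ_ST, Φ_SC) and populations (Φ_CT); with very few populations per group
  the Φ_CT permutation distribution is coarse and its p-values granular.
- The median-joining implementation targets the small haplotype sets
  typical of single-locus studies (tens of haplotypes); its triplet scan
  is quadratic-cubic and not tuned for genome-scale inputs.
- The fixed-S Tajima null conditions on the observed number of segregating
  sites; for very small S the null distribution is discrete and p-values
  are correspondingly coarse.
- Weighted medians of small colony multisets are step functions of the
  counts; a one-colony change can move a clade median by a whole SST bin,
  which is a property of the data, not the estimator.
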