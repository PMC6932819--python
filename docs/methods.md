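# Methods

This note documents the models implemented in `squich`, the choices made
where the design was genuinely open, and what the simulations do and do not
show about real experiments.

## Truth model

A population is a multiset of species with exact integer molecule counts
`n_i` (≤ 10¹⁵, exactly representable in int64 and in double precision).  All
protocol arithmetic is integer-exact so conservation can be asserted
exactly.  Fractional fold changes round half-up to whole molecules.  Species
identity is positional; oligo sequences attach only in `squich.codes`, which
decouples the sampling theory from probe design.

The four population builders encode the study conditions used throughout:
one 10¹⁵-molecule background species plus 20 "needles" at 100; a 2-fold
enrichment of 20 species over 262,124 background species at level 100
(the full 2¹⁸ CGA codebook); 10 species at each abundance x·10ʸ (x = 1..10,
y = 0..9) plus 3000 background species at 100; and a single pseudo-cell with
2587 basal transcripts at 100, 10 transcripts at each x·10ʸ (x = 1..9,
y = 0..4) and 100 transcripts at each level 1..10.  The dynamic-range
background count is a parameter (default 3000) because only its approximate
size is pinned down by the regime it emulates.

## Round chemistry

One round exposes each species to encoder amount `E_r` and competitor
amount `C_r`.  Two imperfection parameters:

* `eta` (default 0.95) — per-molecule reaction efficiency.  With probes in
  excess, a fraction `eta` of encounters succeeds; the unreacted remainder
  carries over to later rounds.  The default represents conservative but
  workable hybridization; it is configurable everywhere.
* `eps` (default 0.01) — relative cross-hybridization weight of a
  substitution-distance-1 neighbor.  Rather than modeling the equilibrium
  thermodynamics of real oligo mixtures, cross-hybridization is a
  parametric two-pass allocation: pass 1 satisfies each species' perfect-match demand
  `min(eta·free, E+C)`; pass 2 offers each species' *leftover* capacity,
  scaled by `eps`, to its distance-1 neighbors in proportion to their
  residual demand.  No leakage beyond distance 1.  This captures the
  qualitative effect (closely related codes degrade each other's capacity
  limits) with one interpretable parameter, and vanishes for codebooks with
  minimum distance ≥ 2.

Reacted molecules split into coded (tagged, sampleable) vs destroyed in
proportion to the encoder fraction of the capacity offered — when probes
are in excess they compete for binding, which is exactly what makes
last-round occupancy informative about the leading digit of the abundance.

**Expectation mode** rounds the mean allocation to whole molecules with
largest-remainder rounding (ties to the encoder side) so that
`coded + destroyed + free_after == free_before` holds exactly.  One
deliberate floor: whenever at least one molecule reacts and encoder
capacity is present, at least one molecule is coded.  This is the
deterministic limit of "up to n are captured and tagged" and preserves the
interval-bracketing property `T_{r*-1} < n ≤ T_{r*}` for every abundance;
it is never more than one molecule away from the proportional mean.

**Stochastic mode** draws `reacted ~ Binomial(free, min(1, eta·K/free))`
capped at the offered capacity `K` (ceiling for fractional leaked
capacity), then `coded ~ Binomial(reacted, Ê/K)`.  Note the two modes have
slightly different means when probes are in excess (`free` vs `eta·free`);
the stochastic form treats `eta·K/free` as a per-molecule success
probability, the expectation form as a capacity discount.  All headline
simulations use stochastic mode; expectation mode is the analysis/oracle
limit.

## Protocol, sequencing, SRS

`run_protocol` threads free molecules through the schedule and accumulates
the coded pool `m_{i,r}`.  Schedules are per-round scalars or per-species
vectors; the `geometric` factory implements constant encoders with a
10-fold capacity growth per round (one abundance decade per round), the
default design for the detection and dynamic-range scenarios (16 rounds,
encoder amount 10).  The encoder default of 10 per round follows the
design that also resolves first significant figures, not just orders of
magnitude.

Sequencing draws without replacement (multivariate hypergeometric over the
(species, round) cells), since the pool is a finite physical library; a
depth at or above the pool size returns the pool (exhaustive sampling).  A
`with_replacement` flag switches to multinomial resampling.  The SRS
baseline samples the *original* population with replacement: exact
multinomial up to depth 10⁷ and totals within float64's exact-integer
range, otherwise independent per-species Poisson draws with mean
`depth·n_i/total` (the standard small-fraction approximation; the switch
depends only on problem size, so it is seed-stable).  Replicates use
independent seeded substreams spawned from one master seed.

## Estimators

* `sem_interval`: last observed round r* brackets the abundance in
  `(T_{r*-1}, T_{r*}]`; never observed means not detected (point 0).  A
  species still saturating the final round is flagged *censored*: its true
  abundance may exceed the upper bracket (a 16-round decade schedule can
  only say "> T_R" beyond its range).  Intervals are always reported as the
  bracket; censoring is a flag, not an infinite bound.
* `sem_point`: `n̂ = T_{r*-1} + K_{r*}·min(1, c_{i,r*}/q_{r*})`.  The
  full-occupancy level `q_r` is the median count among species still tagged
  in round r+1 (they necessarily consumed all of round r's capacity).
  Rounds without calibrators — typically the last informative round —
  inherit the calibrated per-encoder read level scaled by their encoder
  amount, since at full occupancy reads scale with encoders offered.
  Final fallbacks: the max count in the round, then 1.  `tau_reads`
  (default 1) is the per-round evidence floor.  The estimator reduces to
  the interval logic in the deterministic limit and recovers abundances
  exactly when occupancy denominators are exact; it is registered as the
  "sem" strategy so an alternative reconstruction can be slotted in.
* `call_enriched`: for screens where the schedule exhausts the background
  level before an encoder-only final round, the final-round count is the
  evidence statistic.  Background leakage (unreacted carry-over) is modeled
  as Poisson with mean estimated by the upper-quartile mean of final-round
  counts (an upward-biased, hence conservative, null estimate); the
  threshold is the smallest k with `S·P(Pois(μ) ≥ k) ≤ α` — Bonferroni
  family-wise control, chosen because the headline claim is zero false
  positives across ~262k species, for which FWER control is the natural
  match.
* `srs_point`: raw counts, detected iff count ≥ 1.

## Scenario schedules

Simulation 2 (fold change) uses competitor-only rounds (100, 20, 5)
followed by an encoder-only round of 100.  The margin above the background
level absorbs the stochastic tail of unreacted background molecules: with
`eta = 0.95`, ~5 molecules per background species survive round 1, a tail
that reaches ~20; the tapering rounds exhaust it before encoders appear, so
background species contribute no tagged molecules at all and false
positives are controlled by design, while enriched species (level 200)
retain ~80 molecules for the final round.  This is the "modulate competitor
amounts to tune FP and FN separately" design point.

## Metrics

Dropout counts *species* with truth > 0 and no detection; a
molecule-weighted counter is also emitted because the species/molecule
reading is ambiguous in this setting.  log-MSE uses base 10 (the scenarios
are decade-structured) and floors both estimate and truth at 1 molecule so
undetected species contribute a finite `(log₁₀ n)²` penalty.  Correlations
are plain Pearson/Spearman over all species; undefined cases (zero
variance, empty positive set) are reported as absent, not errors.

## Analytic bounds

The two-species detection bounds use the natural logarithm (the base only
rescales both sides identically).  The leading digits x₁, x₂ are carried in
the query object but do not enter the bounds.  `srs_detection_prob` is the
Poisson closed form `1 − exp(−depth·n/N)` used to validate the SRS sampler.

## Codebooks and reads

CGA codebooks: the 2ⁿ targets `A[(C/G)A]ⁿ`, with bit k of the index
selecting C/G at base 2k+1 (most significant bit first).  Distance-1
neighbors are single bit flips, computed arithmetically.
`select_min_distance` is the greedy lexicographic sphere-packing selection.
Round tags are 6-mers over {A, C, T} with a ternary parity digit (pairwise
Hamming distance ≥ 2, ≥ 243 rounds).  Probe and read layouts are schematic
sequence bookkeeping: terminator chemistry is represented by a fixed motif
and not simulated, and the real experimental sequence dialect (degenerate
bases) is out of scope.  Read decoding is strict exact-match; 1-mismatch
rescue is allowed only for codebook subsets with minimum distance ≥ 3.

## Problem sizes and reproducibility

The bundled scenario presets default to 1000 replicates for
needle-in-haystack and 100 elsewhere; the acceptance script and the
end-to-end tests run 100 replicates per scenario, which resolves the
reported quantities well (binary outcomes are extreme — recall misses and
false positives have per-replicate probabilities below 10⁻⁵ at the chosen
schedules — and the dropout means have sub-percent standard errors).
Every run is determined by (config, seed).

## Known limitations

* The cross-hybridization model is a parametric stand-in, not equilibrium
  thermodynamics; with the default `eta = 0.95, eps = 0.01` the simulated
  chemistry is cleaner than a wet-lab library (no synthesis errors, no PCR
  bias, no sequencing errors inside the protocol path), so dynamic-range
  dropout is lower than a real experiment would show.
* Expectation and stochastic modes differ slightly in mean when probes are
  in excess (see above).
* Populations are single pools; the single-cell scenario is one
  pseudo-cell, not a cell-by-gene matrix.
* SRS dropout at a given depth depends on the assumed background complexity
  of the dynamic-range population; the background count is exposed as a
  parameter rather than fixed.
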