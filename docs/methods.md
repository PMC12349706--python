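# Methods

## The generative model

A meiosis is simulated on a single bivalent whose genetic axis carries
three linked markers defining two adjacent intervals, I1 and I2 (lengths
`d1`, `d2` in cM; optional flanking lengths on either side).  Positions are
handled internally in Morgans; every interface takes cM.  Intervals are
half-open `[left, right)`.

Crossovers arise from two independent, superposed point processes:

* **Class I (interfering).**  A stationary gamma renewal process with
  inter-event distances `Gamma(shape = nu, mean = 1/rate1)`.  `nu = 1`
  recovers the homogeneous Poisson process (no interference); larger `nu`
  gives more evenly spaced events.  Stationarity comes from drawing the
  first event from the equilibrium (length-biased residual) distribution,
  sampled exactly via the identity that a length-biased
  `Gamma(nu, scale)` interval is `Gamma(nu + 1, scale)` and the residual is
  a Uniform(0,1) fraction of it.  The expected event count over a span `S`
  is then exactly `rate1 · S` and the placement of the marker triplet on
  the bivalent is statistically irrelevant — which is why the flanks
  default to zero.
* **Class II (non-interfering).**  A homogeneous Poisson process with rate
  `rate2`.

With `total_rate` the expected CO number per bivalent per Morgan and
`frac_class2` the Class II share, `rate1 = (1 − frac_class2) · total_rate`
and `rate2 = frac_class2 · total_rate`.  The two pathways do not interact;
no cross-pathway interference, chromatid interference, or obligate-CO rule
is imposed.

Each crossover joins one chromatid from each homolog, chosen uniformly and
independently (all four non-sister pairings equiprobable).  **Exchange
semantics matter:** a crossover cuts the two *original* chromatids at its
position and rejoins them crosswise, so a meiotic product follows its
strand through each exchange (transpositions composed left-to-right at the
value level).  Modelling the exchange as a swap of the current *contents*
of two product slots is subtly wrong — it renders three-strand double
crossovers phenotypically cryptic and biases the coefficient of
coincidence toward 0.5 under independence.  Under the correct semantics
every crossover is phenotypically visible, the no-interference CoC is 1,
and Perkins distances are unbiased regardless of flanking length.  The
test suite pins all of this.

Markers are in coupling: one parent carries all three fluorophores.  A
spore's phenotype at a marker is the parental origin of its strand at that
position; 2:2 segregation holds by construction.  `simulate_sample` is a
batched implementation of the same process (per-column renewal draws, then
vectorised strand bookkeeping per marker) and is deterministic given
`(map, params, seed, n)`; a chi-square test checks it against the
per-tetrad generator.

### Default parameters

| parameter | default | meaning and rationale |
|---|---|---|
| `nu` | 8 | gamma shape of Class I spacing; strong interference of the magnitude seen in Arabidopsis male meiosis |
| `frac_class2` | 0.15 | Class II share of COs; Arabidopsis Class II is ~10–20% of total |
| `total_rate` | 2 /Morgan | expected COs per bivalent per Morgan; a single CO recombines 2 of 4 chromatids, so this value makes recombinant-spore fraction equal map distance |
| `d1`, `d2` | 10 cM | generic adjacent-interval geometry used for calibration runs |

## Tetrad classification

Restricted to either marker pair a tetrad is a parental ditype (P),
tetratype (T) or non-parental ditype (N).  Jointly, brute-force enumeration
of all chromatid assignments of 0–2 crossovers per interval yields exactly
**12 distinguishable phenotype multisets**, lettered A–L in a documented
canonical order: A=(P,P); B=(T,P), C=(P,T); D=(N,P), E=(P,N);
F,G,H,I=(T,T) — the two-strand, two three-strand and four-strand
configurations of an across-interval double crossover, all distinct;
J=(T,N), K=(N,T); L=(N,N).  Letters are presentation: all estimators
depend only on the ditype pairs, the letter key is written into every CSV,
and a remap facility converts foreign letter conventions via their ditype
pairs.  Spore order never matters (multiset logic).  Complementing all
phenotypes (swapping which parent carries the fluorophores) preserves every
ditype pair and exchanges only the two three-strand (T,T) classes, which
are mutual complements.  Tetrads violating 2:2 segregation go to an
explicit overflow category and are counted, never silently dropped —
mirroring FTL scoring practice, where aberrant tetrads are excluded.

## Estimators

**Perkins distance.** `X = 100 (T/2 + 3·NPD)/n` cM per interval, with the
multinomial delta-method SE
`Var(X)/100² = [t(1−t)/4 + 9q(1−q) − 3tq]/n` for `t = T/n`, `q = NPD/n`.
On 50,000 simulated tetrads it recovers interval lengths within 0.5 cM up
to 15 cM, with or without interference.

**CoC and interference.** `f1`, `f2`, `f12` are fractions of *tetrads*
recombinant (T or N) in I1, I2 and both; an NPD is not double-weighted
(an alternative CO-number weighting is exposed as an option).
`CoC = f12/(f1 f2)`, interference `= 1 − CoC`.  The SE comes from the
delta method on the multinomial 2×2 recombinant/non-recombinant table; a
seeded tetrad-resampling bootstrap is the reference implementation and
agrees within 15% at the sample sizes used.  `f1 = 0` or `f2 = 0` is an
error carrying the counts; `f12 = 0` with positive marginals yields
interference exactly 1 with a `no_doubles` flag — an observation, not an
error, since short intervals routinely show no doubles.

**Genotype comparisons.**  CO frequencies are compared with the pooled
two-proportion Z-test; interference with
`z = (I₁ − I₂)/√(se₁² + se₂²)` using delta-method SEs (bootstrap
optional).  The exact form of the interference test is a package choice
validated by simulation: under the null (identical parameters, 2,000
tetrads per genotype) its type-I error at α = 0.05 sits inside
[0.03, 0.07] over 1,000 replicates, and it separates `nu = 1` from
`nu = 8` at p < 0.01 in ≥95% of replicates at 5,000 tetrads each.

**Pooled versus per-plant.**  Experiments pool plants; reports show both
the pooled-count estimate (the headline value) and the per-plant mean with
an exclusion log for plants whose CoC is undefined.

**Cytology.**  Chiasmata per cell are scored from bivalent shapes —
ring 2, rod 1, univalent pair 0, annotated ring 3; the 3-chiasma case is an
input annotation because no shape criterion defines it.  On simulated
metaphase cells (5 bivalents, Poisson COs per arm) the shape estimator
never exceeds the retained truth, and its undercount grows with the
per-arm rate (quantified in `analysis/04_cytology_bias.py`).  Focus-count
histograms use closed bins {0}, [1,2], [3,10], [11,20], [21,50], [51,∞).
Group tests follow the explicit-contract rule: the test applied is always
named in the result; the D'Agostino–Pearson normality screen is advisory
output and never switches the test silently.  Mann–Whitney uses exact
enumeration when `n_a · n_b ≤ 400` and the data are tie-free, otherwise
the tie- and continuity-corrected normal approximation (worst-case
exhaustive deviation from exact at 15 vs 15 is 0.0057, at central U where
both p ≈ 0.46); Dunn's post hoc z uses the tie-corrected rank variance
with a configurable multiplicity adjustment (Holm default).

## The headline experiment

`headline_simulation` compares two scenarios constrained to share
`total_rate` (a config error otherwise — that constraint *is* the
experiment) while `frac_class2` drops from 0.15 to 0.  Reported per
scenario: interference, per-interval genetic distance, and the mean Class I
event count per meiosis — the in-silico proxy for an MLH1/HEI10 focus
count.  "CO frequency unchanged" is asserted on the *genetic distances*:
re-channeling preserves the mean CO number exactly, and the Perkins
distance tracks that mean, whereas the raw recombinant-tetrad fraction
P(≥1 CO) also feels the shape of the count distribution and shifts by a
few permil at these interval sizes.  Both quantities are reported.

## Synthetic data: what it does and does not show

The simulator emulates: heterozygous three-marker FTL tetrads in coupling
with 2:2 segregation; two-pathway crossover statistics; ring/rod bivalent
configurations; and over-dispersed focus counts (Poisson,
gamma-Poisson negative binomial, zero-inflated Poisson families).  It does
not model physical (bp) coordinates, hot/cold spots, pairing dynamics, the
synaptonemal complex, scoring error, or obligate crossovers.  Passing
tests therefore demonstrate correctness of the estimators under the
declared statistical model, not robustness to cytological artefacts.

`meiocross.synthetic_tables` is a separate, clearly labelled thing:
deterministic integer tables constructed to be *consistent with published
group-level summaries* (per-genotype interference values; chiasma,
bivalent and focus means with their sample sizes) for use where the
original per-tetrad/per-cell raw data are not redistributed.  Interval
geometries there (I1bc ≈ 5.7 + 10.3 cM; I2fg ≈ 2.2 + 5.4 cM) are plausible
assumed values; within-group dispersion and per-plant structure are
invented.  Only the group-level summaries of those tables are meaningful,
and every such file is named `synthetic_*`.

## Numerical choices and problem sizes

Simulation-based checks use 50,000 tetrads for calibration properties
(no-interference null, parameter recovery, re-channeling), 10,000 for
classification consistency, and 1,000 replicate experiments for test
calibration — sizes at which Monte-Carlo SEs are small enough for the
stated tolerances while a full run stays in the minutes range on one CPU.
All randomness flows from one `numpy` Generator per call, seeded
explicitly; every runner records seed, package version and a config hash,
and identical inputs reproduce outputs bit for bit.  Monte-Carlo
assertions use 2–3 SE slack as stated per property.

## Known limitations

* The gamma-renewal form of Class I interference is a modelling choice;
  the underlying biology fixes only "interfering vs not".  `nu` is not
  fitted to data here.
* The interference Z-test assumes approximate normality of the CoC; with
  very few double-recombinant tetrads (short intervals) the delta-method
  SE degrades — the bootstrap option and the `no_doubles` flag exist for
  exactly that regime.
* Chiasma counts from shapes are lower bounds; comparisons between
  genotypes with different true CO rates inherit a rate-dependent bias.
* The letter→pattern correspondence of external class-count tables must be
  confirmed against their source's schematics before ingestion; the remap
  facility plus the `n = Σ counts` validation is the guard rail.
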