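# Methods

## Model and statistics

A gene is modelled as a set of *star alleles*, each defined by a set of core
variants (the reference allele \*1 by an empty set) and annotated with an
activity value (0 = no function, 0.25/0.5 = decreased, 1 = normal) and/or a
function class (`normal`, `decreased`, `no`, `increased`, `unknown`). The
gene also carries a *known-variant universe*: every variant listed for it in
the source frequency tables, which is the coverage denominator.

For a panel targeting variant set `T` and a gene with known universe `K`,

    coverage % = 100 · |T ∩ K| / |K|.

Diplotype frequencies come either directly from a diplotype-level table or
from Hardy–Weinberg expansion of haplotype frequencies (p² for homozygotes,
2pq for heterozygotes, per population). Each diplotype is translated to a
predicted phenotype by one of two routes: the copy-number-weighted activity
score `a₁·cn₁ + a₂·cn₂` (CYP2C9, CYP2D6), or a function-class-pair lookup
with optional diplotype-specific overrides (CYP2B6, CYP2C19, CYP3A5). A
diplotype is an *altered metabolizer* when its phenotype would trigger a
CPIC-guided change of therapy; the shipped criteria are:

| gene | altered when |
|---|---|
| CYP2B6 | intermediate or poor |
| CYP2C19 | ultrarapid, rapid, likely intermediate, intermediate, likely poor, or poor |
| CYP2C9 | activity score < 2 |
| CYP2D6 | activity score < 1.25 or > 2.25 |
| CYP3A5 | intermediate or extensive (expressers) |

Interval rules are strict at both ends: scores exactly at the normal
interval's boundary are not altered. The CYP2D6 normal window is the closed
interval [1.25, 2.25]. "Likely intermediate" and "likely poor" are distinct
vocabulary entries, not collapsed into their unqualified labels. For CYP2C9
and CYP2D6 the activity score is authoritative for classification; labels
are attached only for reporting.

A diplotype is *detectable* by a panel when, for both alleles, all defining
core variants are targeted; the reference allele is always detectable,
because targeted-variant assays report \*1 by default when no targeted
variant is found. The detection rate for (panel, gene, population) is

    100 · Σ f(d) [d altered and detectable] / Σ f(d) [d altered],

undefined (never 0, never imputed) when the denominator is zero. AMP Tier
1/2 allele sets are evaluated through exactly the same code path by
expressing them as panels.

## Parameters and conventions

* **Frequency-sum tolerance.** Per-population sums may lie in
  [0, 1 + 1e-6]; sums below 1 are legitimate (curated tables omit rare
  alleles) and the residual is *not* reassigned to \*1. HWE expansion of an
  incomplete column requires an explicit `renormalize=True`.
* **Missing ≠ zero.** A blank frequency cell is missing; a population column
  with no entries is flagged missing, excluded from summaries and rendered
  `NA` / annotated in plots, never treated as 0.
* **Detectability semantics.** ALL defining variants of an allele must be
  targeted (core-allele semantics); `mode="any"` relaxes this for
  sensitivity analysis. Because default-\*1 detectability can mask false
  negatives, `default_call_fraction` reports the share of detectable altered
  mass resting on a default \*1 call.
* **Unknown-function alleles** are excluded from classification with a
  warning, and hence from both numerator and denominator of the detection
  rate; `unknown_as_normal=True` opts into treating them as normal.
* **Copy number** is parsed from an `xN` allele-name suffix when not given
  explicitly and multiplies the allele's activity value.
* **Variant identifiers** are free-form strings compared exactly after
  trimming; no rsID↔coordinate resolution is attempted, since inputs are
  curated lists rather than genomic coordinates.
* **Population labels** canonicalize case-insensitively onto the nine
  standard groups (AAAC, Amer, CSA, EA, Eur, Lat, NE, Oc, SSA) and are
  user-extensible beyond them.
* **Summaries** are unweighted arithmetic means with min/max ranges over
  *defined* cells; undefined (0/0) cells are excluded and counted rather
  than imputed to 0 or 100. Rankings break ties lexicographically by test
  name and report all tied tests. Percentages are printed at one decimal
  with half-even rounding. Heatmap colour scales are anchored at 0–100, not
  data-scaled, so images are comparable across genes.

## Synthetic-data generator

`SimulationConfig` + `simulate_*` emulate the statistical shape of curated
multi-population star-allele data: a dominant reference allele whose mass is
Beta-jittered around `reference_mass` per population, non-reference mass
split by a symmetric Dirichlet with parameter `concentration` (both jitters
tighten as concentration grows, so populations converge to a shared vector
in the limit), function classes drawn from `function_mix`, 1–k defining
variants per allele, optional x2 duplications, and extra known variants
(default 25 %) so that full-allele panels still have < 100 % coverage.
Defaults — 6 alleles, 9 populations, reference mass 0.6, concentration 5,
mix 0.3/0.3/0.3/0.1 over normal/decreased/no/increased — were chosen to
reproduce the qualitative pattern of real panels: altered-metabolizer
prevalences spanning roughly 10–90 % across populations and detection rates
spanning most of [0, 100] as coverage varies. All randomness flows through a
single seeded `numpy` generator; identical seed and config give
byte-identical serialized outputs.

What the generator does *not* emulate: linkage between variants, sampling
noise of finite cohorts, realistic star-allele nomenclature, or fitting to
any real frequency table. Passing tests therefore demonstrate correctness of
the statistics and plumbing, not calibration to any real population; real
PharmGKB/GTR-derived inputs in the documented TSV/JSON dialects are consumed
verbatim by the same pipeline.

`brute_force_oracle` is the independent verification path: it enumerates
every unordered allele pair, derives its frequency directly from the
haplotype column, classifies and checks detectability inline, and shares no
code with the pipeline modules. It refuses models with more than 8 alleles
to keep the enumeration auditable. The central property of the test suite is
pipeline/oracle agreement to 1e-9 across randomized configurations (200
bundles in the acceptance script, up to 6 alleles × 9 populations × 5
panels), alongside panel-growth monotonicity (50 bundles) and exact recovery
of constructed ground-truth detection rates {0, 25, 50, 75, 100} % (the
ground-truth table uses binary-exact frequencies of 1/8 so recovery is exact
in floating point).

## Numerical choices and degenerate inputs

Detection rates are clamped at 100 against float round-off (the numerator is
a subset sum of the denominator). Diplotypes are stored in canonical
lexicographic order so `*2/*1` and `*1/*2` hash, compare and serialize
identically. A 0 % coverage target is realized with decoy identifiers
outside the known universe, since panels must target at least one variant
per listed gene. Results TSVs round-trip at the declared precision (nine
decimals for frequencies, one for percentages). Zero altered mass yields an
explicit `undefined` status; a gene a test omits yields `not_applicable`;
both are distinct from `missing_population`.

## Known limitations

Means across tests are unweighted, and the choice to exclude undefined cells
from averages is this package's documented convention — sources differ on
whether such cells enter per-gene averages. Phenotype translation ships only
generic CPIC-style function-pair tables for the three categorical CYPs;
gene-specific exceptions (e.g. allele-specific CYP2B6 calls) should be
supplied as diplotype override rows. Drug-specific dosing, phenoconversion
from co-medication, non-CYP genes, coordinate liftover and statistical
testing of rate differences are out of scope.
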