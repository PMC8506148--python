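# cpgx-eval

Evaluation of combinatorial pharmacogenomic (CPGx) test panels by the CYP
variants they target.

Targeted-variant PGx assays genotype a fixed list of variants per gene and
report the reference star allele (\*1) by default whenever none of the
targeted variants is found. A panel that omits variants common in a
particular population will therefore *mischaracterize* carriers of those
variants as normal metabolizers. `cpgx-eval` quantifies that risk for any
panel, gene and population from star-allele definitions and PharmGKB-style
frequency tables:

* **Coverage percentage** — how much of a gene's known variant universe a
  panel targets:

  ```
  coverage % = 100 · |targeted ∩ known variants| / |known variants|
  ```

* **Detection rate** — the share of a population's altered-metabolizer
  diplotype mass the panel can actually call:

  ```
  detection rate % = 100 · Σ f(d) over altered, detectable d
                          ───────────────────────────────────
                           Σ f(d) over altered d
  ```

  A diplotype `a/b` is *detectable* when the panel targets every defining
  core variant of both `a` and `b` (\*1, with no defining variants, is
  detectable by default). A diplotype is an *altered metabolizer* when its
  CPIC-predicted phenotype would change drug or dose: per the shipped rules,
  activity score < 2 for CYP2C9; score < 1.25 or > 2.25 for CYP2D6;
  intermediate/poor for CYP2B6; anything but normal for CYP2C19;
  intermediate/extensive (i.e. CYP3A5 expressers) for CYP3A5.

The package includes haplotype→diplotype Hardy–Weinberg expansion
(p², 2pq), activity-score and function-class phenotype translation, a
synthetic-data generator producing PharmGKB-style bundles with known ground
truth, an independent brute-force oracle for verification, and a CLI with
heatmap/prevalence plots. AMP Tier 1/Tier 2 recommended allele sets can be
evaluated simply by expressing them as panels.

## Worked example

Three star alleles of a CYP2C9-like gene — \*1 (activity 1, frequency 0.5),
\*2 and \*3 (no function, frequencies 0.3 and 0.2, one defining variant
each) — with the score-below-2 altered rule and a panel targeting only \*2's
variant:

```python
from cpgx_eval import (
    FrequencyTable, GeneModel, StarAllele, TestPanel,
    altered_diplotype_set, detection_rate, hwe_diplotype_expansion,
    population_altered_frequency,
)
from cpgx_eval.simulate import interval_rule_set

model = GeneModel("CYPX", (
    StarAllele("CYPX", "*1", activity_value=1.0, function_class="normal"),
    StarAllele("CYPX", "*2", frozenset({"v2"}), 0.0, "no"),
    StarAllele("CYPX", "*3", frozenset({"v3"}), 0.0, "no"),
), known_variants=frozenset({"v2", "v3"}))

haps = FrequencyTable("CYPX", "haplotype", ("POP1",),
    {("*1", "POP1"): 0.5, ("*2", "POP1"): 0.3, ("*3", "POP1"): 0.2})
dips = hwe_diplotype_expansion(haps)          # *1/*1=.25, *1/*2=.30, ...
rules = interval_rule_set("CYPX", lo=2.0)     # altered iff score < 2
altered = altered_diplotype_set(dips, model, rules)
panel = TestPanel("toy", {"CYPX": frozenset({"v2"})})

print(sorted(str(d) for d in altered))
print(population_altered_frequency(dips, altered, "POP1"))
print(detection_rate(dips, altered, panel, model, "POP1"))
```

prints

```
['*1/*2', '*1/*3', '*2/*2', '*2/*3', '*3/*3']
0.75
52.0
```

Every diplotype except \*1/\*1 scores below 2, so 75 % of the population are
altered metabolizers. The panel sees only \*2, so of that altered mass just
\*1/\*2 (0.30) and \*2/\*2 (0.09) are detectable: 0.39 / 0.75 = **52 %
detection rate** — the other 48 % would be reported as normal \*1 calls.

The same pipeline runs from the shell:

```sh
cpgx-eval simulate --seed 42 --out sim/          # synthetic PharmGKB-style bundle
cpgx-eval run --genes sim/CYPSIM.model.json --freq sim/CYPSIM.freq.tsv \
    --panels sim/panels.json --out results/ --renormalize
cpgx-eval heatmap --results results/ --gene CYPSIM
```

`run` writes `results.tsv` (one row per test × gene × population, `NA` for
undefined cells), per-gene summary tables (unweighted mean/min/max over
defined cells) and red–blue detection-rate heatmaps with coverage bars.

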