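"""Synthetic gene models, population frequency tables and panels.

Emulates the statistical shape of curated multi-population star-allele
frequency data: a dominant reference allele, skewed and
population-differentiated non-reference frequencies (symmetric Dirichlet
scaled to the non-reference mass, reference mass jittered with a Beta draw),
rare alleles, function-class annotations including copy-number duplications,
and panels of controlled variant coverage.  Everything is driven by a single
seeded :class:`numpy.random.Generator` — identical seed and config give
identical outputs.

The module also houses :func:`brute_force_oracle`, an exhaustive enumerator
that recomputes a detection result from first principles without calling any
of the pipeline code paths, so pipeline and oracle can disagree only if one
of them is wrong.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, MissingDataError, UntranslatableError
from .model import (
    CANONICAL_POPULATIONS,
    STATUS_OK,
    STATUS_UNDEFINED,
    Diplotype,
    DetectionResult,
    FrequencyTable,
    GeneModel,
    PhenotypeRuleSet,
    PhenotypeRule,
    StarAllele,
    TestPanel,
    canonical_population,
)
from .phenotype import TranslationTable

logger = logging.getLogger(__name__)

_ORACLE_ALLELE_CAP = 8


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters controlling the synthetic PharmGKB-style bundle.

    ``reference_mass`` is the expected *1 frequency; ``concentration`` is the
    symmetric-Dirichlet parameter controlling how strongly non-reference
    frequencies differ across populations (small = strongly differentiated);
    ``function_mix`` gives the class probabilities for non-reference alleles;
    ``copy_number_prob`` is the chance a non-reference allele is an ``x2``
    duplication.
    """

    seed: int
    gene: str = "CYPSIM"
    n_alleles: int = 6
    n_populations: int = 9
    reference_mass: float = 0.6
    concentration: float = 5.0
    function_mix: tuple[tuple[str, float], ...] = (
        ("normal", 0.3),
        ("decreased", 0.3),
        ("no", 0.3),
        ("increased", 0.1),
    )
    variants_per_allele: tuple[int, int] = (1, 3)
    copy_number_prob: float = 0.1
    extra_variant_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.n_alleles < 2:
            raise ConfigError("n_alleles must be >= 2 (reference plus one variant allele)")
        if self.n_populations < 1:
            raise ConfigError("n_populations must be >= 1")
        if not (0.0 < self.reference_mass < 1.0):
            raise ConfigError("reference_mass must lie in (0, 1)")
        if self.concentration <= 0:
            raise ConfigError("concentration must be positive")
        lo, hi = self.variants_per_allele
        if lo < 1 or hi < lo:
            raise ConfigError("variants_per_allele must be a range with 1 <= lo <= hi")
        if not (0.0 <= self.copy_number_prob <= 1.0):
            raise ConfigError("copy_number_prob must lie in [0, 1]")
        probs = dict(self.function_mix)
        if abs(sum(probs.values()) - 1.0) > 1e-9 or any(p < 0 for p in probs.values()):
            raise ConfigError("function_mix probabilities must be non-negative and sum to 1")
        bad = set(probs) - {"normal", "decreased", "no", "increased"}
        if bad:
            raise ConfigError(f"function_mix classes {sorted(bad)} not allowed")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def population_labels(self) -> tuple[str, ...]:
        if self.n_populations == len(CANONICAL_POPULATIONS):
            return CANONICAL_POPULATIONS
        return tuple(f"POP{i + 1}" for i in range(self.n_populations))


_ACTIVITY_BY_CLASS = {"normal": (1.0,), "decreased": (0.5, 0.25), "no": (0.0,), "increased": (1.0,)}


def simulate_gene_model(config: SimulationConfig) -> GeneModel:
    """Draw a star-allele model: reference *1 plus annotated variant alleles."""
    rng = config.rng()
    classes, probs = zip(*config.function_mix)
    alleles = [
        StarAllele(
            gene=config.gene, name="*1", activity_value=1.0, function_class="normal"
        )
    ]
    counter = itertools.count(1)
    lo, hi = config.variants_per_allele
    for i in range(2, config.n_alleles + 1):
        fclass = str(rng.choice(classes, p=probs))
        activity = float(rng.choice(_ACTIVITY_BY_CLASS[fclass]))
        n_var = int(rng.integers(lo, hi + 1))
        variants = frozenset(f"{config.gene}_v{next(counter)}" for _ in range(n_var))
        copy_number = 2 if rng.random() < config.copy_number_prob else 1
        name = f"*{i}" if copy_number == 1 else f"*{i}x2"
        alleles.append(
            StarAllele(
                gene=config.gene,
                name=name,
                defining_variants=variants,
                activity_value=activity,
                function_class=fclass,
                copy_number=copy_number,
            )
        )
    defined = frozenset().union(*(a.defining_variants for a in alleles))
    n_extra = math.ceil(config.extra_variant_fraction * len(defined))
    extras = frozenset(f"{config.gene}_x{i + 1}" for i in range(n_extra))
    return GeneModel(gene=config.gene, alleles=tuple(alleles), known_variants=defined | extras)


def simulate_population_frequencies(
    model: GeneModel, config: SimulationConfig
) -> FrequencyTable:
    """Draw per-population haplotype frequencies summing exactly to 1.

    Reference mass is Beta-jittered around ``reference_mass``; the remaining
    mass is split over non-reference alleles by a symmetric Dirichlet.  Both
    jitters tighten as ``concentration`` grows, so all populations converge
    to a shared frequency vector in the high-concentration limit.
    """
    rng = config.rng()
    non_ref = [a.name for a in model.alleles if not a.is_reference]
    freqs: dict[tuple[str, str], float] = {}
    kappa = 10.0 * config.concentration
    for pop in config.population_labels():
        ref_p = float(
            rng.beta(config.reference_mass * kappa, (1.0 - config.reference_mass) * kappa)
        )
        if non_ref:
            weights = rng.dirichlet([config.concentration] * len(non_ref))
            rest = (1.0 - ref_p) * weights
            for name, f in zip(non_ref, rest):
                freqs[(name, pop)] = float(f)
            freqs[("*1", pop)] = 1.0 - float(rest.sum())
        else:
            freqs[("*1", pop)] = 1.0
    return FrequencyTable(
        gene=model.gene,
        level="haplotype",
        populations=config.population_labels(),
        frequencies=freqs,
    )


def simulate_panels(
    model: GeneModel,
    coverage_targets: list[float],
    config: SimulationConfig,
) -> tuple[TestPanel, ...]:
    """Build one panel per coverage target, drawn uniformly without replacement.

    Realized coverage is within one variant's granularity of the target.  A
    0% target is realized with decoy identifiers outside the known universe
    (flagged), since panels must target at least one variant per gene.
    """
    rng = config.rng()
    known = sorted(model.known_variants)
    n_known = len(known)
    panels = []
    for target in coverage_targets:
        if not (0.0 <= target <= 100.0):
            raise ConfigError(
                f"coverage target {target} unachievable: granularity is "
                f"{100.0 / n_known:.3g}% per variant over [0, 100]"
            )
        n_pick = round(target / 100.0 * n_known)
        name = f"panel_cov{target:g}"
        if n_pick == 0:
            logger.warning(
                "%s: coverage target %g%% is below one variant's granularity; "
                "realized with decoy variants outside the known universe",
                name,
                target,
            )
            targets = frozenset({f"{model.gene}_decoy1"})
        else:
            targets = frozenset(rng.choice(known, size=n_pick, replace=False).tolist())
        panels.append(TestPanel(test_name=name, targets={model.gene: targets}))
    return tuple(panels)


def simulate_bundle(
    config: SimulationConfig, coverage_targets: list[float] | None = None
) -> tuple[GeneModel, FrequencyTable, tuple[TestPanel, ...]]:
    """Model + frequency table + panels from one config (convenience)."""
    if coverage_targets is None:
        coverage_targets = [5, 25, 50, 75, 100]
    model = simulate_gene_model(config)
    table = simulate_population_frequencies(model, config)
    panels = simulate_panels(model, coverage_targets, config)
    return model, table, panels


def interval_rule_set(
    gene: str, lo: float = 2.0, hi: float = math.inf
) -> PhenotypeRuleSet:
    """An activity-score rule set for one gene (normal interval [lo, hi])."""
    return PhenotypeRuleSet.from_rules(
        [PhenotypeRule(gene=gene, rule_kind="activity_interval", normal_interval=(lo, hi))]
    )


# ---------------------------------------------------------------------------
# Independent brute-force oracle


def brute_force_oracle(
    model: GeneModel,
    haps: FrequencyTable,
    panel: TestPanel,
    rules: PhenotypeRuleSet,
    population: str,
    lookup: TranslationTable | None = None,
) -> DetectionResult:
    """Recompute one detection cell by exhaustive first-principles enumeration.

    Lists every unordered allele pair, derives its frequency directly from
    the haplotype column (p² / 2pq), classifies it against the rule inline,
    checks detectability by raw set arithmetic, and sums.  Shares no code
    with the pipeline modules; limited to small models where enumeration is
    trivially auditable.
    """
    if len(model.alleles) > _ORACLE_ALLELE_CAP:
        raise ConfigError(
            f"oracle refuses models with more than {_ORACLE_ALLELE_CAP} alleles "
            f"(got {len(model.alleles)})"
        )
    wanted = canonical_population(population)
    col = {
        ident: f
        for (ident, pop), f in haps.frequencies.items()
        if pop == wanted
    }
    if not col:
        raise MissingDataError(f"{model.gene} [{population}]: no haplotype frequencies")
    total = sum(col.values())
    by_name = {a.name: a for a in model.alleles}
    rule = rules.rules[model.gene]
    targets = panel.targets.get(model.gene, frozenset())

    altered_mass = 0.0
    detectable_altered_mass = 0.0
    names = sorted(col)
    for i, a_name in enumerate(names):
        for b_name in names[i:]:
            p, q = col[a_name] / total, col[b_name] / total
            freq = p * p if a_name == b_name else 2.0 * p * q
            a, b = by_name[a_name], by_name[b_name]
            if a.function_class == "unknown" or b.function_class == "unknown":
                continue
            # classify inline
            if rule.rule_kind == "activity_interval":
                if a.activity_value is None or b.activity_value is None:
                    raise UntranslatableError(
                        f"{model.gene} {a_name}/{b_name}: allele without activity value"
                    )
                score = a.activity_value * a.copy_number + b.activity_value * b.copy_number
                lo, hi = rule.normal_interval
                altered = score < lo or score > hi
            else:
                if lookup is None:
                    raise UntranslatableError(f"{model.gene}: categorical rule needs a lookup")
                dip = Diplotype(model.gene, a_name, b_name)
                label = lookup.lookup(model.gene, dip, a, b)
                if label is None:
                    raise UntranslatableError(
                        f"{model.gene} {dip}: no translation entry for "
                        f"{a.function_class}/{b.function_class}"
                    )
                altered = label in rule.altered_categories
            if not altered:
                continue
            altered_mass += freq
            side_ok = []
            for allele in (a, b):
                if not allele.defining_variants:
                    side_ok.append(True)  # default *1 call
                else:
                    side_ok.append(allele.defining_variants <= targets)
            if side_ok[0] and side_ok[1]:
                detectable_altered_mass += freq

    cov = 100.0 * len(targets & model.known_variants) / len(model.known_variants)
    if altered_mass == 0.0:
        return DetectionResult(
            panel.test_name,
            model.gene,
            population,
            coverage_pct=cov,
            population_altered_freq=0.0,
            detectable_altered_freq=0.0,
            status=STATUS_UNDEFINED,
        )
    return DetectionResult(
        panel.test_name,
        model.gene,
        population,
        coverage_pct=cov,
        population_altered_freq=altered_mass,
        detectable_altered_freq=detectable_altered_mass,
        detection_rate_pct=min(100.0, 100.0 * detectable_altered_mass / altered_mass),
        status=STATUS_OK,
    )


# ---------------------------------------------------------------------------
# Ground-truth construction


def ground_truth_bundle(
    gene: str = "CYPGT", fractions: tuple[float, ...] = (0.0, 25.0, 50.0, 75.0, 100.0)
) -> tuple[GeneModel, FrequencyTable, dict[float, TestPanel], PhenotypeRuleSet]:
    """A bundle whose panels carry exactly known fractions of altered mass.

    Four no-function alleles each appear only in one heterozygous diplotype of
    frequency 1/8 (binary-exact), so a panel covering k of them is detectable
    for exactly 25·k % of the altered mass.  Used to verify ground-truth
    recovery end to end.
    """
    n_var = 4
    alleles = [StarAllele(gene=gene, name="*1", activity_value=1.0, function_class="normal")]
    for i in range(2, n_var + 2):
        alleles.append(
            StarAllele(
                gene=gene,
                name=f"*{i}",
                defining_variants=frozenset({f"{gene}_v{i}"}),
                activity_value=0.0,
                function_class="no",
            )
        )
    model = GeneModel(
        gene=gene,
        alleles=tuple(alleles),
        known_variants=frozenset(f"{gene}_v{i}" for i in range(2, n_var + 2)),
    )
    freqs: dict[tuple[str, str], float] = {("*1/*1", "POP1"): 0.5}
    for i in range(2, n_var + 2):
        freqs[(f"*1/*{i}", "POP1")] = 0.125
    table = FrequencyTable(
        gene=gene, level="diplotype", populations=("POP1",), frequencies=freqs
    )
    panels: dict[float, TestPanel] = {}
    for frac in fractions:
        k = round(frac / 100.0 * n_var)
        if abs(k * 100.0 / n_var - frac) > 1e-9:
            raise ConfigError(f"fraction {frac} not representable with {n_var} alleles")
        if k == 0:
            targets = frozenset({f"{gene}_decoy"})
        else:
            targets = frozenset(f"{gene}_v{i}" for i in range(2, 2 + k))
        panels[frac] = TestPanel(test_name=f"gt_{frac:g}", targets={gene: targets})
    rules = interval_rule_set(gene, lo=2.0, hi=math.inf)
    return model, table, panels, rules
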