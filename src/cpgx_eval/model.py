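"""Domain types for CPGx panel evaluation.

The vocabulary follows standard pharmacogenomics usage: a *star allele* is a
named haplotype of a pharmacogene (CYP2C9*3) defined by a set of core
variants, with *1 the reference allele called by default when no targeted
variant is found; a *diplotype* is the unordered pair of star alleles an
individual carries; an *activity score* is the copy-number-weighted sum of
per-allele activity values used by CPIC to predict metabolizer phenotype for
CYP2C9/CYP2D6.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import MissingDataError, ValidationError

#: Function classes a star allele may carry.
FUNCTION_CLASSES = frozenset({"normal", "decreased", "no", "increased", "unknown"})

#: Controlled vocabulary of metabolizer phenotype labels.
PHENOTYPE_LABELS = frozenset(
    {
        "ultrarapid",
        "rapid",
        "normal",
        "likely intermediate",
        "intermediate",
        "likely poor",
        "poor",
        "extensive",
    }
)

#: The nine population groups used in PharmGKB-style frequency tables.
CANONICAL_POPULATIONS = (
    "AAAC",  # African American / Afro-Caribbean
    "Amer",  # American
    "CSA",  # Central / South Asian
    "EA",  # East Asian
    "Eur",  # European
    "Lat",  # Latino
    "NE",  # Near Eastern
    "Oc",  # Oceanian
    "SSA",  # Sub-Saharan African
)

_CANONICAL_POP_LOOKUP = {p.lower(): p for p in CANONICAL_POPULATIONS}

#: Tolerance on per-population frequency sums (sums below 1 are legitimate:
#: PharmGKB tables omit rare alleles).
FREQ_SUM_TOL = 1e-6

_XN_RE = re.compile(r"x(\d+)$")


def canonical_population(label: str) -> str:
    """Map a population label onto the canonical abbreviation, case-insensitively.

    Labels outside the canonical nine are returned trimmed but otherwise
    untouched — the vocabulary is user-extensible.
    """
    return _CANONICAL_POP_LOOKUP.get(label.strip().lower(), label.strip())


def parse_copy_number(allele_name: str) -> int:
    """Infer copy number from an ``xN`` allele-name suffix (``*1x2`` -> 2)."""
    m = _XN_RE.search(allele_name)
    return int(m.group(1)) if m else 1


@dataclass(frozen=True)
class StarAllele:
    """One star allele: its defining core variants and functional annotation."""

    gene: str
    name: str
    defining_variants: frozenset[str] = frozenset()
    activity_value: float | None = None
    function_class: str | None = None
    copy_number: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "defining_variants", frozenset(self.defining_variants))
        if self.copy_number < 1:
            raise ValidationError(
                f"{self.gene}{self.name}: copy_number must be >= 1, got {self.copy_number}"
            )
        if self.function_class is not None and self.function_class not in FUNCTION_CLASSES:
            raise ValidationError(
                f"{self.gene}{self.name}: unknown function class {self.function_class!r}"
            )
        if self.activity_value is not None and (
            self.activity_value < 0 or not math.isfinite(self.activity_value)
        ):
            raise ValidationError(
                f"{self.gene}{self.name}: activity_value must be a finite non-negative "
                f"number, got {self.activity_value}"
            )

    @property
    def is_reference(self) -> bool:
        """The reference allele has no defining variants (default *1 call)."""
        return not self.defining_variants


@dataclass(frozen=True)
class GeneModel:
    """A gene's star alleles plus the universe of known variants.

    ``known_variants`` is the coverage denominator: the variants listed for
    the gene in the source frequency tables, whether or not any shipped panel
    targets them.
    """

    gene: str
    alleles: tuple[StarAllele, ...]
    known_variants: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", tuple(self.alleles))
        object.__setattr__(self, "known_variants", frozenset(self.known_variants))
        names = [a.name for a in self.alleles]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"{self.gene}: duplicate allele names {dupes}")
        for a in self.alleles:
            missing = a.defining_variants - self.known_variants
            if missing:
                raise ValidationError(
                    f"{self.gene}{a.name}: defining variants {sorted(missing)} "
                    "absent from known_variants"
                )

    def allele(self, name: str) -> StarAllele:
        for a in self.alleles:
            if a.name == name:
                return a
        raise ValidationError(f"{self.gene}: no allele named {name!r}")

    @property
    def allele_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.alleles)


@dataclass(frozen=True, order=True)
class Diplotype:
    """An unordered pair of star alleles, stored in canonical order.

    ``Diplotype("G", "*2", "*1")`` and ``Diplotype("G", "*1", "*2")`` compare,
    hash and serialize identically.
    """

    gene: str
    allele_a: str
    allele_b: str

    def __init__(self, gene: str, allele_a: str, allele_b: str) -> None:
        a, b = sorted((allele_a, allele_b))
        object.__setattr__(self, "gene", gene)
        object.__setattr__(self, "allele_a", a)
        object.__setattr__(self, "allele_b", b)

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_a, self.allele_b)

    @property
    def is_homozygous(self) -> bool:
        return self.allele_a == self.allele_b

    def __str__(self) -> str:
        return f"{self.allele_a}/{self.allele_b}"

    @classmethod
    def parse(cls, gene: str, text: str) -> "Diplotype":
        """Parse an ``A/B`` identifier (order-insensitive)."""
        parts = text.strip().split("/")
        if len(parts) != 2 or not all(parts):
            raise ValidationError(f"{gene}: malformed diplotype identifier {text!r}")
        return cls(gene, parts[0].strip(), parts[1].strip())


@dataclass
class FrequencyTable:
    """Per-population frequencies of haplotypes or diplotypes for one gene.

    ``frequencies`` maps ``(identifier, population)`` to a frequency in
    [0, 1]; absent keys mean *missing*, never zero.  A population listed in
    ``populations`` but carrying no entries is *missing* and excluded from
    summaries rather than contributing zeros.
    """

    gene: str
    level: str  # "haplotype" | "diplotype"
    populations: tuple[str, ...]
    frequencies: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level not in ("haplotype", "diplotype"):
            raise ValidationError(f"{self.gene}: level must be haplotype|diplotype")
        self.populations = tuple(canonical_population(p) for p in self.populations)
        self.frequencies = {
            (ident, canonical_population(pop)): float(f)
            for (ident, pop), f in self.frequencies.items()
        }
        self.validate()

    def validate(self) -> None:
        for (ident, pop), f in self.frequencies.items():
            if not (0.0 <= f <= 1.0):
                raise ValidationError(
                    f"{self.gene} {ident} [{pop}]: frequency {f} outside [0, 1]"
                )
            if pop not in self.populations:
                raise ValidationError(f"{self.gene}: entry for unlisted population {pop!r}")
        for pop in self.populations:
            total = self.population_total(pop)
            if total is not None and total > 1.0 + FREQ_SUM_TOL:
                raise ValidationError(
                    f"{self.gene} [{pop}]: frequencies sum to {total:.6g} > 1"
                )

    @property
    def identifiers(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for ident, _ in self.frequencies:
            seen.setdefault(ident)
        return tuple(seen)

    def population_total(self, population: str) -> float | None:
        """Sum of present frequencies for a population, or None if missing."""
        pop = canonical_population(population)
        vals = [f for (_, p), f in self.frequencies.items() if p == pop]
        return sum(vals) if vals else None

    def is_population_missing(self, population: str) -> bool:
        return self.population_total(population) is None

    @property
    def missing_populations(self) -> tuple[str, ...]:
        return tuple(p for p in self.populations if self.is_population_missing(p))

    def get(self, identifier: str, population: str) -> float | None:
        return self.frequencies.get((identifier, canonical_population(population)))

    def column(self, population: str) -> dict[str, float]:
        """All present frequencies of one population, keyed by identifier.

        Raises :class:`MissingDataError` if the population is missing.
        """
        pop = canonical_population(population)
        if pop not in self.populations:
            raise MissingDataError(f"{self.gene}: population {population!r} not in table")
        col = {i: f for (i, p), f in self.frequencies.items() if p == pop}
        if not col:
            raise MissingDataError(
                f"{self.gene} [{pop}]: no frequencies documented for this population"
            )
        return col

    def diplotypes(self) -> tuple[Diplotype, ...]:
        if self.level != "diplotype":
            raise ValidationError(f"{self.gene}: table is at {self.level} level")
        return tuple(Diplotype.parse(self.gene, i) for i in self.identifiers)


@dataclass(frozen=True)
class TestPanel:
    """The variant identifiers one CPGx assay targets, per gene."""

    __test__ = False  # "Test" here means assay, not a pytest case

    test_name: str
    targets: Mapping[str, frozenset[str]]
    lab: str | None = None

    def __post_init__(self) -> None:
        frozen = {g: frozenset(v.strip() for v in vs) for g, vs in self.targets.items()}
        for gene, vs in frozen.items():
            if not vs:
                raise ValidationError(
                    f"panel {self.test_name!r}: empty target set for gene {gene}"
                )
        object.__setattr__(self, "targets", frozen)

    def genes(self) -> tuple[str, ...]:
        return tuple(self.targets)

    def covers_gene(self, gene: str) -> bool:
        return gene in self.targets


@dataclass(frozen=True)
class PhenotypeRule:
    """Altered-metabolizer criterion for one gene.

    Either categorical (a set of phenotype labels counts as altered) or an
    activity-score interval: scores strictly outside the closed
    ``normal_interval`` are altered (CPIC wording "less than"/"greater than"
    is strict, so the interval endpoints themselves are *not* altered).
    """

    gene: str
    rule_kind: str  # "categorical" | "activity_interval"
    altered_categories: frozenset[str] = frozenset()
    normal_interval: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.rule_kind == "categorical":
            cats = frozenset(self.altered_categories)
            bad = cats - PHENOTYPE_LABELS
            if bad:
                raise ValidationError(
                    f"{self.gene}: altered categories {sorted(bad)} outside vocabulary"
                )
            object.__setattr__(self, "altered_categories", cats)
        elif self.rule_kind == "activity_interval":
            if self.normal_interval is None:
                raise ValidationError(f"{self.gene}: interval rule needs normal_interval")
            lo, hi = self.normal_interval
            if lo > hi:
                raise ValidationError(f"{self.gene}: interval lo {lo} > hi {hi}")
            object.__setattr__(self, "normal_interval", (float(lo), float(hi)))
        else:
            raise ValidationError(f"{self.gene}: unknown rule kind {self.rule_kind!r}")


@dataclass(frozen=True)
class PhenotypeRuleSet:
    """One altered-metabolizer rule per gene."""

    rules: Mapping[str, PhenotypeRule]

    def __post_init__(self) -> None:
        for gene, rule in self.rules.items():
            if rule.gene != gene:
                raise ValidationError(f"rule keyed {gene} carries gene {rule.gene}")
        object.__setattr__(self, "rules", dict(self.rules))

    @classmethod
    def from_rules(cls, rules: Iterable[PhenotypeRule]) -> "PhenotypeRuleSet":
        rules = list(rules)
        genes = [r.gene for r in rules]
        if len(genes) != len(set(genes)):
            raise ValidationError("duplicate gene in rule set")
        return cls({r.gene: r for r in rules})

    def rule_for(self, gene: str) -> PhenotypeRule:
        try:
            return self.rules[gene]
        except KeyError:
            raise ValidationError(f"no altered-metabolizer rule for gene {gene}") from None

    def genes(self) -> tuple[str, ...]:
        return tuple(self.rules)


# Cell status values for DetectionResult.
STATUS_OK = "ok"
STATUS_UNDEFINED = "undefined"  # 0/0: no altered mass in the population
STATUS_MISSING_POPULATION = "missing_population"
STATUS_NOT_APPLICABLE = "not_applicable"  # test does not cover the gene


@dataclass(frozen=True)
class DetectionResult:
    """One (test, gene, population) cell: coverage and detection statistics.

    ``detection_rate_pct`` is None exactly when the cell is not "ok": an
    undefined 0/0 ratio, a missing population, or a gene the test omits.  The
    undefinedness is carried as an explicit status, never as a NaN sentinel.
    """

    test_name: str
    gene: str
    population: str
    coverage_pct: float | None = None
    population_altered_freq: float | None = None
    detectable_altered_freq: float | None = None
    detection_rate_pct: float | None = None
    status: str = STATUS_OK

    def __post_init__(self) -> None:
        if self.status == STATUS_OK:
            if self.detection_rate_pct is None:
                raise ValidationError("ok cell must carry a detection rate")
            if not (0.0 <= self.detection_rate_pct <= 100.0 + 1e-9):
                raise ValidationError(
                    f"detection rate {self.detection_rate_pct} outside [0, 100]"
                )
        if (
            self.population_altered_freq is not None
            and self.detectable_altered_freq is not None
            and self.detectable_altered_freq > self.population_altered_freq + 2e-9
        ):
            raise ValidationError(
                "detectable altered frequency exceeds population altered frequency"
            )
        if self.coverage_pct is not None and not (
            -1e-9 <= self.coverage_pct <= 100.0 + 1e-9
        ):
            raise ValidationError(f"coverage {self.coverage_pct} outside [0, 100]")

    @property
    def defined(self) -> bool:
        return self.status == STATUS_OK
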