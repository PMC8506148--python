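"""Diplotype-to-phenotype translation and altered-metabolizer classification.

Two translation paths exist, matching how CPIC guidelines treat the CYPs:

* *activity-score genes* (CYP2C9, CYP2D6): each allele carries a numeric
  activity value (1 normal, 0.5/0.25 decreased, 0 none), the diplotype score
  is the copy-number-weighted sum over the two alleles, and the altered rule
  is an interval on the score.
* *categorical genes* (CYP2B6, CYP2C19, CYP3A5): a function-class pair (or
  an explicit diplotype override) maps to a metabolizer label, and the
  altered rule is a label set.

Unknown-function alleles cannot be classified; by default their diplotypes
are excluded (with a warning) from both numerator and denominator of any
downstream frequency, never silently treated as normal.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import RuleMismatchError, UnscorableError, UntranslatableError
from .model import (
    Diplotype,
    FrequencyTable,
    GeneModel,
    PhenotypeRule,
    PhenotypeRuleSet,
    StarAllele,
)

logger = logging.getLogger(__name__)


@dataclass
class TranslationTable:
    """Function-pair -> phenotype label lookup, with diplotype overrides.

    Function pairs are unordered; overrides win over pair entries.
    """

    function_pairs: dict[tuple[str, frozenset[str] | tuple[str, str]], str] = field(
        default_factory=dict
    )
    diplotype_overrides: dict[tuple[str, str], str] = field(default_factory=dict)

    @staticmethod
    def _pair_key(a: str, b: str):
        a, b = sorted((a.strip(), b.strip()))
        return (a, b)

    def add_function_pair(self, gene: str, a: str, b: str, label: str) -> None:
        self.function_pairs[(gene, self._pair_key(a, b))] = label

    def add_diplotype_override(self, gene: str, diplotype: str, label: str) -> None:
        canonical = str(Diplotype.parse(gene, diplotype))
        self.diplotype_overrides[(gene, canonical)] = label

    def lookup(self, gene: str, diplotype: Diplotype, a: StarAllele, b: StarAllele) -> str | None:
        override = self.diplotype_overrides.get((gene, str(diplotype)))
        if override is not None:
            return override
        if a.function_class is None or b.function_class is None:
            return None
        return self.function_pairs.get((gene, self._pair_key(a.function_class, b.function_class)))


@dataclass(frozen=True)
class PhenotypeCall:
    """The predicted phenotype for one diplotype: a score, a label, or both."""

    diplotype: Diplotype
    activity_score: float | None = None
    phenotype_label: str | None = None

    def __post_init__(self) -> None:
        if self.activity_score is None and self.phenotype_label is None:
            raise UntranslatableError(
                f"{self.diplotype.gene} {self.diplotype}: neither score nor label"
            )


def diplotype_activity_score(diplotype: Diplotype, model: GeneModel) -> float:
    """Copy-number-weighted sum of the two alleles' activity values.

    Commutative in allele order by construction (diplotypes are canonical).
    """
    total = 0.0
    for name in diplotype.alleles:
        allele = model.allele(name)
        if allele.activity_value is None:
            raise UnscorableError(
                f"{model.gene}{allele.name}: no activity value; cannot score {diplotype}"
            )
        total += allele.activity_value * allele.copy_number
    return total


def assign_phenotype(
    diplotype: Diplotype,
    model: GeneModel,
    lookup: TranslationTable | None = None,
) -> PhenotypeCall:
    """Translate one diplotype to a phenotype call.

    An activity score is attached whenever both alleles are scorable; a label
    is attached whenever the lookup resolves.  At least one must succeed.
    """
    a = model.allele(diplotype.allele_a)
    b = model.allele(diplotype.allele_b)
    score: float | None
    try:
        score = diplotype_activity_score(diplotype, model)
    except UnscorableError:
        score = None
    label = lookup.lookup(model.gene, diplotype, a, b) if lookup is not None else None
    if score is None and label is None:
        raise UntranslatableError(
            f"{model.gene} {diplotype}: no translation entry and no scorable path "
            f"(functions {a.function_class!r}/{b.function_class!r})"
        )
    return PhenotypeCall(diplotype=diplotype, activity_score=score, phenotype_label=label)


def classify_altered(call: PhenotypeCall, rules: PhenotypeRuleSet, gene: str) -> bool:
    """Apply the gene's altered-metabolizer rule to a phenotype call.

    Interval rules are strict at both ends: a score exactly at the normal
    interval's boundary is not altered.
    """
    rule: PhenotypeRule = rules.rule_for(gene)
    if rule.rule_kind == "activity_interval":
        if call.activity_score is None:
            raise RuleMismatchError(
                f"{gene} {call.diplotype}: activity-score rule but call has no score"
            )
        lo, hi = rule.normal_interval
        return call.activity_score < lo or call.activity_score > hi
    if call.phenotype_label is None:
        raise RuleMismatchError(
            f"{gene} {call.diplotype}: categorical rule but call has no label"
        )
    return call.phenotype_label in rule.altered_categories


def _has_unknown_function(diplotype: Diplotype, model: GeneModel) -> bool:
    return any(model.allele(n).function_class == "unknown" for n in diplotype.alleles)


def altered_diplotype_set(
    table: FrequencyTable,
    model: GeneModel,
    rules: PhenotypeRuleSet,
    lookup: TranslationTable | None = None,
    *,
    unknown_as_normal: bool = False,
) -> frozenset[Diplotype]:
    """The diplotypes in a diplotype-level table classified as altered.

    Diplotypes carrying an unknown-function allele are excluded (warned)
    unless ``unknown_as_normal`` treats unknown as normal function.  Every
    other diplotype is classified or raises explicitly — none is silently
    dropped.
    """
    altered = set()
    for dip in table.diplotypes():
        if not unknown_as_normal and _has_unknown_function(dip, model):
            logger.warning(
                "%s %s: unknown-function allele; excluded from classification",
                model.gene,
                dip,
            )
            continue
        call = assign_phenotype(dip, model, lookup)
        if classify_altered(call, rules, model.gene):
            altered.add(dip)
    return frozenset(altered)


def classifiable_diplotypes(
    table: FrequencyTable,
    model: GeneModel,
    *,
    unknown_as_normal: bool = False,
) -> frozenset[Diplotype]:
    """Diplotypes that enter classification (complement of unknown-excluded)."""
    dips = table.diplotypes()
    if unknown_as_normal:
        return frozenset(dips)
    return frozenset(d for d in dips if not _has_unknown_function(d, model))
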