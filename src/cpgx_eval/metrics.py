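"""Coverage percentage, detectability, detection rate and summaries.

The two headline statistics:

* coverage percentage — the share of a gene's known variant universe a panel
  targets, ``100 * |targets ∩ known| / |known|``;
* detection rate — within one population, the share of the altered-metabolizer
  diplotype mass the panel can actually call,
  ``100 * Σ freq(altered ∧ detectable) / Σ freq(altered)``, undefined when the
  population carries no altered mass at all.

A diplotype is *detectable* when the panel targets every defining core
variant of both constituent alleles; the reference allele is detectable by
construction, because targeted-variant assays report *1 by default when no
targeted variant is found.  That default-call convention can mask false
negatives, so each cell also carries the fraction of detectable altered mass
that rests on a default *1 call (the ``default_call_fraction`` diagnostic).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .errors import MissingDataError, ValidationError
from .model import (
    STATUS_MISSING_POPULATION,
    STATUS_NOT_APPLICABLE,
    STATUS_OK,
    STATUS_UNDEFINED,
    Diplotype,
    DetectionResult,
    FrequencyTable,
    GeneModel,
    PhenotypeRuleSet,
    TestPanel,
)
from .phenotype import TranslationTable, altered_diplotype_set, classifiable_diplotypes

DetectMode = Literal["all", "any"]

#: How far a haplotype column may drift from summing to 1 before HWE
#: expansion demands explicit renormalization.
HWE_SUM_TOL = 1e-6


def hwe_diplotype_expansion(
    haps: FrequencyTable, *, renormalize: bool = False
) -> FrequencyTable:
    """Expand haplotype frequencies to diplotype frequencies under HWE.

    Per population: homozygote ``A/A`` gets p², heterozygote ``A/B`` gets
    2pq.  The output column sums to (the square of) the input column's sum,
    i.e. exactly 1 for a complete column; incomplete columns require
    ``renormalize=True``.
    """
    if haps.level != "haplotype":
        raise ValidationError(f"{haps.gene}: expansion needs a haplotype-level table")
    freqs: dict[tuple[str, str], float] = {}
    for pop in haps.populations:
        if haps.is_population_missing(pop):
            continue
        col = haps.column(pop)
        total = sum(col.values())
        if abs(total - 1.0) > HWE_SUM_TOL:
            if not renormalize:
                raise ValidationError(
                    f"{haps.gene} [{pop}]: haplotype frequencies sum to {total:.6g}; "
                    "pass renormalize=True to rescale"
                )
            col = {a: f / total for a, f in col.items()}
        names = sorted(col)
        for i, a in enumerate(names):
            for b in names[i:]:
                dip = str(Diplotype(haps.gene, a, b))
                f = col[a] ** 2 if a == b else 2.0 * col[a] * col[b]
                freqs[(dip, pop)] = f
    return FrequencyTable(
        gene=haps.gene, level="diplotype", populations=haps.populations, frequencies=freqs
    )


def coverage_percentage(panel: TestPanel, gene: str, model: GeneModel) -> float:
    """Share of the gene's known variant universe the panel targets, in percent."""
    if not panel.covers_gene(gene):
        raise ValidationError(f"panel {panel.test_name!r} does not cover gene {gene}")
    if not model.known_variants:
        raise ValidationError(f"{gene}: empty known-variant universe; coverage undefined")
    targeted = panel.targets[gene] & model.known_variants
    return 100.0 * len(targeted) / len(model.known_variants)


def _allele_detectable(
    allele_name: str, panel: TestPanel, model: GeneModel, mode: DetectMode
) -> bool:
    allele = model.allele(allele_name)
    if allele.is_reference:
        return True  # untargeted variants are reported as a default *1 call
    targets = panel.targets.get(model.gene, frozenset())
    if mode == "any":
        return bool(allele.defining_variants & targets)
    return allele.defining_variants <= targets


def is_detectable(
    diplotype: Diplotype,
    panel: TestPanel,
    model: GeneModel,
    *,
    mode: DetectMode = "all",
) -> bool:
    """True iff the panel can call both alleles of the diplotype.

    An allele is detectable when all of its defining core variants are
    targeted (``mode="any"`` relaxes to at least one, for sensitivity
    analysis); one-sided coverage is insufficient.
    """
    return all(_allele_detectable(n, panel, model, mode) for n in diplotype.alleles)


def population_altered_frequency(
    dips: FrequencyTable, altered: Iterable[Diplotype], population: str
) -> float:
    """Sum of altered-diplotype frequencies in one population.

    Raises :class:`MissingDataError` when the population has no documented
    frequencies — missing is never zero.
    """
    col = dips.column(population)
    altered_ids = {str(d) for d in altered}
    return sum(f for ident, f in col.items() if ident in altered_ids)


def detection_rate(
    dips: FrequencyTable,
    altered: Iterable[Diplotype],
    panel: TestPanel,
    model: GeneModel,
    population: str,
    *,
    mode: DetectMode = "all",
) -> float | None:
    """Eq.-2 detection rate in percent, or None when no altered mass exists."""
    altered = list(altered)
    denom = population_altered_frequency(dips, altered, population)
    if denom == 0.0:
        return None
    col = dips.column(population)
    num = sum(
        col.get(str(d), 0.0) for d in altered if is_detectable(d, panel, model, mode=mode)
    )
    return min(100.0, 100.0 * num / denom)  # num <= denom up to float round-off


@dataclass
class DetectionMatrix:
    """Fully crossed (test × gene × population) grid of detection results."""

    tests: tuple[str, ...]
    genes: tuple[str, ...]
    populations: tuple[str, ...]
    cells: dict[tuple[str, str, str], DetectionResult] = field(default_factory=dict)

    def get(self, test: str, gene: str, population: str) -> DetectionResult:
        return self.cells[(test, gene, population)]

    def results(self) -> tuple[DetectionResult, ...]:
        return tuple(
            self.cells[(t, g, p)]
            for t, g, p in itertools.product(self.tests, self.genes, self.populations)
        )

    def defined(self) -> tuple[DetectionResult, ...]:
        return tuple(r for r in self.results() if r.defined)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "test": r.test_name,
                "gene": r.gene,
                "population": r.population,
                "coverage_pct": r.coverage_pct,
                "population_altered_freq": r.population_altered_freq,
                "detectable_altered_freq": r.detectable_altered_freq,
                "detection_rate_pct": r.detection_rate_pct,
                "status": r.status,
            }
            for r in self.results()
        ]
        return pd.DataFrame(rows)


def evaluate_panels(
    panels: Sequence[TestPanel],
    models: Mapping[str, GeneModel],
    tables: Mapping[str, FrequencyTable],
    rules: PhenotypeRuleSet,
    lookup: TranslationTable | None = None,
    *,
    mode: DetectMode = "all",
    renormalize: bool = False,
    unknown_as_normal: bool = False,
) -> DetectionMatrix:
    """Evaluate every panel against every gene and population.

    Haplotype-level tables are HWE-expanded first.  Cells for (test, gene)
    pairs the test omits are marked not-applicable (never 0); populations
    with no documented frequencies are marked missing.
    """
    names = [p.test_name for p in panels]
    if len(names) != len(set(names)):
        raise ValidationError("duplicate test names in panel collection")
    genes = tuple(g for g in models if g in tables)
    dip_tables: dict[str, FrequencyTable] = {}
    altered_sets: dict[str, frozenset[Diplotype]] = {}
    populations: list[str] = []
    for gene in genes:
        table = tables[gene]
        if table.level == "haplotype":
            table = hwe_diplotype_expansion(table, renormalize=renormalize)
        dip_tables[gene] = table
        altered_sets[gene] = altered_diplotype_set(
            table, models[gene], rules, lookup, unknown_as_normal=unknown_as_normal
        )
        for pop in table.populations:
            if pop not in populations:
                populations.append(pop)

    matrix = DetectionMatrix(tests=tuple(names), genes=genes, populations=tuple(populations))
    for panel, gene, pop in itertools.product(panels, genes, populations):
        key = (panel.test_name, gene, pop)
        if not panel.covers_gene(gene):
            matrix.cells[key] = DetectionResult(
                panel.test_name, gene, pop, status=STATUS_NOT_APPLICABLE
            )
            continue
        cov = coverage_percentage(panel, gene, models[gene])
        table = dip_tables[gene]
        if pop not in table.populations or table.is_population_missing(pop):
            matrix.cells[key] = DetectionResult(
                panel.test_name, gene, pop, coverage_pct=cov, status=STATUS_MISSING_POPULATION
            )
            continue
        altered = altered_sets[gene]
        denom = population_altered_frequency(table, altered, pop)
        col = table.column(pop)
        num = sum(
            col.get(str(d), 0.0)
            for d in altered
            if is_detectable(d, panel, models[gene], mode=mode)
        )
        if denom == 0.0:
            matrix.cells[key] = DetectionResult(
                panel.test_name,
                gene,
                pop,
                coverage_pct=cov,
                population_altered_freq=0.0,
                detectable_altered_freq=0.0,
                status=STATUS_UNDEFINED,
            )
        else:
            matrix.cells[key] = DetectionResult(
                panel.test_name,
                gene,
                pop,
                coverage_pct=cov,
                population_altered_freq=denom,
                detectable_altered_freq=num,
                detection_rate_pct=min(100.0, 100.0 * num / denom),
                status=STATUS_OK,
            )
    return matrix


def default_call_fraction(
    dips: FrequencyTable,
    altered: Iterable[Diplotype],
    panel: TestPanel,
    model: GeneModel,
    population: str,
    *,
    mode: DetectMode = "all",
) -> float | None:
    """Share of detectable altered mass resting on a default *1 call.

    Diagnoses how much of a panel's detection rate depends on reporting the
    reference allele whenever no targeted variant is found.
    """
    col = dips.column(population)
    detectable = [
        d for d in altered if is_detectable(d, panel, model, mode=mode)
    ]
    total = sum(col.get(str(d), 0.0) for d in detectable)
    if total == 0.0:
        return None
    ref = sum(
        col.get(str(d), 0.0)
        for d in detectable
        if any(model.allele(n).is_reference for n in d.alleles)
    )
    return ref / total


def summarize(matrix: DetectionMatrix, by: str | Sequence[str] = "gene") -> pd.DataFrame:
    """Unweighted mean / min / max of detection rate over defined cells.

    Undefined, missing and not-applicable cells are excluded from the
    statistics and counted in ``n_excluded``; a group with no defined cells
    reports NA statistics rather than an imputed value.
    """
    if isinstance(by, str):
        by = [by]
    valid = {"test", "gene", "population"}
    if not set(by) <= valid:
        raise ValidationError(f"summary axes must be among {sorted(valid)}")
    df = matrix.to_frame()
    if df.empty:
        raise ValidationError("empty matrix")
    rows = []
    for keys, group in df.groupby(list(by), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        defined = group[group["status"] == STATUS_OK]["detection_rate_pct"]
        row = dict(zip(by, keys))
        row["n_defined"] = len(defined)
        row["n_excluded"] = len(group) - len(defined)
        if len(defined):
            row["mean_detection_rate_pct"] = float(defined.mean())
            row["min_detection_rate_pct"] = float(defined.min())
            row["max_detection_rate_pct"] = float(defined.max())
        else:
            row["mean_detection_rate_pct"] = None
            row["min_detection_rate_pct"] = None
            row["max_detection_rate_pct"] = None
        rows.append(row)
    return pd.DataFrame(rows)


def rank_tests(matrix: DetectionMatrix, gene: str, population: str) -> tuple[str, ...]:
    """Tests ordered by detection rate (descending), ties broken by name.

    All tests sharing the top rate are reported; callers see ties explicitly.
    """
    cells = [
        matrix.get(t, gene, population)
        for t in matrix.tests
        if matrix.get(t, gene, population).defined
    ]
    if not cells:
        raise MissingDataError(f"{gene} [{population}]: no defined cells to rank")
    return tuple(
        c.test_name for c in sorted(cells, key=lambda c: (-c.detection_rate_pct, c.test_name))
    )
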