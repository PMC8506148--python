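"""Readers and writers for gene models, frequency tables, panels, rules and results.

File dialects
-------------
* Gene model TSV: ``gene, allele, defining_variants, activity_value,
  function_class, copy_number`` with semicolon-separated variants (empty for
  the reference allele).  The known-variant universe may come from a
  companion single-column TSV; otherwise it is the union of defining
  variants.  A JSON dialect mirrors the :class:`~cpgx_eval.model.GeneModel`
  fields directly.
* Frequency TSV: ``gene, identifier, <POP1>, <POP2>, ...`` — one column per
  population, blank cells meaning *missing* (never zero).
* Panel JSON: ``{"tests": [{"name": ..., "lab": ..., "targets": {gene:
  [variant, ...]}}]}``.
* Rule JSON mirrors :class:`~cpgx_eval.model.PhenotypeRuleSet`; the shipped
  default encodes the CPIC-derived altered-metabolizer criteria for CYP2B6,
  CYP2C19, CYP2C9, CYP2D6 and CYP3A5.
* Results TSV: one row per (test, gene, population), percentages at one
  decimal (half-even), undefined cells rendered as ``NA``.
"""
from __future__ import annotations

import json
import logging
import math
from decimal import ROUND_HALF_EVEN, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError, ValidationError
from .model import (
    STATUS_OK,
    DetectionResult,
    FrequencyTable,
    GeneModel,
    PhenotypeRule,
    PhenotypeRuleSet,
    StarAllele,
    TestPanel,
    parse_copy_number,
)
from .phenotype import TranslationTable

logger = logging.getLogger(__name__)

RESULT_COLUMNS = (
    "test",
    "gene",
    "population",
    "coverage_pct",
    "population_altered_freq",
    "detectable_altered_freq",
    "detection_rate_pct",
    "status",
)

#: Decimal places used when serializing frequencies / percentages.
FREQ_DECIMALS = 9
PCT_DECIMALS = 1


def round_half_even(x: float, decimals: int = PCT_DECIMALS) -> float:
    """Round with banker's rounding at a fixed number of decimals."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_EVEN))


def _fmt(x: float | None, decimals: int) -> str:
    if x is None:
        return "NA"
    return f"{round_half_even(x, decimals):.{decimals}f}"


# ---------------------------------------------------------------------------
# Gene models


def read_gene_model(path: str | Path, known_variants_path: str | Path | None = None) -> GeneModel:
    """Read a gene model from TSV or JSON (dispatch on suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _read_gene_model_json(path)
    return _read_gene_model_tsv(path, known_variants_path)


def _read_gene_model_json(path: Path) -> GeneModel:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    try:
        alleles = tuple(
            StarAllele(
                gene=doc["gene"],
                name=a["name"],
                defining_variants=frozenset(a.get("defining_variants", [])),
                activity_value=a.get("activity_value"),
                function_class=a.get("function_class"),
                copy_number=a.get("copy_number", parse_copy_number(a["name"])),
            )
            for a in doc["alleles"]
        )
        known = frozenset(doc.get("known_variants", []))
    except KeyError as exc:
        raise FormatError(f"{path}: missing field {exc}") from exc
    if not known:
        known = frozenset().union(*(a.defining_variants for a in alleles))
    return GeneModel(gene=doc["gene"], alleles=alleles, known_variants=known)


def _read_gene_model_tsv(path: Path, known_variants_path: str | Path | None) -> GeneModel:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pandas raises several parser error types
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc
    required = {"gene", "allele", "defining_variants"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    genes = df["gene"].unique()
    if len(genes) != 1:
        raise FormatError(f"{path}: expected a single gene, found {list(genes)}")
    gene = genes[0]
    alleles = []
    for i, row in df.iterrows():
        variants = frozenset(v.strip() for v in row["defining_variants"].split(";") if v.strip())
        act = row.get("activity_value", "")
        func = row.get("function_class", "")
        cn = row.get("copy_number", "")
        try:
            activity = float(act) if act not in ("", None) else None
        except ValueError:
            raise FormatError(f"{path} line {i + 2}: bad activity_value {act!r}") from None
        copy_number = int(cn) if cn not in ("", None) else parse_copy_number(row["allele"])
        alleles.append(
            StarAllele(
                gene=gene,
                name=row["allele"].strip(),
                defining_variants=variants,
                activity_value=activity,
                function_class=func.strip() or None,
                copy_number=copy_number,
            )
        )
    known = frozenset().union(*(a.defining_variants for a in alleles)) if alleles else frozenset()
    if known_variants_path is not None:
        extra = pd.read_csv(known_variants_path, sep="\t", dtype=str, keep_default_na=False)
        known |= frozenset(v.strip() for v in extra.iloc[:, 0] if v.strip())
    return GeneModel(gene=gene, alleles=tuple(alleles), known_variants=known)


def write_gene_model(model: GeneModel, path: str | Path) -> None:
    """Write a gene model as JSON (lossless: keeps extra known variants)."""
    doc = {
        "gene": model.gene,
        "alleles": [
            {
                "name": a.name,
                "defining_variants": sorted(a.defining_variants),
                "activity_value": a.activity_value,
                "function_class": a.function_class,
                "copy_number": a.copy_number,
            }
            for a in model.alleles
        ],
        "known_variants": sorted(model.known_variants),
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


# ---------------------------------------------------------------------------
# Frequency tables


def read_frequency_table(path: str | Path, level: str) -> FrequencyTable:
    """Read a PharmGKB-style frequency TSV: blanks are missing, never zero."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc
    if df.columns[:2].tolist() != ["gene", "identifier"]:
        raise FormatError(f"{path}: first columns must be gene, identifier")
    pops = tuple(df.columns[2:])
    if not pops:
        raise FormatError(f"{path}: no population columns")
    genes = df["gene"].unique()
    if len(genes) != 1:
        raise FormatError(f"{path}: expected a single gene, found {list(genes)}")
    freqs: dict[tuple[str, str], float] = {}
    for i, row in df.iterrows():
        for pop in pops:
            cell = row[pop].strip()
            if cell == "":
                continue
            try:
                value = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path} line {i + 2} [{pop}]: non-numeric frequency {cell!r}"
                ) from None
            freqs[(row["identifier"].strip(), pop)] = value
    table = FrequencyTable(gene=genes[0], level=level, populations=pops, frequencies=freqs)
    for pop in table.missing_populations:
        logger.warning("%s [%s]: population has no documented frequencies", table.gene, pop)
    return table


def write_frequency_table(table: FrequencyTable, path: str | Path) -> None:
    rows = []
    for ident in table.identifiers:
        row: dict[str, object] = {"gene": table.gene, "identifier": ident}
        for pop in table.populations:
            f = table.get(ident, pop)
            row[pop] = "" if f is None else f"{f:.{FREQ_DECIMALS}f}"
        rows.append(row)
    pd.DataFrame(rows, columns=["gene", "identifier", *table.populations]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Panels


def read_panels(
    path: str | Path, models: dict[str, GeneModel] | None = None
) -> tuple[TestPanel, ...]:
    """Read panel definitions, validating targets against gene models if given.

    Variants absent from a model's known universe are logged and *dropped*
    (they cannot enter coverage numerators); a panel naming a gene with no
    model at all is an error.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    tests = doc.get("tests")
    if not isinstance(tests, list):
        raise FormatError(f"{path}: top-level 'tests' list required")
    panels = []
    seen: set[str] = set()
    for entry in tests:
        name = entry.get("name")
        if not name:
            raise FormatError(f"{path}: panel without a name")
        if name in seen:
            raise ValidationError(f"{path}: duplicate test name {name!r}")
        seen.add(name)
        targets = {g: frozenset(vs) for g, vs in entry.get("targets", {}).items()}
        if models is not None:
            unknown_genes = [g for g in targets if g not in models]
            if unknown_genes:
                raise ValidationError(
                    f"panel {name!r} targets genes with no gene model: {unknown_genes}"
                )
            cleaned = {}
            for g, vs in targets.items():
                stray = vs - models[g].known_variants
                if stray:
                    logger.warning(
                        "panel %s / %s: ignoring variants not in known universe: %s",
                        name,
                        g,
                        sorted(stray),
                    )
                kept = vs & models[g].known_variants
                # keep the raw set if nothing survives so the panel stays valid
                cleaned[g] = kept if kept else vs
            targets = cleaned
        panels.append(TestPanel(test_name=name, targets=targets, lab=entry.get("lab")))
    return tuple(panels)


def write_panels(panels: Iterable[TestPanel], path: str | Path) -> None:
    doc = {
        "tests": [
            {
                "name": p.test_name,
                "lab": p.lab,
                "targets": {g: sorted(vs) for g, vs in sorted(p.targets.items())},
            }
            for p in panels
        ]
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


# ---------------------------------------------------------------------------
# Phenotype rules


def read_rules(path: str | Path) -> PhenotypeRuleSet:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    rules = []
    for gene, body in doc.items():
        kind = body.get("rule_kind")
        if kind == "categorical":
            rules.append(
                PhenotypeRule(
                    gene=gene,
                    rule_kind="categorical",
                    altered_categories=frozenset(body.get("altered_categories", [])),
                )
            )
        elif kind == "activity_interval":
            lo = body["normal_interval"][0]
            hi = body["normal_interval"][1]
            hi = math.inf if hi is None else hi
            lo = -math.inf if lo is None else lo
            rules.append(
                PhenotypeRule(gene=gene, rule_kind="activity_interval", normal_interval=(lo, hi))
            )
        else:
            raise FormatError(f"{path}: gene {gene}: unknown rule_kind {kind!r}")
    return PhenotypeRuleSet.from_rules(rules)


def write_rules(rules: PhenotypeRuleSet, path: str | Path) -> None:
    doc: dict[str, dict] = {}
    for gene, rule in rules.rules.items():
        if rule.rule_kind == "categorical":
            doc[gene] = {
                "rule_kind": "categorical",
                "altered_categories": sorted(rule.altered_categories),
            }
        else:
            lo, hi = rule.normal_interval
            doc[gene] = {
                "rule_kind": "activity_interval",
                "normal_interval": [
                    None if math.isinf(lo) else lo,
                    None if math.isinf(hi) else hi,
                ],
            }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def default_rules() -> PhenotypeRuleSet:
    """The shipped CPIC-derived altered-metabolizer criteria for the five CYPs."""
    with resources.as_file(resources.files("cpgx_eval.data") / "default_rules.json") as p:
        return read_rules(p)


# ---------------------------------------------------------------------------
# Phenotype translation lookup


def read_translation_table(path: str | Path) -> TranslationTable:
    """Read a translation lookup TSV.

    Function-pair rows are ``gene, function_a, function_b, label``; diplotype
    override rows put the ``A/B`` identifier in ``function_a`` and leave
    ``function_b`` blank.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc
    needed = {"gene", "function_a", "function_b", "label"}
    if not needed <= set(df.columns):
        raise FormatError(f"{path}: columns must include {sorted(needed)}")
    table = TranslationTable()
    for i, row in df.iterrows():
        gene, a, b, label = (row["gene"], row["function_a"], row["function_b"], row["label"])
        if not label:
            raise FormatError(f"{path} line {i + 2}: empty label")
        if "/" in a and not b:
            table.add_diplotype_override(gene, a, label)
        elif a and b:
            table.add_function_pair(gene, a, b, label)
        else:
            raise FormatError(f"{path} line {i + 2}: neither function pair nor diplotype")
    return table


def default_translation_table() -> TranslationTable:
    """The shipped CPIC function-pair translations for the categorical genes."""
    with resources.as_file(resources.files("cpgx_eval.data") / "default_translation.tsv") as p:
        return read_translation_table(p)


# ---------------------------------------------------------------------------
# Results


def write_results(results: Sequence[DetectionResult], path: str | Path) -> None:
    """Write detection results as a fixed-column TSV (``NA`` for undefined)."""
    if not results:
        raise ValidationError("no results to write")
    rows = []
    for r in results:
        rows.append(
            {
                "test": r.test_name,
                "gene": r.gene,
                "population": r.population,
                "coverage_pct": _fmt(r.coverage_pct, PCT_DECIMALS),
                "population_altered_freq": _fmt(r.population_altered_freq, FREQ_DECIMALS),
                "detectable_altered_freq": _fmt(r.detectable_altered_freq, FREQ_DECIMALS),
                "detection_rate_pct": _fmt(r.detection_rate_pct, PCT_DECIMALS),
                "status": r.status,
            }
        )
    pd.DataFrame(rows, columns=list(RESULT_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> tuple[DetectionResult, ...]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc
    if df.columns.tolist() != list(RESULT_COLUMNS):
        raise FormatError(f"{path}: unexpected columns {df.columns.tolist()}")

    def _num(cell: str) -> float | None:
        return None if cell == "NA" else float(cell)

    return tuple(
        DetectionResult(
            test_name=row["test"],
            gene=row["gene"],
            population=row["population"],
            coverage_pct=_num(row["coverage_pct"]),
            population_altered_freq=_num(row["population_altered_freq"]),
            detectable_altered_freq=_num(row["detectable_altered_freq"]),
            detection_rate_pct=_num(row["detection_rate_pct"]),
            status=row["status"] or STATUS_OK,
        )
        for _, row in df.iterrows()
    )
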