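"""Heatmap and prevalence-bar rendering of detection results.

Heatmaps use a diverging red-blue scale anchored at 0–100 (bright red =
high detection rate, dark blue = low) so images are comparable across
genes, with a side bar panel showing each test's coverage percentage and a
distinct grey hatch for NA cells.
"""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .errors import ValidationError
from .metrics import DetectionMatrix
from .model import FrequencyTable, GeneModel, PhenotypeRuleSet, STATUS_OK
from .phenotype import TranslationTable, altered_diplotype_set


def _save(fig, path: str | Path) -> list[Path]:
    path = Path(path)
    written = []
    for suffix in (".png", ".svg"):
        target = path.with_suffix(suffix)
        fig.savefig(target, bbox_inches="tight", dpi=150)
        written.append(target)
    plt.close(fig)
    return written


def render_heatmap(matrix: DetectionMatrix, gene: str, path: str | Path) -> list[Path]:
    """Render one gene's detection-rate heatmap plus a coverage bar panel.

    Rows are tests (AMP tier rows included if passed as panels), columns are
    populations.  Writes both PNG and SVG next to ``path``; returns the
    written paths.
    """
    tests = [
        t
        for t in matrix.tests
        if any(matrix.get(t, gene, p).status != "not_applicable" for p in matrix.populations)
    ]
    if not tests:
        raise ValidationError(f"no cells for gene {gene}")
    pops = list(matrix.populations)
    values = np.full((len(tests), len(pops)), np.nan)
    coverage = np.zeros(len(tests))
    any_defined = False
    for i, t in enumerate(tests):
        for j, p in enumerate(pops):
            cell = matrix.get(t, gene, p)
            if cell.coverage_pct is not None:
                coverage[i] = cell.coverage_pct
            if cell.status == STATUS_OK:
                values[i, j] = cell.detection_rate_pct
                any_defined = True
    if not any_defined:
        raise ValidationError(f"{gene}: no defined detection-rate cells to render")

    fig, (ax, axbar) = plt.subplots(
        1,
        2,
        figsize=(1.0 + 0.6 * len(pops) + 2.0, 0.8 + 0.45 * len(tests)),
        gridspec_kw={"width_ratios": [len(pops), 3]},
        sharey=True,
    )
    cmap = matplotlib.colormaps["RdBu_r"].copy()
    masked = np.ma.masked_invalid(values)
    cmap.set_bad("0.85")
    im = ax.imshow(masked, cmap=cmap, vmin=0, vmax=100, aspect="auto")
    for i in range(len(tests)):
        for j in range(len(pops)):
            if np.isnan(values[i, j]):
                ax.text(j, i, "NA", ha="center", va="center", fontsize=7, color="0.3")
            else:
                ax.text(
                    j,
                    i,
                    f"{values[i, j]:.0f}",
                    ha="center",
                    va="center",
                    fontsize=7,
                    color="black",
                )
    ax.set_xticks(range(len(pops)), pops, rotation=45, ha="right")
    ax.set_yticks(range(len(tests)), tests)
    ax.set_title(f"{gene} detection rate (%)")
    fig.colorbar(im, ax=ax, shrink=0.8, label="detection rate (%)")

    axbar.barh(range(len(tests)), coverage, color="0.4")
    axbar.set_xlim(0, 100)
    axbar.set_xlabel("coverage (%)")
    axbar.set_title("coverage")
    return _save(fig, path)


def render_prevalence_chart(
    tables: dict[str, FrequencyTable],
    models: dict[str, GeneModel],
    rules: PhenotypeRuleSet,
    path: str | Path,
    lookup: TranslationTable | None = None,
) -> list[Path]:
    """Grouped bars of population altered-metabolizer frequency per gene.

    Missing populations are drawn at zero height and annotated with ``*``,
    following the convention that zeros mark undocumented frequencies rather
    than true absence.
    """
    from .metrics import hwe_diplotype_expansion, population_altered_frequency

    genes = [g for g in tables if g in models]
    if not genes:
        raise ValidationError("no genes shared between tables and models")
    pops: list[str] = []
    for g in genes:
        for p in tables[g].populations:
            if p not in pops:
                pops.append(p)
    fig, ax = plt.subplots(figsize=(1.5 + 0.5 * len(pops) * len(genes), 4))
    width = 0.8 / len(genes)
    x = np.arange(len(pops))
    for k, gene in enumerate(genes):
        table = tables[gene]
        if table.level == "haplotype":
            table = hwe_diplotype_expansion(table, renormalize=True)
        altered = altered_diplotype_set(table, models[gene], rules, lookup)
        heights, annotate = [], []
        for p in pops:
            if p not in table.populations or table.is_population_missing(p):
                heights.append(0.0)
                annotate.append(True)
            else:
                heights.append(100.0 * population_altered_frequency(table, altered, p))
                annotate.append(False)
        bars = ax.bar(x + k * width, heights, width=width, label=gene)
        for bar, note in zip(bars, annotate):
            if note:
                ax.text(
                    bar.get_x() + bar.get_width() / 2, 1, "*", ha="center", fontsize=10
                )
    ax.set_xticks(x + 0.4 - width / 2, pops, rotation=45, ha="right")
    ax.set_ylabel("altered metabolizer frequency (%)")
    ax.set_ylim(0, 100)
    ax.legend(fontsize=8)
    ax.set_title("Altered-metabolizer prevalence (* = frequencies undocumented)")
    return _save(fig, path)
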