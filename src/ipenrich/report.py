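"""Scatter-table construction, top-enriched ranking, and optional plotting.

The scatter table encodes the standard presentation of a bait-vs-control
interactome screen: log10 bait intensity on x, log2 ratio on y, red for
significance 2, green for significance 1, blue for nonspecific binders,
open markers where the control intensity was imputed, and dot size
proportional to the razor+unique peptide count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .enrichment import EnrichmentRecord

_COLOR_BY_SIGNIFICANCE = {0: "blue", 1: "green", 2: "red"}

SCATTER_COLUMNS = (
    "protein_ids",
    "x",
    "y",
    "color_class",
    "open_marker",
    "dot_size",
    "label",
)


@dataclass
class ScatterRow:
    protein_ids: str
    x: float
    y: float
    color_class: str
    open_marker: bool
    dot_size: int
    label: str = ""


def make_scatter_table(
    results: Sequence[EnrichmentRecord],
    annotations: Optional[Mapping[str, str]] = None,
) -> list[ScatterRow]:
    """One scatter row per enrichment record.

    ``annotations`` optionally maps protein_ids to a display label (for
    example known complex members to highlight); unannotated proteins get
    an empty label.
    """
    annotations = annotations or {}
    return [
        ScatterRow(
            protein_ids=rec.protein_ids,
            x=rec.log10_bait,
            y=rec.log2_ratio,
            color_class=_COLOR_BY_SIGNIFICANCE[rec.significance],
            open_marker=rec.control_imputed,
            dot_size=rec.peptides_razor_unique,
            label=annotations.get(rec.protein_ids, ""),
        )
        for rec in results
    ]


def write_scatter_table(path: str | Path, rows: Sequence[ScatterRow]) -> None:
    pd.DataFrame(
        {col: [getattr(row, col) for row in rows] for col in SCATTER_COLUMNS},
        columns=list(SCATTER_COLUMNS),
    ).to_csv(path, sep="\t", index=False, float_format="%.12g")


def rank_top_enriched(
    results: Sequence[EnrichmentRecord],
    n: int = 30,
    class_first: bool = True,
) -> list[EnrichmentRecord]:
    """Top-n enriched proteins.

    Enriched-direction records sorted by significance class (descending),
    then log2 ratio (descending), then protein_ids as a stable tie-break.
    With ``class_first=False`` the ratio alone ranks (class ignored).

    Raises
    ------
    ValueError
        If ``n`` is not positive.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    enriched = [rec for rec in results if rec.direction == "enriched"]
    if class_first:
        key = lambda rec: (-rec.significance, -rec.log2_ratio, rec.protein_ids)
    else:
        key = lambda rec: (-rec.log2_ratio, rec.protein_ids)
    return sorted(enriched, key=key)[:n]


def plot_scatter(
    rows: Sequence[ScatterRow],
    path: str | Path,
    size_scale: float = 3.0,
) -> None:
    """Render the scatter table to an image file (optional convenience).

    Filled/open circles, red/green/blue classes and peptide-count dot
    sizes follow the scatter-table encoding; labelled rows are annotated.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for open_marker in (False, True):
        subset = [row for row in rows if row.open_marker == open_marker]
        if not subset:
            continue
        ax.scatter(
            [row.x for row in subset],
            [row.y for row in subset],
            s=[size_scale * row.dot_size for row in subset],
            c="none" if open_marker else [row.color_class for row in subset],
            edgecolors=[row.color_class for row in subset],
            linewidths=0.8,
            alpha=0.7,
        )
    for row in rows:
        if row.label:
            ax.annotate(row.label, (row.x, row.y), fontsize=7,
                        xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("log10 bait LFQ intensity")
    ax.set_ylabel("log2 ratio (bait / control)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
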