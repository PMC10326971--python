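"""Category-level aggregation of per-protein effect sizes.

The computations behind category violin plots, top-N cargo rankings, and
significant-protein counts: group per-protein values (Log2FC or a fitted
step coefficient) by organelle or ER subcompartment class and summarize.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differential import ALPHA_DEFAULT

UNASSIGNED = "unassigned"


@dataclass
class CategorySummary:
    """Summary statistics for one annotation category."""

    category: str
    n: int
    mean: float
    median: float
    q1: float
    q3: float
    values: pd.Series = field(repr=False, default_factory=pd.Series)


def _category_series(annotations: pd.DataFrame, grouping: str) -> pd.Series:
    if grouping == "organelle":
        cats = annotations["organelle"]
    elif grouping == "er_class":
        # ER proteins keyed by subcompartment; everything else by organelle
        cats = annotations["er_class"].where(
            annotations["er_class"] != "", annotations["organelle"]
        )
    else:
        raise ValueError(f"grouping must be 'organelle' or 'er_class' (got {grouping!r})")
    return pd.Series(cats.to_numpy(), index=annotations["protein_id"].to_numpy())


def summarize_by_category(
    values: pd.Series | dict,
    annotations: pd.DataFrame,
    grouping: str = "er_class",
) -> list[CategorySummary]:
    """Summarize per-protein values by annotation category.

    Each protein lands in exactly one category per grouping; proteins
    without an annotation are grouped under "unassigned".  The returned
    summaries carry the member values so violins can be rendered without
    recomputation.
    """
    vals = pd.Series(values, dtype=float)
    cats = _category_series(annotations, grouping)
    mapped = vals.index.map(cats.to_dict()).fillna(UNASSIGNED)
    out = []
    frame = pd.DataFrame({"value": vals.to_numpy(), "category": mapped}, index=vals.index)
    for cat, grp in frame.groupby("category", sort=True):
        v = grp["value"]
        out.append(
            CategorySummary(
                category=str(cat),
                n=int(len(v)),
                mean=float(v.mean()),
                median=float(v.median()),
                q1=float(v.quantile(0.25)),
                q3=float(v.quantile(0.75)),
                values=v,
            )
        )
    return out


def summaries_to_frame(summaries: list[CategorySummary]) -> pd.DataFrame:
    """Tabular view of category summaries (drops the raw member values)."""
    return pd.DataFrame(
        [
            {
                "category": s.category,
                "n": s.n,
                "mean": s.mean,
                "median": s.median,
                "q1": s.q1,
                "q3": s.q3,
            }
            for s in summaries
        ]
    )


def er_protein_ids(annotations: pd.DataFrame) -> list[str]:
    """The ER proteome: union of every ER subcompartment class."""
    return annotations.loc[
        annotations["organelle"] == "ER", "protein_id"
    ].tolist()


def rank_top(
    values: pd.Series | dict,
    n: int = 25,
    direction: str = "up",
) -> pd.Series:
    """Top-n proteins by value ("up": largest first; "down": smallest first).

    Ordering is stable and fully deterministic: ties are broken by
    protein_id lexicographic order.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down' (got {direction!r})")
    vals = pd.Series(values, dtype=float)
    ascending = direction == "down"
    ordered = vals.sort_index().sort_values(ascending=ascending, kind="stable")
    return ordered.iloc[:n]


def count_significant(
    fits: pd.DataFrame,
    step: int,
    alpha: float = ALPHA_DEFAULT,
    annotations: pd.DataFrame | None = None,
    category_filter: tuple[str, str] | None = None,
) -> tuple[int, int]:
    """Count proteins with significant positive / negative step coefficients.

    ``category_filter`` is an optional ``(grouping, category)`` pair, e.g.
    ``("er_class", "membrane")``, applied via ``annotations``.  A protein
    with q < alpha but a coefficient of exactly 0 counts in neither
    direction.  Returns ``(n_up, n_down)``.
    """
    if step not in (1, 2, 3, 4):
        raise ValueError(f"step must be in 1..4 (got {step})")
    beta = fits[f"beta{step}"]
    q = fits[f"q{step}"]
    mask = pd.Series(True, index=fits.index)
    if category_filter is not None:
        if annotations is None:
            raise ValueError("category_filter requires annotations")
        grouping, category = category_filter
        cats = _category_series(annotations, grouping)
        mask = pd.Series(fits.index.map(cats.to_dict()) == category, index=fits.index)
    sig = (q < alpha) & mask
    n_up = int((sig & (beta > 0)).sum())
    n_down = int((sig & (beta < 0)).sum())
    return n_up, n_down
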