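"""Hierarchical fold-change profiling over a KEGG-Orthology-style tree.

A four-level hierarchy (category > subcategory > pathway > enzyme, with
enzymes mapping to zero or more genes) is aggregated top-down: each node
carries the gene-weighted mean log2 fold change of the *changed* genes
beneath it. Nodes whose enzymes map to no genes at all are kept in the
output with status ``absent`` so profiles from different contrasts stay
structurally comparable; nodes with mapped but unchanged genes are
``no-change``. A gene annotated to several enzymes contributes once per
enzyme.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

LEVEL_COLS = ("level1", "level2", "level3", "enzyme")


@dataclass
class KOHierarchy:
    """Deduplicated flat hierarchy with stable (file-order) node lists."""

    table: pd.DataFrame  # columns level1, level2, level3, enzyme, gene

    def __post_init__(self) -> None:
        missing = [c for c in (*LEVEL_COLS, "gene") if c not in self.table.columns]
        if missing:
            raise ValueError(f"hierarchy table lacks columns: {missing}")
        self._check_forest()

    def _check_forest(self) -> None:
        """Every node must have a single parent (no cycles/conflicts)."""
        for child, parent in (
            ("level2", "level1"),
            ("level3", "level2"),
            ("enzyme", "level3"),
        ):
            parents = self.table.groupby(child)[parent].nunique()
            bad = parents[parents > 1]
            if len(bad):
                raise ValueError(
                    f"node {bad.index[0]!r} has conflicting parents at {child}"
                )

    def nodes(self) -> list[tuple[int, str]]:
        """(level, label) in first-appearance order, levels 1..4."""
        seen: list[tuple[int, str]] = []
        have = set()
        for _, row in self.table.iterrows():
            for lvl, col in enumerate(LEVEL_COLS, start=1):
                key = (lvl, row[col])
                if key not in have:
                    have.add(key)
                    seen.append(key)
        return seen

    def units(self) -> pd.DataFrame:
        """Distinct (enzyme, gene) contribution units with their ancestry."""
        with_gene = self.table[self.table["gene"] != ""]
        return with_gene.drop_duplicates(subset=["enzyme", "gene"])

    def parent_of(self, level: int, label: str) -> str | None:
        if level == 1:
            return None
        child_col = LEVEL_COLS[level - 1]
        parent_col = LEVEL_COLS[level - 2]
        rows = self.table[self.table[child_col] == label]
        return rows[parent_col].iloc[0]


def load_hierarchy(path_or_df: str | Path | pd.DataFrame) -> KOHierarchy:
    """Load a flat TSV (level1, level2, level3, enzyme, gene).

    Duplicate rows collapse (idempotent load); a row with an empty
    intermediate level is rejected with its line number; an empty gene
    field means the enzyme maps to no gene.
    """
    if isinstance(path_or_df, pd.DataFrame):
        tab = path_or_df.copy()
    else:
        tab = pd.read_csv(path_or_df, sep="\t", dtype=str, keep_default_na=False)
    for col in LEVEL_COLS:
        blank = tab[col].astype(str).str.strip() == ""
        if blank.any():
            line = int(np.flatnonzero(blank.to_numpy())[0]) + 2  # 1-based + header
            raise ValueError(f"missing {col} at line {line}")
    tab["gene"] = tab.get("gene", "").astype(str).str.strip()
    tab = tab.drop_duplicates().reset_index(drop=True)
    return KOHierarchy(tab)


def aggregate_profile(
    h: KOHierarchy,
    fold_changes: Mapping[str, float],
    changed: Iterable[str],
    weighting: str = "gene",
) -> pd.DataFrame:
    """Mean log2FC per node over its changed genes, aggregated upward.

    Enzyme value = mean log2FC over the enzyme's changed genes; with the
    default gene weighting every ancestor's value is the mean over all
    changed (enzyme, gene) units beneath it. ``weighting="pathway"``
    instead averages the contributing pathway means unweighted at the
    category/subcategory levels. Status: ``absent`` (no mapped genes at
    all), ``no-change`` (mapped genes but none changed, or mean exactly
    0), else ``up``/``down`` by sign.
    """
    if weighting not in ("gene", "pathway"):
        raise ValueError("weighting must be 'gene' or 'pathway'")
    changed = set(changed)
    missing = [g for g in changed if g not in fold_changes]
    if missing:
        raise ValueError(f"changed gene {missing[0]!r} has no fold change")
    units = h.units()
    is_changed = units["gene"].isin(changed)
    lfc = units["gene"].map(fold_changes).astype(float)

    def pathway_weighted_mean(label: str, col: str) -> float:
        paths = units.loc[units[col] == label, "level3"].unique()
        means = []
        for p in paths:
            sel = (units["level3"] == p) & is_changed
            if sel.any():
                means.append(float(lfc[sel].mean()))
        return float(np.mean(means)) if means else np.nan

    rows = []
    for level, label in h.nodes():
        col = LEVEL_COLS[level - 1]
        under = units[col] == label
        n_mapped = int(under.sum())
        sel = under & is_changed
        n_changed = int(sel.sum())
        if not n_changed:
            mean = np.nan
        elif weighting == "pathway" and level <= 2:
            mean = pathway_weighted_mean(label, col)
        else:
            mean = float(lfc[sel].mean())
        if n_mapped == 0:
            status = "absent"
        elif n_changed == 0 or mean == 0:
            status = "no-change"
        else:
            status = "up" if mean > 0 else "down"
        rows.append(
            {
                "level": level,
                "label": label,
                "parent": h.parent_of(level, label),
                "mean_log2fc": mean,
                "n_changed": n_changed,
                "n_mapped": n_mapped,
                "status": status,
            }
        )
    return pd.DataFrame(rows)


def export_circular_table(profile: pd.DataFrame, h: KOHierarchy) -> pd.DataFrame:
    """Plot-ready table for a circular (ring-per-level) layout.

    Each node's angular share is proportional to the number of enzymes
    beneath it, so shares sum to 1 within every ring; absent nodes keep
    their position with a zero-height bar.
    """
    enzymes = h.table.drop_duplicates(subset=["enzyme"])
    total = len(enzymes)
    out = profile.copy()
    shares, starts = [], []
    cursor = {lvl: 0.0 for lvl in range(1, 5)}
    for _, row in out.iterrows():
        lvl, label = int(row["level"]), row["label"]
        col = LEVEL_COLS[lvl - 1]
        n_enz = int((enzymes[col] == label).sum())
        share = n_enz / total
        shares.append(share)
        starts.append(cursor[lvl])
        cursor[lvl] += share
    out["angular_share"] = shares
    out["angular_start"] = starts
    out["bar_height"] = np.where(
        out["status"].isin(["absent", "no-change"]), 0.0, out["mean_log2fc"].abs()
    )
    return out
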