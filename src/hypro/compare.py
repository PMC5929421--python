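"""Directional overlap of differentially expressed gene sets.

Two contrasts (e.g. the hypoxia response of one stage and the expression
change across one progression step) each yield a set of called genes with
a direction. Genes shared by both sets are *co-regulated* when the
directions agree and *anti-regulated* when they oppose. Percentages are
reported with half-up rounding to the nearest integer alongside the raw
fractions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


def round_half_up(x: float) -> int:
    """Nearest integer, halves away from zero (89.5 -> 90)."""
    return int(math.floor(x + 0.5))


@dataclass
class RegulationSet:
    """Called genes of one contrast with their log2 fold changes.

    Direction is the sign of the fold change; a zero fold change violates
    the contract (a called gene must move).
    """

    label: str
    log2fc: dict[str, float]

    def __post_init__(self) -> None:
        for gene, v in self.log2fc.items():
            if v == 0 or not np.isfinite(v):
                raise ValueError(
                    f"gene {gene!r} in {self.label!r} has no direction (log2FC={v})"
                )

    @property
    def direction(self) -> dict[str, int]:
        return {g: (1 if v > 0 else -1) for g, v in self.log2fc.items()}

    def __len__(self) -> int:
        return len(self.log2fc)

    @property
    def n_up(self) -> int:
        return sum(1 for v in self.log2fc.values() if v > 0)

    @property
    def n_down(self) -> int:
        return len(self) - self.n_up

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"gene": list(self.log2fc), "log2fc": list(self.log2fc.values())}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, label: str | None = None) -> "RegulationSet":
        tab = pd.read_csv(path, sep="\t")
        return cls(
            label=label or Path(path).stem,
            log2fc=dict(zip(tab["gene"], tab["log2fc"])),
        )


@dataclass
class OverlapSummary:
    """Counts and percentages for one pair of directional sets."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    shared: int
    co: int
    anti: int
    breakdown: dict[str, int] = field(default_factory=dict)

    @property
    def co_pct(self) -> int | None:
        """Co-regulated percentage of shared genes (half-up), None if no overlap."""
        if self.shared == 0:
            return None
        return round_half_up(100.0 * self.co / self.shared)

    @property
    def anti_pct(self) -> int | None:
        if self.shared == 0:
            return None
        return round_half_up(100.0 * self.anti / self.shared)

    @property
    def co_fraction(self) -> float | None:
        return None if self.shared == 0 else self.co / self.shared

    @property
    def shared_pct_of_a(self) -> int | None:
        return None if self.n_a == 0 else round_half_up(100.0 * self.shared / self.n_a)

    @property
    def shared_pct_of_b(self) -> int | None:
        return None if self.n_b == 0 else round_half_up(100.0 * self.shared / self.n_b)

    def to_dict(self) -> dict:
        return {
            "set_a": self.label_a,
            "set_b": self.label_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "shared": self.shared,
            "co": self.co,
            "anti": self.anti,
            "co_pct": self.co_pct,
            "anti_pct": self.anti_pct,
            "co_fraction": self.co_fraction,
            "shared_pct_of_a": self.shared_pct_of_a,
            "shared_pct_of_b": self.shared_pct_of_b,
            "breakdown": self.breakdown,
        }


def intersect_and_classify(
    a: RegulationSet, b: RegulationSet
) -> tuple[OverlapSummary, pd.DataFrame]:
    """Classify shared genes as co- or anti-regulated.

    Returns the summary plus a per-gene table (gene, l2fc_a, l2fc_b,
    class) for scatter/regression export. Empty sets are allowed and
    yield an empty summary with undefined percentages.
    """
    dir_a, dir_b = a.direction, b.direction
    shared = sorted(set(dir_a) & set(dir_b))
    rows = []
    breakdown = {"up-up": 0, "down-down": 0, "up-down": 0, "down-up": 0}
    for g in shared:
        da, db = dir_a[g], dir_b[g]
        key = ("up" if da > 0 else "down") + "-" + ("up" if db > 0 else "down")
        breakdown[key] += 1
        rows.append(
            {
                "gene": g,
                "l2fc_a": a.log2fc[g],
                "l2fc_b": b.log2fc[g],
                "class": "co" if da == db else "anti",
            }
        )
    co = breakdown["up-up"] + breakdown["down-down"]
    summary = OverlapSummary(
        label_a=a.label,
        label_b=b.label,
        n_a=len(a),
        n_b=len(b),
        shared=len(shared),
        co=co,
        anti=len(shared) - co,
        breakdown=breakdown,
    )
    table = pd.DataFrame(rows, columns=["gene", "l2fc_a", "l2fc_b", "class"])
    return summary, table


def pairwise_overlap_grid(sets: list[RegulationSet]) -> pd.DataFrame:
    """All-pairs overlap summaries as a labelled DataFrame of objects.

    The grid is symmetric in shared/co/anti; the diagonal is the
    self-overlap (100% co-regulated).
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    labels = [s.label for s in sets]
    grid = pd.DataFrame(index=labels, columns=labels, dtype=object)
    for i, si in enumerate(sets):
        for j, sj in enumerate(sets):
            grid.iloc[i, j], _ = intersect_and_classify(si, sj)
    return grid


def regression_of_shared(table: pd.DataFrame) -> dict | None:
    """OLS slope/intercept of l2fc_b on l2fc_a over shared genes.

    Omitted (None) with fewer than 2 shared genes or zero variance in x.
    """
    if len(table) < 2 or table["l2fc_a"].nunique() < 2:
        return None
    slope, intercept = np.polyfit(table["l2fc_a"], table["l2fc_b"], 1)
    return {"slope": float(slope), "intercept": float(intercept), "n": int(len(table))}


def export_summaries(
    sets: list[RegulationSet],
    pairs: list[tuple[RegulationSet, RegulationSet]] | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Arc-plot counts, Venn counts and paired-log2FC regressions.

    ``pairs`` defaults to consecutive sets. The arc table lists up/down
    totals per set (Table-1 layout); each pair contributes Venn counts
    (a-only, shared, b-only) and, when >= 2 genes are shared, the OLS
    regression of the paired fold changes.
    """
    if pairs is None:
        pairs = list(zip(sets[:-1], sets[1:]))
    arc = [
        {"set": s.label, "up": s.n_up, "down": s.n_down, "total": len(s)}
        for s in sets
    ]
    venn, regressions = [], []
    for a, b in pairs:
        summary, table = intersect_and_classify(a, b)
        venn.append(
            {
                "set_a": a.label,
                "set_b": b.label,
                "a_only": len(a) - summary.shared,
                "shared": summary.shared,
                "b_only": len(b) - summary.shared,
                "co": summary.co,
                "anti": summary.anti,
            }
        )
        reg = regression_of_shared(table)
        regressions.append(
            {"set_a": a.label, "set_b": b.label, "regression": reg}
        )
    out = {"arc": arc, "venn": venn, "regressions": regressions}
    if outdir is not None:
        outdir = Path(outdir)
        pd.DataFrame(arc).to_csv(outdir / "arc_counts.tsv", sep="\t", index=False)
        pd.DataFrame(venn).to_csv(outdir / "venn_counts.tsv", sep="\t", index=False)
        (outdir / "regressions.json").write_text(json.dumps(regressions, indent=2))
    return out
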