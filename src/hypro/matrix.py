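"""Expression containers and within-sample normalization.

Counts are held gene-by-sample together with gene lengths and a sample
sheet mapping each sample to a (stage, condition, replicate) cell of the
design. TPM (transcripts per million) is the within-sample abundance:

    TPM_g = (count_g / length_g) / sum_j (count_j / length_j) * 1e6

A gene is *expressed* when its TPM exceeds 1 in at least one sample
(strict inequality). Filtering to expressed genes does not rescale TPM:
values stay as computed on the full matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

SAMPLE_COLUMNS = ("stage", "condition", "replicate")


@dataclass
class CountMatrix:
    """Gene x sample integer counts with gene lengths and sample metadata.

    counts : DataFrame, genes in rows, samples in columns.
    lengths : Series of per-gene lengths in bp, indexed like counts.
    samples : DataFrame indexed by sample id with columns stage,
        condition, replicate.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()][0]
            raise ValueError(f"missing length for gene {missing!r}")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample sheet lacks columns: {missing}")
        if set(self.samples.index) != set(self.counts.columns):
            raise ValueError("sample sheet does not match count columns")
        self.samples = self.samples.loc[self.counts.columns]
        self.counts.index.name = "gene"
        self.lengths.index.name = "gene"

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def samples_for(self, stage: str | None = None, condition: str | None = None) -> list[str]:
        """Sample ids matching a stage and/or condition."""
        mask = pd.Series(True, index=self.samples.index)
        if stage is not None:
            mask &= self.samples["stage"] == stage
        if condition is not None:
            mask &= self.samples["condition"] == condition
        return list(self.samples.index[mask])

    def to_tsv(self, counts_path: str | Path, samples_path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "length", self.lengths)
        out.to_csv(counts_path, sep="\t", index_label="gene")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, counts_path: str | Path, samples_path: str | Path) -> "CountMatrix":
        tab = pd.read_csv(counts_path, sep="\t", index_col="gene")
        lengths = tab.pop("length")
        samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
        return cls(counts=tab, lengths=lengths, samples=samples)


@dataclass
class ExpressionMatrix:
    """TPM values with the expressed-gene flag (TPM > 1 in >= 1 sample)."""

    tpm: pd.DataFrame
    samples: pd.DataFrame
    expressed: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.expressed is None:
            self.expressed = (self.tpm > 1).any(axis=1)
        self.expressed = self.expressed.reindex(self.tpm.index)

    def to_tsv(self, path: str | Path) -> None:
        out = self.tpm.copy()
        out["expressed"] = self.expressed
        out.to_csv(path, sep="\t", index_label="gene")


def counts_to_tpm(cm: CountMatrix) -> ExpressionMatrix:
    """Length-normalize counts to TPM; every sample column sums to 1e6.

    Raises on zero/missing gene lengths and on all-zero sample columns
    (TPM undefined there).
    """
    lengths = cm.lengths.astype(float)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"non-positive length for gene {bad!r}")
    rate = cm.counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise ValueError(f"sample {bad!r} has an all-zero count column")
    tpm = rate.div(totals, axis=1) * 1e6
    return ExpressionMatrix(tpm=tpm, samples=cm.samples)


def aggregate_transcript_tpm(
    transcript_tpm: pd.DataFrame, transcript_to_gene: pd.Series
) -> pd.DataFrame:
    """Gene-level TPM from transcript-level TPM by summing per gene.

    ``transcript_to_gene`` maps transcript ids (index) to gene ids. Since
    transcript TPMs within a sample sum to 1e6, the gene-level columns do
    too. Gene-level input bypasses this step entirely.
    """
    missing = transcript_tpm.index.difference(transcript_to_gene.index)
    if len(missing):
        raise ValueError(f"transcript {missing[0]!r} has no gene mapping")
    return transcript_tpm.groupby(transcript_to_gene.reindex(transcript_tpm.index)).sum()


def filter_expressed(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Restrict to genes with TPM > 1 somewhere; TPM values are not rescaled."""
    keep = expr.expressed[expr.expressed].index
    return ExpressionMatrix(
        tpm=expr.tpm.loc[keep],
        samples=expr.samples,
        expressed=expr.expressed.loc[keep],
    )


def group_means(expr: ExpressionMatrix) -> pd.DataFrame:
    """Mean TPM across replicates per (stage, condition) group.

    Columns are labelled ``stage_condition`` in design order.
    """
    groups: dict[str, list[str]] = {}
    for sid, row in expr.samples.iterrows():
        groups.setdefault(f"{row['stage']}_{row['condition']}", []).append(sid)
    return pd.DataFrame(
        {label: expr.tpm[cols].mean(axis=1) for label, cols in groups.items()}
    )


def correlation_cluster(
    expr: ExpressionMatrix,
    pseudocount: float = 1.0,
    method: str = "average",
) -> tuple[pd.DataFrame, list[str]]:
    """Spearman correlation of log2(mean TPM + pseudocount) across groups.

    Replicates are averaged per (stage, condition) first; the Spearman
    rank correlation is then computed between every pair of groups, and
    hierarchical clustering (default average linkage on 1 - rho) gives a
    display order. The pseudocount only guards log2(0); rank correlation
    is invariant to its value.

    Returns (correlation matrix, dendrogram leaf order).
    """
    means = group_means(expr)
    if means.shape[1] < 2:
        raise ValueError("need at least two (stage, condition) groups")
    logged = np.log2(means + pseudocount)
    for label in logged.columns:
        if logged[label].nunique() <= 1:
            raise ValueError(f"constant expression vector in group {label!r}")
    rho, _ = spearmanr(logged.to_numpy())
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    corr = pd.DataFrame(rho, index=logged.columns, columns=logged.columns)
    np.fill_diagonal(corr.values, 1.0)
    dist = squareform(np.clip(1.0 - corr.to_numpy(), 0.0, None), checks=False)
    order_idx = leaves_list(linkage(dist, method=method))
    order = [str(corr.columns[i]) for i in order_idx]
    return corr, order
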