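"""Synthetic data for the four-stage isogenic hypoxia design.

Emulates a stages x oxygen-conditions x replicates bulk RNA-seq experiment
(default: 4 stages -- primary, immortalized, transformed, metastasizing --
under atmospheric and moderate-hypoxia oxygen, 2 replicates each) with
negative-binomial counts, planted hypoxia-responsive genes per stage and
planted progression genes per stage transition, plus a survival cohort
whose hazard steps at a planted expression cutoff.

The planted truth is constructed, not sampled: the fraction of genes
shared between a hypoxia set and a progression set that carry concordant
signs equals the requested co-regulated fraction exactly (up to one gene
of rounding), so downstream overlap classification can be validated
against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import CountMatrix

DEFAULT_STAGES = ("primary", "immortalized", "transformed", "metastasizing")
DEFAULT_CONDITIONS = ("atm", "hypoxia")


@dataclass
class ModelDesign:
    """Layout of the stages x conditions x replicates experiment."""

    stages: tuple[str, ...] = DEFAULT_STAGES
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    replicates_per_cell: int = 2
    n_genes: int = 2000
    length_range: tuple[int, int] = (500, 5000)

    def __post_init__(self) -> None:
        if self.replicates_per_cell < 1:
            raise ValueError("replicates_per_cell must be positive")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if len(self.conditions) != 2:
            raise ValueError("exactly two oxygen conditions expected")

    @property
    def n_samples(self) -> int:
        return len(self.stages) * len(self.conditions) * self.replicates_per_cell

    @property
    def genes(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]

    def sample_sheet(self) -> pd.DataFrame:
        rows = []
        for stage in self.stages:
            for cond in self.conditions:
                for rep in range(1, self.replicates_per_cell + 1):
                    rows.append((f"{stage}_{cond}_rep{rep}", stage, cond, rep))
        return pd.DataFrame(
            rows, columns=["sample", "stage", "condition", "replicate"]
        ).set_index("sample")

    def transitions(self) -> list[str]:
        return [
            f"{self.stages[i]}_to_{self.stages[i + 1]}"
            for i in range(len(self.stages) - 1)
        ]


@dataclass
class PlantedTruth:
    """Planted effects: per-stage hypoxia log2FCs, per-transition
    progression log2FCs, and the constructed co-regulated fraction for
    each (stage, transition) pair that shares genes."""

    hdeg_sets: dict[str, dict[str, float]]
    deg_sets: dict[str, dict[str, float]]
    co_fraction: dict[tuple[str, str], float]
    baseline_mean: pd.Series = None  # type: ignore[assignment]
    dispersion: pd.Series = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for sets in (self.hdeg_sets, self.deg_sets):
            for label, mapping in sets.items():
                for gene, lfc in mapping.items():
                    if lfc == 0:
                        raise ValueError(
                            f"planted log2FC must be nonzero ({label}: {gene})"
                        )
        for pair, frac in self.co_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"co_fraction out of [0,1] for {pair}")
        if self.dispersion is not None and (self.dispersion <= 0).any():
            raise ValueError("dispersion must be positive")

    def realized_co_fraction(self, stage: str, transition: str) -> float | None:
        """Sign-concordant fraction among genes planted in both sets."""
        a = self.hdeg_sets.get(stage, {})
        b = self.deg_sets.get(transition, {})
        shared = set(a) & set(b)
        if not shared:
            return None
        co = sum(1 for g in shared if np.sign(a[g]) == np.sign(b[g]))
        return co / len(shared)

    def write_tsv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        rows = [
            {"set": "hdeg", "contrast": s, "gene": g, "log2fc": v}
            for s, m in self.hdeg_sets.items()
            for g, v in m.items()
        ] + [
            {"set": "deg", "contrast": t, "gene": g, "log2fc": v}
            for t, m in self.deg_sets.items()
            for g, v in m.items()
        ]
        pd.DataFrame(rows).to_csv(outdir / "truth_effects.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"stage": s, "transition": t, "co_fraction": f}
                for (s, t), f in self.co_fraction.items()
            ]
        ).to_csv(outdir / "truth_pairs.tsv", sep="\t", index=False)
        if self.baseline_mean is not None:
            gene_tab = pd.DataFrame(
                {"baseline_mean": self.baseline_mean, "dispersion": self.dispersion}
            )
            gene_tab.to_csv(outdir / "truth_genes.tsv", sep="\t", index_label="gene")


@dataclass
class SurvivalTruth:
    """Step-hazard survival cohort parameters.

    Event times are exponential with rate ``hazard_low`` below the
    expression cutoff and ``hazard_high`` at/above it, so the planted
    hazard ratio is hazard_high / hazard_low. Expression follows a
    lognormal law (FPKM-like scale).
    """

    n_patients: int = 541
    cutoff_expression: float = 62.0  # ~60th pct of lognormal(4, 0.5)
    hazard_low: float = 0.03
    hazard_high: float = 0.09
    censor_rate: float = 0.05
    meanlog: float = 4.0
    sdlog: float = 0.5
    horizon: float | None = 15.0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive (empty cohort rejected)")
        if min(self.hazard_low, self.hazard_high) <= 0:
            raise ValueError("hazard rates must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be non-negative")

    @property
    def true_hr(self) -> float:
        return self.hazard_high / self.hazard_low


def default_truth(
    design: ModelDesign,
    seed: int,
    n_hdeg: int = 150,
    n_deg: int = 200,
    n_shared: int = 100,
    effect: float = 3.0,
    co_fractions: tuple[float, ...] = (0.70, 0.40, 0.92),
    baseline_median: float = 80.0,
    baseline_sigma: float = 1.0,
    dispersion: float = 0.05,
) -> PlantedTruth:
    """Construct the default strong-effect planted truth.

    Each stage gets ``n_hdeg`` hypoxia genes; each transition gets
    ``n_deg`` progression genes; the aligned (stage i, transition i->i+1)
    pair shares ``n_shared`` genes of which round(co * n_shared) are
    sign-concordant. Gene blocks are disjoint across pairs so every
    planted overlap is attributable.
    """
    rng = np.random.default_rng(seed)
    genes = design.genes
    n_trans = len(design.stages) - 1
    need = n_trans * (n_hdeg + n_deg - n_shared) + n_hdeg  # + last stage's own set
    if need > design.n_genes:
        raise ValueError(f"need at least {need} genes for the planted sets")
    pool = list(rng.permutation(genes))
    hdeg_sets: dict[str, dict[str, float]] = {}
    deg_sets: dict[str, dict[str, float]] = {}
    co_fraction: dict[tuple[str, str], float] = {}

    def take(k: int) -> list[str]:
        out = pool[:k]
        del pool[:k]
        return out

    for i in range(n_trans):
        stage = design.stages[i]
        trans = design.transitions()[i]
        co = co_fractions[i % len(co_fractions)]
        shared = take(n_shared)
        h_only = take(n_hdeg - n_shared)
        d_only = take(n_deg - n_shared)
        h_map: dict[str, float] = {}
        d_map: dict[str, float] = {}
        n_co = int(np.floor(co * n_shared + 0.5))
        for j, g in enumerate(shared):
            s_h = rng.choice([-1.0, 1.0])
            s_d = s_h if j < n_co else -s_h
            h_map[g] = s_h * effect
            d_map[g] = s_d * effect
        for g in h_only:
            h_map[g] = rng.choice([-1.0, 1.0]) * effect
        for g in d_only:
            d_map[g] = rng.choice([-1.0, 1.0]) * effect
        hdeg_sets[stage] = h_map
        deg_sets[trans] = d_map
        co_fraction[(stage, trans)] = co
    last = design.stages[-1]
    hdeg_sets[last] = {
        g: rng.choice([-1.0, 1.0]) * effect for g in take(n_hdeg)
    }

    baseline = pd.Series(
        baseline_median * np.exp(rng.normal(0.0, baseline_sigma, design.n_genes)),
        index=genes,
    )
    # planted genes are robustly expressed: called DEG sets are conditioned
    # on expression (TPM > 1), so the planted programs sample that stratum
    planted = {g for m in hdeg_sets.values() for g in m} | {
        g for m in deg_sets.values() for g in m
    }
    idx = baseline.index.isin(planted)
    baseline[idx] = np.maximum(baseline[idx], baseline_median)
    disp = pd.Series(np.full(design.n_genes, dispersion), index=genes)
    return PlantedTruth(hdeg_sets, deg_sets, co_fraction, baseline, disp)


def _mean_matrix(design: ModelDesign, truth: PlantedTruth) -> pd.DataFrame:
    """Expected count (before library scaling) per gene and sample.

    Progression effects accumulate along stages; the hypoxia effect of a
    stage applies only in the hypoxic condition of that stage. Effects
    compose multiplicatively on the NB mean.
    """
    genes = pd.Index(design.genes)
    for label, mapping in list(truth.hdeg_sets.items()) + list(truth.deg_sets.items()):
        unknown = set(mapping) - set(genes)
        if unknown:
            raise ValueError(
                f"planted set {label!r} references unknown gene {sorted(unknown)[0]!r}"
            )
    base = truth.baseline_mean.reindex(genes).to_numpy(float)
    stage_mult = {design.stages[0]: np.ones(design.n_genes)}
    for i, trans in enumerate(design.transitions()):
        mult = stage_mult[design.stages[i]].copy()
        d = truth.deg_sets.get(trans, {})
        if d:
            idx = genes.get_indexer(list(d))
            mult = mult.copy()
            mult[idx] = mult[idx] * np.exp2(np.fromiter(d.values(), float))
        stage_mult[design.stages[i + 1]] = mult
    cols = {}
    sheet = design.sample_sheet()
    for sid, row in sheet.iterrows():
        mean = base * stage_mult[row["stage"]]
        if row["condition"] == design.conditions[1]:
            h = truth.hdeg_sets.get(row["stage"], {})
            if h:
                idx = genes.get_indexer(list(h))
                mean = mean.copy()
                mean[idx] = mean[idx] * np.exp2(np.fromiter(h.values(), float))
        cols[sid] = mean
    return pd.DataFrame(cols, index=genes)


def simulate_counts(
    design: ModelDesign,
    truth: PlantedTruth,
    seed: int,
    lib_factor_sigma: float = 0.1,
) -> tuple[CountMatrix, PlantedTruth]:
    """Draw NB counts for the full design; deterministic given the seed.

    Per-sample library factors are lognormal (sigma ``lib_factor_sigma``)
    so between-sample normalization is non-trivial. Counts for gene g in
    sample s are NB with mean baseline_g * 2^(planted effects) * factor_s
    and the gene's dispersion (Poisson at dispersion ~ 0).
    """
    rng = np.random.default_rng(seed)
    means = _mean_matrix(design, truth)
    sheet = design.sample_sheet()
    lengths = pd.Series(
        rng.integers(design.length_range[0], design.length_range[1] + 1, design.n_genes),
        index=means.index,
    )
    factors = np.exp(rng.normal(0.0, lib_factor_sigma, design.n_samples))
    disp = truth.dispersion.reindex(means.index).to_numpy(float)
    mat = np.empty(means.shape, dtype=np.int64)
    m = means.to_numpy() * factors[None, :]
    poisson = disp < 1e-12
    for j in range(means.shape[1]):
        mj = m[:, j]
        col = np.empty(means.shape[0], dtype=np.int64)
        if poisson.any():
            col[poisson] = rng.poisson(mj[poisson])
        if (~poisson).any():
            r = 1.0 / disp[~poisson]
            p = r / (r + mj[~poisson])
            col[~poisson] = rng.negative_binomial(r, p)
        mat[:, j] = col
    counts = pd.DataFrame(mat, index=means.index, columns=means.columns)
    cm = CountMatrix(counts=counts, lengths=lengths, samples=sheet)
    return cm, truth


def simulate_survival(truth: SurvivalTruth, seed: int) -> pd.DataFrame:
    """Survival cohort with a step hazard at the planted expression cutoff.

    Returns a DataFrame with columns patient_id, time, event, expression.
    Observed time = min(event time, censoring time[, horizon]); event = 1
    when death is observed.
    """
    rng = np.random.default_rng(seed)
    n = truth.n_patients
    expr = np.exp(rng.normal(truth.meanlog, truth.sdlog, n))
    high = expr >= truth.cutoff_expression
    rate = np.where(high, truth.hazard_high, truth.hazard_low)
    t_event = rng.exponential(1.0 / rate)
    if truth.censor_rate > 0:
        t_cens = rng.exponential(1.0 / truth.censor_rate, n)
    else:
        t_cens = np.full(n, np.inf)
    if truth.horizon is not None:
        t_cens = np.minimum(t_cens, truth.horizon)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {
            "patient_id": [f"p{i:04d}" for i in range(n)],
            "time": time,
            "event": event,
            "expression": expr,
        }
    )


def synthetic_hierarchy(
    genes: list[str],
    seed: int,
    n_categories: int = 3,
    subcats_per_cat: int = 2,
    pathways_per_subcat: int = 3,
    enzymes_per_pathway: int = 4,
    genes_per_enzyme: int = 3,
    absent_categories: int = 1,
) -> pd.DataFrame:
    """A small KO-style 4-level hierarchy over a subset of ``genes``.

    ``absent_categories`` trailing categories get enzymes with no mapped
    genes, exercising absent-category preservation.
    """
    rng = np.random.default_rng(seed)
    rows = []
    total = n_categories + absent_categories
    for c in range(total):
        cat = f"cat{c + 1}"
        for s in range(subcats_per_cat):
            sub = f"{cat}.sub{s + 1}"
            for p in range(pathways_per_subcat):
                path = f"{sub}.path{p + 1}"
                for e in range(enzymes_per_pathway):
                    enz = f"{path}.enz{e + 1}"
                    if c >= n_categories:
                        rows.append((cat, sub, path, enz, ""))
                    else:
                        for g in rng.choice(genes, genes_per_enzyme, replace=False):
                            rows.append((cat, sub, path, enz, g))
    return pd.DataFrame(
        rows, columns=["level1", "level2", "level3", "enzyme", "gene"]
    )
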