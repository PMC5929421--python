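"""Parameter-recovery and calibration harnesses.

Each function simulates data with the generator, runs the corresponding
estimator, and returns the measured quantity. They are used both by the
test suite and by the reproducibility script, so the numbers reported
there are always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .de import bh_adjust, de_contrast, estimate_dispersion, nb_exact_test
from .matrix import CountMatrix
from .simulate import ModelDesign, PlantedTruth, SurvivalTruth, simulate_counts, simulate_survival
from .surv import cox_hr, scan_cutoff


def _one_stage_design(n_genes: int) -> ModelDesign:
    return ModelDesign(stages=("primary",), n_genes=n_genes)


def _truth(
    design: ModelDesign,
    seed: int,
    n_planted: int,
    effect: float,
    dispersion: float,
    baseline_median: float = 80.0,
    baseline_sigma: float = 1.0,
) -> PlantedTruth:
    rng = np.random.default_rng(seed)
    genes = design.genes
    planted = rng.choice(genes, n_planted, replace=False) if n_planted else []
    signs = rng.choice([-1.0, 1.0], n_planted)
    return PlantedTruth(
        hdeg_sets={"primary": dict(zip(planted, signs * effect))} if n_planted else {},
        deg_sets={},
        co_fraction={},
        baseline_mean=pd.Series(
            baseline_median * np.exp(rng.normal(0, baseline_sigma, design.n_genes)),
            index=genes,
        ),
        dispersion=pd.Series(dispersion, index=genes),
    )


def null_type_one_error(
    seed: int, n_genes: int = 2000, dispersion: float = 0.1, alpha: float = 0.05
) -> float:
    """Fraction of raw exact-test p-values below ``alpha`` on null data.

    Counts are NB with no planted effects (2 vs 2); the dispersion is
    estimated from the data, as in a real analysis.
    """
    design = _one_stage_design(n_genes)
    truth = _truth(design, seed, 0, 0.0, dispersion)
    cm, _ = simulate_counts(design, truth, seed=seed + 1)
    ga = cm.samples_for(condition="atm")
    gb = cm.samples_for(condition="hypoxia")
    est = estimate_dispersion(cm.counts, [ga, gb])
    p = nb_exact_test(cm.counts, ga, gb, est.per_gene)
    return float((p < alpha).mean())


def planted_recovery(
    seed: int,
    n_genes: int = 2000,
    n_planted: int = 200,
    effect: float = 2.0,
    dispersion: float = 0.05,
) -> tuple[float, float]:
    """(sensitivity, empirical FDR) of the full DE calling rule on
    counts with ``n_planted`` genes at |log2FC| = ``effect``."""
    design = _one_stage_design(n_genes)
    truth = _truth(design, seed, n_planted, effect, dispersion)
    cm, _ = simulate_counts(design, truth, seed=seed + 1)
    ga = cm.samples_for(condition="atm")
    gb = cm.samples_for(condition="hypoxia")
    table = de_contrast(cm, ga, gb, label="planted")
    called = set(table.index[table["called"]])
    planted = set(truth.hdeg_sets["primary"])
    tp = len(called & planted)
    sens = tp / len(planted)
    fdr = (len(called) - tp) / len(called) if called else 0.0
    return sens, fdr


def bh_against_quadratic_oracle(seed: int, n_vectors: int = 100) -> bool:
    """Exact agreement of the step-up adjustment with an O(m^2) loop."""
    rng = np.random.default_rng(seed)
    for _ in range(n_vectors):
        p = rng.uniform(size=int(rng.integers(1, 200)))
        m = p.size
        order = np.argsort(p, kind="mergesort")
        oracle = np.empty(m)
        for pos, idx in enumerate(order):
            best = 1.0
            for pos2 in range(pos, m):
                best = min(best, p[order[pos2]] * m / (pos2 + 1))
            oracle[idx] = best
        if not np.array_equal(bh_adjust(p), oracle):
            return False
    return True


def cox_hr_recovery(
    seeds: list[int],
    n_patients: int = 500,
    true_hr: float = 3.0,
) -> list[float]:
    """Cox HR estimates at the planted cutoff over step-hazard cohorts.

    Harness conditions: balanced split (cutoff at the expression median),
    light censoring, no administrative horizon — the information-optimal
    design for HR recovery at fixed n.
    """
    truth = SurvivalTruth(
        n_patients=n_patients,
        cutoff_expression=float(np.exp(4.0)),  # lognormal(4, .5) median
        hazard_low=0.03,
        hazard_high=0.03 * true_hr,
        censor_rate=0.01,
        horizon=None,
    )
    out = []
    for seed in seeds:
        cohort = simulate_survival(truth, seed=seed)
        groups = (cohort["expression"] >= truth.cutoff_expression).astype(float)
        out.append(cox_hr(cohort, groups)["hr"])
    return out


def cutpoint_recovery(
    seeds: list[int], n_patients: int = 500
) -> list[tuple[float, float]]:
    """(selected percentile, planted percentile) per seed for the
    minimal-p scan on cohorts with a cutpoint at the 60th percentile."""
    truth = SurvivalTruth(n_patients=n_patients, censor_rate=0.02)
    out = []
    for seed in seeds:
        cohort = simulate_survival(truth, seed=seed)
        res = scan_cutoff(cohort, fit_cox=False)
        planted_pct = float(
            (cohort["expression"] <= truth.cutoff_expression).mean() * 100
        )
        out.append((res.cutoff_percentile, planted_pct))
    return out
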