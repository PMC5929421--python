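"""Expression-stratified survival: KM curves, log-rank, minimal-p cutpoint.

The cutpoint scan reproduces the common (and knowingly anti-conservative)
prognostic-marker procedure: every distinct expression value between the
20th and 80th percentiles is tried as a threshold, the log-rank p-value
is computed for the resulting high (> cutoff) vs low split, and the
cutoff minimizing p is selected. Because of the implicit multiple
testing, the selected p-value is descriptive, not a calibrated test
level. The hazard ratio of high vs low is the exponentiated Cox
proportional-hazards coefficient (Efron tie handling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank


def _as_arrays(cohort: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = cohort["time"].to_numpy(float)
    e = cohort["event"].to_numpy(int)
    x = cohort["expression"].to_numpy(float)
    if (t < 0).any():
        raise ValueError("negative follow-up times")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("event flags must be 0/1")
    if not np.isfinite(x).all():
        raise ValueError("expression values must be finite")
    return t, e, x


def km_estimate(cohort: pd.DataFrame, groups: pd.Series | np.ndarray) -> dict[str, pd.DataFrame]:
    """Product-limit survival curve per group.

    Returns, per group label, a table with the timeline, the survival
    estimate, and the risk-set bookkeeping (at_risk, observed) used to
    build it. Every group needs at least one subject.
    """
    t, e, _ = _as_arrays(cohort)
    groups = np.asarray(groups)
    out: dict[str, pd.DataFrame] = {}
    for label in pd.unique(groups):
        mask = groups == label
        if mask.sum() == 0:
            raise ValueError(f"empty group {label!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask])
        tab = kmf.event_table.copy()
        tab["survival"] = kmf.survival_function_["KM_estimate"].reindex(tab.index)
        out[str(label)] = tab.reset_index().rename(columns={"event_at": "time"})
    return out


def logrank_test(cohort: pd.DataFrame, groups: pd.Series | np.ndarray) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p) with 1 df.

    Zero observed events across both groups yields (0, 1).
    """
    t, e, _ = _as_arrays(cohort)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError("exactly two non-empty groups required")
    if e.sum() == 0:
        return 0.0, 1.0
    a = groups == labels[0]
    res = _ll_logrank(t[a], t[~a], event_observed_A=e[a], event_observed_B=e[~a])
    return float(res.test_statistic), float(res.p_value)


def cox_hr(
    cohort: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    ties: str = "efron",
) -> dict:
    """Cox PH hazard ratio of group 1 vs group 0 on a binary indicator.

    Returns hr, coef, se and a convergence flag. On divergence (e.g.
    complete separation) the model is refit with a small ridge penalty
    and flagged, with the coefficient bounded.
    """
    t, e, _ = _as_arrays(cohort)
    x = np.asarray(groups, dtype=float)
    if set(np.unique(x)) - {0.0, 1.0}:
        raise ValueError("groups must be a binary 0/1 indicator")
    if e.sum() < 1:
        raise ValueError("at least one event required")
    df = pd.DataFrame({"time": t, "event": e, "group": x})
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph = CoxPHFitter()
            cph.fit(
                df, duration_col="time", event_col="event",
                fit_options={"precision": 1e-9},
            )
            coef = float(cph.params_["group"])
            if not np.isfinite(coef) or abs(coef) > 10:
                raise ConvergenceError("unbounded coefficient")
        except Exception:  # noqa: BLE001 - any fit failure triggers the fallback
            converged = False
            cph = CoxPHFitter(penalizer=0.1)
            cph.fit(df, duration_col="time", event_col="event")
            coef = float(np.clip(cph.params_["group"], -10, 10))
    if not converged:
        warnings.warn(
            "Cox fit diverged (possible separation); ridge-penalized "
            "bounded estimate reported",
            stacklevel=2,
        )
    se = float(cph.standard_errors_["group"])
    return {"hr": float(np.exp(coef)), "coef": coef, "se": se, "converged": converged}


@dataclass
class CutpointScanResult:
    """Full trace of the minimal-p expression-cutpoint scan."""

    grid: pd.DataFrame  # cutoff, p, statistic, n_low, n_high
    cutoff: float
    p: float
    statistic: float
    n_low: int
    n_high: int
    hr: float = np.nan
    coef: float = np.nan
    se: float = np.nan
    cutoff_percentile: float = np.nan
    cox: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.grid.to_csv(path, sep="\t", index=False)


def truncate_followup(cohort: pd.DataFrame, horizon: float) -> pd.DataFrame:
    """Administratively censor follow-up at ``horizon`` time units."""
    out = cohort.copy()
    over = out["time"] > horizon
    out.loc[over, "time"] = horizon
    out.loc[over, "event"] = 0
    return out


def scan_cutoff(
    cohort: pd.DataFrame,
    lo_pct: float = 20.0,
    hi_pct: float = 80.0,
    fit_cox: bool = True,
    horizon: float | None = None,
) -> CutpointScanResult:
    """Minimal-log-rank-p expression cutoff between two percentiles.

    Every distinct observed expression value within [P_lo, P_hi] is
    tested as a threshold ("high" = expression > cutoff). The argmin
    cutoff is returned with the full trace; p-value ties break toward the
    cutoff nearest the median. The selected p is NOT corrected for the
    scan and is reported as descriptive. ``horizon`` optionally censors
    follow-up administratively before scanning.
    """
    if horizon is not None:
        cohort = truncate_followup(cohort, horizon)
    t, e, x = _as_arrays(cohort)
    if len(t) < 10:
        raise ValueError("need at least 10 patients for a cutpoint scan")
    if e.sum() < 1:
        raise ValueError("need at least one event")
    if np.unique(x).size < 2:
        raise ValueError("all expression values identical: no valid cutoff")
    lo, hi = np.percentile(x, [lo_pct, hi_pct])
    candidates = np.unique(x)
    candidates = candidates[(candidates >= lo) & (candidates <= hi)]
    candidates = np.array([c for c in candidates if 0 < (x > c).sum() < len(x)])
    if candidates.size == 0:
        raise ValueError("no valid cutoff inside the percentile window")

    rows = []
    for c in candidates:
        high = x > c
        if e.sum() == 0:
            stat, p = 0.0, 1.0
        else:
            res = _ll_logrank(
                t[~high], t[high], event_observed_A=e[~high], event_observed_B=e[high]
            )
            stat, p = float(res.test_statistic), float(res.p_value)
        rows.append(
            {
                "cutoff": float(c),
                "statistic": stat,
                "p": p,
                "n_low": int((~high).sum()),
                "n_high": int(high.sum()),
            }
        )
    grid = pd.DataFrame(rows)
    pmin = grid["p"].min()
    tied = grid[grid["p"] == pmin]
    median = float(np.median(x))
    sel = tied.iloc[(tied["cutoff"] - median).abs().argmin()]

    result = CutpointScanResult(
        grid=grid,
        cutoff=float(sel["cutoff"]),
        p=float(sel["p"]),
        statistic=float(sel["statistic"]),
        n_low=int(sel["n_low"]),
        n_high=int(sel["n_high"]),
        cutoff_percentile=float((x <= sel["cutoff"]).mean() * 100.0),
    )
    if fit_cox:
        cox = cox_hr(cohort, (x > result.cutoff).astype(float))
        result.hr, result.coef, result.se = cox["hr"], cox["coef"], cox["se"]
        result.cox = cox
    return result
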