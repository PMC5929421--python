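"""Negative-binomial two-group differential expression for count data.

The pipeline mirrors the classical exact-test workflow for small
replicated designs:

1. TMM (trimmed mean of M-values) factors put samples on a common
   effective library scale.
2. Dispersion is estimated by maximizing the NB conditional likelihood
   (common value across genes) and shrunk per gene toward it by weighted
   likelihood (default prior weight equivalent to 10 degrees of freedom).
3. An exact two-sided p-value per gene compares the two group sums after
   quantile-adjusting counts to a common library size: the conditional
   distribution of one group's sum given the total is enumerated, and the
   smaller tail (observed outcome included in both tails) is doubled and
   capped at 1.
4. Benjamini-Hochberg step-up adjustment controls the FDR.

A gene is *called* differentially expressed when adjusted p < 0.01,
|log2FC| > 1 and at least one compared sample exceeds 1 TPM (all strict,
all configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.stats import nbinom, poisson

from .compare import RegulationSet
from .matrix import CountMatrix, counts_to_tpm

_POISSON_EPS = 1e-8  # below this dispersion the NB is treated as Poisson


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _choose_reference(counts: np.ndarray, lib_sizes: np.ndarray) -> int:
    """Sample whose upper-quartile count fraction is closest to the mean."""
    uq = np.array(
        [np.percentile(counts[:, j] / lib_sizes[j], 75) for j in range(counts.shape[1])]
    )
    return int(np.argmin(np.abs(uq - uq.mean())))


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float,
    abundance_trim: float,
    min_genes: int,
) -> float:
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    if o.size == 0:
        warnings.warn("no shared nonzero genes; TMM factor set to 1", stacklevel=3)
        return 1.0
    m = (np.log2(o) - np.log2(n_obs)) - (np.log2(r) - np.log2(n_ref))
    a = 0.5 * ((np.log2(o) - np.log2(n_obs)) + (np.log2(r) - np.log2(n_ref)))
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, o, r = m[finite], a[finite], o[finite], r[finite]
    n = m.size
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
    lo_a, hi_a = np.floor(n * abundance_trim) + 1, n - np.floor(n * abundance_trim)
    # ordinal ranks: ties must not all fall outside the trim window
    rank_m = pd.Series(m).rank(method="first").to_numpy()
    rank_a = pd.Series(a).rank(method="first").to_numpy()
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep2.sum() < min_genes:
        warnings.warn(
            f"only {int(keep2.sum())} usable genes after trimming; TMM factor set to 1",
            stacklevel=3,
        )
        return 1.0
    # inverse asymptotic (delta-method) variance weights
    v = (n_obs - o[keep2]) / (n_obs * o[keep2]) + (n_ref - r[keep2]) / (n_ref * r[keep2])
    f = np.sum(m[keep2] / v) / np.sum(1.0 / v)
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame,
    lib_sizes: pd.Series | None = None,
    logratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
    min_genes: int = 20,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors (geometric mean 1).

    M-values (log count ratios vs a reference sample) are trimmed 30%
    two-sided, A-values (average log abundance) 5% two-sided, and the
    surviving M-values are combined by precision weighting. Samples with
    fewer than ``min_genes`` usable genes fall back to factor 1 with a
    warning.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    mat = counts.to_numpy(float)
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    libs = lib_sizes.to_numpy(float)
    if (libs == 0).any():
        bad = lib_sizes.index[libs == 0][0]
        raise ValueError(f"sample {bad!r} has zero library size")
    ref_idx = _choose_reference(mat, libs)
    f = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            continue
        f[j] = _tmm_pair(
            mat[:, j], mat[:, ref_idx], libs[j], libs[ref_idx],
            logratio_trim, abundance_trim, min_genes,
        )
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=counts.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# Library-size equalization (quantile adjustment)
# ---------------------------------------------------------------------------

def _quantile_adjust(
    counts: np.ndarray,
    eff_libs: np.ndarray,
    common_lib: float,
    phi: np.ndarray,
) -> np.ndarray:
    """Map counts to a common library size by NB quantile matching.

    Each observed count is converted to a mid-probability under its
    fitted NB (mean = gene abundance x own library, gene dispersion) and
    back through the quantile function at the common library size.
    """
    lam = counts.sum(axis=1) / eff_libs.sum()
    out = np.empty_like(counts, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, float), (counts.shape[0],))
    for j in range(counts.shape[1]):
        m_in = lam * eff_libs[j]
        m_out = lam * common_lib
        y = counts[:, j]
        pois = phi < _POISSON_EPS
        p_mid = np.empty(counts.shape[0])
        if pois.any():
            p_mid[pois] = poisson.cdf(y[pois], m_in[pois]) - 0.5 * poisson.pmf(
                y[pois], m_in[pois]
            )
        nb = ~pois
        if nb.any():
            r = 1.0 / phi[nb]
            pr = r / (r + m_in[nb])
            p_mid[nb] = nbinom.cdf(y[nb], r, pr) - 0.5 * nbinom.pmf(y[nb], r, pr)
        p_mid = np.clip(p_mid, 1e-12, 1.0 - 1e-12)
        if pois.any():
            out[pois, j] = poisson.ppf(p_mid[pois], m_out[pois])
        if nb.any():
            r = 1.0 / phi[nb]
            pr = r / (r + m_out[nb])
            out[nb, j] = nbinom.ppf(p_mid[nb], r, pr)
    zero_total = counts.sum(axis=1) == 0
    out[zero_total] = 0.0
    return out


# ---------------------------------------------------------------------------
# Dispersion estimation
# ---------------------------------------------------------------------------

@dataclass
class DispersionEstimates:
    common: float
    per_gene: pd.Series
    prior_df: float


def _group_cond_loglik(y: np.ndarray, r: float | np.ndarray) -> np.ndarray:
    """NB conditional log-likelihood (given the group sum) per gene.

    Assumes equalized library sizes within the group; terms constant in
    the dispersion are dropped.
    """
    n = y.shape[1]
    z = y.sum(axis=1)
    r = np.asarray(r, float)
    return (
        gammaln(y + r[..., None]).sum(axis=-1)
        - n * gammaln(r)
        + gammaln(n * r)
        - gammaln(z + n * r)
    )


def _total_cond_loglik(pseudo_groups: list[np.ndarray], phi: float) -> float:
    r = 1.0 / phi
    return float(sum(_group_cond_loglik(y, r).sum() for y in pseudo_groups))


def estimate_dispersion(
    counts: pd.DataFrame,
    groups: list[list[str]],
    eff_lib_sizes: pd.Series | None = None,
    prior_df: float = 10.0,
    phi_bounds: tuple[float, float] = (1e-6, 5.0),
    grid_size: int = 29,
    user_dispersion: float | None = None,
) -> DispersionEstimates:
    """Common + empirical-Bayes shrunken per-gene NB dispersions.

    The common dispersion maximizes the conditional likelihood summed over
    genes (counts quantile-adjusted to a common library size, refined over
    two rounds). Per-gene values maximize the gene's own conditional
    likelihood plus ``prior_df / residual_df`` times the average
    likelihood profile, so they shrink toward the common value as the
    prior weight grows (``prior_df = inf`` returns the common value
    exactly). Without replication anywhere, a ``user_dispersion`` must be
    supplied.
    """
    reps = [g for g in groups if len(g) >= 2]
    if not reps:
        if user_dispersion is None:
            raise ValueError(
                "no replicated group: supply user_dispersion explicitly"
            )
        per = pd.Series(user_dispersion, index=counts.index)
        return DispersionEstimates(user_dispersion, per, prior_df)
    if eff_lib_sizes is None:
        eff_lib_sizes = counts.sum(axis=0)
    mat = counts.to_numpy(float)
    libs = eff_lib_sizes.loc[counts.columns].to_numpy(float)
    common_lib = float(np.exp(np.mean(np.log(libs))))
    col_idx = {s: i for i, s in enumerate(counts.columns)}

    phi = 0.1
    for _ in range(2):
        pseudo = np.round(_quantile_adjust(mat, libs, common_lib, np.full(mat.shape[0], phi)))
        pgroups = [pseudo[:, [col_idx[s] for s in g]] for g in reps]
        res = minimize_scalar(
            lambda lp: -_total_cond_loglik(pgroups, 10.0**lp),
            bounds=(np.log10(phi_bounds[0]), np.log10(phi_bounds[1])),
            method="bounded",
            options={"xatol": 1e-4},
        )
        phi = float(10.0 ** res.x)
    common = phi

    if np.isinf(prior_df):
        return DispersionEstimates(
            common, pd.Series(common, index=counts.index), prior_df
        )

    df_res = sum(len(g) - 1 for g in reps)
    w = prior_df / df_res
    grid = np.logspace(-4.0, np.log10(phi_bounds[1]), grid_size)
    # likelihood profile per gene over the grid
    ll = np.zeros((mat.shape[0], grid_size))
    for k, ph in enumerate(grid):
        for y in pgroups:
            ll[:, k] += _group_cond_loglik(y, 1.0 / ph)
    avg = ll.mean(axis=0)
    obj = ll + w * avg[None, :]
    best = obj.argmax(axis=1)
    # quadratic interpolation in log-phi around the grid maximum
    logphi = np.log10(grid)
    per = np.empty(mat.shape[0])
    for g in range(mat.shape[0]):
        k = best[g]
        if k == 0 or k == grid_size - 1:
            per[g] = logphi[k]
            continue
        y0, y1, y2 = obj[g, k - 1], obj[g, k], obj[g, k + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.0 if denom >= 0 else 0.5 * (y0 - y2) / denom
        per[g] = logphi[k] + np.clip(shift, -0.5, 0.5) * (logphi[k] - logphi[k - 1])
    return DispersionEstimates(common, pd.Series(10.0**per, index=counts.index), prior_df)


# ---------------------------------------------------------------------------
# Exact test
# ---------------------------------------------------------------------------

def exact_nb_pvalue(s1: int, s2: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided exact NB p-value for group sums at equalized libraries.

    The conditional distribution of the first group's sum given the total
    is enumerated from the joint NB probabilities (sums of n_i iid NB
    variables with common mean and dispersion ``phi``); the observed
    outcome is included in both tails, the smaller tail is doubled, and
    the result is capped at 1. At dispersion ~ 0 the conditional law is
    Binomial(total, n1/(n1+n2)).
    """
    s1, s2 = int(round(s1)), int(round(s2))
    t = s1 + s2
    if t == 0:
        return 1.0
    x = np.arange(t + 1)
    if phi < _POISSON_EPS:
        from scipy.stats import binom

        lp = binom.logpmf(x, t, n1 / (n1 + n2))
    else:
        mu = t / (n1 + n2)
        r1, r2 = n1 / phi, n2 / phi
        p1 = r1 / (r1 + n1 * mu)
        p2 = r2 / (r2 + n2 * mu)
        lp = nbinom.logpmf(x, r1, p1) + nbinom.logpmf(t - x, r2, p2)
    lp = lp - logsumexp(lp)
    p_low = float(np.exp(logsumexp(lp[: s1 + 1])))
    p_high = float(np.exp(logsumexp(lp[s1:])))
    return min(1.0, 2.0 * min(p_low, p_high))


def nb_exact_test(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    dispersion: pd.Series | float,
    eff_lib_sizes: pd.Series | None = None,
) -> pd.Series:
    """Per-gene two-sided exact NB p-values between two sample groups.

    Counts are quantile-adjusted to the geometric-mean effective library
    size before the group sums are compared. Genes with zero total count
    get p = 1.
    """
    cols = list(group_a) + list(group_b)
    sub = counts[cols]
    if eff_lib_sizes is None:
        eff_lib_sizes = sub.sum(axis=0)
    libs = eff_lib_sizes.loc[cols].to_numpy(float)
    common_lib = float(np.exp(np.mean(np.log(libs))))
    phi = (
        dispersion.reindex(counts.index).to_numpy(float)
        if isinstance(dispersion, pd.Series)
        else np.full(len(counts.index), float(dispersion))
    )
    pseudo = np.round(_quantile_adjust(sub.to_numpy(float), libs, common_lib, phi))
    n1, n2 = len(group_a), len(group_b)
    s1 = pseudo[:, :n1].sum(axis=1)
    s2 = pseudo[:, n1:].sum(axis=1)
    pvals = np.ones(len(counts.index))
    for g in range(len(pvals)):
        pvals[g] = exact_nb_pvalue(s1[g], s2[g], n1, n2, phi[g])
    return pd.Series(pvals, index=counts.index, name="pval")


# ---------------------------------------------------------------------------
# Multiple testing and calling
# ---------------------------------------------------------------------------

def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(i) = min_{j >= i} (m / j) p_(j), clipped at 1, in the original
    order. NaNs propagate and are excluded from m.
    """
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    vals = arr[ok]
    m = vals.size
    if m:
        order = np.argsort(vals, kind="mergesort")
        ranked = vals[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.clip(adj, 0.0, 1.0)
        res = np.empty(m)
        res[order] = adj
        out[ok] = res
    if isinstance(p, pd.Series):
        return pd.Series(out, index=p.index, name="padj")
    return out


def de_contrast(
    cm: CountMatrix,
    group_a: list[str],
    group_b: list[str],
    label: str = "contrast",
    alpha: float = 0.01,
    min_l2fc: float = 1.0,
    min_tpm: float = 1.0,
    prior_count: float = 0.5,
    dispersion: DispersionEstimates | float | None = None,
    filter_before_test: bool = True,
    tpm_filter_mode: str = "any_sample",
    tpm: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full two-group DE table for ``group_b`` over ``group_a``.

    Columns: gene, log2FC, pval, padj, tpm_g1, tpm_g2, called, direction.
    The expression filter (TPM > min_tpm in any compared sample, or in
    either group mean with ``tpm_filter_mode="group_mean"``) is applied
    before testing by default, so untested genes carry NaN p-values and
    are never called.
    """
    if tpm_filter_mode not in ("any_sample", "group_mean"):
        raise ValueError("tpm_filter_mode must be 'any_sample' or 'group_mean'")
    cols = list(group_a) + list(group_b)
    sub = cm.counts[cols]
    if tpm is None:
        tpm = counts_to_tpm(cm).tpm
    tpm_cols = tpm[cols]
    if tpm_filter_mode == "group_mean":
        max_tpm = pd.concat(
            [tpm_cols[list(group_a)].mean(axis=1), tpm_cols[list(group_b)].mean(axis=1)],
            axis=1,
        ).max(axis=1)
    else:
        max_tpm = tpm_cols.max(axis=1)
    testable = max_tpm > min_tpm if filter_before_test else pd.Series(True, index=sub.index)

    factors = tmm_factors(sub)
    eff = sub.sum(axis=0) * factors
    tested = sub.loc[testable]
    if isinstance(dispersion, DispersionEstimates):
        disp = dispersion.per_gene.reindex(tested.index)
    elif dispersion is not None:
        disp = pd.Series(float(dispersion), index=tested.index)
    else:
        est = estimate_dispersion(tested, [group_a, group_b], eff_lib_sizes=eff)
        disp = est.per_gene
    pvals = nb_exact_test(tested, group_a, group_b, disp, eff_lib_sizes=eff)
    padj = bh_adjust(pvals)

    cpm = sub.div(eff, axis=1) * 1e6
    mean_a = cpm[list(group_a)].mean(axis=1)
    mean_b = cpm[list(group_b)].mean(axis=1)
    l2fc = np.log2((mean_b + prior_count) / (mean_a + prior_count))

    table = pd.DataFrame(
        {
            "log2FC": l2fc,
            "pval": pvals.reindex(sub.index),
            "padj": padj.reindex(sub.index),
            "tpm_g1": tpm_cols[list(group_a)].mean(axis=1),
            "tpm_g2": tpm_cols[list(group_b)].mean(axis=1),
            "max_tpm": max_tpm,
        },
        index=sub.index,
    )
    table.index.name = "gene"
    table["called"] = (
        (table["padj"] < alpha)
        & (table["log2FC"].abs() > min_l2fc)
        & (table["max_tpm"] > min_tpm)
    ).fillna(False)
    table["direction"] = np.where(
        table["called"], np.sign(table["log2FC"]).astype(int), 0
    )
    table.attrs["label"] = label
    return table


def call_degs(table: pd.DataFrame, label: str | None = None) -> RegulationSet:
    """Extract the called genes of a DE table as a directional set."""
    called = table[table["called"]]
    return RegulationSet(
        label=label or table.attrs.get("label", "contrast"),
        log2fc={g: float(v) for g, v in called["log2FC"].items()},
    )
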