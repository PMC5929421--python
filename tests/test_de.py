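"""DE engine: TMM, dispersion, exact test, BH — each against an
independent oracle or closed-form limit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom, nbinom

from hypro.de import (
    bh_adjust,
    de_contrast,
    estimate_dispersion,
    exact_nb_pvalue,
    nb_exact_test,
    tmm_factors,
)

# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------


def test_tmm_identical_columns_give_unit_factors():
    rng = np.random.default_rng(0)
    col = rng.poisson(60, 300)
    counts = pd.DataFrame({"a": col, "b": col, "c": col})
    assert np.allclose(tmm_factors(counts), 1.0)


def test_tmm_pure_depth_change_gives_unit_factors():
    rng = np.random.default_rng(1)
    base = rng.poisson(100, 300)
    counts = pd.DataFrame({"a": base, "b": 2 * base})
    assert np.allclose(tmm_factors(counts), 1.0, atol=1e-12)


def test_tmm_spiked_sample_matches_brute_force():
    """10 of 100 genes spiked 8-fold: factors within 2% of an independent
    plain trimmed-mean computation."""
    rng = np.random.default_rng(42)
    mu = rng.integers(50, 500, 100).astype(float)
    a = rng.poisson(mu).astype(float)
    b = rng.poisson(mu).astype(float)
    b[:10] *= 8
    counts = pd.DataFrame({"a": a, "b": b})
    f = tmm_factors(counts)
    na, nb = a.sum(), b.sum()
    m = np.log2((b / nb) / (a / na))
    av = 0.5 * np.log2((b / nb) * (a / na))
    keep = (av >= np.quantile(av, 0.05)) & (av <= np.quantile(av, 0.95))
    ms = np.sort(m[keep])
    k = int(np.floor(ms.size * 0.30))
    brute = 2.0 ** ms[k : ms.size - k].mean()
    assert f["b"] / f["a"] == pytest.approx(brute, rel=0.02)


def test_tmm_geometric_mean_is_one(small_dataset):
    cm, _ = small_dataset
    f = tmm_factors(cm.counts)
    assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)


def test_tmm_few_usable_genes_falls_back_with_warning():
    counts = pd.DataFrame({"a": [5, 9, 3, 0, 0], "b": [4, 8, 2, 0, 0]})
    with pytest.warns(UserWarning, match="TMM factor set to 1"):
        f = tmm_factors(counts)
    assert np.allclose(f, 1.0)


# ---------------------------------------------------------------------------
# Dispersion
# ---------------------------------------------------------------------------


def _nb_counts(rng, mean, phi, shape):
    if phi < 1e-12:
        return rng.poisson(np.broadcast_to(mean, shape))
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mean), shape)


def test_common_dispersion_near_zero_on_poisson_data():
    rng = np.random.default_rng(3)
    mu = 80 * np.exp(rng.normal(0, 1, 2000))
    counts = pd.DataFrame(
        rng.poisson(mu[:, None], (2000, 4)), columns=["a1", "a2", "b1", "b2"]
    )
    est = estimate_dispersion(counts, [["a1", "a2"], ["b1", "b2"]])
    assert est.common <= 1e-3


def test_common_dispersion_recovers_planted_value():
    rng = np.random.default_rng(4)
    mu = 80 * np.exp(rng.normal(0, 1, 2000))
    counts = pd.DataFrame(
        _nb_counts(rng, mu[:, None], 0.1, (2000, 4)),
        columns=["a1", "a2", "b1", "b2"],
    )
    est = estimate_dispersion(counts, [["a1", "a2"], ["b1", "b2"]])
    assert est.common == pytest.approx(0.1, rel=0.2)
    # shrunken per-gene values concentrate around the common value
    assert np.median(est.per_gene) == pytest.approx(est.common, rel=0.5)


def test_infinite_prior_weight_returns_common_exactly():
    rng = np.random.default_rng(5)
    counts = pd.DataFrame(
        _nb_counts(rng, 100.0, 0.05, (200, 4)), columns=["a1", "a2", "b1", "b2"]
    )
    est = estimate_dispersion(
        counts, [["a1", "a2"], ["b1", "b2"]], prior_df=np.inf
    )
    assert (est.per_gene == est.common).all()


def test_no_replication_requires_user_dispersion():
    counts = pd.DataFrame({"a": [1, 2], "b": [3, 4]})
    with pytest.raises(ValueError, match="user_dispersion"):
        estimate_dispersion(counts, [["a"], ["b"]])
    est = estimate_dispersion(counts, [["a"], ["b"]], user_dispersion=0.2)
    assert (est.per_gene == 0.2).all()


# ---------------------------------------------------------------------------
# Exact test
# ---------------------------------------------------------------------------


def _oracle_exact(s1: int, s2: int, n1: int, n2: int, phi: float) -> float:
    """Naive float-loop enumeration of the conditional NB tail."""
    t = s1 + s2
    if t == 0:
        return 1.0
    mu = t / (n1 + n2)
    r1, r2 = n1 / phi, n2 / phi
    probs = [
        nbinom.pmf(x, r1, r1 / (r1 + n1 * mu))
        * nbinom.pmf(t - x, r2, r2 / (r2 + n2 * mu))
        for x in range(t + 1)
    ]
    tot = sum(probs)
    lo = sum(probs[: s1 + 1]) / tot
    hi = sum(probs[s1:]) / tot
    return min(1.0, 2.0 * min(lo, hi))


def test_exact_test_matches_brute_force_enumeration():
    rng = np.random.default_rng(6)
    for _ in range(60):
        s1 = int(rng.integers(0, 60))
        s2 = int(rng.integers(0, 60))
        n1 = int(rng.integers(1, 4))
        n2 = int(rng.integers(1, 4))
        phi = float(rng.uniform(0.01, 0.5))
        assert exact_nb_pvalue(s1, s2, n1, n2, phi) == pytest.approx(
            _oracle_exact(s1, s2, n1, n2, phi), abs=1e-10
        )


def test_exact_test_fixture_2_2_vs_40_40():
    p = exact_nb_pvalue(2 + 2, 40 + 40, 2, 2, 0.05)
    assert p == pytest.approx(_oracle_exact(4, 80, 2, 2, 0.05), abs=1e-12)
    assert p < 1e-6


def test_exact_test_poisson_limit_is_binomial():
    """dispersion -> 0: conditional law is Binomial(t, n1/(n1+n2))."""
    rng = np.random.default_rng(7)
    for _ in range(40):
        s1 = int(rng.integers(0, 100))
        s2 = int(rng.integers(0, 100))
        t = s1 + s2
        lo = binom.cdf(s1, t, 0.5) if t else 1.0
        hi = 1.0 - binom.cdf(s1 - 1, t, 0.5) if t else 1.0
        expected = min(1.0, 2 * min(lo, hi))
        assert exact_nb_pvalue(s1, s2, 2, 2, 1e-12) == pytest.approx(
            expected, abs=1e-6
        )


def test_exact_test_symmetric_sums_give_p_one():
    assert exact_nb_pvalue(25, 25, 2, 2, 0.1) == 1.0


def test_exact_test_zero_total_gives_p_one():
    assert exact_nb_pvalue(0, 0, 2, 2, 0.1) == 1.0


def test_exact_test_monotone_in_group_gap():
    """Widening the gap at fixed total never increases p."""
    t = 60
    prev = 1.1
    for s1 in range(30, -1, -5):
        p = exact_nb_pvalue(s1, t - s1, 2, 2, 0.1)
        assert p <= prev + 1e-12
        prev = p


def test_group_label_swap_negates_l2fc_keeps_p(small_dataset):
    cm, _ = small_dataset
    ga = cm.samples_for(stage="primary", condition="atm")
    gb = cm.samples_for(stage="primary", condition="hypoxia")
    t_ab = de_contrast(cm, ga, gb, dispersion=0.05)
    t_ba = de_contrast(cm, gb, ga, dispersion=0.05)
    assert np.allclose(t_ab["log2FC"], -t_ba["log2FC"], equal_nan=True)
    assert np.allclose(
        t_ab["pval"].fillna(-1), t_ba["pval"].fillna(-1), atol=1e-9
    )


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------


def _bh_oracle(p: np.ndarray) -> np.ndarray:
    """O(m^2) double-loop step-up."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for pos, idx in enumerate(order):
        best = 1.0
        for pos2 in range(pos, m):
            cand = p[order[pos2]] * m / (pos2 + 1)
            best = min(best, cand)
        adj[idx] = best
    return adj


def test_bh_hand_example():
    assert np.allclose(bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])


def test_bh_degenerate_cases():
    assert np.allclose(bh_adjust(np.array([1.0, 1.0])), 1.0)
    assert bh_adjust(np.array([0.137]))[0] == pytest.approx(0.137)


def test_bh_nan_propagates_and_reduces_m():
    out = bh_adjust(np.array([0.01, np.nan, 0.04]))
    assert np.isnan(out[1])
    # m = 2 among non-NaN values
    assert np.allclose(out[[0, 2]], _bh_oracle(np.array([0.01, 0.04])))


def test_bh_matches_quadratic_oracle_exactly():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(8)
    for _ in range(25):
        p = rng.uniform(size=rng.integers(1, 60))
        adj = bh_adjust(p)
        assert np.array_equal(adj, _bh_oracle(p))
        assert np.allclose(adj, multipletests(p, method="fdr_bh")[1], atol=1e-12)


@settings(max_examples=30, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
def test_bh_monotone_in_rank_and_bounded(ps):
    p = np.array(ps)
    adj = bh_adjust(p)
    assert ((adj >= 0) & (adj <= 1)).all()
    order = np.argsort(p, kind="mergesort")
    assert (np.diff(adj[order]) >= -1e-15).all()


# ---------------------------------------------------------------------------
# Calling rule
# ---------------------------------------------------------------------------


def test_calling_rule_strict_boundaries():
    table = pd.DataFrame(
        {
            "log2FC": [1.01, 1.0, -1.2, 2.0],
            "pval": [0.001, 0.001, 0.001, 0.02],
            "padj": [0.009, 0.009, 0.009, 0.011],
            "tpm_g1": [5.0, 5.0, 5.0, 5.0],
            "tpm_g2": [9.0, 9.0, 2.0, 20.0],
            "max_tpm": [9.0, 9.0, 5.0, 20.0],
        },
        index=["just_in", "at_fc_boundary", "down", "padj_out"],
    )
    table["called"] = (
        (table["padj"] < 0.01) & (table["log2FC"].abs() > 1) & (table["max_tpm"] > 1)
    )
    table["direction"] = np.where(table["called"], np.sign(table["log2FC"]), 0)
    assert bool(table.loc["just_in", "called"])
    assert not bool(table.loc["at_fc_boundary", "called"])  # strict >
    assert not bool(table.loc["padj_out", "called"])  # strict <
    assert table.loc["down", "direction"] == -1


def test_de_contrast_recovers_planted_hypoxia_genes(small_dataset):
    cm, truth = small_dataset
    from hypro import call_degs

    ga = cm.samples_for(stage="primary", condition="atm")
    gb = cm.samples_for(stage="primary", condition="hypoxia")
    table = de_contrast(cm, ga, gb, label="primary_hypoxia_vs_atm")
    rs = call_degs(table)
    planted = truth.hdeg_sets["primary"]
    called = set(rs.log2fc)
    sens = len(called & set(planted)) / len(planted)
    assert sens >= 0.9
    # directions agree with the planted signs on recovered genes
    for g in called & set(planted):
        assert np.sign(rs.log2fc[g]) == np.sign(planted[g])


def test_group_mean_tpm_filter_is_stricter_than_any_sample(small_dataset):
    cm, _ = small_dataset
    ga = cm.samples_for(stage="primary", condition="atm")
    gb = cm.samples_for(stage="primary", condition="hypoxia")
    t_any = de_contrast(cm, ga, gb, dispersion=0.05)
    t_mean = de_contrast(cm, ga, gb, dispersion=0.05, tpm_filter_mode="group_mean")
    tested_any = t_any["pval"].notna().sum()
    tested_mean = t_mean["pval"].notna().sum()
    assert tested_mean <= tested_any
    with pytest.raises(ValueError, match="tpm_filter_mode"):
        de_contrast(cm, ga, gb, dispersion=0.05, tpm_filter_mode="median")
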