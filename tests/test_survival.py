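"""Survival stage: median split, log-rank, Cox, infiltration association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cernet.simulate import SimConfig, PlantedAxis, TruthSet, generate_survival
from cernet.survival import (
    ConvergenceError,
    DegenerateDataError,
    cox_score_test,
    cox_univariate,
    infiltration_assoc,
    logrank,
    median_split,
)


# -- median split ------------------------------------------------------------

def test_even_split():
    labels = median_split([1.0, 2.0, 3.0, 4.0])
    assert list(labels) == ["low", "low", "high", "high"]


def test_all_equal_is_degenerate():
    with pytest.raises(DegenerateDataError):
        median_split([2.0, 2.0, 2.0, 2.0])


def test_value_at_median_goes_low():
    labels = median_split([1.0, 2.0, 3.0])  # median = 2
    assert list(labels) == ["low", "low", "high"]


# -- log-rank ----------------------------------------------------------------

def test_identical_curves_give_zero_statistic():
    t = np.array([2.0, 4.0, 6.0, 2.0, 4.0, 6.0])
    e = np.array([1, 1, 0, 1, 1, 0])
    g = np.array(["a"] * 3 + ["b"] * 3)
    stat, p = logrank(t, e, g)
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_hand_computed_observed_minus_expected_table():
    # times:  g1: 1(event), 3(event), 5(censored);  g2: 2(event), 4(event), 6(event)
    t = np.array([1.0, 3.0, 5.0, 2.0, 4.0, 6.0])
    e = np.array([1, 1, 0, 1, 1, 1])
    g = np.array(["g1", "g1", "g1", "g2", "g2", "g2"])
    # hand summation of O1-E1 and V over event times 1,2,3,4,6 (group g1):
    # t=1: n=6 n1=3 d=1 d1=1 -> O-E = 1-1/2,  V = (1/2)(1/2)
    # t=2: n=5 n1=2 d=1 d1=0 -> O-E = -2/5,   V = (2/5)(3/5)
    # t=3: n=4 n1=2 d=1 d1=1 -> O-E = 1/2,    V = (1/2)(1/2)
    # t=4: n=3 n1=1 d=1 d1=0 -> O-E = -1/3,   V = (1/3)(2/3)
    # t=6: n=1 n1=0 d=1 d1=0 -> O-E = 0,      V = 0
    ome = 0.5 - 0.4 + 0.5 - 1 / 3 + 0.0
    v = 0.25 + 0.24 + 0.25 + 2 / 9 + 0.0
    stat, p = logrank(t, e, g)
    assert stat == pytest.approx(ome**2 / v, abs=1e-9)


def test_logrank_matches_lifelines(rng):
    pytest.importorskip("lifelines")
    from lifelines.statistics import logrank_test

    x = rng.integers(0, 2, 120)
    t = rng.exponential(1 / (0.01 * 1.8**x))
    e = (rng.random(120) > 0.25).astype(int)
    g = np.where(x == 1, "high", "low")
    stat, p = logrank(t, e, g)
    ref = logrank_test(t[x == 1], t[x == 0], e[x == 1], e[x == 0])
    assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
    assert p == pytest.approx(ref.p_value, rel=1e-9)


def test_logrank_invariant_to_group_relabeling(rng):
    x = rng.integers(0, 2, 60)
    t = rng.exponential(1, 60)
    e = np.ones(60, dtype=int)
    s1, _ = logrank(t, e, np.where(x == 1, "a", "b"))
    s2, _ = logrank(t, e, np.where(x == 1, "b", "a"))
    assert s1 == pytest.approx(s2, rel=1e-12)


def test_logrank_errors():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    with pytest.raises(DegenerateDataError):
        logrank(t, [0, 0, 0, 0], ["a", "a", "b", "b"])
    with pytest.raises(DegenerateDataError):
        logrank(t, [1, 1, 1, 1], ["a", "a", "a", "a"])


# -- Cox ----------------------------------------------------------------------

def grid_search_beta(t, e, x, lo=-3, hi=3, steps=20001):
    """Exhaustive partial-likelihood grid oracle (Efron)."""
    from cernet.survival import _efron_terms

    grid = np.linspace(lo, hi, steps)
    lls = [_efron_terms(t, e, x, b)[2] for b in grid]
    return grid[int(np.argmax(lls))]


def test_cox_matches_grid_oracle(rng):
    n = 60
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1 / np.exp(0.5 * x))
    e = np.ones(n, dtype=int)
    hr, se, p = cox_univariate(t, e, x)
    beta_grid = grid_search_beta(t, e, x)
    assert np.log(hr) == pytest.approx(beta_grid, abs=1e-3)


def test_cox_matches_lifelines_with_ties(rng):
    pytest.importorskip("lifelines")
    from lifelines import CoxPHFitter

    n = 150
    x = rng.integers(0, 2, n).astype(float)
    t = np.ceil(rng.exponential(20 / np.exp(0.4 * x)))  # heavy ties
    e = (rng.random(n) > 0.2).astype(int)
    hr, se, _ = cox_univariate(t, e, x)
    cph = CoxPHFitter().fit(pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e")
    assert np.log(hr) == pytest.approx(cph.params_["x"], abs=1e-6)
    assert se == pytest.approx(cph.standard_errors_["x"], abs=1e-6)


def test_null_association_hr_near_one(rng):
    n = 3000
    x = rng.integers(0, 2, n)
    t = rng.exponential(1.0, n)
    e = np.ones(n, dtype=int)
    hr, _, _ = cox_univariate(t, e, x.astype(float))
    assert 0.8 < hr < 1.25


def test_score_test_equals_logrank_on_tie_free_data(rng):
    for _ in range(5):
        n = 80
        x = rng.integers(0, 2, n)
        t = rng.exponential(1 / (0.01 * 1.5**x))  # continuous: no ties a.s.
        e = (rng.random(n) > 0.3).astype(int)
        if e.sum() == 0:
            continue
        g = np.where(x == 1, "high", "low")
        stat, _ = logrank(t, e, g)
        assert cox_score_test(t, e, g) == pytest.approx(stat, abs=1e-6)


def test_planted_hazard_ratio_recovery():
    """Generator HR 1.48 at n=2000 is recovered within [1.33, 1.63].

    The estimate is averaged over replicate survival draws so the check
    targets estimator recovery rather than single-cohort sampling noise.
    """
    cfg = SimConfig(n_tumour=2000, n_normal=5, n_mrna=5, n_lncrna=1, n_mirna=1,
                    prognostic_gene="gene0001", prognostic_hr=1.48, rng_seed=11)
    from cernet.simulate import generate_cohort

    genes, _, truth = generate_cohort(cfg)
    ts = genes.samples_in_group("tumour")
    expr = genes.values.loc["gene0001", ts].to_numpy(dtype=float)
    labels = median_split(expr)
    log_hrs = []
    for rep in range(10):
        clin = generate_survival(genes, truth, rng_seed=rep, censor_rate=0.3)
        clin = clin.set_index("sample").loc[ts]
        hr, _, _ = cox_univariate(clin["time"].to_numpy(),
                                  clin["event"].to_numpy(), labels)
        log_hrs.append(np.log(hr))
    assert 1.33 < np.exp(np.mean(log_hrs)) < 1.63


def test_complete_separation_is_flagged():
    t = np.r_[np.arange(1, 21.0), np.arange(100, 120.0)]
    e = np.ones(40, dtype=int)
    x = np.r_[np.ones(20), np.zeros(20)]
    with pytest.raises((ConvergenceError, DegenerateDataError)):
        cox_univariate(t, e, x)


# -- infiltration -------------------------------------------------------------

def test_monotone_transform_gives_rho_one(rng):
    x = rng.normal(size=50)
    infil = pd.DataFrame([np.exp(x), -np.exp(x)], index=["Macrophage", "Neutrophil"],
                         columns=[f"s{i}" for i in range(50)])
    recs = infiltration_assoc(x, infil, gene="g")
    by_ct = {r.cell_type: r for r in recs}
    assert by_ct["Macrophage"].correlation == pytest.approx(1.0)
    assert by_ct["Neutrophil"].correlation == pytest.approx(-1.0)
    assert recs[0].cell_type == "Macrophage"  # sorted descending
    for r in recs:
        assert r.adj_p >= r.p - 1e-15


def test_planted_macrophage_and_neutrophil_are_extremes():
    from cernet.simulate import generate_cohort, generate_infiltration

    cfg = SimConfig(n_tumour=120, n_normal=5, n_mrna=10, n_lncrna=2, n_mirna=2,
                    prognostic_gene="gene0001", rng_seed=4)
    genes, _, truth = generate_cohort(cfg)
    infil = generate_infiltration(genes, truth, noise_sd=0.5, rng_seed=4)
    ts = genes.samples_in_group("tumour")
    x = genes.values.loc["gene0001", ts].to_numpy(dtype=float)
    recs = infiltration_assoc(x, infil, gene="gene0001")
    assert recs[0].cell_type == "Macrophage"   # strongest positive
    assert recs[-1].cell_type == "Neutrophil"  # strongest negative
    assert recs[0].adj_p < 0.05 and recs[-1].adj_p < 0.05
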