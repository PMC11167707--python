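"""Median-split survival analysis and immune-infiltration association.

For each candidate gene, tumour samples are dichotomized at the gene's median
expression (ties go to the low group), and the high/low groups are compared
with the two-group log-rank test and a univariate Cox proportional-hazards
fit.  Both are implemented here directly: the log-rank statistic is the
classical (O - E)^2 / V sum over distinct event times with the hypergeometric
variance, and the Cox model maximizes the partial likelihood by Newton's
method with the Efron approximation for tied event times.  On tie-free data
the Cox score test at beta = 0 coincides with the log-rank statistic, which
the test suite checks numerically.

Gene-infiltration association is a Spearman rank correlation per immune cell
type with Benjamini-Hochberg adjustment across cell types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DegenerateDataError",
    "ConvergenceError",
    "SurvivalResult",
    "InfiltrationAssoc",
    "median_split",
    "logrank",
    "cox_univariate",
    "cox_score_test",
    "survival_screen",
    "infiltration_assoc",
    "read_clinical",
]


class DegenerateDataError(ValueError):
    """Raised when the data cannot support the requested test."""


class ConvergenceError(RuntimeError):
    """Raised when the partial-likelihood Newton iteration fails."""


@dataclass(frozen=True)
class SurvivalResult:
    gene: str
    hazard_ratio: float
    cox_p: float
    logrank_stat: float
    logrank_p: float
    n_high: int
    n_low: int


@dataclass(frozen=True)
class InfiltrationAssoc:
    gene: str
    cell_type: str
    correlation: float
    p: float
    adj_p: float


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def median_split(expr) -> np.ndarray:
    """Label samples 'high' (value > median) or 'low' (value <= median).

    Raises :class:`DegenerateDataError` when either group would be empty
    (e.g. all values identical).
    """
    x = np.asarray(expr, dtype=float)
    med = np.median(x)
    labels = np.where(x > med, "high", "low")
    if (labels == "high").sum() == 0 or (labels == "low").sum() == 0:
        raise DegenerateDataError("median split produced an empty group")
    return labels


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def _as_binary(groups) -> np.ndarray:
    g = np.asarray(groups)
    levels = sorted(set(g.tolist()), key=str)
    if len(levels) != 2:
        raise DegenerateDataError(f"need exactly two groups, got {levels}")
    # 'high' is the exposed group in a median split; otherwise the second
    # level in sorted order is coded 1 (log-rank is invariant to the choice)
    one = "high" if levels == ["high", "low"] else levels[1]
    return (g == one).astype(int)


def logrank(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test.

    statistic = (sum_k (O1k - E1k))^2 / sum_k Vk over distinct event times,
    with Vk the hypergeometric variance; p from chi-square on 1 df.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    x = _as_binary(groups)
    if x.sum() == 0 or x.sum() == len(x):
        raise DegenerateDataError("one group is empty")
    if e.sum() == 0:
        raise DegenerateDataError("no observed events")

    order = np.argsort(t, kind="stable")
    ts, es, xs = t[order], e[order], x[order]
    uniq, start = np.unique(ts, return_index=True)
    ntot = len(ts)
    # at-risk counts just before each unique time
    n_at_risk = ntot - start
    n1_at_risk = xs[::-1].cumsum()[::-1][start]
    # event counts at each unique time
    d_all = np.add.reduceat(es, start)
    d1_all = np.add.reduceat(es * xs, start)
    has_event = d_all > 0
    n, n1 = n_at_risk[has_event], n1_at_risk[has_event]
    d, d1 = d_all[has_event], d1_all[has_event]
    o_minus_e = (d1 - d * n1 / n).sum()
    ok = n > 1
    var = (d[ok] * (n1[ok] / n[ok]) * (1 - n1[ok] / n[ok])
           * (n[ok] - d[ok]) / (n[ok] - 1)).sum()
    if var == 0:
        return 0.0, 1.0
    stat = o_minus_e**2 / var
    return float(stat), float(stats.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# Cox partial likelihood (Efron ties)
# ---------------------------------------------------------------------------

def _efron_terms(t, e, x, beta):
    """Score U(beta) and information I(beta) of the Efron partial likelihood."""
    order = np.argsort(-t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    w = np.exp(beta * x)
    cs0 = np.cumsum(w)
    cs1 = np.cumsum(w * x)
    cs2 = np.cumsum(w * x * x)
    U = 0.0
    info = 0.0
    loglik = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        # block [i, j) shares a time; risk set = indices 0..j-1
        dmask = e[i:j] == 1
        d = int(dmask.sum())
        if d > 0:
            S0r, S1r, S2r = cs0[j - 1], cs1[j - 1], cs2[j - 1]
            xd = x[i:j][dmask]
            wd = w[i:j][dmask]
            S0d, S1d, S2d = wd.sum(), (wd * xd).sum(), (wd * xd * xd).sum()
            U += xd.sum()
            loglik += beta * xd.sum()
            for k in range(d):
                f = k / d
                phi0 = S0r - f * S0d
                phi1 = S1r - f * S1d
                phi2 = S2r - f * S2d
                U -= phi1 / phi0
                info += phi2 / phi0 - (phi1 / phi0) ** 2
                loglik -= np.log(phi0)
        i = j
    return U, info, loglik


def cox_score_test(times, events, groups) -> float:
    """Score statistic U(0)^2 / I(0) of the Cox partial likelihood.

    Equals the log-rank statistic on tie-free data.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    x = _as_binary(groups).astype(float)
    U, info, _ = _efron_terms(t, e, x, 0.0)
    if info == 0:
        raise DegenerateDataError("zero information at beta = 0")
    return float(U * U / info)


def cox_univariate(
    times, events, covariate, max_iter: int = 50, tol: float = 1e-9
) -> tuple[float, float, float]:
    """Univariate Cox PH fit: returns (hazard ratio, se(beta), Wald p).

    The covariate may be a binary group labelling or a numeric vector.
    Newton's method on the Efron partial likelihood; complete separation or
    non-convergence raises :class:`ConvergenceError`.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    cov = np.asarray(covariate)
    if cov.dtype.kind in "OUS":
        x = _as_binary(cov).astype(float)
    else:
        x = cov.astype(float)
    if e.sum() == 0:
        raise DegenerateDataError("no observed events")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant covariate")

    beta = 0.0
    for _ in range(max_iter):
        U, info, _ = _efron_terms(t, e, x, beta)
        if info <= 0:
            raise ConvergenceError(f"non-positive information at beta={beta:.3g}")
        step = U / info
        # dampen absurd steps (near-separation)
        step = float(np.clip(step, -5.0, 5.0))
        beta += step
        if abs(beta) > 15:
            raise ConvergenceError(
                "coefficient diverging; groups may be completely separated"
            )
        if abs(step) < tol:
            break
    else:
        raise ConvergenceError(f"no convergence in {max_iter} iterations (beta={beta:.4g})")
    _, info, _ = _efron_terms(t, e, x, beta)
    se = 1.0 / np.sqrt(info)
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return float(np.exp(beta)), float(se), float(p)


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------

def survival_screen(
    expr_matrix: pd.DataFrame, clinical: pd.DataFrame, genes
) -> list[SurvivalResult]:
    """Median-split log-rank + Cox for each requested gene.

    ``expr_matrix`` is features x samples over tumour samples; ``clinical``
    has columns (sample, time, event).  Samples are joined on ids; genes with
    degenerate splits are skipped.
    """
    clin = clinical.set_index("sample")
    common = [s for s in expr_matrix.columns if s in clin.index]
    if len(common) < 4:
        raise DegenerateDataError("too few samples with clinical data")
    times = clin.loc[common, "time"].to_numpy(dtype=float)
    events = clin.loc[common, "event"].to_numpy(dtype=int)
    results = []
    for gene in genes:
        if gene not in expr_matrix.index:
            continue
        x = expr_matrix.loc[gene, common].to_numpy(dtype=float)
        try:
            labels = median_split(x)
            stat, lr_p = logrank(times, events, labels)
            hr, _, cox_p = cox_univariate(times, events, labels)
        except (DegenerateDataError, ConvergenceError):
            continue
        results.append(
            SurvivalResult(
                gene, hr, cox_p, stat, lr_p,
                int((labels == "high").sum()), int((labels == "low").sum()),
            )
        )
    return results


def infiltration_assoc(
    gene_expr,
    infiltration: pd.DataFrame,
    gene: str = "",
    method: str = "spearman",
) -> list[InfiltrationAssoc]:
    """Correlate one gene's expression with every infiltration cell type.

    ``infiltration`` is cell-type x sample, aligned with ``gene_expr``.
    Returns records sorted by correlation descending, BH-adjusted across the
    cell types.
    """
    x = np.asarray(gene_expr, dtype=float)
    if infiltration.shape[1] != len(x):
        raise ValueError("infiltration columns must match expression samples")
    rows = []
    for ct in infiltration.index:
        y = infiltration.loc[ct].to_numpy(dtype=float)
        if method == "spearman":
            rho, p = stats.spearmanr(x, y)
        elif method == "pearson":
            rho, p = stats.pearsonr(x, y)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append((str(ct), float(rho), float(p)))
    adj = multipletests([p for _, _, p in rows], method="fdr_bh")[1]
    recs = [
        InfiltrationAssoc(gene, ct, rho, p, float(a))
        for (ct, rho, p), a in zip(rows, adj)
    ]
    recs.sort(key=lambda r: -r.correlation)
    return recs


def read_clinical(path) -> pd.DataFrame:
    clin = pd.read_csv(path, sep="\t")
    if not {"sample", "time", "event"} <= set(clin.columns):
        raise ValueError("clinical table needs sample, time, event columns")
    if (clin["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not set(clin["event"].unique()) <= {0, 1}:
        raise ValueError("event must be 0 (censored) or 1 (observed)")
    return clin
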