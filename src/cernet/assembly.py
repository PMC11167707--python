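"""ceRNA triple assembly and regulatory network construction.

A (lncRNA, miRNA, mRNA) triple is a candidate competing-endogenous-RNA
relation when three criteria hold:

1. the differentially expressed lncRNA and mRNA are positively co-expressed
   (Pearson r strictly above ``r_min`` with p below ``alpha``);
2. interaction tables link the lncRNA to the miRNA and the miRNA to the mRNA,
   the miRNA is differentially expressed opposite to both partners, and the
   miRNA-mRNA prediction score is at least ``score_min`` (inclusive);
3. the triple therefore falls in one of two direction classes:
   up (lncRNA up / miRNA down / mRNA up) or down (the mirror).

Triples are grouped into an up- and a down-regulated tripartite network,
merged, and the top decile of nodes by degree (ties included) are reported as
hubs.

Boundary semantics are deliberate: r > r_min strict, p < alpha strict,
score >= score_min inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DERecord, ExpressionMatrix, TUMOUR

__all__ = [
    "CorrelationRecord",
    "CeRNATriple",
    "pearson_with_p",
    "correlated_pairs",
    "filter_interactions",
    "assemble_triples",
    "build_networks",
    "merge_and_hubs",
    "direction_map",
    "network_to_sif",
]


@dataclass(frozen=True)
class CorrelationRecord:
    lncrna: str
    mrna: str
    r: float
    p: float


@dataclass(frozen=True)
class CeRNATriple:
    lncrna: str
    mirna: str
    mrna: str
    direction_class: str  # "up" (lnc up, mi down, mRNA up) or "down"
    r: float
    p: float
    score: float


def direction_map(records: list[DERecord]) -> dict[str, str]:
    """feature id -> direction for significant records only."""
    return {r.feature_id: r.direction for r in records if r.direction != "ns"}


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-sided t-transform p-value.

    p is derived from t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom.
    Constant input vectors are rejected (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("vectors must have equal length")
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.dot(xc, xc)
    sy = np.dot(yc, yc)
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.dot(xc, yc) / np.sqrt(sx * sy))
    r = max(-1.0, min(1.0, r))
    p = _t_pvalue(r, n)
    return r, p


def _t_pvalue(r, n):
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return p if p.ndim else float(p)


def correlated_pairs(
    lnc_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    r_min: float = 0.8,
    alpha: float = 0.05,
    samples: list[str] | None = None,
) -> list[CorrelationRecord]:
    """Exhaustive DElncRNA x DEmRNA Pearson screen.

    Returns pairs with r strictly greater than ``r_min`` and p < ``alpha``,
    computed over ``samples`` (default: tumour samples).  Constant features
    are skipped (their correlation is undefined).
    """
    if samples is None:
        samples = lnc_expr.samples_in_group(TUMOUR)
    X = lnc_expr.values[samples].to_numpy(dtype=float)
    Y = mrna_expr.values[samples].to_numpy(dtype=float)
    n = len(samples)
    if n < 3:
        raise ValueError("need at least 3 samples for correlation")
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xn = np.sqrt((Xc * Xc).sum(axis=1))
    yn = np.sqrt((Yc * Yc).sum(axis=1))
    ok_x = xn > 0
    ok_y = yn > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Xc @ Yc.T) / np.outer(xn, yn)
    R = np.clip(R, -1.0, 1.0)
    out = []
    lnc_ids = list(lnc_expr.feature_ids)
    mrna_ids = list(mrna_expr.feature_ids)
    ii, jj = np.where(np.outer(ok_x, ok_y) & (R > r_min))
    P = _t_pvalue(R[ii, jj], n)
    for i, j, r, p in zip(ii, jj, R[ii, jj], np.atleast_1d(P)):
        if p < alpha:
            out.append(CorrelationRecord(lnc_ids[i], mrna_ids[j], float(r), float(p)))
    out.sort(key=lambda c: (c.lncrna, c.mrna))
    return out


# ---------------------------------------------------------------------------
# interaction filtering
# ---------------------------------------------------------------------------

def filter_interactions(
    lnc_mi: pd.DataFrame,
    mi_mrna: pd.DataFrame,
    de_lnc: dict[str, str],
    de_mi: dict[str, str],
    de_mrna: dict[str, str],
    score_min: float = 0.95,
) -> tuple[list[tuple[str, str]], list[tuple[str, str, float]]]:
    """Keep interactions whose endpoints are DE with opposite directions.

    lncRNA-miRNA rows require both ends DE and opposite; miRNA-mRNA rows
    additionally require prediction score >= score_min (inclusive).
    """
    lm = []
    for ln, mi in zip(lnc_mi["lncrna"], lnc_mi["mirna"]):
        dl, dm = de_lnc.get(ln), de_mi.get(mi)
        if dl is not None and dm is not None and dl != dm:
            lm.append((str(ln), str(mi)))
    mg = []
    scores = mi_mrna["score"] if "score" in mi_mrna else [None] * len(mi_mrna)
    for mi, g, s in zip(mi_mrna["mirna"], mi_mrna["mrna"], scores):
        if s is None:
            raise ValueError("miRNA-mRNA rows require a prediction score")
        dm, dg = de_mi.get(mi), de_mrna.get(g)
        if dm is not None and dg is not None and dm != dg and float(s) >= score_min:
            mg.append((str(mi), str(g), float(s)))
    return sorted(set(lm)), sorted(set(mg))


def assemble_triples(
    lnc_mi_pairs: list[tuple[str, str]],
    mi_mrna_pairs: list[tuple[str, str, float]],
    corr_records: list[CorrelationRecord],
    de_lnc: dict[str, str] | None = None,
    de_mrna: dict[str, str] | None = None,
) -> list[CeRNATriple]:
    """Join retained pairs on the shared miRNA, gated by co-expression.

    (L, M, G) is emitted iff (L, M) was retained, (M, G) was retained, and a
    correlation record for (L, G) exists.  When DE direction maps are given,
    the lncRNA and mRNA must share a direction (that becomes the triple's
    direction class); pairs retained by :func:`filter_interactions` already
    oppose the miRNA to both partners.  Output is sorted lexicographically on
    (L, M, G).
    """
    corr = {(c.lncrna, c.mrna): c for c in corr_records}
    by_mi: dict[str, list[tuple[str, float]]] = {}
    for mi, g, s in mi_mrna_pairs:
        by_mi.setdefault(mi, []).append((g, s))
    triples = []
    for ln, mi in lnc_mi_pairs:
        for g, s in by_mi.get(mi, ()):
            c = corr.get((ln, g))
            if c is None:
                continue
            dl = de_lnc.get(ln) if de_lnc is not None else None
            dg = de_mrna.get(g) if de_mrna is not None else None
            if dl is not None and dg is not None and dl != dg:
                continue  # direction class inconsistent
            klass = dl or dg or "up"
            triples.append(CeRNATriple(ln, mi, g, klass, c.r, c.p, float(s)))
    triples.sort(key=lambda t: (t.lncrna, t.mirna, t.mrna))
    return triples


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def _add_triple(g: nx.Graph, t: CeRNATriple, mi_dir: str) -> None:
    g.add_node(t.lncrna, kind="lncRNA", direction=t.direction_class)
    g.add_node(t.mirna, kind="miRNA", direction=mi_dir)
    g.add_node(t.mrna, kind="mRNA", direction=t.direction_class)
    g.add_edge(t.lncrna, t.mirna, kind="lnc-mi")
    g.add_edge(t.mirna, t.mrna, kind="mi-mRNA")


def build_networks(triples: list[CeRNATriple]) -> tuple[nx.Graph, nx.Graph]:
    """Split triples by direction class into the up and down networks."""
    up, down = nx.Graph(), nx.Graph()
    up.graph["triples"] = []
    down.graph["triples"] = []
    for t in triples:
        if t.direction_class == "up":
            _add_triple(up, t, "down")
            up.graph["triples"].append(t)
        else:
            _add_triple(down, t, "up")
            down.graph["triples"].append(t)
    return up, down


def merge_and_hubs(
    up: nx.Graph, down: nx.Graph, decile: float = 0.10
) -> tuple[nx.Graph, set[str]]:
    """Merge the direction networks and return top-decile degree hubs.

    k = ceil(decile * node count); the hub set is every node whose degree is
    at least the k-th largest degree, so boundary ties are all included.
    """
    merged = nx.Graph()
    merged.graph["triples"] = list(up.graph.get("triples", [])) + list(
        down.graph.get("triples", [])
    )
    for g in (up, down):
        merged.add_nodes_from(g.nodes(data=True))
        merged.add_edges_from(g.edges(data=True))
    n = merged.number_of_nodes()
    if n == 0:
        return merged, set()
    k = int(np.ceil(decile * n))
    degrees = dict(merged.degree())
    threshold = sorted(degrees.values(), reverse=True)[k - 1]
    hubs = {v for v, d in degrees.items() if d >= threshold}
    return merged, hubs


def network_to_sif(g: nx.Graph) -> str:
    lines = []
    for a, b, data in sorted(g.edges(data=True)):
        lines.append(f"{a}\t{data.get('kind', 'pp')}\t{b}")
    return "\n".join(lines) + ("\n" if lines else "")
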