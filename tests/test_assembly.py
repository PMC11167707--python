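"""Triple assembly: correlation gating, interaction filters, networks, hubs."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cernet.assembly import (
    CorrelationRecord,
    assemble_triples,
    build_networks,
    correlated_pairs,
    filter_interactions,
    merge_and_hubs,
    pearson_with_p,
)
from cernet.diffexpr import ExpressionMatrix


def expr_from_rows(rows, ids):
    n = len(rows[0])
    cols = [f"s{i}" for i in range(n)]
    groups = pd.Series(["tumour"] * n, index=cols)
    # correlation screens need both groups formally; add a dummy normal col
    df = pd.DataFrame(np.c_[np.asarray(rows, dtype=float), np.zeros((len(rows), 1))],
                      index=ids, columns=cols + ["norm0"])
    groups = pd.concat([groups, pd.Series(["normal"], index=["norm0"])])
    return ExpressionMatrix(df, groups, "log2")


# -- Pearson ---------------------------------------------------------------

def test_perfect_linear_relation():
    x = np.arange(10.0)
    r, p = pearson_with_p(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    assert p < 1e-12


def test_perfect_anticorrelation():
    r, _ = pearson_with_p([1, 2, 3], [3, 2, 1])
    assert r == pytest.approx(-1.0)


def test_pearson_matches_covariance_and_t_oracle(rng):
    for _ in range(20):
        x = rng.normal(size=20)
        y = rng.normal(size=20) + 0.5 * x
        r, p = pearson_with_p(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r_oracle = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        t = r_oracle * np.sqrt(18 / (1 - r_oracle**2))
        p_oracle = 2 * stats.t.sf(abs(t), df=18)
        assert abs(r - r_oracle) < 1e-10
        assert abs(p - p_oracle) < 1e-10


def test_constant_vector_is_rejected():
    with pytest.raises(ValueError, match="constant"):
        pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# -- correlated_pairs boundary semantics ------------------------------------

def test_exact_r_080_is_excluded():
    """The co-expression gate is strict: r must exceed 0.8."""
    u = np.array([1.0, 1.0, -1.0, -1.0])
    v = np.array([1.0, -1.0, 1.0, -1.0])
    y = 4 * u + 3 * v  # corr(y, u) = 4/5 exactly, in exact float arithmetic
    lnc = expr_from_rows([u], ["L1"])
    mrna = expr_from_rows([y], ["G1"])
    r, _ = pearson_with_p(u, y)
    assert r == 0.8
    assert correlated_pairs(lnc, mrna, r_min=0.8) == []


def test_strong_pair_is_included(rng):
    x = rng.normal(size=20)
    y = x + rng.normal(scale=0.25, size=20)
    r, p = pearson_with_p(x, y)
    assert r > 0.8 and p < 0.05
    recs = correlated_pairs(expr_from_rows([x], ["L1"]), expr_from_rows([y], ["G1"]))
    assert len(recs) == 1 and recs[0].r == pytest.approx(r)


def test_anticorrelated_pair_is_excluded(rng):
    x = rng.normal(size=20)
    recs = correlated_pairs(expr_from_rows([x], ["L1"]),
                            expr_from_rows([-x + rng.normal(scale=0.1, size=20)], ["G1"]))
    assert recs == []


# -- interaction filtering ---------------------------------------------------

def test_same_direction_rows_dropped_and_score_boundary():
    lnc_mi = pd.DataFrame({"lncrna": ["L1", "L2"], "mirna": ["M1", "M1"]})
    mi_mrna = pd.DataFrame(
        {"mirna": ["M1", "M1"], "mrna": ["G1", "G2"], "score": [0.94, 0.95]}
    )
    de_lnc = {"L1": "up", "L2": "down"}
    de_mi = {"M1": "down"}
    de_mrna = {"G1": "up", "G2": "up"}
    lm, mg = filter_interactions(lnc_mi, mi_mrna, de_lnc, de_mi, de_mrna)
    assert lm == [("L1", "M1")]  # L2/M1 are both 'down' -> same direction, dropped
    assert mg == [("M1", "G2", 0.95)]  # 0.94 below the inclusive 0.95 gate


def test_filter_matches_brute_force_row_scan(rng):
    ids_l = [f"L{i}" for i in range(8)]
    ids_m = [f"M{i}" for i in range(6)]
    ids_g = [f"G{i}" for i in range(10)]
    de_lnc = {i: rng.choice(["up", "down"]) for i in ids_l if rng.random() < 0.8}
    de_mi = {i: rng.choice(["up", "down"]) for i in ids_m if rng.random() < 0.8}
    de_mrna = {i: rng.choice(["up", "down"]) for i in ids_g if rng.random() < 0.8}
    lnc_mi = pd.DataFrame(
        [(l, m) for l in ids_l for m in ids_m if rng.random() < 0.5],
        columns=["lncrna", "mirna"],
    )
    mi_mrna = pd.DataFrame(
        [(m, g, float(rng.uniform(0.8, 1.0))) for m in ids_m for g in ids_g
         if rng.random() < 0.5],
        columns=["mirna", "mrna", "score"],
    )
    lm, mg = filter_interactions(lnc_mi, mi_mrna, de_lnc, de_mi, de_mrna)
    lm_oracle = sorted({
        (r.lncrna, r.mirna) for r in lnc_mi.itertuples()
        if de_lnc.get(r.lncrna) and de_mi.get(r.mirna)
        and de_lnc[r.lncrna] != de_mi[r.mirna]
    })
    mg_oracle = sorted({
        (r.mirna, r.mrna, r.score) for r in mi_mrna.itertuples()
        if de_mi.get(r.mirna) and de_mrna.get(r.mrna)
        and de_mi[r.mirna] != de_mrna[r.mrna] and r.score >= 0.95
    })
    assert lm == lm_oracle and mg == mg_oracle


# -- triple assembly ---------------------------------------------------------

def test_published_molecules_assemble_into_up_triple():
    lm = [("AL161785.1", "hsa-miR-139-5p")]
    mg = [("hsa-miR-139-5p", "MS4A6A", 0.99)]
    corr = [CorrelationRecord("AL161785.1", "MS4A6A", 0.9, 1e-6)]
    de_lnc = {"AL161785.1": "up"}
    de_mrna = {"MS4A6A": "up"}
    triples = assemble_triples(lm, mg, corr, de_lnc, de_mrna)
    assert len(triples) == 1
    t = triples[0]
    assert (t.lncrna, t.mirna, t.mrna) == ("AL161785.1", "hsa-miR-139-5p", "MS4A6A")
    assert t.direction_class == "up" and t.r == 0.9

    # without the co-expression record the triple disappears
    assert assemble_triples(lm, mg, [], de_lnc, de_mrna) == []


def brute_force_triples(lm, mg, corr_keys):
    out = set()
    for (l, m1) in lm:
        for (m2, g, _) in mg:
            if m1 == m2 and (l, g) in corr_keys:
                out.add((l, m1, g))
    return out


def test_assembly_equals_exhaustive_oracle(rng):
    for _ in range(30):
        L = [f"L{i}" for i in range(rng.integers(1, 15))]
        M = [f"M{i}" for i in range(rng.integers(1, 15))]
        G = [f"G{i}" for i in range(rng.integers(1, 15))]
        lm = [(l, m) for l in L for m in M if rng.random() < 0.3]
        mg = [(m, g, 0.99) for m in M for g in G if rng.random() < 0.3]
        corr = [CorrelationRecord(l, g, 0.9, 0.001)
                for l in L for g in G if rng.random() < 0.3]
        got = assemble_triples(lm, mg, corr)
        expect = brute_force_triples(lm, mg, {(c.lncrna, c.mrna) for c in corr})
        assert {(t.lncrna, t.mirna, t.mrna) for t in got} == expect
        # monotone: adding rows never removes triples
        more = assemble_triples(lm + [("LX", "M0")], mg, corr)
        assert {(t.lncrna, t.mirna, t.mrna) for t in more} >= expect


# -- networks ----------------------------------------------------------------

def tri(l, m, g, klass="up"):
    from cernet.assembly import CeRNATriple

    return CeRNATriple(l, m, g, klass, 0.9, 1e-4, 0.99)


def test_single_triple_network_shape():
    up, down = build_networks([tri("L1", "M1", "G1")])
    assert up.number_of_nodes() == 3 and up.number_of_edges() == 2
    assert down.number_of_nodes() == 0


def test_shared_mirna_deduplicates():
    up, _ = build_networks([tri("L1", "M1", "G1"), tri("L2", "M1", "G2")])
    assert up.number_of_nodes() == 5 and up.number_of_edges() == 4


def test_network_is_tripartite_and_degree_conserves(rng):
    triples = [tri(f"L{rng.integers(5)}", f"M{rng.integers(5)}",
                   f"G{rng.integers(5)}", rng.choice(["up", "down"]))
               for _ in range(30)]
    up, down = build_networks(triples)
    merged, _ = merge_and_hubs(up, down)
    for a, b in merged.edges():
        kinds = {merged.nodes[a]["kind"], merged.nodes[b]["kind"]}
        assert kinds in ({"lncRNA", "miRNA"}, {"miRNA", "mRNA"})
    assert sum(d for _, d in merged.degree()) == 2 * merged.number_of_edges()
    assert all(d > 0 for _, d in merged.degree())


def test_hub_rule_includes_boundary_ties_on_star_forest():
    g = nx.Graph()
    g.graph["triples"] = []
    for i in range(1, 11):
        for j in range(i):
            g.add_edge(f"hub{i:02d}", f"leaf{i:02d}_{j}")
    empty = nx.Graph()
    empty.graph["triples"] = []
    merged, hubs = merge_and_hubs(g, empty, decile=0.10)
    n = merged.number_of_nodes()
    k = int(np.ceil(0.1 * n))
    degs = sorted((d for _, d in merged.degree()), reverse=True)
    thr = degs[k - 1]
    assert hubs == {v for v, d in merged.degree() if d >= thr}


def test_total_degree_tie_returns_everyone():
    g = nx.cycle_graph(10)  # all degree 2
    g = nx.relabel_nodes(g, str)
    g.graph["triples"] = []
    e = nx.Graph()
    e.graph["triples"] = []
    _, hubs = merge_and_hubs(g, e, decile=0.10)
    assert len(hubs) == 10


def test_hubs_match_sort_and_slice_oracle(rng):
    g = nx.gnp_random_graph(40, 0.15, seed=3)
    g = nx.relabel_nodes(g, str)
    g.remove_nodes_from(list(nx.isolates(g)))
    g.graph["triples"] = []
    e = nx.Graph()
    e.graph["triples"] = []
    merged, hubs = merge_and_hubs(g, e, decile=0.10)
    degs = dict(merged.degree())
    k = int(np.ceil(0.1 * len(degs)))
    thr = sorted(degs.values(), reverse=True)[k - 1]
    assert hubs == {v for v, d in degs.items() if d >= thr}
    assert len(hubs) >= k


def test_empty_network_has_no_hubs():
    a, b = nx.Graph(), nx.Graph()
    a.graph["triples"] = []
    b.graph["triples"] = []
    merged, hubs = merge_and_hubs(a, b)
    assert hubs == set() and merged.number_of_nodes() == 0
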