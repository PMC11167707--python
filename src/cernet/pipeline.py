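"""End-to-end orchestration of the ceRNA inference workflow.

Stages: (optional) cohort simulation -> differential expression ->
correlation-gated triple assembly -> merged-network hubs -> MCODE clustering
of the DEmRNA PPI subgraph -> lncRNA-miRNA-seed subnetwork and axes ->
median-split survival and immune-infiltration association.

Configuration is one YAML file; the ``paper`` preset pins every stage
threshold (alpha 0.05, |log2FC| > 1, r > 0.8, score >= 0.95, PPI confidence
0.4, MCODE {5, 0.2, 2, 100}, hub decile 0.10, log-rank alpha 0.05).  All
randomness flows from one root seed through named substreams, and the run
report is a pure function of (config, seed): two runs with the same seed
write byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import assembly, diffexpr, mcode, seednet, simulate, survival

__all__ = ["PipelineConfig", "PAPER_THRESHOLDS", "run_pipeline", "validate_inputs"]

log = logging.getLogger("cernet")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)

#: Stage thresholds of the ``paper`` preset.
PAPER_THRESHOLDS = {
    "alpha": 0.05,
    "lfc_min": 1.0,
    "mirna_alpha": 0.05,
    "mirna_adjust": "none",
    "min_count": 10,
    "prior_count": 0.5,
    "r_min": 0.8,
    "corr_alpha": 0.05,
    "corr_samples": "tumour",
    "score_min": 0.95,
    "ppi_min_confidence": 0.4,
    "mcode_degree_cutoff": 5,
    "mcode_node_score_cutoff": 0.2,
    "mcode_k_core": 2,
    "mcode_max_depth": 100,
    "hub_decile": 0.10,
    "logrank_alpha": 0.05,
}

_INPUT_KEYS = (
    "counts", "samples", "annotation", "mirna", "lnc_mi", "mi_mrna",
    "ppi", "clinical", "infiltration",
)


@dataclass
class PipelineConfig:
    outdir: str = "cernet_out"
    seed: int = 0
    simulate: simulate.SimConfig | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    thresholds: dict = field(default_factory=lambda: dict(PAPER_THRESHOLDS))

    def __post_init__(self) -> None:
        unknown = set(self.thresholds) - set(PAPER_THRESHOLDS)
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        merged = dict(PAPER_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged
        _validate_threshold_domains(self.thresholds)
        bad = set(self.inputs) - set(_INPUT_KEYS)
        if bad:
            raise ValueError(f"unknown input keys: {sorted(bad)}")
        if self.simulate is None and not self.inputs:
            raise ValueError("config needs either a simulate block or input paths")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        unknown = set(d) - {"outdir", "seed", "simulate", "inputs", "thresholds", "preset"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        preset = d.pop("preset", "paper")
        if preset != "paper":
            raise ValueError(f"unknown preset {preset!r}")
        sim = d.pop("simulate", None)
        if sim is not None:
            sim = dict(sim)
            axes = sim.pop("planted_axes", None)
            known = {f.name for f in dataclasses.fields(simulate.SimConfig)}
            bad = set(sim) - known
            if bad:
                raise ValueError(f"unknown simulate keys: {sorted(bad)}")
            if axes is None:
                cfg = simulate.default_config(seed=d.get("seed", 0))
                sim.setdefault("prognostic_gene", cfg.prognostic_gene)
                sim["planted_axes"] = cfg.planted_axes
            else:
                sim["planted_axes"] = [simulate.PlantedAxis(**a) for a in axes]
            sim.setdefault("rng_seed", d.get("seed", 0))
            sim = simulate.SimConfig(**sim)
        return cls(
            outdir=d.get("outdir", "cernet_out"),
            seed=int(d.get("seed", 0)),
            simulate=sim,
            inputs=dict(d.get("inputs", {})),
            thresholds=dict(d.get("thresholds", {})),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _validate_threshold_domains(t: dict) -> None:
    for key in ("alpha", "mirna_alpha", "corr_alpha", "logrank_alpha", "hub_decile"):
        if not 0.0 < t[key] <= 1.0:
            raise ValueError(f"{key} must be in (0, 1]")
    if not -1.0 <= t["r_min"] <= 1.01:
        # r_min slightly above 1 is allowed as an explicit 'nothing passes'
        raise ValueError("r_min out of range")
    if t["mirna_adjust"] not in ("none", "BH"):
        raise ValueError("mirna_adjust must be 'none' or 'BH'")
    if t["corr_samples"] not in ("tumour", "all"):
        raise ValueError("corr_samples must be 'tumour' or 'all'")


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

def validate_inputs(paths: dict[str, str]) -> list[dict]:
    """Cross-check the input files; returns diagnostics.

    Each diagnostic is {"level": "fatal"|"warning", "message": str}.  Fatal:
    sample-sheet samples missing from matrices, annotation not covering the
    count matrix.  Warnings: interaction rows naming unknown features,
    clinical samples without expression.
    """
    diags: list[dict] = []

    def fatal(msg):
        diags.append({"level": "fatal", "message": msg})

    def warn(msg):
        diags.append({"level": "warning", "message": msg})

    counts = pd.read_csv(paths["counts"], sep="\t", index_col=0)
    groups = diffexpr.read_sample_sheet(paths["samples"])
    missing = [s for s in groups.index if s not in counts.columns]
    if missing:
        fatal(f"{len(missing)} sample-sheet samples missing from count matrix: {missing[:3]}")
    ann = pd.read_csv(paths["annotation"], sep="\t")
    unann = set(counts.index) - set(ann["feature"])
    if unann:
        fatal(f"{len(unann)} count-matrix features lack a biotype annotation")

    mirna = pd.read_csv(paths["mirna"], sep="\t", index_col=0)
    lnc_ids = set(ann.loc[ann["biotype"] == "lncRNA", "feature"])
    mi_ids = set(mirna.index)
    lnc_mi = pd.read_csv(paths["lnc_mi"], sep="\t")
    n_bad = int((~lnc_mi["lncrna"].isin(lnc_ids) | ~lnc_mi["mirna"].isin(mi_ids)).sum())
    if n_bad:
        warn(f"{n_bad} lncRNA-miRNA rows name unknown features (dropped)")
    mrna_ids = set(ann.loc[ann["biotype"] == "mRNA", "feature"])
    mi_mrna = pd.read_csv(paths["mi_mrna"], sep="\t")
    n_bad = int((~mi_mrna["mirna"].isin(mi_ids) | ~mi_mrna["mrna"].isin(mrna_ids)).sum())
    if n_bad:
        warn(f"{n_bad} miRNA-mRNA rows name unknown features (dropped)")

    if "clinical" in paths:
        clin = survival.read_clinical(paths["clinical"])
        n_missing = int((~clin["sample"].isin(counts.columns)).sum())
        if n_missing:
            warn(f"{n_missing} clinical samples have no expression column")
    return diags


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; write artifacts under ``config.outdir``.

    Returns the run report (also written as ``report.json``).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t = config.thresholds

    if config.simulate is not None:
        log.info("stage=simulate seed=%d", config.seed)
        sim_cfg = dataclasses.replace(config.simulate, rng_seed=config.seed)
        paths = simulate.write_simulation(out / "inputs", sim_cfg)
    else:
        paths = dict(config.inputs)

    diags = validate_inputs(paths)
    if any(d["level"] == "fatal" for d in diags):
        raise ValueError("fatal input diagnostics: "
                         + "; ".join(d["message"] for d in diags if d["level"] == "fatal"))

    # --- differential expression -----------------------------------------
    genes = diffexpr.read_matrix(paths["counts"], paths["samples"], scale="counts")
    ann = diffexpr.read_annotation(paths["annotation"])
    mirna = diffexpr.read_matrix(paths["mirna"], paths["samples"], scale="log2")

    filtered = diffexpr.filter_by_expression(genes, min_count=t["min_count"])
    logexpr = diffexpr.log_cpm(filtered, prior_count=t["prior_count"])
    gene_records = diffexpr.differential_test(
        logexpr, alpha=t["alpha"], lfc_min=t["lfc_min"], adjust="BH"
    )
    de_mrna_recs, de_lnc_recs = diffexpr.split_by_biotype(gene_records, ann)
    mirna_records = diffexpr.differential_test(
        mirna, alpha=t["mirna_alpha"], lfc_min=t["lfc_min"], adjust=t["mirna_adjust"]
    )
    de_mi = assembly.direction_map(mirna_records)
    de_lnc = assembly.direction_map(de_lnc_recs)
    de_mrna = assembly.direction_map(de_mrna_recs)
    log.info("stage=diffexpr de_mrna=%d de_lncrna=%d de_mirna=%d",
             len(de_mrna), len(de_lnc), len(de_mi))
    diffexpr.write_de_table(
        [r for r in gene_records if ann[r.feature_id] == "mRNA"], out / "de_mrna.tsv")
    diffexpr.write_de_table(
        [r for r in gene_records if ann[r.feature_id] == "lncRNA"], out / "de_lncrna.tsv")
    diffexpr.write_de_table(mirna_records, out / "de_mirna.tsv")

    # --- correlation + triple assembly -----------------------------------
    lnc_present = [f for f in de_lnc if f in logexpr.feature_ids]
    mrna_present = [f for f in de_mrna if f in logexpr.feature_ids]
    samples = (
        logexpr.samples_in_group(diffexpr.TUMOUR)
        if t["corr_samples"] == "tumour"
        else list(logexpr.sample_ids)
    )
    corr = (
        assembly.correlated_pairs(
            logexpr.subset_features(lnc_present),
            logexpr.subset_features(mrna_present),
            r_min=t["r_min"], alpha=t["corr_alpha"], samples=samples,
        )
        if lnc_present and mrna_present and t["r_min"] <= 1.0
        else []
    )
    lnc_mi_tab = pd.read_csv(paths["lnc_mi"], sep="\t")
    mi_mrna_tab = pd.read_csv(paths["mi_mrna"], sep="\t")
    lm_pairs, mg_pairs = assembly.filter_interactions(
        lnc_mi_tab, mi_mrna_tab, de_lnc, de_mi, de_mrna, score_min=t["score_min"]
    )
    triples = assembly.assemble_triples(lm_pairs, mg_pairs, corr, de_lnc, de_mrna)
    up_net, down_net = assembly.build_networks(triples)
    merged, hubs = assembly.merge_and_hubs(up_net, down_net, decile=t["hub_decile"])
    log.info("stage=assemble corr_pairs=%d lnc_mi=%d mi_mrna=%d triples=%d hubs=%d",
             len(corr), len(lm_pairs), len(mg_pairs), len(triples), len(hubs))

    pd.DataFrame(
        [dataclasses.astuple(tr) for tr in triples],
        columns=["lncrna", "mirna", "mrna", "direction_class", "r", "p", "score"],
    ).to_csv(out / "triples.tsv", sep="\t", index=False, float_format="%.10g")
    (out / "merged_network.sif").write_text(assembly.network_to_sif(merged))
    _write_graphml(merged, out / "merged_network.graphml")
    pd.DataFrame({"hub": sorted(hubs)}).to_csv(out / "hubs.tsv", sep="\t", index=False)

    # --- MCODE on the DEmRNA PPI subgraph ---------------------------------
    ppi = mcode.read_ppi_edges(paths["ppi"], min_confidence=t["ppi_min_confidence"])
    net_mrna = {v for v, d in merged.nodes(data=True) if d.get("kind") == "mRNA"}
    ppi_sub = ppi.subgraph([v for v in ppi if v in net_mrna]).copy()
    params = mcode.MCODEParams(
        degree_cutoff=t["mcode_degree_cutoff"],
        node_score_cutoff=t["mcode_node_score_cutoff"],
        k_core=t["mcode_k_core"],
        max_depth=t["mcode_max_depth"],
    )
    complexes = mcode.find_complexes(ppi_sub, params)
    seeds = [c.seed for c in complexes]
    log.info("stage=mcode ppi_nodes=%d ppi_edges=%d complexes=%d",
             ppi_sub.number_of_nodes(), ppi_sub.number_of_edges(), len(complexes))
    pd.DataFrame(
        [(c.rank, f"{c.score:.10g}", c.seed, ",".join(c.members)) for c in complexes],
        columns=["rank", "score", "seed", "members"],
    ).to_csv(out / "mcode_complexes.tsv", sep="\t", index=False)

    # --- seed subnetwork + critical set -----------------------------------
    subnet = seednet.extract_seed_network(merged, seeds)
    axes = seednet.enumerate_axes(subnet)
    _write_graphml(subnet, out / "seed_network.graphml")
    pd.DataFrame(
        [(a.lncrna, a.mirna, a.mrna, a.direction_class, len(a.evidence)) for a in axes],
        columns=["lncrna", "mirna", "mrna", "direction", "n_triples"],
    ).to_csv(out / "axes.tsv", sep="\t", index=False)

    # --- survival + infiltration ------------------------------------------
    surv_results: list[survival.SurvivalResult] = []
    flagged: list[str] = []
    if "clinical" in paths and seeds:
        clin = survival.read_clinical(paths["clinical"])
        t_samples = genes.samples_in_group(diffexpr.TUMOUR)
        expr = logexpr.values[[s for s in t_samples if s in logexpr.sample_ids]]
        surv_results = survival.survival_screen(expr, clin, sorted(seeds))
        flagged = [r.gene for r in surv_results if r.logrank_p < t["logrank_alpha"]]
        pd.DataFrame(
            [
                (r.gene, r.hazard_ratio, r.cox_p, r.logrank_stat, r.logrank_p,
                 r.n_high, r.n_low)
                for r in surv_results
            ],
            columns=["gene", "HR", "cox_p", "logrank_stat", "logrank_p",
                     "n_high", "n_low"],
        ).to_csv(out / "survival.tsv", sep="\t", index=False, float_format="%.10g")
    log.info("stage=survival tested=%d flagged=%d", len(surv_results), len(flagged))

    infil_rows = []
    if "infiltration" in paths and flagged:
        infil = pd.read_csv(paths["infiltration"], sep="\t", index_col=0)
        t_samples = [s for s in infil.columns if s in logexpr.sample_ids]
        for gene in flagged:
            recs = survival.infiltration_assoc(
                logexpr.values.loc[gene, t_samples], infil[t_samples], gene=gene
            )
            infil_rows += [
                (r.gene, r.cell_type, r.correlation, r.adj_p) for r in recs
            ]
        pd.DataFrame(
            infil_rows, columns=["gene", "cell_type", "correlation", "adj_p"]
        ).to_csv(out / "infiltration_assoc.tsv", sep="\t", index=False,
                 float_format="%.10g")

    # --- report ------------------------------------------------------------
    n_up = sum(1 for tr in triples if tr.direction_class == "up")
    report = {
        "seed": config.seed,
        "software_version": _version(),
        "thresholds": dict(sorted(t.items())),
        "diagnostics": diags,
        "counts": {
            "de_mrna": {"up": sum(d == "up" for d in de_mrna.values()),
                        "down": sum(d == "down" for d in de_mrna.values())},
            "de_lncrna": {"up": sum(d == "up" for d in de_lnc.values()),
                          "down": sum(d == "down" for d in de_lnc.values())},
            "de_mirna": {"up": sum(d == "up" for d in de_mi.values()),
                         "down": sum(d == "down" for d in de_mi.values())},
            "correlated_pairs": len(corr),
            "lnc_mi_pairs": len(lm_pairs),
            "mi_mrna_pairs": len(mg_pairs),
            "triples": {"up": n_up, "down": len(triples) - n_up},
            "merged_nodes": merged.number_of_nodes(),
            "merged_edges": merged.number_of_edges(),
            "hubs": len(hubs),
            "ppi_nodes": ppi_sub.number_of_nodes(),
            "ppi_edges": ppi_sub.number_of_edges(),
            "complexes": len(complexes),
            "axes": len(axes),
        },
        "hub_nodes": sorted(hubs),
        "seed_genes": sorted(seeds),
        "axes": [a.label() for a in axes],
        "survival_flagged": sorted(flagged),
        "critical_intersection": sorted(
            seednet.intersect_critical(hubs, set(subnet.nodes())).intersection
        ),
    }
    assert report["counts"]["axes"] <= max(
        1, report["counts"]["lnc_mi_pairs"] * report["counts"]["mi_mrna_pairs"]
    )
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _write_graphml(g: nx.Graph, path) -> None:
    clean = nx.Graph()
    clean.add_nodes_from((v, dict(d)) for v, d in sorted(g.nodes(data=True)))
    clean.add_edges_from((a, b, dict(d)) for a, b, d in sorted(g.edges(data=True)))
    nx.write_graphml(clean, path)


def _version() -> str:
    from importlib.metadata import version, PackageNotFoundError

    try:
        return version("cernet")
    except PackageNotFoundError:
        return "unknown"
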