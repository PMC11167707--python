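"""Synthetic multi-omic cohort generator with planted ground truth.

Every downstream stage of the ceRNA pipeline is exercised against cohorts in
which the interesting structure is planted and therefore recoverable:

* **ceRNA axes** — triples (lncRNA, miRNA, mRNA) where the lncRNA and mRNA are
  shifted together in tumour samples, co-vary through a shared per-sample
  latent factor (giving a controllable Pearson correlation), and the miRNA is
  shifted and loaded in the opposite direction.
* **differential expression** — a configurable fraction of background features
  receives a tumour/normal mean shift on the log2 scale.
* **a dense protein-interaction cluster** — emitted as a clique so that
  density-based complex detection has an exact target.
* **a prognostic gene** — survival times are exponential with a planted hazard
  ratio between the high/low median-split expression groups.
* **immune-infiltration correlates** — selected cell-type scores are signed
  transforms of a planted gene's expression.

Counts are negative binomial with a common dispersion; the miRNA matrix is
Gaussian log2 intensity (microarray-like).  All outputs are pure functions of
(config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import ExpressionMatrix, TUMOUR, NORMAL

__all__ = [
    "PlantedAxis",
    "SimConfig",
    "TruthSet",
    "CELL_TYPES",
    "default_config",
    "generate_cohort",
    "generate_interactions",
    "generate_ppi",
    "generate_survival",
    "generate_infiltration",
    "write_simulation",
]

#: The 24 immune cell types scored by the infiltration stage.
CELL_TYPES = [
    "DC", "Bcell", "Monocyte", "Macrophage", "NK", "Neutrophil",
    "CD4_T", "CD8_T", "NKT", "Gamma_delta", "CD4_naive", "CD8_naive",
    "Cytotoxic", "Exhausted", "Tr1", "nTreg", "iTreg",
    "Th1", "Th2", "Th17", "Tfh",
    "Central_memory", "Effector_memory", "MAIT",
]

LN2_SQ = math.log(2.0) ** 2


@dataclass(frozen=True)
class PlantedAxis:
    """A ground-truth ceRNA triple.

    ``direction`` is the direction of the lncRNA and mRNA in tumour relative
    to normal; the miRNA moves the opposite way.  ``lnc_mrna_corr`` is the
    target Pearson correlation between the lncRNA and mRNA in tumour samples.
    """

    lncrna_id: str
    mirna_id: str
    mrna_id: str
    direction: str = "up"
    lnc_mrna_corr: float = 0.9
    log2fc_magnitude: float = 4.0

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if not 0.0 < self.lnc_mrna_corr <= 1.0:
            raise ValueError("lnc_mrna_corr must be in (0, 1]")
        if self.log2fc_magnitude <= 0:
            raise ValueError("log2fc_magnitude must be positive")
        if len({self.lncrna_id, self.mirna_id, self.mrna_id}) != 3:
            raise ValueError("axis ids must be distinct")


@dataclass
class SimConfig:
    """Free parameters of the cohort generator.

    Cohort sizes default to the 169 tumour / 5 normal design the pipeline is
    calibrated for.  ``de_log2fc`` is the mean shift applied to background
    differentially expressed features.
    """

    n_tumour: int = 169
    n_normal: int = 5
    n_mrna: int = 1200
    n_lncrna: int = 300
    n_mirna: int = 150
    planted_axes: list[PlantedAxis] = field(default_factory=list)
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    base_mean: float = 200.0
    dispersion: float = 0.2
    mirna_sd: float = 0.5
    decoy_interaction_fraction: float = 0.02
    prognostic_gene: str = ""
    prognostic_hr: float = 1.48
    censor_rate: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mrna, self.n_lncrna, self.n_mirna) < 1:
            raise ValueError("feature counts must be >= 1")
        if self.n_tumour < 3 or self.n_normal < 2:
            raise ValueError("need n_tumour >= 3 and n_normal >= 2")
        for name in ("de_fraction", "decoy_interaction_fraction", "censor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.base_mean <= 0 or self.mirna_sd < 0 or self.dispersion < 0:
            raise ValueError("base_mean positive; dispersion, mirna_sd non-negative")
        if self.prognostic_hr <= 0:
            raise ValueError("prognostic_hr must be positive")

    # feature universes ----------------------------------------------------
    def mrna_ids(self) -> list[str]:
        return [f"gene{i:04d}" for i in range(1, self.n_mrna + 1)]

    def lncrna_ids(self) -> list[str]:
        return [f"lnc{i:04d}" for i in range(1, self.n_lncrna + 1)]

    def mirna_ids(self) -> list[str]:
        return [f"mir{i:04d}" for i in range(1, self.n_mirna + 1)]


@dataclass
class TruthSet:
    """Planted structure used as the recovery oracle for every stage."""

    planted_axes: list[PlantedAxis] = field(default_factory=list)
    de_features: set[tuple[str, str]] = field(default_factory=set)
    ppi_clusters: list[dict] = field(default_factory=list)  # {"members": [...], "seed": id}
    prognostic_gene: str = ""
    prognostic_hr: float = 1.0
    infiltration_targets: dict[str, tuple[str, int]] = field(default_factory=dict)

    # lossless JSON round-trip --------------------------------------------
    def to_json(self) -> str:
        payload = {
            "planted_axes": [asdict(a) for a in self.planted_axes],
            "de_features": sorted(list(t) for t in self.de_features),
            "ppi_clusters": [
                {"members": sorted(c["members"]), "seed": c["seed"]}
                for c in self.ppi_clusters
            ],
            "prognostic_gene": self.prognostic_gene,
            "prognostic_hr": self.prognostic_hr,
            "infiltration_targets": {
                ct: list(v) for ct, v in sorted(self.infiltration_targets.items())
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        d = json.loads(text)
        return cls(
            planted_axes=[PlantedAxis(**a) for a in d["planted_axes"]],
            de_features={(f, dr) for f, dr in d["de_features"]},
            ppi_clusters=d["ppi_clusters"],
            prognostic_gene=d["prognostic_gene"],
            prognostic_hr=d["prognostic_hr"],
            infiltration_targets={
                ct: (g, int(s)) for ct, (g, s) in d["infiltration_targets"].items()
            },
        )


def default_config(seed: int = 0) -> SimConfig:
    """The standard simulated study: 12 axes, one 8-gene clique, HR 1.48."""
    axes = []
    for i in range(1, 13):
        axes.append(
            PlantedAxis(
                lncrna_id=f"lnc{i:04d}",
                mirna_id=f"mir{i:04d}",
                mrna_id=f"gene{i:04d}",
                direction="up" if i <= 6 else "down",
                lnc_mrna_corr=0.9,
                log2fc_magnitude=4.0,
            )
        )
    return SimConfig(planted_axes=axes, prognostic_gene="gene0001", rng_seed=seed)


# ---------------------------------------------------------------------------
# internal helpers
# ---------------------------------------------------------------------------

def _substream(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


def _log_count_noise_var(mean: float, dispersion: float) -> float:
    """Variance of log2(count) for NB(mean, dispersion).

    Uses the Poisson-Gamma representation: for X = Poisson(mean * G) with
    G ~ Gamma(1/a, a), Var(ln X) ~= trigamma(1/a) + 1/(mean*(1-a)) for a < 1,
    which is accurate to a few percent at the count depths simulated here.
    Falls back to the delta method for the Poisson limit / large dispersion.
    """
    a = dispersion
    if a < 1e-8:
        return 1.0 / (mean * LN2_SQ)
    if a < 1.0:
        from scipy.special import polygamma

        return (float(polygamma(1, 1.0 / a)) + 1.0 / (mean * (1.0 - a))) / LN2_SQ
    return (1.0 + a * mean) / (mean * LN2_SQ)


def _factor_loading(target_corr: float, noise_var: float) -> float:
    """Loading lambda with corr(lam*z + e1, lam*z + e2) = target_corr.

    Solves lam^2 / (lam^2 + noise_var) = c for lam.
    """
    c = target_corr
    if c >= 1.0:
        c = 1.0 - 1e-9
    return math.sqrt(c * noise_var / (1.0 - c))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion < 1e-8:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_cohort(config: SimConfig) -> tuple[ExpressionMatrix, ExpressionMatrix, TruthSet]:
    """Generate (gene counts, miRNA log2 intensity, truth set).

    Gene counts cover mRNAs + lncRNAs; the miRNA matrix is on the log2 scale.
    Background DE features are drawn per class at ``de_fraction`` (planted
    axis members excluded from the draw; they are DE by construction).
    """
    mrna = config.mrna_ids()
    lnc = config.lncrna_ids()
    mir = config.mirna_ids()
    gene_ids = mrna + lnc
    if len(set(gene_ids)) != len(gene_ids) or len(set(mir)) != len(mir):
        raise ValueError("duplicate feature ids")

    axis_ids: set[str] = set()
    for ax in config.planted_axes:
        if ax.lncrna_id not in set(lnc) or ax.mrna_id not in set(mrna) or ax.mirna_id not in set(mir):
            raise ValueError(f"axis {ax} references unknown feature ids")
        for fid in (ax.lncrna_id, ax.mirna_id, ax.mrna_id):
            if fid in axis_ids:
                raise ValueError(f"feature {fid} used by more than one planted axis")
            axis_ids.add(fid)
    if config.prognostic_gene and config.prognostic_gene not in set(mrna):
        raise ValueError("prognostic_gene must be an mRNA id")

    n_t, n_n = config.n_tumour, config.n_normal
    samples = [f"T{i:04d}" for i in range(1, n_t + 1)] + [
        f"N{i:04d}" for i in range(1, n_n + 1)
    ]
    groups = pd.Series([TUMOUR] * n_t + [NORMAL] * n_n, index=samples)
    tumour_mask = np.array([True] * n_t + [False] * n_n)

    rng_de = _substream(config.rng_seed, 1)
    rng_counts = _substream(config.rng_seed, 2)
    rng_mirna = _substream(config.rng_seed, 3)

    # background DE assignment per class
    truth_de: set[tuple[str, str]] = set()

    def _pick_background(ids: list[str]) -> dict[str, str]:
        pool = [f for f in ids if f not in axis_ids]
        k = int(round(config.de_fraction * len(ids)))
        k = min(k, len(pool))
        chosen = rng_de.choice(len(pool), size=k, replace=False)
        dirs = rng_de.choice(["up", "down"], size=k)
        return {pool[i]: d for i, d in zip(chosen, dirs)}

    bg_mrna = _pick_background(mrna)
    bg_lnc = _pick_background(lnc)
    bg_mir = _pick_background(mir)

    # per-feature tumour-shift and latent loading
    shift = {f: 0.0 for f in gene_ids}
    loading = {f: 0.0 for f in gene_ids}  # signed loading on the axis factor
    axis_of = {}
    for f, d in {**bg_mrna, **bg_lnc}.items():
        shift[f] = config.de_log2fc if d == "up" else -config.de_log2fc
        truth_de.add((f, d))

    base_log = math.log2(config.base_mean)
    factors = rng_counts.standard_normal((len(config.planted_axes), n_t))

    for k, ax in enumerate(config.planted_axes):
        s = ax.log2fc_magnitude if ax.direction == "up" else -ax.log2fc_magnitude
        # loading solved against the log-count noise at the shifted tumour mean
        noise_var = _log_count_noise_var(config.base_mean * 2.0**s, config.dispersion)
        lam = _factor_loading(ax.lnc_mrna_corr, noise_var)
        for f in (ax.lncrna_id, ax.mrna_id):
            shift[f] = s
            loading[f] = lam
            axis_of[f] = k
            truth_de.add((f, ax.direction))
        mi_dir = "down" if ax.direction == "up" else "up"
        truth_de.add((ax.mirna_id, mi_dir))
    for f, d in bg_mir.items():
        truth_de.add((f, d))

    # gene count matrix ----------------------------------------------------
    logmu = np.full((len(gene_ids), n_t + n_n), base_log)
    for i, f in enumerate(gene_ids):
        if shift[f]:
            logmu[i, tumour_mask] += shift[f]
        if loading[f]:
            logmu[i, tumour_mask] += loading[f] * factors[axis_of[f]]
    counts = _nb_draw(rng_counts, np.exp2(logmu), config.dispersion)
    genes = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=samples), groups, scale="counts"
    )

    # miRNA log2-intensity matrix -----------------------------------------
    mirna_base = 8.0
    lam_mi = {}
    for k, ax in enumerate(config.planted_axes):
        v = max(config.mirna_sd ** 2, 1e-12)
        lam_mi[ax.mirna_id] = (k, _factor_loading(ax.lnc_mrna_corr, v))
    mi_mean = np.full((len(mir), n_t + n_n), mirna_base)
    for i, f in enumerate(mir):
        d = bg_mir.get(f)
        for ax in config.planted_axes:
            if ax.mirna_id == f:
                d = "down" if ax.direction == "up" else "up"
        if d is not None:
            # background miRNAs shift by de_log2fc, planted ones by the axis
            # magnitude (opposite sign to the lncRNA/mRNA by construction)
            mag = config.de_log2fc
            for ax in config.planted_axes:
                if ax.mirna_id == f:
                    mag = ax.log2fc_magnitude
            mi_mean[i, tumour_mask] += mag if d == "up" else -mag
        if f in lam_mi:
            k, lam = lam_mi[f]
            mi_mean[i, tumour_mask] -= lam * factors[k]
    intensities = mi_mean + rng_mirna.standard_normal(mi_mean.shape) * config.mirna_sd
    mirnas = ExpressionMatrix(
        pd.DataFrame(intensities, index=mir, columns=samples), groups, scale="log2"
    )

    truth = TruthSet(
        planted_axes=list(config.planted_axes),
        de_features=truth_de,
        ppi_clusters=_default_clusters(config),
        prognostic_gene=config.prognostic_gene,
        prognostic_hr=config.prognostic_hr,
        infiltration_targets=_default_infiltration_targets(config),
    )
    return genes, mirnas, truth


def _default_clusters(config: SimConfig) -> list[dict]:
    """One dense cluster over the first (up to) 8 planted-axis mRNAs."""
    members = [ax.mrna_id for ax in config.planted_axes[:8]]
    if len(members) < 3:
        return []
    return [{"members": sorted(members), "seed": min(members)}]


def _default_infiltration_targets(config: SimConfig) -> dict[str, tuple[str, int]]:
    if not config.prognostic_gene:
        return {}
    return {
        "Macrophage": (config.prognostic_gene, 1),
        "Neutrophil": (config.prognostic_gene, -1),
    }


def generate_interactions(
    truth: TruthSet, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit (lncRNA-miRNA, miRNA-mRNA) interaction tables.

    Planted axes contribute their rows (miRNA-mRNA score drawn >= 0.95);
    decoy rows are Bernoulli draws at ``decoy_interaction_fraction`` over the
    remaining cross pairs, with scores uniform in [0.5, 1.0].
    """
    rng = _substream(config.rng_seed, 4)
    lnc_ids, mir_ids, mrna_ids = (
        config.lncrna_ids(), config.mirna_ids(), config.mrna_ids(),
    )
    planted_lm = {(ax.lncrna_id, ax.mirna_id) for ax in truth.planted_axes}
    planted_mg = {(ax.mirna_id, ax.mrna_id) for ax in truth.planted_axes}

    lm_rows = [
        (ln, mi, "high") for ln, mi in sorted(planted_lm)
    ]
    mg_rows = [
        (mi, g, float(rng.uniform(0.95, 1.0))) for mi, g in sorted(planted_mg)
    ]

    frac = config.decoy_interaction_fraction
    if frac > 0:
        lm_all = [
            (ln, mi)
            for ln in lnc_ids
            for mi in mir_ids
            if (ln, mi) not in planted_lm
        ]
        mask = rng.random(len(lm_all)) < frac
        conf = rng.choice(["low", "high"], size=len(lm_all))
        lm_rows += [
            (ln, mi, str(c)) for (ln, mi), m, c in zip(lm_all, mask, conf) if m
        ]
        mg_all = [
            (mi, g)
            for mi in mir_ids
            for g in mrna_ids
            if (mi, g) not in planted_mg
        ]
        mask = rng.random(len(mg_all)) < frac
        scores = rng.uniform(0.5, 1.0, size=len(mg_all))
        mg_rows += [
            (mi, g, float(s)) for (mi, g), m, s in zip(mg_all, mask, scores) if m
        ]

    lnc_mi = pd.DataFrame(lm_rows, columns=["lncrna", "mirna", "confidence"])
    mi_mrna = pd.DataFrame(mg_rows, columns=["mirna", "mrna", "score"])
    assert not lnc_mi.duplicated(["lncrna", "mirna"]).any()
    assert not mi_mrna.duplicated(["mirna", "mrna"]).any()
    return lnc_mi, mi_mrna


def generate_ppi(
    truth: TruthSet, background_p: float, rng_seed: int, config: SimConfig | None = None
) -> pd.DataFrame:
    """Edge list over mRNA ids: truth clusters as cliques + ER background.

    Background edges are Erdos-Renyi(background_p) among pairs not inside a
    cluster.  Returns columns (protein_a, protein_b, confidence), undirected
    with protein_a < protein_b, no self-loops or duplicates.
    """
    if not 0.0 <= background_p <= 1.0:
        raise ValueError("background_p must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed) & 0x7FFFFFFF, 5]))
    universe = sorted(
        config.mrna_ids()
        if config is not None
        else {m for c in truth.ppi_clusters for m in c["members"]}
        | {truth.prognostic_gene} - {""}
    )
    cluster_pairs: set[tuple[str, str]] = set()
    rows = []
    for c in truth.ppi_clusters:
        members = sorted(c["members"])
        if not set(members) <= set(universe):
            raise ValueError("cluster members outside the mRNA universe")
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                cluster_pairs.add((a, b))
                rows.append((a, b, 0.99))
    if background_p > 0:
        n = len(universe)
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(len(iu)) < background_p
        confs = rng.uniform(0.4, 1.0, size=len(iu))
        for i, j, c_ in zip(iu[mask], ju[mask], confs[mask]):
            a, b = universe[i], universe[j]
            if (a, b) not in cluster_pairs:
                rows.append((a, b, float(c_)))
    return pd.DataFrame(rows, columns=["protein_a", "protein_b", "confidence"])


def generate_survival(
    tumour_expression: ExpressionMatrix,
    truth: TruthSet,
    baseline_hazard: float = 0.002,
    rng_seed: int = 0,
    censor_rate: float | None = None,
) -> pd.DataFrame:
    """Clinical table with a planted median-split hazard ratio.

    Event times are exponential with hazard ``baseline * hr^g`` where g
    indicates expression of the prognostic gene above its median across
    tumour samples.  Censoring is an independent exponential time whose rate
    is set so the marginal censored fraction equals ``censor_rate`` (the
    observation is the earlier of the two times).
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    gene = truth.prognostic_gene
    if gene not in tumour_expression.feature_ids:
        raise ValueError(f"prognostic gene {gene!r} not in expression matrix")
    if censor_rate is None:
        censor_rate = 0.3
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed) & 0x7FFFFFFF, 6]))
    t_samples = tumour_expression.samples_in_group(TUMOUR)
    expr = tumour_expression.values.loc[gene, t_samples].to_numpy(dtype=float)
    high = expr > np.median(expr)
    hazard = baseline_hazard * truth.prognostic_hr ** high.astype(float)
    times = rng.exponential(1.0 / hazard)
    if censor_rate >= 1.0:
        obs_times, events = times, np.zeros(len(times), dtype=int)
    elif censor_rate <= 0.0:
        obs_times, events = times, np.ones(len(times), dtype=int)
    else:
        c_rate = censor_rate / (1.0 - censor_rate) * float(hazard.mean())
        c_times = rng.exponential(1.0 / c_rate, size=len(times))
        events = (times <= c_times).astype(int)
        obs_times = np.minimum(times, c_times)
    return pd.DataFrame(
        {
            "sample": t_samples,
            "time": np.maximum(obs_times, 1e-9),
            "event": events,
        }
    )


def generate_infiltration(
    tumour_expression: ExpressionMatrix,
    truth: TruthSet,
    noise_sd: float = 0.5,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Cell-type x sample infiltration scores.

    Targeted cell types are sign * standardized expression of their target
    gene plus Gaussian(0, noise_sd); the rest are standard-normal noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed) & 0x7FFFFFFF, 7]))
    t_samples = tumour_expression.samples_in_group(TUMOUR)
    n = len(t_samples)
    scores = rng.standard_normal((len(CELL_TYPES), n))
    for i, ct in enumerate(CELL_TYPES):
        if ct in truth.infiltration_targets:
            gene, sign = truth.infiltration_targets[ct]
            if gene not in tumour_expression.feature_ids:
                raise ValueError(f"infiltration target gene {gene!r} absent")
            x = tumour_expression.values.loc[gene, t_samples].to_numpy(dtype=float)
            sd = x.std()
            z = (x - x.mean()) / (sd if sd > 0 else 1.0)
            scores[i] = sign * z + rng.standard_normal(n) * noise_sd
    return pd.DataFrame(scores, index=CELL_TYPES, columns=t_samples)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_simulation(outdir, config: SimConfig, baseline_hazard: float = 0.002) -> dict:
    """Run every generator and write the seven input files; returns paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genes, mirnas, truth = generate_cohort(config)
    lnc_mi, mi_mrna = generate_interactions(truth, config)
    ppi = generate_ppi(truth, background_p=0.002, rng_seed=config.rng_seed, config=config)
    clinical = generate_survival(
        genes, truth, baseline_hazard=baseline_hazard,
        rng_seed=config.rng_seed, censor_rate=config.censor_rate,
    )
    infiltration = generate_infiltration(genes, truth, rng_seed=config.rng_seed)

    paths = {
        "counts": out / "counts.tsv",
        "samples": out / "samples.tsv",
        "annotation": out / "annotation.tsv",
        "mirna": out / "mirna_log2.tsv",
        "lnc_mi": out / "lncrna_mirna.tsv",
        "mi_mrna": out / "mirna_mrna.tsv",
        "ppi": out / "ppi_edges.tsv",
        "clinical": out / "clinical.tsv",
        "infiltration": out / "infiltration.tsv",
        "truth": out / "truth.json",
    }
    genes.values.to_csv(paths["counts"], sep="\t")
    pd.DataFrame({"sample": genes.sample_ids, "group": genes.groups.values}).to_csv(
        paths["samples"], sep="\t", index=False
    )
    ann = pd.DataFrame(
        {
            "feature": config.mrna_ids() + config.lncrna_ids(),
            "biotype": ["mRNA"] * config.n_mrna + ["lncRNA"] * config.n_lncrna,
        }
    )
    ann.to_csv(paths["annotation"], sep="\t", index=False)
    mirnas.values.to_csv(paths["mirna"], sep="\t", float_format="%.8g")
    lnc_mi.to_csv(paths["lnc_mi"], sep="\t", index=False, float_format="%.8g")
    mi_mrna.to_csv(paths["mi_mrna"], sep="\t", index=False, float_format="%.8g")
    ppi.to_csv(paths["ppi"], sep="\t", index=False, float_format="%.8g")
    clinical.to_csv(paths["clinical"], sep="\t", index=False, float_format="%.8g")
    infiltration.to_csv(paths["infiltration"], sep="\t", float_format="%.8g")
    paths["truth"].write_text(truth.to_json())
    return {k: str(v) for k, v in paths.items()}
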