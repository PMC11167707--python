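"""Differential expression between tumour and normal groups.

Implements the DE stage of the ceRNA pipeline: expression filtering on raw
counts, log2 counts-per-million transformation, a per-feature Welch two-sample
t-test with Benjamini-Hochberg FDR control, and the biotype split into
DEmRNA / DElncRNA sets.

The moderated-statistics machinery of voom/limma is deliberately not
reproduced here: the DE stage is pluggable behind :class:`DERecord`, and a
Welch t on log-CPM is an adequate, transparent test for the simulated cohorts
this package ships with.  miRNA microarray matrices (already on a log2 scale)
go through the same test without the count preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

TUMOUR = "tumour"
NORMAL = "normal"

__all__ = [
    "ExpressionMatrix",
    "DERecord",
    "GeneAnnotation",
    "filter_by_expression",
    "log_cpm",
    "differential_test",
    "split_by_biotype",
    "read_matrix",
    "read_sample_sheet",
    "read_annotation",
    "write_de_table",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Features x samples expression matrix with tumour/normal labels.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with sample ids as columns.  Raw
        counts (``scale="counts"``) or log2 intensities (``scale="log2"``).
    groups
        Series mapping sample id -> ``"tumour"`` | ``"normal"``; must cover
        every column of ``values``.
    scale
        ``"counts"`` or ``"log2"``.
    """

    values: pd.DataFrame
    groups: pd.Series
    scale: str = "counts"

    def __post_init__(self) -> None:
        if self.scale not in ("counts", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.values.isna().any().any():
            raise ValueError("missing values in expression matrix")
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()].tolist()
            raise ValueError(f"samples without group label: {missing[:5]}")
        bad = set(self.groups.unique()) - {TUMOUR, NORMAL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if (self.groups == TUMOUR).sum() == 0 or (self.groups == NORMAL).sum() == 0:
            raise ValueError("both tumour and normal groups must be non-empty")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def subset_features(self, ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(ids)], self.groups, self.scale)


@dataclass(frozen=True)
class DERecord:
    """Per-feature differential expression call (tumour minus normal)."""

    feature_id: str
    log2fc: float
    p: float
    adj_p: float
    direction: str  # "up" | "down" | "ns"


@dataclass
class GeneAnnotation:
    """Total mapping feature id -> biotype ("mRNA" | "lncRNA")."""

    biotype: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.biotype.values()) - {"mRNA", "lncRNA"}
        if bad:
            raise ValueError(f"unknown biotypes: {sorted(bad)}")

    def __getitem__(self, feature_id: str) -> str:
        return self.biotype[feature_id]

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.biotype


# ---------------------------------------------------------------------------
# count preprocessing
# ---------------------------------------------------------------------------

def filter_by_expression(
    m: ExpressionMatrix,
    min_count: int = 10,
    min_samples: int | None = None,
) -> ExpressionMatrix:
    """Keep features with count >= min_count in >= min_samples samples.

    ``min_samples`` defaults to the smaller group size.  Boundaries are
    inclusive.  Sample set is unchanged; an empty result is allowed.
    """
    if m.scale != "counts":
        raise ValueError("expression filtering applies to count matrices")
    if min_samples is None:
        min_samples = min(
            (m.groups == TUMOUR).sum(), (m.groups == NORMAL).sum()
        )
    keep = (m.values.to_numpy() >= min_count).sum(axis=1) >= min_samples
    return ExpressionMatrix(m.values.loc[keep], m.groups, m.scale)


def log_cpm(m: ExpressionMatrix, prior_count: float = 0.5) -> ExpressionMatrix:
    """log2 counts-per-million with a prior count.

    value = log2((count + prior) / (library_size + 2*prior) * 1e6), with
    library_size the column sum.  The prior keeps zero counts finite.
    """
    if m.scale != "counts":
        raise ValueError("log-CPM applies to count matrices")
    if prior_count <= 0:
        raise ValueError("prior_count must be positive")
    counts = m.values.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    vals = np.log2((counts + prior_count) / (lib + 2.0 * prior_count) * 1e6)
    out = pd.DataFrame(vals, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(out, m.groups, scale="log2")


# ---------------------------------------------------------------------------
# testing
# ---------------------------------------------------------------------------

def differential_test(
    m: ExpressionMatrix,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    adjust: str = "BH",
) -> list[DERecord]:
    """Welch two-sample t per feature, with optional BH adjustment.

    log2fc = mean(tumour) - mean(normal).  ``direction`` is ``up`` when the
    (adjusted, if ``adjust="BH"``) p-value is below ``alpha`` and
    log2fc > lfc_min; ``down`` symmetric; otherwise ``ns``.  A feature with
    zero variance in both groups and equal means gets p = 1, log2fc = 0.
    """
    if m.scale != "log2":
        raise ValueError("differential_test expects a log2-scale matrix")
    if adjust not in ("BH", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    t_cols = m.samples_in_group(TUMOUR)
    n_cols = m.samples_in_group(NORMAL)
    if len(t_cols) < 2 or len(n_cols) < 2:
        raise ValueError("need at least two samples per group")

    xt = m.values[t_cols].to_numpy(dtype=float)
    xn = m.values[n_cols].to_numpy(dtype=float)
    lfc = xt.mean(axis=1) - xn.mean(axis=1)

    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant features trip scipy's precision warning; the truly
        # degenerate cases are overwritten explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(xt, xn, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)

    # degenerate features: zero variance in both groups
    var0 = (xt.var(axis=1) == 0) & (xn.var(axis=1) == 0)
    degen_equal = var0 & (lfc == 0)
    degen_diff = var0 & (lfc != 0)
    p[degen_equal] = 1.0
    p[degen_diff] = 0.0

    if adjust == "BH":
        adj = multipletests(p, method="fdr_bh")[1]
    else:
        adj = p.copy()

    crit = adj if adjust == "BH" else p
    records = []
    for fid, l, pv, ap, cv in zip(m.feature_ids, lfc, p, adj, crit):
        if cv < alpha and l > lfc_min:
            direction = "up"
        elif cv < alpha and l < -lfc_min:
            direction = "down"
        else:
            direction = "ns"
        records.append(DERecord(str(fid), float(l), float(pv), float(ap), direction))
    return records


def split_by_biotype(
    records: list[DERecord], ann: GeneAnnotation
) -> tuple[list[DERecord], list[DERecord]]:
    """Partition significant records into (DEmRNA, DElncRNA); ns dropped."""
    mrna, lnc = [], []
    for rec in records:
        if rec.direction == "ns":
            continue
        if rec.feature_id not in ann:
            raise KeyError(f"feature {rec.feature_id} missing from annotation")
        (mrna if ann[rec.feature_id] == "mRNA" else lnc).append(rec)
    return mrna, lnc


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_matrix(matrix_path, sample_sheet_path, scale: str = "counts") -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    groups = read_sample_sheet(sample_sheet_path)
    return ExpressionMatrix(values, groups, scale)


def read_sample_sheet(path) -> pd.Series:
    sheet = pd.read_csv(path, sep="\t")
    if not {"sample", "group"} <= set(sheet.columns):
        raise ValueError("sample sheet needs 'sample' and 'group' columns")
    return pd.Series(sheet["group"].values, index=sheet["sample"].values)


def read_annotation(path) -> GeneAnnotation:
    ann = pd.read_csv(path, sep="\t")
    if not {"feature", "biotype"} <= set(ann.columns):
        raise ValueError("annotation needs 'feature' and 'biotype' columns")
    return GeneAnnotation(dict(zip(ann["feature"], ann["biotype"])))


def write_de_table(records: list[DERecord], path) -> None:
    df = pd.DataFrame(
        [(r.feature_id, r.log2fc, r.p, r.adj_p, r.direction) for r in records],
        columns=["feature", "log2FC", "p", "adj_p", "direction"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
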