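"""Expression-matrix analysis and qPCR relative quantification.

Transcript abundance matrices are log10(x+1)-transformed, grouped by
average-linkage hierarchical clustering of z-scored profiles, and screened
for differential expression with Welch's unequal-variance t-test. qPCR Ct
tables are analysed by the Livak 2^-ddCt method against a reference gene
and a control condition, with per-replicate dCt values carrying the
significance test (star convention: * p<0.05, ** p<0.01, *** p<0.001).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage


@dataclass
class ExpressionMatrix:
    """Genes x samples abundances plus per-sample condition metadata."""

    values: pd.DataFrame  # genes (rows) x samples (columns), nonnegative
    samples: pd.DataFrame  # index = sample names; columns: condition, replicate, is_control

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample metadata must match matrix columns")
        if not self.samples["is_control"].any():
            raise ValueError("no control condition designated")

    @property
    def control_condition(self) -> str:
        return str(
            self.samples.loc[self.samples["is_control"], "condition"].iloc[0])

    def condition_columns(self, condition: str) -> list[str]:
        mask = self.samples["condition"] == condition
        return list(self.samples.index[mask])


def log_transform(values: pd.DataFrame) -> pd.DataFrame:
    """x -> log10(x + 1); monotone and zero-preserving."""
    arr = values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    return pd.DataFrame(np.log10(arr + 1.0), index=values.index,
                        columns=values.columns)


def cluster_genes(transformed: pd.DataFrame, k: int) -> pd.Series:
    """Cut an average-linkage dendrogram of z-scored genes into k groups.

    Rows are z-scored (constant rows set to 0) and clustered on Euclidean
    distance; output is a gene-indexed Series of group labels 1..k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(transformed):
        raise ValueError("k exceeds number of genes")
    arr = transformed.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (arr - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    if len(transformed) == 1:
        return pd.Series([1], index=transformed.index, name="group")
    tree = linkage(z, method="average", metric="euclidean")
    labels = fcluster(tree, t=k, criterion="maxclust")
    return pd.Series(labels, index=transformed.index, name="group")


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t statistic, df, and two-sided p-value.

    Computed from the textbook formula with the Welch-Satterthwaite
    degrees of freedom; identical samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("need >= 2 replicates per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        return 0.0, float(nx + ny - 2), 1.0
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


@dataclass
class DECall:
    gene: str
    condition: str
    log2fc: float
    p_value: float
    direction: str  # up | down | unchanged


def call_de(
    em: ExpressionMatrix,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> list[DECall]:
    """Differential-expression calls of each condition against control.

    Welch's t-test runs on log2(x+1) replicate values; the reported
    log2 fold change is the difference of group means on that scale.
    """
    ctrl = em.control_condition
    ctrl_cols = em.condition_columns(ctrl)
    if not ctrl_cols:
        raise ValueError("missing control condition")
    log2 = np.log2(em.values.to_numpy(dtype=float) + 1.0)
    log2 = pd.DataFrame(log2, index=em.values.index, columns=em.values.columns)
    calls = []
    conditions = [c for c in em.samples["condition"].unique() if c != ctrl]
    for cond in conditions:
        cols = em.condition_columns(cond)
        for gene in em.values.index:
            x = log2.loc[gene, cols].to_numpy()
            y = log2.loc[gene, ctrl_cols].to_numpy()
            _, _, p = welch_t(x, y)
            lfc = float(x.mean() - y.mean())
            if p < alpha and lfc >= lfc_threshold:
                direction = "up"
            elif p < alpha and lfc <= -lfc_threshold:
                direction = "down"
            else:
                direction = "unchanged"
            calls.append(DECall(str(gene), str(cond), lfc, p, direction))
    return calls


@dataclass
class CtTable:
    """Replicate Ct measurements for target genes and a reference gene."""

    rows: pd.DataFrame  # columns: gene, condition, replicate, ct_target, ct_reference
    reference_gene: str = "reference"

    def __post_init__(self) -> None:
        required = {"gene", "condition", "replicate", "ct_target",
                    "ct_reference"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        if self.rows["ct_reference"].isna().any():
            raise ValueError("missing reference-gene Ct values")
        ct = self.rows[["ct_target", "ct_reference"]].to_numpy()
        if ((ct <= 0) | (ct >= 45)).any():
            raise ValueError("Ct values must lie in (0, 45)")
        counts = self.rows.groupby(["gene", "condition"]).size()
        if (counts < 2).any():
            raise ValueError("need >= 2 replicates per (gene, condition)")


def stars(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class RqResult:
    gene: str
    condition: str
    ddct: float
    rq: float
    p_value: float
    stars: str


def ddct(ct: CtTable, control_condition: str) -> list[RqResult]:
    """Livak 2^-ddCt relative quantification against a control condition.

    Per replicate dCt = Ct_target - Ct_reference; ddCt is the difference
    of mean dCt between condition and control; RQ = 2^-ddCt. Welch's
    t-test compares per-replicate dCt values; the control compared with
    itself has RQ = 1 exactly.
    """
    df = ct.rows.copy()
    df["dct"] = df["ct_target"] - df["ct_reference"]
    results = []
    for gene, gene_rows in df.groupby("gene", sort=True):
        ctrl = gene_rows.loc[gene_rows["condition"] == control_condition,
                             "dct"].to_numpy()
        if len(ctrl) == 0:
            raise ValueError(
                f"gene {gene!r}: control condition "
                f"{control_condition!r} absent")
        for cond, cond_rows in gene_rows.groupby("condition", sort=True):
            treat = cond_rows["dct"].to_numpy()
            delta = float(treat.mean() - ctrl.mean())
            if cond == control_condition:
                delta = 0.0  # control vs itself, exactly
            _, _, p = welch_t(treat, ctrl)
            results.append(RqResult(
                gene=str(gene), condition=str(cond), ddct=delta,
                rq=2.0 ** (-delta), p_value=p, stars=stars(p)))
    return results


def read_ct_table(path, reference_gene: str = "reference") -> CtTable:
    return CtTable(pd.read_csv(path, sep="\t"), reference_gene)


def read_expression(values_path, samples_path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    samples["is_control"] = samples["is_control"].astype(bool)
    return ExpressionMatrix(values, samples)
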