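"""PKS-candidate expression statistics.

Covers the gene-expression side of the analysis: fourth-root TPM
normalisation, per-gene z-scores across stations, ordinary least-squares
regressions of expression against environmental covariates (salinity,
longitude, dissolved silicate, inorganic N:P, ...), seed-gene euclidean
coexpression clusters with a hard size cap, and hypergeometric pathway
fold-enrichment of those clusters:

    fold = (x / k) / (m / N)

with x in-pathway genes in the cluster, k cluster genes, m in-pathway genes
in the universe, N universe size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_CUTOFF = 1.0
DEFAULT_MAX_CLUSTER = 1000


class MissingGeneError(KeyError):
    pass


class UndefinedRegressionError(ValueError):
    pass


def tpm_transform(expr: pd.DataFrame) -> pd.DataFrame:
    """Element-wise fourth root (TPM^0.25); variance-stabilising and monotone."""
    x = expr.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("TPM values must be non-negative")
    return expr.astype(float) ** 0.25


def zscore(values: pd.Series | np.ndarray) -> np.ndarray:
    """Z-scores with the sample (n-1) standard deviation.

    A constant vector is degenerate and returns all zeros with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least three values to z-score")
    sd = v.std(ddof=1)
    if sd == 0:
        logger.warning("constant vector: z-scores undefined, returning zeros")
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def zscore_frame(expr: pd.DataFrame) -> pd.DataFrame:
    """Row-wise (per gene, across stations) z-scores of a matrix."""
    return pd.DataFrame(
        np.vstack([zscore(expr.loc[g].to_numpy()) for g in expr.index]),
        index=expr.index,
        columns=expr.columns,
    )


@dataclass
class RegressionResult:
    gene_id: str
    parameter: str
    slope: float
    p_value: float
    sign: str  # positive / negative / n.s.
    n_used: int


def env_regression(
    z_expr: pd.DataFrame,
    env: pd.DataFrame,
    parameter: str,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-gene OLS of expression z-scores on one environmental parameter.

    Stations are matched on the expression columns / environment index;
    rows with a missing value in either variable are dropped pairwise.
    Returns a table with slope, two-sided p for slope = 0, BH-adjusted p,
    and the sign classification at ``alpha`` (on the raw p, mirroring a
    plain per-gene lm(y ~ x) reading).
    """
    if parameter not in env.columns:
        raise KeyError(f"unknown environmental parameter {parameter!r}")
    stations = [s for s in z_expr.columns if s in env.index]
    if len(stations) < 4:
        raise ValueError("need at least four stations shared by expression and environment")
    x_all = env.loc[stations, parameter].to_numpy(dtype=float)
    finite_x = np.isfinite(x_all)
    if np.nanstd(x_all) == 0 or finite_x.sum() < 4:
        raise UndefinedRegressionError(f"parameter {parameter!r} is constant or too sparse")

    rows = []
    for g in z_expr.index:
        y = z_expr.loc[g, stations].to_numpy(dtype=float)
        ok = finite_x & np.isfinite(y)
        n_dropped = int((~ok).sum())
        if n_dropped:
            logger.info("gene %s vs %s: dropped %d station(s) pairwise", g, parameter, n_dropped)
        if ok.sum() < 4 or np.std(x_all[ok]) == 0:
            rows.append((g, parameter, np.nan, np.nan, "n.s.", int(ok.sum())))
            continue
        if np.std(y[ok]) == 0:
            rows.append((g, parameter, 0.0, 1.0, "n.s.", int(ok.sum())))
            continue
        fit = stats.linregress(x_all[ok], y[ok])
        sign = "n.s."
        if fit.pvalue < alpha:
            sign = "positive" if fit.slope > 0 else "negative"
        rows.append((g, parameter, fit.slope, fit.pvalue, sign, int(ok.sum())))
    out = pd.DataFrame(
        rows, columns=["gene_id", "parameter", "slope", "p_value", "sign", "n_used"]
    )
    valid = out["p_value"].notna()
    out["fdr"] = np.nan
    out.loc[valid, "fdr"] = bh_adjust(out.loc[valid, "p_value"].to_numpy())
    return out[["gene_id", "parameter", "slope", "p_value", "fdr", "sign", "n_used"]]


@dataclass
class CoexprCluster:
    seed_gene: str
    members: list[str]
    distances: np.ndarray

    def __post_init__(self) -> None:
        if len(self.members) != len(self.distances):
            raise ValueError("members and distances must align")


def coexpression_clusters(
    expr: pd.DataFrame,
    seed_genes: Sequence[str],
    cutoff: float = DEFAULT_CUTOFF,
    max_size: int = DEFAULT_MAX_CLUSTER,
) -> dict[str, CoexprCluster]:
    """Euclidean neighbourhoods of seed genes in the (transformed, unscaled)
    expression matrix: all genes within ``cutoff`` of the seed profile,
    sorted ascending by distance (ties by gene id), capped at ``max_size``
    nearest, seed excluded."""
    missing = [g for g in seed_genes if g not in expr.index]
    if missing:
        raise MissingGeneError(f"seed gene(s) absent from matrix: {missing}")
    mat = expr.to_numpy(dtype=float)
    ids = np.array(expr.index, dtype=object)
    pos = {g: i for i, g in enumerate(expr.index)}
    out: dict[str, CoexprCluster] = {}
    for seed in seed_genes:
        d = np.sqrt(((mat - mat[pos[seed]]) ** 2).sum(axis=1))
        keep = (d <= cutoff) & (ids != seed)
        order = np.lexsort((ids[keep], d[keep]))[:max_size]
        out[seed] = CoexprCluster(
            seed_gene=seed,
            members=list(ids[keep][order]),
            distances=d[keep][order],
        )
    return out


@dataclass
class EnrichmentResult:
    pathway: str
    x: int
    k: int
    m: int
    N: int
    fold: float
    p_value: float
    fdr: float = np.nan


def fold_and_pvalue(x: int, k: int, m: int, N: int) -> tuple[float, float]:
    """Fold enrichment (x/k)/(m/N) and the hypergeometric upper-tail
    P(X >= x | N, m, k)."""
    if k < 1 or m < 1:
        raise ValueError("k and m must be >= 1")
    if m > N or k > N:
        raise ValueError("m and k cannot exceed the universe size N")
    if x > min(k, m) or x < 0:
        raise ValueError("x must satisfy 0 <= x <= min(k, m)")
    fold = (x / k) / (m / N)
    p = float(stats.hypergeom.sf(x - 1, N, m, k))
    return fold, min(p, 1.0)


def fold_enrichment(
    cluster: CoexprCluster,
    pathway_members: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Pathway over-representation of one coexpression cluster.

    The universe is the set of pathway-annotated genes in the dataset;
    cluster genes outside it do not enter the counts.  P-values are BH
    adjusted across pathways within the cluster.
    """
    uni = set(universe)
    N = len(uni)
    members = [g for g in cluster.members if g in uni]
    k = len(members)
    rows: list[EnrichmentResult] = []
    for pw, genes in pathway_members.items():
        pw_genes = set(genes) & uni
        m = len(pw_genes)
        if m == 0 or k == 0:
            continue
        x = len(pw_genes.intersection(members))
        fold, p = fold_and_pvalue(x, k, m, N)
        rows.append(EnrichmentResult(pathway=pw, x=x, k=k, m=m, N=N, fold=fold, p_value=p))
    if rows:
        adj = bh_adjust([r.p_value for r in rows])
        for r, q in zip(rows, adj):
            r.fdr = float(q)
    return pd.DataFrame(
        [(r.pathway, r.x, r.k, r.m, r.N, r.fold, r.p_value, r.fdr) for r in rows],
        columns=["pathway", "x", "k", "m", "N", "fold", "p_value", "fdr"],
    )
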