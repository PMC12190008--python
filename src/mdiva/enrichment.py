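"""KS-like random-walk enrichment on edge intensities (GSVAm) and genes (GSVA).

For one sample s and one gene set, edges are ranked by |U_rs|^tau descending
and the walk accumulates the contrast between the weighted in-set cumulative
fraction and the unweighted complement cumulative fraction:

    E(w) = sum_{r<=w} |U_rs|^tau C_r / sum_{r<=R} |U_rs|^tau C_r
         - sum_{r<=w} 1(C_r = 0)   / sum_{r<=R} 1(C_r = 0)

where C_r counts how many of the set's annotations the edge's mass
difference carries.  The two adaptations relative to a classical
two-sample KS statistic are the intensity weighting (|U|^tau) and the
annotation-multiplicity counts C.  The enrichment score (ES) is the walk
value at the position of maximum absolute deviation, signed; with tau = 0
and binary C the ES reduces exactly to the signed two-sample KS statistic
between in-set and out-of-set rank positions.

Group-mean walks, bloom-minus-pre-bloom residual walks with quadrant
classification, permutation / analytic p-values for the maximum deviation,
and the gene-level GSVA analogue (genes ranked by TPM^tau) live here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_TAU = 1.0
DEFAULT_N_PERM = 999


class DegenerateSetError(ValueError):
    """Gene set with empty in-set weight or empty complement on this ranking."""


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    members: frozenset[str]
    class_id: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")


@dataclass
class WalkProfile:
    """One KS-like walk: values over ranked positions 1..R and its ES."""

    values: np.ndarray
    es: float
    set_id: str = ""
    sample_id: str = ""
    tau: float = DEFAULT_TAU


@dataclass
class ResidualWalk:
    """Bloom-group mean walk, its residual versus pre-bloom, and quadrant."""

    set_id: str
    bloom: np.ndarray
    pre: np.ndarray
    residual: np.ndarray = field(init=False)
    quadrant: int | None = field(init=False)
    max_deviation: float = field(init=False)
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.bloom.shape != self.pre.shape:
            raise ValueError("bloom and pre-bloom walks must have equal length")
        self.residual = self.bloom - self.pre
        w_bloom = int(np.argmax(np.abs(self.bloom)))
        self.max_deviation = float(self.bloom[w_bloom])
        # The quadrant is read at the peak of the dominant group's walk (the
        # group deviating farther from zero), with the first axis expressed
        # from the bloom perspective: when the bloom walk dominates — the
        # canonical case — this is literally (sign of bloom walk at its max
        # deviation, sign of residual there); when the pre-bloom walk
        # dominates, its peak value enters with flipped sign.  Built this way
        # the label is exactly antisymmetric under group swap (1<->3, 2<->4).
        w_pre = int(np.argmax(np.abs(self.pre)))
        if np.abs(self.bloom[w_bloom]) >= np.abs(self.pre[w_pre]):
            w, a1 = w_bloom, float(self.bloom[w_bloom])
        else:
            w, a1 = w_pre, -float(self.pre[w_pre])
        a2 = float(self.residual[w])
        if a1 > 0 and a2 > 0:
            self.quadrant = 1
        elif a1 > 0 and a2 < 0:
            self.quadrant = 2
        elif a1 < 0 and a2 < 0:
            self.quadrant = 3
        elif a1 < 0 and a2 > 0:
            self.quadrant = 4
        else:
            self.quadrant = None


# ---------------------------------------------------------------------------
# ranking and the walk itself
# ---------------------------------------------------------------------------


def rank_edges(
    u_column: np.ndarray,
    delta_masses: np.ndarray,
    edge_ids: Sequence[str],
    tau: float = DEFAULT_TAU,
) -> np.ndarray:
    """Permutation ordering edges by |U|^tau descending.

    Ties are broken by MD delta mass ascending, then edge id
    lexicographically, so the order is stable and deterministic; tau = 0
    makes every weight 1 and the order is purely the tie-break order.
    """
    u = np.asarray(u_column, dtype=float)
    if u.size < 2:
        raise ValueError("need at least two edges to rank")
    w = np.abs(u) ** tau
    if not w.any():
        logger.warning("all-zero intensity column: ranking falls back to tie-break order")
    ids = np.asarray(edge_ids, dtype=object)
    return np.lexsort((ids, np.asarray(delta_masses, dtype=float), -w))


def ks_walk(
    ranked_u: np.ndarray,
    counts: np.ndarray,
    tau: float = DEFAULT_TAU,
    set_id: str = "",
    sample_id: str = "",
) -> WalkProfile:
    """KS-like walk over edges already in ranked order.

    ``counts`` is the annotation count vector C in the same ranked order.
    Raises DegenerateSetError when the set has no in-set weight or no
    complement positions.
    """
    u = np.abs(np.asarray(ranked_u, dtype=float))
    c = np.asarray(counts, dtype=float)
    if u.shape != c.shape:
        raise ValueError("ranked_u and counts must align")
    w = u**tau
    in_w = w * c
    denom = in_w.sum()
    comp = c == 0
    n_comp = int(comp.sum())
    if denom <= 0 or n_comp == 0:
        raise DegenerateSetError(
            f"set {set_id or '<anon>'}: in-set weight {denom:g}, complement size {n_comp}"
        )
    values = np.cumsum(in_w) / denom - np.cumsum(comp) / n_comp
    es = float(values[np.argmax(np.abs(values))])
    return WalkProfile(values=values, es=es, set_id=set_id, sample_id=sample_id, tau=tau)


def _walk_values_batch(weights: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Vectorised walks for a batch of count vectors on one ranked weight row.

    weights: (R,) already |U|^tau in ranked order; counts: (B, R).
    Rows with zero in-set weight or empty complement come back as NaN.
    """
    in_w = weights[None, :] * counts
    denom = in_w.sum(axis=1, keepdims=True)
    comp = counts == 0
    n_comp = comp.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.cumsum(in_w, axis=1) / denom - np.cumsum(comp, axis=1) / n_comp
    vals[(denom[:, 0] <= 0) | (n_comp[:, 0] == 0)] = np.nan
    return vals


def sample_walks(
    U: pd.DataFrame,
    counts: Mapping[str, np.ndarray],
    delta_masses: np.ndarray,
    tau: float = DEFAULT_TAU,
) -> dict[str, dict[str, WalkProfile]]:
    """All walks for an edge-intensity matrix.

    Edges are re-ranked within each sample independently.  Returns
    {set_id: {sample_id: WalkProfile}}.  Degenerate sets raise.
    """
    edge_ids = list(U.index)
    orders = {
        s: rank_edges(U[s].to_numpy(), delta_masses, edge_ids, tau) for s in U.columns
    }
    out: dict[str, dict[str, WalkProfile]] = {}
    for set_id, c in counts.items():
        c = np.asarray(c)
        per_sample: dict[str, WalkProfile] = {}
        for s in U.columns:
            o = orders[s]
            per_sample[s] = ks_walk(
                U[s].to_numpy()[o], c[o], tau=tau, set_id=set_id, sample_id=s
            )
        out[set_id] = per_sample
    return out


def enrichment_scores(walks: Mapping[str, Mapping[str, WalkProfile]]) -> pd.DataFrame:
    """ES table, gene sets x samples."""
    sets = list(walks)
    samples = list(next(iter(walks.values()))) if sets else []
    data = [[walks[g][s].es for s in samples] for g in sets]
    return pd.DataFrame(data, index=sets, columns=samples)


# ---------------------------------------------------------------------------
# percentiles, group means, residual quadrants
# ---------------------------------------------------------------------------


def walk_percentiles(walks: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Percentile (0-100) of each set's walk value across sets, per position.

    Mean-rank ties; with a single set every position degenerates to 50.
    """
    set_ids = list(walks)
    if len(set_ids) < 2:
        logger.warning("walk percentiles need >= 2 sets; returning constant 50")
        return {g: np.full_like(np.asarray(walks[g], dtype=float), 50.0) for g in set_ids}
    mat = np.vstack([np.asarray(walks[g], dtype=float) for g in set_ids])
    n = mat.shape[0]
    ranks = stats.rankdata(mat, axis=0, method="average")
    pct = (ranks - 0.5) / n * 100.0
    return {g: pct[i] for i, g in enumerate(set_ids)}


def group_walks(
    walks: Mapping[str, WalkProfile] | Mapping[str, np.ndarray],
    grouping: Mapping[str, str],
) -> dict[str, np.ndarray]:
    """Position-wise mean walk per group for one gene set."""
    unknown = set(grouping) - set(walks)
    if unknown:
        raise ValueError(f"grouping refers to unknown samples: {sorted(unknown)}")
    by_group: dict[str, list[np.ndarray]] = {}
    for sample, group in grouping.items():
        w = walks[sample]
        vals = w.values if isinstance(w, WalkProfile) else np.asarray(w, dtype=float)
        by_group.setdefault(group, []).append(vals)
    return {g: np.mean(np.vstack(v), axis=0) for g, v in by_group.items()}


def residual_quadrant(bloom: np.ndarray, pre: np.ndarray, set_id: str = "") -> ResidualWalk:
    """Residual walk (bloom minus pre-bloom) with its quadrant label.

    The quadrant is read at the position of maximum |bloom| deviation:
    (+,+) -> 1 dominant in the bloom, (+,-) -> 2, (-,-) -> 3 depleted in the
    bloom, (-,+) -> 4; a zero in either sign gives no quadrant.
    """
    return ResidualWalk(set_id=set_id, bloom=np.asarray(bloom, float), pre=np.asarray(pre, float))


# ---------------------------------------------------------------------------
# p-values for the maximum deviation
# ---------------------------------------------------------------------------


def _analytic_kolmogorov_p(max_dev: float, n_in: int, n_comp: int, n_eff_groups: float = 1.0) -> float:
    """Kolmogorov asymptotic tail for a maximum deviation.

    Effective size is the harmonic combination of in-set and complement
    position counts; for residual walks it is further multiplied by the
    harmonic group-size factor (an approximation — the permutation method is
    the calibrated one).
    """
    if max_dev <= 0:
        return 1.0
    en = n_in * n_comp / (n_in + n_comp) * n_eff_groups
    p = float(stats.kstwobign.sf(np.sqrt(en) * max_dev))
    return min(max(p, np.finfo(float).tiny), 1.0)


def _permuted_counts(
    c: np.ndarray, n_perm: int, rng: np.random.Generator, blocks: np.ndarray | None
) -> np.ndarray:
    """(n_perm, R) matrix of null count vectors in edge space.

    With ``blocks`` (the edge -> mass-difference index map), annotation
    labels are permuted at the block level — the count value of each MD is
    reassigned to a random MD and expanded back to its edges — which is the
    exchangeable null for annotations that live on mass differences.
    Without blocks, counts are permuted over positions directly.
    """
    if blocks is None:
        return np.vstack([rng.permutation(c) for _ in range(n_perm)])
    blocks = np.asarray(blocks)
    uniq, inverse = np.unique(blocks, return_inverse=True)
    c_block = np.zeros(len(uniq), dtype=c.dtype)
    c_block[inverse] = c  # C is constant within a block by construction
    perms = np.vstack([rng.permutation(c_block) for _ in range(n_perm)])
    return perms[:, inverse]


def walk_max_pvalue(
    u_column: np.ndarray,
    counts: np.ndarray,
    delta_masses: np.ndarray,
    edge_ids: Sequence[str],
    tau: float = DEFAULT_TAU,
    method: str = "permutation",
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    blocks: np.ndarray | None = None,
) -> tuple[WalkProfile, float]:
    """P-value for the maximum |walk| deviation of one sample x one set.

    Permutation method: the annotation count vector is permuted n_perm
    times (at the mass-difference block level when ``blocks`` is given, so
    that edges of one MD keep a shared count under the null), the walk
    recomputed each time, and
    p = (1 + #{max|perm walk| >= max|observed|}) / (n_perm + 1).
    """
    order = rank_edges(u_column, delta_masses, edge_ids, tau)
    u = np.asarray(u_column, float)[order]
    c = np.asarray(counts)[order]
    obs = ks_walk(u, c, tau=tau)
    obs_max = float(np.max(np.abs(obs.values)))
    if method == "analytic":
        p = _analytic_kolmogorov_p(obs_max, int((c > 0).sum()), int((c == 0).sum()))
        return obs, p
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    w = np.abs(u) ** tau
    perms = _permuted_counts(
        np.asarray(counts), n_perm, rng, blocks
    )[:, order]
    vals = _walk_values_batch(w, perms)
    perm_max = np.nanmax(np.abs(vals), axis=1)
    p = (1.0 + float(np.sum(perm_max >= obs_max - 1e-12))) / (n_perm + 1.0)
    return obs, p


def residual_max_pvalue(
    U: pd.DataFrame,
    counts: np.ndarray,
    delta_masses: np.ndarray,
    grouping: Mapping[str, str],
    group_a: str,
    group_b: str,
    tau: float = DEFAULT_TAU,
    method: str = "permutation",
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    set_id: str = "",
    blocks: np.ndarray | None = None,
) -> ResidualWalk:
    """Residual walk between two groups with a maximum-deviation p-value.

    The statistic is max |residual| where residual = mean walk of group_a
    minus mean walk of group_b; the null permutes the annotation labels
    (one shared permutation across samples, since C is a property of the
    master network's edges; pass ``blocks`` = the edge-to-MD index map to
    permute labels over mass differences, the calibrated default in the
    pipeline)."""
    samples = [s for s in U.columns if s in grouping]
    if not samples:
        raise ValueError("no samples in grouping")
    edge_ids = list(U.index)
    c = np.asarray(counts)
    orders = {s: rank_edges(U[s].to_numpy(), delta_masses, edge_ids, tau) for s in samples}
    per_sample = {
        s: ks_walk(U[s].to_numpy()[orders[s]], c[orders[s]], tau=tau, set_id=set_id, sample_id=s)
        for s in samples
    }
    groups = group_walks(per_sample, {s: grouping[s] for s in samples})
    rw = ResidualWalk(set_id=set_id, bloom=groups[group_a], pre=groups[group_b])
    obs_max = float(np.max(np.abs(rw.residual)))

    if method == "analytic":
        n_in = int((c > 0).sum())
        n_comp = int((c == 0).sum())
        n_a = sum(1 for s in samples if grouping[s] == group_a)
        n_b = sum(1 for s in samples if grouping[s] == group_b)
        rw.p_value = _analytic_kolmogorov_p(obs_max, n_in, n_comp, n_a * n_b / (n_a + n_b))
        return rw
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    perms = _permuted_counts(c, n_perm, rng, blocks)  # (B, R) in edge space
    acc: dict[str, np.ndarray] = {}
    group_counts: dict[str, int] = {}
    for s in samples:
        o = orders[s]
        w = np.abs(U[s].to_numpy()[o]) ** tau
        vals = _walk_values_batch(w, perms[:, o])
        g = grouping[s]
        acc[g] = acc.get(g, 0) + vals
        group_counts[g] = group_counts.get(g, 0) + 1
    resid = acc[group_a] / group_counts[group_a] - acc[group_b] / group_counts[group_b]
    perm_max = np.nanmax(np.abs(resid), axis=1)
    rw.p_value = (1.0 + float(np.sum(perm_max >= obs_max - 1e-12))) / (n_perm + 1.0)
    return rw


# ---------------------------------------------------------------------------
# gene-level GSVA and gene-set utilities
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentScoreTable:
    es: pd.DataFrame  # sets x samples
    difference: pd.Series | None = None  # mean(group A) - mean(group B) per set
    skipped: list[str] = field(default_factory=list)


def gsva_genes(
    expr: pd.DataFrame,
    gene_sets: Iterable[GeneSet],
    tau: float = DEFAULT_TAU,
    annotations: Mapping[str, Iterable[str]] | None = None,
    grouping: Mapping[str, str] | None = None,
    group_a: str | None = None,
    group_b: str | None = None,
) -> EnrichmentScoreTable:
    """Gene-level GSVA: the same walk machinery on a TPM matrix.

    Genes are ranked per sample by TPM^tau descending (ties by gene id) and
    the count vector is the per-gene overlap with the set.  When
    ``annotations`` is None, gene ids themselves are the annotation ids.
    Sets degenerate on this matrix (no expressed member, or covering every
    gene) are skipped with a log entry.
    """
    gene_ids = np.array(expr.index, dtype=object)
    if len(gene_ids) < 2:
        raise ValueError("need at least two genes")
    x = expr.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("expression values must be non-negative")
    if annotations is None:
        ann = {g: {g} for g in gene_ids}
    else:
        ann = {g: set(annotations.get(g, ())) for g in gene_ids}

    zero_delta = np.zeros(len(gene_ids))  # no mass tie-break for genes
    orders = {
        s: rank_edges(expr[s].to_numpy(), zero_delta, gene_ids, tau) for s in expr.columns
    }
    rows: dict[str, list[float]] = {}
    skipped: list[str] = []
    for gs in gene_sets:
        c = np.array([len(ann[g] & gs.members) for g in gene_ids], dtype=np.int64)
        try:
            rows[gs.set_id] = [
                ks_walk(expr[s].to_numpy()[orders[s]], c[orders[s]], tau=tau,
                        set_id=gs.set_id, sample_id=s).es
                for s in expr.columns
            ]
        except DegenerateSetError as err:
            logger.warning("skipping degenerate gene set: %s", err)
            skipped.append(gs.set_id)
    es = pd.DataFrame.from_dict(rows, orient="index", columns=list(expr.columns))
    diff = None
    if grouping is not None:
        if group_a is None or group_b is None:
            raise ValueError("group_a and group_b required with grouping")
        a = [s for s in expr.columns if grouping.get(s) == group_a]
        b = [s for s in expr.columns if grouping.get(s) == group_b]
        diff = es[a].mean(axis=1) - es[b].mean(axis=1)
    return EnrichmentScoreTable(es=es, difference=diff, skipped=skipped)


def merge_gene_sets(
    sets: Iterable[GeneSet], merge_map: Mapping[str, str]
) -> list[GeneSet]:
    """Merge pathways into broader classes; class members are the union of
    their pathways' members.  Pathways absent from the map are retained as
    their own class with a warning."""
    classes: dict[str, set[str]] = {}
    order: list[str] = []
    for gs in sets:
        cls = merge_map.get(gs.set_id)
        if cls is None:
            logger.warning("pathway %s missing from merge map; kept as its own class", gs.set_id)
            cls = gs.set_id
        if cls not in classes:
            classes[cls] = set()
            order.append(cls)
        classes[cls] |= gs.members
    return [GeneSet(set_id=c, members=frozenset(classes[c]), class_id=c) for c in order]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
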