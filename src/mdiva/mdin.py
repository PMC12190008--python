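"""Mass-difference network (MDiN) construction and edge-intensity projection.

An MDiN is a directed graph over mass-spectrometric features.  An edge runs
from a lower-mass feature i to a higher-mass feature j whenever their mass
gap matches an entry of an annotated mass-difference list K within an
absolute tolerance:

    |m_j - m_i - delta_e| <= tol,   delta_e in K,  m_j > m_i.

Each mass difference corresponds to an enzymatic substrate->product
transformation and carries enzyme/annotation identifiers; these make the
edge set of the network addressable by gene sets.  One master network is
built for the whole sample set, and per-sample feature intensities are
projected onto its edges by the geometric mean of the two endpoints,
yielding the edge-intensity matrix U on which enrichment walks run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formula import Formula

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE_DA = 0.001


class InvalidSeedError(ValueError):
    """A propagation seed formula is inconsistent with its feature's mass."""


@dataclass(frozen=True)
class MassDifference:
    """One annotated reaction mass delta.

    delta_formula is the signed element-count change (product minus
    substrate) or None when unknown; annotations are enzyme/protein
    identifiers that define gene-set membership of edges carrying this MD.
    """

    md_id: str
    delta_mass: float
    delta_formula: Formula | None = None
    annotations: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.delta_mass <= 0:
            raise ValueError(f"MD {self.md_id}: delta_mass must be > 0")


class MassDifferenceList:
    """Ordered collection of MassDifference entries with unique ids."""

    def __init__(self, entries: Iterable[MassDifference]) -> None:
        self.entries: list[MassDifference] = list(entries)
        ids = [e.md_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("md_ids must be unique within K")
        self._by_id = {e.md_id: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, md_id: str) -> MassDifference:
        return self._by_id[md_id]

    @property
    def delta_masses(self) -> np.ndarray:
        return np.array([e.delta_mass for e in self.entries], dtype=float)

    def all_annotations(self) -> set[str]:
        out: set[str] = set()
        for e in self.entries:
            out |= e.annotations
        return out


class FeatureTable:
    """Features x samples non-negative intensity matrix with neutral masses.

    Parameters
    ----------
    masses:
        Per-feature neutral monoisotopic mass in Da, indexed by feature id.
    intensities:
        DataFrame, rows = feature ids (same index as masses), columns =
        sample ids, values >= 0.
    formulas:
        Optional mapping feature id -> Formula for assigned features.
    """

    def __init__(
        self,
        masses: pd.Series,
        intensities: pd.DataFrame,
        formulas: Mapping[str, Formula] | None = None,
    ) -> None:
        if not masses.index.equals(intensities.index):
            raise ValueError("masses and intensities must share the feature index")
        if (masses <= 0).any():
            bad = masses.index[masses <= 0][0]
            raise ValueError(f"feature {bad!r}: mass must be positive")
        if (intensities.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")
        self.masses = masses.astype(float)
        self.intensities = intensities.astype(float)
        self.formulas: dict[str, Formula] = dict(formulas or {})

    @property
    def feature_ids(self) -> list[str]:
        return list(self.masses.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def __len__(self) -> int:
        return len(self.masses)


@dataclass(frozen=True)
class Edge:
    """Directed low-mass -> high-mass edge labelled by the matching MD."""

    source: str
    target: str
    md_id: str


@dataclass
class MDiN:
    """The master mass-difference network over a feature table.

    Edges are held both as Edge records and as parallel index arrays into
    the feature table / MD list for vectorised downstream computation.
    Edge order is canonical (sorted by source mass, target mass, ids), so
    the network is invariant to the input order of the features.
    """

    features: FeatureTable
    md_list: MassDifferenceList
    tolerance: float
    edges: list[Edge]
    source_idx: np.ndarray
    target_idx: np.ndarray
    md_idx: np.ndarray
    provenance: str = ""
    edge_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.edge_ids:
            self.edge_ids = [f"{e.source}|{e.target}|{e.md_id}" for e in self.edges]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_delta_masses(self) -> np.ndarray:
        deltas = self.md_list.delta_masses
        return deltas[self.md_idx]

    def to_networkx(self):
        import networkx as nx

        g = nx.MultiDiGraph(tolerance=self.tolerance, provenance=self.provenance)
        for fid, mass in self.features.masses.items():
            g.add_node(fid, mass_da=float(mass))
        deltas = self.md_list.delta_masses
        for e, mi in zip(self.edges, self.md_idx):
            g.add_edge(e.source, e.target, key=e.md_id, md_id=e.md_id,
                       delta_mass_da=float(deltas[mi]))
        return g


def build_mdin(
    features: FeatureTable,
    md_list: MassDifferenceList,
    tolerance: float = DEFAULT_TOLERANCE_DA,
) -> MDiN:
    """Build the master MDiN by matching all feature pairs against K.

    For every ordered pair (i, j) with m_j > m_i and every MD e with
    |m_j - m_i - delta_e| <= tolerance, exactly one edge (i, j, e) is
    created.  Several MDs matching one pair yield parallel edges, each with
    its own annotations.  An empty K yields an empty edge set.

    Uses a sorted-mass binary search per (feature, MD), O(n k log n).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    masses = features.masses.to_numpy()
    ids = np.array(features.feature_ids, dtype=object)
    order = np.argsort(masses, kind="stable")
    sm = masses[order]

    src_parts: list[np.ndarray] = []
    tgt_parts: list[np.ndarray] = []
    md_parts: list[np.ndarray] = []
    for k, md in enumerate(md_list):
        lo = np.searchsorted(sm, sm + md.delta_mass - tolerance, side="left")
        hi = np.searchsorted(sm, sm + md.delta_mass + tolerance, side="right")
        counts = hi - lo
        if counts.sum() == 0:
            continue
        src = np.repeat(np.arange(len(sm)), counts)
        tgt = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi) if b > a])
        keep = sm[tgt] > sm[src]  # strict direction; also kills self/zero-gap pairs
        if keep.any():
            src_parts.append(order[src[keep]])
            tgt_parts.append(order[tgt[keep]])
            md_parts.append(np.full(int(keep.sum()), k, dtype=np.intp))

    if src_parts:
        src_idx = np.concatenate(src_parts)
        tgt_idx = np.concatenate(tgt_parts)
        md_idx = np.concatenate(md_parts)
        # canonical edge order: by endpoint masses, then ids, then MD id
        md_ids = np.array([e.md_id for e in md_list], dtype=object)
        key = np.lexsort(
            (
                md_ids[md_idx],
                ids[tgt_idx],
                ids[src_idx],
                masses[tgt_idx],
                masses[src_idx],
            )
        )
        src_idx, tgt_idx, md_idx = src_idx[key], tgt_idx[key], md_idx[key]
    else:
        src_idx = np.empty(0, dtype=np.intp)
        tgt_idx = np.empty(0, dtype=np.intp)
        md_idx = np.empty(0, dtype=np.intp)

    md_entries = md_list.entries
    edges = [
        Edge(ids[s], ids[t], md_entries[m].md_id)
        for s, t, m in zip(src_idx, tgt_idx, md_idx)
    ]
    logger.info("built MDiN: %d features, %d MDs, %d edges",
                len(features), len(md_list), len(edges))
    return MDiN(
        features=features,
        md_list=md_list,
        tolerance=tolerance,
        edges=edges,
        source_idx=src_idx,
        target_idx=tgt_idx,
        md_idx=md_idx,
    )


def brute_force_edges(
    masses: Sequence[float],
    ids: Sequence[str],
    md_list: MassDifferenceList,
    tolerance: float,
) -> set[tuple[str, str, str]]:
    """Independent O(n^2 k) reference: the literal triple loop over Eq-style
    matching.  Used as an oracle in tests; kept free of the searchsorted path.
    """
    out: set[tuple[str, str, str]] = set()
    n = len(masses)
    for i in range(n):
        for j in range(n):
            if masses[j] <= masses[i]:
                continue
            gap = masses[j] - masses[i]
            for md in md_list:
                if abs(gap - md.delta_mass) <= tolerance:
                    out.add((ids[i], ids[j], md.md_id))
    return out


# ---------------------------------------------------------------------------
# formula propagation
# ---------------------------------------------------------------------------

ASSIGNED = "assigned"
UNASSIGNED = "unassigned"
CONFLICT = "conflict"


@dataclass(frozen=True)
class FormulaAssignment:
    status: str
    formula: Formula | None = None


def propagate_formulas(
    net: MDiN, seeds: Mapping[str, Formula]
) -> dict[str, FormulaAssignment]:
    """Propagate molecular formulas from seed features across the network.

    A candidate for the target of an edge is formula(source) plus the edge's
    delta formula (minus when traversing against the edge direction).
    Candidates with any negative element count, or whose mass disagrees with
    the feature's measured mass beyond the network tolerance, are rejected.
    The full closure of reachable candidates is computed before features are
    classified, so the result is independent of traversal order: a feature
    ending up with exactly one surviving candidate is assigned; with two or
    more distinct candidates it is marked conflicted and left unassigned.
    Edges whose MD has an unknown delta formula are skipped.
    """
    masses = net.features.masses
    tol = net.tolerance
    for fid, f in seeds.items():
        if fid not in masses.index:
            raise InvalidSeedError(f"seed feature {fid!r} not in the network")
        if abs(f.monoisotopic_mass - masses[fid]) > tol:
            raise InvalidSeedError(
                f"seed {fid!r}: formula mass {f.monoisotopic_mass:.6f} "
                f"inconsistent with feature mass {masses[fid]:.6f}"
            )

    # adjacency: fid -> list of (neighbor fid, signed delta Formula)
    adj: dict[str, list[tuple[str, Formula]]] = {}
    empty = Formula()
    for e in net.edges:
        df = net.md_list[e.md_id].delta_formula
        if df is None:
            continue
        adj.setdefault(e.source, []).append((e.target, df))
        adj.setdefault(e.target, []).append((e.source, empty - df))

    candidates: dict[str, set[Formula]] = {fid: {f} for fid, f in seeds.items()}
    stack: list[tuple[str, Formula]] = [(fid, f) for fid, f in seeds.items()]
    while stack:
        fid, f = stack.pop()
        for nb, delta in adj.get(fid, ()):
            if nb in seeds:  # seeds are authoritative anchors, never revised
                continue
            cand = f + delta
            if not cand.is_nonnegative():
                continue
            if abs(cand.monoisotopic_mass - masses[nb]) > tol:
                continue
            known = candidates.setdefault(nb, set())
            if cand not in known:
                known.add(cand)
                stack.append((nb, cand))

    out: dict[str, FormulaAssignment] = {}
    for fid in net.features.feature_ids:
        cands = candidates.get(fid, set())
        if len(cands) == 1:
            out[fid] = FormulaAssignment(ASSIGNED, next(iter(cands)))
        elif len(cands) > 1:
            out[fid] = FormulaAssignment(CONFLICT)
        else:
            out[fid] = FormulaAssignment(UNASSIGNED)
    return out


# ---------------------------------------------------------------------------
# edge projection and annotation counts
# ---------------------------------------------------------------------------


def project_edges(net: MDiN, X: FeatureTable | None = None) -> pd.DataFrame:
    """Project per-sample feature intensities onto edges.

    U_rs = sqrt(x_is * x_js) for edge r = (i, j): the geometric mean of the
    two endpoint intensities.  A zero at either endpoint gives U = 0; the
    edge is retained so U has a constant row set across samples.

    Returns a DataFrame with edge ids as index and sample ids as columns.
    """
    if X is None:
        X = net.features
    missing = set(net.features.feature_ids) - set(X.feature_ids)
    if missing:
        raise ValueError(f"edge endpoints missing from feature table: {sorted(missing)[:5]}")
    xi = X.intensities.to_numpy()
    if (xi < 0).any():
        raise ValueError("intensities must be non-negative")
    pos = {fid: i for i, fid in enumerate(X.feature_ids)}
    src = np.array([pos[e.source] for e in net.edges], dtype=np.intp)
    tgt = np.array([pos[e.target] for e in net.edges], dtype=np.intp)
    u = np.sqrt(xi[src, :] * xi[tgt, :])
    return pd.DataFrame(u, index=net.edge_ids, columns=X.sample_ids)


def edge_annotation_counts(net: MDiN, gene_set: Iterable[str]) -> np.ndarray:
    """Count vector C over edges: C_r = |annotations(md(r)) ∩ gene_set|.

    One MD annotated more than once with the same identifier still counts it
    once (set semantics).  Identifiers in the gene set that appear on no MD
    are ignored with a warning.
    """
    members = set(gene_set)
    known = net.md_list.all_annotations()
    unknown = members - known
    if unknown:
        logger.warning("gene set contains %d annotation ids absent from K, e.g. %s",
                       len(unknown), sorted(unknown)[:3])
    per_md = np.array(
        [len(md.annotations & members) for md in net.md_list], dtype=np.int64
    )
    return per_md[net.md_idx]
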