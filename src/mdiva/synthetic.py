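"""Synthetic study generator with known ground truth.

Emulates the inputs of a fjord bloom survey at desk scale: an FT-ICR-MS-like
feature table (features with exact neutral masses placed so that controlled
pairs differ by listed reaction mass deltas), an annotated mass-difference
list with gene sets and a pathway->class merge map, a TPM expression matrix
with station covariates, and planted effects — pathway-level intensity
shifts between a pre-bloom and a bloom group, and gene subsets correlated
with a chosen environmental parameter.  Everything is deterministic given
the seed.

Intensities are log-normal on the log10 scale with a per-sample
multiplicative depth factor; planted effects act on feature intensities
(node level) and reach the edge matrix through the geometric-mean
projection, matching the causal direction of the real assay.  Raw spectra,
isotopologues, adducts and read-level sequencing are deliberately not
modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import GeneSet
from .formula import Formula
from .mdin import (
    FeatureTable,
    MassDifference,
    MassDifferenceList,
    build_mdin,
    edge_annotation_counts,
)

logger = logging.getLogger(__name__)


class ConfigConflictError(ValueError):
    """Simulation parameters contradict each other (e.g. tolerance too wide)."""


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic metabolome.

    Defaults mirror the design being emulated: two station groups
    (pre-bloom vs bloom) with triplicate samples, a feature table two
    orders of magnitude below the real survey's scale, and a planted
    two-fold pathway effect.
    """

    n_features: int = 200
    n_samples_per_group: int = 3
    groups: tuple[str, str] = ("pre_bloom", "bloom")
    n_md: int = 20
    n_pathways: int = 10
    effect_log2fc: float = 1.0
    frac_affected: float = 1.0
    noise_sigma: float = 0.2
    mass_range: tuple[float, float] = (100.0, 800.0)
    tolerance: float = 0.001
    seed: int = 0
    decoy_fraction: float = 0.3
    n_affected_pathways: int = 1
    n_formulas: int = 80

    def __post_init__(self) -> None:
        for name in ("n_features", "n_samples_per_group", "n_md", "n_pathways", "n_formulas"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.frac_affected <= 1.0:
            raise ValueError("frac_affected must lie in [0, 1]")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be > 0")
        if not self.mass_range[0] < self.mass_range[1]:
            raise ValueError("mass_range lower bound must be below upper bound")
        if not 0.0 <= self.decoy_fraction < 1.0:
            raise ValueError("decoy_fraction must lie in [0, 1)")
        if len(self.groups) != 2:
            raise ValueError("exactly two groups (pre-bloom, bloom) are supported")


@dataclass
class GroundTruth:
    """What was planted: which pathways, in which direction, via which features."""

    affected_pathways: set[str] = field(default_factory=set)
    direction: dict[str, str] = field(default_factory=dict)  # pathway -> up/down
    affected_features: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "affected_pathways": sorted(self.affected_pathways),
            "direction": dict(sorted(self.direction.items())),
            "affected_features": sorted(self.affected_features),
        }


# ---------------------------------------------------------------------------
# formula universe and mass-difference list
# ---------------------------------------------------------------------------

_HETERO = ("N", "O", "P", "S", "Cl")


def gen_formula_universe(
    n: int, seed: int, mass_range: tuple[float, float] = (100.0, 800.0)
) -> list[Formula]:
    """Draw ``n`` distinct, chemically plausible CHNOPS(Cl) formulas.

    Plausibility constraints: H <= 2C + 2 and total heteroatom count <= C,
    the coarse rules that hold for the vast majority of dissolved organic
    matter assignments.  Deterministic given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[Formula] = []
    seen: set[Formula] = set()
    for _ in range(n * 2000):
        if len(out) >= n:
            break
        c = int(rng.integers(4, 40))
        h = int(rng.integers(max(2, c // 2), 2 * c + 3))
        counts = {"C": c, "H": h}
        budget = c
        for el, hi in (("O", 18), ("N", 4), ("S", 2), ("P", 2), ("Cl", 2)):
            k = int(rng.integers(0, min(hi, budget) + 1))
            counts[el] = k
            budget -= k
        f = Formula(counts)
        m = f.monoisotopic_mass
        if mass_range[0] <= m <= mass_range[1] and f not in seen:
            seen.add(f)
            out.append(f)
    if len(out) < n:
        raise ValueError(f"could not generate {n} formulas in mass range {mass_range}")
    return out


def gen_md_list(
    formulas: Sequence[Formula],
    n_md: int,
    n_pathways: int,
    seed: int,
    min_gap: float = 0.02,
    delta_range: tuple[float, float] = (1.0, 200.0),
) -> tuple[MassDifferenceList, list[GeneSet], dict[str, str]]:
    """Derive an annotated MD list from substrate->product formula pairs.

    Each entry's delta mass and signed delta formula come from an actual
    pair in the universe (product minus substrate); chosen deltas are kept
    at least ``min_gap`` Da apart so a sane matching tolerance exists.
    Annotation ids are partitioned (with overlap) into ``n_pathways`` gene
    sets, and pathways are folded into broader classes in the merge map.
    """
    if n_md < 1:
        raise ValueError("n_md must be >= 1")
    rng = np.random.default_rng(seed)
    pairs: list[tuple[float, Formula]] = []
    for i in range(len(formulas)):
        for j in range(len(formulas)):
            if i == j:
                continue
            delta = formulas[j] - formulas[i]
            dm = delta.monoisotopic_mass
            if delta_range[0] <= dm <= delta_range[1]:
                pairs.append((dm, delta))
    if not pairs:
        raise ValueError("formula universe yields no usable substrate-product pairs")
    order = rng.permutation(len(pairs))
    chosen: list[tuple[float, Formula]] = []
    taken: list[float] = []
    for idx in order:
        dm, delta = pairs[idx]
        if all(abs(dm - t) >= min_gap for t in taken):
            chosen.append((dm, delta))
            taken.append(dm)
            if len(chosen) == n_md:
                break
    if len(chosen) < n_md:
        raise ValueError(
            f"only {len(chosen)} distinct mass differences available, {n_md} requested"
        )
    chosen.sort(key=lambda t: t[0])

    n_ann = max(n_md, int(np.ceil(n_md * 1.5)))
    ann_pool = [f"ENZ{i:04d}" for i in range(1, n_ann + 1)]
    entries = []
    for k, (dm, delta) in enumerate(chosen):
        size = int(rng.integers(1, 4))
        anns = rng.choice(n_ann, size=size, replace=False)
        entries.append(
            MassDifference(
                md_id=f"MD{k + 1:03d}",
                delta_mass=round(dm, 6),
                delta_formula=delta,
                annotations=frozenset(ann_pool[a] for a in anns),
            )
        )
    md_list = MassDifferenceList(entries)

    # every annotation gets a home pathway, then pathways gain extra members
    pw_ids = [f"PW{i:02d}" for i in range(1, n_pathways + 1)]
    members: dict[str, set[str]] = {p: set() for p in pw_ids}
    for a, ann in enumerate(ann_pool):
        members[pw_ids[int(rng.integers(0, n_pathways))]].add(ann)
    for p in pw_ids:
        extra = int(rng.integers(0, max(1, n_ann // n_pathways)))
        for a in rng.choice(n_ann, size=extra, replace=False):
            members[p].add(ann_pool[a])
        if not members[p]:
            members[p].add(ann_pool[int(rng.integers(0, n_ann))])
    n_classes = max(1, int(np.ceil(n_pathways / 3)))
    merge_map = {p: f"CL{(i % n_classes) + 1:02d}" for i, p in enumerate(pw_ids)}
    gene_sets = [
        GeneSet(set_id=p, members=frozenset(members[p]), class_id=merge_map[p])
        for p in pw_ids
    ]
    return md_list, gene_sets, merge_map


# ---------------------------------------------------------------------------
# feature table with planted pathway effects
# ---------------------------------------------------------------------------


def gen_feature_table(
    config: SimulationConfig,
    md_list: MassDifferenceList,
    gene_sets: Sequence[GeneSet] | None = None,
) -> tuple[FeatureTable, GroundTruth]:
    """Generate masses linked by listed MDs, log-normal intensities, and
    planted pathway effects in the bloom group.

    Connected features are laid down as random chains whose consecutive
    masses differ by randomly drawn MD deltas; a ``decoy_fraction`` of
    features gets masses matching no listed delta.  With a non-zero
    ``effect_log2fc``, ``n_affected_pathways`` pathways are picked and
    ``frac_affected`` of the features incident to their annotated edges are
    shifted by 2**effect_log2fc (direction alternating up/down across the
    picked pathways) in every bloom-group sample.
    """
    deltas = np.sort(md_list.delta_masses)
    gaps = np.diff(deltas)
    if gaps.size and config.tolerance >= gaps.min():
        raise ConfigConflictError(
            f"tolerance {config.tolerance} is not below the smallest MD gap {gaps.min():.6f}"
        )
    rng = np.random.default_rng(config.seed)
    lo, hi = config.mass_range
    n_connected = max(2, int(round(config.n_features * (1.0 - config.decoy_fraction))))
    masses: list[float] = []
    while len(masses) < n_connected:
        current = float(rng.uniform(lo, hi - deltas.max()))
        masses.append(current)
        for _ in range(int(rng.integers(2, 8))):
            if len(masses) >= n_connected:
                break
            current += float(deltas[rng.integers(0, len(deltas))])
            if current > hi:
                break
            masses.append(current)
    # decoys: masses whose gap to every existing mass matches no listed delta
    while len(masses) < config.n_features:
        for _ in range(50):
            cand = float(rng.uniform(lo, hi))
            arr = np.asarray(masses)
            gaps_to = np.abs(np.abs(arr - cand)[:, None] - deltas[None, :])
            if (gaps_to > 2 * config.tolerance).all():
                break
        masses.append(cand)
    masses_arr = np.array(masses[: config.n_features])
    ids = [f"F{i + 1:05d}" for i in range(len(masses_arr))]

    sample_ids = [
        f"{g}_{i + 1}" for g in config.groups for i in range(config.n_samples_per_group)
    ]
    bloom_cols = [s for s in sample_ids if s.startswith(config.groups[1])]

    base_log10 = rng.normal(6.0, 0.5, size=len(ids))
    depth = rng.uniform(0.8, 1.25, size=len(sample_ids))
    noise = rng.normal(0.0, config.noise_sigma, size=(len(ids), len(sample_ids)))
    log10_int = base_log10[:, None] + noise
    intensities = pd.DataFrame(
        depth[None, :] * 10.0**log10_int, index=ids, columns=sample_ids
    )

    gt = GroundTruth()
    if config.effect_log2fc != 0.0 and config.frac_affected > 0.0 and gene_sets:
        table_tmp = FeatureTable(pd.Series(masses_arr, index=ids), intensities)
        net = build_mdin(table_tmp, md_list, config.tolerance)
        eligible = []
        for gs in gene_sets:
            c = edge_annotation_counts(net, gs.members)
            if c.sum() > 0:
                eligible.append((gs, c))
        # plant on the best network-supported pathways: an effect on a pathway
        # with a handful of annotated edges is a degenerate study design
        eligible.sort(key=lambda t: (-int((t[1] > 0).sum()), t[0].set_id))
        picked = eligible[: config.n_affected_pathways]
        if len(picked) < config.n_affected_pathways:
            logger.warning("only %d pathway(s) have annotated edges", len(picked))
        for rank, (gs, c) in enumerate(picked):
            hit = c > 0
            incident = sorted(
                {net.edges[i].source for i in np.flatnonzero(hit)}
                | {net.edges[i].target for i in np.flatnonzero(hit)}
            )
            n_pick = max(1, int(np.ceil(config.frac_affected * len(incident))))
            sel = sorted(rng.choice(len(incident), size=n_pick, replace=False))
            chosen = [incident[i] for i in sel]
            direction = "up" if rank % 2 == 0 else "down"
            factor = 2.0 ** (config.effect_log2fc if direction == "up" else -config.effect_log2fc)
            intensities.loc[chosen, bloom_cols] *= factor
            gt.affected_pathways.add(gs.set_id)
            gt.direction[gs.set_id] = direction
            gt.affected_features.update(chosen)

    table = FeatureTable(pd.Series(masses_arr, index=ids, name="mass_da"), intensities)
    return table, gt


# ---------------------------------------------------------------------------
# expression + environment
# ---------------------------------------------------------------------------

_ENV_RANGES = {
    "temperature": (4.0, 10.0),
    "salinity": (30.0, 35.0),
    "longitude": (18.0, 26.0),
    "sio4": (0.5, 6.0),
    "np_ratio": (2.0, 25.0),
}


@dataclass
class ExpressionSimulation:
    expr: pd.DataFrame  # genes x stations, TPM (columns sum to 1e6)
    env: pd.DataFrame  # stations x parameters
    annotations: dict[str, set[str]]  # gene -> pathway ids
    planted_genes: list[str]
    parameter: str
    planted_corr: float


def gen_expression_dataset(
    n_genes: int,
    n_stations: int,
    env_params: Sequence[str] = ("np_ratio", "salinity", "longitude", "sio4"),
    planted_corr: float = 0.9,
    seed: int = 0,
    n_planted: int | None = None,
    n_pathways: int = 12,
) -> ExpressionSimulation:
    """TPM matrix and station covariates with a planted expression-environment
    correlation.

    A designated gene subset is generated on the fourth-root scale as
    rho * z(env) + sqrt(1 - rho^2) * noise against the first listed
    parameter; columns are normalised to sum to exactly 1e6 (TPM).  Genes
    carry KEGG-pathway-style annotations for downstream enrichment.
    """
    if abs(planted_corr) > 1:
        raise ValueError("|planted_corr| must be <= 1")
    if n_stations < 4:
        raise ValueError("need at least 4 stations")
    rng = np.random.default_rng(seed)
    stations = [f"St{i + 1:02d}" for i in range(n_stations)]
    env = pd.DataFrame(
        {
            p: rng.uniform(*_ENV_RANGES.get(p, (0.0, 10.0)), size=n_stations)
            for p in env_params
        },
        index=pd.Index(stations, name="station"),
    )
    target = env_params[0]
    ez = env[target].to_numpy()
    ez = (ez - ez.mean()) / ez.std(ddof=1)

    if n_planted is None:
        n_planted = max(5, n_genes // 20)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    planted = genes[:n_planted]
    mu = rng.uniform(2.0, 6.0, size=n_genes)
    eps = rng.standard_normal((n_genes, n_stations))
    signal = np.tile(ez, (n_genes, 1))
    rho = planted_corr
    mix = eps.copy()
    mix[:n_planted] = rho * signal[:n_planted] + np.sqrt(max(0.0, 1 - rho**2)) * eps[:n_planted]
    q = np.clip(mu[:, None] + 0.8 * mix, 0.05, None)  # fourth-root scale
    raw = q**4
    tpm = raw / raw.sum(axis=0, keepdims=True) * 1e6
    expr = pd.DataFrame(tpm, index=genes, columns=stations)

    pw_ids = [f"ko{i + 1:05d}" for i in range(n_pathways)]
    annotations: dict[str, set[str]] = {}
    for g in genes:
        if rng.random() < 0.8:
            k = int(rng.integers(1, 3))
            annotations[g] = {pw_ids[i] for i in rng.choice(n_pathways, size=k, replace=False)}
        else:
            annotations[g] = set()
    return ExpressionSimulation(
        expr=expr,
        env=env,
        annotations=annotations,
        planted_genes=list(planted),
        parameter=target,
        planted_corr=planted_corr,
    )


# ---------------------------------------------------------------------------
# one-call study bundle
# ---------------------------------------------------------------------------


@dataclass
class StudyBundle:
    config: SimulationConfig
    formulas: list[Formula]
    md_list: MassDifferenceList
    gene_sets: list[GeneSet]
    merge_map: dict[str, str]
    features: FeatureTable
    ground_truth: GroundTruth
    grouping: dict[str, str]


def simulate_study(config: SimulationConfig) -> StudyBundle:
    """Generate a complete, internally consistent synthetic study."""
    ss = np.random.SeedSequence(config.seed)
    s_formulas, s_md = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))
    formulas = gen_formula_universe(config.n_formulas, s_formulas, config.mass_range)
    md_list, gene_sets, merge_map = gen_md_list(
        formulas, config.n_md, config.n_pathways, s_md
    )
    features, gt = gen_feature_table(config, md_list, gene_sets)
    grouping = {
        s: (config.groups[0] if s.startswith(config.groups[0]) else config.groups[1])
        for s in features.sample_ids
    }
    return StudyBundle(
        config=config,
        formulas=formulas,
        md_list=md_list,
        gene_sets=gene_sets,
        merge_map=merge_map,
        features=features,
        ground_truth=gt,
        grouping=grouping,
    )
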