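"""End-to-end pipeline: simulate / build network / project / walk / report.

Chains the stages master-MDiN construction -> edge projection -> per-sample
KS-like walks -> group residual/quadrant report, and, when expression
inputs are configured, gene-level GSVA and the PKS coexpression statistics.
Every run writes a manifest (config hash, input checksums, seed, timings)
and stamps the config hash into each output's comment header, so identical
configurations reproduce identical files.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .enrichment import (
    DegenerateSetError,
    GeneSet,
    bh_adjust,
    enrichment_scores,
    gsva_genes,
    merge_gene_sets,
    residual_max_pvalue,
    sample_walks,
)
from .expression import coexpression_clusters, env_regression, fold_enrichment, tpm_transform, zscore_frame
from .mdin import build_mdin, edge_annotation_counts, project_edges
from .synthetic import SimulationConfig, gen_expression_dataset, simulate_study

logger = logging.getLogger("mdiva")
__version__ = "0.1.0"


def setup_logging(level: int = logging.INFO) -> None:
    """Log to standard error so results on stdout never interleave with logs."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger()
    if not root.handlers:
        root.addHandler(handler)
    root.setLevel(level)


@dataclass
class PipelineConfig:
    """File paths and numeric parameters for one end-to-end run."""

    features: str = ""
    md_list: str = ""
    gene_sets: str = ""
    grouping: str = ""
    out_dir: str = "results"
    merge_map: str | None = None
    expression: str | None = None
    env_table: str | None = None
    seed_genes: str | None = None
    group_a: str = "bloom"  # the bloom side of residuals
    group_b: str = "pre_bloom"
    tolerance: float = 0.001
    tau: float = 1.0
    n_perm: int = 999
    alpha: float = 0.05
    cutoff: float = 1.0
    max_cluster: int = 1000
    p_method: str = "permutation"
    env_parameters: list[str] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        data = asdict(self)
        data.pop("out_dir")  # analysis-irrelevant: same inputs => same hash
        return mio.config_hash(data)


def _substream(seed: int, label: str) -> int:
    """Named substream of the master seed, stable across execution order
    and across processes (label hashed with sha256, not the builtin hash)."""
    import hashlib

    tag = int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "big")
    h = np.random.SeedSequence([seed, tag])
    return int(h.generate_state(1)[0] % 2**31)


def simulate_to_dir(config: SimulationConfig, out_dir: str | Path,
                    with_expression: bool = True) -> dict[str, str]:
    """Run the synthetic generator and write every pipeline input format."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = simulate_study(config)
    chash = mio.config_hash(asdict(config))
    comment = f"config_hash={chash}"
    paths = {
        "features": str(out / "features.tsv"),
        "md_list": str(out / "md_list.tsv"),
        "gene_sets": str(out / "gene_sets.gmt"),
        "merge_map": str(out / "merge_map.tsv"),
        "grouping": str(out / "grouping.csv"),
        "ground_truth": str(out / "ground_truth.json"),
    }
    mio.write_feature_table(bundle.features, paths["features"], comment)
    mio.write_md_list(bundle.md_list, paths["md_list"], comment)
    mio.write_gmt(bundle.gene_sets, paths["gene_sets"])
    mio.write_merge_map(bundle.merge_map, paths["merge_map"])
    mio.write_grouping(bundle.grouping, paths["grouping"])
    mio.write_json(bundle.ground_truth.to_dict(), paths["ground_truth"])
    if with_expression:
        sim = gen_expression_dataset(
            n_genes=300, n_stations=4 * config.n_samples_per_group,
            seed=_substream(config.seed, "expression"),
        )
        paths["expression"] = str(out / "expression.tsv")
        paths["env_table"] = str(out / "environment.csv")
        paths["seed_genes"] = str(out / "seed_genes.txt")
        mio.write_expression(sim.expr, paths["expression"], sim.annotations, comment)
        mio.write_env_table(sim.env, paths["env_table"], comment)
        with open(paths["seed_genes"], "w", encoding="utf-8", newline="\n") as fh:
            fh.writelines(g + "\n" for g in sim.planted_genes[:5])
    return paths


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run manifest (also written)."""
    t0 = time.time()
    out = Path(config.out_dir)
    required = {"features": config.features, "md_list": config.md_list,
                "gene_sets": config.gene_sets, "grouping": config.grouping}
    optional = {"merge_map": config.merge_map, "expression": config.expression,
                "env_table": config.env_table, "seed_genes": config.seed_genes}
    missing = [name for name, p in required.items() if not p or not Path(p).exists()]
    missing += [name for name, p in optional.items() if p and not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing}")
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    comment = f"config_hash={chash}"
    timings: dict[str, float] = {}

    def stage(name: str):
        logger.info("stage %s", name)
        timings[name] = time.time()
        return name

    def done(name: str) -> None:
        timings[name] = round(time.time() - timings[name], 3)
        logger.info("stage %s finished in %.2fs", name, timings[name])

    stage("read")
    features = mio.read_feature_table(config.features)
    md_list = mio.read_md_list(config.md_list)
    gene_sets = mio.read_gmt(config.gene_sets)
    grouping = mio.read_grouping(config.grouping)
    merge_map = mio.read_merge_map(config.merge_map) if config.merge_map else None
    done("read")

    stage("build_mdin")
    net = build_mdin(features, md_list, config.tolerance)
    net.provenance = chash
    mio.write_graphml(net, out / "network.graphml")
    mio.write_edge_list(net, out / "edges.tsv", comment)
    done("build_mdin")

    stage("project")
    U = project_edges(net)
    mio.write_u_matrix(U, out / "U.tsv", comment)
    done("project")

    stage("walks")
    sets = merge_gene_sets(gene_sets, merge_map) if merge_map else list(gene_sets)
    counts = {}
    degenerate: list[str] = []
    for gs in sets:
        c = edge_annotation_counts(net, gs.members)
        if c.sum() == 0 or (c == 0).sum() == 0:
            degenerate.append(gs.set_id)
            continue
        counts[gs.set_id] = c
    if degenerate:
        logger.warning("skipping %d degenerate set(s): %s", len(degenerate), degenerate)
    walks = sample_walks(U, counts, net.edge_delta_masses(), config.tau)
    es = enrichment_scores(walks)
    mio._write_frame(es.rename_axis("set_id"), out / "es.tsv", "\t", comment, "set_id")
    rows = []
    for set_id, per_sample in walks.items():
        for s, wp in per_sample.items():
            for pos, val in enumerate(wp.values, 1):
                rows.append((set_id, s, pos, val))
    walks_df = pd.DataFrame(rows, columns=["set_id", "sample_id", "position", "value"])
    mio._write_frame(walks_df.set_index("set_id"), out / "walks.tsv", "\t", comment, "set_id")
    done("walks")

    stage("residuals")
    deltas = net.edge_delta_masses()
    report = []
    for set_id, c in counts.items():
        try:
            rw = residual_max_pvalue(
                U, c, deltas, grouping, config.group_a, config.group_b,
                tau=config.tau, method=config.p_method, n_perm=config.n_perm,
                seed=_substream(config.seed, f"perm:{set_id}"), set_id=set_id,
            )
        except DegenerateSetError as err:
            logger.warning("residuals: %s", err)
            continue
        report.append((set_id, rw.quadrant if rw.quadrant else "none",
                       rw.max_deviation, float(np.max(np.abs(rw.residual))), rw.p_value))
    rep = pd.DataFrame(report, columns=["set_id", "quadrant", "max_deviation",
                                        "max_residual", "p_value"])
    rep["fdr"] = bh_adjust(rep["p_value"].to_numpy()) if len(rep) else []
    rep["p_method"] = config.p_method
    mio._write_frame(rep.set_index("set_id"), out / "residual_report.tsv", "\t", comment, "set_id")
    done("residuals")

    if config.expression:
        stage("gsva")
        expr, annotations = mio.read_expression(config.expression)
        # gene sets for GSVA come from the expression matrix's own pathway
        # annotations (one set per KEGG-style pathway id)
        pathways: dict[str, set[str]] = {}
        for anns in annotations.values():
            for a in anns:
                pathways.setdefault(a, set())
        expr_sets = [GeneSet(set_id=p, members=frozenset({p})) for p in sorted(pathways)]
        # station-level grouping for expression: reuse groups when columns match
        expr_grouping = {s: grouping[s] for s in expr.columns if s in grouping}
        kwargs = {}
        if expr_grouping:
            kwargs = dict(grouping=expr_grouping, group_a=config.group_a, group_b=config.group_b)
        table = gsva_genes(tpm_transform(expr), expr_sets, tau=config.tau,
                           annotations=annotations, **kwargs)
        mio._write_frame(table.es.rename_axis("set_id"), out / "gsva_es.tsv", "\t", comment, "set_id")
        if table.difference is not None:
            diff = table.difference.rename("es_difference").to_frame()
            mio._write_frame(diff.rename_axis("set_id"), out / "gsva_difference.tsv",
                             "\t", comment, "set_id")
        done("gsva")

    if config.expression and config.env_table:
        stage("pks")
        expr, annotations = mio.read_expression(config.expression)
        env = mio.read_env_table(config.env_table)
        tr = tpm_transform(expr)
        z = zscore_frame(tr)
        params = config.env_parameters or list(env.columns)
        reg = pd.concat([env_regression(z, env, p, config.alpha) for p in params],
                        ignore_index=True)
        mio._write_frame(reg.set_index("gene_id"), out / "regressions.tsv", "\t", comment, "gene_id")
        if config.seed_genes:
            seeds = [l.strip() for l in open(config.seed_genes, encoding="utf-8")
                     if l.strip()]
            clusters = coexpression_clusters(tr, seeds, config.cutoff, config.max_cluster)
            universe = {g for g, a in annotations.items() if a}
            pw_members: dict[str, set[str]] = {}
            for g, anns in annotations.items():
                for a in anns:
                    pw_members.setdefault(a, set()).add(g)
            crows, erows = [], []
            for seed_gene, cl in clusters.items():
                for gene, d in zip(cl.members, cl.distances):
                    crows.append((seed_gene, gene, d))
                enr = fold_enrichment(cl, pw_members, universe)
                enr.insert(0, "seed_gene", seed_gene)
                erows.append(enr)
            cdf = pd.DataFrame(crows, columns=["seed_gene", "member", "distance"])
            mio._write_frame(cdf.set_index("seed_gene"), out / "clusters.tsv", "\t",
                             comment, "seed_gene")
            if erows:
                edf = pd.concat(erows, ignore_index=True)
                mio._write_frame(edf.set_index("seed_gene"), out / "cluster_enrichment.tsv",
                                 "\t", comment, "seed_gene")
        done("pks")

    manifest = {
        "tool": "mdiva",
        "version": __version__,
        "config_hash": chash,
        "config": asdict(config),
        "seed": config.seed,
        "inputs": {name: {"path": p, "sha256": mio.sha256_file(p)}
                   for name, p in {**required, **optional}.items() if p},
        "timings_s": timings,
        "total_s": round(time.time() - t0, 3),
    }
    mio.write_json(manifest, out / "manifest.json")
    logger.info("pipeline finished in %.2fs", manifest["total_s"])
    return manifest
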