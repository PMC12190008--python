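"""Readers and writers for the pipeline's tabular exchange formats.

All tables are UTF-8, tab-separated (environment tables are CSV), POSIX
newlines, floats at six significant digits, and may begin with ``#``
comment lines carrying provenance (config hash); readers skip them.
Gene sets travel as GMT, networks as GraphML or an edge-list TSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .enrichment import GeneSet
from .formula import Formula
from .mdin import FeatureTable, MassDifference, MassDifferenceList, MDiN

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


def _write_frame(df: pd.DataFrame, path: Path, sep: str, header_comment: str | None,
                 index_label: str | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep=sep, float_format=FLOAT_FMT, index_label=index_label,
                  lineterminator="\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, set_id <tab> description <tab>
    members...  Duplicate members are deduplicated with a warning."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            set_id, desc, *members = fields
            members = [m for m in members if m]
            uniq = set(members)
            if len(uniq) != len(members):
                logger.warning("%s:%d: duplicate members in set %s deduplicated",
                               path, lineno, set_id)
            sets.append(GeneSet(set_id=set_id, members=frozenset(uniq), description=desc))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gs in sets:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.set_id}\t{gs.description or gs.class_id or '-'}\t{members}\n")


def read_merge_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV pathway -> class (header optional)."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            if lineno == 1 and fields[0].lower() in {"pathway", "pathway_id", "set_id"}:
                continue
            out[fields[0]] = fields[1]
    return out


def write_merge_map(merge_map: Mapping[str, str], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("pathway\tclass\n")
        for pw, cls in merge_map.items():
            fh.write(f"{pw}\t{cls}\n")


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------


def read_feature_table(path: str | Path) -> FeatureTable:
    """TSV with columns feature_id, mass_da, [formula], sample columns."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"feature_id": str})
    for col in ("feature_id", "mass_da"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df = df.set_index("feature_id")
    has_formula = "formula" in df.columns
    sample_cols = [c for c in df.columns if c not in ("mass_da", "formula")]
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns found")
    for col in ["mass_da", *sample_cols]:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if len(bad) or numeric.isna().any():
            row = bad[0] if len(bad) else df.index[numeric.isna()][0]
            raise ValueError(f"{path}: non-numeric value at row {row!r}, column {col!r}")
        if col == "mass_da":
            if (numeric <= 0).any():
                row = df.index[numeric <= 0][0]
                raise ValueError(f"{path}: non-positive mass at row {row!r}")
        elif (numeric < 0).any():
            row = df.index[numeric < 0][0]
            raise ValueError(f"{path}: negative intensity at row {row!r}, column {col!r}")
        df[col] = numeric
    formulas: dict[str, Formula] = {}
    if has_formula:
        for fid, text in df["formula"].items():
            if isinstance(text, str) and text and text != "-":
                formulas[fid] = Formula(text)
    return FeatureTable(df["mass_da"], df[sample_cols], formulas)


def write_feature_table(table: FeatureTable, path: str | Path,
                        header_comment: str | None = None) -> None:
    df = pd.DataFrame(index=pd.Index(table.feature_ids, name="feature_id"))
    df["mass_da"] = [f"{m:.6f}" for m in table.masses]
    df["formula"] = [str(table.formulas.get(f, "")) or "-" for f in table.feature_ids]
    for s in table.sample_ids:
        df[s] = [_fmt(v) for v in table.intensities[s]]
    _write_frame(df, Path(path), "\t", header_comment, "feature_id")


# ---------------------------------------------------------------------------
# mass-difference list
# ---------------------------------------------------------------------------


def read_md_list(path: str | Path) -> MassDifferenceList:
    """TSV with columns md_id, delta_mass_da, delta_formula, annotation_ids
    (semicolon-joined)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"md_id", "delta_mass_da", "annotation_ids"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    entries = []
    for _, row in df.iterrows():
        text = row.get("delta_formula")
        delta_formula = (
            Formula(text) if isinstance(text, str) and text and text != "-" else None
        )
        anns = row["annotation_ids"]
        annotations = frozenset(a for a in str(anns).split(";") if a) if pd.notna(anns) else frozenset()
        entries.append(
            MassDifference(
                md_id=row["md_id"],
                delta_mass=float(row["delta_mass_da"]),
                delta_formula=delta_formula,
                annotations=annotations,
            )
        )
    return MassDifferenceList(entries)


def write_md_list(md_list: MassDifferenceList, path: str | Path,
                  header_comment: str | None = None) -> None:
    df = pd.DataFrame(
        {
            "md_id": [e.md_id for e in md_list],
            "delta_mass_da": [f"{e.delta_mass:.6f}" for e in md_list],
            "delta_formula": [str(e.delta_formula) if e.delta_formula else "-" for e in md_list],
            "annotation_ids": [";".join(sorted(e.annotations)) for e in md_list],
        }
    ).set_index("md_id")
    _write_frame(df, Path(path), "\t", header_comment, "md_id")


# ---------------------------------------------------------------------------
# matrices, environment, grouping
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Expression TSV: gene_id, [kegg_ids semicolon-joined], sample columns.
    Returns (genes x samples TPM frame, gene -> pathway-annotation sets)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: missing gene_id column")
    df = df.set_index("gene_id")
    annotations: dict[str, set[str]] = {}
    if "kegg_ids" in df.columns:
        for g, text in df["kegg_ids"].items():
            annotations[g] = (
                {a for a in str(text).split(";") if a}
                if isinstance(text, str) and text not in ("", "-")
                else set()
            )
        df = df.drop(columns=["kegg_ids"])
    expr = df.apply(pd.to_numeric, errors="raise").astype(float)
    if (expr.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative expression values")
    return expr, annotations


def write_expression(expr: pd.DataFrame, path: str | Path,
                     annotations: Mapping[str, Iterable[str]] | None = None,
                     header_comment: str | None = None) -> None:
    df = pd.DataFrame(index=pd.Index(expr.index, name="gene_id"))
    if annotations is not None:
        df["kegg_ids"] = [";".join(sorted(annotations.get(g, ()))) or "-" for g in expr.index]
    for s in expr.columns:
        df[s] = [_fmt(v) for v in expr[s]]
    _write_frame(df, Path(path), "\t", header_comment, "gene_id")


def read_env_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if "station" not in df.columns:
        raise ValueError(f"{path}: missing station column")
    return df.set_index("station").apply(pd.to_numeric, errors="coerce")


def write_env_table(env: pd.DataFrame, path: str | Path,
                    header_comment: str | None = None) -> None:
    _write_frame(env, Path(path), ",", header_comment, "station")


def read_grouping(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, comment="#", dtype=str)
    if not {"sample_id", "group"} <= set(df.columns):
        raise ValueError(f"{path}: need sample_id and group columns")
    return dict(zip(df["sample_id"], df["group"]))


def write_grouping(grouping: Mapping[str, str], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id,group\n")
        for s, g in grouping.items():
            fh.write(f"{s},{g}\n")


def read_u_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="edge_id")
    return df.astype(float)


def write_u_matrix(U: pd.DataFrame, path: str | Path,
                   header_comment: str | None = None) -> None:
    _write_frame(U.rename_axis("edge_id"), Path(path), "\t", header_comment, "edge_id")


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------


def write_edge_list(net: MDiN, path: str | Path, header_comment: str | None = None) -> None:
    deltas = net.edge_delta_masses()
    df = pd.DataFrame(
        {
            "source": [e.source for e in net.edges],
            "target": [e.target for e in net.edges],
            "md_id": [e.md_id for e in net.edges],
            "delta_mass_da": [f"{d:.6f}" for d in deltas],
        }
    )
    _write_frame(df.set_index("source"), Path(path), "\t", header_comment, "source")


def write_graphml(net: MDiN, path: str | Path) -> None:
    import networkx as nx

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(net.to_networkx(), path)


# ---------------------------------------------------------------------------
# JSON helpers
# ---------------------------------------------------------------------------


def write_json(obj, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
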