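"""Readers and writers for the pipeline's external formats.

Formats handled here:

* STRING-style edge-list TSV (``protein1  protein2  combined_score``), with
  automatic detection of the score dialect: integer scores in [0, 1000] are
  divided by 1000, floats in [0, 1] are taken as-is.
* Expression matrix TSV (genes in rows, samples in columns, log2 scale) with
  a sample-metadata TSV (columns ``sample``, ``organ``, ``treatment`` and an
  optional ``batch``).
* GMT gene-set collections (``name<TAB>description<TAB>member...``).
* Stage outputs: regulatory modules as node/edge TSV pairs plus a JSON
  summary, cluster partitions, cluster-expression profiles, centrality and
  enrichment tables, and the CRN edge-frequency long table.  Every writer has
  a matching reader and the pair round-trips exactly (IDs verbatim, floats to
  full ``repr`` precision).
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import TYPE_CHECKING

import pandas as pd

from .network import InteractionNetwork, canonical_edge

if TYPE_CHECKING:  # pragma: no cover
    from .modisco import RegulatoryModule

logger = logging.getLogger(__name__)

__all__ = [
    "read_network",
    "read_expression",
    "read_gmt",
    "write_gmt",
    "write_module",
    "read_module",
    "write_partition",
    "read_partition",
    "write_matrix",
    "read_matrix",
    "write_crn",
    "read_crn",
    "write_results",
]


# ---------------------------------------------------------------------------
# network edge list
# ---------------------------------------------------------------------------

def read_network(path: str | Path, score_threshold: float = 0.7) -> InteractionNetwork:
    """Read a STRING-dialect edge-list TSV, keeping edges with score >= threshold.

    Score dialect is auto-detected over the whole file: if any score parses
    as a number > 1, all scores must be integers in [0, 1000] (STRING flat
    file convention) and are divided by 1000; otherwise all scores must
    already lie in [0, 1].  Mixing the two dialects is an error.  Duplicate
    unordered pairs are merged keeping the maximum score; self-loops are
    dropped (their node is retained).
    """
    path = Path(path)
    records: list[tuple[int, str, str, float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns, got {len(fields)}")
            u, v, score_str = fields[0].strip(), fields[1].strip(), fields[2].strip()
            try:
                score = float(score_str)
            except ValueError:
                if lineno == 1:  # header line: third column not numeric
                    continue
                raise ValueError(f"{path}:{lineno}: malformed score {score_str!r}") from None
            if not u or not v:
                raise ValueError(f"{path}:{lineno}: empty node identifier")
            if score < 0:
                raise ValueError(f"{path}:{lineno}: negative score {score}")
            records.append((lineno, u, v, score))

    string_dialect = any(s > 1.0 for _, _, _, s in records)
    if string_dialect:
        for lineno, _, _, s in records:
            if s != int(s) or s > 1000:
                raise ValueError(
                    f"{path}:{lineno}: mixed score dialects — file contains scores > 1 "
                    f"(0-1000 integer dialect) but score {s} is not an integer in [0, 1000]"
                )

    n_self, n_dup = 0, 0
    merged: dict[tuple[str, str], float] = {}
    nodes: set[str] = set()
    for _, u, v, s in records:
        if string_dialect:
            s /= 1000.0
        nodes.update((u, v))
        if u == v:
            n_self += 1
            continue
        key = canonical_edge(u, v)
        if key in merged:
            n_dup += 1
            merged[key] = max(merged[key], s)
        else:
            merged[key] = s

    kept = {e: s for e, s in merged.items() if s >= score_threshold}
    n_filtered = len(merged) - len(kept)
    logger.info(
        "read_network(%s): %d records, %d self-loops dropped, %d duplicates merged, "
        "%d edges below threshold %.3g dropped, %d nodes / %d edges retained",
        path, len(records), n_self, n_dup, n_filtered, score_threshold, len(nodes), len(kept),
    )
    return InteractionNetwork.from_scored_edges(kept, extra_nodes=nodes)


def write_network(net: InteractionNetwork, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\t{net.score(u, v)!r}\n")


# ---------------------------------------------------------------------------
# expression + metadata
# ---------------------------------------------------------------------------

def read_expression(
    matrix_path: str | Path, metadata_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a genes-by-samples log2 expression TSV and its sample metadata.

    Returns ``(expr, meta)`` where ``expr`` is a float DataFrame (genes in
    rows) and ``meta`` is indexed by sample in the matrix's column order with
    columns ``organ`` and ``treatment`` (plus ``batch`` if present).  Samples
    present in the matrix but missing from the metadata are an error; extra
    metadata rows are dropped with a warning.
    """
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    if raw.index.duplicated().any():
        dupes = sorted(raw.index[raw.index.duplicated()].unique())
        raise ValueError(f"duplicated gene ID(s) in {matrix_path}: {dupes}")
    if raw.columns.duplicated().any():
        raise ValueError(f"duplicated sample ID(s) in {matrix_path}")
    expr = raw.apply(pd.to_numeric, errors="coerce")
    if expr.isna().any().any():
        bad = expr.stack(future_stack=True)
        bad = bad[bad.isna()]
        gene, sample = bad.index[0]
        raise ValueError(
            f"non-numeric expression value at gene {gene!r}, sample {sample!r} "
            f"in {matrix_path}"
        )
    expr = expr.astype(float)
    expr.index.name = None
    expr.columns.name = None

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"sample", "organ", "treatment"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata {metadata_path} must have columns {sorted(required)}")
    if meta["sample"].duplicated().any():
        raise ValueError(f"duplicated sample ID(s) in metadata {metadata_path}")
    meta = meta.set_index("sample")

    missing = [s for s in expr.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples in matrix missing from metadata: {missing}")
    extra = [s for s in meta.index if s not in expr.columns]
    if extra:
        warnings.warn(f"metadata rows without matrix column dropped: {extra}")
    meta = meta.loc[list(expr.columns)]
    logger.info(
        "read_expression: %d genes x %d samples, organs=%s",
        expr.shape[0], expr.shape[1], sorted(meta["organ"].unique()),
    )
    return expr, meta


def write_expression(
    expr: pd.DataFrame, meta: pd.DataFrame, matrix_path: str | Path, metadata_path: str | Path
) -> None:
    _write_float_frame(expr, matrix_path, index_label="gene")
    meta.to_csv(metadata_path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file into ``{set name: member set}`` (descriptions dropped)."""
    sets: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
            name, members = fields[0], set(fields[2:]) - {""}
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not members:
                raise ValueError(f"{path}:{lineno}: empty gene set {name!r}")
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with Path(path).open("w") as fh:
        for name in sorted(sets):
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(sets[name])]) + "\n")


# ---------------------------------------------------------------------------
# stage outputs
# ---------------------------------------------------------------------------

def _write_float_frame(df: pd.DataFrame, path: str | Path, index_label: str) -> None:
    # str(float) == repr in py3 -> round-trips exactly through float()
    df.to_csv(path, sep="\t", index_label=index_label)


def write_module(module: "RegulatoryModule", prefix: str | Path) -> None:
    """Write a module as ``<prefix>.nodes.tsv``, ``<prefix>.edges.tsv``,
    ``<prefix>.json`` (counts, stability, parameters)."""
    prefix = Path(prefix)
    with open(f"{prefix}.nodes.tsv", "w") as fh:
        fh.write("protein\n")
        for n in sorted(module.nodes):
            fh.write(n + "\n")
    with open(f"{prefix}.edges.tsv", "w") as fh:
        fh.write("protein1\tprotein2\n")
        for u, v in sorted(module.edges):
            fh.write(f"{u}\t{v}\n")
    summary = {
        "organ": module.organ,
        "n_nodes": len(module.nodes),
        "n_edges": len(module.edges),
        "n_significant_cliques": module.n_significant_cliques,
        "node_stability": module.node_stability,
        "edge_stability": module.edge_stability,
    }
    with open(f"{prefix}.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_module(prefix: str | Path) -> "RegulatoryModule":
    from .modisco import RegulatoryModule

    prefix = Path(prefix)
    nodes = pd.read_csv(f"{prefix}.nodes.tsv", sep="\t", dtype=str)
    edges = pd.read_csv(f"{prefix}.edges.tsv", sep="\t", dtype=str)
    with open(f"{prefix}.json") as fh:
        summary = json.load(fh)
    return RegulatoryModule(
        nodes=frozenset(nodes["protein"]) if len(nodes) else frozenset(),
        edges=frozenset(
            canonical_edge(u, v) for u, v in zip(edges["protein1"], edges["protein2"])
        ),
        organ=summary["organ"],
        n_significant_cliques=summary["n_significant_cliques"],
        node_stability=summary["node_stability"],
        edge_stability=summary["edge_stability"],
    )


def write_partition(clusters: dict[int, frozenset[str]], path: str | Path) -> None:
    """Two-column TSV (protein, cluster), proteins sorted within cluster."""
    with Path(path).open("w") as fh:
        fh.write("protein\tcluster\n")
        for cid in sorted(clusters):
            for n in sorted(clusters[cid]):
                fh.write(f"{n}\t{cid}\n")


def read_partition(path: str | Path) -> dict[int, frozenset[str]]:
    df = pd.read_csv(path, sep="\t", dtype={"protein": str, "cluster": int})
    return {
        int(cid): frozenset(sub["protein"]) for cid, sub in df.groupby("cluster")
    }


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    _write_float_frame(df, path, index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip").astype(float)


def write_crn(freq: pd.DataFrame, path: str | Path) -> None:
    """CRN edge frequencies as a long-format TSV (source, target_cluster, frequency).

    The undefined diagonal (cluster i -> cluster i) is omitted.
    """
    with Path(path).open("w") as fh:
        fh.write("source\ttarget_cluster\tfrequency\n")
        for src in freq.index:
            for tgt in freq.columns:
                val = freq.loc[src, tgt]
                if pd.isna(val):
                    continue
                fh.write(f"{src}\t{tgt}\t{float(val)!r}\n")


def read_crn(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype={"source": str, "target_cluster": str}, float_precision="round_trip"
    )
    wide = df.pivot(index="source", columns="target_cluster", values="frequency")
    wide.index.name = None
    wide.columns.name = None
    return wide


def write_results(out_dir: str | Path, **artifacts) -> None:
    """Write any completed stage outputs into ``out_dir``.

    Recognised keyword artifacts: ``modules`` (mapping organ -> RegulatoryModule),
    ``partition`` (dict cluster -> member set), ``cluster_expression`` /
    ``cluster_expression_scaled`` (DataFrame), ``centrality`` (DataFrame),
    ``enrichment`` (DataFrame), ``crn`` (frequency DataFrame), ``degs``
    (mapping organ -> DataFrame), ``summary`` (JSON-serialisable dict).
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc

    if "modules" in artifacts:
        for organ, module in artifacts["modules"].items():
            write_module(module, out / f"module_{organ}")
    if "degs" in artifacts:
        for organ, table in artifacts["degs"].items():
            _write_float_frame(table, out / f"degs_{organ}.tsv", index_label="gene")
    if "partition" in artifacts:
        write_partition(artifacts["partition"], out / "clusters.tsv")
    if "cluster_expression" in artifacts:
        write_matrix(artifacts["cluster_expression"], out / "cluster_expression.tsv", "cluster")
    if "cluster_expression_scaled" in artifacts:
        write_matrix(
            artifacts["cluster_expression_scaled"], out / "cluster_expression_scaled.tsv", "cluster"
        )
    if "centrality" in artifacts:
        artifacts["centrality"].to_csv(out / "centrality.tsv", sep="\t", index=False)
    if "enrichment" in artifacts:
        artifacts["enrichment"].to_csv(out / "enrichment.tsv", sep="\t", index=False)
    if "crn" in artifacts:
        write_crn(artifacts["crn"], out / "crn.tsv")
    if "summary" in artifacts:
        with (out / "summary.json").open("w") as fh:
            json.dump(artifacts["summary"], fh, indent=2, sort_keys=True)
            fh.write("\n")
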