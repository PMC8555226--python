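"""Readers and writers for the network and annotation formats the analysis touches.

Networks are normalised to simple undirected :class:`networkx.Graph` objects
with opaque string-compatible node identifiers: self-loops are dropped (and
counted), duplicate edges — including the mirrored A–B / B–A orientations of
STRING ``protein.links`` files — are collapsed to a single undirected edge.

Per-node annotations (target status, target class, citation and
disease-association counts, GO/domain tokens) are carried as a pandas
DataFrame indexed by node id, one row per graph node.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: allowed target statuses: targets of selective approved drugs ("phase4"),
#: exploratory bioactivity targets ("all_target"), everything else ("other")
TARGET_STATUSES = ("phase4", "all_target", "other")

#: broad functional target classes
TARGET_CLASSES = (
    "channel_transporter",
    "enzyme",
    "gpcr",
    "kinase",
    "nuclear_receptor",
    "other",
)

ANNOTATION_COLUMNS = (
    "target_status",
    "target_class",
    "citations",
    "disease_associations",
    "go_terms",
    "domains",
)


def _finalize(graph: nx.Graph, n_self_loops: int, drop_isolated: bool = True) -> nx.Graph:
    if n_self_loops:
        logger.info("dropped %d self-loop(s)", n_self_loops)
    if drop_isolated:
        isolated = [n for n, d in graph.degree() if d == 0]
        if isolated:
            logger.info("dropped %d isolated node(s)", len(isolated))
            graph.remove_nodes_from(isolated)
    return graph


def read_string_links(path: str | Path, score_cutoff: float) -> nx.Graph:
    """Read a STRING ``protein.links`` style file into a simple graph.

    Each line holds two node ids and an integer combined score in [0, 1000];
    every association appears in both orientations.  Edges are kept when
    ``score > 1000 * score_cutoff`` (strict inequality, the same filter as
    ``awk '($3 > 700)'`` at cutoff 0.7).  A single header line is tolerated.
    """
    if not 0.0 <= score_cutoff <= 1.0:
        raise ValueError(f"score_cutoff must be in [0, 1], got {score_cutoff}")
    threshold = 1000.0 * score_cutoff
    graph = nx.Graph()
    n_self = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 columns, got {len(fields)}")
            try:
                score = int(fields[2])
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise ValueError(
                    f"{path}: line {lineno}: non-integer score {fields[2]!r}"
                ) from None
            if not 0 <= score <= 1000:
                raise ValueError(f"{path}: line {lineno}: score {score} outside [0, 1000]")
            if score <= threshold:
                continue
            a, b = fields[0], fields[1]
            if a == b:
                n_self += 1
                continue
            graph.add_edge(a, b)
    return _finalize(graph, n_self)


def read_edge_list(path: str | Path, dialect: str = "tsv2col") -> nx.Graph:
    """Read a SIF (``node relation node ...``) or 2-column TSV edge list."""
    if dialect not in ("sif", "tsv2col"):
        raise ValueError(f"unknown dialect {dialect!r}")
    graph = nx.Graph()
    n_self = 0
    n_dup = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            fields = line.split("\t") if "\t" in line else line.split()
            fields = [f.strip() for f in fields if f.strip()]
            if not fields:
                continue
            if dialect == "sif":
                if len(fields) < 3:
                    raise ValueError(f"{path}: line {lineno}: SIF line needs >=3 tokens")
                src, targets = fields[0], fields[2:]
            else:
                if len(fields) < 2:
                    raise ValueError(f"{path}: line {lineno}: expected 2 columns")
                src, targets = fields[0], [fields[1]]
            for tgt in targets:
                if src == tgt:
                    n_self += 1
                    graph.add_node(src)
                elif graph.has_edge(src, tgt):
                    n_dup += 1
                else:
                    graph.add_edge(src, tgt)
    if n_dup:
        logger.info("collapsed %d duplicate edge(s)", n_dup)
    return _finalize(graph, n_self, drop_isolated=False)


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Write the graph as a 2-column TSV (one undirected edge per line)."""
    with open(path, "w") as handle:
        for a, b in sorted((sorted(map(str, e)) for e in graph.edges()), key=tuple):
            handle.write(f"{a}\t{b}\n")


def empty_annotations(nodes) -> pd.DataFrame:
    """Default annotation table: status/class 'other', zero counts, empty sets."""
    idx = pd.Index([str(n) for n in nodes], name="node")
    return pd.DataFrame(
        {
            "target_status": "other",
            "target_class": "other",
            "citations": 0,
            "disease_associations": 0,
            "go_terms": [frozenset() for _ in idx],
            "domains": [frozenset() for _ in idx],
        },
        index=idx,
    )


def _parse_tokens(value) -> frozenset:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return frozenset()
    return frozenset(t for t in str(value).replace(",", "|").split("|") if t)


def read_annotations(path: str | Path, graph: nx.Graph) -> pd.DataFrame:
    """Read a per-node annotation TSV and align it with the graph's node set.

    The header must name at least ``node`` and ``target_status``; unknown
    columns are ignored.  Rows for nodes absent from the graph are counted
    and dropped; graph nodes without a row get defaults (status/class
    ``other``, zero counts, empty token sets).  Duplicate rows for a node
    with conflicting statuses raise.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    raw.columns = [c.strip().lower() for c in raw.columns]
    if "node" not in raw.columns or "target_status" not in raw.columns:
        raise ValueError(f"{path}: header must name 'node' and 'target_status' columns")
    raw["node"] = raw["node"].astype(str)
    raw["target_status"] = raw["target_status"].str.strip().str.casefold()

    dupes = raw[raw.duplicated("node", keep=False)]
    conflicting = sorted(
        node
        for node, grp in dupes.groupby("node")
        if grp["target_status"].nunique() > 1
    )
    if conflicting:
        raise ValueError(f"{path}: conflicting target_status for node(s): {', '.join(conflicting)}")
    raw = raw.drop_duplicates("node")

    graph_nodes = {str(n) for n in graph.nodes()}
    unmatched = (~raw["node"].isin(graph_nodes)).sum()
    if unmatched:
        logger.info("%d annotation row(s) did not match any graph node", unmatched)
    raw = raw[raw["node"].isin(graph_nodes)].set_index("node")

    ann = empty_annotations(graph.nodes())
    status = raw["target_status"]
    bad = sorted(set(status) - set(TARGET_STATUSES))
    if bad:
        raise ValueError(f"{path}: unknown target_status value(s): {', '.join(bad)}")
    ann.loc[status.index, "target_status"] = status
    if "target_class" in raw.columns:
        cls = raw["target_class"].str.strip().str.casefold().replace("", "other")
        bad = sorted(set(cls) - set(TARGET_CLASSES))
        if bad:
            raise ValueError(f"{path}: unknown target_class value(s): {', '.join(bad)}")
        ann.loc[cls.index, "target_class"] = cls
    for col in ("citations", "disease_associations"):
        if col in raw.columns:
            counts = pd.to_numeric(raw[col].replace("", "0"))
            if (counts < 0).any() or (counts != counts.astype(int)).any():
                raise ValueError(f"{path}: column {col} must hold nonnegative integers")
            ann.loc[counts.index, col] = counts.astype(int)
    for col in ("go_terms", "domains"):
        if col in raw.columns:
            parsed = raw[col].map(_parse_tokens)
            ann.loc[parsed.index, col] = parsed
    return ann


def write_annotations(ann: pd.DataFrame, path: str | Path) -> None:
    out = ann.copy()
    for col in ("go_terms", "domains"):
        out[col] = out[col].map(lambda s: "|".join(sorted(s)))
    out.to_csv(path, sep="\t", index=True, index_label="node")


def read_gaf(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a GAF 2.x file into ``{object id: set of GO term ids}``.

    Comment lines start with ``!``; column 2 is the object id, column 4 the
    qualifier and column 5 the GO id.  ``NOT``-qualified rows are excluded;
    rows with fewer than 15 columns are skipped with a logged count.
    """
    terms: dict[str, set[str]] = {}
    n_skipped = 0
    with open(path) as handle:
        for line in handle:
            if line.startswith("!") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 15:
                n_skipped += 1
                continue
            if "NOT" in fields[3].split("|"):
                continue
            terms.setdefault(fields[1], set()).add(fields[4])
    if n_skipped:
        logger.info("skipped %d malformed GAF row(s)", n_skipped)
    return {k: frozenset(v) for k, v in terms.items()}
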