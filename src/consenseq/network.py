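"""Interaction subnetworks over consensus candidates: STRING-dialect edge
loading, induced-subgraph construction with orphan removal, temporal
annotation, two-experiment merging, and crosstalk extraction around shared
targets with direction-concordance classification.

Temporal dynamics are carried as node attributes (first supra-threshold
timepoint, per-timepoint up/down/none segments, max |LFC|) in GraphML and
TSV exports instead of any renderer-specific styling.
"""

from __future__ import annotations

import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .preprocess import ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "load_edges",
    "build_subnetwork",
    "annotate_first_de",
    "merge_networks",
    "extract_crosstalk",
    "classify_direction",
    "classify_common_targets",
    "write_graphml",
    "write_node_table",
    "write_edge_table",
]

_COLUMN_ALIASES = {"node1": "node1", "protein1": "node1", "#node1": "node1",
                   "node2": "node2", "protein2": "node2",
                   "combined_score": "combined_score", "score": "combined_score"}


def load_edges(path, min_score: int = 400) -> pd.DataFrame:
    """Load a STRING-export edge TSV (node1/node2/combined_score, with the
    protein1/protein2 header dialect also accepted).

    Scores below ``min_score`` are dropped (400 is STRING's medium
    confidence); edges are canonicalized to undirected (sorted endpoints),
    self-loops removed, duplicates collapsed keeping the maximum score.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    df = df.rename(columns=_COLUMN_ALIASES)
    missing = {"node1", "node2", "combined_score"} - set(df.columns)
    if missing:
        raise ValidationError(f"edge table missing columns: {sorted(missing)}")
    bad = df.index[pd.to_numeric(df["combined_score"], errors="coerce").isna()].tolist()
    if bad:
        raise ValidationError(f"malformed combined_score at data rows {[i + 2 for i in bad[:5]]}")
    df["combined_score"] = df["combined_score"].astype(int)
    out_of_range = df[(df["combined_score"] < 0) | (df["combined_score"] > 1000)]
    if len(out_of_range):
        raise ValidationError(
            f"combined_score outside 0-1000 at data rows {[i + 2 for i in out_of_range.index[:5]]}")
    df = df[df["combined_score"] >= min_score]
    df = df[df["node1"] != df["node2"]]
    n1, n2 = df["node1"].astype(str), df["node2"].astype(str)
    swap = n1 > n2
    df = pd.DataFrame({"node1": n1.where(~swap, n2), "node2": n2.where(~swap, n1),
                       "combined_score": df["combined_score"]})
    df = (df.groupby(["node1", "node2"], as_index=False)["combined_score"].max()
            .sort_values(["node1", "node2"]).reset_index(drop=True))
    return df


def build_subnetwork(candidates, edges: pd.DataFrame) -> nx.Graph:
    """Induced subgraph on the candidate genes with degree-0 nodes removed.

    The fraction of candidates retained is stored as ``G.graph['coverage']``.
    """
    candidates = set(candidates)
    if not candidates:
        raise ValidationError("empty candidate set")
    g = nx.Graph()
    sel = edges[edges["node1"].isin(candidates) & edges["node2"].isin(candidates)]
    for a, b, s in sel.itertuples(index=False):
        g.add_edge(a, b, combined_score=int(s))
    if g.number_of_nodes() == 0:
        warnings.warn("no candidate pair is connected; network is empty", stacklevel=2)
    g.graph["coverage"] = g.number_of_nodes() / len(candidates)
    return g


def annotate_first_de(network: nx.Graph, lfc_table: pd.DataFrame, lam: float,
                      experiment: str | None = None) -> nx.Graph:
    """Attach temporal attributes to every node.

    ``first_de`` = earliest timepoint with |LFC| >= lam ('none' if never),
    ``dir_<t>h`` = up/down/none segments, ``max_abs_lfc``. Modifies and
    returns the graph; records the experiment label on the graph.
    """
    missing = [n for n in network.nodes if n not in lfc_table.index]
    if missing:
        raise ValidationError(f"nodes missing from LFC table: {sorted(missing)[:10]}")
    for n in network.nodes:
        prof = lfc_table.loc[n]
        first = "none"
        for t in prof.index:
            v = float(prof[t])
            network.nodes[n][f"dir_{t}h"] = ("up" if (abs(v) >= lam and v > 0)
                                             else "down" if (abs(v) >= lam and v < 0) else "none")
            if first == "none" and abs(v) >= lam:
                first = f"{int(t)}h"
        network.nodes[n]["first_de"] = first
        network.nodes[n]["max_abs_lfc"] = float(prof.abs().max())
    if experiment is not None:
        network.graph["experiment"] = experiment
        for n in network.nodes:
            network.nodes[n]["experiment"] = experiment
    return network


def merge_networks(net_a: nx.Graph, net_b: nx.Graph) -> nx.Graph:
    """Node and edge union of two annotated experiment networks.

    Shared nodes are tagged ``experiment='both'`` and keep both experiments'
    annotations under suffixed keys (e.g. ``first_de_sb``); conflicting edge
    scores resolve to the maximum (logged).
    """
    exp_a = str(net_a.graph.get("experiment", "A"))
    exp_b = str(net_b.graph.get("experiment", "B"))
    merged = nx.Graph()
    merged.graph["experiment"] = f"{exp_a}+{exp_b}"
    for net, exp in ((net_a, exp_a), (net_b, exp_b)):
        suf = exp.lower()
        for n, attrs in net.nodes(data=True):
            if n not in merged:
                merged.add_node(n)
            node = merged.nodes[n]
            node["experiment"] = "both" if node.get("experiment") not in (None, exp) else exp
            for k, v in attrs.items():
                if k == "experiment":
                    continue
                node[f"{k}_{suf}"] = v
        for a, b, attrs in net.edges(data=True):
            s = int(attrs.get("combined_score", 0))
            if merged.has_edge(a, b):
                prev = merged.edges[a, b].get("combined_score", 0)
                if prev != s:
                    log.info("edge %s-%s score conflict (%d vs %d); keeping max", a, b, prev, s)
                merged.edges[a, b]["combined_score"] = max(prev, s)
            else:
                merged.add_edge(a, b, combined_score=s)
    return merged


def extract_crosstalk(merged: nx.Graph, shared_targets) -> nx.Graph:
    """Subgraph induced on the shared targets plus their direct neighbors.

    Shared targets absent from the merged network are logged and skipped.
    An empty shared set yields an empty graph with a warning.
    """
    shared = set(shared_targets)
    missing = sorted(shared - set(merged.nodes))
    if missing:
        log.warning("shared targets absent from merged network, skipped: %s", missing[:10])
    present = shared & set(merged.nodes)
    if not present:
        warnings.warn("no shared targets present; crosstalk network is empty", stacklevel=2)
        out = nx.Graph()
        out.graph.update(merged.graph)
        return out
    keep = set(present)
    for s in present:
        keep.update(merged.neighbors(s))
    out = merged.subgraph(keep).copy()
    for n in out.nodes:
        out.nodes[n]["shared_target"] = n in present
    return out


def classify_direction(lfc_a: pd.Series, lfc_b: pd.Series,
                       lam_a: float = 0.0, lam_b: float = 0.0) -> str:
    """Concordance of a common target between two experiments.

    Each experiment contributes the sign of its LFC at the timepoint of
    maximum |LFC|; if either side stays below its threshold the call is
    ``indeterminate``, equal signs are ``synergistic``, opposite signs
    ``antagonistic``.
    """
    va = float(lfc_a.loc[lfc_a.abs().idxmax()])
    vb = float(lfc_b.loc[lfc_b.abs().idxmax()])
    if abs(va) < lam_a or abs(vb) < lam_b or va == 0 or vb == 0:
        return "indeterminate"
    return "synergistic" if np.sign(va) == np.sign(vb) else "antagonistic"


def classify_common_targets(common_genes, lfc_a: pd.DataFrame, lfc_b: pd.DataFrame,
                            lam_a: float, lam_b: float,
                            labels: tuple[str, str] = ("SB", "SU")) -> pd.DataFrame:
    rows = []
    for g in sorted(common_genes):
        cls = classify_direction(lfc_a.loc[g], lfc_b.loc[g], lam_a, lam_b)
        rows.append({"gene_id": g, "classification": cls,
                     f"max_lfc_{labels[0]}": float(lfc_a.loc[g].abs().max()),
                     f"max_lfc_{labels[1]}": float(lfc_b.loc[g].abs().max())})
    return pd.DataFrame(rows, columns=["gene_id", "classification",
                                       f"max_lfc_{labels[0]}", f"max_lfc_{labels[1]}"])


def _ordered_copy(g: nx.Graph) -> nx.Graph:
    out = nx.Graph()
    out.graph.update(sorted(g.graph.items()))
    for n in sorted(g.nodes):
        out.add_node(n, **{k: g.nodes[n][k] for k in sorted(g.nodes[n])})
    for a, b in sorted(tuple(sorted(e)) for e in g.edges):
        out.add_edge(a, b, **{k: g.edges[a, b][k] for k in sorted(g.edges[a, b])})
    return out


def write_graphml(g: nx.Graph, path) -> None:
    """GraphML export with stable node/edge/attribute ordering, so identical
    inputs produce byte-identical files."""
    nx.write_graphml(_ordered_copy(g), path)


def write_node_table(g: nx.Graph, path) -> None:
    rows = [{"gene_id": n, **g.nodes[n]} for n in sorted(g.nodes)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_edge_table(g: nx.Graph, path) -> None:
    rows = [{"node1": a, "node2": b, **g.edges[a, b]}
            for a, b in sorted(tuple(sorted(e)) for e in g.edges)]
    pd.DataFrame(rows, columns=["node1", "node2", "combined_score"]).to_csv(path, sep="\t", index=False)
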