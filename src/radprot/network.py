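"""Protein–protein interaction network analysis for differential proteins.

Per dose group a network is built as the induced subgraph of a merged
interactome on the union (across groups) of differentially regulated
proteins, with node attributes carrying *this* group's log2 fold change.
Nodes are classed up-/down-/un-regulated at |log2FC| strictly greater than
0.263 (= log2 of the 1.2 fold-change cutoff).  The giant connected component
(GCC) is scored for size significance against a permutation null that
resamples node sets of equal size uniformly from the interactome; the hub
score of a node is log2FC × Degree, and node size for visual export is
(DC + 1) × (|log2FC| + 1).
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LOG2FC_CUT_DEFAULT = 0.263  # log2(1.2) to three decimals, the printed cutoff


@dataclass(frozen=True)
class GccSignificance:
    """Observed GCC size against a resampling null."""

    observed_gcc: int
    null_mean: float
    null_sd: float
    z: float
    empirical_p: float
    n_permutations: int
    seed: int

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# interactome loading


def _parse_mitab_line(fields: list[str]) -> tuple[str, str, str, str] | None:
    def clean(ident: str) -> str:
        ident = ident.split("|")[0]
        return ident.split(":", 1)[1] if ":" in ident else ident

    a, b = clean(fields[0]), clean(fields[1])
    if not a or not b:
        return None
    source = "unknown"
    if len(fields) > 12 and fields[12]:
        m = re.search(r"\(([^)]+)\)", fields[12])
        source = m.group(1) if m else fields[12]
    evidence = "physical"
    if len(fields) > 11 and fields[11]:
        low = fields[11].lower()
        if "complex" in low or "association" in low:
            evidence = "complex"
        elif "phospho" in low or "kinase" in low:
            evidence = "kinase-substrate"
    return a, b, source, evidence


def load_interactome(paths: Sequence[str | Path]) -> nx.Graph:
    """Merge edge-list TSV and/or minimal PSI-MITAB files into one simple
    undirected graph.

    Self-loops are dropped, duplicate unordered pairs are merged with their
    source labels unioned (';'-joined, sorted).  Malformed lines are logged
    and skipped; an empty merged edge set is an error.
    """
    graph = nx.Graph()
    n_skipped = 0
    for path in paths:
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n")
            cols = header.split("\t")
            is_tsv = cols[:2] == ["protein_a", "protein_b"]
            lines = fh if is_tsv else [header, *fh]
            for line in lines:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    n_skipped += 1
                    logger.warning("malformed line skipped in %s: %r", path, line)
                    continue
                if is_tsv:
                    a, b = fields[0], fields[1]
                    source = fields[2] if len(fields) > 2 and fields[2] else "unknown"
                    evidence = fields[3] if len(fields) > 3 and fields[3] else "physical"
                else:
                    parsed = _parse_mitab_line(fields)
                    if parsed is None:
                        n_skipped += 1
                        logger.warning("malformed MITAB line skipped in %s", path)
                        continue
                    a, b, source, evidence = parsed
                if a == b:
                    n_skipped += 1
                    logger.info("self-loop %s-%s skipped", a, b)
                    continue
                if graph.has_edge(a, b):
                    sources = set(graph[a][b]["source"].split(";"))
                    sources.add(source)
                    graph[a][b]["source"] = ";".join(sorted(sources))
                    evidences = set(graph[a][b]["evidence"].split(";"))
                    evidences.add(evidence)
                    graph[a][b]["evidence"] = ";".join(sorted(evidences))
                else:
                    graph.add_edge(a, b, source=source, evidence=evidence)
    if graph.number_of_edges() == 0:
        raise ValueError("no usable interaction edges found")
    if n_skipped:
        logger.info("skipped %d malformed/self-loop lines", n_skipped)
    return graph


# ---------------------------------------------------------------------------
# network construction


def modulation_class(log2_fc: float, cut: float = LOG2FC_CUT_DEFAULT) -> str:
    """Node colour class: strict inequalities, |log2FC| = cut is un-regulated."""
    if log2_fc > cut:
        return "up-regulated"
    if log2_fc < -cut:
        return "down-regulated"
    return "un-regulated"


def build_group_network(
    log2_fc: Mapping[str, float],
    interactome: nx.Graph,
    selected: Iterable[str] | None = None,
    cut: float = LOG2FC_CUT_DEFAULT,
) -> nx.Graph:
    """Induced subgraph of the interactome on the selected protein list,
    annotated with one group's fold changes.

    ``selected`` defaults to the keys of ``log2_fc``; in the full pipeline it
    is the union of differential proteins across all dose groups (so nodes
    not differential in this group appear as un-regulated).  Isolated nodes
    are dropped.
    """
    selected = set(selected) if selected is not None else set(log2_fc)
    if not selected:
        raise ValueError("empty differential protein list")
    present = selected & set(interactome.nodes)
    sub = interactome.subgraph(present).copy()
    sub.remove_nodes_from(list(nx.isolates(sub)))
    if sub.number_of_nodes() == 0:
        raise ValueError("no selected protein has any interaction in the interactome")
    for node in sub.nodes:
        lfc = float(log2_fc.get(node, 0.0))
        sub.nodes[node]["log2_fc"] = lfc
        sub.nodes[node]["modulation"] = modulation_class(lfc, cut)
    return sub


def extract_gcc(network: nx.Graph) -> tuple[nx.Graph, int]:
    """Largest connected component; ties broken by the component containing
    the lexicographically smallest node id."""
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    components = list(nx.connected_components(network))
    size = max(len(c) for c in components)
    candidates = [c for c in components if len(c) == size]
    best = min(candidates, key=lambda c: min(str(n) for n in c))
    return network.subgraph(best).copy(), size


# ---------------------------------------------------------------------------
# GCC permutation significance


def _adjacency(graph: nx.Graph) -> dict:
    return {n: set(graph[n]) for n in graph.nodes}


def _induced_gcc_size(adj: dict, nodes: set) -> int:
    """GCC size of the induced subgraph on ``nodes`` (plain BFS; fast enough
    for 10^5-scale permutations)."""
    best = 0
    seen: set = set()
    for start in nodes:
        if start in seen:
            continue
        seen.add(start)
        stack = [start]
        size = 0
        while stack:
            u = stack.pop()
            size += 1
            for v in adj[u]:
                if v in nodes and v not in seen:
                    seen.add(v)
                    stack.append(v)
        if size > best:
            best = size
    return best


def gcc_significance(
    interactome: nx.Graph,
    n_selected: int,
    observed_gcc: int,
    n_permutations: int = 10_000,
    seed: int = 0,
    null: str = "uniform",
    selected: Iterable[str] | None = None,
    n_strata: int = 10,
) -> GccSignificance:
    """Empirical z-score and p-value of an observed GCC size.

    Each permutation draws ``n_selected`` nodes without replacement from the
    interactome node set, and records the GCC size of their induced
    subgraph.  z = (observed − null mean)/null sd; the empirical p uses the
    add-one convention (#null ≥ observed + 1)/(B + 1) so it is never zero.

    ``null='degree_stratified'`` resamples within degree deciles of the
    observed selection (pass ``selected``) instead of uniformly.
    """
    if n_permutations < 1000:
        raise ValueError("use at least 1000 permutations")
    node_list = sorted(interactome.nodes)
    if n_selected > len(node_list):
        raise ValueError("n_selected exceeds interactome size")
    adj = _adjacency(interactome)
    rng = np.random.default_rng(seed)
    nodes_arr = np.array(node_list, dtype=object)

    if null == "uniform":
        def draw() -> set:
            return set(rng.choice(nodes_arr, size=n_selected, replace=False))
    elif null == "degree_stratified":
        if selected is None:
            raise ValueError("degree_stratified null requires the observed selection")
        degrees = np.array([len(adj[n]) for n in node_list])
        edges = np.quantile(degrees, np.linspace(0, 1, n_strata + 1))
        edges = np.unique(edges)
        bins = np.clip(np.searchsorted(edges, degrees, side="right") - 1, 0, len(edges) - 2)
        per_bin = [nodes_arr[bins == b] for b in range(len(edges) - 1)]
        sel_deg = np.array([len(adj[n]) for n in selected if n in adj])
        sel_bins = np.clip(np.searchsorted(edges, sel_deg, side="right") - 1, 0, len(edges) - 2)
        counts = np.bincount(sel_bins, minlength=len(edges) - 1)

        def draw() -> set:
            out: set = set()
            for b, c in enumerate(counts):
                if c:
                    out.update(rng.choice(per_bin[b], size=min(c, len(per_bin[b])), replace=False))
            return out
    else:
        raise ValueError(f"unknown null model: {null!r}")

    null_sizes = np.empty(n_permutations)
    for i in range(n_permutations):
        null_sizes[i] = _induced_gcc_size(adj, draw())
    null_mean = float(null_sizes.mean())
    null_sd = float(null_sizes.std(ddof=1))
    if null_sd > 0:
        z = (observed_gcc - null_mean) / null_sd
    else:
        logger.warning("degenerate permutation null (sd = 0); z undefined")
        z = float("nan")
    empirical_p = (int((null_sizes >= observed_gcc).sum()) + 1) / (n_permutations + 1)
    return GccSignificance(
        observed_gcc=int(observed_gcc),
        null_mean=null_mean,
        null_sd=null_sd,
        z=float(z),
        empirical_p=float(empirical_p),
        n_permutations=int(n_permutations),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# node metrics and hub ranking


def centralities(network: nx.Graph) -> pd.DataFrame:
    """DC (raw degree), BC (unnormalised betweenness), CC (intra-component
    closeness), and local clustering coefficient per node."""
    dc = dict(network.degree())
    bc = nx.betweenness_centrality(network, normalized=False)
    cc = nx.closeness_centrality(network, wf_improved=False)
    clust = nx.clustering(network)
    out = pd.DataFrame(
        {
            "protein_id": sorted(network.nodes, key=str),
        }
    )
    out["DC"] = [dc[n] for n in out["protein_id"]]
    out["BC"] = [bc[n] for n in out["protein_id"]]
    out["CC"] = [cc[n] for n in out["protein_id"]]
    out["clustering"] = [clust[n] for n in out["protein_id"]]
    return out


def node_size(log2_fc: float, dc: int) -> float:
    """(DC + 1) × (|log2FC| + 1) — emphasises regulated, well-connected nodes."""
    if dc < 0:
        raise ValueError("degree must be non-negative")
    return (dc + 1) * (abs(log2_fc) + 1)


def annotate_metrics(network: nx.Graph) -> pd.DataFrame:
    """Attach DC/BC/CC/clustering/hub_score/node_size attributes to the graph
    and return them as a table."""
    table = centralities(network)
    lfc = {n: network.nodes[n].get("log2_fc", 0.0) for n in network.nodes}
    table["log2_fc"] = [lfc[n] for n in table["protein_id"]]
    table["hub_score"] = table["log2_fc"] * table["DC"]
    table["node_size"] = [node_size(l, d) for l, d in zip(table["log2_fc"], table["DC"])]
    table["modulation"] = [network.nodes[n].get("modulation", "un-regulated")
                           for n in table["protein_id"]]
    for row in table.itertuples():
        node = network.nodes[row.protein_id]
        node.update(
            DC=int(row.DC), BC=float(row.BC), CC=float(row.CC),
            clustering=float(row.clustering), hub_score=float(row.hub_score),
            node_size=float(row.node_size),
        )
    return table


def hub_rank(network: nx.Graph, k: int = 10) -> pd.DataFrame:
    """Top-k hub nodes by |log2FC × Degree| (sign retained in the output).

    Ties broken by higher degree then lexicographic protein id.  If k exceeds
    the node count all nodes are returned (with a warning).
    """
    table = annotate_metrics(network)
    if k > len(table):
        logger.warning("k=%d exceeds node count %d; returning all", k, len(table))
        k = len(table)
    ranked = table.assign(_abs=table["hub_score"].abs()).sort_values(
        by=["_abs", "DC", "protein_id"],
        ascending=[False, False, True],
        kind="stable",
    ).head(k)
    ranked = ranked.drop(columns="_abs").reset_index(drop=True)
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    return ranked


# ---------------------------------------------------------------------------
# export


_REQUIRED_NODE_ATTRS = ("log2_fc", "modulation", "node_size", "hub_score",
                        "DC", "BC", "CC", "clustering")


def export_network(network: nx.Graph, path: str | Path, fmt: str | None = None) -> Path:
    """Write the annotated network as GEXF or GraphML (node and edge
    attributes round-trip on re-import).

    The GEXF ``lastmodifieddate`` stamp is pinned so repeated exports of the
    same network are byte-identical.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in {"gexf", "graphml"}:
        raise ValueError(f"unknown export format: {fmt!r}")
    for node, data in network.nodes(data=True):
        missing = [a for a in _REQUIRED_NODE_ATTRS if a not in data]
        if missing:
            raise ValueError(f"node {node} missing attributes {missing}; "
                             "run annotate_metrics first")
    if fmt == "gexf":
        nx.write_gexf(network, path)
        text = path.read_text(encoding="utf-8")
        text = re.sub(r'lastmodifieddate="[^"]*"', 'lastmodifieddate="1970-01-01"', text)
        path.write_text(text, encoding="utf-8")
    else:
        nx.write_graphml(network, path)
    return path
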