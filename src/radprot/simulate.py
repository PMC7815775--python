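"""Synthetic-data generators with planted ground truth for every pipeline
stage.

The generators emulate the study design end to end: a pooled reference group
(reporter label 114) against three pooled comparison groups (115/116/117),
each quantified in two technical replicates; a planted minority of up/down
regulated proteins; annotation terms enriched in the planted set; a
scale-free interactome harbouring a dense module among planted proteins;
qPCR Ct tables with planted fold changes and stable reference genes; and
survey-meter dosimetry records (each rate the mean of three readings).

Replicate noise is applied on the log2 scale (multiplicative on ratios),
matching the multiplicative error structure of reporter-ion ratios.  Every
generator is deterministic under a fixed seed, and the planted truth is
returned alongside the data so downstream recovery is always checkable.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .dosimetry import CONVERSION_FACTOR  # noqa: F401  (doc cross-reference)

GROUPS_DEFAULT = ("II", "III", "IV")

_SOURCES = ("dbA", "dbB", "dbC")
_EVIDENCE = ("physical", "complex", "kinase-substrate")


def _protein_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def gen_quant(
    n_proteins: int,
    de_fraction: float,
    effect_range_log2: tuple[float, float] = (0.5, 1.5),
    replicate_noise_sd: float = 0.1,
    n_replicates: int = 2,
    groups: Sequence[str] = GROUPS_DEFAULT,
    up_fraction: float = 0.5,
    group_presence: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-replicate reporter ratios with planted regulation.

    Exactly ``round(n_proteins * de_fraction)`` proteins are planted (non-null
    in at least one group); ``up_fraction`` of them are up-regulated.  Each
    planted protein receives one |log2FC| magnitude drawn uniformly from
    ``effect_range_log2`` (lower bound must be ≥ log2(1.2), the calling
    threshold) and appears in each comparison group with probability
    ``group_presence``.  Null proteins have true log2 ratio 0.  Replicate
    log2 ratios are the truth plus Normal(0, replicate_noise_sd) noise.

    Returns (quant, truth): quant has columns protein_id, group, replicate,
    ratio; truth has per-group status/log2fc columns plus module_member
    (filled in by :func:`gen_interactome`).
    """
    if n_proteins <= 0:
        raise ValueError("n_proteins must be positive")
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must lie in [0, 1]")
    lo, hi = effect_range_log2
    if lo > hi:
        raise ValueError("empty effect range")
    if de_fraction > 0 and lo < math.log2(1.2):
        raise ValueError("minimum planted effect must be ≥ log2(1.2)")
    rng = np.random.default_rng(seed)
    ids = _protein_ids(n_proteins)
    n_de = round(n_proteins * de_fraction)
    planted_idx = np.sort(rng.choice(n_proteins, size=n_de, replace=False))
    n_up = round(n_de * up_fraction)
    signs = np.ones(n_de)
    signs[n_up:] = -1.0
    rng.shuffle(signs)
    magnitudes = rng.uniform(lo, hi, size=n_de)

    status = {g: np.array(["null"] * n_proteins, dtype=object) for g in groups}
    lfc = {g: np.zeros(n_proteins) for g in groups}
    presence = rng.random((n_de, len(groups))) < group_presence
    forced = rng.integers(0, len(groups), size=n_de)
    for j in range(n_de):
        if not presence[j].any():  # keep the planted count exact
            presence[j, forced[j]] = True
    for gi, g in enumerate(groups):
        for j, pi in enumerate(planted_idx):
            if presence[j, gi]:
                lfc[g][pi] = signs[j] * magnitudes[j]
                status[g][pi] = "up" if signs[j] > 0 else "down"

    rows = []
    for g in groups:
        noise = rng.normal(0.0, replicate_noise_sd, size=(n_proteins, n_replicates))
        ratios = np.power(2.0, lfc[g][:, None] + noise)
        for rep in range(1, n_replicates + 1):
            rows.append(
                pd.DataFrame(
                    {
                        "protein_id": ids,
                        "group": g,
                        "replicate": rep,
                        "ratio": ratios[:, rep - 1],
                    }
                )
            )
    quant = pd.concat(rows, ignore_index=True)

    truth = pd.DataFrame({"protein_id": ids})
    for g in groups:
        truth[f"status_{g}"] = status[g]
        truth[f"log2fc_{g}"] = lfc[g]
    truth["module_member"] = False
    return quant, truth


def planted_proteins(truth: pd.DataFrame) -> list[str]:
    """Proteins with non-null planted status in at least one group."""
    status_cols = [c for c in truth.columns if c.startswith("status_")]
    mask = (truth[status_cols] != "null").any(axis=1)
    return truth.loc[mask, "protein_id"].tolist()


def gen_annotation(
    truth: pd.DataFrame,
    n_terms: int,
    term_size_range: tuple[int, int] = (10, 40),
    n_enriched: int = 5,
    enrichment_odds: float = 8.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str, list[str]]], list[str]]:
    """Simulate a GMT-style term collection with planted enrichment.

    Enriched terms draw members with planted:null odds ``enrichment_odds``
    (``inf`` forces all members planted); other terms draw uniformly.

    Returns (terms, enriched_ids): terms as (term_id, description, members).
    """
    if n_enriched > n_terms:
        raise ValueError("n_enriched cannot exceed n_terms")
    ids = truth["protein_id"].to_numpy(dtype=object)
    lo, hi = term_size_range
    if hi > len(ids):
        raise ValueError("term size exceeds proteome size")
    rng = np.random.default_rng(seed)
    planted = set(planted_proteins(truth))
    is_planted = np.array([p in planted for p in ids])
    term_ids = [f"T{i:03d}" for i in range(1, n_terms + 1)]
    enriched = sorted(rng.choice(term_ids, size=n_enriched, replace=False).tolist())
    terms = []
    for tid in term_ids:
        size = int(rng.integers(lo, hi + 1))
        if tid in enriched:
            if math.isinf(enrichment_odds):
                pool = ids[is_planted]
                members = rng.choice(pool, size=min(size, len(pool)), replace=False)
            else:
                w = np.where(is_planted, enrichment_odds, 1.0)
                members = rng.choice(ids, size=size, replace=False, p=w / w.sum())
        else:
            members = rng.choice(ids, size=size, replace=False)
        label = "enriched" if tid in enriched else "background"
        terms.append((tid, f"synthetic {label} term", sorted(members.tolist())))
    return terms, enriched


def gen_interactome(
    n_nodes: int,
    attachment_m: int,
    planted_module_size: int,
    planted_density: float,
    truth: pd.DataFrame,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Scale-free background interactome plus a dense planted module.

    The background is a Barabási–Albert preferential-attachment graph on
    ``n_nodes`` proteins (planted module members always included); edges are
    then added among ``planted_module_size`` planted proteins until the
    module's edge density reaches ``planted_density``.  No self-loops, no
    duplicate unordered pairs.  ``truth['module_member']`` is set in place.

    Returns (edges, module_members); edges have columns protein_a,
    protein_b, source, evidence.
    """
    if not 0.0 <= planted_density <= 1.0:
        raise ValueError("planted_density must lie in [0, 1]")
    ids = truth["protein_id"].tolist()
    if n_nodes > len(ids):
        raise ValueError("n_nodes exceeds proteome size")
    planted = planted_proteins(truth)
    if planted_module_size > len(planted):
        raise ValueError("planted_module_size exceeds number of planted proteins")
    rng = np.random.default_rng(seed)
    module = sorted(rng.choice(np.array(planted, dtype=object),
                               size=planted_module_size, replace=False).tolist())
    rest = [p for p in ids if p not in set(module)]
    extra = rng.choice(np.array(rest, dtype=object),
                       size=n_nodes - planted_module_size, replace=False).tolist()
    node_ids = np.array(module + extra, dtype=object)
    rng.shuffle(node_ids)

    bg = nx.barabasi_albert_graph(n_nodes, attachment_m,
                                  seed=int(rng.integers(2**31)))
    graph = nx.relabel_nodes(bg, dict(enumerate(node_ids)))

    n_pairs = planted_module_size * (planted_module_size - 1) // 2
    target_edges = math.ceil(planted_density * n_pairs)
    pairs = [(a, b) for i, a in enumerate(module) for b in module[i + 1:]]
    rng.shuffle(pairs)
    have = sum(1 for a, b in pairs if graph.has_edge(a, b))
    for a, b in pairs:
        if have >= target_edges:
            break
        if not graph.has_edge(a, b):
            graph.add_edge(a, b)
            have += 1

    edges = sorted((min(a, b), max(a, b)) for a, b in graph.edges())
    table = pd.DataFrame(edges, columns=["protein_a", "protein_b"])
    table["source"] = rng.choice(_SOURCES, size=len(table))
    table["evidence"] = rng.choice(_EVIDENCE, size=len(table))
    truth["module_member"] = truth["protein_id"].isin(module)
    return table, module


def gen_ct(
    genes: Sequence[str],
    ref_genes: Sequence[str],
    planted_log2fc: Mapping[str, float],
    n_per_group: int = 5,
    ct_noise_sd: float = 0.2,
    groups: Sequence[str] = ("I", "II", "III"),
    calibrator_group: str = "I",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table with planted fold changes.

    A planted log2 fold change of x shifts the treated-group target Ct by
    −x cycles relative to the calibrator group (template doubling per
    cycle).  Reference genes are stable across groups up to the Ct noise and
    must have planted fold change 0.
    """
    if set(genes) & set(ref_genes):
        raise ValueError("target and reference gene ids must not overlap")
    for g in ref_genes:
        if planted_log2fc.get(g, 0.0) != 0.0:
            raise ValueError(f"reference gene {g} must have planted log2fc 0")
    rng = np.random.default_rng(seed)
    all_genes = [*genes, *ref_genes]
    base_ct = {g: rng.uniform(18.0, 28.0) for g in all_genes}
    rows = []
    for group in groups:
        for i in range(1, n_per_group + 1):
            sample = f"{group}_s{i:02d}"
            for gene in all_genes:
                shift = 0.0
                if group != calibrator_group and gene not in ref_genes:
                    shift = planted_log2fc.get(gene, 0.0)
                ct = base_ct[gene] - shift + rng.normal(0.0, ct_noise_sd)
                rows.append({"sample": sample, "group": group, "gene": gene, "ct": ct})
    return pd.DataFrame(rows)


def gen_dosimetry(
    n_subjects: int,
    rate_range_uR_per_h: tuple[float, float] = (5.0, 400.0),
    occupancy_indoor: float = 0.8,
    reading_noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate survey-meter dose records (rates in μR/h).

    True indoor and outdoor rates are drawn uniformly from the given range;
    each reported rate is the mean of three simulated readings (readings are
    true rate + Normal(0, reading_noise_sd)).
    """
    lo, hi = rate_range_uR_per_h
    if lo <= 0 or hi < lo:
        raise ValueError("rate range must be positive and ordered")
    if not 0.0 <= occupancy_indoor <= 1.0:
        raise ValueError("occupancy_indoor must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(1, n_subjects + 1):
        indoor = rng.uniform(lo, hi)
        outdoor = rng.uniform(lo, hi)
        indoor_mean = float(np.mean(indoor + rng.normal(0, reading_noise_sd, 3)))
        outdoor_mean = float(np.mean(outdoor + rng.normal(0, reading_noise_sd, 3)))
        rows.append(
            {
                "subject": f"S{i:03d}",
                "indoor_rate": indoor_mean,
                "outdoor_rate": outdoor_mean,
                "occupancy_indoor": occupancy_indoor,
            }
        )
    return pd.DataFrame(
        rows, columns=["subject", "indoor_rate", "outdoor_rate", "occupancy_indoor"]
    )
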