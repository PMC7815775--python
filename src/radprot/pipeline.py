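"""Pipeline orchestration: simulate → differential → enrichment → network →
qPCR → dosimetry, each stage re-runnable from its intermediate files.

Every stage writes plain-text outputs under the run directory and appends
its parameters to ``provenance.json``.  Randomness is derived from the
single run seed via independent substreams, so a rerun with the same
configuration is checksum-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential, dosimetry, enrichment, io, network, qpcr, simulate
from .config import RunConfig

logger = logging.getLogger(__name__)

GROUPS = ("II", "III", "IV")


def _stage_seeds(seed: int) -> dict[str, int]:
    """Independent per-stage seeds derived from the run seed."""
    names = ["quant", "annotation", "interactome", "ct", "dose", "gcc"]
    ss = np.random.SeedSequence(seed)
    states = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(len(names))]
    return dict(zip(names, states))


def stage_simulate(config: RunConfig, outdir: Path) -> None:
    """Generate all synthetic inputs (with truth tables written beside them)."""
    seeds = _stage_seeds(config.seed)
    quant, truth = simulate.gen_quant(
        n_proteins=config.n_proteins,
        de_fraction=config.de_fraction,
        effect_range_log2=config.effect_range_log2,
        replicate_noise_sd=config.replicate_noise_sd,
        up_fraction=config.up_fraction,
        group_presence=config.group_presence,
        seed=seeds["quant"],
    )
    terms, enriched = simulate.gen_annotation(
        truth,
        n_terms=config.n_terms,
        term_size_range=config.term_size_range,
        n_enriched=config.n_enriched,
        enrichment_odds=config.enrichment_odds,
        seed=seeds["annotation"],
    )
    edges, module = simulate.gen_interactome(
        n_nodes=config.n_nodes,
        attachment_m=config.attachment_m,
        planted_module_size=config.planted_module_size,
        planted_density=config.planted_density,
        truth=truth,
        seed=seeds["interactome"],
    )
    planted_fc = {
        g: (config.qpcr_planted_log2fc if i % 2 == 0 else 0.0)
        for i, g in enumerate(config.qpcr_targets)
    }
    ct = simulate.gen_ct(
        genes=list(config.qpcr_targets),
        ref_genes=list(config.qpcr_ref_genes),
        planted_log2fc=planted_fc,
        n_per_group=config.qpcr_n_per_group,
        ct_noise_sd=config.ct_noise_sd,
        seed=seeds["ct"],
    )
    dose = simulate.gen_dosimetry(
        n_subjects=config.n_subjects,
        rate_range_uR_per_h=config.rate_range_uR_per_h,
        occupancy_indoor=config.occupancy_indoor,
        seed=seeds["dose"],
    )
    io.write_tsv(quant, outdir / "quant.tsv")
    io.write_tsv(truth, outdir / "truth.tsv")
    io.write_gmt(terms, outdir / "annotation.gmt")
    io.write_tsv(edges, outdir / "interactome.tsv")
    io.write_tsv(ct, outdir / "ct.tsv")
    io.write_tsv(dose, outdir / "dosimetry.tsv")
    (outdir / "simulation_truth.json").write_text(
        json.dumps(
            {"enriched_terms": enriched, "module_members": module,
             "qpcr_planted_log2fc": planted_fc},
            indent=2, sort_keys=True,
        ),
        encoding="utf-8",
    )


def stage_differential(config: RunConfig, outdir: Path) -> pd.DataFrame:
    quant = io.read_quant(config.quant_path or outdir / "quant.tsv")
    calls, qc = differential.call_differential(
        quant, fc_up=config.fc_up, fc_down=config.fc_down, alpha=config.alpha_adj
    )
    io.write_tsv(calls, outdir / "differential.tsv")
    io.write_tsv(qc, outdir / "differential_qc.tsv")
    io.write_tsv(differential.volcano_table(calls), outdir / "volcano.tsv")
    sets = differential.differential_sets(calls)
    venn = differential.venn_partition(sets) if sets else {}
    (outdir / "venn.json").write_text(
        json.dumps(venn, indent=2, sort_keys=True), encoding="utf-8"
    )
    return calls


def stage_enrichment(config: RunConfig, outdir: Path) -> dict[str, pd.DataFrame]:
    calls = io.read_tsv(outdir / "differential.tsv")
    terms = io.read_gmt(config.gmt_path or outdir / "annotation.gmt")
    per_group: dict[str, pd.DataFrame] = {}
    for group, sub in calls.groupby("group", sort=True):
        background = set(sub["protein_id"])
        selected = set(sub.loc[sub["status"] != "unchanged", "protein_id"])
        if not selected:
            logger.warning("group %s: no differential proteins, enrichment skipped", group)
            continue
        res = enrichment.fisher_enrich(selected, background, terms,
                                       alpha=config.enrich_alpha)
        io.write_tsv(res, outdir / f"enrichment_{group}.tsv")
        per_group[group] = res
    if per_group:
        matrix = enrichment.comparative_matrix(per_group)
        matrix.to_csv(outdir / "enrichment_matrix.tsv", sep="\t")
    return per_group


def stage_network(config: RunConfig, outdir: Path) -> dict[str, dict]:
    calls = io.read_tsv(outdir / "differential.tsv")
    paths = list(config.interactome_paths) or [outdir / "interactome.tsv"]
    interactome = network.load_interactome(paths)
    seeds = _stage_seeds(config.seed)
    sets = differential.differential_sets(calls)
    union = sorted(set().union(*sets.values())) if sets else []
    results: dict[str, dict] = {}
    for group, sub in calls.groupby("group", sort=True):
        lfc = dict(zip(sub["protein_id"], sub["log2_fc"]))
        try:
            net = network.build_group_network(
                lfc, interactome, selected=union, cut=config.hub_log2fc_cut
            )
        except ValueError as exc:
            logger.warning("group %s: %s", group, exc)
            continue
        _, gcc_size = network.extract_gcc(net)
        n_selected = len(set(union) & set(interactome.nodes))
        sig = network.gcc_significance(
            interactome,
            n_selected=n_selected,
            observed_gcc=gcc_size,
            n_permutations=config.n_permutations,
            seed=seeds["gcc"],
            null=config.gcc_null,
            selected=union if config.gcc_null == "degree_stratified" else None,
        )
        hubs = network.hub_rank(net, k=config.top_k)
        io.write_tsv(hubs, outdir / f"hubs_{group}.tsv")
        network.export_network(net, outdir / f"network_{group}.gexf")
        network.export_network(net, outdir / f"network_{group}.graphml")
        (outdir / f"gcc_{group}.json").write_text(sig.to_json(), encoding="utf-8")
        results[group] = {
            "n_nodes": net.number_of_nodes(),
            "n_edges": net.number_of_edges(),
            "gcc": json.loads(sig.to_json()),
            "top_hub": hubs.iloc[0]["protein_id"] if len(hubs) else None,
        }
    return results


def stage_qpcr(config: RunConfig, outdir: Path) -> pd.DataFrame:
    ct = io.read_ct(config.ct_path or outdir / "ct.tsv")
    stability = qpcr.reference_stability(ct, list(config.qpcr_ref_genes))
    io.write_tsv(stability, outdir / "reference_stability.tsv")
    results = qpcr.analyze_expression(
        ct, list(config.qpcr_targets), list(config.qpcr_ref_genes),
        calibrator_group="I",
    )
    io.write_tsv(results, outdir / "qpcr_results.tsv")
    return results


def stage_dosimetry(config: RunConfig, outdir: Path) -> pd.DataFrame:
    dose = io.read_dose(config.dose_path or outdir / "dosimetry.tsv")
    out = dosimetry.process_dosimetry(
        dose, boundary_to_hlnra=config.nlnra_boundary_to_hlnra
    )
    io.write_tsv(out, outdir / "dose_groups.tsv")
    return out


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage and write a consolidated summary.

    Returns the summary dict (also written as ``summary.json``).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    stage_simulate(config, outdir)
    calls = stage_differential(config, outdir)
    enrich = stage_enrichment(config, outdir)
    net = stage_network(config, outdir)
    qp = stage_qpcr(config, outdir)
    dose = stage_dosimetry(config, outdir)

    sig = calls[calls["status"] != "unchanged"]
    counts = {
        g: {
            "up": int((sub["status"] == "up").sum()),
            "down": int((sub["status"] == "down").sum()),
        }
        for g, sub in calls.groupby("group", sort=True)
    }
    venn = json.loads((outdir / "venn.json").read_text(encoding="utf-8"))

    truth_path = outdir / "truth.tsv"
    recovery = {}
    if truth_path.exists():
        truth = io.read_tsv(truth_path)
        recovery = planted_recovery(calls, truth)

    summary = {
        "seed": config.seed,
        "differential_counts": counts,
        "venn_partition": venn,
        "enriched_terms": {
            g: df.loc[df["significant"], "term_id"].tolist() for g, df in enrich.items()
        },
        "network": net,
        "qpcr": qp.to_dict(orient="records"),
        "dose_group_counts": dose["group"].value_counts().sort_index().to_dict(),
        "planted_recovery": recovery,
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str), encoding="utf-8"
    )
    provenance = {
        "config": json.loads(json.dumps(config.__dict__, default=list)),
        "stage_seeds": _stage_seeds(config.seed),
        "n_differential_total": int(sig["protein_id"].nunique()),
    }
    (outdir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True), encoding="utf-8"
    )
    return summary


def planted_recovery(calls: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Compare differential calls with the planted truth: per-group true/false
    positive counts and the correct-sign recovery rate among planted proteins."""
    out: dict = {}
    truth = truth.copy()
    status_cols = [c for c in truth.columns if c.startswith("status_")]
    truth[status_cols] = truth[status_cols].fillna("null")  # 'null' reads as NaN
    for group, sub in calls.groupby("group", sort=True):
        status_col = f"status_{group}"
        if status_col not in truth.columns:
            continue
        merged = sub.merge(
            truth[["protein_id", status_col]], on="protein_id", how="left"
        )
        planted = merged[merged[status_col] != "null"]
        nulls = merged[merged[status_col] == "null"]
        tp = int((planted["status"] == planted[status_col]).sum())
        fp = int((nulls["status"] != "unchanged").sum())
        out[group] = {
            "n_planted": int(len(planted)),
            "true_positive_correct_sign": tp,
            "recovery_rate": tp / len(planted) if len(planted) else float("nan"),
            "false_positives": fp,
            "false_positive_rate": fp / len(nulls) if len(nulls) else float("nan"),
        }
    return out
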