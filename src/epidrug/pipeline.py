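"""End-to-end orchestration: simulate -> differential -> DMEG -> classify ->
proximity -> signature, with every stage output written to disk and a
machine-readable summary JSON.
"""

from __future__ import annotations

import contextlib
import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import classify, differential, dmeg, io, proximity, signature, synthetic

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Thresholds and sizes for a full run; defaults follow the study design."""

    outdir: str = "epidrug_out"
    meth_fdr: float = 0.01
    delta_beta: float = 0.1
    expr_fdr: float = 0.01
    log2fc: float = 2.0
    enrich_fdr: float = 0.05
    proximity_fdr: float = 0.01
    regions: Sequence[str] = ("Body", "TSS200", "TSS1500")
    n_perm: int = 10_000
    n_runs: int = 1000
    cv_folds: int = 10
    horizons: Sequence[float] = (1.0, 3.0, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("meth_fdr", "delta_beta", "expr_fdr", "log2fc", "enrich_fdr", "proximity_fdr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def simulate(
    config: PipelineConfig,
    cohort: synthetic.CohortConfig | None = None,
    network: synthetic.NetworkConfig | None = None,
) -> dict:
    """Generate every pipeline input under ``outdir`` and return the paths."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = cohort or synthetic.CohortConfig(seed=config.seed)
    beta, manifest, truth = synthetic.generate_methylation(cohort)
    expr = synthetic.generate_expression(cohort, truth)
    planted = sorted({g for gl in truth.dmeg_genes.values() for g in gl})
    up_genes = truth.dmeg_genes["HyperUp"] + truth.dmeg_genes["HypoUp"]
    prognostic = up_genes[:3] if len(up_genes) >= 3 else planted[:3]
    truth.prognostic_genes = prognostic
    surv_cfg = synthetic.SurvivalConfig(
        true_genes=prognostic, true_coefs=[0.8] * len(prognostic), seed=config.seed
    )
    tumor_ids, _ = synthetic.sample_ids(cohort)
    survival = synthetic.generate_survival(expr[tumor_ids], surv_cfg)

    network = network or synthetic.NetworkConfig(
        n_nodes=cohort.n_genes, disease_set_size=min(20, max(5, len(planted) // 4)),
        seed=config.seed,
    )
    G, drug_table, net_truth = synthetic.generate_network(
        network,
        node_names=sorted(expr.index),
        disease_genes=planted,
    )
    truth.proximal_drugs = net_truth.proximal_drugs
    truth.disease_genes = net_truth.disease_genes

    io.write_matrix(beta, out / "beta.tsv")
    io.write_manifest(manifest, out / "manifest.csv")
    io.write_matrix(expr, out / "expression.tsv")
    synthetic.sample_sheet(cohort).to_csv(out / "samples.tsv", sep="\t", index=False)
    io.write_survival(survival, out / "survival.tsv")
    io.write_edge_list(G, out / "ppi_edges.tsv")
    io.write_drug_table(drug_table, out / "drug_targets.tsv")
    truth.to_json(out / "truth.json")
    return {"outdir": str(out), "truth": truth}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@contextlib.contextmanager
def _stage(name: str):
    logger.info("stage %s: start", name)
    try:
        yield
    except Exception as err:  # noqa: BLE001 - abort must name the stage
        raise StageError(f"stage '{name}' failed: {err}") from err


def run_demo(
    config: PipelineConfig,
    cohort: synthetic.CohortConfig | None = None,
    simulate_first: bool = True,
) -> dict:
    """Synthetic end-to-end run; returns the summary dict (also written as JSON).

    With ``simulate_first=False`` the inputs must already exist under
    ``outdir`` (e.g. from a previous :func:`simulate` call).
    """
    out = Path(config.outdir)
    if simulate_first:
        with _stage("simulate"):
            simulate(config, cohort=cohort)
    with _stage("load-inputs"):
        beta = io.read_matrix(out / "beta.tsv")
        manifest = io.read_manifest(out / "manifest.csv")
        expr = io.read_matrix(out / "expression.tsv")
        sheet = io.read_sample_sheet(out / "samples.tsv")
        groups = dict(zip(sheet["sample"], sheet["group"]))
        G = io.read_edge_list(out / "ppi_edges.tsv")
        drugs = io.read_drug_table(out / "drug_targets.tsv")
        with open(out / "truth.json") as fh:
            truth = json.load(fh)

    summary: dict = {"seed": config.seed}

    # differential methylation per region, expression once
    logger.info("stage differential: %d probes, %d genes", len(beta), len(expr))
    meth_results = {}
    for region in config.regions:
        rb = differential.aggregate_probes(beta, manifest, region)
        res = differential.diff_methylation(rb, groups, config.meth_fdr, config.delta_beta)
        res.insert(0, "region", region)
        res.rename_axis("gene").reset_index().to_csv(out / f"dmr_{region}.tsv", sep="\t", index=False)
        meth_results[region] = res
    expr_res = differential.diff_expression(expr, groups, config.expr_fdr, config.log2fc)
    expr_res.rename_axis("gene").reset_index().to_csv(out / "deg.tsv", sep="\t", index=False)
    summary["n_deg"] = int((expr_res["status"] != "NotSig").sum())
    summary["dmg_counts"] = {
        r: {"Hyper": int((m["status"] == "Hyper").sum()), "Hypo": int((m["status"] == "Hypo").sum())}
        for r, m in meth_results.items()
    }

    # DMEG intersection and union
    tables = [dmeg.intersect_dmeg(meth_results[r], expr_res, region=r) for r in config.regions]
    union, counts = dmeg.union_dmeg(tables)
    union.to_csv(out / "dmeg.tsv", sep="\t", index=False)
    summary["dmeg_group_counts"] = counts
    summary["n_dmeg"] = int(len(union))

    # classification on DMEG features (expression + region-mean methylation)
    dmeg_genes = sorted(union["gene"]) if len(union) else sorted(expr.index[:10])
    feats = [expr.loc[[g for g in dmeg_genes if g in expr.index]].T.add_prefix("expr:")]
    rb_body = differential.aggregate_probes(beta, manifest, "Body")
    feats.append(rb_body.loc[[g for g in dmeg_genes if g in rb_body.index]].T.add_prefix("meth:"))
    features = pd.concat(feats, axis=1)
    clf = classify.evaluate_split(features, groups, seed=config.seed)
    clf["model"].to_json(out / "classifier.json")
    summary["classifier"] = {"auc_train": clf["auc_train"], "auc_test": clf["auc_test"]}

    # proximity screen against the planted disease module
    disease = [g for g in truth["disease_genes"] if G.has_node(g)]
    prox = proximity.screen_drugs(disease, drugs, G, n_perm=config.n_perm, seed=config.seed)
    prox.to_csv(out / "proximity.tsv", sep="\t", index=False)
    hits = prox.loc[prox["fdr"] < config.proximity_fdr, "drug"]
    summary["proximity"] = {
        "n_drugs": int(len(prox)),
        "n_hits": int(len(hits)),
        "top_drug": prox.iloc[0]["drug"] if len(prox) else None,
    }

    # prognostic signature on tumor samples
    with _stage("signature"):
        survival = io.read_survival(out / "survival.tsv")
        tumor_ids = [s for s in expr.columns if groups[s] == "tumor"]
        sig_expr = expr.loc[dmeg_genes, tumor_ids] if dmeg_genes else expr[tumor_ids]
        model, ev, freq = signature.fit_signature(
            sig_expr, survival, n_runs=config.n_runs, cv_folds=config.cv_folds,
            seed=config.seed, horizons=config.horizons,
        )
    model.to_json(out / "signature.json")
    freq.counts.sort_values(ascending=False).rename_axis("gene").reset_index().to_csv(
        out / "selection_frequency.tsv", sep="\t", index=False
    )
    summary["signature"] = {
        "genes": model.genes,
        "coefficients": [round(c, 6) for c in model.coefficients],
        "cutoff": round(model.cutoff, 6) if model.cutoff is not None else None,
        "logrank_p": ev.p,
        "hazard_ratio": ev.hazard_ratio,
        "auc_by_horizon": {str(k): v for k, v in ev.auc_by_horizon.items()},
    }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=float)
    return summary
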