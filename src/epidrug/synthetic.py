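"""Synthetic cohorts with planted ground truth for every pipeline stage.

The generators emulate the shape of a 450K methylation + RNA-seq tumor
study: Beta-distributed probe intensities with planted region-level
tumor-normal shifts, log-normal (Gaussian on the log2 scale) expression
with planted fold changes, proportional-hazards survival driven by a
linear risk score over planted genes, and a scale-free protein-
interaction surrogate with drugs whose targets sit on or next to the
disease module. Every generator is a pure function of its config,
including the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .dmeg import DMEG_GROUPS

PLANT_REGIONS = ("Body", "TSS200", "TSS1500")


@dataclass
class CohortConfig:
    """Sizes, planted effects and noise for a methylation+expression cohort.

    ``delta_beta_effect`` is the planted tumor-normal difference of region-
    mean beta values (Table-style calling floor is 0.1) and ``log2fc_effect``
    the planted expression difference on the log2 scale (calling floor 2).
    ``beta_noise_conc`` is the concentration c of the Beta(mu*c, (1-mu)*c)
    probe noise; larger is cleaner.
    """

    n_tumor: int = 100
    n_normal: int = 100
    n_genes: int = 500
    n_probes_per_gene_region: int = 3
    planted_dmeg: Mapping[str, int] = field(
        default_factory=lambda: {"HyperUp": 25, "HyperDown": 25, "HypoUp": 25, "HypoDown": 25}
    )
    delta_beta_effect: float = 0.15
    log2fc_effect: float = 3.0
    beta_noise_conc: float = 50.0
    expr_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_tumor, self.n_normal) < 1:
            raise ValueError("need at least 1 sample per group")
        if self.n_genes < 1 or self.n_probes_per_gene_region < 1:
            raise ValueError("counts must be positive")
        unknown = set(self.planted_dmeg) - set(DMEG_GROUPS)
        if unknown:
            raise ValueError(f"unknown DMEG groups: {sorted(unknown)}")
        if any(v < 0 for v in self.planted_dmeg.values()):
            raise ValueError("planted counts must be non-negative")
        if sum(self.planted_dmeg.values()) > self.n_genes:
            raise ValueError("planted gene counts exceed n_genes")
        if self.delta_beta_effect < 0.1:
            raise ValueError("delta_beta_effect below the 0.1 calling floor")
        if self.log2fc_effect < 2.0:
            raise ValueError("log2fc_effect below the 2.0 calling floor")
        if self.beta_noise_conc <= 0 or self.expr_sd <= 0:
            raise ValueError("noise parameters must be positive")


@dataclass
class SurvivalConfig:
    true_genes: Sequence[str]
    true_coefs: Sequence[float]
    baseline_hazard: float = 0.15
    censor_rate: float = 0.3
    max_followup: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.true_genes) != len(self.true_coefs):
            raise ValueError("true_genes and true_coefs must have equal length")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must be in [0, 1)")
        if self.baseline_hazard <= 0 or self.max_followup <= 0:
            raise ValueError("baseline_hazard and max_followup must be positive")


@dataclass
class NetworkConfig:
    n_nodes: int = 300
    attach_m: int = 3
    disease_set_size: int = 20
    n_drugs: int = 20
    targets_per_drug: int = 3
    planted_proximal_drugs: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.attach_m < 1 or self.attach_m >= self.n_nodes:
            raise ValueError("attach_m must satisfy 1 <= attach_m < n_nodes")
        if not (0 < self.disease_set_size < self.n_nodes):
            raise ValueError("disease_set_size must be < n_nodes")
        if self.targets_per_drug < 1 or self.targets_per_drug > self.n_nodes:
            raise ValueError("targets_per_drug must be in [1, n_nodes]")
        if self.planted_proximal_drugs > self.n_drugs:
            raise ValueError("planted_proximal_drugs exceeds n_drugs")


@dataclass
class GroundTruth:
    dmeg_genes: dict[str, list[str]] = field(default_factory=dict)
    prognostic_genes: list[str] = field(default_factory=list)
    proximal_drugs: list[str] = field(default_factory=list)
    disease_genes: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def sample_ids(config: CohortConfig) -> tuple[list[str], list[str]]:
    tumor = [f"T{i:04d}" for i in range(1, config.n_tumor + 1)]
    normal = [f"N{i:04d}" for i in range(1, config.n_normal + 1)]
    return tumor, normal


def sample_sheet(config: CohortConfig, n_batches: int = 1) -> pd.DataFrame:
    """Sample sheet with group, batch and a KRAS-status inclusion column."""
    tumor, normal = sample_ids(config)
    ids = tumor + normal
    group = ["tumor"] * len(tumor) + ["normal"] * len(normal)
    batch = [f"B{(i % n_batches) + 1}" for i in range(len(ids))]
    return pd.DataFrame({"sample": ids, "group": group, "batch": batch, "kras": "WT"})


def generate_methylation(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Probe beta matrix, probe manifest and planted DMEG ground truth.

    Planted Hyper/Hypo genes get their region-mean beta shifted by
    ``delta_beta_effect`` in the tumor arm, in every analysis region
    (Body, TSS200, TSS1500). Per-probe values are Beta(mu*c, (1-mu)*c).
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    tumor, normal = sample_ids(config)
    samples = tumor + normal
    n_t = len(tumor)

    # assign planted genes to groups, deterministically from the config seed
    order = rng.permutation(config.n_genes)
    truth = GroundTruth(dmeg_genes={g: [] for g in DMEG_GROUPS})
    pos = 0
    meth_dir: dict[str, int] = {}  # gene -> +1 hyper, -1 hypo
    for grp in DMEG_GROUPS:
        k = int(config.planted_dmeg.get(grp, 0))
        chosen = [genes[i] for i in order[pos : pos + k]]
        truth.dmeg_genes[grp] = sorted(chosen)
        d = +1 if grp.startswith("Hyper") else -1
        for g in chosen:
            meth_dir[g] = d
        pos += k

    probes, probe_gene, probe_region = [], [], []
    rows = []
    c = config.beta_noise_conc
    pid = 0
    for gi, g in enumerate(genes):
        d = meth_dir.get(g, 0)
        for region in PLANT_REGIONS:
            # baseline region mean leaves room for the planted shift
            if d > 0:
                mu_n = rng.uniform(0.2, 0.5)
            elif d < 0:
                mu_n = rng.uniform(0.5, 0.8)
            else:
                mu_n = rng.uniform(0.2, 0.8)
            mu_t = np.clip(mu_n + d * config.delta_beta_effect, 0.02, 0.98)
            for _ in range(config.n_probes_per_gene_region):
                pid += 1
                probe = f"cg{pid:08d}"
                jitter = rng.uniform(-0.03, 0.03)
                mt = float(np.clip(mu_t + jitter, 0.02, 0.98))
                mn = float(np.clip(mu_n + jitter, 0.02, 0.98))
                vals_t = rng.beta(mt * c, (1 - mt) * c, size=n_t)
                vals_n = rng.beta(mn * c, (1 - mn) * c, size=len(normal))
                probes.append(probe)
                probe_gene.append(g)
                probe_region.append(region)
                rows.append(np.concatenate([vals_t, vals_n]))

    beta = pd.DataFrame(np.vstack(rows), index=pd.Index(probes, name="probe_id"), columns=samples)
    manifest = pd.DataFrame({"probe_id": probes, "gene": probe_gene, "region": probe_region})
    return beta, manifest, truth


def generate_expression(config: CohortConfig, truth: GroundTruth) -> pd.DataFrame:
    """Log2 expression with planted fold changes matching the DMEG groups.

    Up-group genes (HyperUp, HypoUp) get +log2fc_effect in tumors, Down
    groups -log2fc_effect; everything else is null. Noise is Gaussian on
    the log2 scale with SD ``expr_sd``.
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = _gene_names(config.n_genes)
    known = set(genes)
    planted = [g for gl in truth.dmeg_genes.values() for g in gl]
    if not set(planted) <= known:
        raise ValueError("ground truth refers to genes outside this cohort")
    direction = {}
    for grp, gl in truth.dmeg_genes.items():
        d = +1 if grp.endswith("Up") else -1
        for g in gl:
            direction[g] = d
    tumor, normal = sample_ids(config)
    base = rng.uniform(4.0, 10.0, size=config.n_genes)
    x = rng.normal(0.0, config.expr_sd, size=(config.n_genes, len(tumor) + len(normal)))
    x += base[:, None]
    for i, g in enumerate(genes):
        d = direction.get(g, 0)
        if d:
            x[i, : len(tumor)] += d * config.log2fc_effect
    return pd.DataFrame(x, index=pd.Index(genes, name="gene"), columns=tumor + normal)


def generate_survival(expr: pd.DataFrame, config: SurvivalConfig) -> pd.DataFrame:
    """Event times by exponential inversion under a proportional-hazards truth.

    The linear predictor is sum of true_coefs times mean-centered expression
    of the true genes; T ~ Exponential(rate = baseline_hazard * exp(lp)).
    With censor_rate = 0 there is no censoring at all; otherwise each sample
    is independently given a Uniform(0, max_followup) censoring time with
    probability censor_rate and the administrative cap max_followup otherwise.
    """
    missing = [g for g in config.true_genes if g not in expr.index]
    if missing:
        raise ValueError(f"true genes missing from expression matrix: {missing}")
    rng = np.random.default_rng(config.seed + 2)
    n = expr.shape[1]
    lp = np.zeros(n)
    for g, b in zip(config.true_genes, config.true_coefs):
        v = expr.loc[g].to_numpy(dtype=float)
        lp += b * (v - v.mean())
    rate = config.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0, size=n) / rate
    if config.censor_rate == 0:
        time, event = t_event, np.ones(n, dtype=int)
    else:
        is_random = rng.uniform(size=n) < config.censor_rate
        c = np.where(is_random, rng.uniform(0, config.max_followup, size=n), config.max_followup)
        event = (t_event <= c).astype(int)
        time = np.minimum(t_event, c)
    time = np.maximum(time, 1e-6)
    return pd.DataFrame({"time": time, "event": event}, index=pd.Index(expr.columns, name="sample"))


def generate_network(
    config: NetworkConfig,
    node_names: Sequence[str] | None = None,
    disease_genes: Sequence[str] | None = None,
) -> tuple[nx.Graph, pd.DataFrame, GroundTruth]:
    """Scale-free PPI surrogate, drug-target table and planted proximal drugs.

    The graph is Barabási–Albert preferential attachment (degree-
    heterogeneous, so the -ln(D+1) weight is actually exercised). The
    disease set is a BFS ball around a random node unless ``disease_genes``
    is given. Planted drugs draw all targets from the disease set and its
    direct neighbors; decoys draw targets uniformly.
    """
    rng = np.random.default_rng(config.seed + 3)
    G = nx.barabasi_albert_graph(config.n_nodes, config.attach_m, seed=int(rng.integers(2**31 - 1)))
    if node_names is not None:
        if len(set(node_names)) != config.n_nodes:
            raise ValueError("node_names must provide n_nodes unique names")
        G = nx.relabel_nodes(G, dict(zip(range(config.n_nodes), node_names)))
    nodes = sorted(G.nodes)

    if disease_genes is not None:
        S = [g for g in disease_genes if G.has_node(g)]
        if not S:
            raise ValueError("no disease gene present in the graph")
    else:
        start = nodes[rng.integers(len(nodes))]
        S, frontier = [], [start]
        seen = {start}
        while frontier and len(S) < config.disease_set_size:
            nxt = []
            for u in frontier:
                if len(S) >= config.disease_set_size:
                    break
                S.append(u)
                for v in sorted(G[u]):
                    if v not in seen:
                        seen.add(v)
                        nxt.append(v)
            frontier = nxt
        S = S[: config.disease_set_size]

    # planted drugs target the disease module itself (distance 0, well inside
    # the <= 1 neighborhood); decoys sample uniformly over all nodes
    module = sorted(S) if len(S) >= config.targets_per_drug else sorted(
        set(S) | {v for u in S for v in G[u]}
    )
    drug_rows = []
    proximal = []
    for k in range(config.n_drugs):
        drug = f"D{k + 1:03d}"
        if k < config.planted_proximal_drugs:
            pool = module
            proximal.append(drug)
        else:
            pool = nodes
        targets = rng.choice(len(pool), size=min(config.targets_per_drug, len(pool)), replace=False)
        for t in targets:
            drug_rows.append((drug, pool[t]))
    drug_table = pd.DataFrame(drug_rows, columns=["drug_id", "target_gene"])
    truth = GroundTruth(proximal_drugs=proximal, disease_genes=sorted(S))
    return G, drug_table, truth
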