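import numpy as np
import pandas as pd
import pytest

from epidrug import synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """60 + 60 samples, 80 genes, 5 planted genes per DMEG group."""
    cfg = synthetic.CohortConfig(
        n_tumor=60,
        n_normal=60,
        n_genes=80,
        planted_dmeg={"HyperUp": 5, "HyperDown": 5, "HypoUp": 5, "HypoDown": 5},
        seed=11,
    )
    beta, manifest, truth = synthetic.generate_methylation(cfg)
    expr = synthetic.generate_expression(cfg, truth)
    tumor, normal = synthetic.sample_ids(cfg)
    groups = {s: "tumor" for s in tumor} | {s: "normal" for s in normal}
    return {
        "config": cfg,
        "beta": beta,
        "manifest": manifest,
        "truth": truth,
        "expr": expr,
        "groups": groups,
    }


@pytest.fixture(scope="session")
def survival_cohort():
    """300 tumor samples, 3 planted prognostic genes among 50 nulls."""
    cfg = synthetic.CohortConfig(n_tumor=300, n_normal=2, n_genes=53, planted_dmeg={}, seed=7)
    expr = synthetic.generate_expression(cfg, synthetic.GroundTruth())
    tumor, _ = synthetic.sample_ids(cfg)
    expr = expr[tumor]
    true_genes = list(expr.index[:3])
    scfg = synthetic.SurvivalConfig(true_genes=true_genes, true_coefs=[1.0] * 3, seed=7)
    survival = synthetic.generate_survival(expr, scfg)
    return {"expr": expr, "survival": survival, "true_genes": true_genes}


# --------------------------------------------------------------------------
# independent oracles shared across test modules


def bh_stepup_oracle(p):
    """Literal Benjamini–Hochberg step-up, written independently."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adj[i] = running_min
    return adj


def logrank_oracle(time, event, group):
    """Hand-tabulated two-sample log-rank chi-square: sum over event times of
    observed-minus-expected in group 1, variance by the hypergeometric form."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, int)  # 1 = group of interest
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return o_minus_e**2 / var


def concordance_auc_oracle(scores, labels):
    """AUC as the tie-corrected pairwise concordance probability."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))
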