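"""Region-level differential methylation and differential expression calling.

Probe-level beta values (fractions of methylated signal, in [0, 1]) are
aggregated into per-gene region means for the standard 450K annotation
windows (TSS200, TSS1500, gene body, ...), then tested tumor vs. normal
with a Welch two-sample t-test per row and Benjamini–Hochberg control.
Calls use the conventional thresholds FDR < 0.01 with |Δβ| > 0.1 for
methylation and FDR < 0.01 with |log2FC| > 2 for expression.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Closed vocabulary of probe-to-gene region labels.
REGION_VOCAB = frozenset({"TSS200", "TSS1500", "Body", "5'UTR", "3'UTR", "1stExon"})

#: Regions the default analysis runs on.
DEFAULT_REGIONS = ("Body", "TSS200", "TSS1500")

TUMOR = "tumor"
NORMAL = "normal"


def _group_masks(sample_ids: Iterable[str], groups: Mapping[str, str]) -> tuple[np.ndarray, np.ndarray]:
    labels = np.array([groups[s] for s in sample_ids])
    tum = labels == TUMOR
    nrm = labels == NORMAL
    if tum.sum() < 2 or nrm.sum() < 2:
        raise ValueError(
            f"need at least 2 samples per group, got {int(tum.sum())} tumor / {int(nrm.sum())} normal"
        )
    return tum, nrm


def aggregate_probes(beta: pd.DataFrame, manifest: pd.DataFrame, region: str) -> pd.DataFrame:
    """Average probe beta values into per-gene means for one region.

    Parameters
    ----------
    beta
        Probe x sample matrix of beta values in [0, 1], indexed by probe id.
    manifest
        Columns ``probe_id``, ``gene``, ``region``. A probe may map to
        several genes; exact duplicate (probe, gene, region) rows collapse.
    region
        One of :data:`REGION_VOCAB`.

    Returns
    -------
    Gene x sample DataFrame of mean beta values; ``.attrs["region"]`` holds
    the region label.
    """
    if region not in REGION_VOCAB:
        raise ValueError(f"unknown region {region!r}; expected one of {sorted(REGION_VOCAB)}")
    bad = set(manifest["region"]) - REGION_VOCAB
    if bad:
        raise ValueError(f"manifest contains regions outside the vocabulary: {sorted(bad)}")

    sub = manifest.loc[manifest["region"] == region, ["probe_id", "gene"]].drop_duplicates()
    missing = ~sub["probe_id"].isin(beta.index)
    if missing.any():
        logger.warning(
            "%d manifest probes for region %s absent from the beta matrix; skipped",
            int(missing.sum()), region,
        )
        sub = sub.loc[~missing]
    if sub.empty:
        raise ValueError(f"no manifest probes for region {region!r} present in the beta matrix")

    vals = beta.loc[sub["probe_id"].to_numpy()]
    vals.index = pd.Index(sub["gene"].to_numpy(), name="gene")
    out = vals.groupby(level="gene", sort=True).mean()
    out.attrs["region"] = region
    return out


def _welch_rowwise(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch t-test p-values; constant rows get p = 1."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance rows emit RuntimeWarnings
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups -> nan; define p = 1 so BH stays well posed
    return np.where(np.isfinite(p), p, 1.0)


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def diff_methylation(
    region_beta: pd.DataFrame,
    groups: Mapping[str, str],
    fdr_threshold: float = 0.01,
    delta_threshold: float = 0.1,
) -> pd.DataFrame:
    """Per-gene differential methylation for one region.

    Returns a DataFrame indexed like ``region_beta`` with columns
    ``mean_tumor``, ``mean_normal``, ``delta_beta`` (tumor - normal),
    ``p``, ``fdr`` and ``status`` in {Hyper, Hypo, NotSig}.
    """
    tum, nrm = _group_masks(region_beta.columns, groups)
    x = region_beta.to_numpy(dtype=float)
    mean_t = x[:, tum].mean(axis=1)
    mean_n = x[:, nrm].mean(axis=1)
    delta = mean_t - mean_n
    p = _welch_rowwise(x[:, tum], x[:, nrm])
    fdr = bh_adjust(p)
    status = np.where(
        (fdr < fdr_threshold) & (delta > delta_threshold), "Hyper",
        np.where((fdr < fdr_threshold) & (delta < -delta_threshold), "Hypo", "NotSig"),
    )
    out = pd.DataFrame(
        {
            "mean_tumor": mean_t,
            "mean_normal": mean_n,
            "delta_beta": delta,
            "p": p,
            "fdr": fdr,
            "status": status,
        },
        index=region_beta.index,
    )
    out.attrs["region"] = region_beta.attrs.get("region")
    return out


def diff_expression(
    expr: pd.DataFrame,
    groups: Mapping[str, str],
    fdr_threshold: float = 0.01,
    lfc_threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-gene differential expression on an already log2-scale matrix.

    ``log2fc`` is the difference of group means (tumor - normal); status is
    Up / Down / NotSig at FDR < ``fdr_threshold`` and |log2FC| > ``lfc_threshold``.
    """
    tum, nrm = _group_masks(expr.columns, groups)
    x = expr.to_numpy(dtype=float)
    lfc = x[:, tum].mean(axis=1) - x[:, nrm].mean(axis=1)
    p = _welch_rowwise(x[:, tum], x[:, nrm])
    fdr = bh_adjust(p)
    status = np.where(
        (fdr < fdr_threshold) & (lfc > lfc_threshold), "Up",
        np.where((fdr < fdr_threshold) & (lfc < -lfc_threshold), "Down", "NotSig"),
    )
    return pd.DataFrame(
        {"log2fc": lfc, "p": p, "fdr": fdr, "status": status}, index=expr.index
    )


def region_overlap(
    results: Mapping[str, pd.DataFrame], status: str
) -> tuple[pd.DataFrame, dict[frozenset, int]]:
    """Cross-region membership of genes carrying ``status`` (Hyper or Hypo).

    Returns the per-gene boolean membership table (genes x regions) and the
    Venn cell counts keyed by the frozenset of regions a gene appears in.
    Cell counts sum to the union size.
    """
    if status not in {"Hyper", "Hypo"}:
        raise ValueError("status must be 'Hyper' or 'Hypo'")
    if len(results) < 2:
        raise ValueError("need results for at least 2 regions")
    sets = {reg: set(df.index[df["status"] == status]) for reg, df in results.items()}
    union = sorted(set().union(*sets.values()))
    member = pd.DataFrame(
        {reg: [g in s for g in union] for reg, s in sets.items()}, index=pd.Index(union, name="gene")
    )
    regions = list(sets)
    cells: dict[frozenset, int] = {}
    for r in range(1, len(regions) + 1):
        for combo in itertools.combinations(regions, r):
            inside = frozenset(combo)
            mask = np.ones(len(union), dtype=bool)
            for reg in regions:
                mask &= member[reg].to_numpy() == (reg in inside)
            cells[inside] = int(mask.sum())
    return member, cells


def batch_standardize(expr: pd.DataFrame, batches: Mapping[str, str]) -> pd.DataFrame:
    """Location–scale adjust each batch to the pooled per-gene mean and SD.

    A deliberately simple stand-in for empirical-Bayes batch correction:
    per gene, every batch is shifted and rescaled so its mean and SD match
    the pooled values. Batches whose within-batch SD is zero are shifted only.
    """
    labels = np.array([batches[s] for s in expr.columns])
    for b in np.unique(labels):
        if (labels == b).sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")
    x = expr.to_numpy(dtype=float)
    pooled_mean = x.mean(axis=1, keepdims=True)
    pooled_sd = x.std(axis=1, ddof=1, keepdims=True)
    out = np.empty_like(x)
    for b in np.unique(labels):
        cols = labels == b
        bm = x[:, cols].mean(axis=1, keepdims=True)
        bs = x[:, cols].std(axis=1, ddof=1, keepdims=True)
        scale = np.where(bs > 0, np.where(pooled_sd > 0, pooled_sd, 1.0) / np.where(bs > 0, bs, 1.0), 1.0)
        out[:, cols] = (x[:, cols] - bm) * scale + pooled_mean
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("batch standardization produced non-finite values")
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)
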