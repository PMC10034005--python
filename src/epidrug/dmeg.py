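"""Differentially methylated & expressed genes (DMEGs) and over-representation tests.

A DMEG is a gene that is simultaneously differentially methylated in a
promoter/body region and differentially expressed, classified into four
groups by the signs of the two effects: HyperUp, HyperDown, HypoUp,
HypoDown. Region tables are unioned into one gene-level table, and gene
sets (GMT collections) are tested for enrichment with an upper-tail
hypergeometric over-representation test with BH control.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust

logger = logging.getLogger(__name__)

DMEG_GROUPS = ("HyperUp", "HyperDown", "HypoUp", "HypoDown")


def intersect_dmeg(meth: pd.DataFrame, expr: pd.DataFrame, region: str | None = None) -> pd.DataFrame:
    """Intersect one region's methylation calls with the expression calls.

    Keeps genes significant in both inputs and labels each with the group
    formed by concatenating its methylation status (Hyper/Hypo) and
    expression status (Up/Down).
    """
    region = region or meth.attrs.get("region") or ""
    m = meth.loc[meth["status"].isin(["Hyper", "Hypo"])]
    e = expr.loc[expr["status"].isin(["Up", "Down"])]
    genes = m.index.intersection(e.index)
    out = pd.DataFrame(
        {
            "gene": genes,
            "region": region,
            "meth_status": m.loc[genes, "status"].to_numpy(),
            "expr_status": e.loc[genes, "status"].to_numpy(),
            "delta_beta": m.loc[genes, "delta_beta"].to_numpy(),
            "log2fc": e.loc[genes, "log2fc"].to_numpy(),
        }
    )
    out["group"] = out["meth_status"] + out["expr_status"]
    return out.reset_index(drop=True)


def union_dmeg(tables: Iterable[pd.DataFrame]) -> tuple[pd.DataFrame, dict[str, int]]:
    """Union per-region DMEG tables into one gene-level table.

    Each gene appears once. If a gene's methylation status conflicts across
    regions (Hyper in one, Hypo in another) the region with the larger
    |delta_beta| wins and the conflict is logged.

    Returns the gene-level table and the per-group counts, which always sum
    to the union size.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("need at least one region table")
    allrows = pd.concat(tables, ignore_index=True)
    if allrows.empty:
        return allrows, {g: 0 for g in DMEG_GROUPS}
    rows = []
    for gene, grp in allrows.groupby("gene", sort=True):
        if grp["meth_status"].nunique() > 1:
            logger.warning(
                "gene %s has conflicting methylation status across regions %s; "
                "resolved by largest |delta_beta|", gene, list(grp["region"]),
            )
        best = grp.loc[grp["delta_beta"].abs().idxmax()]
        rows.append(best)
    out = pd.DataFrame(rows).reset_index(drop=True)
    counts = {g: int((out["group"] == g).sum()) for g in DMEG_GROUPS}
    return out, counts


def ora_enrichment(
    query: Iterable[str],
    collections: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    For a universe of N genes, a set of K and a query of n, the p-value is
    the upper tail P(X >= k) with X ~ Hypergeom(N, K, n) and k the observed
    overlap. Sets with no member in the universe are dropped; p-values are
    BH-adjusted across the tested sets.
    """
    universe = set(universe)
    query = set(query)
    if not universe or not query:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for name, members in collections.items():
        K_set = set(members) & universe
        if not K_set:
            continue
        k = len(K_set & query)
        p = float(stats.hypergeom.sf(k - 1, N, len(K_set), n))
        rows.append((name, k, len(K_set), n, N, min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["set_name", "overlap", "set_size", "query_size", "universe_size", "p"]
    )
    out["fdr"] = bh_adjust(out["p"]) if len(out) else np.nan
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file: tab-separated set name, description, members."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, ""] + list(members)) + "\n")
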