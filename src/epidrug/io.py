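"""Readers and writers for the plain-text exchange formats.

All matrices travel as TSV with row ids in the first column; the probe
manifest is CSV with header ``probe_id,gene,region``; edge lists and
drug-target tables are two-column TSV (edges may carry an optional third
confidence-score column, filtered at load time).
"""

from __future__ import annotations

import networkx as nx
import pandas as pd


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expect = {"probe_id", "gene", "region"}
    if not expect <= set(df.columns):
        raise ValueError(f"manifest must have columns {sorted(expect)}")
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    df[["probe_id", "gene", "region"]].to_csv(path, index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns or "group" not in df.columns:
        raise ValueError("sample sheet needs 'sample' and 'group' columns")
    return df.set_index("sample", drop=False)


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "time", "event"} <= set(df.columns):
        raise ValueError("survival table needs columns sample,time,event")
    return df.set_index("sample")[["time", "event"]]


def write_survival(df: pd.DataFrame, path) -> None:
    df.reset_index().rename(columns={"index": "sample"}).to_csv(path, sep="\t", index=False)


def read_edge_list(path, min_score: float | None = None) -> nx.Graph:
    """Edge-list TSV; a third numeric column is a confidence score and rows
    below ``min_score`` are dropped (STRING-style, e.g. a 400 threshold)."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError("edge list needs at least two columns")
    if min_score is not None and len(cols) >= 3:
        df = df[pd.to_numeric(df[cols[2]], errors="coerce") >= min_score]
    G = nx.Graph()
    G.add_edges_from(zip(df[cols[0]].astype(str), df[cols[1]].astype(str)))
    G.remove_edges_from(nx.selfloop_edges(G))
    return G


def write_edge_list(G: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for u, v in sorted(tuple(sorted(map(str, e))) for e in G.edges):
            fh.write(f"{u}\t{v}\n")


def read_drug_table(path) -> dict[str, set]:
    df = pd.read_csv(path, sep="\t")
    if not {"drug_id", "target_gene"} <= set(df.columns):
        raise ValueError("drug table needs columns drug_id,target_gene")
    return {d: set(g["target_gene"].astype(str)) for d, g in df.groupby("drug_id", sort=True)}


def write_drug_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
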