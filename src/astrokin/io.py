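"""Readers and writers for the plain-text formats the pipeline consumes.

Every format is tab- or comma-separated UTF-8 text with a '.' decimal
separator: differential-expression tables, GMT gene-set collections,
STRING-style edge lists (combined_score on the 0-1000 scale, normalized to a
confidence in (0, 1] on read), regulon tables, signature matrices with MOA
annotations, term-embedding matrices, and long-format kinome-array runs.
"""

from __future__ import annotations

import os

import networkx as nx
import pandas as pd

DE_COLUMNS = ["gene", "log2FC", "pvalue", "padj"]
KINOME_COLUMNS = ["peptide", "sample", "group", "chip", "exposure_ms", "intensity"]


# ---------------------------------------------------------------------------
# differential expression tables

def read_de_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a DE statistics table (columns gene, log2FC, pvalue, padj)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    if df["gene"].duplicated().any():
        raise ValueError("DE table has duplicate gene ids")
    return df[DE_COLUMNS]


def write_de_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[DE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | os.PathLike) -> set[str]:
    """One gene id per line; '#' starts a comment."""
    genes: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.add(line)
    return genes


def write_gene_list(genes, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


# ---------------------------------------------------------------------------
# GMT gene sets / kinase-substrate maps

def read_gmt(path: str | os.PathLike) -> dict[str, tuple[str, set[str]]]:
    """Read GMT: set_id <tab> description <tab> member1 <tab> member2 ..."""
    sets: dict[str, tuple[str, set[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            if parts[0] in sets:
                raise ValueError(f"duplicate set id in GMT: {parts[0]}")
            members = {m for m in parts[2:] if m}
            if not members:
                raise ValueError(f"empty gene set in GMT: {parts[0]}")
            sets[parts[0]] = (parts[1], members)
    return sets


def write_gmt(sets: dict[str, tuple[str, set[str]]], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id in sorted(sets):
            desc, members = sets[set_id]
            fh.write("\t".join([set_id, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# STRING-style PPI edge lists

def read_string_edges(path: str | os.PathLike) -> nx.Graph:
    """Read a STRING-style TSV (protein1, protein2, combined_score 0-1000).

    Scores are divided by 1000 into a confidence in (0, 1] stored on each
    edge. Self-loops are rejected; duplicate pairs keep the higher score.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("protein1", "protein2", "combined_score"):
        if col not in df.columns:
            raise ValueError(f"edge table missing column {col}")
    g = nx.Graph()
    for u, v, s in df.itertuples(index=False):
        if u == v:
            raise ValueError(f"self-loop on {u}")
        conf = float(s) / 1000.0
        if not 0.0 < conf <= 1.0:
            raise ValueError(f"confidence out of (0,1] for edge {u}-{v}")
        if g.has_edge(u, v):
            conf = max(conf, g[u][v]["confidence"])
        g.add_edge(u, v, confidence=conf)
    return g


def write_string_edges(g: nx.Graph, path: str | os.PathLike) -> None:
    rows = [
        (u, v, int(round(d["confidence"] * 1000)))
        for u, v, d in sorted(g.edges(data=True), key=lambda e: tuple(sorted(e[:2])))
    ]
    pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# regulons

def read_regulons(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("source", "target", "weight"):
        if col not in df.columns:
            raise ValueError(f"regulon table missing column {col}")
    if df.duplicated(["source", "target"]).any():
        raise ValueError("duplicate (source, target) pairs in regulon table")
    return df[["source", "target", "weight"]]


def write_regulons(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[["source", "target", "weight"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# perturbagen signature matrices

def read_signature_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Gene x perturbagen matrix; first column holds gene ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_signature_matrix(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_moa_labels(path: str | os.PathLike) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    for col in ("perturbagen", "moa"):
        if col not in df.columns:
            raise ValueError(f"MOA table missing column {col}")
    return df.set_index("perturbagen")["moa"]


def write_moa_labels(labels: pd.Series, path: str | os.PathLike) -> None:
    labels.rename("moa").rename_axis("perturbagen").reset_index().to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# term embeddings

def read_embeddings(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise ValueError("embedding matrix has no numeric columns")
    return df


def write_embeddings(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index_label="term")


# ---------------------------------------------------------------------------
# kinome runs

def read_kinome_run(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(KINOME_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"kinome run missing columns: {sorted(missing)}")
    if (df["intensity"] < 0).any():
        raise ValueError("negative intensities in kinome run")
    return df[KINOME_COLUMNS]


def write_kinome_run(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[KINOME_COLUMNS].to_csv(path, index=False)
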