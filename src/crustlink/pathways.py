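"""Pathway-level aggregation of gene-expression fold-changes.

Transcriptomic sanity check for the autotroph's release predictions:
genes are grouped into KEGG-style pathways and, per pathway and wet-up
time point, the arithmetic mean and standard error of member-gene
fold-changes (relative to dry crust) are reported. Anabolic pathways for
released metabolites are expected to spike during early wet-up while the
corresponding catabolic pathways stay flat.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def summarize_pathways(
    records: pd.DataFrame,
    pathways=None,
    log_scale: bool = False,
) -> pd.DataFrame:
    """Mean ± SEM of gene fold-changes per pathway per time point.

    ``records`` is long-format with columns gene_id, pathway_id, time,
    fold_change (> 0, relative to dry crust); a gene annotated to
    several pathways appears once per pathway and contributes to each.
    SEM is sample SD (n-1 denominator) / sqrt(n), reported as 0 and
    flagged when a pathway/time cell has a single gene. ``log_scale``
    averages log2 fold-changes instead of raw ratios.

    Returns columns pathway_id, time, mean_fc, sem_fc, n_genes,
    single_gene.
    """
    required = {"gene_id", "pathway_id", "time", "fold_change"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"gene table lacks columns {sorted(missing)}")
    if (records["fold_change"] <= 0).any():
        raise ValueError("fold-changes must be positive")
    df = records
    if pathways is not None:
        pathways = list(pathways)
        present = set(df["pathway_id"])
        absent = [p for p in pathways if p not in present]
        if absent:
            raise ValueError(f"no genes for requested pathway(s): {absent}")
        df = df[df["pathway_id"].isin(pathways)]
    vals = np.log2(df["fold_change"]) if log_scale else df["fold_change"]
    df = df.assign(_v=vals)
    out = (
        df.groupby(["pathway_id", "time"])["_v"]
        .agg(mean_fc="mean", sd="std", n_genes="size")
        .reset_index()
    )
    out["sem_fc"] = np.where(
        out["n_genes"] > 1, out["sd"] / np.sqrt(out["n_genes"]), 0.0
    )
    out["single_gene"] = out["n_genes"] == 1
    return out.drop(columns="sd")


def anabolic_catabolic_contrast(
    summaries: pd.DataFrame, pairing: dict[str, str]
) -> pd.DataFrame:
    """Compare anabolic vs catabolic pathway trajectories.

    ``pairing`` maps an anabolic pathway id to its catabolic
    counterpart. Per pair and shared time point the ratio of mean
    fold-changes (anabolic / catabolic) is reported with a flag when the
    anabolic mean exceeds the catabolic one.
    """
    indexed = summaries.set_index(["pathway_id", "time"])["mean_fc"]
    present = set(summaries["pathway_id"])
    rows = []
    for ana, cat in pairing.items():
        for label in (ana, cat):
            if label not in present:
                raise ValueError(f"pathway {label!r} not summarized")
        times_a = {t for p, t in indexed.index if p == ana}
        times_c = {t for p, t in indexed.index if p == cat}
        for t in sorted(times_a & times_c):
            ma, mc = indexed[(ana, t)], indexed[(cat, t)]
            rows.append({
                "anabolic": ana, "catabolic": cat, "time": t,
                "mean_anabolic": ma, "mean_catabolic": mc,
                "ratio": ma / mc, "anabolic_dominant": bool(ma > mc),
            })
    return pd.DataFrame(rows)


def load_gene_table(path) -> pd.DataFrame:
    """Read a tab-separated gene table into long format.

    Expected columns: gene_id, pathway_ids (semicolon-delimited), then
    one ``fc_<time>`` column per time point.
    """
    wide = pd.read_csv(path, sep="\t")
    fc_cols = [c for c in wide.columns if c.startswith("fc_")]
    if not fc_cols or "pathway_ids" not in wide.columns:
        raise ValueError("expected pathway_ids and fc_<time> columns")
    rows = []
    for _, rec in wide.iterrows():
        for pw in str(rec["pathway_ids"]).split(";"):
            pw = pw.strip()
            if not pw:
                continue
            for col in fc_cols:
                rows.append({
                    "gene_id": rec["gene_id"],
                    "pathway_id": pw,
                    "time": float(col[3:]),
                    "fold_change": float(rec[col]),
                })
    return pd.DataFrame(rows)
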