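"""Tab-separated table and FASTA input/output.

All tables are UTF-8, tab-separated, '.' decimal, empty cell = missing.
Peak-area tables travel as a pair of files: the area matrix
(metabolite x sample) and a sample-metadata sidecar keyed by sample_id.
Group-indexed matrices (taxon or metabolite x (stage, time)) flatten the
column MultiIndex to "stage|time" on disk.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .metabolome import PeakAreaTable


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_peak_table(table: PeakAreaTable, areas_path, meta_path) -> None:
    write_tsv(table.areas, areas_path)
    write_tsv(table.meta, meta_path)


def read_peak_table(areas_path, meta_path) -> PeakAreaTable:
    areas = read_tsv(areas_path)
    meta = read_tsv(meta_path)
    meta.index.name = "sample_id"
    return PeakAreaTable(areas, meta.loc[areas.columns])


def write_group_matrix(df: pd.DataFrame, path) -> None:
    """Write a matrix whose columns are a (stage, time) MultiIndex."""
    flat = df.copy()
    flat.columns = [f"{s}|{t:g}" for s, t in df.columns]
    write_tsv(flat, path)


def read_group_matrix(path) -> pd.DataFrame:
    flat = read_tsv(path)
    cols = [c.split("|") for c in flat.columns]
    flat.columns = pd.MultiIndex.from_tuples(
        [(s, float(t)) for s, t in cols], names=["stage", "time"]
    )
    return flat


def write_fasta(seqs: dict[str, str], path, wrap: int = 80) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
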