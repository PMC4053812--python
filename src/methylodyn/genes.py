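"""Gene annotation table (refFlat-like) shared by the analysis modules."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

_COLUMNS = [
    "gene_id",
    "chrom",
    "strand",
    "tx_start",
    "tx_end",
    "cds_start",
    "cds_end",
    "exon_starts",
    "exon_ends",
]


class GeneTable:
    """Per-gene transcript structure.

    Backed by a DataFrame with columns gene_id, chrom, strand, tx_start,
    tx_end, cds_start, cds_end, exon_starts, exon_ends; the exon columns hold
    tuples of 0-based half-open coordinates. The TSS is the transcript start
    on the + strand and the transcript end − 1 on the − strand.
    """

    def __init__(self, df: pd.DataFrame) -> None:
        missing = set(_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"gene table missing columns: {sorted(missing)}")
        df = df.reset_index(drop=True).copy()
        for row in df.itertuples(index=False):
            starts, ends = row.exon_starts, row.exon_ends
            if len(starts) != len(ends) or len(starts) == 0:
                raise ValueError(f"{row.gene_id}: malformed exon lists")
            if min(starts) < row.tx_start or max(ends) > row.tx_end:
                raise ValueError(f"{row.gene_id}: exon outside transcript")
            prev_end = None
            for s, e in zip(starts, ends):
                if s >= e or (prev_end is not None and s < prev_end):
                    raise ValueError(f"{row.gene_id}: exons overlap or are unsorted")
                prev_end = e
        df["tss"] = np.where(df["strand"] == "+", df["tx_start"], df["tx_end"] - 1)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"GeneTable({len(self)} genes)"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.df["gene_id"])

    def introns(self, gene_id: str) -> list[tuple[int, int]]:
        row = self.df[self.df["gene_id"] == gene_id].iloc[0]
        return [
            (e, s)
            for e, s in zip(row.exon_ends[:-1], row.exon_starts[1:])
            if e < s
        ]


def read_gene_table(path: str | Path) -> GeneTable:
    """Read a refFlat-like TSV (header row; exon lists comma-separated)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("exon_starts", "exon_ends"):
        df[col] = df[col].apply(
            lambda s: tuple(int(x) for x in str(s).rstrip(",").split(","))
        )
    return GeneTable(df)


def write_gene_table(genes: GeneTable, path: str | Path) -> None:
    out = genes.df[_COLUMNS].copy()
    for col in ("exon_starts", "exon_ends"):
        out[col] = out[col].apply(lambda t: ",".join(str(x) for x in t))
    out.to_csv(path, sep="\t", index=False)
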