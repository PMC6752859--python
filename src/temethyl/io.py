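"""Reading and writing of the on-disk formats used by the pipeline.

FASTA goes through Biopython.  Annotations travel as GFF3 (1-based, closed
intervals on disk; converted to 0-based half-open in memory).  Per-cytosine
calls, tiles and truth tables are plain TSV.
"""

from __future__ import annotations

import urllib.parse
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CALL_COLUMNS = ["chrom", "pos", "strand", "context", "mc_count", "total_count"]

TE_GFF_ATTRS = ["family", "superfamily", "order", "nested"]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_gene_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    _write_gff3(genes, path, feature="gene", attr_cols=[])


def write_te_gff3(tes: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in TE_GFF_ATTRS if c in tes.columns]
    _write_gff3(tes, path, feature="transposable_element", attr_cols=cols)


def _write_gff3(df: pd.DataFrame, path: str | Path, feature: str, attr_cols) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in df.itertuples(index=False):
            attrs = [f"ID={urllib.parse.quote(str(row.id))}"]
            for col in attr_cols:
                val = getattr(row, col)
                if col == "nested":
                    val = "true" if bool(val) else "false"
                attrs.append(f"{col}={urllib.parse.quote(str(val))}")
            strand = getattr(row, "strand", "+") or "+"
            fh.write(
                "\t".join(
                    [
                        str(row.chrom),
                        "temethyl",
                        feature,
                        str(int(row.start) + 1),  # GFF3 is 1-based closed
                        str(int(row.end)),
                        ".",
                        strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read a GFF3 file into a 0-based half-open DataFrame.

    Recognised attributes (ID, family, superfamily, order, nested) become
    columns; everything else is ignored.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            row = {
                "chrom": parts[0],
                "start": int(parts[3]) - 1,
                "end": int(parts[4]),
                "strand": parts[6],
                "id": urllib.parse.unquote(attrs.get("ID", "")),
            }
            for col in TE_GFF_ATTRS:
                if col in attrs:
                    val = urllib.parse.unquote(attrs[col])
                    row[col] = (val == "true") if col == "nested" else val
            rows.append(row)
    return pd.DataFrame(rows)


def read_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"calls table missing columns: {sorted(missing)}")
    return df


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_bedgraph(
    tiles: pd.DataFrame, path: str | Path, context: str = "CG"
) -> None:
    """Write one context's tile ratios as bedGraph, skipping no-data tiles."""
    col = f"{context.lower()}_ratio"
    sub = tiles.dropna(subset=[col])
    sub[["chrom", "start", "end", col]].to_csv(
        path, sep="\t", index=False, header=False
    )
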