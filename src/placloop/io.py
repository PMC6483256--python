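"""Readers and writers for the plain-text formats the pipeline exchanges.

All tables are tab-delimited; genomic intervals follow the BED convention
(0-based, half-open). Floating-point columns are written with ``%.6g`` so
a write/read/write cycle is byte-stable.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .features import FEATURE_COLUMNS
from .pairs import AlignmentRecord, BIN_PAIR_COLUMNS

_FLOAT_FMT = "%.6g"


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path, value_column: bool = False) -> pd.DataFrame:
    """Read BED3 (chrom, start, end); BED4 with ``value_column``."""
    names = ["chrom", "start", "end"] + (["value"] if value_column else [])
    return pd.read_csv(
        path, sep="\t", header=None, comment="#", usecols=range(len(names)),
        names=names,
    )


def read_stranded_bed(path) -> pd.DataFrame:
    """Read BED6 keeping chrom, start, end, strand (e.g. motif calls)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=[0, 1, 2, 3, 4, 5],
    )
    return df[["chrom", "start", "end", "strand"]]


def write_bed(intervals: pd.DataFrame, path) -> None:
    intervals[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_features_tsv(features: pd.DataFrame, path) -> None:
    features[FEATURE_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_features_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    return df[FEATURE_COLUMNS]


def write_binpairs_tsv(bin_pairs: pd.DataFrame, path) -> None:
    bin_pairs[BIN_PAIR_COLUMNS].to_csv(path, sep="\t", index=False)


def read_binpairs_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")[BIN_PAIR_COLUMNS]


def write_normalized_tsv(normalized: pd.DataFrame, path) -> None:
    normalized.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_normalized_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_short_pairs_tsv(short_pairs: pd.DataFrame, path) -> None:
    short_pairs[["chrom", "pos1", "pos2", "strand1", "strand2"]].to_csv(
        path, sep="\t", index=False
    )


def read_short_pairs_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_alignment_table(path) -> list[AlignmentRecord]:
    """Read a tab-delimited alignment table: read_id, chrom, pos, strand, mapq."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["read_id", "chrom", "pos", "strand", "mapq"],
        dtype={"read_id": str, "chrom": str, "pos": int, "strand": str, "mapq": int},
    )
    return [AlignmentRecord(*row) for row in df.itertuples(index=False)]


def write_alignment_table(records, path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.read_id}\t{r.chrom}\t{r.pos}\t{r.strand}\t{r.mapq}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def read_triplets(path) -> pd.DataFrame:
    """Read a sparse contact-matrix triplet table: chrom, bin1, bin2, value."""
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "bin1", "bin2", "value"]
    )
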