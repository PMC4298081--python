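"""Readers and writers for the pipeline's plain-text interchange formats.

Everything is FASTA or tab-separated with a header row, 1-based
coordinates throughout.  Round-trips are exact for all tables.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sites import PILEUP_COLUMNS
from .markers import MARKER_COLUMNS


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(contigs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_pileup(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "ref": str})
    df["indel"] = df["indel"].astype(bool)
    return df[PILEUP_COLUMNS]


def write_pileup(pileup: pd.DataFrame, path) -> None:
    out = pileup.copy()
    out["indel"] = out["indel"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"contig": str})


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_boundaries(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    return {c: sorted(sub["pos"].astype(int)) for c, sub in df.groupby("contig")}


def read_markers(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    df["pos"] = df["pos"].astype(int)
    return df


def write_markers(markers: pd.DataFrame, path) -> None:
    cols = [c for c in MARKER_COLUMNS if c in markers.columns]
    extra = [c for c in ("n_shared", "shared_with", "triallelic", "redundancy_status")
             if c in markers.columns]
    markers[cols + extra].to_csv(path, sep="\t", index=False)


def write_genotype_long(genotypes: pd.DataFrame, path) -> None:
    """Marker x hybrid matrix to the long `marker hybrid call` layout."""
    long = genotypes.stack().rename("call").rename_axis(["marker", "hybrid"]).reset_index()
    long.to_csv(path, sep="\t", index=False)


def read_genotype_long(path) -> pd.DataFrame:
    long = pd.read_csv(path, sep="\t", dtype=str)
    wide = long.pivot(index="marker", columns="hybrid", values="call")
    wide.index.name = None
    wide.columns.name = None
    return wide.fillna("NA")
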