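"""Genome anchoring of markers and marker-density summaries.

Markers designed on transcriptome contigs are placed on a genome either
by the built-in exact-match anchorer (adequate for synthetic/desk-scale
genomes) or by loading a coordinate table produced by an external
aligner.  In both routes the alignment start of the 101-mer is corrected
by +50 to the SNP base itself, which sits at the centre of the query, so
the correction is strand-independent.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ANCHOR_COLUMNS = ["marker", "scaffold", "snp_pos", "strand", "placement"]

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _find_all(haystack: str, needle: str) -> list:
    hits, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def anchor_markers(
    markers: pd.DataFrame,
    genome: Mapping[str, str],
    unplaced_scaffolds: Iterable[str] = (),
    alt_fallback: bool = True,
) -> pd.DataFrame:
    """Exact-match anchoring of marker 101-mers against a genome.

    The query is ``left_flank + ref + right_flank`` searched on both
    strands of every scaffold; a unique hit places the marker with
    ``snp_pos = hit_start + 50`` (1-based).  Zero hits are retried with
    the alternate allele at the centre when ``alt_fallback`` is set —
    useful when the genome carries the donor state.  Markers hitting a
    scaffold named in ``unplaced_scaffolds`` are tallied separately.
    Outcomes: placed / unplaced_scaffold / unanchored / multi_hit.
    """
    unplaced = set(unplaced_scaffolds)
    rows = []
    for rec in markers.to_dict("records"):
        queries = [rec["left_flank"] + rec["ref"] + rec["right_flank"]]
        if alt_fallback:
            queries.append(rec["left_flank"] + rec["alt"] + rec["right_flank"])
        hits = []
        for qi, q in enumerate(queries):
            q = q.upper()
            rc = revcomp(q)
            for scaf, seq in genome.items():
                for start0 in _find_all(seq, q):
                    hits.append((scaf, start0, "+"))
                for start0 in _find_all(seq, rc):
                    hits.append((scaf, start0, "-"))
            if hits:
                break  # alt allele tried only when the ref query fails
        if not hits:
            rows.append({"marker": rec["id"], "scaffold": None, "snp_pos": -1,
                         "strand": ".", "placement": "unanchored"})
        elif len(hits) > 1:
            rows.append({"marker": rec["id"], "scaffold": None, "snp_pos": -1,
                         "strand": ".", "placement": "multi_hit"})
        else:
            scaf, start0, strand = hits[0]
            placement = "unplaced_scaffold" if scaf in unplaced else "placed"
            rows.append({"marker": rec["id"], "scaffold": scaf,
                         "snp_pos": start0 + 51, "strand": strand,
                         "placement": placement})
    out = pd.DataFrame(rows, columns=ANCHOR_COLUMNS)
    if "species" in markers.columns:
        out["species"] = markers["species"].to_numpy()
    return out


def load_anchor_table(
    table: pd.DataFrame,
    scaffold_lengths: Mapping[str, int],
    flank: int = 50,
    unplaced_scaffolds: Iterable[str] = (),
) -> pd.DataFrame:
    """Build anchors from an external aligner's coordinate table.

    ``table`` columns: ``marker_id scaffold align_start strand`` with
    1-based alignment starts of the full 101-mer.  The SNP position is
    ``align_start + flank``; bounds are validated against
    ``scaffold_lengths``; markers with several rows become multi_hit.
    """
    unplaced = set(unplaced_scaffolds)
    rows = []
    for mid, sub in table.groupby("marker_id", sort=False):
        if len(sub) > 1:
            rows.append({"marker": mid, "scaffold": None, "snp_pos": -1,
                         "strand": ".", "placement": "multi_hit"})
            continue
        rec = sub.iloc[0]
        scaf = rec["scaffold"]
        if scaf not in scaffold_lengths:
            raise ValueError(f"unknown scaffold {scaf!r} for marker {mid}")
        snp_pos = int(rec["align_start"]) + flank
        if not 1 <= snp_pos <= scaffold_lengths[scaf]:
            raise ValueError(
                f"marker {mid}: SNP position {snp_pos} outside scaffold {scaf}"
            )
        placement = "unplaced_scaffold" if scaf in unplaced else "placed"
        rows.append({"marker": mid, "scaffold": scaf, "snp_pos": snp_pos,
                     "strand": rec["strand"], "placement": placement})
    return pd.DataFrame(rows, columns=ANCHOR_COLUMNS)


def placement_summary(anchors: pd.DataFrame, ndigits: int = 2) -> dict:
    """Placement tallies plus the percent of markers anchored uniquely."""
    counts = anchors["placement"].value_counts().to_dict()
    total = len(anchors)
    placed = counts.get("placed", 0)
    return {
        "total": total,
        "placed": placed,
        "unplaced_scaffold": counts.get("unplaced_scaffold", 0),
        "unanchored": counts.get("unanchored", 0),
        "multi_hit": counts.get("multi_hit", 0),
        "percent_placed": round(100.0 * placed / total, ndigits) if total else None,
    }


def window_density(
    anchors: pd.DataFrame,
    scaffold_lengths: Mapping[str, int],
    window: int = 1_000_000,
    step: int = 100_000,
) -> pd.DataFrame:
    """Sliding-window marker density per scaffold.

    Density in a window is the number of placed markers (of one species,
    if a ``species`` column is present) falling in the window divided by
    the species' total placed markers — so densities over disjoint
    windows (step == window) partition to 1.
    """
    if window < step:
        raise ValueError("window must be >= step")
    placed = anchors[anchors["placement"] == "placed"]
    species_groups = (
        placed.groupby("species") if "species" in placed.columns else [(None, placed)]
    )
    rows = []
    for sp, sub in species_groups:
        n_total = len(sub)
        if n_total == 0:
            warnings.warn(f"no placed markers for species {sp!r}; empty density series")
            continue
        for scaf, length in scaffold_lengths.items():
            pos = sub.loc[sub["scaffold"] == scaf, "snp_pos"].to_numpy()
            start = 1
            while start <= length:
                end = min(start + window - 1, length)
                n_in = int(((pos >= start) & (pos <= end)).sum())
                rows.append({"scaffold": scaf, "window_start": start,
                             "window_end": end, "density": n_in / n_total,
                             "species": sp})
                start += step
    return pd.DataFrame(rows, columns=["scaffold", "window_start", "window_end", "density", "species"])
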