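"""Marker design: flanking-sequence extraction and Class I/II/III assignment.

A genotyping assay (e.g. KASP) needs the SNP plus 50 bp of flanking
sequence on each side.  Markers are classified per species from the
polymorphism context of their contig:

* Class I — the only SNP called on the contig for that species,
* Class II — other same-species SNPs on the contig, all > 50 bp away,
* Class III — another same-species SNP within 50 bp (flank overlap;
  such markers assay poorly).

Classification is recomputed from the full post-filter candidate set of a
species — including candidates later dropped for short flanks or
redundancy — never from a cached subset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MARKER_COLUMNS = [
    "id", "species", "contig", "pos", "ref", "alt",
    "snp_class", "left_flank", "right_flank",
]


@dataclass(frozen=True)
class Marker:
    id: str
    species: str
    contig: str
    pos: int
    ref: str
    alt: str
    left_flank: str
    right_flank: str
    snp_class: str = "I"

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"marker {self.id}: ref and alt alleles are identical")


def classify_contig_markers(positions: Sequence[int], window: int = 50) -> list:
    """Assign Class I/II/III to each SNP position of one species on one contig.

    Returns a list of class labels aligned with ``positions``.
    """
    pos = np.asarray(positions)
    n = len(pos)
    if n == 0:
        return []
    if n == 1:
        return ["I"]
    dist = np.abs(pos[:, None] - pos[None, :]).astype(float)
    np.fill_diagonal(dist, np.inf)
    near = dist.min(axis=1) <= window
    return ["III" if flag else "II" for flag in near]


def classify_candidates(candidates: pd.DataFrame, window: int = 50) -> pd.DataFrame:
    """Add a ``snp_class`` column, classifying per (species, contig)."""
    out = candidates.copy()
    out["snp_class"] = pd.Series(dtype=object)
    for (_, _), sub in out.groupby(["species", "contig"], sort=False):
        out.loc[sub.index, "snp_class"] = classify_contig_markers(
            sub["pos"].to_list(), window=window
        )
    return out


def extract_marker(
    candidate: Mapping, contigs: Mapping[str, str], flank: int = 50
) -> Marker | None:
    """Build a named marker with ``flank``-bp flanks, or None if too close
    to a contig end for full-length flanks.

    Raises if the position falls outside the contig or the assembly base
    disagrees with the candidate's reference allele.
    """
    contig = candidate["contig"]
    pos = int(candidate["pos"])
    seq = contigs[contig]
    if not 1 <= pos <= len(seq):
        raise ValueError(f"position {pos} outside contig {contig} (length {len(seq)})")
    if seq[pos - 1] != candidate["ref"]:
        raise ValueError(
            f"assembly base {seq[pos - 1]} != candidate ref {candidate['ref']} at {contig}:{pos}"
        )
    if pos - 1 < flank or len(seq) - pos < flank:
        return None
    return Marker(
        id=f"{contig}_{pos}",
        species=candidate["species"],
        contig=contig,
        pos=pos,
        ref=candidate["ref"],
        alt=candidate["alt"],
        left_flank=seq[pos - 1 - flank: pos - 1],
        right_flank=seq[pos: pos + flank],
        snp_class=candidate.get("snp_class", "I"),
    )


def extract_markers(
    candidates: pd.DataFrame, contigs: Mapping[str, str], flank: int = 50
) -> tuple[pd.DataFrame, int]:
    """Vector version of :func:`extract_marker` over a candidate table.

    Returns the marker table and the number of candidates excluded for
    short flanks.  Candidates should already carry ``snp_class`` (see
    :func:`classify_candidates`); missing classes default to "I".
    """
    rows, excluded = [], 0
    for rec in candidates.to_dict("records"):
        m = extract_marker(rec, contigs, flank=flank)
        if m is None:
            excluded += 1
        else:
            rows.append(
                {
                    "id": m.id, "species": m.species, "contig": m.contig,
                    "pos": m.pos, "ref": m.ref, "alt": m.alt,
                    "snp_class": m.snp_class,
                    "left_flank": m.left_flank, "right_flank": m.right_flank,
                }
            )
    if not rows:
        return pd.DataFrame(columns=MARKER_COLUMNS), excluded
    return pd.DataFrame(rows)[MARKER_COLUMNS], excluded
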