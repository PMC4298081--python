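"""Pileup-level interspecific SNP candidate calling.

Discovering allele-SNPs between a donor *Gossypium* species and the
allotetraploid *G. hirsutum* reference transcriptome is complicated by
collapsed homeologous gene copies: a site where the A- and D-subgenome
copies differ looks like a SNP in any read pileup (a "homeo-SNP") but is
useless as an interspecific marker.  The cascade implemented here turns
per-site pileup summaries into candidate allele-SNPs:

1. :func:`filter_sites` — drop indel-flagged records and shallow sites,
2. :func:`call_candidates` — call a candidate where the donor pileup is
   effectively homozygous for a base that differs from the assembly base,
3. :func:`filter_intron_proximity` — drop candidates near predicted
   intron–exon boundaries (flanking primers would span the junction),
4. :func:`apply_homeo_mask` — drop positions that already look
   heterozygous when the reference accession's own reads are mapped back
   to the assembly (:func:`build_homeo_mask`).

All tabular data are pandas DataFrames with 1-based inclusive
coordinates.  A pileup frame has columns
``contig pos ref depth A C G T indel``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")

PILEUP_COLUMNS = ["contig", "pos", "ref", "depth", "A", "C", "G", "T", "indel"]

#: candidate table columns; ``depth`` is the site depth, ``alt_depth`` the
#: count of the called alternate base
CANDIDATE_COLUMNS = [
    "species", "contig", "pos", "ref", "alt", "depth", "alt_depth", "purity",
]


@dataclass(frozen=True)
class SiteObservation:
    """A single pileup position (record-level view of one pileup row)."""

    contig: str
    pos: int
    ref: str
    depth: int
    base_counts: Mapping[str, int]
    indel: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos} on {self.contig}")
        if self.ref not in BASES:
            raise ValueError(f"unknown reference base {self.ref!r} at {self.contig}:{self.pos}")

    def to_row(self) -> dict:
        row = {"contig": self.contig, "pos": self.pos, "ref": self.ref,
               "depth": self.depth, "indel": self.indel}
        for b in BASES:
            row[b] = int(self.base_counts.get(b, 0))
        return row


def sites_to_frame(sites: Iterable[SiteObservation]) -> pd.DataFrame:
    rows = [s.to_row() for s in sites]
    if not rows:
        return pd.DataFrame(columns=PILEUP_COLUMNS)
    return pd.DataFrame(rows)[PILEUP_COLUMNS]


@dataclass
class HomeoMask:
    """Positions that behave like homeo-SNPs on the reference self-remap.

    ``entries`` is a set of ``(contig, pos)`` pairs; the thresholds used to
    build the mask are kept for provenance.
    """

    entries: set = field(default_factory=set)
    minor_frac: float = 0.2
    min_depth: int = 3

    def __contains__(self, key) -> bool:
        return tuple(key) in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def _validate_pileup(pileup: pd.DataFrame) -> None:
    if pileup.empty:
        return
    bad_pos = pileup["pos"] < 1
    if bad_pos.any():
        row = pileup[bad_pos].iloc[0]
        raise ValueError(f"malformed pileup record: pos {row['pos']} < 1 on {row['contig']}")
    bad_ref = ~pileup["ref"].isin(BASES)
    if bad_ref.any():
        row = pileup[bad_ref].iloc[0]
        raise ValueError(
            f"malformed pileup record: unknown base {row['ref']!r} at {row['contig']}:{row['pos']}"
        )


def filter_sites(pileup: pd.DataFrame, min_depth: int = 3) -> pd.DataFrame:
    """Drop indel-flagged records and records below ``min_depth`` coverage.

    Input order is preserved; records are validated (1-based positions,
    A/C/G/T reference base) before filtering.
    """
    _validate_pileup(pileup)
    if pileup.empty:
        return pileup.copy()
    keep = (~pileup["indel"].astype(bool)) & (pileup["depth"] >= min_depth)
    return pileup[keep].copy()


def build_homeo_mask(
    self_pileup: pd.DataFrame, minor_frac: float = 0.2, min_depth: int = 3
) -> HomeoMask:
    """Index putative homeo-SNP positions from the reference self-remap.

    A site is masked when its depth is at least ``min_depth`` and its
    second-most-frequent base reaches a frequency of at least
    ``minor_frac`` — the signature of two collapsed homeologous copies
    segregating reads roughly 50/50.
    """
    _validate_pileup(self_pileup)
    mask = HomeoMask(minor_frac=minor_frac, min_depth=min_depth)
    if self_pileup.empty:
        return mask
    deep = self_pileup[self_pileup["depth"] >= min_depth]
    if deep.empty:
        return mask
    counts = deep[list(BASES)].to_numpy(dtype=float)
    second = np.sort(counts, axis=1)[:, -2]
    depth = deep["depth"].to_numpy(dtype=float)
    hit = second / depth >= minor_frac
    mask.entries = set(zip(deep["contig"].to_numpy()[hit], deep["pos"].to_numpy()[hit]))
    return mask


def call_candidates(
    pileup: pd.DataFrame,
    species: str,
    min_depth: int = 10,
    purity: float = 0.9,
) -> pd.DataFrame:
    """Call homozygous-difference SNP candidates from a filtered pileup.

    A candidate is emitted where depth >= ``min_depth``, the modal base
    differs from the assembly base, and the modal base accounts for at
    least ``purity`` of the depth (the operational reading of
    "homozygous for a different base").  Sites where two non-reference
    bases split the reads (neither reaching ``purity``) yield nothing.
    """
    _validate_pileup(pileup)
    if pileup.empty:
        return pd.DataFrame(columns=CANDIDATE_COLUMNS)
    deep = pileup[pileup["depth"] >= min_depth]
    if deep.empty:
        return pd.DataFrame(columns=CANDIDATE_COLUMNS)
    counts = deep[list(BASES)].to_numpy(dtype=float)
    modal_idx = np.argmax(counts, axis=1)  # ties break A<C<G<T; purity guards them
    modal_count = counts[np.arange(len(deep)), modal_idx]
    modal_base = np.array(BASES)[modal_idx]
    depth = deep["depth"].to_numpy(dtype=float)
    frac = modal_count / depth
    hit = (modal_base != deep["ref"].to_numpy()) & (frac >= purity)
    out = pd.DataFrame(
        {
            "species": species,
            "contig": deep["contig"].to_numpy()[hit],
            "pos": deep["pos"].to_numpy()[hit],
            "ref": deep["ref"].to_numpy()[hit],
            "alt": modal_base[hit],
            "depth": deep["depth"].to_numpy()[hit],
            "alt_depth": modal_count[hit].astype(int),
            "purity": frac[hit],
        }
    )
    return out.reset_index(drop=True)


def filter_intron_proximity(
    candidates: pd.DataFrame,
    boundaries: Mapping[str, Iterable[int]],
    window: int = 50,
) -> pd.DataFrame:
    """Remove candidates within ``window`` bp of an intron–exon boundary.

    ``boundaries`` maps contig id to 1-based boundary positions on that
    contig; "within" is inclusive (distance <= window removes).
    """
    if candidates.empty:
        return candidates.copy()
    keep = np.ones(len(candidates), dtype=bool)
    pos = candidates["pos"].to_numpy()
    for contig, sub in candidates.groupby("contig", sort=False):
        bpos = np.asarray(list(boundaries.get(contig, ())), dtype=float)
        if bpos.size == 0:
            continue
        idx = candidates.index.get_indexer(sub.index)
        dist = np.abs(pos[idx][:, None] - bpos[None, :]).min(axis=1)
        keep[idx] = dist > window
    return candidates[keep].copy()


def apply_homeo_mask(candidates: pd.DataFrame, mask: HomeoMask) -> pd.DataFrame:
    """Remove candidates whose ``(contig, pos)`` is a masked homeo-SNP site."""
    if candidates.empty or len(mask) == 0:
        return candidates.copy()
    keys = list(zip(candidates["contig"], candidates["pos"]))
    keep = [k not in mask.entries for k in keys]
    return candidates[keep].copy()
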