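"""Redundancy removal across marker sets and summary accounting.

Identical markers (same 50-bp flanks, same allele pair) arise from
paralogous or homeologous gene copies and from the same locus being
polymorphic in several donor species.  They are handled in three stages:

1. removal of markers already present in an intraspecific reference set
   (exact identity over the full 101-mer plus allele pair),
2. within-species partition: keys seen from more than one contig of the
   same species move wholly to an "overlap" set (they cannot be assigned
   a unique locus),
3. cross-species deduplication by a fixed species hierarchy, keeping the
   record in the highest-ranked species and annotating it with how many
   and which species share it.

The module also carries the transition/transversion tally and the
Table-style accounting arithmetic used in the run report.
"""

from __future__ import annotations

from collections import namedtuple
from typing import Iterable, Mapping

import pandas as pd

#: default donor-species hierarchy, highest priority first:
#: G. barbadense, G. tomentosum, G. mustelinum, G. armourianum, G. longicalyx
DEFAULT_HIERARCHY = ["Gb", "Gt", "Gm", "Ga", "Gl"]

# IUPAC degenerate code for an unordered base pair
_IUPAC = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("AC"): "M",
    frozenset("GT"): "K", frozenset("CG"): "S", frozenset("AT"): "W",
}

TsTv = namedtuple("TsTv", "n_transitions n_transversions ratio")
NsS = namedtuple("NsS", "n_nonsyn n_syn ratio")

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def marker_key(left_flank: str, ref: str, alt: str, right_flank: str) -> str:
    """Canonical 101-mer: flanks around the IUPAC code of the allele pair.

    Two markers are redundant iff their keys are equal — this encodes
    "100% identity over 100% length" plus an equal (unordered) allele
    pair.  No reverse-complement matching: transcriptome strand is fixed
    by the assembly.
    """
    pair = frozenset((ref, alt))
    if pair not in _IUPAC:
        raise ValueError(f"invalid allele pair {ref}/{alt}")
    return f"{left_flank}{_IUPAC[pair]}{right_flank}".upper()


def add_keys(markers: pd.DataFrame) -> pd.DataFrame:
    """Attach ``key`` (allele-aware) and ``locus_key`` (allele-blind) columns."""
    out = markers.copy()
    if out.empty:
        out["key"] = pd.Series(dtype=object)
        out["locus_key"] = pd.Series(dtype=object)
        return out
    out["key"] = [
        marker_key(l, r, a, rt)
        for l, r, a, rt in zip(out["left_flank"], out["ref"], out["alt"], out["right_flank"])
    ]
    out["locus_key"] = (out["left_flank"] + "N" + out["right_flank"]).str.upper()
    return out


def dedup_against_reference(
    markers: pd.DataFrame, reference: pd.DataFrame | Iterable[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split markers into (kept, removed-vs-reference) by exact key identity."""
    markers = add_keys(markers) if "key" not in markers else markers.copy()
    if isinstance(reference, pd.DataFrame):
        ref_keys = set(add_keys(reference)["key"]) if "key" not in reference else set(reference["key"])
    else:
        ref_keys = set(reference)
    hit = markers["key"].isin(ref_keys)
    removed = markers[hit].copy()
    removed["redundancy_status"] = "removed_vs_reference"
    kept = markers[~hit].copy()
    return kept, removed


def within_species_partition(markers: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition one species' markers into (unique, overlap) sets.

    Keys occurring two or more times — identical marker sequence derived
    from different contigs — go *wholly* to the overlap set; no
    representative is retained.
    """
    markers = add_keys(markers) if "key" not in markers else markers.copy()
    if markers.empty:
        return markers.copy(), markers.copy()
    dup = markers["key"].duplicated(keep=False)
    overlap = markers[dup].copy()
    overlap["redundancy_status"] = "within_species_overlap"
    unique = markers[~dup].copy()
    return unique, overlap


def cross_species_dedup(
    species_sets: Mapping[str, pd.DataFrame],
    hierarchy: Iterable[str] = DEFAULT_HIERARCHY,
) -> tuple[dict, pd.DataFrame, dict]:
    """Hierarchical cross-species deduplication with sharing annotations.

    For every key present in k species, the record is kept only in the
    highest-ranked species, annotated with ``n_shared=k`` and the ordered
    ``shared_with`` species string; lower-ranked copies are returned in
    the removed table.  Keys whose allele pair differs between species
    (same flanks, different alternate base) are triallelic: every record
    is retained in its species set, flagged, and excluded from the Venn
    tallies and from any shared-across-all-species analysis.

    Returns ``(kept_sets, removed, venn)`` where ``venn`` maps a
    hierarchy-ordered species tuple to its count of shared keys.
    """
    hierarchy = list(hierarchy)
    rank = {sp: i for i, sp in enumerate(hierarchy)}
    unknown = [sp for sp in species_sets if sp not in rank]
    if unknown:
        raise ValueError(f"species not in hierarchy: {unknown}")

    frames = []
    for sp in hierarchy:
        if sp in species_sets:
            df = species_sets[sp]
            frames.append(add_keys(df) if "key" not in df else df.copy())
    if not frames:
        return {}, pd.DataFrame(), {}
    pool = pd.concat(frames, ignore_index=True)
    pool = pool.sort_values(
        ["key", "species", "contig", "pos"],
        key=lambda s: s.map(rank) if s.name == "species" else s,
    ).reset_index(drop=True)

    # triallelic: one locus (flank context), >1 distinct allele-aware key
    tri_loci = {
        lk for lk, sub in pool.groupby("locus_key", sort=False) if sub["key"].nunique() > 1
    }
    pool["triallelic"] = pool["locus_key"].isin(tri_loci)

    keep_rows, removed_rows, venn = [], [], {}
    for key, sub in pool.groupby("key", sort=False):
        species_here = sorted(set(sub["species"]), key=rank.get)
        n_shared = len(species_here)
        shared_str = "".join(species_here)
        sub = sub.assign(n_shared=n_shared, shared_with=shared_str)
        if sub["triallelic"].iloc[0]:
            # retained everywhere, no cross-species removal
            keep_rows.append(sub.assign(redundancy_status="unique"))
            continue
        venn[tuple(species_here)] = venn.get(tuple(species_here), 0) + 1
        top = species_here[0]
        keep_rows.append(sub[sub["species"] == top].assign(redundancy_status="unique"))
        rm = sub[sub["species"] != top]
        if not rm.empty:
            removed_rows.append(rm.assign(redundancy_status="removed_cross_species"))

    kept = pd.concat(keep_rows, ignore_index=True)
    removed = (
        pd.concat(removed_rows, ignore_index=True)
        if removed_rows
        else pool.iloc[0:0].assign(n_shared=0, shared_with="", redundancy_status="")
    )
    kept_sets = {}
    for sp in hierarchy:
        if sp in species_sets:
            kept_sets[sp] = (
                kept[kept["species"] == sp]
                .sort_values(["contig", "pos"])
                .reset_index(drop=True)
            )
    return kept_sets, removed.sort_values(["contig", "pos"]).reset_index(drop=True), venn


def ts_tv_ratio(markers) -> TsTv:
    """Count transitions (A<->G, C<->T) vs transversions over allele pairs.

    ``markers`` may be a DataFrame with ``ref``/``alt`` columns or an
    iterable of (ref, alt) pairs.  The ratio is reported to 2 dp; if
    there are no transversions it is None (undefined).
    """
    if isinstance(markers, pd.DataFrame):
        pairs = zip(markers["ref"], markers["alt"])
    else:
        pairs = iter(markers)
    ts = tv = 0
    for ref, alt in pairs:
        if frozenset((ref, alt)) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    ratio = round(ts / tv, 2) if tv else None
    return TsTv(ts, tv, ratio)


def accounting_summary(class_counts: Mapping[str, Mapping[str, int]]) -> pd.DataFrame:
    """Per-species Class I/II/III (+ overlap) accounting with grand totals.

    ``class_counts`` maps species to a dict with keys among
    ``{"I", "II", "III", "overlap"}``.  The returned frame carries per-row
    ``class_i_ii`` and ``total`` columns and a final ``ALL`` row of column
    sums — the row/column arithmetic of the published accounting tables.
    """
    rows = []
    for sp, c in class_counts.items():
        i, ii, iii = int(c.get("I", 0)), int(c.get("II", 0)), int(c.get("III", 0))
        ov = int(c.get("overlap", 0))
        rows.append(
            {"species": sp, "class_i": i, "class_ii": ii, "class_iii": iii,
             "overlap": ov, "class_i_ii": i + ii, "total": i + ii + iii + ov}
        )
    table = pd.DataFrame(rows).set_index("species")
    table.loc["ALL"] = table.sum()
    return table
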