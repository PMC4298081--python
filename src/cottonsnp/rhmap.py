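"""Wide-cross whole-genome radiation hybrid (WWRH) deletion bin mapping.

An irradiated-pollen F1 panel carries random chromosomal deletions; a
marker's deletion is read out as a genotype shift from the expected F1
heterozygote to the homozygote of the non-irradiated parent's cluster
being lost (the "deletion genotype").  Co-deletion of two markers across
hybrids measures their physical proximity.

The two-point model is the standard equal-retention RH likelihood: with
retention probability ``r`` per marker and breakage probability ``theta``
between two markers, the per-hybrid cell probabilities (1 = retained) are

    P11 = (1-theta) r + theta r^2
    P10 = P01 = theta r (1-r)
    P00 = (1-theta)(1-r) + theta (1-r)^2

with closed-form maximum-likelihood estimates
``r_hat = (2 n11 + n10 + n01) / 2N`` and
``theta_hat = (n10 + n01) / (2 N r_hat (1-r_hat))`` clipped to [0, 1],
LOD against the unlinked model (theta = 1), and distance in centiRays
``-100 ln(1-theta_hat)``.

Marker order within a syntenic group is advisory only (panels of this
size rarely resolve it); groups are reported as bins of markers with
indistinguishable deletion patterns, ordered second.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

GENOTYPES = ("HET", "HOM_REF", "HOM_DONOR", "NA")

LINK_COLUMNS = ["a", "b", "n11", "n10", "n01", "n00", "r", "theta", "lod", "cR"]


@dataclass(frozen=True)
class PairLink:
    marker_a: str
    marker_b: str
    n11: int
    n10: int
    n01: int
    n00: int
    r_hat: float
    theta_hat: float
    lod: float
    distance_cR: float


def call_deletions(
    genotypes: pd.DataFrame, deletion_genotype: str = "HOM_DONOR"
) -> tuple[pd.DataFrame, dict]:
    """Translate a marker x hybrid genotype matrix into deletion indicators.

    HET -> 0 (no deletion), ``deletion_genotype`` -> 1, NA -> missing.
    The *opposite* homozygote is biologically unexpected in this cross
    and is treated as missing, with a per-marker warning count returned.
    Markers scored in no hybrid are dropped with a warning.
    """
    if deletion_genotype not in ("HOM_DONOR", "HOM_REF"):
        raise ValueError(f"deletion_genotype must be a homozygote code, got {deletion_genotype}")
    unexpected = "HOM_REF" if deletion_genotype == "HOM_DONOR" else "HOM_DONOR"
    values = genotypes.to_numpy(dtype=object)
    known = np.isin(values, GENOTYPES)
    if not known.all():
        bad = values[~known][0]
        raise ValueError(f"unknown genotype code {bad!r}")
    out = np.full(values.shape, np.nan)
    out[values == "HET"] = 0.0
    out[values == deletion_genotype] = 1.0
    mat = pd.DataFrame(out, index=genotypes.index, columns=genotypes.columns)
    warn_counts = {
        m: int(n) for m, n in zip(genotypes.index, (values == unexpected).sum(axis=1)) if n
    }
    all_na = mat.isna().all(axis=1)
    if all_na.any():
        warnings.warn(f"dropping {int(all_na.sum())} marker(s) with no scored hybrid")
        mat = mat[~all_na]
    return mat, warn_counts


def prune_markers(matrix: pd.DataFrame) -> pd.DataFrame:
    """Drop markers that are uninformative for mapping.

    Markers with no deletion among the scored hybrids carry no linkage
    signal and are removed; markers deleted in *every* scored hybrid are
    pathological (likely assay failure) and removed with a warning.
    """
    n_del = matrix.sum(axis=1, skipna=True)
    n_scored = matrix.notna().sum(axis=1)
    all_ones = (n_del == n_scored) & (n_scored > 0)
    if all_ones.any():
        warnings.warn(
            f"removing {int(all_ones.sum())} marker(s) deleted in every scored hybrid"
        )
    keep = (n_del > 0) & ~all_ones
    return matrix[keep]


def _cell_logprob(n11, n1001, n00, theta, r):
    """Log10-likelihood of pooled counts under (theta, r)."""
    p11 = (1 - theta) * r + theta * r * r
    p10 = theta * r * (1 - r)
    p00 = (1 - theta) * (1 - r) + theta * (1 - r) * (1 - r)
    ll = 0.0
    for n, p in ((n11, p11), (n1001, p10), (n00, p00)):
        if n:
            if p <= 0:
                return -math.inf
            ll += n * math.log10(p)
    return ll


def link_from_counts(
    marker_a: str, marker_b: str, n11: int, n10: int, n01: int, n00: int
) -> PairLink | None:
    """Two-point estimates from a complete-pair 2x2 retention table.

    Returns None (undefined link) when the pooled retention fraction is
    0 or 1, in which case theta cannot be estimated.
    """
    N = n11 + n10 + n01 + n00
    if N == 0:
        raise ValueError(f"no pairwise-complete hybrid for {marker_a}/{marker_b}")
    r_hat = (2 * n11 + n10 + n01) / (2 * N)
    if r_hat in (0.0, 1.0):
        log.info("link %s/%s undefined: retention fraction %s", marker_a, marker_b, r_hat)
        return None
    theta_hat = (n10 + n01) / (2 * N * r_hat * (1 - r_hat))
    theta_hat = min(1.0, max(0.0, theta_hat))
    lod = _cell_logprob(n11, n10 + n01, n00, theta_hat, r_hat) - _cell_logprob(
        n11, n10 + n01, n00, 1.0, r_hat
    )
    lod = max(lod, 0.0)
    dist = math.inf if theta_hat >= 1.0 else -100.0 * math.log(1.0 - theta_hat)
    return PairLink(marker_a, marker_b, n11, n10, n01, n00, r_hat, theta_hat, lod, dist)


def two_point_link(marker_a: str, marker_b: str, matrix: pd.DataFrame) -> PairLink | None:
    """Two-point link between two markers of a deletion matrix.

    Counting is pairwise-complete: hybrids missing either marker are
    ignored.  Counts are in *retention* space (1 = not deleted).
    """
    a = matrix.loc[marker_a].to_numpy(dtype=float)
    b = matrix.loc[marker_b].to_numpy(dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    ra, rb = 1 - a[ok], 1 - b[ok]
    n11 = int(np.sum((ra == 1) & (rb == 1)))
    n10 = int(np.sum((ra == 1) & (rb == 0)))
    n01 = int(np.sum((ra == 0) & (rb == 1)))
    n00 = int(np.sum((ra == 0) & (rb == 0)))
    return link_from_counts(marker_a, marker_b, n11, n10, n01, n00)


def pairwise_links(matrix: pd.DataFrame) -> pd.DataFrame:
    """All-pairs two-point links, vectorised over the deletion matrix.

    Undefined links (pooled retention 0 or 1) are omitted.  Symmetric:
    each unordered pair appears once, a < b in index order.
    """
    markers = list(matrix.index)
    vals = matrix.to_numpy(dtype=float)
    scored = ~np.isnan(vals)
    R = np.where(scored, 1.0 - vals, 0.0)  # retained indicator
    D = np.where(scored, vals, 0.0)        # deleted indicator
    n11 = R @ R.T
    n10 = R @ D.T
    n01 = D @ R.T
    n00 = D @ D.T
    N = (scored.astype(float) @ scored.astype(float).T)
    rows = []
    for i, j in itertools.combinations(range(len(markers)), 2):
        if N[i, j] == 0:
            continue
        link = link_from_counts(
            markers[i], markers[j],
            int(n11[i, j]), int(n10[i, j]), int(n01[i, j]), int(n00[i, j]),
        )
        if link is None:
            continue
        rows.append(
            {"a": link.marker_a, "b": link.marker_b, "n11": link.n11,
             "n10": link.n10, "n01": link.n01, "n00": link.n00,
             "r": link.r_hat, "theta": link.theta_hat,
             "lod": link.lod, "cR": link.distance_cR}
        )
    return pd.DataFrame(rows, columns=LINK_COLUMNS)


def build_groups(
    links: pd.DataFrame,
    markers: Iterable[str],
    lod_min: float = 3.0,
    max_cr: float = 100.0,
) -> tuple[list, list]:
    """Single-linkage syntenic grouping at LOD >= lod_min and <= max_cr.

    Transitive closure over significant pairs; markers joined by no
    significant pair fall out as singletons.  Returns (groups,
    singletons) with groups as sorted marker lists.
    """
    g = nx.Graph()
    g.add_nodes_from(markers)
    sig = links[(links["lod"] >= lod_min) & (links["cR"] <= max_cr)]
    g.add_edges_from(zip(sig["a"], sig["b"]))
    groups, singles = [], []
    for comp in nx.connected_components(g):
        if len(comp) > 1:
            groups.append(sorted(comp))
        else:
            singles.extend(comp)
    groups.sort(key=lambda grp: grp[0])
    return groups, sorted(singles)


def _compatible(a: np.ndarray, b: np.ndarray) -> bool:
    ok = ~np.isnan(a) & ~np.isnan(b)
    return bool(np.all(a[ok] == b[ok]))


def bin_group(group: Iterable[str], matrix: pd.DataFrame) -> list:
    """Partition a syntenic group into bins of indistinguishable markers.

    Markers land in one bin when their deletion values agree on every
    mutually scored hybrid (missing cells are wildcards).  Assignment is
    greedy over markers in sorted order against all current members of a
    bin, so the partition is independent of input order.
    """
    bins: list[list[str]] = []
    for m in sorted(group):
        row = matrix.loc[m].to_numpy(dtype=float)
        for b in bins:
            if all(_compatible(row, matrix.loc[other].to_numpy(dtype=float)) for other in b):
                b.append(m)
                break
        else:
            bins.append([m])
    return bins


def obligate_breaks(order: Iterable[str], matrix: pd.DataFrame) -> int:
    """Total obligate chromosome breaks implied by a marker order.

    Per hybrid, the sequence of scored deletion states along the order is
    walked and every state change counted; missing cells are skipped.
    """
    sub = matrix.loc[list(order)].to_numpy(dtype=float)
    total = 0
    for h in range(sub.shape[1]):
        col = sub[:, h]
        col = col[~np.isnan(col)]
        if col.size > 1:
            total += int(np.sum(col[1:] != col[:-1]))
    return total


def order_group(
    group: Iterable[str], matrix: pd.DataFrame, seed: int = 0
) -> tuple[list, int]:
    """Advisory within-group marker order minimising obligate breaks.

    Greedy nearest-neighbour seeding from a randomly chosen start, then
    window reversals ("flips") and single-marker reinsertion
    ("polishing") to a local optimum.  Deterministic under ``seed``.
    """
    group = sorted(group)
    if len(group) <= 2:
        return group, obligate_breaks(group, matrix)
    rng = np.random.default_rng(seed)

    # pairwise adjacent-cost matrix for the greedy seed
    sub = matrix.loc[group].to_numpy(dtype=float)
    n = len(group)
    cost = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(sub[i]) & ~np.isnan(sub[j])
            c = int(np.sum(sub[i][ok] != sub[j][ok]))
            cost[i, j] = cost[j, i] = c

    start = int(rng.integers(n))
    order = [start]
    remaining = set(range(n)) - {start}
    while remaining:
        last = order[-1]
        nxt = min(remaining, key=lambda k: (cost[last, k], k))
        order.append(nxt)
        remaining.remove(nxt)

    def score(idx_order):
        return obligate_breaks([group[i] for i in idx_order], matrix)

    best = score(order)
    improved = True
    while improved:
        improved = False
        # flips: reverse every window
        for i in range(n - 1):
            for j in range(i + 1, n):
                cand = order[:i] + order[i:j + 1][::-1] + order[j + 1:]
                s = score(cand)
                if s < best:
                    order, best, improved = cand, s, True
        # polishing: re-insert each marker at its best position
        for i in range(n):
            base = order[:i] + order[i + 1:]
            for j in range(n):
                cand = base[:j] + [order[i]] + base[j:]
                s = score(cand)
                if s < best:
                    order, best, improved = cand, s, True
                    break
    return [group[i] for i in order], best


def chromosome_by_aneuploid(
    aneuploid_calls: pd.DataFrame,
    line_chromosome: Mapping[str, str],
    deletion_genotype: str = "HOM_DONOR",
) -> dict:
    """Deficiency mapping: assign markers to chromosomes via hypo-aneuploids.

    A marker showing the deletion genotype only in line(s) missing one
    chromosome — and the heterozygote in every other scored line — is
    assigned that chromosome.  Deletion signatures in lines missing
    different chromosomes give "ambiguous"; no signature gives None.
    Unscored (NA) line calls are neutral.
    """
    out = {}
    for m in aneuploid_calls.index:
        calls = aneuploid_calls.loc[m]
        del_lines = [l for l in calls.index if calls[l] == deletion_genotype]
        chroms = {line_chromosome[l] for l in del_lines}
        if not chroms:
            out[m] = None
        elif len(chroms) > 1:
            out[m] = "ambiguous"
        else:
            others = [l for l in calls.index if l not in del_lines]
            clean = all(calls[l] in ("HET", "NA") for l in others)
            out[m] = chroms.pop() if clean else "ambiguous"
    return out


def tukey_hinges(values: Iterable[float]) -> tuple[float, float]:
    """Lower/upper quartiles as medians of the data halves.

    For odd n the overall median belongs to neither half.  At least four
    values are required for stable quartiles.
    """
    s = sorted(values)
    n = len(s)
    if n < 4:
        raise ValueError(f"need >= 4 values for quartiles, got {n}")
    half = n // 2
    lower, upper = s[:half], s[n - half:]

    def med(x):
        m = len(x)
        return x[m // 2] if m % 2 else 0.5 * (x[m // 2 - 1] + x[m // 2])

    return med(lower), med(upper)


@dataclass
class OutlierResult:
    counts: pd.Series
    q1: float
    q3: float
    threshold: float
    flagged: list


def deletion_outliers(matrix: pd.DataFrame) -> OutlierResult:
    """Flag markers with anomalously many deletions (Tukey 1.5 x IQR).

    Per-marker deletion counts over scored hybrids are summarised by
    quartiles; counts strictly above Q3 + 1.5 (Q3 - Q1) are flagged.
    """
    counts = matrix.sum(axis=1, skipna=True).astype(int)
    q1, q3 = tukey_hinges(counts.to_list())
    threshold = q3 + 1.5 * (q3 - q1)
    flagged = sorted(counts.index[counts > threshold])
    return OutlierResult(counts=counts, q1=q1, q3=q3, threshold=threshold, flagged=flagged)
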