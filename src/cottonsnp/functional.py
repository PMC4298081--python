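"""Shared-allele loci and synonymous/non-synonymous substitution calls.

Loci where every donor species carries the same non-reference allele are
candidates for ancestral states at which the cultivated reference has
diverged — of particular interest for domestication.  For each such
locus the substitution is classified against a CDS annotation by
translating the containing codon with the reference and with the
alternate base (standard genetic code, strand-aware).  The headline
statistic is the plain count ratio non-synonymous : synonymous — no
per-site normalisation.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .anchoring import revcomp
from .redundancy import NsS

SHARED_COLUMNS = ["contig", "pos", "ref", "alt", "n_species", "triallelic"]

_STOP = "*"


def find_shared_loci(
    candidate_sets: Mapping[str, pd.DataFrame], species: Sequence[str] | None = None
) -> pd.DataFrame:
    """Loci called in *every* analysed species, with triallelic flags.

    A locus (contig, pos) is emitted iff each species in ``species``
    (default: all keys of ``candidate_sets``) carries a candidate there.
    If the species disagree on the alternate base the locus is flagged
    triallelic (three alleles counting the reference) and must be
    excluded from substitution-ratio arithmetic; its ``alt`` is the
    comma-joined set of alternates.
    """
    species = list(species) if species is not None else list(candidate_sets)
    frames = [candidate_sets[sp].assign(species=sp) for sp in species]
    pool = pd.concat(frames, ignore_index=True)
    rows = []
    for (contig, pos), sub in pool.groupby(["contig", "pos"], sort=True):
        present = set(sub["species"])
        if present != set(species):
            continue
        alts = sorted(set(sub["alt"]))
        rows.append(
            {"contig": contig, "pos": pos, "ref": sub["ref"].iloc[0],
             "alt": ",".join(alts), "n_species": len(present),
             "triallelic": len(alts) > 1}
        )
    return pd.DataFrame(rows, columns=SHARED_COLUMNS)


def classify_substitution(
    contig_seq: str,
    pos: int,
    ref: str,
    alt: str,
    cds: Mapping | None,
) -> str:
    """Classify one substitution given its contig's CDS annotation.

    ``cds`` needs ``cds_start``/``cds_end`` (1-based inclusive),
    ``strand`` and ``frame`` (bases to skip before the first complete
    codon); None means no annotation.  Returns one of ``non_coding``,
    ``synonymous``, ``non_synonymous`` or ``untranslated`` (frame/length
    defects, premature stop in the reference, or position inside the
    frame offset).
    """
    if cds is None:
        return "non_coding"
    start, end = int(cds["cds_start"]), int(cds["cds_end"])
    strand, frame = cds["strand"], int(cds["frame"])
    if not start <= pos <= end:
        return "non_coding"
    coding = contig_seq[start - 1: end].upper()
    if strand == "-":
        coding = revcomp(coding)
        idx = end - pos
        base_ref, base_alt = revcomp(ref), revcomp(alt)
    else:
        idx = pos - start
        base_ref, base_alt = ref.upper(), alt.upper()
    coding = coding[frame:]
    idx -= frame
    if idx < 0:
        return "untranslated"
    if len(coding) % 3 != 0:
        warnings.warn("CDS length not divisible by 3; marking untranslated")
        return "untranslated"
    protein = str(Seq(coding).translate())
    if _STOP in protein[:-1]:
        return "untranslated"  # premature stop: annotation unreliable
    codon_i = idx // 3
    codon = coding[3 * codon_i: 3 * codon_i + 3]
    if len(codon) < 3:
        return "untranslated"
    if codon[idx % 3] != base_ref:
        raise ValueError(
            f"reference allele {ref} disagrees with contig sequence at position {pos}"
        )
    alt_codon = codon[: idx % 3] + base_alt + codon[idx % 3 + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    return "synonymous" if aa_ref == aa_alt else "non_synonymous"


def classify_loci(
    shared: pd.DataFrame,
    cds_table: pd.DataFrame,
    contigs: Mapping[str, str],
) -> pd.DataFrame:
    """Attach ``substitution_class`` to a shared-locus table.

    Triallelic loci get class ``triallelic`` and never enter the ratio.
    """
    cds_by_contig = {rec["contig"]: rec for rec in cds_table.to_dict("records")}
    classes = []
    for rec in shared.to_dict("records"):
        if rec["triallelic"]:
            classes.append("triallelic")
            continue
        classes.append(
            classify_substitution(
                contigs[rec["contig"]], int(rec["pos"]), rec["ref"], rec["alt"],
                cds_by_contig.get(rec["contig"]),
            )
        )
    out = shared.copy()
    out["substitution_class"] = classes
    return out


def ns_s_ratio(classes) -> NsS:
    """Non-synonymous : synonymous count ratio, 4-dp.

    ``classes`` is an iterable of substitution-class labels (a classified
    locus table's column works); only synonymous/non_synonymous entries
    count.  With no synonymous calls the ratio is undefined (None).
    """
    if isinstance(classes, pd.DataFrame):
        classes = classes["substitution_class"]
    n_non = n_syn = 0
    for c in classes:
        if c == "non_synonymous":
            n_non += 1
        elif c == "synonymous":
            n_syn += 1
    ratio = round(n_non / n_syn, 4) if n_syn else None
    return NsS(n_non, n_syn, ratio)


def sample_comparator(
    markers: pd.DataFrame, n: int = 118, seed: int = 0
) -> pd.DataFrame:
    """Random comparator set: ``n`` markers from distinct contigs.

    Contigs are sampled uniformly without replacement, then one marker
    per chosen contig; with fewer than ``n`` distinct contigs the sample
    shrinks to one marker per contig with a warning.  Deterministic under
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    contigs = sorted(markers["contig"].unique())
    if len(contigs) < n:
        warnings.warn(
            f"only {len(contigs)} distinct contigs for a comparator of {n}; sampling fewer"
        )
        chosen = contigs
    else:
        chosen = list(rng.choice(contigs, size=n, replace=False))
    picks = []
    for c in chosen:
        sub = markers[markers["contig"] == c].sort_values("pos")
        picks.append(sub.index[int(rng.integers(len(sub)))])
    return markers.loc[picks].reset_index(drop=True)


def longest_orf(seq: str, min_codons: int = 90) -> dict | None:
    """Annotation-free fallback CDS: longest ATG-to-stop open reading frame.

    Scans both strands and all three frames; returns a CDS record
    (1-based inclusive forward coordinates, strand, frame 0) for the
    longest ORF of at least ``min_codons`` codons, or None.
    """
    seq = seq.upper()
    n = len(seq)
    best = None
    for strand in ("+", "-"):
        s = seq if strand == "+" else revcomp(seq)
        for off in range(3):
            i = off
            start = None
            while i + 3 <= n:
                codon = s[i: i + 3]
                if start is None and codon == "ATG":
                    start = i
                elif start is not None and codon in ("TAA", "TAG", "TGA"):
                    length = i + 3 - start
                    if length // 3 >= min_codons and (best is None or length > best[0]):
                        best = (length, strand, start, i + 3)
                    start = None
                i += 3
    if best is None:
        return None
    length, strand, s0, s1 = best
    if strand == "+":
        start1, end1 = s0 + 1, s1
    else:
        start1, end1 = n - s1 + 1, n - s0
    return {"cds_start": start1, "cds_end": end1, "strand": strand, "frame": 0}
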