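"""Synthetic data with known ground truth for the whole pipeline.

The generator emulates the study system end to end: an allotetraploid
reference transcriptome whose contigs contain collapsed homeologous
sites, donor species that differ from the reference by planted
allele-SNPs at a controlled per-bp density, Poisson-depth pileups with a
per-base miscall rate for each donor and for the reference accession's
self-remap, one CDS annotation per contig, intron–exon boundary
positions, and a radiation-hybrid panel in which chromosomal deletion
segments arise from a Poisson break process along a centiRay axis.

Every random draw descends from the single config seed through
substreams keyed by (stage, unit), so outputs are reproducible and
independent of generation order.

Defaults state the emulated world: 131 hybrids and a 6.9% per-marker
deletion rate as in the real panel, ~30x mean pileup depth (the
per-species depths of the source data span 20.9–48.5x), 1% base error
typical of the sequencing platform, contigs around the source assembly's
N50 of ~1.1 kb (scaled to desk size), and free choices documented in the
methods note (homeolog-site and divergence densities, boundary rate,
deletion-segment scale).
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sites import BASES, PILEUP_COLUMNS
from .redundancy import DEFAULT_HIERARCHY

_BASE_ARR = np.array(BASES)


@dataclass
class SimulationConfig:
    n_contigs: int = 80
    contig_length_mean: float = 900.0
    contig_length_sd: float = 250.0
    homeolog_site_rate: float = 0.005
    donor_divergence: float = 0.003
    shared_site_rate: float = 0.0005
    shared_triallelic_frac: float = 0.05
    transition_bias: float = 0.62
    mean_depth: float = 30.0
    depth_dist: str = "poisson"  # or "constant"
    error_rate: float = 0.01
    indel_rate: float = 0.001
    boundary_rate: float = 1 / 400  # expected intron-exon boundaries per bp
    rh_n_hybrids: int = 131
    rh_deletion_freq: float = 0.069
    rh_segment_scale: float = 50.0  # mean deletion-segment extent, cR
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("homeolog_site_rate", "donor_divergence", "shared_site_rate",
                     "shared_triallelic_frac", "transition_bias", "error_rate",
                     "indel_rate", "rh_deletion_freq", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_contigs < 1 or self.rh_n_hybrids < 1:
            raise ValueError("counts must be >= 1")
        if self.contig_length_mean < 101:
            raise ValueError(
                "contig_length_mean below 101 bp cannot host a marker with 50-bp flanks"
            )
        if self.depth_dist not in ("poisson", "constant"):
            raise ValueError(f"unknown depth_dist {self.depth_dist!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


@dataclass
class TruthSet:
    """Ground truth recorded while simulating, for oracle comparisons."""

    planted_snps: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["species", "contig", "pos", "ref", "alt"])
    )
    homeolog_sites: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["contig", "pos", "ref", "other"])
    )
    shared_loci: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["contig", "pos", "ref", "triallelic"])
    )
    boundary_truth: dict = field(default_factory=dict)
    cds_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    rh_true_chromosome: dict = field(default_factory=dict)
    rh_true_deletions: pd.DataFrame = field(default_factory=pd.DataFrame)


def substream(seed: int, *keys) -> np.random.Generator:
    """Deterministic child generator keyed by (stage, unit) strings/ints."""
    tail = [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng([int(seed)] + tail)


def _other_bases(rng: np.random.Generator, ref_idx: np.ndarray) -> np.ndarray:
    """Uniform base different from ref, vectorised over ref indices."""
    shift = rng.integers(1, 4, size=ref_idx.shape)
    return (ref_idx + shift) % 4


def _alt_bases(rng: np.random.Generator, ref_idx: np.ndarray, ts_prob: float) -> np.ndarray:
    """Alternate allele with a transition bias.

    With probability ``ts_prob`` the alt is the transition partner
    (A<->G, C<->T, i.e. index +2 mod 4); otherwise one of the two
    transversion partners uniformly.
    """
    is_ts = rng.random(ref_idx.shape) < ts_prob
    tv_shift = np.where(rng.random(ref_idx.shape) < 0.5, 1, 3)
    shift = np.where(is_ts, 2, tv_shift)
    return (ref_idx + shift) % 4


_STOPS = {"TAA", "TAG", "TGA"}


def _cds_plan(config: SimulationConfig, name: str, length: int) -> tuple[int, int, str]:
    """Deterministic CDS interval/strand for a contig (shared substream).

    Both the reference generator (which keeps the region stop-free) and
    :func:`simulate_cds_annotations` derive the plan from the same keyed
    substream, so annotation and sequence always agree.
    """
    rng = substream(config.seed, "cds", name)
    start = int(rng.integers(1, max(2, length // 3)))
    span = int(0.6 * length)
    span -= span % 3
    span = max(3, span)
    end = min(start + span - 1, length)
    end -= (end - start + 1) % 3
    strand = "+" if rng.random() < 0.5 else "-"
    return start, end, strand


def _remove_stops(base_idx: np.ndarray, start: int, end: int, strand: str) -> None:
    """Rewrite in-frame stop codons inside [start, end] (1-based) in place.

    A stop's third base becomes C (TAC = Tyr, TGC = Cys), keeping the
    simulated reference translatable end to end on the coding strand.
    """
    comp = np.array([3, 2, 1, 0])  # A<->T, C<->G on index space
    region = base_idx[start - 1: end]
    coding = comp[region][::-1] if strand == "-" else region
    c_idx = {b: i for i, b in enumerate(BASES)}
    for k in range(0, len(coding) - 2, 3):
        codon = "".join(_BASE_ARR[coding[k: k + 3]])
        if codon in _STOPS:
            coding[k + 2] = c_idx["C"]
    fixed = comp[coding][::-1] if strand == "-" else coding
    base_idx[start - 1: end] = fixed


def simulate_reference(
    config: SimulationConfig, species: Sequence[str] = tuple(DEFAULT_HIERARCHY)
) -> tuple[dict, TruthSet]:
    """Reference contigs plus planted truth (homeolog sites, boundaries,
    per-species allele-SNPs).

    Contig lengths are normal around the configured mean, floored at
    101 bp so every interior SNP can carry full flanks.
    """
    truth = TruthSet()
    contigs: dict[str, str] = {}
    planted, homeo, shared = [], [], []
    for i in range(config.n_contigs):
        name = f"contig{i:05d}"
        rng = substream(config.seed, "reference", name)
        length = max(101, int(round(rng.normal(config.contig_length_mean,
                                               config.contig_length_sd))))
        base_idx = rng.integers(0, 4, size=length)
        cds_start, cds_end, cds_strand = _cds_plan(config, name, length)
        _remove_stops(base_idx, cds_start, cds_end, cds_strand)
        seq = "".join(_BASE_ARR[base_idx])
        contigs[name] = seq

        # collapsed homeologous sites: a second base segregating ~50/50 on self-remap
        h_hits = np.flatnonzero(rng.random(length) < config.homeolog_site_rate)
        other_idx = _other_bases(rng, base_idx[h_hits])
        for p, oi in zip(h_hits, other_idx):
            homeo.append({"contig": name, "pos": int(p) + 1,
                          "ref": seq[p], "other": str(_BASE_ARR[oi])})
        homeo_pos = set((int(p) + 1) for p in h_hits)

        # intron-exon boundaries left by splicing, uniform along the contig
        n_b = rng.poisson(config.boundary_rate * length)
        bpos = sorted(int(p) + 1 for p in rng.choice(length, size=min(n_b, length), replace=False))
        truth.boundary_truth[name] = bpos

        # shared ancestral-allele sites: every donor species carries the same
        # alternate base (the reference allele is the derived state); a small
        # fraction are triallelic — one species deviates to a second alternate
        rsh = substream(config.seed, "shared", name)
        sh_hits = np.array(
            [p for p in np.flatnonzero(rsh.random(length) < config.shared_site_rate)
             if (p + 1) not in homeo_pos],
            dtype=int,
        )
        taken = set(homeo_pos)
        for p in sh_hits:
            ai = int(_alt_bases(rsh, base_idx[p:p + 1], config.transition_bias)[0])
            tri = bool(rsh.random() < config.shared_triallelic_frac)
            odd_sp = species[int(rsh.integers(len(species)))] if tri else None
            for sp in species:
                a = ai
                if sp == odd_sp:
                    while a == ai or a == base_idx[p]:
                        a = int(rsh.integers(0, 4))
                planted.append({"species": sp, "contig": name, "pos": int(p) + 1,
                                "ref": seq[p], "alt": str(_BASE_ARR[a])})
            shared.append({"contig": name, "pos": int(p) + 1, "ref": seq[p],
                           "triallelic": tri})
            taken.add(int(p) + 1)

        # planted interspecific allele-SNPs, per species, avoiding the above
        for sp in species:
            rsp = substream(config.seed, "plant", name, sp)
            hits = np.flatnonzero(rsp.random(length) < config.donor_divergence)
            hits = np.array([p for p in hits if (p + 1) not in taken], dtype=int)
            if hits.size == 0:
                continue
            alt_idx = _alt_bases(rsp, base_idx[hits], config.transition_bias)
            for p, ai in zip(hits, alt_idx):
                planted.append({"species": sp, "contig": name, "pos": int(p) + 1,
                                "ref": seq[p], "alt": str(_BASE_ARR[ai])})
    if planted:
        truth.planted_snps = pd.DataFrame(planted)
    if homeo:
        truth.homeolog_sites = pd.DataFrame(homeo)
    if shared:
        truth.shared_loci = pd.DataFrame(shared)
    return contigs, truth


def _depths(rng: np.random.Generator, config: SimulationConfig, n: int) -> np.ndarray:
    if config.mean_depth <= 0:
        return np.zeros(n, dtype=int)
    if config.depth_dist == "constant":
        return np.full(n, int(round(config.mean_depth)))
    return rng.poisson(config.mean_depth, size=n)


def _pileup_frame(contig, pos, ref, counts, indel):
    df = pd.DataFrame({
        "contig": contig, "pos": pos, "ref": ref,
        "depth": counts.sum(axis=1),
        "A": counts[:, 0], "C": counts[:, 1], "G": counts[:, 2], "T": counts[:, 3],
        "indel": indel,
    })
    return df[PILEUP_COLUMNS]


def _simulate_pileup_for_contig(
    rng: np.random.Generator,
    config: SimulationConfig,
    name: str,
    seq: str,
    allele_idx: np.ndarray,
    het_pos: Mapping[int, int],
) -> pd.DataFrame | None:
    """Pileup over one contig given the sample's true base per position.

    ``allele_idx`` is the homozygous true-base index per position;
    ``het_pos`` maps 1-based positions to a second base index sampled
    50/50 (collapsed homeologs on the self-remap, or in tetraploid
    donors).  Zero-depth positions produce no record.
    """
    length = len(seq)
    depth = _depths(rng, config, length)
    keep = depth > 0
    if not keep.any():
        return None
    idx = np.flatnonzero(keep)
    depth = depth[keep]
    n = idx.size
    counts = np.zeros((n, 4), dtype=int)

    true_idx = allele_idx[idx]
    n_err = rng.binomial(depth, config.error_rate)
    n_true = depth - n_err
    het_lookup = np.full(length, -1, dtype=int)
    for p1, oi in het_pos.items():
        het_lookup[p1 - 1] = oi
    het_other = het_lookup[idx]
    is_het = het_other >= 0
    # split correct reads 50/50 at heterozygous (collapsed) sites
    n_second = np.where(is_het, rng.binomial(n_true, 0.5), 0)
    n_first = n_true - n_second
    counts[np.arange(n), true_idx] += n_first
    sec = np.where(is_het, het_other, 0)
    counts[np.arange(n), sec] += np.where(is_het, n_second, 0)
    # sequencing errors scatter uniformly over the three other bases
    err_rows = np.flatnonzero(n_err > 0)
    for r in err_rows:
        picks = (true_idx[r] + rng.integers(1, 4, size=n_err[r])) % 4
        np.add.at(counts[r], picks, 1)
    indel = rng.random(n) < config.indel_rate
    return _pileup_frame(name, idx + 1, [seq[p] for p in idx], counts, indel)


def simulate_donor_pileups(
    contigs: Mapping[str, str],
    truth: TruthSet,
    species: str,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Pileup of one donor species against the reference contigs.

    Planted allele-SNP sites read the alternate base; collapsed homeolog
    sites split reads ~50/50 between the two homeologous bases (present
    in the donors too, which share the AD ancestry or map to one
    subgenome of it); everywhere else the reference base dominates up to
    the error rate.
    """
    base_idx = {b: i for i, b in enumerate(BASES)}
    planted = truth.planted_snps
    planted = planted[planted["species"] == species] if not planted.empty else planted
    frames = []
    for name, seq in contigs.items():
        rng = substream(config.seed, "pileup", species, name)
        allele = np.fromiter((base_idx[b] for b in seq), dtype=int, count=len(seq))
        if not planted.empty:
            for rec in planted[planted["contig"] == name].itertuples():
                allele[rec.pos - 1] = base_idx[rec.alt]
        het = {}
        if not truth.homeolog_sites.empty:
            hs = truth.homeolog_sites
            for rec in hs[hs["contig"] == name].itertuples():
                het[rec.pos] = base_idx[rec.other]
        df = _simulate_pileup_for_contig(rng, config, name, seq, allele, het)
        if df is not None:
            frames.append(df)
    if not frames:
        return pd.DataFrame(columns=PILEUP_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def simulate_self_pileups(
    contigs: Mapping[str, str], truth: TruthSet, config: SimulationConfig
) -> pd.DataFrame:
    """Reference accession reads mapped back to its own assembly.

    Pure reference signal except at collapsed homeolog sites, where the
    two subgenome bases each draw ~50% of the reads — the signature the
    homeo mask is built from.
    """
    base_idx = {b: i for i, b in enumerate(BASES)}
    frames = []
    for name, seq in contigs.items():
        rng = substream(config.seed, "pileup", "self", name)
        allele = np.fromiter((base_idx[b] for b in seq), dtype=int, count=len(seq))
        het = {}
        if not truth.homeolog_sites.empty:
            hs = truth.homeolog_sites
            for rec in hs[hs["contig"] == name].itertuples():
                het[rec.pos] = base_idx[rec.other]
        df = _simulate_pileup_for_contig(rng, config, name, seq, allele, het)
        if df is not None:
            frames.append(df)
    if not frames:
        return pd.DataFrame(columns=PILEUP_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def simulate_cds_annotations(
    contigs: Mapping[str, str], config: SimulationConfig
) -> pd.DataFrame:
    """One CDS interval per contig (random strand, frame 0).

    The interval starts in the first third of the contig and spans a
    codon-multiple length of roughly 60% of it, mimicking a transcript
    with UTRs on both sides.
    """
    rows = []
    for name, seq in contigs.items():
        start, end, strand = _cds_plan(config, name, len(seq))
        rows.append({"contig": name, "cds_start": start, "cds_end": end,
                     "strand": strand, "frame": 0})
    return pd.DataFrame(rows, columns=["contig", "cds_start", "cds_end", "strand", "frame"])


def simulate_rh_panel(
    marker_map: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, TruthSet]:
    """Radiation-hybrid panel genotypes from a marker map.

    ``marker_map`` columns: ``marker`` (unique ids), ``chrom``, ``cr``
    (position on a per-chromosome centiRay axis).  Per hybrid and
    chromosome, irradiation breakpoints follow a Poisson process with
    mean spacing ``rh_segment_scale`` cR and each resulting segment is
    deleted with probability ``rh_deletion_freq``, so the marginal
    per-marker deletion probability equals the configured rate while
    nearby markers co-delete.  Genotypes are HET unless the marker's
    segment is deleted (then HOM_DONOR); ``missing_rate`` of calls are
    NA.  Returns the genotype matrix (markers x hybrids) and a truth
    set holding the complete binary deletion matrix and chromosome map.
    """
    if marker_map["marker"].duplicated().any():
        dups = marker_map.loc[marker_map["marker"].duplicated(), "marker"].tolist()
        raise ValueError(f"duplicate marker ids: {dups}")
    markers = marker_map["marker"].to_list()
    hybrids = [f"RH{h + 1:03d}" for h in range(config.rh_n_hybrids)]
    deletions = np.zeros((len(markers), len(hybrids)), dtype=int)
    by_chrom = {
        chrom: (sub.index.to_numpy(), sub["cr"].to_numpy(dtype=float))
        for chrom, sub in marker_map.reset_index(drop=True).groupby("chrom")
    }
    for h, hyb in enumerate(hybrids):
        for chrom, (midx, cr) in by_chrom.items():
            rng = substream(config.seed, "rh", hyb, chrom)
            span = float(cr.max()) + config.rh_segment_scale
            # Poisson process of breakpoints along the cR axis
            breaks = []
            x = 0.0
            while True:
                x += rng.exponential(config.rh_segment_scale)
                if x >= span:
                    break
                breaks.append(x)
            edges = np.array([0.0] + breaks + [span])
            seg_of = np.searchsorted(edges, cr, side="right") - 1
            n_seg = len(edges) - 1
            seg_deleted = rng.random(n_seg) < config.rh_deletion_freq
            deletions[midx, h] = seg_deleted[seg_of].astype(int)
    geno = np.where(deletions == 1, "HOM_DONOR", "HET").astype(object)
    rng_miss = substream(config.seed, "rh", "missing")
    miss = rng_miss.random(geno.shape) < config.missing_rate
    geno[miss] = "NA"
    genotypes = pd.DataFrame(geno, index=markers, columns=hybrids)
    truth = TruthSet(
        rh_true_chromosome=dict(zip(marker_map["marker"], marker_map["chrom"])),
        rh_true_deletions=pd.DataFrame(deletions.T, index=hybrids, columns=markers),
    )
    return genotypes, truth


def write_fixture_bundle(outputs: Mapping[str, object], directory) -> dict:
    """Write a simulated bundle as plain-text files with a hashed manifest.

    Recognised keys: ``contigs`` (dict -> FASTA), ``config``
    (SimulationConfig -> JSON), any ``pileup_*`` (DataFrame -> TSV),
    ``boundaries`` (dict -> TSV), ``cds``/``rh_genotypes``/other
    DataFrames -> TSV.  The manifest lists each file with its sha256 plus
    the seed, the config hash and a bundle hash over the file hashes, so
    identical config+seed reproduce an identical manifest.
    """
    from . import io as csio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}

    def _register(path: Path):
        files[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    config = outputs.get("config")
    for key, value in outputs.items():
        if key == "config":
            path = directory / "config.json"
            path.write_text(json.dumps(value.to_dict(), sort_keys=True, indent=1))
        elif key == "contigs":
            path = directory / "contigs.fasta"
            csio.write_fasta(value, path)
        elif key == "boundaries":
            path = directory / "boundaries.tsv"
            rows = [
                {"contig": c, "pos": p} for c, ps in sorted(value.items()) for p in ps
            ]
            pd.DataFrame(rows, columns=["contig", "pos"]).to_csv(path, sep="\t", index=False)
        elif key == "rh_genotypes":
            path = directory / "rh_genotypes.tsv"
            csio.write_genotype_long(value, path)
        elif isinstance(value, pd.DataFrame):
            path = directory / f"{key}.tsv"
            value.to_csv(path, sep="\t", index=False)
        else:
            raise ValueError(f"cannot serialise bundle entry {key!r}")
        _register(path)

    bundle_hash = hashlib.sha256(
        json.dumps(sorted(files.items())).encode()
    ).hexdigest()
    manifest = {
        "files": files,
        "seed": config.seed if config is not None else None,
        "config_hash": config.hash() if config is not None else None,
        "bundle_hash": bundle_hash,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
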