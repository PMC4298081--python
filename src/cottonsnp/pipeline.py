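"""End-to-end orchestration: simulate → filter → design → dedup → anchor →
RH map → functional analysis, with a conservation ledger and run manifest.

Every stage's input count must equal its output count plus each
categorised removal; a violation aborts the run (it indicates a
bookkeeping bug, not bad data).  All intermediate tables are written as
TSV, summaries as JSON, and the manifest hash is reproducible under a
fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import anchoring, functional, io as csio, markers as md, redundancy as rd, rhmap, sites
from .report import percent
from .simulate import SimulationConfig, simulate_cds_annotations, \
    simulate_donor_pileups, simulate_reference, simulate_rh_panel, \
    simulate_self_pileups, substream


class PipelineError(RuntimeError):
    """A stage invariant (count conservation) was violated."""


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    species: Sequence[str] = tuple(rd.DEFAULT_HIERARCHY)
    hierarchy: Sequence[str] = tuple(rd.DEFAULT_HIERARCHY)
    min_site_depth: int = 3
    call_depth: int = 10
    purity: float = 0.9
    homeo_minor_frac: float = 0.2
    homeo_min_depth: int = 3
    intron_window: int = 50
    flank: int = 50
    class_window: int = 50
    n_scaffolds: int = 5
    density_window: int = 5000
    density_step: int = 2500
    cr_per_bp: float = 0.02
    lod_min: float = 3.0
    max_cr: float = 100.0
    comparator_n: int = 118
    run_rh: bool = True

    def __post_init__(self) -> None:
        missing = [sp for sp in self.species if sp not in set(self.hierarchy)]
        if missing:
            raise ValueError(f"species without hierarchy rank: {missing}")
        for name in ("min_site_depth", "call_depth", "intron_window", "flank",
                     "class_window", "n_scaffolds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["species"] = list(self.species)
        d["hierarchy"] = list(self.hierarchy)
        return d

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()


def _conserve(stage: str, n_in: int, parts: Mapping[str, int]) -> None:
    if n_in != sum(parts.values()):
        raise PipelineError(
            f"conservation violated at {stage}: {n_in} in vs {dict(parts)}"
        )


def build_synthetic_genome(
    contigs: Mapping[str, str], n_scaffolds: int, seed: int, spacer: int = 100
) -> tuple[dict, dict]:
    """Concatenate contigs round-robin into pseudo-chromosome scaffolds.

    Random spacer sequence separates contigs.  Returns the genome and a
    contig → (scaffold, offset) placement map (offset of contig base 1,
    0-based).
    """
    genome = {f"Chr{k + 1:02d}": [] for k in range(n_scaffolds)}
    placement = {}
    cursors = {s: 0 for s in genome}
    for i, (name, seq) in enumerate(contigs.items()):
        scaf = f"Chr{i % n_scaffolds + 1:02d}"
        rng = substream(seed, "genome", name)
        pad = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=spacer)])
        placement[name] = (scaf, cursors[scaf] + spacer)
        genome[scaf].append(pad + seq)
        cursors[scaf] += spacer + len(seq)
    return {s: "".join(parts) for s, parts in genome.items()}, placement


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every stage on a synthetic world; returns the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    ledger: dict = {}
    report: dict = {"config_hash": config.hash(), "seed": sim.seed}

    # --- simulate the world -------------------------------------------------
    contigs, truth = simulate_reference(sim, species=config.species)
    csio.write_fasta(contigs, outdir / "contigs.fasta")
    self_pileup = simulate_self_pileups(contigs, truth, sim)
    mask = sites.build_homeo_mask(
        self_pileup, minor_frac=config.homeo_minor_frac, min_depth=config.homeo_min_depth
    )
    report["homeo_mask_size"] = len(mask)

    # --- per-species candidate calling and marker design --------------------
    candidates_by_species: dict[str, pd.DataFrame] = {}
    markers_by_species: dict[str, pd.DataFrame] = {}
    unfiltered_counts: dict[str, dict] = {}
    for sp in config.species:
        pu = simulate_donor_pileups(contigs, truth, sp, sim)
        filtered = sites.filter_sites(pu, min_depth=config.min_site_depth)
        cands = sites.call_candidates(
            filtered, sp, min_depth=config.call_depth, purity=config.purity
        )
        after_intron = sites.filter_intron_proximity(
            cands, truth.boundary_truth, window=config.intron_window
        )
        after_mask = sites.apply_homeo_mask(after_intron, mask)
        classified = md.classify_candidates(after_mask, window=config.class_window)
        marker_tab, n_short = md.extract_markers(classified, contigs, flank=config.flank)
        stage = {
            "sites": len(pu),
            "sites_kept": len(filtered),
            "candidates": len(cands),
            "removed_intron": len(cands) - len(after_intron),
            "removed_homeo_mask": len(after_intron) - len(after_mask),
            "markers": len(marker_tab),
            "excluded_short_flank": n_short,
        }
        _conserve(f"{sp}: intron+mask", len(cands), {
            "kept": len(after_mask),
            "intron": stage["removed_intron"],
            "mask": stage["removed_homeo_mask"],
        })
        _conserve(f"{sp}: flanks", len(after_mask),
                  {"markers": len(marker_tab), "short": n_short})
        ledger[sp] = stage
        candidates_by_species[sp] = classified
        markers_by_species[sp] = marker_tab
        csio.write_table(classified, outdir / f"candidates_{sp}.tsv")
        unfiltered_counts[sp] = (
            marker_tab["snp_class"].value_counts().reindex(["I", "II", "III"], fill_value=0)
            .rename({"I": "I", "II": "II", "III": "III"}).to_dict()
        )

    # --- redundancy ---------------------------------------------------------
    uniques, overlaps = {}, {}
    for sp in config.species:
        uniq, ov = rd.within_species_partition(markers_by_species[sp])
        _conserve(f"{sp}: within-species", len(markers_by_species[sp]),
                  {"unique": len(uniq), "overlap": len(ov)})
        uniques[sp], overlaps[sp] = uniq, ov
        csio.write_markers(ov, outdir / f"overlap_{sp}.tsv")
    kept_sets, removed_cross, venn = rd.cross_species_dedup(uniques, hierarchy=config.hierarchy)
    _conserve("cross-species", sum(len(u) for u in uniques.values()),
              {"kept": sum(len(k) for k in kept_sets.values()),
               "removed": len(removed_cross)})

    retained_counts = {}
    final_i_ii_frames = []
    class_iii_frames = []
    for sp in config.species:
        kept = kept_sets.get(sp, pd.DataFrame(columns=["snp_class"]))
        cc = kept["snp_class"].value_counts()
        retained_counts[sp] = {
            "I": int(cc.get("I", 0)), "II": int(cc.get("II", 0)),
            "III": int(cc.get("III", 0)), "overlap": len(overlaps[sp]),
        }
        sel = kept[kept["snp_class"].isin(["I", "II"])]
        final_i_ii_frames.append(sel)
        class_iii_frames.append(kept[kept["snp_class"] == "III"])
        csio.write_markers(sel, outdir / f"markers_{sp}_classI_II.tsv")
    final_markers = pd.concat(final_i_ii_frames, ignore_index=True)
    csio.write_markers(pd.concat(class_iii_frames, ignore_index=True),
                       outdir / "markers_classIII_all.tsv")
    (outdir / "venn.json").write_text(
        json.dumps({"+".join(k): v for k, v in sorted(venn.items())}, indent=1)
    )
    tstv = rd.ts_tv_ratio(final_markers)
    report["ts_tv"] = {"transitions": tstv.n_transitions,
                       "transversions": tstv.n_transversions, "ratio": tstv.ratio}
    report["accounting_unfiltered"] = rd.accounting_summary(unfiltered_counts).to_dict("index")
    report["accounting_retained"] = rd.accounting_summary(retained_counts).to_dict("index")
    report["final_class_i_ii_total"] = len(final_markers)

    # --- anchoring ----------------------------------------------------------
    genome, _placement = build_synthetic_genome(contigs, config.n_scaffolds, sim.seed)
    anchors = anchoring.anchor_markers(final_markers, genome)
    csio.write_table(anchors, outdir / "anchors.tsv")
    report["placement"] = anchoring.placement_summary(anchors)
    scaffold_lengths = {s: len(seq) for s, seq in genome.items()}
    density = anchoring.window_density(
        anchors, scaffold_lengths, window=config.density_window, step=config.density_step
    )
    csio.write_table(density, outdir / "density.tsv")

    # --- RH mapping (top-hierarchy species) ---------------------------------
    if config.run_rh:
        top = [sp for sp in config.hierarchy if sp in config.species][0]
        top_ids = set(kept_sets[top]["id"])
        placed = anchors[
            (anchors["placement"] == "placed")
            & (anchors["species"] == top)
            & anchors["marker"].isin(top_ids)
        ].drop_duplicates("marker")
        marker_map = pd.DataFrame({
            "marker": placed["marker"].to_numpy(),
            "chrom": placed["scaffold"].to_numpy(),
            "cr": placed["snp_pos"].to_numpy() * config.cr_per_bp,
        })
        if len(marker_map) >= 4:
            report["rh"] = _run_rh_stage(marker_map, config, outdir, ledger)
        else:
            report["rh"] = {"status": "absent", "reason": "fewer than 4 mappable markers"}
    else:
        report["rh"] = {"status": "absent", "reason": "disabled"}

    # --- functional analysis ------------------------------------------------
    shared = functional.find_shared_loci(candidates_by_species, species=config.species)
    cds_table = simulate_cds_annotations(contigs, sim)
    csio.write_table(cds_table, outdir / "cds.tsv")
    shared_classified = functional.classify_loci(shared, cds_table, contigs)
    csio.write_table(shared_classified, outdir / "shared_loci.tsv")
    nss = functional.ns_s_ratio(shared_classified)
    report["shared"] = {
        "n_loci": len(shared_classified),
        "n_triallelic": int(shared_classified["triallelic"].sum()) if len(shared_classified) else 0,
        "n_nonsyn": nss.n_nonsyn, "n_syn": nss.n_syn, "ns_s_ratio": nss.ratio,
    }
    n_comp = min(config.comparator_n, final_markers["contig"].nunique())
    if n_comp >= 1 and len(final_markers):
        comparator = functional.sample_comparator(final_markers, n=n_comp, seed=sim.seed)
        comp_loci = comparator.rename(columns={})[["contig", "pos", "ref", "alt"]].copy()
        comp_loci["n_species"] = 1
        comp_loci["triallelic"] = False
        comp_classified = functional.classify_loci(comp_loci, cds_table, contigs)
        csio.write_table(comp_classified, outdir / "comparator_loci.tsv")
        nss_c = functional.ns_s_ratio(comp_classified)
        report["comparator"] = {"n": len(comp_classified), "n_nonsyn": nss_c.n_nonsyn,
                                "n_syn": nss_c.n_syn, "ns_s_ratio": nss_c.ratio}

    # --- manifest -----------------------------------------------------------
    report["ledger"] = ledger
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True, default=str))
    files = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(outdir.iterdir()) if p.name != "manifest.json"
    }
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "files": files,
        "bundle_hash": hashlib.sha256(json.dumps(sorted(files.items())).encode()).hexdigest(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _run_rh_stage(marker_map: pd.DataFrame, config: RunConfig, outdir: Path,
                  ledger: dict) -> dict:
    sim = config.simulation
    genotypes, rh_truth = simulate_rh_panel(marker_map, sim)
    csio.write_genotype_long(genotypes, outdir / "rh_genotypes.tsv")
    matrix, warn_counts = rhmap.call_deletions(genotypes)
    pruned = rhmap.prune_markers(matrix)
    links = rhmap.pairwise_links(pruned)
    csio.write_table(links, outdir / "links.tsv")
    groups, singles = rhmap.build_groups(
        links, pruned.index, lod_min=config.lod_min, max_cr=config.max_cr
    )
    group_records = []
    for gi, grp in enumerate(groups):
        bins = rhmap.bin_group(grp, pruned)
        order, breaks = rhmap.order_group(grp, pruned, seed=sim.seed)
        group_records.append({"group": gi, "markers": grp, "bins": bins,
                              "order_advisory": order, "obligate_breaks": breaks})
    (outdir / "groups.json").write_text(json.dumps(
        {"groups": group_records, "singletons": singles}, indent=1))

    # synthetic hypo-aneuploid panel: one line per chromosome, every marker
    # on the missing chromosome shifted to the deletion genotype
    chroms = sorted(marker_map["chrom"].unique())
    aneu = pd.DataFrame(
        {f"aneu_{c}": np.where(marker_map["chrom"] == c, "HOM_DONOR", "HET") for c in chroms},
        index=marker_map["marker"],
    )
    assignments = rhmap.chromosome_by_aneuploid(aneu, {f"aneu_{c}": c for c in chroms})

    out = {
        "status": "run",
        "n_markers_mapped": len(marker_map),
        "n_pruned": int(len(matrix) - len(pruned)),
        "n_groups": len(groups),
        "n_singletons": len(singles),
        "unexpected_genotype_markers": len(warn_counts),
        "aneuploid_assigned": sum(1 for v in assignments.values()
                                  if v not in (None, "ambiguous")),
        "mean_deletions_per_marker": float(pruned.sum(axis=1).mean()) if len(pruned) else None,
    }
    if len(pruned) >= 4:
        res = rhmap.deletion_outliers(pruned)
        csio.write_table(
            pd.DataFrame({"marker": res.counts.index, "deletions": res.counts.values,
                          "flagged": [m in set(res.flagged) for m in res.counts.index]}),
            outdir / "deletion_outliers.tsv",
        )
        out["outliers"] = {"q1": res.q1, "q3": res.q3, "threshold": res.threshold,
                           "flagged": res.flagged,
                           "share_percent": percent(len(res.flagged), len(res.counts), 1)}
    ledger["rh"] = {"markers_in": len(matrix), "pruned_out": out["n_pruned"],
                    "grouped": sum(len(g) for g in groups), "singletons": len(singles)}
    _conserve("rh grouping", len(pruned),
              {"grouped": sum(len(g) for g in groups), "singletons": len(singles)})
    return out


def summarize(run_dir) -> dict:
    """Re-read a completed run directory into the summary report dict.

    Missing sections are flagged rather than fatal, so a partial run can
    still be inspected.
    """
    run_dir = Path(run_dir)
    path = run_dir / "report.json"
    if not path.exists():
        return {"status": "missing", "reason": "no report.json in run directory"}
    report = json.loads(path.read_text())
    for section in ("ts_tv", "placement", "rh", "shared"):
        if section not in report:
            report[section] = {"status": "missing"}
    return report
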