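"""Synthetic-world generator: determinism, planted truth, distributions."""

import numpy as np
import pandas as pd
import pytest

from cottonsnp.simulate import (
    SimulationConfig, simulate_cds_annotations, simulate_donor_pileups,
    simulate_reference, simulate_rh_panel, simulate_self_pileups,
    write_fixture_bundle,
)


class TestConfig:
    def test_rates_validated(self):
        with pytest.raises(ValueError, match="in \\[0, 1\\]"):
            SimulationConfig(error_rate=1.5)

    def test_contig_length_floor(self):
        with pytest.raises(ValueError, match="101"):
            SimulationConfig(contig_length_mean=80)


class TestReference:
    def test_contig_count_and_min_length(self):
        cfg = SimulationConfig(n_contigs=10, contig_length_mean=500, seed=0)
        contigs, _ = simulate_reference(cfg)
        assert len(contigs) == 10
        assert all(len(s) >= 101 for s in contigs.values())

    def test_zero_homeolog_rate_empty(self):
        cfg = SimulationConfig(n_contigs=5, homeolog_site_rate=0.0, seed=0)
        _, truth = simulate_reference(cfg)
        assert truth.homeolog_sites.empty

    def test_homeolog_count_binomial(self):
        cfg = SimulationConfig(n_contigs=100, contig_length_mean=1000,
                               contig_length_sd=0, homeolog_site_rate=0.01, seed=3)
        contigs, truth = simulate_reference(cfg)
        n_bp = sum(len(s) for s in contigs.values())
        mean, sd = n_bp * 0.01, np.sqrt(n_bp * 0.01 * 0.99)
        assert abs(len(truth.homeolog_sites) - mean) < 3 * sd

    def test_planted_positions_inside_contigs(self, small_world):
        _, contigs, truth = small_world
        for rec in truth.planted_snps.itertuples():
            assert 1 <= rec.pos <= len(contigs[rec.contig])
            assert contigs[rec.contig][rec.pos - 1] == rec.ref
            assert rec.alt != rec.ref

    def test_determinism(self):
        cfg = SimulationConfig(n_contigs=6, seed=11)
        c1, t1 = simulate_reference(cfg)
        c2, t2 = simulate_reference(cfg)
        assert c1 == c2
        pd.testing.assert_frame_equal(t1.planted_snps, t2.planted_snps)


class TestDonorPileups:
    def test_error_free_constant_depth_pure_alt(self):
        cfg = SimulationConfig(n_contigs=6, error_rate=0.0, indel_rate=0.0,
                               mean_depth=20, depth_dist="constant", seed=2)
        contigs, truth = simulate_reference(cfg)
        pu = simulate_donor_pileups(contigs, truth, "Gb", cfg)
        planted = truth.planted_snps.query("species == 'Gb'")
        idx = pu.set_index(["contig", "pos"])
        for rec in planted.itertuples():
            row = idx.loc[(rec.contig, rec.pos)]
            assert row[rec.alt] == 20 and row["depth"] == 20

    def test_zero_depth_empty_stream(self):
        cfg = SimulationConfig(n_contigs=3, mean_depth=0, seed=2)
        contigs, truth = simulate_reference(cfg)
        assert simulate_donor_pileups(contigs, truth, "Gb", cfg).empty

    def test_alt_purity_high_under_one_percent_error(self):
        cfg = SimulationConfig(n_contigs=60, contig_length_mean=500,
                               donor_divergence=0.02, error_rate=0.01,
                               mean_depth=20, depth_dist="constant", seed=5)
        contigs, truth = simulate_reference(cfg)
        pu = simulate_donor_pileups(contigs, truth, "Gb", cfg)
        planted = truth.planted_snps.query("species == 'Gb'")
        assert len(planted) > 300
        idx = pu.set_index(["contig", "pos"])
        purities = []
        for rec in planted.itertuples():
            row = idx.loc[(rec.contig, rec.pos)]
            purities.append(row[rec.alt] / row["depth"])
        # P(Binom(20, 0.99) >= 18) ~ 0.999: at least 99% of sites pass 0.9
        assert np.mean(np.asarray(purities) >= 0.9) >= 0.99


class TestSelfPileups:
    def test_no_homeologs_means_pure_reference(self):
        cfg = SimulationConfig(n_contigs=4, homeolog_site_rate=0.0,
                               error_rate=0.01, mean_depth=30, seed=6)
        contigs, truth = simulate_reference(cfg)
        pu = simulate_self_pileups(contigs, truth, cfg)
        ref_counts = pu.apply(lambda r: r[r["ref"]], axis=1)
        assert (ref_counts / pu["depth"] >= 0.8).all()

    def test_homeolog_minor_allele_binomial_half(self):
        cfg = SimulationConfig(n_contigs=80, contig_length_mean=400,
                               homeolog_site_rate=0.02, error_rate=0.0,
                               mean_depth=20, depth_dist="constant", seed=8)
        contigs, truth = simulate_reference(cfg)
        pu = simulate_self_pileups(contigs, truth, cfg)
        idx = pu.set_index(["contig", "pos"])
        fracs = []
        for rec in truth.homeolog_sites.itertuples():
            row = idx.loc[(rec.contig, rec.pos)]
            fracs.append(row[rec.other] / row["depth"])
        fracs = np.asarray(fracs)
        assert len(fracs) > 200
        # mean of Binomial(20, .5)/20 is .5 with SE ~ 0.112/sqrt(n)
        assert abs(fracs.mean() - 0.5) < 4 * 0.112 / np.sqrt(len(fracs))

    def test_stream_deterministic(self):
        cfg = SimulationConfig(n_contigs=4, seed=9)
        contigs, truth = simulate_reference(cfg)
        pd.testing.assert_frame_equal(
            simulate_self_pileups(contigs, truth, cfg),
            simulate_self_pileups(contigs, truth, cfg),
        )


class TestCds:
    def test_every_contig_annotated_in_frame(self, small_world):
        config, contigs, _ = small_world
        cds = simulate_cds_annotations(contigs, config)
        assert set(cds["contig"]) == set(contigs)
        assert len(cds) == len(contigs)
        for rec in cds.itertuples():
            assert 1 <= rec.cds_start <= rec.cds_end <= len(contigs[rec.contig])
            assert (rec.cds_end - rec.cds_start + 1) % 3 == 0
            assert rec.strand in "+-"


class TestRhPanel:
    def _map(self, n=40, chroms=2, rng_seed=0):
        rng = np.random.default_rng(rng_seed)
        return pd.DataFrame({
            "marker": [f"m{i}" for i in range(n)],
            "chrom": [f"chr{i % chroms}" for i in range(n)],
            "cr": rng.uniform(0, 150, n),
        })

    def test_zero_deletion_freq_all_het(self):
        cfg = SimulationConfig(rh_deletion_freq=0.0, missing_rate=0.05, seed=4)
        geno, truth = simulate_rh_panel(self._map(), cfg)
        vals = set(geno.to_numpy().ravel())
        assert vals <= {"HET", "NA"}
        assert truth.rh_true_deletions.to_numpy().sum() == 0

    def test_copositioned_markers_share_truth_columns(self):
        mm = self._map(10, 1)
        mm.loc[1, "cr"] = mm.loc[0, "cr"]
        cfg = SimulationConfig(seed=14)
        _, truth = simulate_rh_panel(mm, cfg)
        td = truth.rh_true_deletions
        assert (td["m0"] == td["m1"]).all()

    def test_duplicate_marker_ids_rejected(self):
        mm = self._map(5, 1)
        mm.loc[1, "marker"] = "m0"
        with pytest.raises(ValueError, match="duplicate"):
            simulate_rh_panel(mm, SimulationConfig(seed=0))

    def test_mean_deletions_per_marker(self):
        mm = self._map(500, 5, rng_seed=1)
        cfg = SimulationConfig(rh_n_hybrids=131, rh_deletion_freq=0.069,
                               missing_rate=0.0, seed=20)
        _, truth = simulate_rh_panel(mm, cfg)
        per_marker = truth.rh_true_deletions.sum(axis=0)
        # Binomial(131, 0.069): mean 9.04, the 500-marker average has a
        # between-marker correlation, so allow 3 SD of the marker-level SD
        assert abs(per_marker.mean() - 131 * 0.069) < 3 * np.sqrt(131 * 0.069 * 0.931)


class TestBundle:
    def _outputs(self, seed):
        cfg = SimulationConfig(n_contigs=4, seed=seed)
        contigs, truth = simulate_reference(cfg)
        return {
            "config": cfg, "contigs": contigs,
            "boundaries": truth.boundary_truth,
            "pileup_self": simulate_self_pileups(contigs, truth, cfg),
            "cds": simulate_cds_annotations(contigs, cfg),
        }

    def test_round_trip_and_hash_stability(self, tmp_path):
        from cottonsnp import io as csio
        out = self._outputs(31)
        m1 = write_fixture_bundle(out, tmp_path / "b1")
        m2 = write_fixture_bundle(self._outputs(31), tmp_path / "b2")
        assert m1["bundle_hash"] == m2["bundle_hash"]
        contigs = csio.read_fasta(tmp_path / "b1" / "contigs.fasta")
        assert contigs == out["contigs"]
        pu = csio.read_pileup(tmp_path / "b1" / "pileup_self.tsv")
        pd.testing.assert_frame_equal(pu, out["pileup_self"])
        bounds = csio.read_boundaries(tmp_path / "b1" / "boundaries.tsv")
        expect = {c: v for c, v in out["boundaries"].items() if v}
        assert bounds == expect

    def test_hash_changes_with_seed(self, tmp_path):
        m1 = write_fixture_bundle(self._outputs(31), tmp_path / "a")
        m2 = write_fixture_bundle(self._outputs(32), tmp_path / "b")
        assert m1["bundle_hash"] != m2["bundle_hash"]
        assert m1["config_hash"] != m2["config_hash"]
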