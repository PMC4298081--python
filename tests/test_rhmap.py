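"""RH deletion calling, two-point likelihood, grouping, binning,
ordering, deficiency mapping and outlier detection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cottonsnp.rhmap import (
    bin_group, build_groups, call_deletions, chromosome_by_aneuploid,
    deletion_outliers, link_from_counts, obligate_breaks, order_group,
    pairwise_links, prune_markers, tukey_hinges, two_point_link,
)


def _geno(rows, hybrids=None):
    hybrids = hybrids or [f"h{i}" for i in range(len(next(iter(rows.values()))))]
    return pd.DataFrame.from_dict(rows, orient="index", columns=hybrids)


class TestCallDeletions:
    def test_code_translation(self):
        g = _geno({"m1": ["HET", "HOM_DONOR", "NA", "HOM_REF"]})
        mat, warn = call_deletions(g)
        row = mat.loc["m1"]
        assert row.iloc[0] == 0 and row.iloc[1] == 1
        assert np.isnan(row.iloc[2]) and np.isnan(row.iloc[3])
        assert warn == {"m1": 1}  # the unexpected homozygote

    def test_direction_switch(self):
        g = _geno({"m1": ["HET", "HOM_REF", "HOM_DONOR"]})
        mat, warn = call_deletions(g, deletion_genotype="HOM_REF")
        assert mat.loc["m1"].iloc[1] == 1 and np.isnan(mat.loc["m1"].iloc[2])

    def test_all_na_marker_dropped(self):
        g = _geno({"m1": ["NA", "NA"], "m2": ["HET", "HOM_DONOR"]})
        with pytest.warns(UserWarning, match="no scored hybrid"):
            mat, _ = call_deletions(g)
        assert list(mat.index) == ["m2"]

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError, match="unknown genotype"):
            call_deletions(_geno({"m1": ["HET", "XX"]}))


class TestPrune:
    def test_zero_deletion_marker_removed(self):
        mat = pd.DataFrame([[0, 0, 0], [0, 1, 0]], index=["m0", "m1"])
        out = prune_markers(mat.astype(float))
        assert list(out.index) == ["m1"]

    def test_all_deleted_marker_removed_with_warning(self):
        mat = pd.DataFrame([[1, 1, 1], [0, 1, 0]], index=["bad", "ok"]).astype(float)
        with pytest.warns(UserWarning, match="every scored hybrid"):
            out = prune_markers(mat)
        assert list(out.index) == ["ok"]


def _grid_oracle(n11, n10, n01, n00, step=1e-3):
    """Exhaustive (theta, r) likelihood grid with local refinement."""
    def ll(n1001, T, R):
        p11 = (1 - T) * R + T * R ** 2
        p10 = T * R * (1 - R)
        p00 = (1 - T) * (1 - R) + T * (1 - R) ** 2
        # terms with zero count contribute 0 even at p=0
        tot = np.zeros_like(T)
        for n, p in ((n11, p11), (n1001, p10), (n00, p00)):
            if n:
                with np.errstate(divide="ignore"):
                    tot = tot + n * np.log(p)
        return np.where(np.isfinite(tot), tot, -np.inf)

    th = np.arange(0, 1 + step / 2, step)
    r = np.arange(0, 1 + step / 2, step)
    T, R = np.meshgrid(th, r, indexing="ij")
    n1001 = n10 + n01
    L = ll(n1001, T, R)
    i, j = np.unravel_index(np.argmax(L), L.shape)
    t0, r0 = th[i], r[j]
    for s in (1e-4, 1e-5):
        th = np.clip(np.arange(t0 - 20 * s, t0 + 20 * s + s / 2, s), 0, 1)
        r = np.clip(np.arange(r0 - 20 * s, r0 + 20 * s + s / 2, s), 0, 1)
        T, R = np.meshgrid(th, r, indexing="ij")
        L = ll(n1001, T, R)
        i, j = np.unravel_index(np.argmax(L), L.shape)
        t0, r0 = th[i], r[j]
    return t0, r0


class TestTwoPoint:
    def test_identical_columns_zero_breakage(self):
        mat = pd.DataFrame([[0, 1, 0, 0, 1], [0, 1, 0, 0, 1]],
                           index=["a", "b"]).astype(float)
        link = two_point_link("a", "b", mat)
        assert link.theta_hat == 0 and link.distance_cR == 0
        assert link.lod > 0

    def test_perfect_coretention_matches_grid(self):
        link = link_from_counts("a", "b", 85, 0, 0, 15)
        tg, rg = _grid_oracle(85, 0, 0, 15)
        assert link.theta_hat == pytest.approx(tg, abs=1e-3)
        assert link.r_hat == pytest.approx(rg, abs=1e-3)
        assert link.theta_hat == 0

    def test_independence_table_theta_one_lod_zero(self):
        # r = 0.9 exactly; discordance matches independent retention
        link = link_from_counts("a", "b", 81, 9, 9, 1)
        assert link.r_hat == pytest.approx(0.9)
        assert link.theta_hat == 1.0
        assert link.lod == 0.0
        assert math.isinf(link.distance_cR)

    def test_undefined_at_full_retention(self):
        assert link_from_counts("a", "b", 50, 0, 0, 0) is None

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(rng.integers(0, 2, size=(2, 60)),
                           index=["a", "b"]).astype(float)
        ab = two_point_link("a", "b", mat)
        ba = two_point_link("b", "a", mat)
        assert ab.lod == pytest.approx(ba.lod)
        assert ab.distance_cR == pytest.approx(ba.distance_cR)

    def test_missing_cells_pairwise_complete(self):
        mat = pd.DataFrame([[0, 1, np.nan, 0], [0, 1, 0, np.nan]],
                           index=["a", "b"]).astype(float)
        link = two_point_link("a", "b", mat)
        assert link.n11 + link.n10 + link.n01 + link.n00 == 2


class TestGrouping:
    def _matrix_for(self, links_spec):
        return None

    def test_threshold_and_transitivity(self):
        links = pd.DataFrame([
            {"a": "a", "b": "b", "lod": 3.1, "cR": 40.0},
            {"a": "b", "b": "c", "lod": 5.0, "cR": 10.0},
            {"a": "a", "b": "c", "lod": 0.2, "cR": 500.0},
            {"a": "c", "b": "d", "lod": 2.9, "cR": 10.0},
        ])
        groups, singles = build_groups(links, ["a", "b", "c", "d"])
        assert groups == [["a", "b", "c"]]
        assert singles == ["d"]

    def test_distance_threshold(self):
        links = pd.DataFrame([{"a": "a", "b": "b", "lod": 9.0, "cR": 101.0}])
        groups, singles = build_groups(links, ["a", "b"])
        assert groups == [] and singles == ["a", "b"]


class TestBins:
    def test_identical_columns_one_bin(self):
        mat = pd.DataFrame([[0, 1, 0], [0, 1, 0], [1, 0, 0]],
                           index=["a", "b", "c"]).astype(float)
        assert bin_group(["a", "b", "c"], mat) == [["a", "b"], ["c"]]

    def test_one_scored_difference_splits(self):
        mat = pd.DataFrame([[0, 1, 0], [0, 1, 1]], index=["a", "b"]).astype(float)
        assert bin_group(["a", "b"], mat) == [["a"], ["b"]]

    def test_missing_is_wildcard(self):
        mat = pd.DataFrame([[0, 1, np.nan], [0, 1, 0]], index=["a", "b"]).astype(float)
        assert bin_group(["b", "a"], mat) == [["a", "b"]]

    def test_input_order_invariance(self):
        rng = np.random.default_rng(8)
        mat = pd.DataFrame(rng.integers(0, 2, (6, 30)),
                           index=list("abcdef")).astype(float)
        ref = bin_group(list("abcdef"), mat)
        assert bin_group(list("fedcba"), mat) == ref


class TestOrdering:
    def test_three_markers_brute_force(self):
        # markers at cR-like spacing 0/10/500: the distant one must be terminal
        rng = np.random.default_rng(3)
        base = rng.integers(0, 2, 80).astype(float)
        near = base.copy()
        near[rng.integers(0, 80, 2)] = 1 - near[rng.integers(0, 80, 2)]
        far = rng.integers(0, 2, 80).astype(float)
        mat = pd.DataFrame([base, near, far], index=["m0", "m10", "m500"])
        order, breaks = order_group(["m0", "m10", "m500"], mat, seed=0)
        best = min(
            (obligate_breaks(list(p), mat) for p in itertools.permutations(mat.index)),
        )
        assert breaks == best
        assert order[1] != "m500"  # distant marker is terminal in an optimal order

    def test_pair_is_trivial(self):
        mat = pd.DataFrame([[0, 1], [1, 0]], index=["a", "b"]).astype(float)
        order, breaks = order_group(["a", "b"], mat)
        assert order == ["a", "b"] and breaks == obligate_breaks(order, mat)

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(12)
        mat = pd.DataFrame(rng.integers(0, 2, (5, 40)), index=list("abcde")).astype(float)
        order, breaks = order_group(list("abcde"), mat, seed=1)
        assert obligate_breaks(order[::-1], mat) == breaks


class TestAneuploids:
    LINES = {"L17": "chr17", "L05": "chr05"}

    def test_single_line_signature_assigns(self):
        calls = pd.DataFrame({"L17": ["HOM_DONOR"], "L05": ["HET"]}, index=["m1"])
        assert chromosome_by_aneuploid(calls, self.LINES) == {"m1": "chr17"}

    def test_het_everywhere_unassigned(self):
        calls = pd.DataFrame({"L17": ["HET"], "L05": ["HET"]}, index=["m1"])
        assert chromosome_by_aneuploid(calls, self.LINES) == {"m1": None}

    def test_two_chromosome_signature_ambiguous(self):
        calls = pd.DataFrame({"L17": ["HOM_DONOR"], "L05": ["HOM_DONOR"]}, index=["m1"])
        assert chromosome_by_aneuploid(calls, self.LINES) == {"m1": "ambiguous"}


class TestOutliers:
    def test_hand_computed_hinges(self):
        counts = [2, 2, 3, 3, 4, 4, 5, 20]
        q1, q3 = tukey_hinges(counts)
        assert (q1, q3) == (2.5, 4.5)
        mat = pd.DataFrame(
            [[1.0] * c + [0.0] * (25 - c) for c in counts],
            index=[f"m{i}" for i in range(8)],
        )
        res = deletion_outliers(mat)
        assert res.threshold == 7.5
        assert res.flagged == ["m7"]

    def test_constant_counts_nothing_flagged(self):
        mat = pd.DataFrame([[1.0, 0.0, 1.0]] * 6, index=[f"m{i}" for i in range(6)])
        assert deletion_outliers(mat).flagged == []

    def test_too_few_markers_refused(self):
        mat = pd.DataFrame([[1.0, 0.0]] * 3, index=list("abc"))
        with pytest.raises(ValueError, match=">= 4"):
            deletion_outliers(mat)

    def test_odd_n_median_excluded_from_both_halves(self):
        assert tukey_hinges([1, 2, 3, 4, 100]) == (1.5, 52.0)


def test_pairwise_links_match_single_pair_route():
    rng = np.random.default_rng(44)
    mat = pd.DataFrame(rng.choice([0.0, 1.0, np.nan], size=(5, 131), p=[0.9, 0.07, 0.03]),
                       index=[f"m{i}" for i in range(5)])
    mat = prune_markers(mat)
    links = pairwise_links(mat)
    for rec in links.itertuples():
        single = two_point_link(rec.a, rec.b, mat)
        assert single.lod == pytest.approx(rec.lod)
        assert single.theta_hat == pytest.approx(rec.theta)
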