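"""Masking, proportions, filters, thinning, concordance and posterior summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lanctk import (
    MISSING,
    PosteriorArray,
    avg_max_posterior,
    concordance_table,
    filter_by_ancestry_threshold,
    filter_reference_panel,
    global_proportions,
    intersect_sites,
    mask_by_ancestry,
    match_diploid_calls,
    thin_markers,
)

from conftest import (
    make_calls,
    make_multi_chrom_sites,
    make_panel,
    make_sites,
    unordered_pairs,
)

LABELS = ("African", "Amerindian", "European")


class TestMask:
    def test_all_target_is_identity(self, rng):
        alleles = rng.integers(0, 2, size=(4, 10))
        panel = make_panel(alleles)
        calls = make_calls(np.ones((4, 10)))
        out = mask_by_ancestry(panel, calls, "African")
        np.testing.assert_array_equal(out.alleles, panel.alleles)

    def test_no_target_is_all_missing(self, rng):
        panel = make_panel(rng.integers(0, 2, size=(4, 10)))
        calls = make_calls(np.full((4, 10), 2))
        out = mask_by_ancestry(panel, calls, "European")
        assert (out.alleles == MISSING).all()

    def test_mixed_rows_masked_fraction(self):
        # row 1 called (Afr, Afr, Eur, Eur), row 2 all Eur; target African
        panel = make_panel(
            [[0, 1, 1, 0], [1, 0, 0, 1]], sample_ids=["a", "b"], copies=[1, 1]
        )
        calls = make_calls([[1, 1, 3, 3], [3, 3, 3, 3]],
                           sample_ids=["a", "b"], copies=[1, 1])
        out = mask_by_ancestry(panel, calls, "African")
        np.testing.assert_array_equal(out.alleles[0], [0, 1, MISSING, MISSING])
        assert (out.alleles[1] == MISSING).all()
        assert (out.alleles == MISSING).sum() == 6  # 6/8 cells masked

    def test_original_missing_stays_missing(self):
        panel = make_panel([[MISSING, 1]], sample_ids=["a"], copies=[1])
        calls = make_calls([[1, 1]], sample_ids=["a"], copies=[1])
        out = mask_by_ancestry(panel, calls, "African")
        assert out.alleles[0, 0] == MISSING

    def test_unknown_target_errors(self, rng):
        panel = make_panel(rng.integers(0, 2, size=(2, 4)))
        calls = make_calls(np.ones((2, 4)))
        with pytest.raises(KeyError):
            mask_by_ancestry(panel, calls, "Oceanian")

    def test_masks_over_all_targets_partition_nonmissing_cells(self, rng):
        alleles = rng.integers(0, 2, size=(6, 40)).astype(np.int8)
        alleles[rng.random(alleles.shape) < 0.1] = MISSING
        panel = make_panel(alleles)
        calls = make_calls(rng.integers(1, 4, size=(6, 40)))
        total = (panel.alleles != MISSING).sum()
        parts = sum(
            (mask_by_ancestry(panel, calls, t).alleles != MISSING).sum()
            for t in LABELS
        )
        assert parts == total


class TestGlobalProportions:
    def test_pure_european_sample(self):
        props = global_proportions(make_calls(np.full((2, 7), 3)))
        np.testing.assert_allclose(props["S0"], [0, 0, 1])

    def test_half_and_half_haplotypes(self):
        calls = make_calls(np.vstack([np.ones(9), np.full(9, 3)]))
        np.testing.assert_allclose(global_proportions(calls)["S0"], [0.5, 0, 0.5])

    def test_direct_count(self):
        mat = np.full((2, 10), 3)
        mat[0, :5] = 1  # 5 African + 15 European cells
        np.testing.assert_allclose(
            global_proportions(make_calls(mat))["S0"], [0.25, 0, 0.75]
        )

    def test_missing_cells_excluded_and_all_missing_flagged(self):
        mat = np.array([[1, MISSING, 3], [3, 3, MISSING]])
        calls = make_calls(mat)
        np.testing.assert_allclose(global_proportions(calls)["S0"], [0.25, 0, 0.75])
        props = global_proportions(make_calls(np.full((2, 3), MISSING)))
        assert props.undefined == ["S0"]
        assert np.isnan(props["S0"]).all()


class TestThresholdFilter:
    def test_boundary_is_inclusive(self):
        calls = make_calls(np.vstack([np.ones(10), np.r_[np.full(5, 2), np.full(5, 3)]]))
        props = global_proportions(calls)  # (0.5, 0.25, 0.25)
        assert filter_by_ancestry_threshold(props, "African", 0.5) == ["S0"]
        assert filter_by_ancestry_threshold(props, "Amerindian", 0.5) == []

    def test_matches_brute_force_on_random_proportions(self, rng):
        n, m = 100, 200
        frac = rng.beta(2, 2, size=n)
        rows = []
        for f in frac:
            n_afr = int(round(f * 2 * m))
            rows.append(np.r_[np.ones(n_afr), np.full(2 * m - n_afr, 3)])
        mat = np.vstack(rows).reshape(n * 1, 2 * m)
        # one haplotype row per "sample" keeps the arithmetic transparent
        calls = make_calls(mat, sample_ids=[f"I{i}" for i in range(n)],
                           copies=[1] * n)
        props = global_proportions(calls)
        got = set(filter_by_ancestry_threshold(props, "African", 0.5))
        expected = {
            f"I{i}" for i in range(n)
            if (mat[i] == 1).sum() / (2 * m) >= 0.5
        }
        assert got == expected


class TestThinMarkers:
    def test_identity_when_target_equals_m(self, rng):
        panel = make_panel(rng.integers(0, 2, size=(2, 50)))
        out = thin_markers(panel, 50)
        np.testing.assert_array_equal(out.alleles, panel.alleles)

    def test_even_spacing_single_chromosome(self, rng):
        panel = make_panel(rng.integers(0, 2, size=(2, 100)))
        out = thin_markers(panel, 10)
        assert out.n_sites == 10
        kept = np.flatnonzero(
            np.isin(panel.sites.pos_bp, out.sites.pos_bp)
        )
        np.testing.assert_array_equal(kept, [0, 11, 22, 33, 44, 55, 66, 77, 88, 99])
        gaps = np.diff(kept)
        assert gaps.max() - gaps.min() <= 1

    def test_largest_remainder_across_chromosomes(self, rng):
        sites = make_multi_chrom_sites([300, 100])
        panel = make_panel(rng.integers(0, 2, size=(2, 400)), sites=sites)
        out = thin_markers(panel, 100)
        counts = pd.Series(out.sites.chrom).value_counts()
        assert counts["1"] == 75 and counts["2"] == 25

    def test_invalid_target_errors(self, rng):
        panel = make_panel(rng.integers(0, 2, size=(2, 10)))
        with pytest.raises(ValueError):
            thin_markers(panel, 0)
        with pytest.raises(ValueError):
            thin_markers(panel, 11)


class TestReferencePanelFilter:
    Q = pd.DataFrame(
        [
            [0.92, 0.05, 0.02, 0.01],
            [0.01, 0.02, 0.02, 0.95],
            [0.89, 0.11, 0.0, 0.0],
        ],
        index=["a", "b", "c"],
        columns=["Africa", "America", "Europe", "EastAsia"],
    )

    def test_high_fraction_retained_with_cluster(self):
        out = filter_reference_panel(self.Q)
        assert ("a", "Africa") in set(map(tuple, out.to_numpy()))

    def test_excluded_cluster_dominant_is_dropped(self):
        out = filter_reference_panel(self.Q, exclude={"EastAsia"})
        assert "b" not in set(out["individual"])

    def test_strictly_below_threshold_dropped(self):
        out = filter_reference_panel(self.Q)
        assert "c" not in set(out["individual"])

    def test_threshold_inclusive(self):
        q = pd.DataFrame([[0.9, 0.1]], index=["x"], columns=["A", "B"])
        assert list(filter_reference_panel(q)["individual"]) == ["x"]

    def test_excluding_all_clusters_errors(self):
        with pytest.raises(ValueError, match="all clusters"):
            filter_reference_panel(self.Q, exclude=set(self.Q.columns))


class TestIntersectSites:
    def test_identical_maps(self):
        sites = make_sites(6)
        ia, ib = intersect_sites(sites, sites)
        np.testing.assert_array_equal(ia, np.arange(6))
        np.testing.assert_array_equal(ib, np.arange(6))

    def test_disjoint_maps(self):
        a = make_sites(4, start=1000)
        b = make_sites(4, start=100500)
        ia, ib = intersect_sites(a, b)
        assert len(ia) == len(ib) == 0

    def test_partial_overlap_matches_set_oracle(self):
        a = make_sites(10, start=1000)  # positions 1000..10000
        b = make_sites(8, start=6000)  # positions 6000..13000
        ia, ib = intersect_sites(a, b)
        shared = sorted(set(a.pos_bp) & set(b.pos_bp))
        assert len(ia) == len(shared) == 5
        np.testing.assert_array_equal(a.pos_bp[ia], shared)
        np.testing.assert_array_equal(b.pos_bp[ib], shared)

    def test_duplicate_positions_error(self):
        tab = make_sites(3).table.copy()
        tab.loc[2, "pos_bp"] = tab.loc[1, "pos_bp"]
        tab = tab.sort_values("pos_bp")
        import lanctk
        dup = lanctk.SiteMap.__new__(lanctk.SiteMap)
        object.__setattr__(dup, "table", tab)
        with pytest.raises(ValueError, match="duplicate"):
            intersect_sites(dup, make_sites(3))


def _match_oracle(a, b):
    """Brute-force maximum agreement over the two alignments."""
    (a1, a2), (b1, b2) = a, b
    return max((a1 == b1) + (a2 == b2), (a1 == b2) + (a2 == b1))


class TestMatchDiploidCalls:
    def test_one_shared_african_haplotype(self):
        # calls African/European vs Amerindian/African agree on one
        # haplotype being African
        afr, amr, eur = 1, 2, 3
        agreement, pairing = match_diploid_calls((afr, eur), (amr, afr))
        assert agreement == 1
        assert (afr, afr) in pairing

    def test_identical_calls_agree_twice(self):
        assert match_diploid_calls((1, 3), (1, 3))[0] == 2

    def test_exhaustive_grid_matches_enumeration_oracle(self):
        for a in unordered_pairs():
            for b in unordered_pairs():
                assert match_diploid_calls(a, b)[0] == _match_oracle(a, b)

    def test_tie_broken_toward_identity(self):
        _, pairing = match_diploid_calls((1, 2), (2, 1))
        assert pairing == ((1, 2), (2, 1)) or pairing[0] == (1, 1)
        # identity and swap both give agreement 0 here; identity retained
        _, pairing = match_diploid_calls((1, 2), (3, 3))
        assert pairing == ((1, 3), (2, 3))


def _concordance_oracle(calls_a, calls_b, k=3):
    counts = np.zeros((k, k))
    ids = calls_a.hap_meta["sample_id"].to_numpy()
    for sid in dict.fromkeys(ids):
        r = np.flatnonzero(ids == sid)
        for m in range(calls_a.n_sites):
            a = (calls_a.calls[r[0], m], calls_a.calls[r[1], m])
            b = (calls_b.calls[r[0], m], calls_b.calls[r[1], m])
            if MISSING in a or MISSING in b:
                continue
            _, pairing = match_diploid_calls(a, b)
            for la, lb in pairing:
                counts[la - 1, lb - 1] += 1
    return counts / counts.sum()


class TestConcordance:
    def test_identical_call_sets_are_fully_diagonal(self, rng):
        calls = make_calls(rng.integers(1, 4, size=(8, 20)))
        table = concordance_table(calls, calls)
        assert table.overall_agreement == pytest.approx(1.0)
        off = table.table.to_numpy()[~np.eye(3, dtype=bool)]
        assert (off == 0).all()

    def test_phase_swap_invariance(self, rng):
        calls = make_calls(rng.integers(1, 4, size=(8, 20)))
        swapped = make_calls(calls.calls.reshape(4, 2, 20)[:, ::-1].reshape(8, 20))
        assert concordance_table(calls, swapped).overall_agreement == pytest.approx(1.0)

    def test_random_relabeling_matches_enumeration_oracle(self, rng):
        a = make_calls(rng.integers(1, 4, size=(40, 50)))
        mat = a.calls.copy()
        flips = rng.random(mat.shape) < 0.05
        mat[flips] = (mat[flips] % 3) + 1
        b = make_calls(mat)
        table = concordance_table(a, b)
        np.testing.assert_allclose(table.table.to_numpy(),
                                   _concordance_oracle(a, b), atol=1e-12)

    def test_swap_of_arguments_transposes_table(self, rng):
        a = make_calls(rng.integers(1, 4, size=(10, 30)))
        mat = a.calls.copy()
        flips = rng.random(mat.shape) < 0.1
        mat[flips] = (mat[flips] % 3) + 1
        b = make_calls(mat)
        t_ab = concordance_table(a, b).table.to_numpy()
        t_ba = concordance_table(b, a).table.to_numpy()
        np.testing.assert_allclose(t_ab, t_ba.T, atol=1e-12)

    def test_dimension_mismatch_errors(self, rng):
        a = make_calls(rng.integers(1, 4, size=(4, 10)))
        b = make_calls(rng.integers(1, 4, size=(4, 11)))
        with pytest.raises(ValueError):
            concordance_table(a, b)


class TestAvgMaxPosterior:
    def test_confident_call_assigned_to_winner(self):
        probs = np.array([[[0.99, 0.009, 0.001]]])
        out = avg_max_posterior(PosteriorArray(probs), LABELS)
        afr = out[out["ancestry"] == "African"].iloc[0]
        assert afr["mean_max_posterior"] == pytest.approx(0.99)
        assert afr["n_cells"] == 1

    def test_uniform_slices_give_one_third(self):
        probs = np.full((4, 3, 3), 1 / 3)
        out = avg_max_posterior(PosteriorArray(probs), LABELS)
        overall = out[out["ancestry"] == "Overall"].iloc[0]
        assert overall["mean_max_posterior"] == pytest.approx(1 / 3)

    def test_group_means_match_loop_oracle(self, rng):
        raw = rng.random((4, 3, 3))
        probs = raw / raw.sum(axis=2, keepdims=True)
        out = avg_max_posterior(PosteriorArray(probs), LABELS)
        sums = {lab: [] for lab in LABELS}
        for h, m in itertools.product(range(4), range(3)):
            j = int(np.argmax(probs[h, m]))
            sums[LABELS[j]].append(probs[h, m, j])
        for lab in LABELS:
            row = out[out["ancestry"] == lab].iloc[0]
            if sums[lab]:
                assert row["mean_max_posterior"] == pytest.approx(np.mean(sums[lab]))
            else:
                assert np.isnan(row["mean_max_posterior"])
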