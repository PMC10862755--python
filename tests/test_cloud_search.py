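import math

import numpy as np
import pytest

from sparsehmm.cloud_search import (AntiDiagBounds, CloudMatrix, CloudScores,
                                    NonIntersecting, PruneParams,
                                    Seed, cloud_search_backward,
                                    cloud_search_forward, cloud_union,
                                    fallback_rectangle, prune_antidiagonal,
                                    reorient_to_rows, trim_cloud)
from sparsehmm.synthetic import (make_profile, random_background_sequence,
                                 sample_homolog)
from sparsehmm.profile import TargetSequence

from oracles import naive_restricted_fill, reachability_oracle

INF = math.inf
NO_PRUNE = PruneParams(INF, INF, 1)


class TestPruneAntidiagonal:
    def test_alpha_rule_prunes_from_ends(self):
        keep = prune_antidiagonal(np.array([0.0, -5.0, -13.0]), 0.0, 0.0,
                                  PruneParams(12.0, 20.0, 1))
        assert keep == (0, 1)  # -13 < 0 - 12

    def test_beta_rule_can_prune_everything(self):
        keep = prune_antidiagonal(np.array([4.0, 3.0]), 4.0, 25.0,
                                  PruneParams(12.0, 20.0, 1))
        assert keep is None  # both < 25 - 20: flood fill stops

    def test_no_pruning_below_gamma_length(self):
        vals = np.array([0.0, -100.0, -200.0])
        keep = prune_antidiagonal(vals, 0.0, 0.0, PruneParams(12.0, 20.0, 5))
        assert keep == (0, 2)

    def test_interior_low_cells_survive(self):
        vals = np.array([0.0, -50.0, 0.0])
        keep = prune_antidiagonal(vals, 0.0, 0.0, PruneParams(12.0, 20.0, 1))
        assert keep == (0, 2)


class TestCloudMatrix:
    def test_mod3_placement_rule(self):
        cm = CloudMatrix(10)
        cm.set_cell(3, 4, -1.5, -2.0, -3.0)
        assert cm.m[1, 4] == -1.5  # (3+4) mod 3 == 1
        assert cm.get_m(3, 4) == -1.5

    def test_row_recycling_mod3(self):
        assert CloudMatrix.row_for(11) == CloudMatrix.row_for(8)
        assert CloudMatrix.row_for(12) != CloudMatrix.row_for(11)

    def test_only_three_rows_resident(self):
        cm = CloudMatrix(64)
        assert cm.m.shape[0] == 3


class TestFloodFill:
    def test_no_pruning_covers_full_quadrant(self, rng):
        hmm = make_profile(10, rng)
        seq = random_background_sequence(12, rng)
        bounds, _, _ = cloud_search_forward(hmm, seq, Seed(2, 3, 6, 7),
                                            NO_PRUNE)
        assert bounds.cell_set() == {(i, j) for i in range(2, 11)
                                     for j in range(3, 13)}

    def test_backward_covers_upleft_quadrant(self, rng):
        hmm = make_profile(10, rng)
        seq = random_background_sequence(12, rng)
        bounds, _, _ = cloud_search_backward(hmm, seq, Seed(2, 3, 8, 9),
                                             NO_PRUNE)
        assert bounds.cell_set() == {(i, j) for i in range(1, 9)
                                     for j in range(1, 10)}

    def test_forward_values_match_restricted_quadratic_fill(self, rng):
        for _ in range(5):
            hmm = make_profile(30, rng)
            hom = sample_homolog(hmm, 0.3, 0.02, rng)
            seed = Seed(1, 1, min(hmm.m, hom.n), hom.n)
            vals = {}
            bounds, best, _ = cloud_search_forward(hmm, hom, seed,
                                                   values_out=vals)
            ref = naive_restricted_fill(hmm, hom, seed, bounds.cell_set())
            for cell, v in vals.items():
                if v == -math.inf:
                    assert ref[cell] == -math.inf
                else:
                    assert v == pytest.approx(ref[cell], abs=1e-9)
            assert best == pytest.approx(
                max(0.0, max(ref[c] for c in bounds.cells())), abs=1e-9)

    def test_seed_outside_matrix_errors(self, rng):
        hmm = make_profile(5, rng)
        seq = random_background_sequence(5, rng)
        with pytest.raises(ValueError, match="outside"):
            cloud_search_forward(hmm, seq, Seed(1, 1, 9, 9))

    def test_bound_storage_is_two_cell_pairs_per_antidiagonal(self, rng):
        hmm = make_profile(20, rng)
        seq = random_background_sequence(25, rng)
        bounds, _, _ = cloud_search_forward(hmm, seq, Seed(1, 1, 20, 25))
        for d in bounds.diagonals:
            ll, ur = bounds.lower_left(d), bounds.upper_right(d)
            assert ll[0] + ll[1] == d and ur[0] + ur[1] == d
            assert ll[0] >= ur[0]

    def test_monotone_in_alpha_beta(self, rng):
        hmm = make_profile(25, rng)
        hom = sample_homolog(hmm, 0.4, 0.02, rng)
        seed = Seed(1, 1, min(hmm.m, hom.n), hom.n)
        tight, _, _ = cloud_search_forward(hmm, hom, seed,
                                           PruneParams(6.0, 10.0, 5))
        loose, _, _ = cloud_search_forward(hmm, hom, seed,
                                           PruneParams(12.0, 20.0, 5))
        assert tight.cell_set() <= loose.cell_set()

    def test_best_infwd_never_exceeds_best_fwd(self, rng):
        for _ in range(5):
            hmm = make_profile(20, rng)
            seq = random_background_sequence(30, rng)
            _, bf, bi = cloud_search_forward(hmm, seq, Seed(2, 2, 10, 15))
            assert bf >= bi
            CloudScores(bf, bi, bf, bi).validate()


class TestUnion:
    def _bounds(self, d_map):
        b = AntiDiagBounds()
        for d, (lo, hi) in d_map.items():
            b.set(d, lo, hi)
        return b

    def test_overlapping_intervals_cover_both(self):
        f = self._bounds({5: (1, 3)})
        b = self._bounds({5: (2, 4)})
        u = cloud_union(f, b)
        assert u.get(5) == (1, 4)

    def test_one_sided_antidiagonal_passes_through(self):
        f = self._bounds({5: (1, 2), 7: (3, 6)})
        b = self._bounds({5: (2, 4)})
        u = cloud_union(f, b)
        assert u.get(7) == (3, 6)

    def test_disjoint_clouds_raise(self):
        f = self._bounds({5: (1, 2)})
        b = self._bounds({5: (4, 6)})
        with pytest.raises(NonIntersecting):
            cloud_union(f, b)

    def test_union_is_superset_of_inputs(self, rng):
        hmm = make_profile(25, rng)
        hom = sample_homolog(hmm, 0.4, 0.02, rng)
        seed = Seed(2, 2, min(hmm.m, hom.n - 1), hom.n - 1)
        f, *_ = cloud_search_forward(hmm, hom, seed)
        b, *_ = cloud_search_backward(hmm, hom, seed)
        u = cloud_union(f, b)
        assert u.cell_set() >= f.cell_set()
        assert u.cell_set() >= b.cell_set()


class TestFallbackRectangle:
    def test_rectangle_rows_and_area(self):
        rb = fallback_rectangle(Seed(2, 3, 5, 9))
        assert rb.rows == [2, 3, 4, 5]
        assert all(rb.get(i) == (3, 9) for i in rb.rows)
        assert rb.num_cells() == 4 * 7

    def test_degenerate_seed_gives_single_cell(self):
        rb = fallback_rectangle(Seed(4, 6, 4, 6))
        assert rb.cell_set() == {(4, 6)}


def _random_union(rng):
    """A realistic random cloud union from two pruned flood fills."""
    m = n = 20
    hmm = make_profile(m, rng)
    if rng.random() < 0.5:
        seq = random_background_sequence(n, rng)
    else:
        hom = sample_homolog(hmm, 0.4, 0.05, rng)
        seq = (TargetSequence("h", hom.residues[:n]) if hom.n >= n else hom)
    nn = seq.n
    seed = Seed(int(rng.integers(1, m // 2)), int(rng.integers(1, nn // 2)),
                int(rng.integers(m // 2, m + 1)), int(rng.integers(nn // 2, nn + 1)))
    p = PruneParams(float(rng.uniform(2, 8)), float(rng.uniform(4, 12)),
                    int(rng.integers(1, 7)))
    f, *_ = cloud_search_forward(hmm, seq, seed, p)
    b, *_ = cloud_search_backward(hmm, seq, seed, p)
    try:
        return cloud_union(f, b)
    except NonIntersecting:
        return None


class TestTrimAndReorient:
    def test_rectangle_is_unchanged(self):
        u = AntiDiagBounds()
        # 3x3 rectangle rows 1..3 x cols 1..3 expressed by anti-diagonals
        for d in range(2, 7):
            lo = max(1, d - 3)
            hi = min(3, d - 1)
            u.set(d, lo, hi)
        t = trim_cloud(u)
        assert t.cell_set() == u.cell_set()

    def test_single_cell_spur_is_removed(self):
        u = AntiDiagBounds()
        u.set(2, 1, 1)
        u.set(3, 1, 2)
        u.set(4, 1, 3)
        u.set(5, 2, 3)
        # spur: cell (1, 5) on d=6 far from the body reaching (3, 3)
        u.set(6, 1, 3)
        t = trim_cloud(u)
        assert (1, 5) not in t.cell_set()
        assert (3, 3) in t.cell_set()

    def test_trim_is_subset_and_rows_contiguous(self, rng):
        done = 0
        while done < 40:
            u = _random_union(rng)
            if u is None:
                continue
            t = trim_cloud(u)
            assert t.cell_set() <= u.cell_set()
            rb = reorient_to_rows(t)  # raises on a row gap
            assert rb.cell_set() == t.cell_set()
            done += 1

    def test_trim_matches_reachability_oracle_on_contiguous_sets(self, rng):
        done = compared = 0
        while done < 60:
            u = _random_union(rng)
            if u is None:
                continue
            done += 1
            ds = u.diagonals
            oracle = reachability_oracle(u.cell_set(), ds[0], ds[-1])
            rows = {}
            for (i, j) in oracle:
                rows.setdefault(i, set()).add(j)
            if not all(max(v) - min(v) + 1 == len(v) for v in rows.values()):
                continue  # oracle set itself not row-contiguous
            compared += 1
            assert trim_cloud(u).cell_set() == oracle
        assert compared >= 10

    def test_reorient_single_antidiagonal(self):
        t = AntiDiagBounds()
        t.set(4, 1, 3)
        rb = reorient_to_rows(t)
        assert dict(rb.items()) == {1: (3, 3), 2: (2, 2), 3: (1, 1)}

    def test_reorient_roundtrip_cell_sets(self, rng):
        done = 0
        while done < 20:
            u = _random_union(rng)
            if u is None:
                continue
            t = trim_cloud(u)
            assert reorient_to_rows(t).cell_set() == t.cell_set()
            done += 1
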