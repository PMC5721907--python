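import itertools

import numpy as np
import pytest

from sdmtools import (Candidate, ExtentSpec, FixtureSpec, Grid,
                      ModelEvaluation, TuningSpec, auc, auto_features,
                      binarize, enforce_dispersal, enumerate_candidates,
                      envelope_model, jackknife_evaluate, make_folds,
                      make_landscape, make_occurrences, oer,
                      partition_occurrences, select_best, split_by_clades,
                      voronoi_regions, write_maxent_batch)
from sdmtools.sdm import FEATURE_COMBOS


def same_partition(a, b):
    """Group labels equal up to relabeling (same co-membership)."""
    mapping = {}
    for x, y in zip(a, b):
        if x in mapping and mapping[x] != y:
            return False
        mapping[x] = y
    return len(set(mapping.values())) == len(mapping)


class TestPartition:
    def test_recovers_separated_clusters(self, occ_factory):
        pts = [(0, 0), (1, 0), (0, 1),
               (100, 100), (101, 100), (100, 101),
               (200, 0), (201, 0), (200, 1)]
        part = partition_occurrences(occ_factory(pts), 3, "segregated", seed=0)
        # oracle: exhaustive assignment minimising within-group sum of squares
        pts_arr = np.asarray(pts, dtype=float)
        best_wss, best_assign = np.inf, None
        for assign in itertools.product(range(3), repeat=9):
            if len(set(assign)) < 3:
                continue
            wss = 0.0
            for g in range(3):
                sel = pts_arr[[i for i, a in enumerate(assign) if a == g]]
                wss += ((sel - sel.mean(axis=0)) ** 2).sum()
            if wss < best_wss:
                best_wss, best_assign = wss, assign
        assert same_partition(part.assignment, best_assign)

    @pytest.mark.parametrize("k", [2, 6])
    def test_group_count_bounds(self, occ_factory, k):
        occ = occ_factory(np.random.default_rng(0).uniform(0, 10, (20, 2)))
        with pytest.raises(ValueError, match=r"\[3, 5\]"):
            partition_occurrences(occ, k)

    def test_fewer_points_than_groups_rejected(self, occ_factory):
        with pytest.raises(ValueError, match="at least"):
            partition_occurrences(occ_factory([(0, 0), (1, 1)]), 3)

    def test_random_mode_balanced_and_deterministic(self, occ_factory):
        occ = occ_factory(np.random.default_rng(1).uniform(0, 10, (17, 2)))
        a = partition_occurrences(occ, 4, "random", seed=9)
        b = partition_occurrences(occ, 4, "random", seed=9)
        assert a.assignment.tolist() == b.assignment.tolist()
        counts = np.bincount(a.assignment, minlength=4)
        assert counts.max() - counts.min() <= 1


class TestVoronoiRegions:
    def test_every_data_cell_assigned(self, occ_factory, unit_grid10):
        occ = occ_factory(np.random.default_rng(0).uniform(0, 10, (6, 2)))
        part = partition_occurrences(occ, 3, "random", seed=0)
        region = voronoi_regions(part, occ, unit_grid10)
        assert region.data_mask().all()
        assert set(np.unique(region.values)) <= {0.0, 1.0, 2.0}

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_nearest_neighbour_brute_force(self, seed, occ_factory):
        rng = np.random.default_rng(seed)
        g = Grid(np.zeros((8, 8)), 0, 0, 1.0)
        pts = rng.uniform(0, 8, (int(rng.integers(4, 9)), 2))
        occ = occ_factory(pts)
        part = partition_occurrences(occ, 3, "random", seed=seed)
        region = voronoi_regions(part, occ, g)
        for r in range(8):
            for c in range(8):
                x, y = g.cell_center(r, c)
                nearest = np.argmin(np.hypot(pts[:, 0] - x, pts[:, 1] - y))
                assert region.values[r, c] == part.assignment[nearest]

    def test_single_group_covers_landscape(self, occ_factory, unit_grid10):
        occ = occ_factory([(2, 2), (8, 8), (5, 5)])
        part = partition_occurrences(occ, 3, "random", seed=0)
        part.assignment[:] = 0
        region = voronoi_regions(part, occ, unit_grid10)
        assert (region.values == 0).all()


class TestFolds:
    def test_k3_structure(self):
        folds = make_folds(3)
        assert folds == [((1, 2), 0), ((0, 2), 1), ((0, 1), 2)]

    def test_k5_leave_one_out(self):
        folds = make_folds(5)
        assert len(folds) == 5
        for train, test in folds:
            assert len(train) == 4 and test not in train

    def test_test_sets_partition_occurrences(self, occ_factory):
        occ = occ_factory(np.random.default_rng(2).uniform(0, 10, (12, 2)))
        part = partition_occurrences(occ, 4, "random", seed=1)
        seen = []
        for train, test in make_folds(part):
            idx = part.group_indices(test)
            seen.extend(idx.tolist())
            train_idx = np.concatenate([part.group_indices(g) for g in train])
            assert sorted([*idx, *train_idx]) == list(range(12))
        assert sorted(seen) == list(range(12))


class TestStatistics:
    def test_oer_counts_strictly_below(self):
        assert oer([0.2, 0.6, 0.7], 0.5) == pytest.approx(1 / 3)
        assert oer([0.5, 0.6], 0.5) == 0.0  # threshold itself is suitable
        assert oer([0.1, 0.2], 0.5) == 1.0

    def test_auc_examples(self):
        assert auc([0.9, 0.8], [0.1, 0.2]) == 1.0
        assert auc([0.5, 0.5], [0.5, 0.5]) == 0.5
        assert auc([0.9, 0.5], [0.5, 0.1]) == 0.875

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pres = np.round(rng.uniform(0, 1, 12), 1)  # coarse -> ties occur
        back = np.round(rng.uniform(0, 1, 15), 1)
        wins = sum((p > b) + 0.5 * (p == b) for p in pres for b in back)
        assert auc(pres, back) == pytest.approx(wins / (12 * 15))

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_complement_and_monotone_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.uniform(0, 1, 10), rng.uniform(0, 1, 13)
        assert auc(x, y) + auc(y, x) == pytest.approx(1.0)
        assert auc(np.exp(3 * x), np.exp(3 * y)) == pytest.approx(auc(x, y))

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            oer([], 0.5)
        with pytest.raises(ValueError):
            auc([], [0.5])


class TestTuningGrid:
    def test_default_five_candidates(self):
        cands = enumerate_candidates(TuningSpec())
        assert len(cands) == 5
        assert [c.combo for c in cands] == list(FEATURE_COMBOS)
        assert all(c.rm == 1.0 for c in cands)

    def test_rm_grid_product(self):
        cands = enumerate_candidates(TuningSpec(rms=[1, 2, 3]))
        assert len(cands) == 15

    def test_threshold_toggle_drops_t(self):
        cands = enumerate_candidates(TuningSpec(threshold_enabled=False))
        assert cands[4].combo == ("L", "Q", "H", "P")
        assert all("T" not in c.combo for c in cands)

    @pytest.mark.parametrize("n,expected", [
        (80, "LQHPT"), (100, "LQHPT"), (79, "LQH"), (15, "LQH"),
        (14, "LQ"), (10, "LQ"), (9, "L"), (1, "L"),
    ])
    def test_auto_features_breakpoints(self, n, expected):
        assert auto_features(n) == frozenset(expected)

    def test_auto_features_rejects_zero(self):
        with pytest.raises(ValueError):
            auto_features(0)


class TestSelection:
    def ev(self, oer_, auc_, rank=1, rm=1.0):
        combo = FEATURE_COMBOS[rank - 1]
        return ModelEvaluation(Candidate(rm, combo, rank), [oer_], [auc_])

    def test_lowest_oer_wins(self):
        a, b = self.ev(0.10, 0.80), self.ev(0.05, 0.70)
        assert select_best([a, b]) is b

    def test_auc_breaks_oer_tie(self):
        a, b = self.ev(0.1, 0.85), self.ev(0.1, 0.80)
        assert select_best([a, b]) is a

    def test_complexity_breaks_remaining_tie(self):
        simple, complex_ = self.ev(0.1, 0.8, rank=1), self.ev(0.1, 0.8, rank=4)
        assert select_best([simple, complex_]) is simple

    def test_lowest_rm_breaks_final_tie(self):
        lo, hi = self.ev(0.1, 0.8, rm=1.0), self.ev(0.1, 0.8, rm=2.0)
        assert select_best([hi, lo]) is lo

    @pytest.mark.parametrize("seed", range(6))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        evals = [self.ev(round(rng.uniform(0, 0.3), 2),
                         round(rng.uniform(0.5, 1.0), 2),
                         rank=int(rng.integers(1, 6)),
                         rm=float(rng.choice([1, 2, 4])))
                 for _ in range(10)]
        winner = select_best(evals)
        for _ in range(5):
            perm = [evals[i] for i in rng.permutation(10)]
            assert select_best(perm).candidate == winner.candidate


class TestMaxentBatch:
    PATHS = {"maxent_jar": "maxent.jar", "environmental_layers": "layers",
             "output_dir": "out", "train_samples": "train_{fold}.csv",
             "test_samples": "test_{fold}.csv", "bias_file": "bias.asc"}

    def test_line_count_is_candidates_times_folds(self):
        text = write_maxent_batch(enumerate_candidates(TuningSpec()),
                                  make_folds(3), self.PATHS)
        assert len(text.strip().splitlines()) == 15

    def test_default_multiplier_written_as_one(self):
        text = write_maxent_batch(enumerate_candidates(TuningSpec()),
                                  make_folds(3), self.PATHS)
        assert all("betamultiplier=1" in line
                   for line in text.strip().splitlines())

    def test_cloglog_selector_on_every_line(self):
        text = write_maxent_batch(enumerate_candidates(TuningSpec()),
                                  make_folds(3), self.PATHS,
                                  output_format="cloglog")
        assert all("outputformat=cloglog" in line
                   for line in text.strip().splitlines())

    def test_feature_toggles_match_combo(self):
        cands = [Candidate(1.0, ("L", "Q"), 2)]
        line = write_maxent_batch(cands, make_folds(3), self.PATHS).splitlines()[0]
        assert "linear=true" in line and "quadratic=true" in line
        assert "hinge=false" in line and "product=false" in line
        assert "threshold=false" in line

    def test_unknown_output_format_rejected(self):
        with pytest.raises(ValueError, match="output format"):
            write_maxent_batch([], make_folds(3), self.PATHS,
                               output_format="bitmap")


class TestEnvelopeModel:
    def env_stack(self):
        g1 = Grid(np.tile(np.arange(10.0), (10, 1)), 0, 0, 1)     # x gradient
        g2 = Grid(np.tile(np.arange(10.0)[:, None], (1, 10)), 0, 0, 1)
        return {"a": g1, "b": g2}

    def test_presence_cell_fully_suitable_at_p0(self, occ_factory):
        env = self.env_stack()
        occ = occ_factory([(2.5, 2.5), (6.5, 6.5)])
        suit = envelope_model(occ, env, percentile=0.0)
        for x, y in occ.coords():
            assert suit.values[suit.index_of(x, y)] == 1.0

    def test_cell_outside_all_envelopes_scores_zero(self, occ_factory):
        env = self.env_stack()
        suit = envelope_model(occ_factory([(2.5, 2.5), (3.5, 3.5)]), env, 0.0)
        assert suit.values[suit.index_of(9.5, 9.5)] == 0.0

    def test_half_inside_scores_half(self, occ_factory):
        env = self.env_stack()
        # envelope: a in [2,3], b in [2,3]; probe cell (2.5, 8.5): a ok, b out
        suit = envelope_model(occ_factory([(2.5, 2.5), (3.5, 3.5)]), env, 0.0)
        assert suit.values[suit.index_of(2.5, 8.5)] == 0.5

    def test_insufficient_presences_rejected(self, occ_factory):
        with pytest.raises(ValueError, match="at least 2"):
            envelope_model(occ_factory([(1, 1)]), self.env_stack(), 0.0)


class TestBinarize:
    def test_fixed_threshold(self):
        g = Grid(np.array([[0.4, 0.6]]), 0, 0, 1)
        out = binarize(g, "fixed", value=0.5)
        assert out.values.tolist() == [[0.0, 1.0]]

    def test_mtp_keeps_every_training_cell(self):
        rng = np.random.default_rng(0)
        g = Grid(rng.uniform(0, 1, (5, 5)), 0, 0, 1)
        scores = [g.values[1, 1], g.values[3, 2], g.values[0, 4]]
        out = binarize(g, "mtp", training_scores=scores)
        assert out.values[1, 1] == out.values[3, 2] == out.values[0, 4] == 1.0

    def test_percentile_linear_interpolation(self):
        scores = np.arange(0.1, 1.05, 0.1)  # 0.1 .. 1.0
        g = Grid(np.array([[0.18, 0.19, 0.20]]), 0, 0, 1)
        out = binarize(g, "percentile", training_scores=scores, value=10)
        # 10th percentile of 0.1..1.0 = 0.19 by linear interpolation
        assert out.values.tolist() == [[0.0, 1.0, 1.0]]

    def test_percentile_without_scores_rejected(self):
        g = Grid(np.zeros((2, 2)), 0, 0, 1)
        with pytest.raises(ValueError, match="training"):
            binarize(g, "percentile", value=10)


class TestCladeSplit:
    def presence_grid(self):
        return Grid(np.ones((10, 10)), 0, 0, 1)

    def test_bisector_split_matches_brute_force(self, occ_factory):
        occ = occ_factory([(2.0, 5.0), (8.0, 5.0)], labels=["east", "west"])
        parts = split_by_clades(self.presence_grid(), occ)
        assert set(parts) == {"east", "west"}
        g = self.presence_grid()
        for r in range(10):
            for c in range(10):
                x, y = g.cell_center(r, c)
                d_e = np.hypot(x - 2, y - 5)
                d_w = np.hypot(x - 8, y - 5)
                winner = "east" if d_e <= d_w else "west"
                assert parts[winner].values[r, c] == 1.0

    def test_single_clade_rejected(self, occ_factory):
        occ = occ_factory([(1, 1), (2, 2)], labels=["a", "a"])
        with pytest.raises(ValueError, match="between 2 and 10"):
            split_by_clades(self.presence_grid(), occ)

    def test_eleven_clades_rejected(self, occ_factory):
        pts = [(i, i) for i in range(11)]
        occ = occ_factory(pts, labels=[f"c{i}" for i in range(11)])
        with pytest.raises(ValueError, match="between 2 and 10"):
            split_by_clades(self.presence_grid(), occ)

    @pytest.mark.parametrize("seed", range(5))
    def test_union_conservation_and_disjointness(self, seed, occ_factory):
        rng = np.random.default_rng(seed)
        vals = (rng.uniform(0, 1, (12, 12)) > 0.4).astype(float)
        vals[0, :] = -9999.0
        binary = Grid(vals, 0, 0, 1)
        n = int(rng.integers(2, 6))
        occ = occ_factory(rng.uniform(0, 12, (n, 2)),
                          labels=[f"c{i}" for i in range(n)])
        parts = split_by_clades(binary, occ)
        union = np.zeros((12, 12))
        for g in parts.values():
            mask = g.values == 1.0
            assert not (union[mask] > 0).any()  # pairwise disjoint
            union[mask] += 1
        assert np.array_equal(union == 1, binary.values == 1.0)


class TestDispersal:
    def test_dmax_zero_is_intersection(self):
        future = Grid(np.array([[0.9, 0.8], [0.7, 0.6]]), 0, 0, 1)
        current = Grid(np.array([[1.0, 0.0], [0.0, 1.0]]), 0, 0, 1)
        out = enforce_dispersal(future, current, 0.0)
        assert out.values.tolist() == [[0.9, 0.0], [0.0, 0.6]]

    def test_large_dmax_leaves_future_unchanged(self):
        rng = np.random.default_rng(0)
        future = Grid(rng.uniform(0, 1, (6, 6)), 0, 0, 1)
        current = Grid(np.eye(6), 0, 0, 1)
        out = enforce_dispersal(future, current, 1000.0)
        assert np.array_equal(out.values, future.values)

    def test_neighbourhood_clip_matches_distance_oracle(self):
        future = Grid(np.ones((7, 7)), 0, 0, 1)
        vals = np.zeros((7, 7))
        vals[3, 3] = 1.0
        current = Grid(vals, 0, 0, 1)
        out = enforce_dispersal(future, current, 1.5)
        expected = np.zeros((7, 7))
        expected[2:5, 2:5] = 1.0  # centers within 1.5 of (3,3) center
        assert np.array_equal(out.values, expected)

    def test_geometry_mismatch_rejected(self):
        a = Grid(np.ones((3, 3)), 0, 0, 1)
        b = Grid(np.ones((4, 4)), 0, 0, 1)
        with pytest.raises(ValueError, match="geometry"):
            enforce_dispersal(a, b, 1.0)


class TestJackknifePipeline:
    def test_spatial_folds_expose_clustered_bias(self):
        """Spatially clustered sampling + spatial folds -> higher omission
        than random folds (random partitions inflate performance)."""
        spatial, random_ = [], []
        for seed in range(8):
            spec = FixtureSpec(seed=seed, extent=ExtentSpec(0, 0, 100, 100),
                               cluster_spread=4.0)
            env = make_landscape(spec)
            occ = make_occurrences(spec)
            s = jackknife_evaluate(occ, env, k=3, mode="segregated", seed=seed)
            r = jackknife_evaluate(occ, env, k=3, mode="random", seed=seed)
            spatial.append(s.mean_oer)
            random_.append(r.mean_oer)
        assert np.mean(spatial) > np.mean(random_)

    def test_auc_uses_training_region_background(self, occ_factory):
        from sdmtools import bias_buffered_mcp
        spec = FixtureSpec(seed=3, extent=ExtentSpec(0, 0, 60, 60))
        env = make_landscape(spec)
        occ = make_occurrences(spec)
        bias = bias_buffered_mcp(occ, 10.0, next(iter(env.values())))
        res = jackknife_evaluate(occ, env, k=3, seed=3, bias=bias,
                                 n_background=200)
        assert len(res.fold_auc) == 3
        assert all(0.0 <= a <= 1.0 for a in res.fold_auc)
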