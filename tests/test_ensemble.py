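"""Coverage set algebra, coverage grids, differential contacts, frame extraction."""

import numpy as np
import pytest

from confland import ensemble, featurize, synthgen
from confland._types import DiscreteTrajectorySet
from confland.ensemble import DiffContactMap
from confland.featurize import ContactMap
from confland.synthgen import BeadChainEnsemble


def dts(dtrajs, n_states=5, groups=None):
    return DiscreteTrajectorySet(dtrajs, n_states, group_ids=groups)


class TestCoverageBySets:
    def test_single_set(self):
        res = ensemble.coverage_by_sets({"A": dts([[0, 1, 2, 2]])}, "A")
        assert res.n_covered == 3
        assert res.covered_states == frozenset({0, 1, 2})

    def test_disjoint_intersection_empty(self):
        sets = {"A": dts([[0]]), "B": dts([[1]])}
        assert ensemble.coverage_by_sets(sets, "A & B").n_covered == 0

    def test_random_sets_match_bruteforce_algebra(self):
        rng = np.random.default_rng(0)
        raw = {
            lab: [rng.integers(0, 12, size=30) for _ in range(3)]
            for lab in ("A", "B", "C")
        }
        sets = {lab: dts(v, 12) for lab, v in raw.items()}
        py = {lab: set(np.concatenate(v).tolist()) for lab, v in raw.items()}
        cases = {
            "A | B": py["A"] | py["B"],
            "A & B": py["A"] & py["B"],
            "(A | B) & C": (py["A"] | py["B"]) & py["C"],
            "A - B": py["A"] - py["B"],
            "A | B | C": py["A"] | py["B"] | py["C"],
        }
        for expr, want in cases.items():
            got = ensemble.coverage_by_sets(sets, expr)
            assert got.covered_states == frozenset(want), expr

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError):
            ensemble.coverage_by_sets({"A": dts([[0]])}, "A | Z")

    def test_venn_regions_match_bruteforce(self):
        rng = np.random.default_rng(1)
        raw = {lab: [rng.integers(0, 10, size=15)] for lab in ("A", "B")}
        sets = {lab: dts(v, 10) for lab, v in raw.items()}
        regions = ensemble.venn_regions(sets)
        a = set(raw["A"][0].tolist())
        b = set(raw["B"][0].tolist())
        assert regions[("A",)] == len(a - b)
        assert regions[("B",)] == len(b - a)
        assert regions[("A", "B")] == len(a & b)


@pytest.fixture(scope="module")
def pool(generator):
    ts = synthgen.sample_trajectories(generator, 30, 400, 6, seed=5)
    return DiscreteTrajectorySet(
        ts.true_micro_paths, generator.n_micro, group_ids=ts.group_ids
    )


class TestCoverageContour:
    def test_full_corner_equals_union_coverage(self, pool):
        n_ax, l_ax, grid = ensemble.coverage_contour(pool, traj_step=10, length_step=100, n_draws=2, seed=0)
        union = ensemble.coverage_by_sets({"all": pool}, "all")
        assert grid[-1, -1] == pytest.approx(union.n_covered)

    def test_zero_axes_give_zero_coverage(self, pool):
        n_ax, l_ax, grid = ensemble.coverage_contour(pool, traj_step=10, length_step=100, n_draws=1, seed=0)
        np.testing.assert_allclose(grid[0, :], 0.0)
        np.testing.assert_allclose(grid[:, 0], 0.0)

    def test_monotone_along_both_axes_per_draw(self, pool):
        # with a single fixed draw the coverage is exactly monotone: adding
        # trajectories or frames can only add visited states
        _, _, grid = ensemble.coverage_contour(pool, traj_step=10, length_step=100, n_draws=1, seed=3)
        assert np.all(np.diff(grid, axis=0) >= 0)
        assert np.all(np.diff(grid, axis=1) >= 0)

    def test_oversized_draw_rejected(self, pool):
        with pytest.raises(ValueError):
            ensemble.coverage_contour(
                DiscreteTrajectorySet([], 5), traj_step=10, length_step=10
            )


class TestMinimalTimeToCoverage:
    def test_fraction_zero_costs_nothing(self):
        n_ax, l_ax = np.array([0, 10]), np.array([0, 100])
        grid = np.array([[0, 0], [0, 50]])
        assert ensemble.minimal_time_to_coverage(n_ax, l_ax, grid, 0.0, 100) == 0.0

    def test_unreachable_target_reported(self):
        n_ax, l_ax = np.array([0, 10]), np.array([0, 100])
        grid = np.array([[0, 0], [0, 50]])
        with pytest.raises(ValueError, match="not attained"):
            ensemble.minimal_time_to_coverage(n_ax, l_ax, grid, 0.9, 100)

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(2)
        n_ax = np.array([0, 5, 10, 15])
        l_ax = np.array([0, 50, 100])
        grid = np.sort(np.sort(rng.integers(0, 80, size=(4, 3)), axis=0), axis=1)
        frac, n_total = 0.5, 80
        got = ensemble.minimal_time_to_coverage(n_ax, l_ax, grid, frac, n_total)
        oracle = min(
            (n_ax[i] * l_ax[j] for i in range(4) for j in range(3)
             if grid[i, j] >= frac * n_total),
            default=None,
        )
        assert got == oracle


class TestDifferentialContactMap:
    def cmap(self, M):
        return ContactMap(matrix=np.asarray(M, float), n_frames=10)

    def z(self, n=6):
        return np.zeros((n, n))

    def test_identical_maps_no_selection(self):
        M = self.z()
        M[0, 4] = M[4, 0] = 0.5
        d = ensemble.differential_contact_map(self.cmap(M), self.cmap(M))
        np.testing.assert_allclose(d.absolute, 0.0)
        assert d.selected_pairs == []

    def test_printed_threshold_case(self):
        # WT 0.1 -> mutant 0.5: absolute 0.4 > 0.2 and relative 4 > 3: selected
        W, M = self.z(), self.z()
        W[0, 4] = W[4, 0] = 0.1
        M[0, 4] = M[4, 0] = 0.5
        d = ensemble.differential_contact_map(self.cmap(M), self.cmap(W))
        assert d.absolute[0, 4] == pytest.approx(0.4)
        assert d.relative[0, 4] == pytest.approx(4.0)
        assert d.selected_pairs == [(0, 4)]

    def test_wildtype_zero_relative_forced_zero(self):
        W, M = self.z(), self.z()
        M[1, 5] = M[5, 1] = 0.5
        d = ensemble.differential_contact_map(self.cmap(M), self.cmap(W))
        assert d.relative[1, 5] == 0.0
        assert d.selected_pairs == []

    def test_swapped_arguments_negate_absolute(self):
        rng = np.random.default_rng(3)
        A = rng.random((5, 5)) * 0.5
        A = np.triu(A, 3)
        A = A + A.T
        B = np.triu(rng.random((5, 5)) * 0.5, 3)
        B = B + B.T
        d1 = ensemble.differential_contact_map(self.cmap(A), self.cmap(B))
        d2 = ensemble.differential_contact_map(self.cmap(B), self.cmap(A))
        np.testing.assert_allclose(d1.absolute, -d2.absolute, atol=1e-14)

    def test_deletion_zeroes_residue_row_and_column(self):
        W, M = self.z(), self.z()
        W[0, 4] = W[4, 0] = 0.1
        M[0, 4] = M[4, 0] = 0.9
        d = ensemble.differential_contact_map(self.cmap(M), self.cmap(W), deletion=4)
        np.testing.assert_allclose(d.absolute[4, :], 0.0)
        np.testing.assert_allclose(d.absolute[:, 4], 0.0)
        assert d.selected_pairs == []


@pytest.fixture(scope="module")
def mutant_traj():
    """200 frames: 100 wild-type-like then 100 with the (1, 8) neo-contact."""
    return synthgen.make_bead_chain_ensemble(
        12, {(0, 5)}, {(1, 8)}, n_frames_base=100, n_frames_perturbed=100, seed=4
    )


class TestExtractCandidateFrames:
    def diff_with_positive(self, pair=(1, 8)):
        A = np.zeros((12, 12))
        A[pair] = A[pair[::-1]] = 0.6
        return DiffContactMap(
            absolute=A, relative=np.where(A != 0, 4.0, 0.0),
            selected_pairs=[pair], abs_thresh=0.2, rel_thresh=3.0,
        )

    def test_every_tenth_qualifying_frame(self, mutant_traj):
        diff = self.diff_with_positive()
        got = ensemble.extract_candidate_frames([mutant_traj], diff, burn_in=0)
        # counting oracle: qualifying frames are 100..199, strided by 10
        assert got == [(0, f) for f in range(100, 200, 10)]

    def test_burn_in_discards_early_frames(self, mutant_traj):
        diff = self.diff_with_positive()
        got = ensemble.extract_candidate_frames([mutant_traj], diff, burn_in=150)
        assert got == [(0, f) for f in range(150, 200, 10)]

    def test_wide_stride_above_cap(self, mutant_traj):
        diff = self.diff_with_positive()
        got = ensemble.extract_candidate_frames(
            [mutant_traj], diff, burn_in=0, stride_cap=50, stride_wide=20
        )
        assert got == [(0, f) for f in range(100, 200, 20)]

    def test_empty_contact_lists_give_empty_set(self, mutant_traj):
        diff = DiffContactMap(
            absolute=np.zeros((12, 12)), relative=np.zeros((12, 12)),
            selected_pairs=[], abs_thresh=0.2, rel_thresh=3.0,
        )
        assert ensemble.extract_candidate_frames([mutant_traj], diff) == []


class TestExpandClusterByRmsd:
    def test_cluster_member_selected(self):
        rng = np.random.default_rng(5)
        frames = rng.standard_normal((40, 6, 3))
        cluster = frames[[20]]
        got = ensemble.expand_cluster_by_rmsd(cluster, frames, threshold=1e-6, stride=10)
        assert got == [20]

    def test_threshold_zero_selects_nothing_new(self):
        rng = np.random.default_rng(6)
        frames = rng.standard_normal((30, 5, 3))
        got = ensemble.expand_cluster_by_rmsd(frames[[0]], frames, threshold=0.0, stride=1)
        assert got == []

    def test_matches_bruteforce_min_rmsd_scan(self):
        from confland.landscape import superpose_rmsd

        rng = np.random.default_rng(7)
        base = rng.standard_normal((6, 3))
        frames = np.stack([base + 0.05 * rng.standard_normal((6, 3)) for _ in range(30)])
        cluster = frames[:3]
        thr, stride = 0.12, 5
        got = ensemble.expand_cluster_by_rmsd(cluster, frames, threshold=thr, stride=stride)
        oracle = [
            k for k in range(0, 30, stride)
            if min(superpose_rmsd(c, frames[k]) for c in cluster) < thr
        ]
        assert got == oracle

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            ensemble.expand_cluster_by_rmsd(np.empty((0, 5, 3)), np.zeros((3, 5, 3)))


class TestDiscoveryCurve:
    def make(self, ref, qry):
        all_trajs = ref + qry
        groups = [0] * len(ref) + [1] * len(qry)
        n = int(max(np.max(np.concatenate(all_trajs)) + 1, 1))
        return DiscreteTrajectorySet(all_trajs, n, group_ids=groups)

    def test_query_subset_of_reference_flat_zero(self):
        d = self.make([[0, 1, 2]], [[1, 2, 2, 0]])
        curve = ensemble.discovery_curve(d, query_groups=1, reference_groups=0)
        np.testing.assert_array_equal(curve, 0)

    def test_fresh_states_plateau(self):
        d = self.make([[0, 1]], [[0, 3, 3, 4, 1]])
        curve = ensemble.discovery_curve(d, query_groups=1, reference_groups=0)
        np.testing.assert_array_equal(curve, [0, 1, 1, 2, 2])

    def test_interleaved_matches_bruteforce_first_visit(self):
        rng = np.random.default_rng(8)
        ref = [rng.integers(0, 8, size=50)]
        qry = [rng.integers(0, 16, size=40) for _ in range(2)]
        d = self.make(ref, qry)
        curve = ensemble.discovery_curve(d, query_groups=1, reference_groups=0)
        seen_ref = set(ref[0].tolist())
        stream = np.concatenate(qry)
        oracle, found = [], set()
        for s in stream:
            if s not in seen_ref:
                found.add(int(s))
            oracle.append(len(found))
        np.testing.assert_array_equal(curve, oracle)
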