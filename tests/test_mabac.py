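"""Fuzzy MABAC stages: assembly, normalization, weighting, BAA, distances, ranks."""

import math

import numpy as np
import pytest

from zefmea import (
    TFN,
    DecisionMatrix,
    assemble_matrix,
    compute_baa,
    compute_distances,
    normalize,
    run_pipeline,
    score_and_rank,
    weight_matrix,
)


def dm_from(rows, alternatives=None, criteria=None, stage="initial"):
    rows = np.asarray(rows, dtype=float)
    n_alt, n_crit = rows.shape[0], rows.shape[1]
    return DecisionMatrix(
        tuple(alternatives or [f"A{i + 1}" for i in range(n_alt)]),
        tuple(criteria or [f"C{j + 1}" for j in range(n_crit)]),
        rows,
        stage,
    )


def crisp_dm(matrix, stage="initial"):
    m = np.asarray(matrix, dtype=float)
    return dm_from(np.repeat(m[:, :, None], 3, axis=2), stage=stage)


class TestAssemble:
    def test_single_expert_identity(self):
        dm = dm_from([[[1, 2, 3]], [[2, 3, 4]]])
        out = assemble_matrix([dm])
        assert np.allclose(out.values, dm.values)

    def test_mean_of_two(self):
        a = dm_from([[[1, 2, 3]]])
        b = dm_from([[[3, 4, 5]]])
        out = assemble_matrix([a, b])
        assert out.cell("A1", "C1") == TFN(2, 3, 4)

    def test_three_identical(self):
        a = dm_from([[[1, 2, 3]], [[0, 1, 2]]])
        out = assemble_matrix([a, a, a])
        assert np.allclose(out.values, a.values)

    def test_shape_mismatch_rejected(self):
        a = dm_from([[[1, 2, 3]]])
        b = dm_from([[[1, 2, 3]], [[1, 2, 3]]])
        with pytest.raises(ValueError):
            assemble_matrix([a, b])


class TestNormalize:
    def test_case_study_severity_anchor(self, case):
        norm = normalize(case.initial_matrix)
        assert norm.cell("A1", "S").as_tuple() == pytest.approx((0.19, 0.37, 0.59), abs=0.005)

    def test_case_study_detection_anchor(self, case):
        norm = normalize(case.initial_matrix)
        assert norm.cell("A3", "D").as_tuple() == pytest.approx((0.0, 0.16, 0.36), abs=0.005)

    def test_extreme_cell_maps_to_unit_interval_ends(self):
        dm = dm_from([[[1, 1, 5]], [[1, 2, 3]]])
        norm = normalize(dm)
        assert norm.cell("A1", "C1").as_tuple() == pytest.approx((0.0, 0.0, 1.0))

    def test_every_column_attains_zero_and_one(self, case):
        norm = normalize(case.initial_matrix)
        v = norm.values
        assert v.min() >= 0 and v.max() <= 1
        for j in range(len(norm.criteria)):
            assert v[:, j, :].min() == pytest.approx(0.0)
            assert v[:, j, :].max() == pytest.approx(1.0)

    def test_cost_direction_flips_and_stays_valid(self):
        dm = dm_from([[[1, 2, 3]], [[4, 5, 6]], [[2, 3, 7]]])
        norm = normalize(dm, directions={"C1": "cost"})
        v = norm.values
        assert ((v[:, :, 0] <= v[:, :, 1]) & (v[:, :, 1] <= v[:, :, 2])).all()
        # the largest alternative becomes the worst (smallest) after flipping
        assert norm.cell("A2", "C1").u == pytest.approx(
            (6 - 4) / 6, abs=1e-12
        ) or norm.cell("A2", "C1").u <= norm.cell("A1", "C1").u

    def test_constant_column_warns_and_zeroes(self):
        dm = dm_from([[[2, 2, 2]], [[2, 2, 2]]])
        with pytest.warns(UserWarning, match="constant"):
            norm = normalize(dm)
        assert (norm.values == 0).all()

    def test_max_divide_variant(self):
        dm = dm_from([[[1, 2, 4]], [[2, 4, 8]]])
        norm = normalize(dm, method="max-divide")
        assert norm.cell("A2", "C1").as_tuple() == pytest.approx((0.25, 0.5, 1.0))

    def test_stage_guard(self):
        dm = dm_from([[[0, 0.5, 1]]], stage="normalized")
        with pytest.raises(ValueError, match="initial"):
            normalize(dm)


class TestWeighting:
    def test_zero_cell_gets_weight_floor(self):
        dm = dm_from([[[0, 0, 0]]], stage="normalized")
        out = weight_matrix(dm, {"C1": TFN(0.3, 0.3, 0.3)})
        assert out.cell("A1", "C1") == TFN(0.3, 0.3, 0.3)

    def test_shifted_product(self):
        dm = dm_from([[[0.59, 0.81, 1.00]]], stage="normalized")
        out = weight_matrix(dm, {"C1": TFN(0.3277, 0.3367, 0.3890)})
        assert out.cell("A1", "C1").as_tuple() == pytest.approx(
            (0.521043, 0.609427, 0.778), abs=1e-6
        )

    def test_crisp_reduction(self):
        dm = crisp_dm([[0.4], [0.7]], stage="normalized")
        out = weight_matrix(dm, {"C1": TFN.crisp(0.25)})
        assert out.cell("A2", "C1").m == pytest.approx(0.25 * 1.7)

    def test_nonpositive_weight_rejected(self):
        dm = dm_from([[[0, 0.5, 1]]], stage="normalized")
        with pytest.raises(ValueError, match="positive"):
            weight_matrix(dm, {"C1": TFN(0.0, 0.1, 0.2)})


class TestBAA:
    def test_two_cell_geometric_mean(self):
        dm = dm_from([[[0.2, 0.3, 0.4]], [[0.8, 0.9, 1.0]]], stage="weighted")
        baa = compute_baa(dm)
        assert baa["C1"].as_tuple() == pytest.approx(
            (math.sqrt(0.16), math.sqrt(0.27), math.sqrt(0.4))
        )

    def test_identical_cells_are_their_own_border(self):
        dm = dm_from([[[0.2, 0.3, 0.4]], [[0.2, 0.3, 0.4]]], stage="weighted")
        assert compute_baa(dm)["C1"].as_tuple() == pytest.approx((0.2, 0.3, 0.4))

    def test_single_alternative(self):
        dm = dm_from([[[0.5, 0.6, 0.7]]], stage="weighted")
        assert compute_baa(dm)["C1"].as_tuple() == pytest.approx((0.5, 0.6, 0.7))

    def test_border_within_column_envelope(self, case):
        weighted = weight_matrix(normalize(case.initial_matrix), case.mean_weights())
        baa = compute_baa(weighted)
        for j, c in enumerate(weighted.criteria):
            col = weighted.values[:, j, :]
            g = baa[c].as_tuple()
            for k in range(3):
                assert col[:, k].min() <= g[k] <= col[:, k].max()

    def test_nonpositive_cells_rejected(self):
        dm = dm_from([[[0.0, 0.1, 0.2]]], stage="weighted")
        with pytest.raises(ValueError, match="positive"):
            compute_baa(dm)


class TestDistances:
    def test_cell_on_border_has_zero_centroid(self):
        dm = dm_from([[[0.2, 0.3, 0.4]], [[0.2, 0.3, 0.4]]], stage="weighted")
        q = compute_distances(dm, compute_baa(dm))
        assert q.cell("A1", "C1").as_tuple() == pytest.approx((-0.2, 0.0, 0.2))
        assert q.cell("A1", "C1").centroid() == pytest.approx(0.0, abs=1e-12)

    def test_subtraction_rule(self):
        dm = dm_from([[[0.52, 0.61, 0.78]], [[0.3076923, 0.443114, 0.5086538]]],
                     stage="weighted")
        baa = compute_baa(dm)
        q = compute_distances(dm, baa)
        g = baa["C1"]
        expected = (0.52 - g.u, 0.61 - g.m, 0.78 - g.l)
        assert q.cell("A1", "C1").as_tuple() == pytest.approx(expected)

    def test_dominating_cell_has_larger_centroid(self):
        dm = dm_from([[[0.5, 0.6, 0.7]], [[0.2, 0.3, 0.4]]], stage="weighted")
        q = compute_distances(dm, compute_baa(dm))
        assert q.cell("A1", "C1").centroid() > q.cell("A2", "C1").centroid()

    def test_distance_linearity_identity(self, case):
        """Sum over alternatives of centroid(q) = sum centroid(v) - m*centroid(g)."""
        weighted = weight_matrix(normalize(case.initial_matrix), case.mean_weights())
        baa = compute_baa(weighted)
        q = compute_distances(weighted, baa)
        m = len(weighted.alternatives)
        for j, c in enumerate(weighted.criteria):
            lhs = sum(TFN(*q.values[i, j]).centroid() for i in range(m))
            rhs = sum(TFN(*weighted.values[i, j]).centroid() for i in range(m)) \
                - m * baa[c].centroid()
            assert lhs == pytest.approx(rhs, abs=1e-9)


class TestScoreAndRank:
    def test_single_alternative_gets_rank_one(self):
        dm = dm_from([[[-0.2, 0.0, 0.2]]], stage="distance")
        res = score_and_rank(dm)
        assert res.ranks == (1,)

    def test_ranks_are_permutation_descending_in_score(self, case):
        res = run_pipeline(case.initial_matrix, case.mean_weights())
        assert sorted(res.ranks) == list(range(1, 31))
        by_rank = sorted(zip(res.ranks, res.scores))
        scores = [s for _, s in by_rank]
        assert all(a >= b - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_tie_break_prefers_larger_mode_then_input_order(self):
        dm = dm_from(
            [[[-0.3, 0.0, 0.3]], [[-0.6, 0.3, 0.3]], [[-0.3, 0.0, 0.3]]],
            stage="distance",
        )
        res = score_and_rank(dm)  # all centroids 0.0
        assert res.ranks == (2, 1, 3)


class TestPipelineProperties:
    def test_rank_invariance_under_columnwise_affine_rescaling(self, case):
        base = run_pipeline(case.initial_matrix, case.mean_weights())
        v = case.initial_matrix.values.copy()
        scale = np.array([2.0, 5.0, 0.3])
        offset = np.array([1.0, -0.5, 4.0])
        v2 = v * scale[None, :, None] + offset[None, :, None]
        dm2 = DecisionMatrix(case.initial_matrix.alternatives,
                             case.initial_matrix.criteria, v2, "initial")
        res2 = run_pipeline(dm2, case.mean_weights())
        assert res2.ranks == base.ranks

    def test_componentwise_dominance_preserved(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            v = np.sort(rng.uniform(0, 10, size=(6, 3, 3)), axis=2)
            # make A1 dominate A2 in every criterion component
            v[0] = v[1] + rng.uniform(0.1, 1.0, size=(3, 3))
            v[0] = np.sort(v[0], axis=1)
            dm = dm_from(v)
            w = {c: TFN.crisp(x) for c, x in zip(dm.criteria, rng.dirichlet(np.ones(3)))}
            res = run_pipeline(dm, w)
            assert res.rank_of("A1") < res.rank_of("A2")

    def test_crisp_pipeline_matches_classical_mabac_oracle(self):
        """On degenerate TFNs the fuzzy pipeline equals plain MABAC to 1e-10."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            x = rng.uniform(1, 10, size=(5, 3))
            w = rng.dirichlet(np.ones(3))
            # independent classical implementation
            n = (x - x.min(axis=0)) / (x.max(axis=0) - x.min(axis=0))
            v = w[None, :] * (n + 1.0)
            g = np.exp(np.log(v).mean(axis=0))
            s = (v - g[None, :]).sum(axis=1)
            res = run_pipeline(
                crisp_dm(x), {c: TFN.crisp(w[j]) for j, c in enumerate(("C1", "C2", "C3"))}
            )
            assert np.allclose(res.scores, s, atol=1e-10, rtol=0)
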