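"""Smooth and hard alignment against enumeration oracles and closed forms."""

import numpy as np
import pytest

from smurf.smooth_align import (AlignParams, AlignmentPath, batched_smooth,
                                brute_force_posterior,
                                brute_force_smooth_score, enumerate_paths,
                                hard_align, path_score, posterior,
                                smooth_score)

from conftest import all_mode_params

LOCAL = AlignParams(align_mode="local", gap=-1.0)
GLOBAL = AlignParams(align_mode="global", gap=-1.0)


# ---------------------------------------------------------------------------
# path_score
# ---------------------------------------------------------------------------

class TestPathScore:
    def test_two_matches_no_gaps(self):
        a = np.array([[1.0, -1.0], [-1.0, 1.0]])
        p = AlignmentPath(((0, 0), (1, 1)))
        assert path_score(a, p, LOCAL) == 2.0

    def test_empty_local_path_scores_zero(self):
        assert path_score(np.zeros((3, 3)), AlignmentPath(()), LOCAL) == 0.0

    def test_global_linear_charges_unmatched_residues(self):
        # 3x2 global, one unmatched x residue between the matches
        a = np.zeros((3, 2))
        p = AlignmentPath(((0, 0), (2, 1)))
        assert path_score(a, p, GLOBAL) == -1.0

    def test_affine_streaks_from_moves_vs_blocks(self):
        a = np.zeros((4, 4))
        params = AlignParams(open=-3.0, extend=-0.5, gap_mode="affine",
                             align_mode="global")
        p = AlignmentPath(((0, 0), (3, 3)), moves="MXXYYM")
        # one x-streak of 2 and one y-streak of 2: 2 * (-3 - 0.5)
        assert path_score(a, p, params) == -7.0
        # match-only representation charges the same canonical blocks
        assert path_score(a, AlignmentPath(((0, 0), (3, 3))), params) == -7.0

    def test_non_monotone_path_rejected(self):
        with pytest.raises(ValueError, match="non-monotone"):
            AlignmentPath(((1, 1), (0, 2)))


# ---------------------------------------------------------------------------
# enumerate_paths
# ---------------------------------------------------------------------------

class TestEnumeratePaths:
    def test_local_1x1_has_empty_and_single_match(self):
        paths = enumerate_paths(1, 1, LOCAL)
        assert len(paths) == 2
        assert {p.matches for p in paths} == {(), ((0, 0),)}

    def test_global_count_matches_recursive_count(self):
        # independent recursion over (moves from the end) with no gap restriction
        def count(i, j):
            if i == 0 and j == 0:
                return 1
            total = 0
            if i and j:
                total += count(i - 1, j - 1)
            if i:
                total += count(i - 1, j)
            if j:
                total += count(i, j - 1)
            return total

        p = AlignParams(align_mode="global", gap=-1.0, restrict_turns=False)
        assert len(enumerate_paths(2, 2, p)) == count(2, 2) == 13

    def test_global_1x1_gap_arrangements(self):
        free = enumerate_paths(1, 1, AlignParams(align_mode="global", gap=-1.0,
                                                 restrict_turns=False))
        restricted = enumerate_paths(1, 1, AlignParams(align_mode="global",
                                                       gap=-1.0))
        assert sorted(p.moves for p in free) == ["M", "XY", "YX"]
        # restrict_turns forbids the y-gap -> x-gap ordering
        assert sorted(p.moves for p in restricted) == ["M", "XY"]

    def test_enumeration_guard(self):
        with pytest.raises(ValueError, match="limited"):
            enumerate_paths(8, 2, LOCAL)


# ---------------------------------------------------------------------------
# smooth_score / posterior vs oracles
# ---------------------------------------------------------------------------

class TestOracleEquivalence:
    @pytest.mark.parametrize("params", all_mode_params(), ids=str)
    def test_dp_matches_enumeration(self, params, rng):
        for _ in range(12):
            n, m = rng.integers(1, 5, 2)
            a = rng.normal(0, 2, (n, m))
            assert smooth_score(a, params) == pytest.approx(
                brute_force_smooth_score(a, params), abs=1e-8)
            assert np.allclose(posterior(a, params).probs,
                               brute_force_posterior(a, params), atol=1e-8)

    def test_local_1x1_closed_form(self):
        p = AlignParams(align_mode="local", gap=-1.0, temperature=1.0)
        assert smooth_score(np.array([[0.0]]), p) == pytest.approx(np.log(2))
        for s in (-2.0, 0.5, 3.0):
            assert brute_force_smooth_score(np.array([[s]]), p) == \
                pytest.approx(np.log(1 + np.exp(s)))
        assert posterior(np.array([[0.0]]), p).probs[0, 0] == pytest.approx(0.5)

    def test_brute_force_monotone_in_temperature(self, rng):
        a = rng.normal(0, 1, (3, 3))
        for mode in ("local", "global"):
            p1 = AlignParams(align_mode=mode, gap=-1.0, temperature=1.0)
            p2 = AlignParams(align_mode=mode, gap=-1.0, temperature=2.0)
            assert brute_force_smooth_score(a, p2) >= brute_force_smooth_score(a, p1)

    def test_diagonal_dominant_posterior_is_identity(self):
        a = np.full((4, 4), -10.0)
        np.fill_diagonal(a, 10.0)
        P = posterior(a, AlignParams(align_mode="global", gap=-1.0)).probs
        assert np.allclose(P, np.eye(4), atol=1e-3)

    def test_nonfinite_scores_rejected(self):
        a = np.zeros((2, 2))
        a[0, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            smooth_score(a, LOCAL)


class TestInvariants:
    def test_temperature_limit_and_upper_bound(self):
        # fixed instance: tie degeneracy k inflates the T->0 gap by T*ln(k),
        # so keep to an instance with at most a two-fold tie
        a = np.random.default_rng(0).integers(-3, 4, (5, 5)).astype(float)
        for params in all_mode_params():
            hs, _ = hard_align(a, params)
            cold = AlignParams(**{**params.__dict__, "temperature": 1e-3})
            assert abs(smooth_score(a, cold) - hs) < 1e-3
            for T1, T2 in ((0.5, 1.0), (1.0, 2.0)):
                s1 = smooth_score(a, AlignParams(**{**params.__dict__, "temperature": T1}))
                s2 = smooth_score(a, AlignParams(**{**params.__dict__, "temperature": T2}))
                assert s2 >= s1 - 1e-10
                assert s1 >= hs - 1e-10  # smooth >= hard at every T

    def test_posterior_matches_finite_differences(self, rng):
        a = rng.normal(0, 1, (4, 5))
        h = 1e-4
        for params in all_mode_params(temperature=0.8):
            P = posterior(a, params).probs
            fd = np.zeros_like(a)
            for i in range(4):
                for j in range(5):
                    ap, am = a.copy(), a.copy()
                    ap[i, j] += h
                    am[i, j] -= h
                    fd[i, j] = (smooth_score(ap, params) - smooth_score(am, params)) / (2 * h)
            assert np.allclose(P, fd, atol=1e-4)

    def test_affine_reduces_to_linear_when_open_equals_extend(self, rng):
        a = rng.normal(0, 1, (4, 4))
        for mode in ("local", "global"):
            lin = AlignParams(align_mode=mode, gap=-0.9, gap_mode="linear")
            aff = AlignParams(align_mode=mode, open=-0.9, extend=-0.9,
                              gap_mode="affine")
            assert smooth_score(a, lin) == pytest.approx(smooth_score(a, aff), abs=1e-8)
            assert np.allclose(posterior(a, lin).probs, posterior(a, aff).probs,
                               atol=1e-8)

    def test_probability_bounds_and_global_row_sums(self, rng):
        a = rng.normal(0, 2, (5, 4))
        for params in all_mode_params():
            P = posterior(a, params).probs
            assert np.all(P >= -1e-12) and np.all(P <= 1 + 1e-8)
            if params.align_mode == "global":
                assert np.all(P.sum(axis=0) <= 1 + 1e-8)
                assert np.all(P.sum(axis=1) <= 1 + 1e-8)

    def test_posterior_increases_with_score(self, rng):
        a = rng.normal(0, 1, (3, 3))
        for params in all_mode_params():
            P0 = posterior(a, params).probs[1, 1]
            a2 = a.copy()
            a2[1, 1] += 0.5
            P1 = posterior(a2, params).probs[1, 1]
            assert P1 > P0


# ---------------------------------------------------------------------------
# hard_align
# ---------------------------------------------------------------------------

class TestHardAlign:
    def test_perfect_match(self):
        a = np.array([[1.0, -1.0], [-1.0, 1.0]])
        score, path = hard_align(a, LOCAL)
        assert score == 2.0 and path.matches == ((0, 0), (1, 1))

    def test_all_negative_local_gives_empty_path(self):
        score, path = hard_align(np.full((3, 3), -2.0), LOCAL)
        assert score == 0.0 and path.matches == ()

    def test_matches_enumeration_maximum(self, rng):
        for params in all_mode_params():
            for _ in range(5):
                a = rng.normal(0, 2, (5, 5))
                best = max(path_score(a, p, params)
                           for p in enumerate_paths(5, 5, params))
                score, path = hard_align(a, params)
                assert score == pytest.approx(best, abs=1e-9)
                assert path_score(a, path, params) == pytest.approx(score, abs=1e-9)


# ---------------------------------------------------------------------------
# batched_smooth
# ---------------------------------------------------------------------------

class TestBatchedSmooth:
    def test_batch_of_one_equals_unbatched(self, rng):
        a = rng.normal(0, 1, (3, 4))
        out = batched_smooth(a[None], np.array([3]), np.array([4]), LOCAL)
        assert np.allclose(out[0].probs, posterior(a, LOCAL).probs, atol=1e-12)

    def test_padding_never_influences_results(self, rng):
        a1 = rng.normal(0, 1, (4, 6))
        a2 = a1[:3, :4]
        stack = np.full((2, 4, 6), 37.0)  # junk padding values
        stack[0] = a1
        stack[1, :3, :4] = a2
        for params in (LOCAL, GLOBAL):
            outs = batched_smooth(stack, np.array([4, 3]), np.array([6, 4]), params)
            assert np.allclose(outs[0].probs, posterior(a1, params).probs, atol=1e-8)
            assert np.allclose(outs[1].probs, posterior(a2, params).probs, atol=1e-8)

    def test_batch_is_permutation_equivariant(self, rng):
        mats = [rng.normal(0, 1, (3, m)) for m in (3, 5, 4)]
        stack = np.zeros((3, 3, 5))
        for k, m in enumerate(mats):
            stack[k, :, : m.shape[1]] = m
        ly = np.array([3, 5, 4])
        fwd = batched_smooth(stack, np.array([3] * 3), ly, LOCAL)
        rev = batched_smooth(stack[::-1].copy(), np.array([3] * 3), ly[::-1], LOCAL)
        for k in range(3):
            assert np.allclose(fwd[k].probs, rev[2 - k].probs, atol=1e-12)

    def test_true_length_exceeding_padding_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            batched_smooth(np.zeros((1, 3, 3)), np.array([4]), np.array([3]), LOCAL)
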