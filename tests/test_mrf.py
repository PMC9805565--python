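"""MRF conditionals, MLM loss, masks and APC contact scores."""

import numpy as np
import pytest

from smurf import _autodiff as ad
from smurf.lam import SoftMSA
from smurf.mrf import (MRFParams, MaskSpec, apc,
                       contact_scores, mlm_loss, mlm_loss_t, mlm_predict,
                       sample_mask, symmetrize_couplings, _sym_t)


def _soft(profiles):
    profiles = np.asarray(profiles, dtype=np.float64)
    return SoftMSA(profiles, 1.0 - profiles.sum(axis=2))


def _mask(arr, rate=0.15, seed=0):
    return MaskSpec(np.asarray(arr, dtype=bool), rate, seed)


class TestMLMPredict:
    def test_zero_couplings_predict_softmax_of_fields(self, rng):
        L, A = 4, 5
        v = rng.normal(0, 1, (L, A))
        mrf = MRFParams(v, np.zeros((L, L, A, A)))
        prof = np.zeros((3, L, A))
        prof[:, :, 0] = 1.0
        probs = mlm_predict(_soft(prof), _mask(np.ones((3, L))), mrf)
        expected = np.exp(v) / np.exp(v).sum(axis=1, keepdims=True)
        for s in range(3):
            assert np.allclose(probs[s], expected)

    def test_two_state_closed_form(self):
        # L=2, A=2, v=0, W_01 = c*I, neighbor fixed at state 0:
        # P(masked residue = 0) = e^c / (e^c + 1)
        c = 1.3
        W = np.zeros((2, 2, 2, 2))
        W[0, 1] = W[1, 0] = np.eye(2) * c
        mrf = MRFParams(np.zeros((2, 2)), W)
        prof = np.zeros((1, 2, 2))
        prof[0, 1, 0] = 1.0  # unmasked neighbor is residue 0
        mask = _mask([[True, False]])
        probs = mlm_predict(_soft(prof), mask, mrf)
        assert probs[0, 0, 0] == pytest.approx(np.exp(c) / (np.exp(c) + 1))

    def test_hard_profile_matches_potts_conditional_oracle(self, rng):
        # independent direct computation of P(x_i | x_{-i}) for a Potts model
        L, A, B = 5, 4, 6
        raw = rng.normal(0, 0.7, (L, L, A, A))
        W = symmetrize_couplings(raw)
        v = rng.normal(0, 1, (L, A))
        mrf = MRFParams(v, W)
        x = rng.integers(0, A, (B, L))
        prof = np.zeros((B, L, A))
        prof[np.arange(B)[:, None], np.arange(L)[None, :], x] = 1.0
        i = 2
        mask = np.zeros((B, L), dtype=bool)
        mask[:, i] = True
        probs = mlm_predict(_soft(prof), _mask(mask), mrf)
        for s in range(B):
            logits = v[i].copy()
            for j in range(L):
                if j != i:
                    logits += W[i, j][:, x[s, j]]
            expected = np.exp(logits - logits.max())
            expected /= expected.sum()
            assert np.allclose(probs[s, i], expected, atol=1e-10)

    def test_distributions_normalize(self, rng):
        L, A = 6, 4
        mrf = MRFParams(rng.normal(0, 1, (L, A)),
                        symmetrize_couplings(rng.normal(0, 1, (L, L, A, A))))
        prof = rng.dirichlet(np.ones(A), size=(3, L)) * 0.9
        probs = mlm_predict(_soft(prof), _mask(np.ones((3, L))), mrf)
        assert np.allclose(probs.sum(axis=2), 1.0, atol=1e-6)

    def test_asymmetric_couplings_rejected(self, rng):
        W = rng.normal(0, 1, (3, 3, 2, 2))
        mrf = MRFParams(np.zeros((3, 2)), W)
        with pytest.raises(ValueError, match="symmetric"):
            mlm_predict(_soft(np.zeros((1, 3, 2))), _mask(np.ones((1, 3))), mrf)


class TestMLMLoss:
    def test_perfect_prediction_zero_loss(self):
        # fields strongly pinned to the one-hot targets, no regularization
        L, A = 3, 4
        prof = np.zeros((2, L, A))
        prof[:, :, 1] = 1.0
        v = np.full((L, A), -50.0)
        v[:, 1] = 50.0
        mrf = MRFParams(v, np.zeros((L, L, A, A)))
        loss = mlm_loss(_soft(prof), _mask(np.ones((2, L))), mrf,
                        lam_v=0.0, lam_w=0.0)
        assert loss == pytest.approx(0.0, abs=1e-8)

    def test_zero_parameter_mrf_gives_log_A(self):
        L, A = 4, 6
        prof = np.zeros((3, L, A))
        prof[:, :, 2] = 1.0
        mrf = MRFParams(np.zeros((L, A)), np.zeros((L, L, A, A)))
        loss = mlm_loss(_soft(prof), _mask(np.ones((3, L))), mrf,
                        lam_v=0.0, lam_w=0.0)
        assert loss == pytest.approx(np.log(A))

    def test_gradient_matches_finite_differences(self, rng):
        L, A, B = 3, 3, 2
        prof = rng.dirichlet(np.ones(A), size=(B, L)) * 0.8
        gap = 1.0 - prof.sum(axis=2)
        mask = sample_mask(B, L, 0.5, 3).masked
        vr = rng.normal(0, 0.5, (L, A))
        wr = rng.normal(0, 0.5, (L, L, A, A))

        def value(v, w):
            vt, wt = ad.const(v), ad.const(w)
            return float(mlm_loss_t(ad.const(prof), ad.const(gap), mask,
                                    vt, _sym_t(wt, L), 0.01, 0.01, B).data)

        vt, wt = ad.var(vr), ad.var(wr)
        loss = mlm_loss_t(ad.const(prof), ad.const(gap), mask, vt,
                          _sym_t(wt, L), 0.01, 0.01, B)
        gv, gw = ad.grad(loss, [vt, wt])
        h = 1e-5
        for idx in [(0, 0), (2, 1)]:
            vp, vm = vr.copy(), vr.copy()
            vp[idx] += h
            vm[idx] -= h
            assert gv[idx] == pytest.approx((value(vp, wr) - value(vm, wr)) / (2 * h),
                                            rel=1e-4, abs=1e-8)
        for idx in [(0, 1, 0, 2), (2, 0, 1, 1)]:
            wp, wm = wr.copy(), wr.copy()
            wp[idx] += h
            wm[idx] -= h
            assert gw[idx] == pytest.approx((value(vr, wp) - value(vr, wm)) / (2 * h),
                                            rel=1e-4, abs=1e-8)

    def test_bad_mask_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            sample_mask(2, 3, 1.5, 0)


class TestSampleMask:
    def test_rate_one_masks_everything(self):
        assert sample_mask(3, 5, 1.0, 0).masked.all()

    def test_deterministic_under_seed(self):
        m1 = sample_mask(10, 20, 0.15, 7).masked
        m2 = sample_mask(10, 20, 0.15, 7).masked
        assert np.array_equal(m1, m2)

    def test_empirical_fraction_within_three_standard_errors(self):
        rate = 0.15
        m = sample_mask(500, 20, rate, 1).masked  # 10^4 entries
        n = m.size
        se = np.sqrt(rate * (1 - rate) / n)
        # the >=1-per-row redraw inflates the rate slightly; allow for it
        assert abs(m.mean() - rate) < 3 * se + 0.01

    def test_every_row_has_a_mask(self):
        m = sample_mask(200, 30, 0.02, 5).masked
        assert m.any(axis=1).all()


class TestContactScores:
    def test_zero_couplings_give_zero_scores(self):
        mrf = MRFParams(np.zeros((5, 3)), np.zeros((5, 5, 3, 3)))
        assert np.allclose(contact_scores(mrf).scores, 0.0)

    def test_single_planted_block_is_argmax_of_raw(self, rng):
        L, A = 8, 4
        W = np.zeros((L, L, A, A))
        W[1, 6] = np.eye(A) * 2.0
        W[6, 1] = np.eye(A) * 2.0
        mrf = MRFParams(np.zeros((L, A)), symmetrize_couplings(W))
        raw = np.sqrt((mrf.couplings ** 2).sum(axis=(2, 3)))
        i, j = np.unravel_index(np.argmax(raw), raw.shape)
        assert {i, j} == {1, 6}

    def test_apc_annihilates_rank_one(self, rng):
        r = rng.uniform(0.5, 2.0, 10)
        raw = np.outer(r, r)
        assert np.max(np.abs(apc(raw))) < 1e-8

    def test_symmetry_and_zero_diagonal(self, rng):
        L, A = 6, 3
        mrf = MRFParams(rng.normal(0, 1, (L, A)),
                        symmetrize_couplings(rng.normal(0, 1, (L, L, A, A))))
        s = contact_scores(mrf).scores
        assert np.allclose(s, s.T)
        assert np.allclose(np.diag(s), 0.0)

    def test_short_chain_rejected(self):
        mrf = MRFParams(np.zeros((2, 3)), np.zeros((2, 2, 3, 3)))
        with pytest.raises(ValueError, match="at least 3"):
            contact_scores(mrf)
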