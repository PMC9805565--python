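"""GREMLIN-style Markov Random Field over alignment columns.

The model assigns residue a at column i the energy
``v_i[a] + sum_j W_ij[a, b_j]``; training is masked language modeling: the
profile content at masked (sequence, column) entries is zeroed, the MRF
predicts a residue distribution there from the remaining columns, and the
loss is the cross entropy against the pre-mask profile (gap mass in the
target is spread uniformly -- the model has no gap state and cannot guess
insertions better than uniform) plus L2 regularization.  Couplings are kept
exactly symmetric with zero diagonal blocks by parameterizing through
``symmetrize_couplings``.

Contact scores are the Frobenius norms of the coupling blocks with the
average-product correction (APC) applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from .lam import SoftMSA

__all__ = [
    "MRFParams", "MaskSpec", "ContactScores", "symmetrize_couplings",
    "sample_mask", "mlm_predict", "mlm_loss", "contact_scores", "apc",
]


def symmetrize_couplings(raw: np.ndarray) -> np.ndarray:
    """(W + W^T)/2 in the (i,a),(j,b) sense, with zeroed diagonal blocks."""
    W = 0.5 * (raw + raw.transpose(1, 0, 3, 2))
    W[np.arange(W.shape[0]), np.arange(W.shape[0])] = 0.0
    return W


def _sym_t(raw_t, L: int):
    mask = np.ones((L, L, 1, 1))
    mask[np.arange(L), np.arange(L)] = 0.0
    return (raw_t + ad.transpose(raw_t, (1, 0, 3, 2))) * 0.5 * ad.const(mask)


@dataclass
class MRFParams:
    """Site fields (L, A) and symmetric pairwise couplings (L, L, A, A)."""

    fields: np.ndarray
    couplings: np.ndarray

    def __post_init__(self):
        self.fields = np.asarray(self.fields, dtype=np.float64)
        self.couplings = np.asarray(self.couplings, dtype=np.float64)
        L, A = self.fields.shape
        if self.couplings.shape != (L, L, A, A):
            raise ValueError("couplings must be (L, L, A, A)")

    def validate_symmetry(self, tol: float = 1e-10) -> None:
        W = self.couplings
        if not np.allclose(W, W.transpose(1, 0, 3, 2), atol=tol):
            raise ValueError("couplings are not symmetric (W_ij[a,b] != W_ji[b,a])")
        diag = W[np.arange(W.shape[0]), np.arange(W.shape[0])]
        if not np.allclose(diag, 0.0, atol=tol):
            raise ValueError("self-couplings W_ii must be zero")

    @property
    def L(self) -> int:
        return self.fields.shape[0]

    @property
    def A(self) -> int:
        return self.fields.shape[1]


@dataclass
class MaskSpec:
    """Boolean (B, L) mask of hidden (sequence, column) entries."""

    masked: np.ndarray
    rate: float
    seed: int

    def __post_init__(self):
        self.masked = np.asarray(self.masked, dtype=bool)
        if not (0.0 < self.rate <= 1.0):
            raise ValueError("mask rate must be in (0, 1]")
        if self.masked.ndim != 2 or not self.masked.any(axis=1).all():
            raise ValueError("every sequence needs at least one masked entry")


def sample_mask(B: int, L: int, rate: float, seed: int) -> MaskSpec:
    """i.i.d. Bernoulli(rate) per entry; rows with no mask are re-drawn."""
    if not (0.0 < rate <= 1.0):
        raise ValueError("mask rate must be in (0, 1]")
    rng = np.random.default_rng(seed)
    masked = rng.random((B, L)) < rate
    empty = ~masked.any(axis=1)
    while empty.any():
        masked[empty] = rng.random((int(empty.sum()), L)) < rate
        empty = ~masked.any(axis=1)
    return MaskSpec(masked, rate, seed)


# ---------------------------------------------------------------------------
# masked-language-model prediction and loss
# ---------------------------------------------------------------------------

def _logits_t(profiles_t, mask: np.ndarray, v_t, Wsym_t, L: int, A: int):
    """logits[s,i,a] = v_i[a] + sum_{j unmasked} sum_b W_ij[a,b] profile[s,j,b];
    masked entries contribute an all-zero profile (the mask token)."""
    B = mask.shape[0]
    pm = profiles_t * ad.const((~mask)[:, :, None].astype(float))
    Wmat = ad.reshape(ad.transpose(Wsym_t, (0, 2, 1, 3)), (L * A, L * A))
    flat = ad.matmul(ad.reshape(pm, (B, L * A)), ad.transpose(Wmat, (1, 0)))
    return ad.reshape(flat, (B, L, A)) + v_t


def mlm_predict(profiles: SoftMSA, mask: MaskSpec, mrf: MRFParams) -> np.ndarray:
    """Residue distributions predicted at masked entries.

    Returns a (B, L, A) array of softmax distributions; only entries where
    ``mask.masked`` holds are predictions (the rest are computed but unused).
    """
    mrf.validate_symmetry()
    prof = np.asarray(profiles.profiles, dtype=np.float64)
    if prof.shape[:2] != mask.masked.shape:
        raise ValueError("mask shape does not match profiles")
    L, A = mrf.L, mrf.A
    logits = _logits_t(ad.const(prof), mask.masked, ad.const(mrf.fields),
                       ad.const(mrf.couplings), L, A)
    return ad.softmax(logits, axis=2).data


def mlm_loss_t(profiles_t, gap_t, mask: np.ndarray, v_t, Wsym_t,
               lam_v: float, lam_w: float, n_seqs: int):
    """Tensor-graph MLM loss (mean masked cross entropy + L2 penalties).

    The target at a masked entry is the pre-mask profile with its gap mass
    spread uniformly over the alphabet.  The coupling penalty follows the
    GREMLIN convention lam_w * (L-1)(A-1), rescaled by 1/(n_seqs * L)
    because the cross entropy here is a mean per masked entry rather than a
    sum over all (sequence, site) terms.
    """
    B, L, A = profiles_t.shape
    logits = _logits_t(profiles_t, mask, v_t, Wsym_t, L, A)
    logp = ad.log_softmax(logits, axis=2)
    target = profiles_t + ad.reshape(gap_t, (B, L, 1)) * (1.0 / A)
    ce = -ad.tsum(target * logp, axis=2)
    mask_f = mask.astype(float)
    loss = ad.tsum(ce * ad.const(mask_f)) * (1.0 / mask_f.sum())
    lw = lam_w * (L - 1) * (A - 1) / (n_seqs * L)
    lv = lam_v / L
    return loss + lv * ad.tsum(v_t * v_t) + lw * ad.tsum(Wsym_t * Wsym_t)


def mlm_loss(profiles: SoftMSA, mask: MaskSpec, mrf: MRFParams,
             lam_v: float = 0.01, lam_w: float = 0.01) -> float:
    mrf.validate_symmetry()
    prof = np.asarray(profiles.profiles, dtype=np.float64)
    gap = np.asarray(profiles.gap_mass, dtype=np.float64)
    loss = mlm_loss_t(ad.const(prof), ad.const(gap), mask.masked,
                      ad.const(mrf.fields), ad.const(mrf.couplings),
                      lam_v, lam_w, prof.shape[0])
    return float(loss.data)


# ---------------------------------------------------------------------------
# contact extraction
# ---------------------------------------------------------------------------

@dataclass
class ContactScores:
    """Symmetric (L, L) matrix, zero diagonal; larger = more contact-like."""

    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)


def apc(raw: np.ndarray) -> np.ndarray:
    """Average-product correction: raw_ij - rowmean_i * rowmean_j / grandmean."""
    r = np.asarray(raw, dtype=np.float64)
    row = r.mean(axis=1)
    grand = r.mean()
    if grand == 0.0:
        return r.copy()
    return r - np.outer(row, row) / grand


def contact_scores(mrf: MRFParams) -> ContactScores:
    """APC-corrected Frobenius norms of the coupling blocks."""
    if mrf.L < 3:
        raise ValueError("contact scoring needs at least 3 columns")
    mrf.validate_symmetry()
    raw = np.sqrt((mrf.couplings ** 2).sum(axis=(2, 3)))
    s = apc(raw)
    s = 0.5 * (s + s.T)
    np.fill_diagonal(s, 0.0)
    return ContactScores(s)
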