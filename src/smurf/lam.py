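"""Learned Alignment Module (LAM).

A single linear convolution over one-hot sequences produces a context
embedding v_i for every residue (window 2w+1, zero padding, so positions map
one-to-one).  The alignment score between query residue i and residue j of
another sequence is the dot product a_ij = v_i . v_j; running the smooth
alignment on each similarity matrix yields one posterior alignment per
sequence, all in query coordinates.  Contracting posteriors with the one-hot
sequences gives a "soft MSA": the expected residue distribution each
sequence contributes to each query column, plus the leftover gap mass.

The whole chain is differentiable with respect to the convolution kernel and
bias; the tensor-graph variants (suffix ``_t``) are what the training loops
backpropagate through.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from .smooth_align import (AlignParams, PosteriorAlignment, hard_align,
                           smooth_dp_batch)

PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYV"   # unknown 'X' -> all-zero row
RNA_ALPHABET = "ACGU"                       # unknown 'N' -> all-zero row

_UNKNOWN = {"protein": "X", "rna": "N"}


def get_alphabet(name: str) -> str:
    if name == "protein":
        return PROTEIN_ALPHABET
    if name == "rna":
        return RNA_ALPHABET
    raise ValueError(f"unknown alphabet {name!r}")


def one_hot(seq: str, alphabet: str = PROTEIN_ALPHABET) -> np.ndarray:
    """One-hot encode a sequence; the unknown symbol maps to an all-zero row."""
    unknown = _UNKNOWN["protein" if alphabet == PROTEIN_ALPHABET else "rna"] \
        if alphabet in (PROTEIN_ALPHABET, RNA_ALPHABET) else None
    idx = {c: k for k, c in enumerate(alphabet)}
    out = np.zeros((len(seq), len(alphabet)))
    for p, c in enumerate(seq.upper()):
        if c in idx:
            out[p, idx[c]] = 1.0
        elif c != unknown:
            raise ValueError(f"symbol {c!r} at position {p} not in alphabet")
    return out


@dataclass
class EncoderParams:
    """Convolutional residue-context encoder: kernel (2w+1, A, F), bias (F,)."""

    kernel: np.ndarray
    bias: np.ndarray

    def __post_init__(self):
        self.kernel = np.asarray(self.kernel, dtype=np.float64)
        self.bias = np.asarray(self.bias, dtype=np.float64)
        if self.kernel.ndim != 3 or self.kernel.shape[0] % 2 != 1:
            raise ValueError("kernel must be (2w+1, A, F) with odd width")
        if self.bias.shape != (self.kernel.shape[2],):
            raise ValueError("bias length must equal the filter count")

    @property
    def window_half_width(self) -> int:
        return (self.kernel.shape[0] - 1) // 2

    @property
    def alphabet_size(self) -> int:
        return self.kernel.shape[1]

    @property
    def filters(self) -> int:
        return self.kernel.shape[2]


def init_encoder(window_half_width: int, alphabet_size: int, filters: int,
                 seed: int) -> EncoderParams:
    """Kernel entries ~ N(0, 1/fan_in), zero bias."""
    rng = np.random.default_rng(seed)
    width = 2 * window_half_width + 1
    scale = 1.0 / np.sqrt(width * alphabet_size)
    return EncoderParams(rng.normal(0.0, scale, (width, alphabet_size, filters)),
                         np.zeros(filters))


def _unfold(onehot: np.ndarray, w: int) -> np.ndarray:
    """(l, A) -> (l, (2w+1)*A) sliding windows with zero padding."""
    l, A = onehot.shape
    padded = np.zeros((l + 2 * w, A))
    padded[w: w + l] = onehot
    width = 2 * w + 1
    out = np.empty((l, width * A))
    for k in range(width):
        out[:, k * A: (k + 1) * A] = padded[k: k + l]
    return out


def encode(onehot: np.ndarray, enc: EncoderParams) -> np.ndarray:
    """Context embedding of every residue: row i depends only on i-w..i+w."""
    onehot = np.asarray(onehot, dtype=np.float64)
    if onehot.ndim != 2 or onehot.shape[1] != enc.alphabet_size:
        raise ValueError("one-hot input must be (length, alphabet_size)")
    w = enc.window_half_width
    kmat = enc.kernel.reshape(-1, enc.filters)
    return _unfold(onehot, w) @ kmat + enc.bias


def similarity(query_vecs: np.ndarray, other_vecs: np.ndarray) -> np.ndarray:
    """Score matrix a_ij = <query vector i, other vector j>."""
    q = np.asarray(query_vecs, dtype=np.float64)
    o = np.asarray(other_vecs, dtype=np.float64)
    if q.shape[1] != o.shape[1]:
        raise ValueError("filter dimensions differ between embeddings")
    return q @ o.T


@dataclass
class SoftMSA:
    """profiles (B, L_query, A): expected residue distribution per column;
    gap_mass (B, L_query) = 1 - aligned mass (profiles + gap sums to one)."""

    profiles: np.ndarray
    gap_mass: np.ndarray


# ---------------------------------------------------------------------------
# tensor-graph chain used by training
# ---------------------------------------------------------------------------

def lam_chain_t(seq_onehots, query_onehot, kernel_t, bias_t, params: AlignParams):
    """Differentiable pipeline: encode -> similarity stack -> posteriors ->
    soft-MSA profiles.  kernel_t is the flattened kernel ((2w+1)*A, F).

    Returns (profiles, gap_mass, P, lens): engine tensors (B, n, A), (B, n),
    (B, n, m_max) plus the per-sequence true lengths.
    """
    if len(seq_onehots) == 0:
        raise ValueError("empty sequence list")
    A = query_onehot.shape[1]
    width_a = kernel_t.shape[0]
    w = (width_a // A - 1) // 2
    n = query_onehot.shape[0]
    lens = np.array([s.shape[0] for s in seq_onehots], dtype=np.intp)
    m_max = int(lens.max())
    B = len(seq_onehots)

    blocks = [_unfold(query_onehot, w)] + [_unfold(s, w) for s in seq_onehots]
    big = ad.const(np.concatenate(blocks, axis=0))
    V = ad.matmul(big, kernel_t) + bias_t
    Vq = V[:n]
    offs = np.concatenate([[n], n + np.cumsum(lens)])
    sims = []
    for k in range(B):
        Vk = V[offs[k]: offs[k + 1]]
        Sk = ad.matmul(Vq, ad.transpose(Vk, (1, 0)))  # (n, l_k)
        if lens[k] < m_max:
            Sk = ad.concat([Sk, ad.const(np.zeros((n, m_max - lens[k])))], axis=1)
        sims.append(Sk)
    s = ad.stack(sims, 0)
    _, P = smooth_dp_batch(s, np.full(B, n, dtype=np.intp), lens, params, True)

    oh_pad = np.zeros((B, m_max, A))
    for k, soh in enumerate(seq_onehots):
        oh_pad[k, : lens[k]] = soh
    profiles = ad.matmul(P, ad.const(oh_pad))
    gap = 1.0 - ad.tsum(P, axis=2)
    return profiles, gap, P, lens


# ---------------------------------------------------------------------------
# public (numpy) operations
# ---------------------------------------------------------------------------

def build_alignment_tensor(seqs, query, enc: EncoderParams,
                           params: AlignParams):
    """Posterior alignment of every sequence against the query, computed on
    the learned similarity matrices."""
    if len(seqs) == 0:
        raise ValueError("empty sequence list")
    vq = encode(query, enc)
    out = []
    for s in seqs:
        a = similarity(vq, encode(s, enc))
        _, P = smooth_dp_batch(a[None], np.array([a.shape[0]]),
                               np.array([a.shape[1]]), params, True)
        out.append(PosteriorAlignment(P.data[0]))
    return out


def soft_msa(alignments, seqs) -> SoftMSA:
    """Contract posterior alignments with one-hot sequences."""
    if len(alignments) != len(seqs):
        raise ValueError("one posterior per sequence required")
    profs, gaps = [], []
    for P, s in zip(alignments, seqs):
        p = P.probs if isinstance(P, PosteriorAlignment) else np.asarray(P)
        s = np.asarray(s, dtype=np.float64)
        if p.shape[1] != s.shape[0]:
            raise ValueError(
                f"posterior has {p.shape[1]} columns but sequence has {s.shape[0]} residues")
        profs.append(p @ s)
        gaps.append(1.0 - p.sum(axis=1))
    return SoftMSA(np.stack(profs), np.stack(gaps))


def harden_msa(seqs, query, enc: EncoderParams, params: AlignParams,
               alphabet: str = PROTEIN_ALPHABET):
    """Hard (classic) alignment of each sequence to the query on the learned
    similarity matrices, exported as A3M rows (query row first)."""
    from .fileio import a3m_row_from_path  # local import avoids cycle

    vq = encode(one_hot(query, alphabet), enc)
    rows = [query.upper()]
    for s in seqs:
        a = similarity(vq, encode(one_hot(s, alphabet), enc))
        _, path = hard_align(a, params)
        rows.append(a3m_row_from_path(s, path, len(query)))
    return rows
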