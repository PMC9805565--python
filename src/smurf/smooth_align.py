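"""Smooth (differentiable) and classic pairwise alignment.

The smooth alignment defines a Gibbs distribution over alignment *lattice
paths* -- sequences of match / x-gap / y-gap moves through the DP grid --
with weight exp(path_score / T).  Replacing max by logsumexp in the usual
Smith-Waterman / Needleman-Wunsch recursion yields the log-partition
function ("smooth score"), and the probability that a given residue pair is
matched (the posterior alignment) is obtained by a forward-backward pass
over the same three-state machine.  The posterior equals the derivative of
the smooth score with respect to the match-score matrix.

Conventions (all isolated behind :class:`AlignParams`):

* three states per grid node: M (last move matched a residue pair),
  X (last move consumed a residue of x unmatched), Y (same for y);
* affine gaps charge ``open`` on the first position of a maximal gap streak
  and ``extend`` thereafter; linear mode is open == extend == gap;
* ``restrict_turns`` forbids the Y -> X transition, so consecutive opposite
  gap runs have a single canonical ordering (x-gaps first);
* local mode: a nonempty path begins and ends with a match, and the empty
  path is valid with score 0; global mode: paths run corner to corner and
  terminal gaps are charged like internal ones;
* gap penalties are additive (pass negative numbers to penalize).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.special import logsumexp as _sp_logsumexp

from . import _autodiff as ad

NEG = -1.0e9  # large negative sentinel standing in for -inf (keeps gradients finite)

_ENUM_GUARD = 7


# ---------------------------------------------------------------------------
# parameter / path containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignParams:
    """Knobs of the smooth alignment.

    temperature: Gibbs temperature T > 0 (T -> 0 recovers the hard score).
    gap: per-residue penalty in linear mode (additive, typically negative).
    open/extend: affine penalties (first / subsequent position of a streak).
    gap_mode: "linear" or "affine".
    align_mode: "local" (Smith-Waterman) or "global" (Needleman-Wunsch).
    restrict_turns: forbid y-gap -> x-gap transitions (removes the double
        counting of equivalent gap orderings).
    """

    temperature: float = 1.0
    gap: float = -1.0
    open: Optional[float] = None
    extend: Optional[float] = None
    gap_mode: str = "linear"
    align_mode: str = "local"
    restrict_turns: bool = True

    def __post_init__(self):
        if not (self.temperature > 0):
            raise ValueError("temperature must be positive")
        if self.gap_mode not in ("linear", "affine"):
            raise ValueError(f"unknown gap_mode {self.gap_mode!r}")
        if self.align_mode not in ("local", "global"):
            raise ValueError(f"unknown align_mode {self.align_mode!r}")
        if self.gap_mode == "affine" and (self.open is None or self.extend is None):
            raise ValueError("affine mode requires both open and extend")

    @property
    def gap_open(self) -> float:
        return self.gap if self.gap_mode == "linear" else float(self.open)

    @property
    def gap_extend(self) -> float:
        return self.gap if self.gap_mode == "linear" else float(self.extend)


@dataclass(frozen=True)
class AlignmentPath:
    """An alignment path: matched residue pairs, optionally with the full
    move string ('M'/'X'/'Y') that disambiguates gap ordering.

    ``start`` is the grid node where the move string begins ((0, 0) for
    global paths; the first match position for local paths).
    """

    matches: Tuple[Tuple[int, int], ...]
    moves: Optional[str] = None
    start: Tuple[int, int] = (0, 0)

    def __post_init__(self):
        prev = (-1, -1)
        for (i, j) in self.matches:
            if not (i > prev[0] and j > prev[1]):
                raise ValueError(
                    f"non-monotone path: {prev} followed by {(i, j)}")
            prev = (i, j)


@dataclass(frozen=True)
class PosteriorAlignment:
    """Expected match-indicator matrix under the Gibbs path distribution."""

    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs)
        if p.ndim != 2:
            raise ValueError("posterior must be a matrix")


def _check_scores(a) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] < 1 or a.shape[1] < 1:
        raise ValueError("score matrix must be 2-D and non-empty")
    if not np.all(np.isfinite(a)):
        raise ValueError("score matrix contains non-finite entries")
    return a


# ---------------------------------------------------------------------------
# path scoring and brute-force enumeration (oracles)
# ---------------------------------------------------------------------------

def path_score(a, path: AlignmentPath, params: AlignParams) -> float:
    """Score of one alignment path: match scores plus gap penalties.

    With a move string, affine streaks are read off the moves directly.
    For match-only paths each contiguous unmatched block per sequence is one
    streak (the canonical ordering; identical to the move-based charge when
    restrict_turns holds).
    """
    a = _check_scores(a)
    n, m = a.shape
    for (i, j) in path.matches:
        if not (0 <= i < n and 0 <= j < m):
            raise ValueError(f"match {(i, j)} outside a {n}x{m} score matrix")
    total = float(sum(a[i, j] for i, j in path.matches))
    go, ge = params.gap_open, params.gap_extend
    if path.moves is not None:
        prev = None
        for mv in path.moves:
            if mv == "M":
                prev = "M"
                continue
            total += go if mv != prev else ge
            prev = mv
        return total

    # match-only representation: charge per unmatched block
    def block(dx: int) -> float:
        if dx <= 0:
            return 0.0
        return go + (dx - 1) * ge

    ms = list(path.matches)
    if params.align_mode == "global":
        bounds = [(-1, -1)] + ms + [(n, m)]
    else:
        if not ms:
            return 0.0
        bounds = ms
    for (i0, j0), (i1, j1) in zip(bounds[:-1], bounds[1:]):
        total += block(i1 - i0 - 1) + block(j1 - j0 - 1)
    return total


def enumerate_paths(len_x: int, len_y: int, params: AlignParams):
    """Exhaustively enumerate every alignment lattice path (testing oracle).

    Paths are move sequences; two paths differing only in the order of
    opposite gap runs are distinct (and restrict_turns removes one order).
    Guarded to short sequences -- the count grows exponentially.
    """
    if len_x > _ENUM_GUARD or len_y > _ENUM_GUARD:
        raise ValueError(f"enumeration limited to lengths <= {_ENUM_GUARD}")
    if len_x < 1 or len_y < 1:
        raise ValueError("sequences must be non-empty")
    rt = params.restrict_turns
    out = []

    def walk(i, j, moves, matches, start):
        if params.align_mode == "global":
            if i == len_x and j == len_y:
                out.append(AlignmentPath(tuple(matches), "".join(moves), start))
        else:
            if moves and moves[-1] == "M":
                out.append(AlignmentPath(tuple(matches), "".join(moves), start))
        if i < len_x and j < len_y:
            matches.append((i, j))
            moves.append("M")
            walk(i + 1, j + 1, moves, matches, start)
            moves.pop()
            matches.pop()
        if i < len_x and not (rt and moves and moves[-1] == "Y"):
            moves.append("X")
            walk(i + 1, j, moves, matches, start)
            moves.pop()
        if j < len_y:
            moves.append("Y")
            walk(i, j + 1, moves, matches, start)
            moves.pop()

    if params.align_mode == "global":
        walk(0, 0, [], [], (0, 0))
    else:
        out.append(AlignmentPath((), "", (0, 0)))  # empty local path
        for i0 in range(len_x):
            for j0 in range(len_y):
                matches = [(i0, j0)]
                moves = ["M"]
                # start with the match at (i0, j0), then continue
                def cont(i, j):
                    if moves[-1] == "M":
                        out.append(AlignmentPath(tuple(matches), "".join(moves), (i0, j0)))
                    if i < len_x and j < len_y:
                        matches.append((i, j))
                        moves.append("M")
                        cont(i + 1, j + 1)
                        moves.pop()
                        matches.pop()
                    if i < len_x and not (rt and moves[-1] == "Y"):
                        moves.append("X")
                        cont(i + 1, j)
                        moves.pop()
                    if j < len_y:
                        moves.append("Y")
                        cont(i, j + 1)
                        moves.pop()

                cont(i0 + 1, j0 + 1)
    return out


def brute_force_smooth_score(a, params: AlignParams) -> float:
    """T * logsumexp over all enumerated path scores (oracle for smooth_score)."""
    a = _check_scores(a)
    paths = enumerate_paths(a.shape[0], a.shape[1], params)
    scores = np.array([path_score(a, p, params) for p in paths])
    T = params.temperature
    return float(T * _sp_logsumexp(scores / T))


def brute_force_posterior(a, params: AlignParams) -> np.ndarray:
    """Expected match matrix by explicit enumeration (oracle for posterior)."""
    a = _check_scores(a)
    paths = enumerate_paths(a.shape[0], a.shape[1], params)
    T = params.temperature
    scores = np.array([path_score(a, p, params) for p in paths]) / T
    w = np.exp(scores - _sp_logsumexp(scores))
    P = np.zeros(a.shape)
    for wk, p in zip(w, paths):
        for (i, j) in p.matches:
            P[i, j] += wk
    return P


# ---------------------------------------------------------------------------
# batched smooth DP (forward and forward-backward), autodiff-friendly
# ---------------------------------------------------------------------------

def _masks(k, i_idx, lx, ly, n):
    j = k - i_idx  # (W,)
    base = (j >= 0) & (i_idx <= lx[:, None]) & (j[None, :] <= ly[:, None])
    mv = base & (i_idx >= 1) & (j[None, :] >= 1)
    dv = base & (i_idx >= 1)[None, :]
    iv = base & (j >= 1)[None, :]
    return base, mv, dv, iv


def smooth_dp_batch(s, lx, ly, params: AlignParams, want_posterior: bool):
    """Batched three-state smooth alignment over the diagonal wavefront.

    s: Tensor or array (B, n, m) of match scores, items padded to (n, m);
    lx, ly: integer arrays (B,) of true lengths (padding beyond them can
    never influence the result -- invalid lattice nodes are pinned to the
    -1e9 sentinel and per-item terminal nodes are addressed exactly).

    Returns (score, P): score is a (B,) Tensor of T * log-partition values;
    P is a (B, n, m) Tensor of match posteriors (or None).
    """
    s = ad.const(s)
    B, n, m = s.shape
    lx = np.asarray(lx, dtype=np.intp)
    ly = np.asarray(ly, dtype=np.intp)
    if np.any(lx < 1) or np.any(ly < 1):
        raise ValueError("true lengths must be >= 1")
    if np.any(lx > n) or np.any(ly > m):
        raise ValueError("true length exceeds padded shape")

    T = params.temperature
    go = params.gap_open / T
    ge = params.gap_extend / T
    local = params.align_mode == "local"
    rt = params.restrict_turns

    sT = s * (1.0 / T)
    s_flat = ad.reshape(sT, (B, n * m))
    W = n + 1
    K = n + m
    i_idx = np.arange(W)

    neg_row = ad.const(np.full((B, W), NEG))
    neg_col = ad.const(np.full((B, 1), NEG))
    zeros_row = ad.const(np.zeros((B, W)))

    def shift_down(t):
        return ad.concat([neg_col, t[:, : W - 1]], axis=1)

    def shift_up(t):
        return ad.concat([t[:, 1:], neg_col], axis=1)

    # ---- forward -----------------------------------------------------
    Ms, Mvalids = [], []
    prev = {"M": neg_row, "D": neg_row, "I": neg_row}   # diag k-1
    prev2 = {"M": neg_row, "D": neg_row, "I": neg_row}  # diag k-2
    if local:
        zacc = ad.const(np.full((B,), NEG))
    else:
        fin = {st: ad.const(np.full((B,), NEG)) for st in "MDI"}
        corner_diag = lx + ly
        batch_arange = np.arange(B)

    for k in range(K + 1):
        base, mv, dv, iv = _masks(k, i_idx, lx, ly, n)
        if k == 0:
            m0 = np.full((B, W), NEG)
            if not local:
                m0[:, 0] = 0.0  # virtual start node (0,0)
            cur = {"M": ad.const(m0), "D": neg_row, "I": neg_row}
        else:
            j = k - i_idx
            fm = np.clip((i_idx - 1) * m + (j - 1), 0, n * m - 1)
            gm = ad.where(mv, ad.take_cols(s_flat, fm), NEG)
            mc = [shift_down(prev2["M"]), shift_down(prev2["D"]), shift_down(prev2["I"])]
            if local:
                mc.append(zeros_row)
            Mk = ad.where(mv, gm + ad.lse(mc), NEG)
            dc = [shift_down(prev["M"]) + go, shift_down(prev["D"]) + ge]
            if not rt:
                dc.append(shift_down(prev["I"]) + go)
            Dk = ad.where(dv, ad.lse(dc), NEG)
            ic = [prev["M"] + go, prev["D"] + go, prev["I"] + ge]
            Ik = ad.where(iv, ad.lse(ic), NEG)
            cur = {"M": Mk, "D": Dk, "I": Ik}

        Ms.append(cur["M"])
        Mvalids.append(mv)
        if local:
            if k >= 2:
                zk = ad.lse_axis(cur["M"], axis=1)
                zacc = ad.lse([zacc, zk])
        else:
            at_corner = corner_diag == k
            if at_corner.any():
                for st in "MDI":
                    cval = cur[st][(batch_arange, lx)]
                    fin[st] = ad.where(at_corner, cval, fin[st])
        prev2, prev = prev, cur

    if local:
        logZ = ad.lse([zacc, ad.const(np.zeros(B))])  # + empty path
    else:
        logZ = ad.lse([fin["M"], fin["D"], fin["I"]])
    score = logZ * T

    if not want_posterior:
        return score, None

    # ---- backward ----------------------------------------------------
    BMs = [None] * (K + 1)
    nxt = {"M": neg_row, "D": neg_row, "I": neg_row}   # diag k+1
    nxt2 = {"M": neg_row, "D": neg_row, "I": neg_row}  # diag k+2
    for k in range(K, -1, -1):
        base, mv, dv, iv = _masks(k, i_idx, lx, ly, n)
        j = k - i_idx
        scv = base & (i_idx[None, :] < lx[:, None]) & (j[None, :] < ly[:, None])
        fm2 = np.clip(i_idx * m + j, 0, n * m - 1)
        g2 = ad.where(scv, ad.take_cols(s_flat, fm2), NEG)
        mt = g2 + shift_up(nxt2["M"])
        bmc = [mt, go + shift_up(nxt["D"]), go + nxt["I"]]
        if local:
            bmc.append(zeros_row)  # a local path may end at this match
        BMk = ad.where(mv, ad.lse(bmc), NEG)
        bdc = [mt, ge + shift_up(nxt["D"]), go + nxt["I"]]
        BDk = ad.where(dv, ad.lse(bdc), NEG)
        bic = [mt, ge + nxt["I"]]
        if not rt:
            bic.append(go + shift_up(nxt["D"]))
        BIk = ad.where(iv, ad.lse(bic), NEG)
        if not local:
            corner2d = (i_idx[None, :] == lx[:, None]) & ((lx + ly) == k)[:, None]
            BMk = ad.where(corner2d, 0.0, BMk)
            BDk = ad.where(corner2d, 0.0, BDk)
            BIk = ad.where(corner2d, 0.0, BIk)
        BMs[k] = BMk
        nxt2 = nxt
        nxt = {"M": BMk, "D": BDk, "I": BIk}

    logZ2 = ad.reshape(logZ, (B, 1))
    parts, cols = [], []
    for k in range(2, K + 1):
        i0, i1 = max(1, k - m), min(n, k - 1)
        if i0 > i1:
            continue
        pk = ad.where(Mvalids[k], ad.exp(Ms[k] + BMs[k] - logZ2), 0.0)
        parts.append(pk[:, i0: i1 + 1])
        ii = np.arange(i0, i1 + 1)
        cols.append((ii - 1) * m + (k - ii - 1))
    vals = ad.concat(parts, axis=1)
    P = ad.reshape(ad.put_cols(vals, np.concatenate(cols), n * m), (B, n, m))
    return score, P


# ---------------------------------------------------------------------------
# public single-pair operations
# ---------------------------------------------------------------------------

def smooth_score(a, params: AlignParams) -> float:
    """Smoothed alignment score T * log sum_paths exp(path_score / T),
    computed by the log-space DP recursion (never by enumeration)."""
    a = _check_scores(a)
    n, m = a.shape
    score, _ = smooth_dp_batch(a[None], np.array([n]), np.array([m]), params, False)
    return float(score.data[0])


def posterior(a, params: AlignParams) -> PosteriorAlignment:
    """Match-pair posterior probabilities under the Gibbs path distribution
    (equals the derivative of smooth_score with respect to each a_ij)."""
    a = _check_scores(a)
    n, m = a.shape
    _, P = smooth_dp_batch(a[None], np.array([n]), np.array([m]), params, True)
    return PosteriorAlignment(P.data[0])


def batched_smooth(a_stack, len_x, len_y, params: AlignParams):
    """Posterior alignments for a stack of padded score matrices.

    a_stack: (B, n, m) array, item k meaningful on [:len_x[k], :len_y[k]].
    Returns a list of PosteriorAlignment, each cropped to its true shape.
    """
    a_stack = np.asarray(a_stack, dtype=np.float64)
    if a_stack.ndim != 3:
        raise ValueError("a_stack must be (B, n, m)")
    if not np.all(np.isfinite(a_stack)):
        raise ValueError("score stack contains non-finite entries")
    _, P = smooth_dp_batch(a_stack, len_x, len_y, params, True)
    return [PosteriorAlignment(P.data[k, : len_x[k], : len_y[k]])
            for k in range(a_stack.shape[0])]


# ---------------------------------------------------------------------------
# classic (hard) alignment
# ---------------------------------------------------------------------------

def hard_align(a, params: AlignParams) -> Tuple[float, AlignmentPath]:
    """Max-score alignment with traceback, same conventions as smooth_score.

    Tie-break priority: match > x-gap > y-gap; among equal-scoring local end
    cells the first in row-major order wins.
    """
    a = _check_scores(a)
    n, m = a.shape
    go, ge = params.gap_open, params.gap_extend
    local = params.align_mode == "local"
    rt = params.restrict_turns

    M = np.full((n + 1, m + 1), NEG)
    D = np.full((n + 1, m + 1), NEG)
    I = np.full((n + 1, m + 1), NEG)
    # predecessor codes: 0=M, 1=D, 2=I, 3=path start
    Mp = np.zeros((n + 1, m + 1), dtype=np.int8)
    Dp = np.zeros((n + 1, m + 1), dtype=np.int8)
    Ip = np.zeros((n + 1, m + 1), dtype=np.int8)
    if not local:
        M[0, 0] = 0.0
        Mp[0, 0] = 3

    def pick(cands):
        best, arg = cands[0]
        for v, c in cands[1:]:
            if v > best:
                best, arg = v, c
        return best, arg

    for i in range(n + 1):
        for j in range(m + 1):
            if i >= 1 and j >= 1:
                cands = [(M[i - 1, j - 1], 0), (D[i - 1, j - 1], 1), (I[i - 1, j - 1], 2)]
                if local:
                    cands.append((0.0, 3))
                v, c = pick(cands)
                if v > NEG / 2:
                    M[i, j] = a[i - 1, j - 1] + v
                    Mp[i, j] = c
            if i >= 1:
                cands = [(M[i - 1, j] + go, 0), (D[i - 1, j] + ge, 1)]
                if not rt:
                    cands.append((I[i - 1, j] + go, 2))
                v, c = pick(cands)
                D[i, j], Dp[i, j] = v, c
            if j >= 1:
                cands = [(M[i, j - 1] + go, 0), (D[i, j - 1] + go, 1), (I[i, j - 1] + ge, 2)]
                v, c = pick(cands)
                I[i, j], Ip[i, j] = v, c

    if local:
        best, cell = 0.0, None
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                if M[i, j] > best:
                    best, cell = M[i, j], (i, j)
        if cell is None:
            return 0.0, AlignmentPath((), "", (0, 0))
        score, (i, j), state = best, cell, 0
    else:
        score, state = pick([(M[n, m], 0), (D[n, m], 1), (I[n, m], 2)])
        i, j = n, m

    moves, matches = [], []
    while True:
        if state == 0:
            p = Mp[i, j]
            if not local and i == 0 and j == 0:
                break
            moves.append("M")
            matches.append((i - 1, j - 1))
            i, j = i - 1, j - 1
            if local and p == 3:
                break
            state = p
        elif state == 1:
            moves.append("X")
            state = Dp[i, j]
            i -= 1
        else:
            moves.append("Y")
            state = Ip[i, j]
            j -= 1
        if not local and i == 0 and j == 0:
            break
    moves.reverse()
    matches.reverse()
    start = matches[0] if (local and matches) else (0, 0)
    return float(score), AlignmentPath(tuple(matches), "".join(moves), start)
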