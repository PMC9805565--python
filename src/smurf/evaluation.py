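"""Contact-prediction and MSA-quality metrics.

Contact AUC is the mean precision of the top-t ranked predicted pairs for
t = 1..L; pairs closer than ``min_sep`` along the chain are excluded from
both the ranking and the truth.  MSA consistency scores every induced
pairwise alignment of an MSA with a substitution matrix and affine gap
penalties -- self-consistent alignments give high pairwise scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from Bio.Align import substitution_matrices

from .mrf import ContactScores


@dataclass(frozen=True)
class ContactTruth:
    """True contacts as 1-based (i, j) pairs with i < j, plus chain length."""

    pairs: frozenset
    L: int

    def __post_init__(self):
        for (i, j) in self.pairs:
            if not (1 <= i < j <= self.L):
                raise ValueError(f"contact {(i, j)} outside 1..{self.L} or unordered")


def _ranked_pairs(scores: np.ndarray, L: int, min_sep: int):
    """Eligible pairs sorted by descending score, ties broken by (i, j)."""
    pairs = [(i, j) for i in range(1, L + 1) for j in range(i + min_sep, L + 1)]
    pairs.sort(key=lambda p: (-scores[p[0] - 1, p[1] - 1], p[0], p[1]))
    return pairs


def _score_matrix(scores) -> np.ndarray:
    if isinstance(scores, ContactScores):
        return scores.scores
    return np.asarray(scores, dtype=np.float64)


def contact_auc(scores, truth: ContactTruth, min_sep: int = 6) -> float:
    """Mean of precision(top-t) for t = 1..L."""
    s = _score_matrix(scores)
    true = {p for p in truth.pairs if p[1] - p[0] >= min_sep}
    if not true:
        raise ValueError("no true contacts at this separation")
    ranked = _ranked_pairs(s, truth.L, min_sep)
    hits = np.cumsum([p in true for p in ranked])
    t = np.arange(1, truth.L + 1)
    prec = hits[: truth.L] / t[: len(hits)]
    return float(prec.mean())


def ppv_curve(scores, truth: ContactTruth, min_sep: int = 6,
              n_max: Optional[int] = None) -> List[Tuple[int, float]]:
    """Positive predictive value of the top-N predictions, N = 1..n_max."""
    s = _score_matrix(scores)
    true = {p for p in truth.pairs if p[1] - p[0] >= min_sep}
    if not true:
        raise ValueError("no true contacts at this separation")
    if n_max is None:
        n_max = 2 * truth.L
    ranked = _ranked_pairs(s, truth.L, min_sep)[:n_max]
    hits = np.cumsum([p in true for p in ranked])
    return [(N, float(hits[N - 1] / N)) for N in range(1, len(ranked) + 1)]


def top_n_recovery(scores, truth: ContactTruth, n: Optional[int] = None,
                   min_sep: int = 6) -> float:
    """Fraction of true contacts among the top-n ranked pairs (n = |truth|)."""
    s = _score_matrix(scores)
    true = {p for p in truth.pairs if p[1] - p[0] >= min_sep}
    if n is None:
        n = len(true)
    ranked = _ranked_pairs(s, truth.L, min_sep)[:n]
    return len(true.intersection(ranked)) / len(true)


# ---------------------------------------------------------------------------
# MSA quality
# ---------------------------------------------------------------------------

@dataclass
class ConsistencyReport:
    """Substitution-matrix scores of all induced pairwise alignments."""

    pair_scores: List[float]
    median: float
    q1: float
    q3: float
    aligned_fraction: float


def _strip_insertions(row: str) -> str:
    return "".join(c for c in row if not c.islower())


def _pair_score(r: str, s: str, submat, gap_open: float, gap_extend: float) -> float:
    total = 0.0
    prev = None  # which row is currently in a gap streak: 'r', 's' or None
    for cr, cs in zip(r, s):
        if cr == "-" and cs == "-":
            continue  # column absent from the induced pairwise alignment
        if cr != "-" and cs != "-":
            total += float(submat[cr, cs])
            prev = None
        else:
            cur = "r" if cr == "-" else "s"
            total += gap_extend if prev == cur else gap_open
            prev = cur
    return total


def aligned_fraction(msa_rows: Sequence[str]) -> float:
    """Fraction of non-query residues matched to a query column (uppercase in
    A3M); lowercase letters are insertions, '-' is not a residue."""
    if len(msa_rows) < 2:
        raise ValueError("need a query and at least one other row")
    matched = residues = 0
    for row in msa_rows[1:]:
        for c in row:
            if c == "-":
                continue
            residues += 1
            if c.isupper():
                matched += 1
    if residues == 0:
        raise ValueError("MSA contains no non-query residues")
    return matched / residues


def msa_consistency(msa_rows: Sequence[str], submat=None,
                    gap_open: float = -11.0, gap_extend: float = -1.0) -> ConsistencyReport:
    """Score the induced pairwise alignment of every unordered row pair.

    Rows are read in query coordinates (lowercase insertion columns are
    dropped first); columns where both rows are gaps are skipped, and each
    maximal one-sided gap streak is charged open + (len-1) * extend.
    """
    if submat is None:
        submat = substitution_matrices.load("BLOSUM62")
    rows = [_strip_insertions(r).upper() for r in msa_rows]
    if len(rows) < 2:
        raise ValueError("need at least two rows")
    width = len(rows[0])
    for k, r in enumerate(rows):
        if len(r) != width:
            raise ValueError(f"row {k} has aligned length {len(r)}, expected {width}")
    scores = [
        _pair_score(rows[a], rows[b], submat, gap_open, gap_extend)
        for a in range(len(rows)) for b in range(a + 1, len(rows))
    ]
    q1, med, q3 = np.percentile(scores, [25, 50, 75])
    try:
        frac = aligned_fraction(msa_rows)
    except ValueError:
        frac = float("nan")
    return ConsistencyReport(scores, float(med), float(q1), float(q3), frac)
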