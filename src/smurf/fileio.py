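"""Readers and writers: FASTA, A3M, contact tables, substitution matrices,
model checkpoints.

A3M dialect: one row per sequence in query coordinates -- uppercase letters
are residues matched to a query column, '-' is a deletion (query column with
no residue), lowercase letters are insertions relative to the query.  The
first record is the query itself.
"""

from __future__ import annotations

import json
from typing import List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

from .evaluation import ContactTruth
from .lam import EncoderParams
from .mrf import ContactScores, MRFParams
from .smooth_align import AlignParams, AlignmentPath

CHECKPOINT_VERSION = 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> List[Tuple[str, str]]:
    """Ordered (id, sequence) records, sequences upper-cased.

    The first record is the query by convention.  Duplicate ids, empty files
    and non-alphabetic residue characters are rejected.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    seen = set()
    out = []
    for k, rec in enumerate(records):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        for c in seq:
            if not c.isalpha():
                raise ValueError(
                    f"{path}: record {rec.id!r} (#{k + 1}) contains illegal "
                    f"character {c!r}")
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} is empty")
        out.append((rec.id, seq.upper()))
    return out


def write_fasta(records: Sequence[Tuple[str, str]], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k: k + width] + "\n")


# ---------------------------------------------------------------------------
# A3M
# ---------------------------------------------------------------------------

def a3m_row_from_path(seq: str, path: AlignmentPath, query_len: int) -> str:
    """Render a sequence and its alignment to the query as one A3M row."""
    cmap = dict(path.matches)
    for (c, j) in path.matches:
        if not (0 <= c < query_len and 0 <= j < len(seq)):
            raise ValueError(f"match {(c, j)} outside query/sequence bounds")
    out = []
    pos = 0
    for col in range(query_len):
        if col in cmap:
            j = cmap[col]
            out.append(seq[pos:j].lower())
            out.append(seq[j].upper())
            pos = j + 1
        else:
            out.append("-")
    out.append(seq[pos:].lower())
    return "".join(out)


def path_from_a3m_row(row: str, query_len: int) -> Tuple[str, AlignmentPath]:
    """Recover (sequence, alignment path) from one A3M row."""
    col = pos = 0
    matches = []
    seq = []
    for c in row:
        if c == "-":
            col += 1
        elif c.isupper():
            matches.append((col, pos))
            seq.append(c)
            col += 1
            pos += 1
        elif c.islower():
            seq.append(c.upper())
            pos += 1
        else:
            raise ValueError(f"illegal A3M character {c!r}")
    if col != query_len:
        raise ValueError(
            f"A3M row covers {col} query columns, expected {query_len}")
    return "".join(seq), AlignmentPath(tuple(matches))


def read_a3m(path) -> List[Tuple[str, str]]:
    """(id, row) records; every row must cover the query's column count."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no A3M records found")
    rows = [(rec.id, str(rec.seq)) for rec in records]
    qlen = sum(1 for c in rows[0][1] if c == "-" or c.isupper())
    for rid, row in rows:
        path_from_a3m_row(row, qlen)  # validates width and characters
    return rows


def write_a3m(records: Sequence[Tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, row in records:
            fh.write(f">{rid}\n{row}\n")


# ---------------------------------------------------------------------------
# contact tables
# ---------------------------------------------------------------------------

def write_contact_scores(scores: ContactScores, path, min_sep: int = 1) -> None:
    """Whitespace-separated '1-based-i 1-based-j score', descending score."""
    s = scores.scores
    L = s.shape[0]
    rows = [(i + 1, j + 1, s[i, j]) for i in range(L) for j in range(i + min_sep, L)]
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    with open(path, "w") as fh:
        for i, j, v in rows:
            fh.write(f"{i} {j} {v:.8g}\n")


def read_contact_scores(path, L: int) -> ContactScores:
    s = np.zeros((L, L))
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            i, j, v = line.split()[:3]
            i, j = int(i) - 1, int(j) - 1
            s[i, j] = s[j, i] = float(v)
    return ContactScores(s)


def read_contact_table(path, L: Optional[int] = None) -> ContactTruth:
    """True contacts as '1-based-i 1-based-j' pairs (extra columns ignored)."""
    pairs = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            i, j = (int(x) for x in line.split()[:2])
            if i > j:
                i, j = j, i
            pairs.add((i, j))
    if not pairs:
        raise ValueError(f"{path}: no contact pairs found")
    if L is None:
        L = max(j for _, j in pairs)
    return ContactTruth(frozenset(pairs), L)


def write_contact_table(truth: ContactTruth, path) -> None:
    with open(path, "w") as fh:
        for i, j in sorted(truth.pairs):
            fh.write(f"{i} {j}\n")


# ---------------------------------------------------------------------------
# substitution matrices
# ---------------------------------------------------------------------------

def read_submat(path=None):
    """NCBI-format substitution matrix; BLOSUM62 when no path is given."""
    if path is None:
        return substitution_matrices.load("BLOSUM62")
    return substitution_matrices.read(str(path))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model, path) -> None:
    """npz archive: encoder kernel/bias, MRF fields/couplings, align params."""
    align = dict(temperature=model.align_params.temperature,
                 gap=model.align_params.gap,
                 open=model.align_params.open,
                 extend=model.align_params.extend,
                 gap_mode=model.align_params.gap_mode,
                 align_mode=model.align_params.align_mode,
                 restrict_turns=model.align_params.restrict_turns)
    np.savez(path, version=CHECKPOINT_VERSION,
             kernel=model.encoder.kernel, bias=model.encoder.bias,
             fields=model.mrf.fields, couplings=model.mrf.couplings,
             align_json=json.dumps(align))


def load_checkpoint(path):
    from .training import SmurfModel

    with np.load(path, allow_pickle=False) as z:
        if int(z["version"]) != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {z['version']}")
        align = json.loads(str(z["align_json"]))
        return SmurfModel(
            EncoderParams(z["kernel"], z["bias"]),
            AlignParams(**align),
            MRFParams(z["fields"], z["couplings"]),
        )
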