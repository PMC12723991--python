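"""FASTA MSA reading/writing, encoding, 3Di projection and pairwise identity.

The on-disk format is plain aligned FASTA (60-column wrapping on output).
Sequences live in memory as an :class:`Msa` (strings) or an
:class:`EncodedMsa` (integer state indices); the one-hot view used by the
VAE is produced by :func:`one_hot`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .alphabets import Alphabet

logger = logging.getLogger(__name__)


class MsaError(ValueError):
    """Raised for malformed or inconsistent alignments."""


@dataclass
class Msa:
    """N aligned sequences of common length L over one alphabet."""

    ids: list
    rows: list
    alphabet: Alphabet

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise MsaError("ids and rows must have equal count")
        if len(self.rows) < 1:
            raise MsaError("no records")
        L = len(self.rows[0])
        for rid, row in zip(self.ids, self.rows):
            if len(row) != L:
                raise MsaError(
                    f"ragged alignment: record {rid!r} has length {len(row)}, expected {L}"
                )
            for col, ch in enumerate(row):
                if ch not in self.alphabet:
                    raise MsaError(
                        f"record {rid!r}, column {col}: character {ch!r} "
                        f"not in alphabet {self.alphabet.name!r}"
                    )

    @property
    def N(self) -> int:
        return len(self.rows)

    @property
    def L(self) -> int:
        return len(self.rows[0])

    def __eq__(self, other):
        return (
            isinstance(other, Msa)
            and self.ids == other.ids
            and self.rows == other.rows
            and self.alphabet.name == other.alphabet.name
        )


@dataclass
class SequenceSet:
    """Unaligned sequences over one alphabet (no common-length constraint)."""

    ids: list
    rows: list
    alphabet: Alphabet

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise MsaError("ids and rows must have equal count")
        if not self.rows:
            raise MsaError("no records")
        for rid, row in zip(self.ids, self.rows):
            for col, ch in enumerate(row):
                if ch not in self.alphabet:
                    raise MsaError(
                        f"record {rid!r}, column {col}: character {ch!r} "
                        f"not in alphabet {self.alphabet.name!r}"
                    )

    @property
    def N(self) -> int:
        return len(self.rows)


@dataclass
class EncodedMsa:
    """Integer-encoded alignment: states[n, i] is the alphabet index."""

    states: np.ndarray  # (N, L) ints in [0, q)
    alphabet: Alphabet
    ids: list = None

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 2:
            raise MsaError("states must be a 2-D array")
        if self.states.min() < 0 or self.states.max() >= self.alphabet.q:
            raise MsaError("state index out of alphabet range")
        if self.ids is None:
            self.ids = [f"seq_{n}" for n in range(self.states.shape[0])]

    @property
    def N(self) -> int:
        return self.states.shape[0]

    @property
    def L(self) -> int:
        return self.states.shape[1]

    @property
    def q(self) -> int:
        return self.alphabet.q


def read_fasta(path, alphabet: Alphabet, aligned: bool = True):
    """Read a FASTA file into an :class:`Msa` (or, if ``aligned`` is False,
    a :class:`SequenceSet` with no common-length requirement).

    Identifiers are the full header lines minus the leading ``>``.  Input is
    case-folded to the alphabet's case; the unknown-residue character ``X``
    is remapped to the gap, with a logged warning count.
    """
    ids, rows = [], []
    cur_id, cur = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if cur_id is not None:
                    ids.append(cur_id)
                    rows.append("".join(cur))
                cur_id, cur = line[1:], []
            else:
                if cur_id is None:
                    raise MsaError(f"{path}: sequence data before first header")
                cur.append(line.strip())
    if cur_id is not None:
        ids.append(cur_id)
        rows.append("".join(cur))
    if not ids:
        raise MsaError(f"{path}: no records")

    n_unknown = 0
    folded = []
    unknown = "X" if alphabet.case == "upper" else "x"
    for row in rows:
        row = alphabet.fold_case(row)
        if unknown in row:
            n_unknown += row.count(unknown)
            row = row.replace(unknown, alphabet.gap_symbol)
        folded.append(row)
    if n_unknown:
        logger.warning("%s: mapped %d unknown '%s' characters to gap", path, n_unknown, unknown)
    cls = Msa if aligned else SequenceSet
    return cls(ids=ids, rows=folded, alphabet=alphabet)


def write_fasta(msa: Msa, path, width: int = 60):
    """Write an :class:`Msa` as FASTA with 60-column line wrapping."""
    with open(path, "w") as fh:
        for rid, row in zip(msa.ids, msa.rows):
            fh.write(f">{rid}\n")
            for start in range(0, len(row), width):
                fh.write(row[start : start + width] + "\n")
    return path


def project_onto_alignment(aa_msa: Msa, unaligned) -> Msa:
    """Project unaligned (e.g. 3Di) sequences onto an existing alignment.

    Each output row places the unaligned symbols at the corresponding AA
    row's non-gap columns and the gap symbol at its gap columns, so the
    projected MSA shares the AA alignment's exact gap mask.
    """
    if aa_msa.N != unaligned.N:
        raise MsaError(
            f"record count mismatch: alignment has {aa_msa.N}, unaligned has {unaligned.N}"
        )
    gap_in = aa_msa.alphabet.gap_symbol
    gap_out = unaligned.alphabet.gap_symbol
    out_rows = []
    for rid, aa_row, u_row in zip(aa_msa.ids, aa_msa.rows, unaligned.rows):
        u_row = u_row.replace(gap_out, "")
        n_res = sum(1 for c in aa_row if c != gap_in)
        if n_res != len(u_row):
            raise MsaError(
                f"projection error for record {rid!r}: alignment row has {n_res} "
                f"non-gap columns but unaligned sequence has {len(u_row)} symbols"
            )
        it = iter(u_row)
        out_rows.append("".join(gap_out if c == gap_in else next(it) for c in aa_row))
    return Msa(ids=list(aa_msa.ids), rows=out_rows, alphabet=unaligned.alphabet)


def encode(msa: Msa) -> EncodedMsa:
    """Index-encode an :class:`Msa`; decoding inverts exactly."""
    idx = msa.alphabet.index
    states = np.array([[idx(c) for c in row] for row in msa.rows], dtype=np.int64)
    return EncodedMsa(states=states, alphabet=msa.alphabet, ids=list(msa.ids))


def decode(encoded: EncodedMsa) -> Msa:
    symbols = encoded.alphabet.symbols
    rows = ["".join(symbols[s] for s in row) for row in encoded.states]
    return Msa(ids=list(encoded.ids), rows=rows, alphabet=encoded.alphabet)


def one_hot(encoded: EncodedMsa) -> np.ndarray:
    """One-hot view of shape (N, q, L): exactly one 1 per (sequence, column)."""
    N, L = encoded.states.shape
    q = encoded.alphabet.q
    out = np.zeros((N, q, L), dtype=np.float64)
    out[np.arange(N)[:, None], encoded.states, np.arange(L)[None, :]] = 1.0
    return out


# ---------------------------------------------------------------------------
# Needleman–Wunsch percent identity
# ---------------------------------------------------------------------------

def pairwise_identity(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
    gap_symbol: str = "-",
) -> float:
    """Global-alignment percent identity between two unaligned sequences.

    Gaps are stripped first, then a Needleman–Wunsch global alignment with
    linear gap penalty is computed.  Identity is 100 × matches / alignment
    length, the alignment length including gap columns.  Among co-optimal
    alignments the one with (max score, then max matches, then min length)
    is used — a symmetric tie-break, so the result is symmetric in its
    arguments.
    """
    a = seq_a.replace(gap_symbol, "")
    b = seq_b.replace(gap_symbol, "")
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    la, lb = len(a), len(b)

    # DP over (score, matches, -length) compared lexicographically; valid
    # because every transition adds a constant tuple and lexicographic order
    # is preserved under tuple addition.
    prev = [None] * (lb + 1)
    prev[0] = (0.0, 0, 0)
    for j in range(1, lb + 1):
        prev[j] = (gap * j, 0, -j)
    for i in range(1, la + 1):
        cur = [None] * (lb + 1)
        cur[0] = (gap * i, 0, -i)
        ai = a[i - 1]
        for j in range(1, lb + 1):
            m = match if ai == b[j - 1] else mismatch
            sd, md, ld = prev[j - 1]
            diag = (sd + m, md + (ai == b[j - 1]), ld - 1)
            su, mu, lu = prev[j]
            up = (su + gap, mu, lu - 1)
            sl, ml, ll = cur[j - 1]
            left = (sl + gap, ml, ll - 1)
            best = diag
            if up > best:
                best = up
            if left > best:
                best = left
            cur[j] = best
        prev = cur
    score, matches, neg_len = prev[lb]
    return 100.0 * matches / (-neg_len)
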