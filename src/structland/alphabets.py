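"""Residue alphabets for amino-acid and 3Di structural sequences.

Both built-in alphabets carry 20 residue-like states plus one gap state
(q = 21); the gap symbol ``-`` always sits at the last index, which keeps
the gap the excluded reference state in mean-field Potts inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Alphabet:
    """An ordered set of single-character sequence states.

    Parameters
    ----------
    name
        Short label ("aa", "tdi", ...).
    symbols
        Ordered unique single-character states, gap included.
    gap_symbol
        The gap character; must be a member of ``symbols``.
    case
        "upper" or "lower"; input is case-folded to this before validation.
    """

    name: str
    symbols: str
    gap_symbol: str = "-"
    case: str = "upper"
    _index: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        if self.gap_symbol not in self.symbols:
            raise ValueError("gap symbol must be a member of the alphabet")
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(self.symbols)})

    @property
    def q(self) -> int:
        """Number of states including the gap."""
        return len(self.symbols)

    @property
    def gap_index(self) -> int:
        return self._index[self.gap_symbol]

    def index(self, symbol: str) -> int:
        return self._index[symbol]

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    def fold_case(self, text: str) -> str:
        return text.upper() if self.case == "upper" else text.lower()


_AA_STATES = "ACDEFGHIKLMNPQRSTVWY"

#: 20 amino acids + gap at the last index (q = 21).
AA = Alphabet(name="aa", symbols=_AA_STATES + "-", case="upper")

#: Foldseek-style 3Di structural alphabet, lowercase, + gap at the last
#: index (q = 21).  Each state encodes the local geometric relationship of
#: a residue to its nearest spatial neighbour.
TDI = Alphabet(name="tdi", symbols=_AA_STATES.lower() + "-", case="lower")

BUILTIN = {"aa": AA, "tdi": TDI}


def get_alphabet(name: str) -> Alphabet:
    try:
        return BUILTIN[name]
    except KeyError:
        raise KeyError(f"unknown alphabet {name!r}; choose from {sorted(BUILTIN)}")


def reduced_alphabet(q: int) -> Alphabet:
    """A q-state alphabet (q-1 residue states + gap) for small fixtures."""
    if not 2 <= q <= 21:
        raise ValueError("q must be in [2, 21]")
    return Alphabet(name=f"reduced{q}", symbols=_AA_STATES[: q - 1] + "-", case="upper")
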