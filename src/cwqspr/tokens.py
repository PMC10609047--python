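"""SMILES tokenization and attribute extraction.

The correlation-weight method treats a SMILES string as a plain sequence of
tokens; every model parameter is attached either to a single token (``Sk``)
or to an adjacent, orientation-free token pair (``SSk``).  Tokenization is
therefore deliberately simple and fully deterministic — no aromaticity
perception, no canonicalization, no chemistry.  The dialect implemented here:

* the two-character element symbols ``Cl`` and ``Br`` are single tokens;
* a bracket atom ``[...]`` from ``[`` through the matching ``]`` is a single
  token;
* ``%NN`` two-digit ring closures are single tokens;
* every other character (organic-subset atoms, aromatic lowercase letters,
  ring digits, bond symbols ``=``, ``#``, ``/``, ``\\``, branch parentheses)
  is its own token.

Hydrogens, stereochemistry markers and isotopes are kept verbatim: the
method models the string as given, and canonicalization is the data
provider's responsibility.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Tuple

__all__ = [
    "SmilesParseError",
    "TokenSequence",
    "AttributeKey",
    "tokenize",
    "extract_attributes",
    "attribute_counts",
]

#: Width of the dot-padded display field used in model files (display only;
#: the rendered form is never parsed back).
RENDER_WIDTH = 12
_PAIR_FIELD = 4


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be tokenized.

    Carries the 0-based ``position`` of the offending character.
    """

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


@dataclass(frozen=True)
class TokenSequence:
    """An ordered sequence of SMILES tokens together with its source string.

    Invariant: ``"".join(tokens) == source`` and every token is non-empty.
    """

    tokens: Tuple[str, ...]
    source: str

    def __post_init__(self) -> None:
        if "".join(self.tokens) != self.source:
            raise ValueError("tokens do not concatenate to the source string")
        if any(not t for t in self.tokens):
            raise ValueError("empty token")

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[str]:
        return iter(self.tokens)


@dataclass(frozen=True, order=True)
class AttributeKey:
    """A single-token (``Sk``) or adjacent-pair (``SSk``) SMILES attribute.

    Pair symbols are stored in canonical order so that ``(a, b)`` and
    ``(b, a)`` compare and hash equal: the member whose first character has
    the larger ASCII value precedes, ties broken by full-string comparison.
    Equality and hashing use the kind and canonical symbols only; the
    dot-padded :meth:`rendered` form is for display.
    """

    kind: str  # "single" | "pair"
    symbols: Tuple[str, ...]

    @staticmethod
    def single(token: str) -> "AttributeKey":
        return AttributeKey("single", (token,))

    @staticmethod
    def pair(a: str, b: str) -> "AttributeKey":
        first, second = sorted((a, b), key=lambda t: (t[0], t), reverse=True)
        return AttributeKey("pair", (first, second))

    def rendered(self) -> str:
        """Dot-padded fixed-width display form, e.g. ``N...C.......``."""
        if self.kind == "single":
            return self.symbols[0].ljust(RENDER_WIDTH, ".")
        a, b = self.symbols
        return (a.ljust(_PAIR_FIELD, ".") + b).ljust(RENDER_WIDTH, ".")


def tokenize(smiles: str) -> TokenSequence:
    """Split a SMILES string into tokens under the package dialect.

    Raises :class:`SmilesParseError` for an empty string, whitespace,
    non-ASCII characters, or an unterminated bracket atom.
    """
    if not smiles:
        raise SmilesParseError("empty SMILES string", 0)
    tokens: List[str] = []
    i = 0
    n = len(smiles)
    while i < n:
        c = smiles[i]
        if c.isspace():
            raise SmilesParseError("whitespace in SMILES", i)
        if not c.isascii():
            raise SmilesParseError(f"non-ASCII character {c!r}", i)
        if c == "[":
            j = smiles.find("]", i)
            if j < 0:
                raise SmilesParseError("unterminated bracket atom", i)
            tokens.append(smiles[i : j + 1])
            i = j + 1
        elif c == "%":
            if len(smiles[i + 1 : i + 3]) < 2 or not smiles[i + 1 : i + 3].isdigit():
                raise SmilesParseError("'%' ring closure needs two digits", i)
            tokens.append(smiles[i : i + 3])
            i += 3
        elif c == "C" and i + 1 < n and smiles[i + 1] == "l":
            tokens.append("Cl")
            i += 2
        elif c == "B" and i + 1 < n and smiles[i + 1] == "r":
            tokens.append("Br")
            i += 2
        else:
            tokens.append(c)
            i += 1
    return TokenSequence(tuple(tokens), smiles)


def extract_attributes(seq: TokenSequence) -> List[AttributeKey]:
    """All attributes of a token sequence, duplicates retained.

    For an *m*-token sequence the result holds *m* single-token attributes
    (one per token occurrence) followed by *m − 1* adjacent-pair attributes
    in canonical orientation-free order.
    """
    singles = [AttributeKey.single(t) for t in seq.tokens]
    pairs = [AttributeKey.pair(a, b) for a, b in zip(seq.tokens, seq.tokens[1:])]
    return singles + pairs


def attribute_counts(seq: TokenSequence) -> Counter:
    """Multiset of attributes as a :class:`collections.Counter`."""
    return Counter(extract_attributes(seq))
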