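"""Substitution matrices for protein alignment scoring.

The scoring model is a similarity matrix to be maximised: a symmetric,
dense, integer-valued map over an ordered residue alphabet.  Built-in
BLOSUM and PAM tables are the NCBI distributions as shipped with
Biopython; a basic IDENTITY matrix (+1 for identical symbols, 0
otherwise) is provided for scoring-free comparisons.  User-supplied
matrices are parsed from NCBI matrix text format.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio.Align import substitution_matrices as _biopython_matrices

__all__ = [
    "SubstitutionMatrix",
    "BUILTIN_MATRICES",
    "CANONICAL_AA",
    "load_builtin_matrix",
    "parse_matrix_file",
]

BUILTIN_MATRICES: tuple[str, ...] = (
    "BLOSUM45",
    "BLOSUM50",
    "BLOSUM62",
    "BLOSUM80",
    "BLOSUM90",
    "PAM30",
    "PAM70",
    "PAM250",
    "IDENTITY",
)

#: The 20 canonical amino acids in the conventional NCBI ordering.
CANONICAL_AA = "ARNDCQEGHILKMFPSTWYV"


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A dense, symmetric, integer substitution-score matrix.

    Parameters
    ----------
    name
        Short identifier (e.g. ``"BLOSUM62"``).
    alphabet
        Ordered residue symbols covered by the matrix.
    scores
        Mapping ``(x, y) -> int`` defined for every ordered symbol pair.
    """

    name: str
    alphabet: tuple[str, ...]
    scores: Mapping[tuple[str, str], int] = field(repr=False)

    def __post_init__(self) -> None:
        symbols = self.alphabet
        if len(set(symbols)) != len(symbols):
            raise ValueError("matrix alphabet contains duplicate symbols")
        for x in symbols:
            for y in symbols:
                if (x, y) not in self.scores:
                    raise ValueError(f"matrix is missing a score for ({x}, {y})")
                v = self.scores[x, y]
                if not isinstance(v, int) or isinstance(v, bool):
                    raise ValueError(f"score for ({x}, {y}) is not an integer: {v!r}")
                if self.scores[x, y] != self.scores[y, x]:
                    raise ValueError(
                        f"matrix is not symmetric: score({x},{y})={self.scores[x, y]} "
                        f"but score({y},{x})={self.scores[y, x]}"
                    )

    def score(self, x: str, y: str) -> int:
        try:
            return self.scores[x, y]
        except KeyError:
            missing = x if x not in self.alphabet else y
            raise ValueError(
                f"symbol {missing!r} is not in the alphabet of matrix {self.name}"
            ) from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.alphabet

    def to_ncbi_text(self) -> str:
        """Serialise to NCBI matrix text format (round-trips through
        :func:`parse_matrix_file`)."""
        lines = ["# " + self.name]
        lines.append("   " + "  ".join(f"{s:>2}" for s in self.alphabet))
        for x in self.alphabet:
            row = " ".join(f"{self.scores[x, y]:>3d}" for y in self.alphabet)
            lines.append(f"{x} {row}")
        return "\n".join(lines) + "\n"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SubstitutionMatrix):
            return NotImplemented
        return self.alphabet == other.alphabet and all(
            self.scores[x, y] == other.scores[x, y]
            for x in self.alphabet
            for y in self.alphabet
        )


def _from_biopython(name: str) -> SubstitutionMatrix:
    arr = _biopython_matrices.load(name)
    alphabet = tuple(arr.alphabet)
    scores: dict[tuple[str, str], int] = {}
    for x in alphabet:
        for y in alphabet:
            v = float(arr[x, y])
            if v != int(v):
                raise ValueError(f"matrix {name} contains non-integer score {v}")
            scores[x, y] = int(v)
    return SubstitutionMatrix(name=name, alphabet=alphabet, scores=scores)


def _identity_matrix() -> SubstitutionMatrix:
    # +1 match / 0 mismatch over the canonical residues plus X, so that
    # structure-derived sequences containing unknown residues still score.
    alphabet = tuple(CANONICAL_AA + "X")
    scores = {
        (x, y): (1 if x == y else 0) for x in alphabet for y in alphabet
    }
    return SubstitutionMatrix(name="IDENTITY", alphabet=alphabet, scores=scores)


def load_builtin_matrix(name: str) -> SubstitutionMatrix:
    """Load one of the built-in matrices.

    Supported names: BLOSUM45, BLOSUM50, BLOSUM62, BLOSUM80, BLOSUM90,
    PAM30, PAM70, PAM250 and IDENTITY.
    """
    key = name.upper()
    if key not in BUILTIN_MATRICES:
        raise ValueError(
            f"unknown matrix {name!r}; supported matrices are: "
            + ", ".join(BUILTIN_MATRICES)
        )
    if key == "IDENTITY":
        return _identity_matrix()
    return _from_biopython(key)


def parse_matrix_file(text: str, name: str = "custom") -> SubstitutionMatrix:
    """Parse a substitution matrix in NCBI matrix text format.

    The format is a header row of symbols followed by one row per symbol;
    lines starting with ``#`` are comments.  The parsed matrix must be
    dense, symmetric and integer-valued.
    """
    try:
        arr = _biopython_matrices.read(io.StringIO(text))
    except Exception as exc:  # Biopython raises bare Exceptions on bad input
        raise ValueError(f"malformed matrix file: {exc}") from exc
    alphabet = tuple(arr.alphabet)
    if not alphabet:
        raise ValueError("matrix file declares an empty alphabet")
    scores: dict[tuple[str, str], int] = {}
    for x in alphabet:
        for y in alphabet:
            v = float(arr[x, y])
            if v != int(v):
                raise ValueError(f"non-integer score {v} for ({x}, {y})")
            scores[x, y] = int(v)
    # SubstitutionMatrix.__post_init__ enforces symmetry and density.
    return SubstitutionMatrix(name=name, alphabet=alphabet, scores=scores)
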