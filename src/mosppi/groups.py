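"""Seven-group reduced amino-acid alphabet.

The 20 standard residues are collapsed into seven classes by side-chain
dipole and volume, the same reduction used by the conjoint-triad family of
protein descriptors:

====== ============
group  residues
====== ============
1      A, G, V
2      I, L, F, P
3      Y, M, T, S
4      H, N, Q, W
5      R, K
6      D, E
7      C
====== ============

A protein sequence over the 20-letter alphabet becomes a *group sequence*:
an integer vector with values in 1..7, one per residue.  For example
``AGCRQTSPLGVKSE`` maps to ``11754332211536``.

Ambiguous or non-standard residue codes (B, J, O, U, X, Z, and anything
else outside the 20 standard letters, including ``*`` and ``-``) are not
mapped; sequences containing them are rejected by :func:`validate_protein`
and raise :class:`InvalidResidueError` in :func:`map_to_groups`.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

import numpy as np

__all__ = [
    "GROUP_MEMBERS",
    "STANDARD_RESIDUES",
    "AMBIGUOUS_RESIDUES",
    "N_GROUPS",
    "GroupAlphabet",
    "InvalidResidueError",
    "ValidationResult",
    "build_group_alphabet",
    "map_to_groups",
    "groups_to_string",
    "validate_protein",
    "compute_group_counts_key",
]

#: Group index -> member residues (dipole / side-chain-volume classes).
GROUP_MEMBERS: Mapping[int, tuple[str, ...]] = MappingProxyType(
    {
        1: ("A", "G", "V"),
        2: ("I", "L", "F", "P"),
        3: ("Y", "M", "T", "S"),
        4: ("H", "N", "Q", "W"),
        5: ("R", "K"),
        6: ("D", "E"),
        7: ("C",),
    }
)

STANDARD_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity / non-standard codes that appear in public sequence databases
#: and are excluded from the descriptor space.
AMBIGUOUS_RESIDUES: frozenset[str] = frozenset("BJOUXZ")

N_GROUPS: int = 7


class InvalidResidueError(ValueError):
    """A residue outside the 20-letter standard alphabet was encountered.

    Attributes
    ----------
    residue : str
        The offending character (upper-cased).
    position : int
        0-based position in the input sequence.
    """

    def __init__(self, residue: str, position: int):
        self.residue = residue
        self.position = position
        super().__init__(
            f"invalid residue {residue!r} at position {position} "
            f"(not one of the 20 standard amino acids)"
        )


@dataclass(frozen=True)
class GroupAlphabet:
    """Immutable mapping from single-letter residue codes to group indices 1..7."""

    residue_to_group: Mapping[str, int]
    n_groups: int = N_GROUPS

    def __post_init__(self):
        groups = set(self.residue_to_group.values())
        if len(self.residue_to_group) != 20:
            raise ValueError("exactly 20 residues must be mapped")
        if groups != set(range(1, self.n_groups + 1)):
            raise ValueError("every group index in 1..n_groups must be used")

    def __getitem__(self, residue: str) -> int:
        return self.residue_to_group[residue]

    def __contains__(self, residue: str) -> bool:
        return residue in self.residue_to_group


def build_group_alphabet() -> GroupAlphabet:
    """Return the fixed seven-class reduction of the 20 standard residues."""
    mapping = {
        res: grp for grp, members in GROUP_MEMBERS.items() for res in members
    }
    return GroupAlphabet(residue_to_group=MappingProxyType(mapping))


# Module-level singleton; the mapping is fixed, so callers may omit it.
_DEFAULT_ALPHABET = build_group_alphabet()


def map_to_groups(seq: str, alphabet: GroupAlphabet | None = None) -> np.ndarray:
    """Map a protein sequence to its group sequence.

    Parameters
    ----------
    seq : str
        Non-empty protein sequence; case-insensitive.
    alphabet : GroupAlphabet, optional
        Defaults to the fixed seven-class alphabet.

    Returns
    -------
    numpy.ndarray of int8
        Group indices in 1..7, same length as ``seq``.

    Raises
    ------
    ValueError
        If ``seq`` is empty.
    InvalidResidueError
        At the first character outside the 20 standard residues
        (B/J/O/U/X/Z, gaps, stops, digits, ...).
    """
    if alphabet is None:
        alphabet = _DEFAULT_ALPHABET
    if not seq:
        raise ValueError("empty sequence cannot be encoded")
    seq = seq.upper()
    out = np.empty(len(seq), dtype=np.int8)
    lut = alphabet.residue_to_group
    for i, ch in enumerate(seq):
        try:
            out[i] = lut[ch]
        except KeyError:
            raise InvalidResidueError(ch, i) from None
    return out


def groups_to_string(gseq: np.ndarray) -> str:
    """Concatenate group indices into the one-digit-per-residue string form."""
    return "".join(str(int(g)) for g in gseq)


@dataclass(frozen=True)
class ValidationResult:
    """Accept/reject verdict for a protein sequence, carrying the first failing rule."""

    accepted: bool
    reason: str | None = None  # None | "empty" | "unusual_residue" | "too_short"
    detail: str | None = None

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.accepted


def validate_protein(seq: str, min_length: int = 50) -> ValidationResult:
    """Check a sequence against the dataset inclusion rules.

    A sequence is rejected if it contains any residue outside the 20
    standard letters (the database ambiguity codes B, J, O, U, X, Z in
    particular) or if it is shorter than ``min_length`` residues.
    Residue checks run first, in sequence order, so the verdict names the
    first offending character.
    """
    if not seq:
        return ValidationResult(False, "empty", "zero-length sequence")
    up = seq.upper()
    for i, ch in enumerate(up):
        if ch not in _DEFAULT_ALPHABET:
            return ValidationResult(
                False, "unusual_residue", f"residue {ch!r} at position {i}"
            )
    if len(up) < min_length:
        return ValidationResult(
            False, "too_short", f"length {len(up)} < {min_length}"
        )
    return ValidationResult(True)


def compute_group_counts_key(seq: str) -> tuple[int, tuple[int, ...]]:
    """(length, per-group counts) — proteins sharing this key have identical
    composition-level descriptors (used by the optional collision filter)."""
    g = map_to_groups(seq)
    counts = np.bincount(g - 1, minlength=N_GROUPS)
    return len(g), tuple(int(c) for c in counts)
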