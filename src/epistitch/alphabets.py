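"""Amino-acid alphabets and reduced-alphabet schemes for composition features.

Three encodings of a peptide are used throughout the package:

* the 20 standard amino-acid letters,
* the 11-group DIAMOND reduced alphabet (the clustering used by the DIAMOND
  aligner for seed matching, repurposed here as a composition alphabet), and
* a 4-class side-chain partition (positively charged, negatively charged,
  polar uncharged, nonpolar).

The DIAMOND partition is fixed; the side-chain partition is the standard
textbook one with aromatics collapsed into the nonpolar class so that exactly
four classes result.  Both are configurable through :class:`AlphabetScheme`
because the assignment of C and Y between polar and nonpolar varies between
textbooks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The 20 standard amino-acid letters, alphabetical.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: DIAMOND 11-group reduced alphabet.  Each group is labelled by its members.
DIAMOND_PARTITION: tuple[str, ...] = (
    "KREDQN", "C", "G", "H", "ILV", "M", "F", "Y", "W", "P", "STA",
)

#: Four side-chain classes.  Aromatics count as nonpolar.
SIDECHAIN_PARTITION: dict[str, str] = {
    "positive": "KRH",
    "negative": "DE",
    "polar": "STNQCY",
    "nonpolar": "GAVLIPFMW",
}


def _expand(partition: dict[str, str]) -> dict[str, str]:
    """Invert a {label: members} partition to a {letter: label} map."""
    out: dict[str, str] = {}
    for label, members in partition.items():
        for letter in members:
            if letter in out:
                raise ValueError(f"letter {letter} assigned to two classes")
            out[letter] = label
    return out


@dataclass(frozen=True, eq=False)  # identity hash: instances may be cache keys
class AlphabetScheme:
    """A pair of reduced alphabets layered over the natural one.

    Attributes
    ----------
    natural:
        The 20 standard letters, in the fixed feature order.
    diamond_groups:
        Map letter -> DIAMOND group label (labels are the member strings,
        e.g. ``"STA"``).
    sidechain_classes:
        Map letter -> one of four side-chain class labels.
    """

    natural: str = AMINO_ACIDS
    diamond_groups: dict[str, str] = field(
        default_factory=lambda: _expand({g: g for g in DIAMOND_PARTITION})
    )
    sidechain_classes: dict[str, str] = field(
        default_factory=lambda: _expand(SIDECHAIN_PARTITION)
    )

    def __post_init__(self) -> None:
        letters = set(self.natural)
        if len(self.natural) != 20 or letters != set(AMINO_ACIDS):
            raise ValueError("natural alphabet must be the 20 standard letters")
        for name, mapping in (
            ("diamond_groups", self.diamond_groups),
            ("sidechain_classes", self.sidechain_classes),
        ):
            if set(mapping) != letters:
                raise ValueError(f"{name} must cover exactly the 20 letters")

    @property
    def diamond_labels(self) -> list[str]:
        return sorted(set(self.diamond_groups.values()))

    @property
    def sidechain_labels(self) -> list[str]:
        return sorted(set(self.sidechain_classes.values()))


DEFAULT_SCHEME = AlphabetScheme()


def validate_peptide(seq: str) -> None:
    """Reject sequences containing non-standard letters (B, J, O, U, X, Z, ...).

    Raises ``ValueError`` naming the first offending position.
    """
    if not isinstance(seq, str):
        raise TypeError("peptide must be a string")
    for i, ch in enumerate(seq):
        if ch not in AMINO_ACIDS:
            raise ValueError(
                f"non-standard amino-acid letter {ch!r} at position {i} in {seq!r}"
            )
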