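"""556-dimensional composition features for peptide sequences.

The feature vector for a peptide is a set of raw counts (not normalized
fractions) over five blocks, in a fixed, alphabetical-within-block order:

====================================  =====
block                                 size
====================================  =====
single amino acids                    20
ordered adjacent amino-acid pairs     400
DIAMOND reduced-alphabet groups       11
ordered adjacent DIAMOND-group pairs  121
side-chain classes                    4
====================================  =====

20 + 400 + 11 + 121 + 4 = 556.  Single-letter blocks each sum to the peptide
length; pair blocks each sum to length - 1.  The fixed ordering makes
serialized models stable across retraining.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .alphabets import AMINO_ACIDS, DEFAULT_SCHEME, AlphabetScheme, validate_peptide

N_FEATURES = 556


@lru_cache(maxsize=8)
def _layout(scheme: AlphabetScheme) -> tuple[tuple[str, ...], dict[str, int]]:
    aa = list(scheme.natural)
    dia = scheme.diamond_labels
    sc = scheme.sidechain_labels
    names: list[str] = []
    names += aa
    names += [a + b for a in aa for b in aa]
    names += [f"d_{g}" for g in dia]
    names += [f"d_{g1}-{g2}" for g1 in dia for g2 in dia]
    names += [f"sc_{c}" for c in sc]
    assert len(names) == N_FEATURES
    return tuple(names), {n: i for i, n in enumerate(names)}


def feature_names(scheme: AlphabetScheme = DEFAULT_SCHEME) -> list[str]:
    """The 556 feature names in their fixed order."""
    return list(_layout(scheme)[0])


@dataclass
class FeatureVector:
    """Named composition counts for one peptide."""

    values: dict[str, int]
    peptide_length: int

    def __len__(self) -> int:
        return len(self.values)

    def to_array(self) -> np.ndarray:
        return np.fromiter(self.values.values(), dtype=np.int64, count=len(self.values))

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, dtype=np.int64)

    def __getitem__(self, name: str) -> int:
        return self.values[name]


def _count_into(seq: str, scheme: AlphabetScheme, out: np.ndarray, index: dict[str, int]) -> None:
    dmap = scheme.diamond_groups
    smap = scheme.sidechain_classes
    prev_aa = None
    prev_d = None
    for ch in seq:
        out[index[ch]] += 1
        d = dmap[ch]
        out[index[f"d_{d}"]] += 1
        out[index[f"sc_{smap[ch]}"]] += 1
        if prev_aa is not None:
            out[index[prev_aa + ch]] += 1
            out[index[f"d_{prev_d}-{d}"]] += 1
        prev_aa, prev_d = ch, d


def featurize_peptide(seq: str, scheme: AlphabetScheme = DEFAULT_SCHEME) -> FeatureVector:
    """Compute the 556 composition counts for one peptide.

    Parameters
    ----------
    seq:
        Amino-acid sequence of length >= 2 over the 20 standard letters.
    scheme:
        Alphabet scheme; the default uses the published DIAMOND 11-group
        partition and the 4-class side-chain partition.

    Raises
    ------
    ValueError
        If the sequence is shorter than 2 residues or contains a
        non-standard letter (the position is reported).
    """
    validate_peptide(seq)
    if len(seq) < 2:
        raise ValueError(f"peptide must be at least 2 residues long, got {len(seq)}")
    names, index = _layout(scheme)
    arr = np.zeros(N_FEATURES, dtype=np.int64)
    _count_into(seq, scheme, arr, index)
    return FeatureVector(values=dict(zip(names, arr.tolist())), peptide_length=len(seq))


def featurize_many(seqs, scheme: AlphabetScheme = DEFAULT_SCHEME) -> pd.DataFrame:
    """Featurize a collection of peptides into a (n_peptides x 556) frame."""
    seqs = list(seqs)
    names, index = _layout(scheme)
    mat = np.zeros((len(seqs), N_FEATURES), dtype=np.int64)
    for row, seq in enumerate(seqs):
        validate_peptide(seq)
        if len(seq) < 2:
            raise ValueError(f"peptide must be at least 2 residues long, got {len(seq)}")
        _count_into(seq, scheme, mat[row], index)
    return pd.DataFrame(mat, columns=list(names))


def reduce_sequence(seq: str, scheme: AlphabetScheme = DEFAULT_SCHEME) -> list[str]:
    """Map each residue to its DIAMOND group label.

    Returns a list of group labels (labels are multi-character, e.g. ``"STA"``,
    so a joined string would be ambiguous).
    """
    validate_peptide(seq)
    return [scheme.diamond_groups[ch] for ch in seq]
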