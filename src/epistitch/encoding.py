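"""Reverse translation and synthesis-ready oligo assembly.

Peptides are reverse translated by sampling codons from an E. coli codon
usage table restricted to codons with relative frequency >= 0.1 (weights
renormalized over the surviving codons).  EcoRI (GAATTC) and HindIII (AAGCTT)
sites — the cloning sites of the display vector — are recoded out of the
insert with synonymous substitutions.  Inserts are brought to a common length
(168 nt for the main library dialect) and flanked by 16-nt PCR adapters to
yield 200-nt oligos.

Padding note: the coding region is padded 3' (three stop codons, then seeded
pseudo-random filler that avoids the forbidden sites and long homopolymers)
so that the open reading frame, and hence the displayed peptide, is intact.
A ``pad_end`` dialect flag exists for the 5' variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

FORBIDDEN_SITES = ("GAATTC", "AAGCTT")  # EcoRI, HindIII
MAIN_PREFIX = "AGGAATTCCGCTGCGT"
MAIN_SUFFIX = "ATGGTCACAGCTGTGC"
ENTERO_PREFIX = "AGGAATTCCGCTGCGT"
ENTERO_SUFFIX = "GTCGTGACTGGGAAAC"
ENTERO_LINKER_DNA = (
    "GCAAGTCCTGCAGCTCCAGCCCCTGCAAGCCCAGCAGCTCCAGCACCAAGTGCACCTG"
    "CTGGCGGAGGAGGTTCTGGCGGGGGCGGGAGC"
)
MAIN_INSERT_NT = 168
ENTERO_INSERT_NT = 120

# Standard E. coli K-12 codon usage, per-amino-acid relative fractions
# (each amino acid's fractions sum to 1).  '*' holds the stop codons.
ECOLI_CODON_USAGE: dict[str, dict[str, float]] = {
    "A": {"GCG": 0.36, "GCC": 0.27, "GCA": 0.21, "GCT": 0.16},
    "R": {"CGC": 0.40, "CGT": 0.38, "CGG": 0.10, "CGA": 0.06, "AGA": 0.04, "AGG": 0.02},
    "N": {"AAC": 0.55, "AAT": 0.45},
    "D": {"GAT": 0.63, "GAC": 0.37},
    "C": {"TGC": 0.55, "TGT": 0.45},
    "Q": {"CAG": 0.65, "CAA": 0.35},
    "E": {"GAA": 0.68, "GAG": 0.32},
    "G": {"GGC": 0.40, "GGT": 0.34, "GGG": 0.15, "GGA": 0.11},
    "H": {"CAT": 0.57, "CAC": 0.43},
    "I": {"ATT": 0.51, "ATC": 0.42, "ATA": 0.07},
    "L": {"CTG": 0.50, "TTA": 0.13, "TTG": 0.13, "CTT": 0.10, "CTC": 0.10, "CTA": 0.04},
    "K": {"AAA": 0.76, "AAG": 0.24},
    "M": {"ATG": 1.00},
    "F": {"TTT": 0.57, "TTC": 0.43},
    "P": {"CCG": 0.52, "CCA": 0.19, "CCT": 0.16, "CCC": 0.13},
    "S": {"AGC": 0.28, "TCT": 0.15, "TCC": 0.15, "TCG": 0.15, "AGT": 0.15, "TCA": 0.12},
    "T": {"ACC": 0.44, "ACG": 0.26, "ACT": 0.17, "ACA": 0.13},
    "W": {"TGG": 1.00},
    "Y": {"TAT": 0.57, "TAC": 0.43},
    "V": {"GTG": 0.37, "GTT": 0.28, "GTC": 0.20, "GTA": 0.15},
    "*": {"TAA": 0.64, "TGA": 0.29, "TAG": 0.07},
}


@dataclass
class CodonUsageTable:
    """Per-amino-acid codon fractions plus stop codons."""

    entries: dict[str, list[tuple[str, float]]]
    stop_codons: list[tuple[str, float]]

    def __post_init__(self) -> None:
        for aa, codons in self.entries.items():
            total = sum(f for _, f in codons)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"codon fractions for {aa} sum to {total}, not 1")

    @classmethod
    def ecoli(cls) -> "CodonUsageTable":
        entries = {
            aa: sorted(codons.items(), key=lambda cf: (-cf[1], cf[0]))
            for aa, codons in ECOLI_CODON_USAGE.items() if aa != "*"
        }
        stops = sorted(ECOLI_CODON_USAGE["*"].items(), key=lambda cf: (-cf[1], cf[0]))
        return cls(entries, stops)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CodonUsageTable":
        """Load a table from TSV with columns amino_acid, codon, fraction."""
        df = pd.read_csv(path, sep="\t", dtype={"amino_acid": str, "codon": str})
        entries: dict[str, list[tuple[str, float]]] = {}
        stops: list[tuple[str, float]] = []
        for row in df.itertuples(index=False):
            rec = (row.codon.upper(), float(row.fraction))
            if row.amino_acid == "*":
                stops.append(rec)
            else:
                entries.setdefault(row.amino_acid, []).append(rec)
        return cls(entries, stops)

    def to_tsv(self, path: str | Path) -> None:
        rows = [(aa, c, f) for aa, codons in sorted(self.entries.items())
                for c, f in codons]
        rows += [("*", c, f) for c, f in self.stop_codons]
        pd.DataFrame(rows, columns=["amino_acid", "codon", "fraction"]).to_csv(
            path, sep="\t", index=False)

    def codons_above(self, aa: str, min_freq: float = 0.1
                     ) -> tuple[list[str], np.ndarray]:
        """Codons for ``aa`` at or above the frequency threshold, renormalized."""
        if aa not in self.entries:
            raise ValueError(f"no codons for amino acid {aa!r}")
        kept = [(c, f) for c, f in self.entries[aa] if f >= min_freq]
        if not kept:
            raise ValueError(f"no codon for {aa!r} above frequency {min_freq}")
        codons = [c for c, _ in kept]
        weights = np.array([f for _, f in kept], dtype=float)
        return codons, weights / weights.sum()


DEFAULT_TABLE = CodonUsageTable.ecoli()


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def translate(dna: str) -> str:
    """Translate coding DNA up to (not including) the first stop."""
    if len(dna) % 3:
        raise ValueError(f"coding length {len(dna)} is not a multiple of 3")
    aa = str(Seq(dna).translate())
    return aa.split("*", 1)[0]


def revtrans(peptide: str, table: CodonUsageTable = DEFAULT_TABLE,
             min_freq: float = 0.1, seed=0) -> str:
    """Reverse translate by frequency-proportional sampling of common codons."""
    rng = _as_rng(seed)
    out = []
    for aa in peptide:
        codons, probs = table.codons_above(aa, min_freq)
        out.append(codons[int(rng.choice(len(codons), p=probs))])
    return "".join(out)


def find_sites(dna: str, forbidden=FORBIDDEN_SITES) -> list[tuple[int, str]]:
    hits = []
    for motif in forbidden:
        start = dna.find(motif)
        while start != -1:
            hits.append((start, motif))
            start = dna.find(motif, start + 1)
    return sorted(hits)


def recode_sites(dna: str, table: CodonUsageTable = DEFAULT_TABLE,
                 forbidden=FORBIDDEN_SITES, min_freq: float = 0.1,
                 seed=0, max_attempts: int = 100) -> str:
    """Remove forbidden restriction sites with synonymous codon swaps.

    Only codons overlapping a site are altered; each replacement is drawn
    from the above-threshold codons of the same amino acid.  Translation is
    unchanged.  Raises if a site survives ``max_attempts`` resamplings.
    """
    if len(dna) % 3:
        raise ValueError("coding DNA must be in frame (length divisible by 3)")
    rng = _as_rng(seed)
    codons = [dna[i : i + 3] for i in range(0, len(dna), 3)]
    original_aa = translate(dna)
    for _round in range(max_attempts):
        seq = "".join(codons)
        hits = find_sites(seq, forbidden)
        if not hits:
            return seq
        pos, motif = hits[0]
        touched = list(range(pos // 3, (pos + len(motif) - 1) // 3 + 1))
        idx = touched[int(rng.choice(len(touched)))]
        aa = str(Seq(codons[idx]).translate())
        choices, probs = table.codons_above(aa, min_freq)
        codons[idx] = choices[int(rng.choice(len(choices), p=probs))]
        if translate("".join(codons)) != original_aa:  # paranoia; synonymous by construction
            raise AssertionError("recoding changed the translation")
    hits = find_sites("".join(codons), forbidden)
    raise ValueError(f"could not recode site(s) {hits} after {max_attempts} attempts")


def _random_filler(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _has_long_homopolymer(dna: str, max_run: int = 8) -> bool:
    run, prev = 0, ""
    for ch in dna:
        run = run + 1 if ch == prev else 1
        prev = ch
        if run > max_run:
            return True
    return False


def pad_to_length(coding: str, target_nt: int, dialect: str = "stop_random",
                  seed=0, table: CodonUsageTable = DEFAULT_TABLE,
                  forbidden=FORBIDDEN_SITES, linker_dna: str = ENTERO_LINKER_DNA,
                  pad_end: str = "3p") -> str:
    """Pad a coding region to a fixed insert length.

    ``stop_random``: three stop codons then pseudo-random filler (filler is
    resampled if it would create a forbidden site or a >8-nt homopolymer).
    ``linker``: a fixed linker DNA, truncated to the needed length.
    """
    if len(coding) > target_nt:
        raise ValueError(f"coding region ({len(coding)} nt) exceeds target {target_nt}")
    need = target_nt - len(coding)
    if need == 0:
        return coding
    rng = _as_rng(seed)
    if dialect == "stop_random":
        if need % 3:
            raise ValueError("stop_random padding requires a multiple-of-3 gap")
        if need < 9:
            raise ValueError("stop_random padding needs room for three stop codons")
        stop_codons = [c for c, _ in table.stop_codons]
        stop_w = np.array([f for _, f in table.stop_codons], dtype=float)
        stop_w /= stop_w.sum()
        for _ in range(100):
            stops = "".join(stop_codons[int(i)] for i in
                            rng.choice(len(stop_codons), size=3, p=stop_w))
            filler = _random_filler(need - 9, rng)
            pad = stops + filler
            padded = coding + pad if pad_end == "3p" else pad + coding
            if not find_sites(padded, forbidden) and not _has_long_homopolymer(pad):
                return padded
        raise ValueError("could not generate clean padding in 100 attempts")
    if dialect == "linker":
        pad = (linker_dna * (need // len(linker_dna) + 1))[:need]
        return coding + pad if pad_end == "3p" else pad + coding
    raise ValueError(f"unknown padding dialect {dialect!r}")


def add_adapters(dna: str, prefix: str = MAIN_PREFIX, suffix: str = MAIN_SUFFIX) -> str:
    """Flank the insert with PCR-amplification adapters."""
    return prefix + dna + suffix


@dataclass
class EncodingDialect:
    """Length and adapter conventions of a synthesized sub-library."""

    insert_nt: int = MAIN_INSERT_NT
    prefix: str = MAIN_PREFIX
    suffix: str = MAIN_SUFFIX
    pad: str = "stop_random"
    pad_end: str = "3p"
    linker_dna: str = ENTERO_LINKER_DNA


MAIN_DIALECT = EncodingDialect()
ENTERO_DIALECT = EncodingDialect(insert_nt=ENTERO_INSERT_NT, prefix=ENTERO_PREFIX,
                                 suffix=ENTERO_SUFFIX, pad="linker")


@dataclass
class OligoRecord:
    peptide_id: str
    coding_dna: str
    full_oligo: str
    prefix: str
    suffix: str
    pad_spec: str = ""

    @property
    def insert(self) -> str:
        return self.full_oligo[len(self.prefix): len(self.full_oligo) - len(self.suffix)]


def encode_peptide(peptide_id: str, peptide: str, dialect: EncodingDialect = MAIN_DIALECT,
                   table: CodonUsageTable = DEFAULT_TABLE, min_freq: float = 0.1,
                   seed=0, append_stop: bool | None = None) -> OligoRecord:
    """Encode one peptide into a full synthesis oligo.

    ``append_stop`` defaults to appending one stop codon whenever the coding
    region would otherwise fall short of the insert length (so 55-mer stitched
    peptides span 56 codon positions and 15-mers get stops ahead of their
    filler), and to no stop when the peptide already fills the insert.
    """
    rng = _as_rng(seed)
    stop_codons = [c for c, _ in table.stop_codons]
    stop_w = np.array([f for _, f in table.stop_codons], dtype=float)
    stop_w /= stop_w.sum()
    for _ in range(100):
        coding = revtrans(peptide, table, min_freq, rng)
        coding = recode_sites(coding, table, FORBIDDEN_SITES, min_freq, rng)
        gap = dialect.insert_nt - len(coding)
        if gap < 0:
            raise ValueError(
                f"{peptide_id}: coding region ({len(coding)} nt) exceeds insert "
                f"length {dialect.insert_nt}")
        # Default: a terminal stop whenever there is room for exactly one
        # (55-aa stitched peptides -> 56 codon positions); the stop_random
        # padding used by shorter peptides carries its own stop codons.
        stop = append_stop if append_stop is not None else gap == 3
        insert = coding
        pad_spec = ""
        if stop:
            if gap < 3:
                raise ValueError(f"{peptide_id}: no room for a terminal stop codon")
            insert = coding + stop_codons[int(rng.choice(len(stop_codons), p=stop_w))]
            pad_spec = "stop"
        if len(insert) < dialect.insert_nt:
            try:
                insert = pad_to_length(insert, dialect.insert_nt, dialect.pad, rng,
                                       table, linker_dna=dialect.linker_dna,
                                       pad_end=dialect.pad_end)
            except ValueError:
                # e.g. a coding region ending in AAGCT forms a HindIII site
                # with any stop codon; redraw the coding region instead
                continue
            pad_spec = (pad_spec + ";" if pad_spec else "") + dialect.pad
        if not find_sites(insert):
            full = add_adapters(insert, dialect.prefix, dialect.suffix)
            return OligoRecord(peptide_id, coding, full, dialect.prefix,
                               dialect.suffix, pad_spec)
    raise ValueError(f"{peptide_id}: could not produce a clean insert")


def encode_library(manifest: pd.DataFrame, table: CodonUsageTable = DEFAULT_TABLE,
                   dialect: EncodingDialect = MAIN_DIALECT, min_freq: float = 0.1,
                   seed: int = 0) -> list[OligoRecord]:
    """Encode every manifest peptide; deterministic for a given seed.

    Each row's random stream derives from the master seed and the peptide
    sequence itself, so duplicate sequences encode to identical coding DNA
    and output is independent of row order.
    """
    import zlib

    if manifest.empty:
        raise ValueError("empty manifest")
    records = []
    for _, row in manifest.iterrows():
        child = np.random.SeedSequence([seed, zlib.crc32(str(row["seq"]).encode())])
        rng = np.random.default_rng(child)
        append_stop = bool(row["stop_codon"]) if "stop_codon" in row else None
        try:
            records.append(encode_peptide(str(row["peptide_id"]), row["seq"], dialect,
                                          table, min_freq, rng, append_stop))
        except ValueError as err:
            raise ValueError(f"while encoding {row['peptide_id']}: {err}") from err
    return records


def oligos_to_fasta(records: list[OligoRecord]) -> str:
    return "".join(f">{r.peptide_id}\n{r.full_oligo}\n" for r in records)
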