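"""Peptide-library design: tiling, scan libraries, epitope selection, stitching.

Three library modes are supported for a set of clustered proteins:

``tile``
    Uniform Pepsyn-style tiling: 56-mers overlapping by 28 aa, with a full
    C-terminal catch-up tile when the protein length is not a multiple of 28.
``epitopes``
    All 15-mer windows whose epitope probability exceeds the cutoff, each
    synthesized individually.
``stitched``
    Per protein cluster, greedily select non-overlapping high-probability
    15-mers, deduplicate identical 15-mers across clusters, and pack three
    epitopes per synthesized peptide joined by GGGGS linkers.  With ``n``
    stitched peptides for a cluster, peptide ``j`` carries the epitopes
    ranked ``j``, ``n+j`` and ``2n+j`` at positions 1, 2 and 3, so the
    highest-probability epitopes are spread over the first positions.

Coordinates are 0-based half-open internally; manifests also carry 1-based
display coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabets import validate_peptide

logger = logging.getLogger(__name__)

TILE_LEN = 56
TILE_OVERLAP = 28
EPITOPE_LEN = 15
DEFAULT_LINKER = "GGGGS"
SCAN_LENGTHS = (15, 20, 25, 30, 35, 40, 45)
SCAN_STEP = 5
PROB_CUTOFF = 0.5


@dataclass(frozen=True)
class ProteinRecord:
    """A protein with cluster (group) and antigen/phage memberships."""

    id: str
    seq: str
    group_id: str
    phage_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"protein {self.id}: empty sequence")
        validate_peptide(self.seq)
        if not self.group_id:
            raise ValueError(f"protein {self.id}: empty group_id")


@dataclass(frozen=True)
class Tile:
    protein_id: str
    start: int
    end: int  # half-open
    seq: str


@dataclass
class TileSet:
    tiles: list[Tile]
    tile_len: int = TILE_LEN
    overlap: int = TILE_OVERLAP


@dataclass
class ScoredWindow:
    """A 15-mer window of a protein-cluster representative."""

    group_id: str
    start: int
    seq: str
    prob: float = float("nan")
    protein_ids: frozenset[str] = frozenset()
    phage_ids: frozenset[str] = frozenset()

    @property
    def end(self) -> int:
        return self.start + len(self.seq)


@dataclass
class StitchedPeptide:
    """Three epitope 15-mers joined by linkers into one synthesized peptide."""

    epitopes: tuple[ScoredWindow, ScoredWindow, ScoredWindow]
    linker: str = DEFAULT_LINKER
    rank_layout: tuple[int, int, int] = (1, 2, 3)
    aa_seq: str = ""
    source_groups: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.aa_seq:
            self.aa_seq = self.linker.join(w.seq for w in self.epitopes)
        if not self.source_groups:
            self.source_groups = frozenset(w.group_id for w in self.epitopes)


# ---------------------------------------------------------------------------
# tiling and scan libraries
# ---------------------------------------------------------------------------

def pepsyn_tile(protein: ProteinRecord, tile_len: int = TILE_LEN,
                overlap: int = TILE_OVERLAP) -> TileSet:
    """Uniformly tile a protein, with a C-terminal catch-up tile.

    Tiles start every ``tile_len - overlap`` residues; if the last regular
    tile does not reach the C-terminus, one extra tile covering the final
    ``tile_len`` residues is appended (it may overlap its predecessor by more
    than ``overlap``).  Proteins shorter than ``tile_len`` yield an empty
    tile set with a logged warning.
    """
    L = len(protein.seq)
    if L < tile_len:
        logger.warning("protein %s (length %d) shorter than tile length %d; skipped",
                       protein.id, L, tile_len)
        return TileSet([], tile_len, overlap)
    step = tile_len - overlap
    starts = list(range(0, L - tile_len + 1, step))
    if starts[-1] + tile_len < L:
        starts.append(L - tile_len)
    tiles = [Tile(protein.id, s, s + tile_len, protein.seq[s : s + tile_len])
             for s in starts]
    return TileSet(tiles, tile_len, overlap)


def kmer_scan(wildtype: str, lengths=SCAN_LENGTHS, step: int = SCAN_STEP
              ) -> list[tuple[int, int, str]]:
    """All (k, start, sub-peptide) windows of a 56-mer, starting every 5 aa."""
    if len(wildtype) != TILE_LEN:
        raise ValueError(f"wildtype must be {TILE_LEN} aa long, got {len(wildtype)}")
    out = []
    for k in lengths:
        for start in range(0, len(wildtype) - k + 1, step):
            out.append((k, start, wildtype[start : start + k]))
    return out


def alanine_scan(wildtype: str) -> list[tuple[int, str]]:
    """Triple-alanine scan variants of a 56-mer.

    One variant per 3-mer start position (54 variants); targeted residues
    become A, except residues that already are A, which become G.
    """
    if len(wildtype) != TILE_LEN:
        raise ValueError(f"wildtype must be {TILE_LEN} aa long, got {len(wildtype)}")
    variants = []
    for pos in range(len(wildtype) - 2):
        chars = list(wildtype)
        for j in range(pos, pos + 3):
            chars[j] = "G" if chars[j] == "A" else "A"
        variants.append((pos, "".join(chars)))
    return variants


def enumerate_windows(protein: ProteinRecord, k: int = EPITOPE_LEN) -> list[ScoredWindow]:
    """All length-k windows (step 1) of a protein, unscored."""
    L = len(protein.seq)
    if L < k:
        logger.warning("protein %s (length %d) shorter than window length %d",
                       protein.id, L, k)
        return []
    return [
        ScoredWindow(protein.group_id, s, protein.seq[s : s + k],
                     protein_ids=frozenset({protein.id}), phage_ids=protein.phage_ids)
        for s in range(L - k + 1)
    ]


# ---------------------------------------------------------------------------
# epitope selection and stitching
# ---------------------------------------------------------------------------

def select_epitopes(windows: list[ScoredWindow], prob_cutoff: float = PROB_CUTOFF
                    ) -> list[ScoredWindow]:
    """Greedy non-overlapping selection of high-probability windows.

    Repeatedly takes the highest-probability window above the cutoff that
    does not overlap any already-selected window (ties broken by smaller
    start).  Returns the selection in descending probability order; may be
    empty.
    """
    groups = {w.group_id for w in windows}
    if len(groups) > 1:
        raise ValueError(f"windows span multiple protein groups: {sorted(groups)}")
    candidates = sorted(
        (w for w in windows if w.prob > prob_cutoff),
        key=lambda w: (-w.prob, w.start),
    )
    chosen: list[ScoredWindow] = []
    for w in candidates:
        if all(w.end <= c.start or w.start >= c.end for c in chosen):
            chosen.append(w)
    return chosen


@dataclass
class CatalogEntry:
    """A deduplicated epitope 15-mer with merged memberships."""

    seq: str
    prob: float
    group_ids: set[str] = field(default_factory=set)
    protein_ids: set[str] = field(default_factory=set)
    phage_ids: set[str] = field(default_factory=set)
    occurrences: list[ScoredWindow] = field(default_factory=list)


def dedupe_epitopes(windows: list[ScoredWindow]) -> list[CatalogEntry]:
    """Merge identical 15-mer sequences selected from different clusters.

    Membership is the union over occurrences; the merged probability is the
    maximum.  Entry order follows first occurrence.
    """
    catalog: dict[str, CatalogEntry] = {}
    for w in windows:
        entry = catalog.get(w.seq)
        if entry is None:
            entry = CatalogEntry(w.seq, w.prob)
            catalog[w.seq] = entry
        entry.prob = max(entry.prob, w.prob)
        entry.group_ids.add(w.group_id)
        entry.protein_ids.update(w.protein_ids)
        entry.phage_ids.update(w.phage_ids)
        entry.occurrences.append(w)
    return list(catalog.values())


def assign_positions(m: int) -> list[tuple[int, int, int]]:
    """Rank layout for ``floor(m/3)`` stitched peptides from ``m`` ranked epitopes.

    Peptide ``j`` (1-based) holds the epitopes ranked ``(j, n+j, 2n+j)`` at
    positions 1..3, spreading the top-ranked epitopes over first positions.
    Ranks beyond ``3n`` are discarded.
    """
    n = m // 3
    return [(j, n + j, 2 * n + j) for j in range(1, n + 1)]


def stitch(e1: ScoredWindow, e2: ScoredWindow, e3: ScoredWindow,
           linker: str = DEFAULT_LINKER,
           rank_layout: tuple[int, int, int] = (1, 2, 3)) -> StitchedPeptide:
    """Join three 15-mer epitopes with linkers (55 aa for the GGGGS default)."""
    for w in (e1, e2, e3):
        if len(w.seq) != EPITOPE_LEN:
            raise ValueError(f"epitope {w.seq!r} is not {EPITOPE_LEN} aa long")
    return StitchedPeptide(epitopes=(e1, e2, e3), linker=linker, rank_layout=rank_layout)


# ---------------------------------------------------------------------------
# whole-library design
# ---------------------------------------------------------------------------

MODES = ("tile", "epitopes", "stitched")


@dataclass
class DesignResult:
    manifest: pd.DataFrame
    coverage: float
    total_rep_aa: int
    skipped_groups: list[str] = field(default_factory=list)


def coverage_ratio(n_peptides: int, aa_per_peptide: int, total_aa: int) -> float:
    """Epitope-bearing residues in the library per representative-proteome residue."""
    if total_aa <= 0:
        raise ValueError("total_aa must be positive")
    return n_peptides * aa_per_peptide / total_aa


def _group_representatives(proteins: list[ProteinRecord]
                           ) -> dict[str, tuple[ProteinRecord, set[str], set[str]]]:
    """First protein per group is the representative; memberships are unions."""
    groups: dict[str, tuple[ProteinRecord, set[str], set[str]]] = {}
    for p in proteins:
        if p.group_id not in groups:
            groups[p.group_id] = (p, set(), set())
        rep, prot_ids, phage_ids = groups[p.group_id]
        prot_ids.add(p.id)
        phage_ids.update(p.phage_ids)
    return groups


def score_windows(groups, scorer, k: int = EPITOPE_LEN) -> dict[str, list[ScoredWindow]]:
    """Enumerate and score every k-mer window per group representative."""
    out: dict[str, list[ScoredWindow]] = {}
    for gid, (rep, prot_ids, phage_ids) in groups.items():
        windows = enumerate_windows(rep, k)
        for w in windows:
            w.protein_ids = frozenset(prot_ids)
            w.phage_ids = frozenset(phage_ids)
        if windows:
            probs = np.asarray(scorer([w.seq for w in windows]), dtype=float)
            for w, p in zip(windows, probs):
                w.prob = float(p)
        out[gid] = windows
    return out


def design_library(proteins: list[ProteinRecord], scorer=None, mode: str = "tile",
                   prob_cutoff: float = PROB_CUTOFF, linker: str = DEFAULT_LINKER,
                   k: int = EPITOPE_LEN) -> DesignResult:
    """Design a peptide library from clustered proteins.

    Parameters
    ----------
    proteins:
        All cluster members; the first protein of each ``group_id`` serves as
        the cluster representative, memberships are unioned over members.
    scorer:
        Callable mapping a list of k-mer sequences to epitope probabilities
        (e.g. ``EpitopeModel.predict_many``); required for the epitope modes.
    mode:
        ``tile`` (uniform 56/28 tiling), ``epitopes`` (individual predicted
        15-mers) or ``stitched`` (three epitopes per peptide, GGGGS linkers).

    Returns a manifest (one row per synthesized peptide) and the coverage
    statistic: epitope-bearing residues per representative-proteome residue
    (56 aa per tile, ``k`` per epitope peptide, ``3k`` per stitched peptide).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if not proteins:
        raise ValueError("no input proteins")
    if mode != "tile" and scorer is None:
        raise ValueError(f"mode {mode!r} requires a scorer")

    groups = _group_representatives(proteins)
    total_rep_aa = sum(len(rep.seq) for rep, _, _ in groups.values())
    rows: list[dict] = []
    skipped: list[str] = []

    if mode == "tile":
        for gid, (rep, prot_ids, phage_ids) in groups.items():
            tileset = pepsyn_tile(rep)
            if not tileset.tiles:
                skipped.append(gid)
            for t in tileset.tiles:
                rows.append({
                    "peptide_id": f"tile|{gid}|{t.start}",
                    "seq": t.seq,
                    "mode": "tile",
                    "group_ids": gid,
                    "protein_ids": ";".join(sorted(prot_ids)),
                    "phage_ids": ";".join(sorted(phage_ids)),
                    "sources": f"{rep.id}:{t.start}-{t.end}",
                    "display_start": t.start + 1,
                    "probs": "",
                })
        cov = coverage_ratio(len(rows), TILE_LEN, total_rep_aa) if rows else 0.0
        return DesignResult(pd.DataFrame(rows), cov, total_rep_aa, skipped)

    scored = score_windows(groups, scorer, k)
    selected: dict[str, list[ScoredWindow]] = {}
    for gid, windows in scored.items():
        sel = select_epitopes(windows, prob_cutoff)
        if sel:
            selected[gid] = sel
        else:
            skipped.append(gid)

    if mode == "epitopes":
        catalog = dedupe_epitopes([w for sel in selected.values() for w in sel])
        for entry in catalog:
            first = entry.occurrences[0]
            rows.append({
                "peptide_id": f"epi|{first.group_id}|{first.start}",
                "seq": entry.seq,
                "mode": "epitopes",
                "group_ids": ";".join(sorted(entry.group_ids)),
                "protein_ids": ";".join(sorted(entry.protein_ids)),
                "phage_ids": ";".join(sorted(entry.phage_ids)),
                "sources": ";".join(f"{next(iter(w.protein_ids))}:{w.start}-{w.end}"
                                    for w in entry.occurrences),
                "display_start": first.start + 1,
                "probs": f"{entry.prob:.6g}",
            })
        cov = coverage_ratio(len(rows), k, total_rep_aa) if rows else 0.0
        return DesignResult(pd.DataFrame(rows), cov, total_rep_aa, skipped)

    # stitched mode: dedupe first, then per-group rank/position assignment;
    # a merged epitope participates in each owning group's peptides but a
    # given stitched amino-acid sequence is synthesized once.
    catalog = dedupe_epitopes([w for sel in selected.values() for w in sel])
    merged_prob = {e.seq: e.prob for e in catalog}
    merged_phages = {e.seq: e.phage_ids for e in catalog}
    merged_proteins = {e.seq: e.protein_ids for e in catalog}
    seen_seqs: set[str] = set()
    for gid, sel in selected.items():
        ranked = sorted(sel, key=lambda w: (-merged_prob[w.seq], w.start))
        if len(ranked) < 3:
            skipped.append(gid)
            continue
        for layout in assign_positions(len(ranked)):
            trio = tuple(ranked[r - 1] for r in layout)
            pep = stitch(*trio, linker=linker, rank_layout=layout)
            if pep.aa_seq in seen_seqs:
                continue
            seen_seqs.add(pep.aa_seq)
            rows.append({
                "peptide_id": f"stitch|{gid}|{layout[0]}",
                "seq": pep.aa_seq,
                "mode": "stitched",
                "group_ids": gid,
                "protein_ids": ";".join(sorted(set().union(
                    *(merged_proteins[w.seq] for w in trio)))),
                "phage_ids": ";".join(sorted(set().union(
                    *(merged_phages[w.seq] for w in trio)))),
                "sources": ";".join(f"{next(iter(w.protein_ids))}:{w.start}-{w.end}"
                                    for w in trio),
                "display_start": trio[0].start + 1,
                "probs": ";".join(f"{merged_prob[w.seq]:.6g}" for w in trio),
                "rank_layout": ";".join(map(str, layout)),
            })
    cov = coverage_ratio(len(rows), 3 * k, total_rep_aa) if rows else 0.0
    return DesignResult(pd.DataFrame(rows), cov, total_rep_aa, skipped)


def with_stop_variants(manifest: pd.DataFrame) -> pd.DataFrame:
    """Double a manifest: each peptide once plain, once with a C-terminal stop.

    Used for scan-style sub-libraries where each epitope peptide is
    synthesized both with and without a terminal stop codon, doubling the
    peptide count.
    """
    plain = manifest.copy()
    plain["stop_codon"] = False
    stopped = manifest.copy()
    stopped["peptide_id"] = stopped["peptide_id"].astype(str) + "|stop"
    stopped["stop_codon"] = True
    return pd.concat([plain, stopped], ignore_index=True)
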