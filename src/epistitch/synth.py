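"""Synthetic data generators for end-to-end testing without external data.

Three generators emulate the data the rest of the toolkit consumes:

* :func:`generate_proteome` — a phage proteome with homologous (shared)
  proteins across phages and planted epitope intervals whose amino-acid
  composition is shifted toward lysine, the serine/threonine/alanine group
  and charged residues, and away from hydrophobics (the direction the
  composition classifier is expected to learn).
* :func:`generate_scan_dataset` — scan-library reactivity: k-mer sub-peptides
  of wildtype 56-mers are reactive in a sample iff they fully contain the
  planted epitope and the sample is seropositive; triple-alanine variants
  lose reactivity iff the substituted 3-mer intersects the epitope.
* :func:`simulate_phipseq` — overdispersed (gamma-Poisson) count matrices
  with mock-IP background columns; sample columns add fold enrichment to
  peptides covering an epitope the sample is seropositive for.

Everything is seeded and byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabets import AMINO_ACIDS
from .design import ProteinRecord, alanine_scan, kmer_scan

#: Default log-enrichment of amino acids inside planted epitopes.  The
#: magnitudes are set so that planted epitopes are strongly separable from
#: background by composition alone (the premise the classifier tests probe):
#: strict-containment labelling puts near-complete epitope overlaps in the
#: negative class, so a weaker shift would cap even a Bayes-optimal
#: composition score near chance-plus.
DEFAULT_COMPOSITION_SHIFT: dict[str, float] = {
    "K": 2.0,
    "S": 1.2, "T": 1.2, "A": 1.2,
    "R": 0.8, "E": 0.8, "D": 0.8, "Q": 0.8, "N": 0.8,
    "I": -1.2, "L": -1.2, "V": -1.2, "F": -1.2, "M": -1.2, "W": -1.2, "C": -1.2,
}


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generators.

    Defaults mirror the screening setting the toolkit targets: a 51-sample
    healthy cohort, ~14-aa public epitopes, moderate per-epitope
    seroprevalence, and overdispersed sequencing counts around a mean depth
    of 100 reads per peptide.
    """

    seed: int = 0
    n_phages: int = 50
    proteins_per_phage: int = 8
    shared_protein_fraction: float = 0.2
    protein_length_range: tuple[int, int] = (100, 400)
    epitope_rate: float = 1.0          # expected epitopes per 100 aa
    epitope_width: int = 14
    composition_shift: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION_SHIFT))
    cohort_size: int = 51
    seroprevalence: float = 0.3        # per (epitope, sample)
    depth: float = 100.0               # mean reads per peptide
    noise_dispersion: float = 0.3      # gamma-Poisson overdispersion
    reactive_phage_fraction: float = 1.0   # phages whose proteins carry epitopes
    enrichment_fold: float = 16.0      # fold enrichment of seropositive peptides
    n_wildtypes: int = 357             # wildtype 56-mers in the scan generator
    spurious_rate: float = 0.005       # stray single-sample reactivity rate

    def background_probs(self) -> np.ndarray:
        return np.full(20, 1 / 20)

    def epitope_probs(self) -> np.ndarray:
        shift = np.array([self.composition_shift.get(a, 0.0) for a in AMINO_ACIDS])
        p = self.background_probs() * np.exp(shift)
        return p / p.sum()


def _random_seq(n: int, probs: np.ndarray, rng: np.random.Generator) -> str:
    letters = rng.choice(list(AMINO_ACIDS), size=n, p=probs)
    return "".join(letters)


def random_peptides(n: int, length: int = 15, seed: int = 0) -> list[str]:
    """Uniform-composition random peptides (general-purpose fixture helper)."""
    rng = np.random.default_rng(seed)
    probs = np.full(20, 1 / 20)
    return [_random_seq(length, probs, rng) for _ in range(n)]


# ---------------------------------------------------------------------------
# proteome generator
# ---------------------------------------------------------------------------

@dataclass
class SynthProteome:
    proteins: list[ProteinRecord]
    membership: pd.DataFrame        # protein_id, group_id, phage_ids (';')
    epitopes: pd.DataFrame          # protein_id, start, end (half-open)
    reactive_phages: list[str]

    def fasta(self) -> str:
        return "".join(f">{p.id}\n{p.seq}\n" for p in self.proteins)


def generate_proteome(config: SynthConfig) -> SynthProteome:
    """Generate a clustered phage proteome with planted epitopes.

    A ``shared_protein_fraction`` of proteins is assigned verbatim to 2-4
    phages (emulating the homology-heavy structure of metagenomic phage
    databases); each unique protein is its own cluster.  Epitope intervals
    (Poisson number at ``epitope_rate`` per 100 aa, non-overlapping) are
    planted only in proteins belonging to the reactive phage subset.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.protein_length_range
    if config.epitope_width > lo:
        raise ValueError(
            f"epitope width {config.epitope_width} exceeds minimum protein length {lo}")
    phage_names = [f"phage_{i:03d}" for i in range(config.n_phages)]
    n_reactive = int(round(config.reactive_phage_fraction * config.n_phages))
    reactive = set(phage_names[:n_reactive])

    bg = config.background_probs()
    epi_probs = config.epitope_probs()
    proteins: list[ProteinRecord] = []
    mem_rows, epi_rows = [], []
    pid = 0
    for phage in phage_names:
        for _ in range(config.proteins_per_phage):
            owners = [phage]
            if rng.random() < config.shared_protein_fraction and config.n_phages > 1:
                k = int(rng.integers(1, 4))
                others = [p for p in phage_names if p != phage]
                extra = rng.choice(others, size=min(k, len(others)), replace=False)
                owners += [str(x) for x in extra]
            L = int(rng.integers(lo, hi + 1))
            seq = list(_random_seq(L, bg, rng))
            name = f"prot_{pid:05d}"
            pid += 1
            plant_epitopes = any(o in reactive for o in owners)
            if plant_epitopes and config.epitope_rate > 0:
                n_epi = int(rng.poisson(config.epitope_rate * L / 100))
                taken: list[tuple[int, int]] = []
                for _e in range(n_epi):
                    for _try in range(20):
                        s = int(rng.integers(0, L - config.epitope_width + 1))
                        e = s + config.epitope_width
                        if all(e <= a or s >= b for a, b in taken):
                            taken.append((s, e))
                            seq[s:e] = list(_random_seq(config.epitope_width,
                                                        epi_probs, rng))
                            epi_rows.append({"protein_id": name, "start": s, "end": e})
                            break
            record = ProteinRecord(name, "".join(seq), group_id=name,
                                   phage_ids=frozenset(owners))
            proteins.append(record)
            mem_rows.append({"protein_id": name, "group_id": name,
                             "phage_ids": ";".join(sorted(owners))})
    membership = pd.DataFrame(mem_rows)
    epitopes = pd.DataFrame(epi_rows, columns=["protein_id", "start", "end"])
    return SynthProteome(proteins, membership, epitopes, sorted(reactive))


# ---------------------------------------------------------------------------
# scan-library generator
# ---------------------------------------------------------------------------

@dataclass
class ScanDataset:
    """Scan-library reactivity tables for classifier training and epitope mapping."""

    kmers: pd.DataFrame        # seq, wildtype_id, k, start + sample columns
    bead_counts: pd.DataFrame  # seq, count
    alanine: pd.DataFrame      # wildtype_id, pos + sample columns
    wildtypes: pd.DataFrame    # wildtype_id, seq, epi_start, epi_end + sample columns


def generate_scan_dataset(config: SynthConfig, lengths=(15, 20, 25, 30, 35, 40, 45),
                          noise_sd: float = 0.3, include_alanine: bool = True
                          ) -> ScanDataset:
    """Scan reactivity for wildtype 56-mers with one planted epitope each.

    A sub-peptide is reactive in a sample iff it fully contains the epitope
    interval and the sample is seropositive for that wildtype's epitope; its
    log hit-fold-change is drawn around 2.5.  Alanine variants retain the
    wildtype's reactivity unless their substituted 3-mer intersects the
    epitope.  A small spurious-reactivity rate adds single-sample noise.
    """
    rng = np.random.default_rng(config.seed)
    w = config.epitope_width
    samples = [f"s{j:03d}" for j in range(config.cohort_size)]
    bg = config.background_probs()
    epi_probs = config.epitope_probs()

    kmer_rows, ala_rows, wt_rows, bead_rows = [], [], [], []
    for i in range(config.n_wildtypes):
        wt_id = f"wt_{i:04d}"
        seq = list(_random_seq(56, bg, rng))
        s = int(rng.integers(0, 56 - w + 1))
        seq[s : s + w] = list(_random_seq(w, epi_probs, rng))
        wt = "".join(seq)
        sero = rng.random(config.cohort_size) < config.seroprevalence
        strength = np.where(sero, np.abs(rng.normal(2.5, 0.5, config.cohort_size)), 0.0)
        wt_rows.append({"wildtype_id": wt_id, "seq": wt, "epi_start": s, "epi_end": s + w,
                        **dict(zip(samples, strength))})

        for k, start, sub in kmer_scan(wt, lengths=lengths):
            contains = start <= s and start + k >= s + w
            if contains:
                vals = np.where(sero, np.abs(rng.normal(2.5, noise_sd,
                                                        config.cohort_size)), 0.0)
            else:
                vals = np.zeros(config.cohort_size)
            spurious = rng.random(config.cohort_size) < config.spurious_rate
            vals = np.where(spurious & (vals == 0),
                            np.abs(rng.normal(1.0, 0.3, config.cohort_size)), vals)
            kmer_rows.append({"seq": sub, "wildtype_id": wt_id, "k": k, "start": start,
                              **dict(zip(samples, vals))})
            bead_rows.append({"seq": sub,
                              "count": int(rng.poisson(config.depth))})

        if include_alanine:
            for pos, _variant in alanine_scan(wt):
                disrupted = pos + 3 > s and pos < s + w
                if disrupted:
                    vals = np.abs(rng.normal(0.0, noise_sd, config.cohort_size))
                else:
                    vals = strength + rng.normal(0.0, noise_sd, config.cohort_size)
                ala_rows.append({"wildtype_id": wt_id, "pos": pos,
                                 **dict(zip(samples, vals))})

    return ScanDataset(pd.DataFrame(kmer_rows), pd.DataFrame(bead_rows),
                       pd.DataFrame(ala_rows), pd.DataFrame(wt_rows))


def classifier_fixture(n_examples: int = 2000, seed: int = 7,
                       cohort_size: int = 40, n_wildtypes: int = 3000):
    """Balanced planted-epitope training examples (the classifier test bed).

    Generates a k=15 scan over ``n_wildtypes`` wildtypes, builds the balanced
    training set, and subsamples positives and negatives to ``n_examples``
    total (preserving wildtype grouping).  Returns a list of training
    examples.
    """
    from .classifier import build_training_set

    config = SynthConfig(seed=seed, cohort_size=cohort_size, n_wildtypes=n_wildtypes)
    data = generate_scan_dataset(config, lengths=(15,), include_alanine=False)
    examples = build_training_set(data.kmers, data.bead_counts)
    pos = [ex for ex in examples if ex.label == 1]
    neg = [ex for ex in examples if ex.label == 0]
    half = n_examples // 2
    if len(pos) < half or len(neg) < half:
        raise ValueError(
            f"fixture too small: {len(pos)} positives / {len(neg)} negatives "
            f"for a target of {half} per class")
    rng = np.random.default_rng(seed)
    keep_pos = rng.choice(len(pos), size=half, replace=False)
    keep_neg = rng.choice(len(neg), size=half, replace=False)
    return [pos[i] for i in sorted(keep_pos)] + [neg[i] for i in sorted(keep_neg)]


# ---------------------------------------------------------------------------
# PhIP-Seq count simulator
# ---------------------------------------------------------------------------

@dataclass
class PhipSeqSim:
    counts: pd.DataFrame      # peptides x samples
    mock: pd.DataFrame        # peptides x mock replicates
    enriched: pd.DataFrame    # boolean truth, peptides x samples
    seropositive: pd.DataFrame  # epitope x sample truth


def _parse_sources(sources: str) -> list[tuple[str, int, int]]:
    out = []
    for token in str(sources).split(";"):
        if not token:
            continue
        prot, span = token.rsplit(":", 1)
        a, b = span.split("-")
        out.append((prot, int(a), int(b)))
    return out


def simulate_phipseq(manifest: pd.DataFrame, epitopes: pd.DataFrame,
                     config: SynthConfig, n_mock: int = 4) -> PhipSeqSim:
    """Simulate a PhIP-Seq screen of a designed library.

    Counts follow a gamma-Poisson model: each peptide has a library abundance
    drawn once (gamma with CV^2 = ``noise_dispersion``), mock columns sample
    pure background, and in a serum column every peptide covering an epitope
    interval the sample is seropositive for is enriched ``enrichment_fold``-x.
    A stitched peptide is enriched iff at least one of its three source
    epitopes is seropositive.
    """
    if manifest.empty:
        raise ValueError("empty manifest")
    rng = np.random.default_rng(config.seed)
    samples = [f"s{j:03d}" for j in range(config.cohort_size)]
    n = len(manifest)

    epi = epitopes.reset_index(drop=True)
    sero = rng.random((len(epi), config.cohort_size)) < config.seroprevalence
    sero_df = pd.DataFrame(sero, columns=samples)
    # epitopes grouped by protein for containment lookups
    by_prot: dict[str, list[tuple[int, int, int]]] = {}
    for e_idx, row in epi.iterrows():
        by_prot.setdefault(str(row.protein_id), []).append(
            (int(row.start), int(row.end), int(e_idx)))

    enriched = np.zeros((n, config.cohort_size), dtype=bool)
    for i, sources in enumerate(manifest["sources"]):
        for prot, a, b in _parse_sources(sources):
            for s, e, e_idx in by_prot.get(prot, []):
                if a <= s and e <= b:
                    enriched[i] |= sero[e_idx]

    disp = max(config.noise_dispersion, 1e-9)
    abundance = rng.gamma(shape=1 / disp, scale=disp, size=n)
    mock = pd.DataFrame(
        rng.poisson(np.outer(abundance * config.depth, np.ones(n_mock))),
        index=manifest["peptide_id"], columns=[f"mock_{m}" for m in range(n_mock)])
    mean = np.outer(abundance * config.depth, np.ones(config.cohort_size))
    mean = mean * np.where(enriched, config.enrichment_fold, 1.0)
    cell_noise = rng.gamma(shape=1 / disp, scale=disp, size=mean.shape)
    counts = pd.DataFrame(rng.poisson(mean * cell_noise),
                          index=manifest["peptide_id"], columns=samples)
    enriched_df = pd.DataFrame(enriched, index=manifest["peptide_id"], columns=samples)
    return PhipSeqSim(counts, mock, enriched_df, sero_df)
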