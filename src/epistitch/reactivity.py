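"""PhIP-Seq reactivity analysis: hit calling, phage aggregate reactivity
scores, and library evaluation summaries.

The central statistic is the phage aggregate reactivity (PhAR) score: for a
phage represented by k peptides in a sub-library, the observed mean log2
fold-change of those peptides is standardized against the empirical
distribution of means of 1,000 random k-peptide sets drawn (without
replacement within a draw) from the sub-library's peptide pool.  The
procedure iterates: peptides of strongly reactive phages (score above 1) are
removed from the null pool and scores are recomputed, up to seven rounds or
until no new phage passes the threshold.  Scores are computed per phage and
sample, only for phages with at least 25 peptides.

Upstream fold-change/p-value estimation is pluggable; a simple scaled-mock
ratio with a Poisson upper tail is provided so the pipeline runs end to end
on raw counts, and precomputed fold-change/p-value tables are accepted
directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

HIT_MIN_COUNT = 15
HIT_MIN_FC = 5.0
HIT_MAX_P = 0.001


# ---------------------------------------------------------------------------
# hit calling
# ---------------------------------------------------------------------------

def call_hits(counts: pd.DataFrame, log2fc: pd.DataFrame, pvals: pd.DataFrame,
              min_count: int = HIT_MIN_COUNT, min_fc: float = HIT_MIN_FC,
              max_p: float = HIT_MAX_P) -> pd.DataFrame:
    """Element-wise hit calls: count > 15 AND fold change > 5 AND p < 0.001.

    All thresholds are strict inequalities.
    """
    for name, m in (("log2fc", log2fc), ("pvals", pvals)):
        if m.shape != counts.shape:
            raise ValueError(f"{name} shape {m.shape} != counts shape {counts.shape}")
    return (counts > min_count) & (np.exp2(log2fc) > min_fc) & (pvals < max_p)


def hit_foldchange(log2fc: pd.DataFrame, hits: pd.DataFrame) -> pd.DataFrame:
    """log2 fold-change where a peptide is a hit, zero elsewhere ("log hfc")."""
    return log2fc.where(hits, 0.0)


def simple_fold_test(counts: pd.DataFrame, mock_counts: pd.DataFrame,
                     pseudocount: float = 1.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Depth-scaled fold change against mock-IP background, Poisson upper tail.

    The mock mean per peptide is scaled to each sample's sequencing depth;
    the fold change is ``(count + pseudo) / (expected + pseudo)`` and the
    p-value is ``P(X >= count)`` for a Poisson with the expected rate.  A
    deliberately simple stand-in for a full count model: monotone in the
    count at fixed background, which is all downstream steps require.
    """
    if mock_counts.shape[1] < 1:
        raise ValueError("need at least one mock-IP column")
    if not counts.index.equals(mock_counts.index):
        raise ValueError("counts and mock_counts must share the peptide index")
    mock_mean = mock_counts.mean(axis=1)
    mock_depth = float(mock_counts.sum(axis=0).mean())
    depth_scale = counts.sum(axis=0) / mock_depth
    expected = np.outer(mock_mean.to_numpy(), depth_scale.to_numpy())
    c = counts.to_numpy(dtype=float)
    fc = (c + pseudocount) / (expected + pseudocount)
    lam = expected + pseudocount
    pv = stats.poisson.sf(c - 1, lam)
    log2fc = pd.DataFrame(np.log2(fc), index=counts.index, columns=counts.columns)
    pvals = pd.DataFrame(pv, index=counts.index, columns=counts.columns)
    return log2fc, pvals


def reactive_fraction(loghfc: pd.DataFrame) -> tuple[pd.Series, float]:
    """Per-peptide reactivity flag (log hfc > 0 in >= 1 sample) and its rate."""
    if loghfc.size == 0:
        raise ValueError("empty reactivity matrix")
    flags = (loghfc > 0).any(axis=1)
    return flags, float(flags.mean())


# ---------------------------------------------------------------------------
# PhAR score
# ---------------------------------------------------------------------------

@dataclass
class PhARscoreTable:
    """Phage x sample aggregate reactivity scores with iteration provenance."""

    scores: pd.DataFrame
    eligible: pd.Series
    iterations_used: int
    removal_log: list[dict[str, list[str]]] = field(default_factory=list)

    def mean_scores(self) -> pd.Series:
        """Per-phage mean score across samples (the phage-level summary)."""
        return self.scores.mean(axis=1)

    def binarized(self, threshold: float = 1.0) -> pd.DataFrame:
        return self.scores > threshold


def _phage_peptides(phage_map: dict[str, list[str]] | pd.DataFrame,
                    peptide_index: pd.Index) -> dict[str, np.ndarray]:
    """Normalize a peptide->phages mapping into phage -> peptide row indices."""
    pep_pos = {p: i for i, p in enumerate(peptide_index)}
    by_phage: dict[str, list[int]] = {}
    if isinstance(phage_map, pd.DataFrame):
        items = ((str(r.peptide_id), str(r.phage_ids).split(";"))
                 for r in phage_map.itertuples(index=False))
    else:
        items = ((p, list(phages)) for p, phages in phage_map.items())
    for pep, phages in items:
        if pep not in pep_pos:
            continue
        for ph in phages:
            if ph:
                by_phage.setdefault(ph, []).append(pep_pos[pep])
    return {ph: np.unique(np.array(idx, dtype=int)) for ph, idx in by_phage.items()}


def pharscore(log2fc: pd.DataFrame, phage_map, min_peptides: int = 25,
              n_draws: int = 1000, score_threshold: float = 1.0, max_iter: int = 7,
              seed: int = 0, global_removal: bool = False) -> PhARscoreTable:
    """Iterative permutation z-scores of phage-level mean reactivity.

    Parameters
    ----------
    log2fc:
        Peptides x samples log2 fold-change matrix for one sub-library.
    phage_map:
        Either a ``{peptide_id: [phage ids]}`` mapping or a data frame with
        ``peptide_id`` and semicolon-joined ``phage_ids`` columns.  Peptides
        may serve several phages.
    global_removal:
        If True, a phage leaves the null pool (in all samples) when its mean
        score across samples exceeds the threshold; by default removal is per
        sample.

    Notes
    -----
    A peptide is removed from a pool only once *every* phage it serves has
    been removed.  If the null standard deviation degenerates (constant
    pool), the score is defined as 0.  Within one sample and iteration all
    phages share the same 1,000 random permutations of the pool, from which
    each phage's size-k prefix sets are taken; draws are without replacement
    within a draw and independent across draws.
    """
    rng = np.random.default_rng(seed)
    values = log2fc.to_numpy(dtype=float)
    n_pep, n_samp = values.shape
    by_phage = _phage_peptides(phage_map, log2fc.index)
    eligible = {ph: idx for ph, idx in by_phage.items() if len(idx) >= min_peptides}
    phages = sorted(eligible)
    if not phages:
        raise ValueError(f"no phage has >= {min_peptides} peptides")
    samples = list(log2fc.columns)

    # peptide -> owning eligible phages, for pool-removal bookkeeping
    owners: dict[int, set[str]] = {}
    for ph, idx in eligible.items():
        for i in idx:
            owners.setdefault(int(i), set()).add(ph)

    scores = pd.DataFrame(np.nan, index=phages, columns=samples)
    removed: dict[str, set[str]] = {s: set() for s in samples}
    removal_log: list[dict[str, list[str]]] = []
    obs_means = {ph: values[idx].mean(axis=0) for ph, idx in eligible.items()}

    iterations = 0
    for _it in range(max_iter):
        iterations += 1
        newly: dict[str, list[str]] = {}
        for j, samp in enumerate(samples):
            gone = removed[samp]
            pool = np.array(
                [i for i in range(n_pep)
                 if not (owners.get(i) and owners[i] <= gone)],
                dtype=int,
            )
            v = values[pool, j]
            if len(pool) < max(len(eligible[ph]) for ph in phages if ph not in gone):
                worst = max((ph for ph in phages if ph not in gone),
                            key=lambda ph: len(eligible[ph]))
                raise ValueError(
                    f"null pool ({len(pool)} peptides) smaller than phage "
                    f"{worst!r} peptide set ({len(eligible[worst])})")
            keys = rng.random((n_draws, len(pool)))
            order = np.argsort(keys, axis=1, kind="stable")
            permuted = v[order]
            csum = np.cumsum(permuted, axis=1)
            for ph in phages:
                if ph in gone:
                    continue
                k = len(eligible[ph])
                null_means = csum[:, k - 1] / k
                mu = float(null_means.mean())
                sd = float(null_means.std())
                z = 0.0 if sd < 1e-12 else (obs_means[ph][j] - mu) / sd
                scores.loc[ph, samp] = z
        # removal step
        if global_removal:
            flagged = [ph for ph in phages
                       if ph not in removed[samples[0]]
                       and float(scores.loc[ph].mean()) > score_threshold]
            for ph in flagged:
                for s in samples:
                    removed[s].add(ph)
            if flagged:
                newly["__all__"] = flagged
        else:
            for samp in samples:
                flagged = [ph for ph in phages if ph not in removed[samp]
                           and float(scores.loc[ph, samp]) > score_threshold]
                if flagged:
                    newly[samp] = flagged
                    removed[samp].update(flagged)
        removal_log.append(newly)
        if not newly:
            break

    return PhARscoreTable(scores, pd.Series({ph: True for ph in phages}),
                          iterations, removal_log)


# ---------------------------------------------------------------------------
# evaluation summaries
# ---------------------------------------------------------------------------

def cost_effectiveness(hits: pd.DataFrame, peptide_order) -> np.ndarray:
    """Cumulative reactivities (over all samples) as peptides are added.

    ``peptide_order`` must be a permutation of the hit matrix's peptide index.
    Returns a non-decreasing curve of length ``n_peptides``.
    """
    order = list(peptide_order)
    if sorted(order) != sorted(hits.index):
        raise ValueError("peptide_order is not a permutation of the peptide index")
    per_pep = hits.loc[order].sum(axis=1).to_numpy(dtype=float)
    return np.cumsum(per_pep)


@dataclass
class RecoveryMetrics:
    """Per-sample protein-recovery metrics of a compressed design."""

    per_sample: pd.DataFrame        # accuracy / recall / precision on shared proteins
    shared_proteins: list[str]
    missing_proteins: list[str]     # in truth but absent from the test design
    full_universe_recall: pd.Series


def protein_recovery(truth_hits: pd.DataFrame, test_hits: pd.DataFrame
                     ) -> RecoveryMetrics:
    """Confusion-matrix metrics for protein-level reactivity recovery.

    Both inputs are boolean protein x sample matrices (a protein is reactive
    if any of its peptides is a hit).  Metrics are computed per sample over
    the proteins present in both designs; proteins missing from the test
    design are reported separately, together with recall over the full truth
    universe.  Samples without any true positives get NaN recall.
    """
    shared = truth_hits.index.intersection(test_hits.index)
    if len(shared) == 0:
        raise ValueError("no shared proteins between designs")
    samples = truth_hits.columns
    if not samples.equals(test_hits.columns):
        raise ValueError("designs must share the sample columns")
    t = truth_hits.loc[shared].to_numpy(bool)
    p = test_hits.loc[shared].to_numpy(bool)
    tp = (t & p).sum(axis=0).astype(float)
    fp = (~t & p).sum(axis=0).astype(float)
    fn = (t & ~p).sum(axis=0).astype(float)
    tn = (~t & ~p).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        metrics = pd.DataFrame({
            "accuracy": (tp + tn) / len(shared),
            "recall": np.where(tp + fn > 0, tp / (tp + fn), np.nan),
            "precision": np.where(tp + fp > 0, tp / (tp + fp), np.nan),
        }, index=samples)
    missing = [str(x) for x in truth_hits.index.difference(test_hits.index)]
    full_tp = tp  # hits on missing proteins cannot be recovered
    full_pos = truth_hits.to_numpy(bool).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        full_recall = pd.Series(
            np.where(full_pos > 0, full_tp / full_pos, np.nan), index=samples)
    return RecoveryMetrics(metrics, [str(x) for x in shared], missing, full_recall)


# ---------------------------------------------------------------------------
# alanine-scan epitope localization
# ---------------------------------------------------------------------------

@dataclass
class AlanineProfile:
    """Aligned alanine-scan difference curves and the 80%-mass epitope width."""

    curves: np.ndarray          # n_curves x grid, NaN outside each curve's span
    mean_curve: np.ndarray
    width: float                # NaN when no single-epitope curves were found
    n_curves: int
    diagnostic: str = ""


def _single_epitope_run(diff: np.ndarray, threshold: float) -> tuple[int, int] | None:
    """Return (start, end) of the disruption run if there is exactly one."""
    above = diff > threshold
    if not above.any():
        return None
    idx = np.flatnonzero(above)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    if len(runs) != 1:
        return None
    return int(runs[0][0]), int(runs[0][-1]) + 1


def mass_width(curve: np.ndarray, center: int, mass_fraction: float = 0.8) -> float:
    """Smallest centered span holding ``mass_fraction`` of the positive mass.

    Starting from ``center``, the span grows one position at a time toward
    whichever side adds more mass (left on ties).
    """
    pos = np.clip(np.nan_to_num(curve, nan=0.0), 0.0, None)
    total = pos.sum()
    if total <= 0:
        return float("nan")
    lo = hi = center
    mass = pos[center]
    while mass < mass_fraction * total:
        left = pos[lo - 1] if lo > 0 else -np.inf
        right = pos[hi + 1] if hi < len(pos) - 1 else -np.inf
        if left >= right:
            lo -= 1
            mass += pos[lo]
        else:
            hi += 1
            mass += pos[hi]
    return float(hi - lo + 1)


def alanine_epitope_profile(variant_values: pd.DataFrame, wildtype_values: pd.DataFrame,
                            rel_threshold: float = 0.5, mass_fraction: float = 0.8
                            ) -> AlanineProfile:
    """Localize epitopes from triple-alanine scan reactivity losses.

    For every (wildtype, sample) with a reactive wildtype, the difference
    curve ``wildtype - variant[pos]`` over the 54 variant positions measures
    reactivity disruption.  Curves with exactly one contiguous disruption run
    (above ``rel_threshold`` x wildtype reactivity) are kept, shifted so the
    run midpoint sits at a common center, and averaged; the epitope width is
    the smallest centered span containing ``mass_fraction`` of the mean
    curve's positive mass.

    Parameters
    ----------
    variant_values:
        Columns ``wildtype_id``, ``pos`` plus one column per sample (log hfc).
    wildtype_values:
        Column ``wildtype_id`` plus the same sample columns.
    """
    samples = [c for c in wildtype_values.columns if c != "wildtype_id"]
    wt_rows = wildtype_values.set_index("wildtype_id")
    n_pos = int(variant_values["pos"].max()) + 1
    grid = 2 * n_pos - 1
    center = n_pos - 1
    aligned: list[np.ndarray] = []
    for wt_id, block in variant_values.groupby("wildtype_id", sort=True):
        block = block.sort_values("pos")
        if wt_id not in wt_rows.index:
            continue
        for samp in samples:
            wt_val = float(wt_rows.loc[wt_id, samp])
            if wt_val <= 0:
                continue  # wildtype not reactive in this sample
            diff = wt_val - block[samp].to_numpy(dtype=float)
            run = _single_epitope_run(diff, rel_threshold * wt_val)
            if run is None:
                continue
            mid = (run[0] + run[1] - 1) // 2
            row = np.full(grid, np.nan)
            shift = center - mid
            lo, hi = shift, shift + len(diff)
            row[max(lo, 0): min(hi, grid)] = diff[max(-lo, 0): len(diff) - max(hi - grid, 0)]
            aligned.append(row)
    if not aligned:
        return AlanineProfile(np.empty((0, grid)), np.full(grid, np.nan), float("nan"),
                              0, "no single-epitope curves found")
    curves = np.vstack(aligned)
    have_data = (~np.isnan(curves)).sum(axis=0) > 0
    mean_curve = np.zeros(grid)  # grid edges no curve reaches carry zero mass
    mean_curve[have_data] = np.nanmean(curves[:, have_data], axis=0)
    width = mass_width(mean_curve, center, mass_fraction)
    return AlanineProfile(curves, mean_curve, width, len(aligned))
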