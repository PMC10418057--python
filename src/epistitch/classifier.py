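"""Random-forest epitope classifier over composition features.

A binary classifier is trained on scan-library reactivity data: 15-mers (or
longer sub-peptides) of immunodominant wildtype 56-mers, labelled reactive if
two or more cohort samples show a positive log hit-fold-change, with
non-reactive, high-bead-background peptides as negatives.  The model is a
100-tree random forest over the 556 composition features with a fixed random
state for reproducibility; out-of-bag probabilities provide an internal
performance estimate.  Train/test splitting is done at the level of wildtype
parents so that near-duplicate sub-sequences never straddle the split.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .alphabets import DEFAULT_SCHEME, AlphabetScheme
from .features import N_FEATURES, feature_names, featurize_many

#: Columns of a scan-reactivity table that are metadata, not sample values.
_META_COLS = {"seq", "wildtype_id", "k", "start", "bead_count"}


@dataclass
class TrainingExample:
    """One labelled sub-peptide.

    ``label`` 1 requires reactivity (log hit-fold-change > 0) in at least two
    samples; ``label`` 0 requires reactivity in none.
    """

    seq: str
    label: int
    wildtype_id: str
    n_reactive_samples: int
    bead_count: int = 0


def _sample_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in _META_COLS]


def build_training_set(
    kmer_reactivity: pd.DataFrame, bead_counts: pd.DataFrame
) -> list[TrainingExample]:
    """Assemble a balanced training set from scan reactivity and bead counts.

    Positives are sub-peptides reactive (value > 0) in >= 2 samples.
    Negative candidates are sub-peptides with zero reactive samples; they are
    ranked by descending bead-background count (summed across bead replicates,
    ties broken lexicographically by sequence) and the top ``n_positives`` are
    taken, yielding a balanced set.  Peptides reactive in exactly one sample
    belong to neither class.

    Parameters
    ----------
    kmer_reactivity:
        Columns ``seq``, ``wildtype_id`` plus one numeric log-hfc column per
        sample (any other of ``k``/``start`` are ignored as metadata).
    bead_counts:
        Columns ``seq``, ``count``.
    """
    for col in ("seq", "wildtype_id"):
        if col not in kmer_reactivity.columns:
            raise ValueError(f"kmer_reactivity must have a {col!r} column")
    samples = _sample_columns(kmer_reactivity)
    if not samples:
        raise ValueError("kmer_reactivity has no sample columns")
    n_reactive = (kmer_reactivity[samples].to_numpy() > 0).sum(axis=1)

    pos_rows = kmer_reactivity.loc[n_reactive >= 2]
    positives = [
        TrainingExample(r.seq, 1, str(r.wildtype_id), int(n))
        for r, n in zip(pos_rows.itertuples(index=False), n_reactive[n_reactive >= 2])
    ]

    bead = bead_counts.groupby("seq", as_index=True)["count"].sum()
    neg_rows = kmer_reactivity.loc[n_reactive == 0].copy()
    neg_rows = neg_rows.drop_duplicates(subset="seq")
    neg_rows["bead"] = neg_rows["seq"].map(bead).fillna(0).astype(int)
    neg_rows = neg_rows.sort_values(["bead", "seq"], ascending=[False, True])

    if len(neg_rows) < len(positives):
        raise ValueError(
            f"not enough non-reactive peptides to balance the set: "
            f"{len(positives)} positives but only {len(neg_rows)} candidates"
        )
    negatives = [
        TrainingExample(r.seq, 0, str(r.wildtype_id), 0, int(r.bead))
        for r in neg_rows.head(len(positives)).itertuples(index=False)
    ]
    return positives + negatives


def split_by_wildtype(
    examples: list[TrainingExample], test_fraction: float = 0.05, seed: int = 0
) -> tuple[list[TrainingExample], list[TrainingExample]]:
    """Split examples into train/test with disjoint wildtype parents.

    Whole wildtype groups are assigned to the test set, in seeded random
    order, until it holds at least ``ceil(test_fraction * n)`` examples.
    """
    if not 0 <= test_fraction < 1:
        raise ValueError("test_fraction must be in [0, 1)")
    if test_fraction == 0:
        return list(examples), []
    groups: dict[str, list[TrainingExample]] = {}
    for ex in examples:
        groups.setdefault(ex.wildtype_id, []).append(ex)
    if len(groups) < 2:
        raise ValueError("cannot split: all examples share a single wildtype")
    target = math.ceil(test_fraction * len(examples))
    order = sorted(groups)
    np.random.default_rng(seed).shuffle(order)
    test: list[TrainingExample] = []
    taken: set[str] = set()
    for wt in order:
        if len(test) >= target:
            break
        test.extend(groups[wt])
        taken.add(wt)
    train = [ex for ex in examples if ex.wildtype_id not in taken]
    return train, test


@dataclass
class EpitopeModel:
    """A trained per-length epitope probability model."""

    peptide_length: int
    forest: RandomForestClassifier
    seed: int
    scheme: AlphabetScheme = field(default=DEFAULT_SCHEME, repr=False)
    oob_auc: float = float("nan")

    # -- prediction ------------------------------------------------------
    def predict_epitope_prob(self, seq: str) -> float:
        """Probability (fraction of trees) that ``seq`` contains an epitope."""
        if len(seq) != self.peptide_length:
            raise ValueError(
                f"expected a {self.peptide_length}-mer, got length {len(seq)}"
            )
        return float(self.predict_many([seq])[0])

    def predict_many(self, seqs) -> np.ndarray:
        X = featurize_many(seqs, self.scheme)
        return self.forest.predict_proba(X.to_numpy())[:, 1]

    def score_long_peptide(self, seq: str) -> float:
        """Mean epitope probability over all length-k windows (step 1)."""
        k = self.peptide_length
        if len(seq) < k:
            raise ValueError(f"sequence shorter ({len(seq)}) than model length {k}")
        windows = [seq[i : i + k] for i in range(len(seq) - k + 1)]
        return float(self.predict_many(windows).mean())

    # -- introspection ---------------------------------------------------
    def feature_importance(self) -> list[tuple[str, float]]:
        """Impurity-based importances, descending; they sum to 1."""
        if not hasattr(self.forest, "feature_importances_"):
            raise ValueError("model has not been trained")
        imp = self.forest.feature_importances_
        names = feature_names(self.scheme)
        order = np.argsort(-imp, kind="stable")
        return [(names[i], float(imp[i])) for i in order]

    # -- persistence -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        joblib.dump(self.forest, path)
        sidecar = {
            "peptide_length": self.peptide_length,
            "seed": self.seed,
            "oob_auc": None if math.isnan(self.oob_auc) else self.oob_auc,
            "n_features": N_FEATURES,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "EpitopeModel":
        path = Path(path)
        forest = joblib.load(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        oob = meta.get("oob_auc")
        return cls(
            peptide_length=int(meta["peptide_length"]),
            forest=forest,
            seed=int(meta["seed"]),
            oob_auc=float("nan") if oob is None else float(oob),
        )


def train_model(
    examples: list[TrainingExample],
    k: int = 15,
    seed: int = 42,
    scheme: AlphabetScheme = DEFAULT_SCHEME,
) -> EpitopeModel:
    """Train a 100-tree random forest on featurized examples of length ``k``.

    All hyperparameters are scikit-learn defaults apart from the fixed random
    state; out-of-bag probability estimates are recorded and summarized as an
    OOB AUC.
    """
    labels = np.array([ex.label for ex in examples], dtype=int)
    if len(examples) < 4 or len(set(labels.tolist())) < 2:
        raise ValueError("need at least 2 examples of each class")
    bad = [ex for ex in examples if len(ex.seq) != k]
    if bad:
        raise ValueError(f"{len(bad)} examples are not length {k} (e.g. {bad[0].seq!r})")
    X = featurize_many([ex.seq for ex in examples], scheme).to_numpy()
    forest = RandomForestClassifier(
        n_estimators=100, random_state=seed, oob_score=True, n_jobs=1
    )
    forest.fit(X, labels)
    oob_prob = forest.oob_decision_function_[:, 1]
    ok = ~np.isnan(oob_prob)
    oob_auc = float("nan")
    if ok.sum() >= 2 and len(set(labels[ok].tolist())) == 2:
        _, _, oob_auc = roc_curve(labels[ok], oob_prob[ok])
    return EpitopeModel(k, forest, seed, scheme, oob_auc)


def roc_curve(labels, scores) -> tuple[np.ndarray, np.ndarray, float]:
    """Empirical ROC curve and trapezoidal AUC.

    With midrank tie handling the AUC equals the normalized Mann-Whitney
    U statistic.  Requires both classes present.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    classes = set(np.unique(labels).tolist())
    if classes != {0, 1}:
        raise ValueError(f"labels must contain both classes 0 and 1, got {classes}")
    fpr, tpr, _ = _sk_roc_curve(labels, scores)
    return fpr, tpr, float(_sk_auc(fpr, tpr))
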