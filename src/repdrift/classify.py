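"""Repertoire classification from V-gene / J-gene / CDRH3-length usage.

A repertoire sample is distilled to a fixed-length feature vector: the
concatenation of its V-gene frequency distribution, J-gene frequency
distribution and CDRH3-length frequency distribution (lengths 5-35 AA), each
block summing to 1. Genes absent from the vocabulary map to a per-block
``OTHER`` bucket. A one-versus-rest linear-kernel support-vector machine
(C = 1.0, features used as-is) classifies samples by (subject, timepoint);
evaluation is leave-one-replicate-out: for each biological replicate held
out in rotation, the classifier trains on feature vectors from the remaining
replicates and scores the held-out ones, and per-class ROC AUC is computed
from the pooled decision scores.

``joint_features=True`` switches to the joint (V, J, length) contingency
frequencies instead of the three marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .errors import ValidationError

__all__ = [
    "FeatureVocabulary",
    "featurize",
    "RepertoireClassifier",
    "evaluate_loro",
    "LoroResult",
]

OTHER = "OTHER"
CDRH3_LENGTH_RANGE = range(5, 36)


@dataclass
class FeatureVocabulary:
    """Fixed feature vocabulary defining the vector layout."""

    v_genes: list
    j_genes: list
    lengths: list = field(default_factory=lambda: list(CDRH3_LENGTH_RANGE))
    joint: bool = False

    @classmethod
    def from_records(cls, records: pd.DataFrame, joint: bool = False) -> "FeatureVocabulary":
        return cls(v_genes=sorted(records["v_gene"].unique()),
                   j_genes=sorted(records["j_gene"].unique()), joint=joint)

    def feature_names(self) -> list:
        if self.joint:
            return [f"{v}|{j}|{l}" for v in self.v_genes + [OTHER]
                    for j in self.j_genes + [OTHER] for l in self.lengths + [OTHER]]
        return ([f"v:{v}" for v in self.v_genes + [OTHER]]
                + [f"j:{j}" for j in self.j_genes + [OTHER]]
                + [f"len:{l}" for l in self.lengths + [OTHER]])

    def __len__(self) -> int:
        if self.joint:
            return (len(self.v_genes) + 1) * (len(self.j_genes) + 1) * (len(self.lengths) + 1)
        return len(self.v_genes) + len(self.j_genes) + len(self.lengths) + 3


def _bucket(values: pd.Series, vocabulary: list) -> np.ndarray:
    """Index of each value in vocabulary, with the OTHER bucket last."""
    lookup = {v: i for i, v in enumerate(vocabulary)}
    return np.asarray([lookup.get(v, len(vocabulary)) for v in values], dtype=int)


def featurize(records: pd.DataFrame, vocabulary: FeatureVocabulary,
              n_sequences: Optional[int] = None,
              rng: Optional[np.random.Generator] = None,
              with_replacement: bool = False,
              return_ids: bool = False):
    """Feature vector from a (sub)sample of a repertoire.

    When ``n_sequences`` is given, that many records are subsampled (without
    replacement by default; pass ``with_replacement=True`` to allow
    ``n_sequences`` above the census size). Frequencies are computed on the
    subsample; each block sums to 1. ``return_ids`` additionally returns the
    sequence_ids used, for leakage auditing.
    """
    if records.empty:
        raise ValidationError("cannot featurize an empty record collection")
    if n_sequences is not None:
        if n_sequences > len(records) and not with_replacement:
            raise ValidationError(
                f"requested {n_sequences} sequences from {len(records)} records; "
                "pass with_replacement=True to oversample")
        rng = rng if rng is not None else np.random.default_rng(0)
        idx = rng.choice(len(records), size=int(n_sequences), replace=with_replacement)
        records = records.iloc[np.sort(idx)]

    vi = _bucket(records["v_gene"], vocabulary.v_genes)
    ji = _bucket(records["j_gene"], vocabulary.j_genes)
    li = _bucket(records["cdrh3_length"], vocabulary.lengths)
    n = len(records)
    if vocabulary.joint:
        nj = len(vocabulary.j_genes) + 1
        nl = len(vocabulary.lengths) + 1
        flat = (vi * nj + ji) * nl + li
        vec = np.bincount(flat, minlength=len(vocabulary)).astype(float) / n
    else:
        v_block = np.bincount(vi, minlength=len(vocabulary.v_genes) + 1).astype(float) / n
        j_block = np.bincount(ji, minlength=len(vocabulary.j_genes) + 1).astype(float) / n
        l_block = np.bincount(li, minlength=len(vocabulary.lengths) + 1).astype(float) / n
        vec = np.concatenate([v_block, j_block, l_block])
    if return_ids:
        return vec, frozenset(records["sequence_id"])
    return vec


class RepertoireClassifier(BaseEstimator, ClassifierMixin):
    """One-versus-rest linear-kernel SVM over repertoire feature vectors.

    sklearn-compatible estimator: ``fit(X, y)`` on featurized samples,
    ``decision_function`` gives per-class one-vs-rest scores. Features are
    already normalized frequency blocks, so no scaling is applied.
    """

    def __init__(self, C: float = 1.0, kernel: str = "linear"):
        self.C = C
        self.kernel = kernel

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValidationError("X must be 2-D with one label per row")
        self.estimator_ = OneVsRestClassifier(SVC(C=self.C, kernel=self.kernel))
        self.estimator_.fit(X, y)
        self.classes_ = self.estimator_.classes_
        return self

    def decision_function(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.decision_function(np.asarray(X, dtype=float))

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict(np.asarray(X, dtype=float))


@dataclass
class LoroResult:
    """Leave-one-replicate-out evaluation output.

    ``auc_table``: one row per (class, size) with the mean one-vs-rest ROC
    AUC over repeats; ``per_repeat``: the underlying per-repeat AUCs;
    ``audit``: one row per (size, repeat, rotation) with the train/test
    sequence-id counts and ``n_leaked``, the size of their intersection
    (0 by construction; asserted in tests).
    """

    auc_table: pd.DataFrame
    per_repeat: pd.DataFrame
    audit: pd.DataFrame

    @property
    def max_leakage(self) -> int:
        return int(self.audit["n_leaked"].max()) if len(self.audit) else 0


def evaluate_loro(records: pd.DataFrame, size_grid: Sequence[int] = (10, 50, 100, 500, 1000),
                  n_repeats: int = 5, seed: int = 0,
                  joint_features: bool = False,
                  with_replacement: bool = False) -> LoroResult:
    """Leave-one-replicate-out ROC AUC versus training/test sample size.

    Classes are (subject, timepoint) pairs; samples are biological
    replicates. For each rotation one replicate label is held out across all
    classes; one feature vector per (class, replicate) is drawn at each size
    from ``size_grid``; the classifier trains on the non-held-out vectors and
    scores the held-out ones. Per-class AUC is computed from scores pooled
    over rotations, then averaged over ``n_repeats`` independent subsampling
    repeats. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    df = records.copy()
    df["class_label"] = df["subject"].astype(str) + "@" + df["timepoint"].astype(str)
    classes = sorted(df["class_label"].unique())
    if len(classes) < 2:
        raise ValidationError("classification requires >= 2 (subject, timepoint) classes")
    replicate_sets = {c: sorted(df.loc[df["class_label"] == c, "replicate"].unique())
                      for c in classes}
    for c, reps in replicate_sets.items():
        if len(reps) < 2:
            raise ValidationError(f"class {c} has a single replicate; need >= 2")
    rotations = sorted(set.intersection(*(set(r) for r in replicate_sets.values())))
    if len(rotations) < 2:
        raise ValidationError("need >= 2 replicate labels common to all classes")

    vocab = FeatureVocabulary.from_records(df, joint=joint_features)
    groups = {(c, r): grp for (c, r), grp in df.groupby(["class_label", "replicate"], sort=True)}

    per_repeat_rows = []
    audit_rows = []
    for size in size_grid:
        for repeat in range(n_repeats):
            scores_by_class = {c: ([], []) for c in classes}  # (y_true, y_score)
            for held_out in rotations:
                X_train, y_train, train_ids = [], [], set()
                X_test, y_test, test_ids = [], [], set()
                for c in classes:
                    for rep in replicate_sets[c]:
                        grp = groups[(c, rep)]
                        vec, ids = featurize(grp, vocab, n_sequences=min(size, len(grp)),
                                             rng=rng, with_replacement=with_replacement,
                                             return_ids=True)
                        if rep == held_out:
                            X_test.append(vec); y_test.append(c); test_ids |= ids
                        else:
                            X_train.append(vec); y_train.append(c); train_ids |= ids
                clf = RepertoireClassifier().fit(np.asarray(X_train), np.asarray(y_train))
                dec = clf.decision_function(np.asarray(X_test))
                if dec.ndim == 1:  # binary: score for classes_[1]
                    dec = np.column_stack([-dec, dec])
                for ci, c in enumerate(clf.classes_):
                    for yt, row in zip(y_test, dec):
                        scores_by_class[c][0].append(1 if yt == c else 0)
                        scores_by_class[c][1].append(row[ci])
                audit_rows.append({
                    "size": size, "repeat": repeat, "held_out": held_out,
                    "n_train_ids": len(train_ids), "n_test_ids": len(test_ids),
                    "n_leaked": len(train_ids & test_ids),
                })
            for c in classes:
                y_true, y_score = scores_by_class[c]
                auc = roc_auc_score(y_true, y_score)
                per_repeat_rows.append({"class_label": c, "size": size,
                                        "repeat": repeat, "auc": float(auc)})

    per_repeat = pd.DataFrame(per_repeat_rows)
    auc_table = (per_repeat.groupby(["class_label", "size"], as_index=False)["auc"]
                 .mean().rename(columns={"auc": "mean_auc"}))
    return LoroResult(auc_table=auc_table, per_repeat=per_repeat,
                      audit=pd.DataFrame(audit_rows))
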