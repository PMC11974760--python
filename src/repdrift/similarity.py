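"""Repertoire similarity on (V gene, J gene, CDRH3 length) species.

For ecological-style similarity analysis each rearrangement is reduced to a
*species*: its (V gene, J gene, CDRH3 length) combination. The Morisita-Horn
index between two species count vectors x, y is

    CH = 2 * sum_i x_i * y_i
         -------------------------------------------
         (sum_i x_i^2 / X^2 + sum_i y_i^2 / Y^2) * X * Y

with X = sum_i x_i and Y = sum_i y_i, summed over the union S of species with
nonzero count in either sample (species absent from one side contribute
x_i * y_i = 0). CH is 0 for disjoint species sets and 1 for identical
frequency distributions.

Bootstrap rarefaction (``subsampled_similarity``) resamples each side with
replacement at a grid of depths; because the resampling is with replacement,
depths exceeding the census size are permitted (they are flagged in the
output). Confidence intervals are 2.5/97.5 percentiles over the bootstrap
draws (default 20 draws).

Replicate clustering follows the similarity-matrix convention: rows of the
pairwise CH matrix are clustered by single linkage under the Euclidean row
metric (``metric="euclidean"``, the default); ``metric="one_minus_ch"``
clusters 1 - CH as a precomputed distance instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, leaves_list
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError

__all__ = [
    "species_reduce",
    "morisita_horn",
    "subsampled_similarity",
    "pairwise_matrix",
    "cluster_replicates",
    "stratified_similarity",
]

SPECIES_COLUMNS = ("v_gene", "j_gene", "cdrh3_length")


def species_reduce(records: pd.DataFrame, weight_by_duplicates: bool = False) -> pd.Series:
    """Species count vector: records reduced to (V gene, J gene, CDRH3 length).

    Returns a Series indexed by the species triple. By default each record
    counts once; ``weight_by_duplicates`` sums ``duplicate_count`` instead.
    """
    if records.empty:
        raise ValidationError("cannot reduce an empty record collection to species")
    if weight_by_duplicates:
        counts = records.groupby(list(SPECIES_COLUMNS), sort=True)["duplicate_count"].sum()
    else:
        counts = records.groupby(list(SPECIES_COLUMNS), sort=True).size()
    counts.name = "count"
    return counts


def _align(x: pd.Series, y: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    union = x.index.union(y.index)
    return (x.reindex(union, fill_value=0).to_numpy(dtype=float),
            y.reindex(union, fill_value=0).to_numpy(dtype=float))


def _ch_from_arrays(xv: np.ndarray, yv: np.ndarray) -> float:
    X = float(xv.sum())
    Y = float(yv.sum())
    if X <= 0 or Y <= 0:
        raise ValidationError("Morisita-Horn requires distributions with positive totals")
    # algebraically identical to 2*sum(xy) / ((sum(x^2)/X^2 + sum(y^2)/Y^2) * X * Y)
    # but exact for integer counts: CH(x,x) == 1.0 and CH(disjoint) == 0.0 exactly
    num = 2.0 * float(np.dot(xv, yv)) * X * Y
    den = float(np.dot(xv, xv)) * Y * Y + float(np.dot(yv, yv)) * X * X
    return num / den


def morisita_horn(x, y) -> float:
    """Morisita-Horn similarity CH in [0, 1] between two species count vectors.

    ``x`` and ``y`` may be Series from :func:`species_reduce`, plain dicts or
    aligned numpy arrays. Symmetric; 1 for identical distributions, 0 for
    disjoint species sets.
    """
    if isinstance(x, dict):
        x = pd.Series(x)
    if isinstance(y, dict):
        y = pd.Series(y)
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        xv, yv = _align(x, y)
    else:
        xv = np.asarray(x, dtype=float)
        yv = np.asarray(y, dtype=float)
        if xv.shape != yv.shape:
            raise ValidationError("array inputs to morisita_horn must be pre-aligned")
    return _ch_from_arrays(xv, yv)


def _species_codes(records: pd.DataFrame) -> np.ndarray:
    """Integer species code per record (codes shared only within one call)."""
    key = (records["v_gene"].astype(str) + "|" + records["j_gene"].astype(str)
           + "|" + records["cdrh3_length"].astype(str))
    return pd.factorize(key)[0]


@dataclass
class SimilarityCurve:
    """Bootstrap Morisita-Horn similarity as a function of sampling depth."""

    table: pd.DataFrame  # depth, mean_ch, ci_low, ci_high, n_boot, exceeds_census

    def __iter__(self):
        return iter(self.table.itertuples(index=False))


def subsampled_similarity(records_a: pd.DataFrame, records_b: pd.DataFrame,
                          depth_grid: Sequence[int], n_boot: int = 20,
                          seed: int = 0) -> SimilarityCurve:
    """Mean Morisita-Horn similarity with 95% CI at each subsampling depth.

    At each depth ``d``, both sides are independently resampled with
    replacement ``n_boot`` times; CH is computed per draw pair. Depths above
    a side's census size are allowed (resampling is with replacement) and
    flagged via ``exceeds_census``.
    """
    depth_grid = [int(d) for d in depth_grid]
    if not depth_grid:
        raise ValidationError("depth grid must be non-empty")
    if min(depth_grid) < 10:
        raise ValidationError("depths below 10 are not meaningful; use >= 10")
    if n_boot < 2:
        raise ValidationError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)

    # joint integer coding so count vectors align by position
    both = pd.concat([records_a, records_b], ignore_index=True)
    codes = _species_codes(both)
    n_species = int(codes.max()) + 1
    codes_a = codes[: len(records_a)]
    codes_b = codes[len(records_a):]

    rows = []
    for depth in depth_grid:
        ch_vals = np.empty(n_boot)
        for b in range(n_boot):
            xa = np.bincount(rng.choice(codes_a, size=depth, replace=True),
                             minlength=n_species).astype(float)
            yb = np.bincount(rng.choice(codes_b, size=depth, replace=True),
                             minlength=n_species).astype(float)
            ch_vals[b] = _ch_from_arrays(xa, yb)
        rows.append({
            "depth": depth,
            "mean_ch": float(ch_vals.mean()),
            "ci_low": float(np.percentile(ch_vals, 2.5)),
            "ci_high": float(np.percentile(ch_vals, 97.5)),
            "n_boot": n_boot,
            "exceeds_census": depth > min(len(records_a), len(records_b)),
        })
    return SimilarityCurve(pd.DataFrame(rows))


def pairwise_matrix(samples: Mapping[str, pd.DataFrame],
                    weight_by_duplicates: bool = False) -> pd.DataFrame:
    """Symmetric matrix of pairwise Morisita-Horn similarities (diagonal 1)."""
    labels = sorted(samples)
    dists = {lab: species_reduce(samples[lab], weight_by_duplicates) for lab in labels}
    mat = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            ch = morisita_horn(dists[a], dists[b])
            mat.loc[a, b] = ch
            mat.loc[b, a] = ch
    return mat


def cluster_replicates(matrix: pd.DataFrame, metric: str = "euclidean"):
    """Single-linkage clustering of the similarity matrix; returns (Z, leaves).

    ``metric="euclidean"`` (default) clusters the matrix *rows* under the
    Euclidean metric; ``metric="one_minus_ch"`` uses 1 - CH directly as a
    precomputed distance. Rows are sorted lexicographically by label first so
    leaf order is deterministic.

    Returns the scipy linkage matrix and the leaf labels in dendrogram order.
    """
    if matrix.shape[0] != matrix.shape[1]:
        raise ValidationError("similarity matrix must be square")
    matrix = matrix.sort_index(axis=0).sort_index(axis=1)
    if metric == "euclidean":
        condensed = pdist(matrix.to_numpy(), metric="euclidean")
    elif metric == "one_minus_ch":
        condensed = squareform(1.0 - matrix.to_numpy(), checks=False)
    else:
        raise ValidationError(f"unknown clustering metric {metric!r}")
    Z = linkage(condensed, method="single")
    order = leaves_list(Z)
    return Z, [matrix.index[i] for i in order]


#: default strata: all sequences, barely mutated IgM (proxy for naive),
#: mutated IgM, and IgG; the mutation cut is "fewer than two" vs ">= two".
DEFAULT_STRATA = {
    "all": lambda df: pd.Series(True, index=df.index),
    "IgM_lt2mut": lambda df: (df["isotype"] == "IgM") & (df["v_mutation_count"] < 2),
    "IgM_ge2mut": lambda df: (df["isotype"] == "IgM") & (df["v_mutation_count"] >= 2),
    "IgG": lambda df: df["isotype"] == "IgG",
}


def stratified_similarity(records: pd.DataFrame, strata: Mapping | None = None,
                          weight_by_duplicates: bool = False):
    """Intra- vs inter-timepoint replicate similarity per stratum.

    For each stratum (default: all / IgM with <2 V mutations / IgM with >=2 /
    IgG) and each subject, computes CH between every pair of biological
    replicate samples of that subject and labels the pair ``intra`` (same
    timepoint) or ``inter`` (across timepoints).

    Returns ``(pairs, summary)``: ``pairs`` has one row per replicate pair
    with its CH; ``summary`` gives median and quartiles per
    (subject, stratum, pair_type). Strata empty for a subject are recorded in
    ``summary`` with NaN statistics rather than raising.
    """
    strata = dict(strata) if strata is not None else dict(DEFAULT_STRATA)
    pair_rows = []
    summary_rows = []
    for subject, sub in records.groupby("subject", sort=True):
        for name, mask_fn in strata.items():
            stratum = sub[mask_fn(sub)]
            groups = {
                (tp, rep): grp
                for (tp, rep), grp in stratum.groupby(["timepoint", "replicate"], sort=True)
                if not grp.empty
            }
            labels = sorted(groups)
            dists = {lab: species_reduce(groups[lab], weight_by_duplicates) for lab in labels}
            ch_by_type = {"intra": [], "inter": []}
            for i, a in enumerate(labels):
                for b in labels[i + 1:]:
                    pair_type = "intra" if a[0] == b[0] else "inter"
                    ch = morisita_horn(dists[a], dists[b])
                    ch_by_type[pair_type].append(ch)
                    pair_rows.append({
                        "subject": subject, "stratum": name, "pair_type": pair_type,
                        "sample_a": "/".join(a), "sample_b": "/".join(b), "ch": ch,
                    })
            for pair_type, vals in ch_by_type.items():
                arr = np.asarray(vals, dtype=float)
                summary_rows.append({
                    "subject": subject, "stratum": name, "pair_type": pair_type,
                    "n_pairs": len(arr),
                    "median_ch": float(np.median(arr)) if len(arr) else float("nan"),
                    "q1_ch": float(np.percentile(arr, 25)) if len(arr) else float("nan"),
                    "q3_ch": float(np.percentile(arr, 75)) if len(arr) else float("nan"),
                })
    return pd.DataFrame(pair_rows), pd.DataFrame(summary_rows)
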