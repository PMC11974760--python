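"""Turnover and persistence between timepoints; persistent/public clonotypes.

Turnover between two timepoints is computed over *species*, where the species
unit is either the clonotype (V gene, J gene, CDRH3 amino acids) or the unique
nucleotide sequence (full nucleotide junction identity):

    turnover%    = 100 * (appearing + disappearing) / total species observed
    persistence% = 100 - turnover% = 100 * shared / total

with appearing = species present only at the later timepoint, disappearing =
present only at the earlier one, and total = the union. Nucleotide identity
refines clonotype identity, so sequence-level persistence can never exceed
clonotype-level persistence on the same data.

Sharing-vs-depth curves quantify how observed overlap grows with sampling
depth (bootstrap resampling with replacement per depth); observed sharing at
finite depth underestimates true overlap and increases with depth, so these
curves are a diagnostic, not a depth-corrected estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .clonotypes import clonotype_keys, collapse, public_clonotypes
from .errors import ValidationError

__all__ = [
    "PersistenceReport",
    "persistence_report",
    "sharing_vs_depth",
    "characterize_persistent",
    "persistent_public",
    "logo_matrix",
    "CharacterizationSummary",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

LEVELS = ("clonotype", "sequence")


def _species_set(records: pd.DataFrame, level: str) -> set:
    if level == "clonotype":
        return set(clonotype_keys(records))
    if level == "sequence":
        return set(records["junction"])
    raise ValidationError(f"unknown persistence level {level!r}; choose from {LEVELS}")


@dataclass
class PersistenceReport:
    """Appearing/disappearing/shared species counts and derived percentages."""

    level: str
    n_appearing: int
    n_disappearing: int
    n_shared: int

    @property
    def n_total(self) -> int:
        return self.n_appearing + self.n_disappearing + self.n_shared

    @property
    def turnover_pct(self) -> float:
        return 100.0 * (self.n_appearing + self.n_disappearing) / self.n_total

    @property
    def persistence_pct(self) -> float:
        return 100.0 - self.turnover_pct

    def as_dict(self) -> dict:
        return {
            "level": self.level,
            "n_appearing": self.n_appearing,
            "n_disappearing": self.n_disappearing,
            "n_shared": self.n_shared,
            "n_total": self.n_total,
            "turnover_pct": self.turnover_pct,
            "persistence_pct": self.persistence_pct,
        }


def persistence_report(records_t1: pd.DataFrame, records_t2: pd.DataFrame,
                       level: str = "clonotype") -> PersistenceReport:
    """Turnover/persistence between two timepoints at the chosen species level."""
    if records_t1.empty or records_t2.empty:
        raise ValidationError("persistence requires non-empty records at both timepoints")
    s1 = _species_set(records_t1, level)
    s2 = _species_set(records_t2, level)
    return PersistenceReport(
        level=level,
        n_appearing=len(s2 - s1),
        n_disappearing=len(s1 - s2),
        n_shared=len(s1 & s2),
    )


def sharing_vs_depth(records_t1: pd.DataFrame, records_t2: pd.DataFrame,
                     depth_grid: Sequence[int], n_boot: int = 20, seed: int = 0,
                     level: str = "clonotype") -> pd.DataFrame:
    """Mean fraction of subsampled t1 species also found in subsampled t2.

    Per depth, both timepoints are resampled with replacement ``n_boot``
    times; the shared fraction is |S1 ∩ S2| / |S1| over the subsampled
    species sets. The expectation is nondecreasing in depth.
    """
    depth_grid = [int(d) for d in depth_grid]
    if not depth_grid:
        raise ValidationError("depth grid must be non-empty")
    if n_boot < 2:
        raise ValidationError("n_boot must be >= 2")
    if level == "clonotype":
        sp1 = clonotype_keys(records_t1).to_numpy()
        sp2 = clonotype_keys(records_t2).to_numpy()
    elif level == "sequence":
        sp1 = records_t1["junction"].to_numpy()
        sp2 = records_t2["junction"].to_numpy()
    else:
        raise ValidationError(f"unknown persistence level {level!r}; choose from {LEVELS}")
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depth_grid:
        fracs = np.empty(n_boot)
        for b in range(n_boot):
            s1 = set(rng.choice(sp1, size=depth, replace=True))
            s2 = set(rng.choice(sp2, size=depth, replace=True))
            fracs[b] = len(s1 & s2) / len(s1)
        rows.append({
            "depth": depth,
            "mean_shared_fraction": float(fracs.mean()),
            "ci_low": float(np.percentile(fracs, 2.5)),
            "ci_high": float(np.percentile(fracs, 97.5)),
            "se_mean": float(fracs.std(ddof=1) / np.sqrt(n_boot)),
            "n_boot": n_boot,
        })
    return pd.DataFrame(rows)


def logo_matrix(cdrh3_sequences: Sequence[str], cdrh3_length: int) -> pd.DataFrame:
    """Position x amino-acid frequency matrix for CDRH3s of one fixed length.

    Rows are the 20 amino acids, columns are positions 1..length; each column
    sums to 1. Raises if no sequence has the requested length.
    """
    seqs = [s for s in cdrh3_sequences if len(s) == cdrh3_length]
    if not seqs:
        raise ValidationError(f"no CDRH3 sequences of length {cdrh3_length}")
    mat = np.zeros((len(AA_ALPHABET), cdrh3_length))
    aa_index = {aa: i for i, aa in enumerate(AA_ALPHABET)}
    for seq in seqs:
        for pos, aa in enumerate(seq):
            if aa in aa_index:
                mat[aa_index[aa], pos] += 1
    mat /= mat.sum(axis=0, keepdims=True)
    return pd.DataFrame(mat, index=list(AA_ALPHABET),
                        columns=[f"pos{p + 1}" for p in range(cdrh3_length)])


#: per-clonotype measures compared between shared/unshared groups
_MEASURES = ("cdrh3_length", "igg_frequency", "mean_v_mutations", "multi_replicate")


@dataclass
class CharacterizationSummary:
    """Per-group clonotype summaries and rank-test comparisons.

    ``groups`` maps group name -> per-clonotype DataFrame (one row per
    clonotype-timepoint observation with the four compared measures);
    ``tests`` holds two-sided Mann-Whitney results with Benjamini-Hochberg
    adjusted p-values; ``logos`` maps group name -> logo matrix at
    ``logo_length`` (missing when a group has no CDRH3 of that length).
    ``missing_groups`` lists groups of size zero.
    """

    groups: dict
    tests: pd.DataFrame
    logos: dict
    logo_length: int
    missing_groups: list = field(default_factory=list)

    def group_sizes(self) -> dict:
        return {name: len(df) for name, df in self.groups.items()}


def _group_measures(table: pd.DataFrame) -> pd.DataFrame:
    out = table.loc[:, ["cdrh3_length", "igg_frequency", "mean_v_mutations"]].copy()
    out["multi_replicate"] = (table["n_replicates_observed"] > 1).astype(float)
    return out


def _compare_groups(groups: dict, logo_length: int) -> CharacterizationSummary:
    groups = {name: _group_measures(df).assign(cdrh3_aa=df["cdrh3_aa"].to_numpy())
              for name, df in groups.items()}
    missing = [name for name, df in groups.items() if df.empty]
    test_rows = []
    names = list(groups)
    if len(names) == 2 and not missing:
        a, b = (groups[n] for n in names)
        pvals = []
        for measure in _MEASURES:
            stat, p = mannwhitneyu(a[measure], b[measure], alternative="two-sided")
            test_rows.append({
                "measure": measure,
                "group_a": names[0], "group_b": names[1],
                "median_a": float(a[measure].median()),
                "median_b": float(b[measure].median()),
                "mean_a": float(a[measure].mean()),
                "mean_b": float(b[measure].mean()),
                "u_statistic": float(stat),
                "p_value": float(p),
            })
            pvals.append(p)
        adj = multipletests(pvals, method="fdr_bh")[1]
        for row, p_adj in zip(test_rows, adj):
            row["p_adjusted"] = float(p_adj)
    tests = pd.DataFrame(test_rows)
    logos = {}
    for name, df in groups.items():
        seqs = df.loc[df["cdrh3_length"] == logo_length, "cdrh3_aa"]
        if len(seqs):
            logos[name] = logo_matrix(seqs.tolist(), logo_length)
    return CharacterizationSummary(
        groups=groups, tests=tests, logos=logos,
        logo_length=logo_length, missing_groups=missing)


def characterize_persistent(records_t1: pd.DataFrame, records_t2: pd.DataFrame,
                            logo_length: int = 13) -> CharacterizationSummary:
    """Compare shared (persistent) vs unshared clonotypes between timepoints.

    Clonotypes of each timepoint are grouped by whether they also occur at
    the other timepoint; each clonotype-timepoint observation contributes its
    CDRH3 length, per-clonotype IgG frequency, mean V-gene mutation count and
    multi-biological-replicate occurrence (within its own timepoint). Group
    differences are tested with two-sided Mann-Whitney rank tests,
    Benjamini-Hochberg corrected across the four measures. Sequence logos at
    ``logo_length`` are included per group.
    """
    t1 = collapse(records_t1)
    t2 = collapse(records_t2)
    shared_keys = set(t1.index) & set(t2.index)
    obs = pd.concat([t1, t2], axis=0)
    obs["shared"] = obs.index.isin(shared_keys)
    groups = {
        "shared": obs[obs["shared"]].copy(),
        "unshared": obs[~obs["shared"]].copy(),
    }
    return _compare_groups(groups, logo_length)


def persistent_public(subject_timepoint_records: Mapping[str, Mapping[str, pd.DataFrame]],
                      mode: str = "all", logo_length: int = 13):
    """Identify persistent public clonotypes and characterize them.

    ``subject_timepoint_records`` maps subject -> timepoint -> records. A
    clonotype is *public* if present in every subject (any timepoint) and
    *persistent within a subject* if present at every one of that subject's
    timepoints. ``mode="all"`` (default) requires persistence in every
    subject; ``mode="any"`` in at least one.

    Returns ``(persistent_public_set, summary)`` where the summary compares
    persistent-public against public-but-not-persistent clonotypes (CDRH3
    length and logo). Raises with fewer than two subjects.
    """
    if len(subject_timepoint_records) < 2:
        raise ValidationError("persistent-public analysis requires >= 2 subjects")
    if mode not in ("all", "any"):
        raise ValidationError(f"unknown persistent_public mode {mode!r}")

    per_subject_union: dict[str, set] = {}
    per_subject_persistent: dict[str, set] = {}
    union_tables = []
    for subject, by_tp in subject_timepoint_records.items():
        if len(by_tp) < 2:
            raise ValidationError(f"subject {subject!r} needs >= 2 timepoints")
        tp_sets = {tp: set(clonotype_keys(df)) for tp, df in by_tp.items()}
        per_subject_union[subject] = set.union(*tp_sets.values())
        per_subject_persistent[subject] = set.intersection(*tp_sets.values())
        union_tables.append(collapse(pd.concat(list(by_tp.values()), ignore_index=True)))

    public = public_clonotypes(per_subject_union)
    if mode == "all":
        persistent = set.intersection(*per_subject_persistent.values())
    else:
        persistent = set.union(*per_subject_persistent.values())
    pp = public & persistent

    all_obs = pd.concat(union_tables, axis=0)
    pub_obs = all_obs[all_obs.index.isin(public)]
    # one row per clonotype for length/logo comparison
    pub_obs = pub_obs[~pub_obs.index.duplicated(keep="first")].copy()
    groups = {
        "persistent_public": pub_obs[pub_obs.index.isin(pp)].copy(),
        "non_persistent_public": pub_obs[~pub_obs.index.isin(pp)].copy(),
    }
    summary = _compare_groups(groups, logo_length)
    return pp, summary
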