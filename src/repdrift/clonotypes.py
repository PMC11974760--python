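"""Clonotype collapsing and overlap set algebra.

A *clonotype* is the set of sequences using the same V gene, the same J gene
and encoding an identical CDRH3 amino-acid sequence. Keys are represented as
``"V|J|CDRH3"`` strings (hashable, orderable, exact string equality); allele
information is discarded by gene-level normalization upstream. A config switch
(``use_junction=True``) keys on the full IMGT junction instead of the
anchor-trimmed CDRH3, for sensitivity analysis; it is off by default.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .errors import ValidationError
from .io import ISOTYPES

__all__ = ["clonotype_keys", "collapse", "shared_clonotypes", "public_clonotypes"]


def clonotype_keys(records: pd.DataFrame, use_junction: bool = False) -> pd.Series:
    """Clonotype key per record: ``v_gene|j_gene|cdrh3_aa`` strings.

    Raises :class:`ValidationError` if any record has an empty CDRH3.
    """
    seq_col = "junction_aa" if use_junction else "cdrh3_aa"
    if (records[seq_col].str.len() == 0).any():
        raise ValidationError("record with empty CDRH3 cannot be clonotyped")
    return records["v_gene"] + "|" + records["j_gene"] + "|" + records[seq_col]


def collapse(records: pd.DataFrame, use_junction: bool = False) -> pd.DataFrame:
    """Collapse rearrangements into a clonotype table.

    Returns a DataFrame indexed by clonotype key with columns: ``v_gene``,
    ``j_gene``, ``cdrh3_aa``, ``cdrh3_length``, ``n_sequences`` (record
    count), ``total_duplicate_count`` (duplicate_count-weighted),
    ``n_replicates_observed`` (distinct biological replicates, identified by
    their (subject, timepoint, replicate) labels), per-isotype counts
    (``n_IgM``, ``n_IgG``, ...), ``igg_frequency`` and ``mean_v_mutations``.

    Raises :class:`ValidationError` on empty input.
    """
    if records.empty:
        raise ValidationError("cannot collapse an empty record collection")
    df = records.copy()
    df["clonotype"] = clonotype_keys(df, use_junction=use_junction)
    df["_replicate_key"] = df["subject"] + "/" + df["timepoint"] + "/" + df["replicate"]

    grouped = df.groupby("clonotype", sort=True)
    table = grouped.agg(
        v_gene=("v_gene", "first"),
        j_gene=("j_gene", "first"),
        cdrh3_aa=("cdrh3_aa", "first"),
        cdrh3_length=("cdrh3_length", "first"),
        n_sequences=("sequence_id", "size"),
        total_duplicate_count=("duplicate_count", "sum"),
        n_replicates_observed=("_replicate_key", "nunique"),
        mean_v_mutations=("v_mutation_count", "mean"),
    )
    iso = pd.crosstab(df["clonotype"], df["isotype"])
    for isotype in ISOTYPES:
        table[f"n_{isotype}"] = iso[isotype].reindex(table.index, fill_value=0) if isotype in iso else 0
    table["igg_frequency"] = table["n_IgG"] / table["n_sequences"]
    return table


def _keys(table) -> set:
    """Accept a clonotype table (index = keys), a Series of keys, or a set."""
    if isinstance(table, pd.DataFrame):
        return set(table.index)
    if isinstance(table, pd.Series):
        return set(table)
    return set(table)


def shared_clonotypes(table_a, table_b) -> tuple[set, set, set]:
    """Partition the union of two clonotype sets into (shared, only_a, only_b)."""
    a, b = _keys(table_a), _keys(table_b)
    return a & b, a - b, b - a


def public_clonotypes(tables_by_subject: Mapping[str, object]) -> set:
    """Clonotypes present in every subject's table.

    Raises :class:`ValidationError` with fewer than two subjects — publicness
    is defined by sharing across individuals.
    """
    if len(tables_by_subject) < 2:
        raise ValidationError("public clonotypes require tables from >= 2 subjects")
    sets = [_keys(t) for t in tables_by_subject.values()]
    return set.intersection(*sets)
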