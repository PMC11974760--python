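"""Read, write and validate annotated heavy-chain rearrangement tables.

A repertoire is represented throughout the package as a :class:`pandas.DataFrame`
with one row per rearrangement. Column naming follows the AIRR Rearrangement
schema where a field exists there (``sequence_id``, ``v_call``, ``j_call``,
``junction`` for the nucleotide junction, ``junction_aa``, ``duplicate_count``).
Provenance fields (``subject``, ``timepoint``, ``replicate``) and annotation
extensions (``isotype``, ``v_mutation_count``) are extension columns with plain
names, documented here.

Derived columns added on load:

``v_gene`` / ``j_gene``
    gene-level names: the allele call truncated at the first ``*``
    (``IGHV4-34*01`` -> ``IGHV4-34``). Clonotype identity is gene-level, not
    allele-level.
``cdrh3_aa`` / ``cdrh3_length``
    the IMGT junction minus its conserved first (Cys104) and last (Trp118/Phe)
    residues; every "CDRH3 length" statistic in the package uses this
    convention.

Validation on load checks that the nucleotide junction translates to the
amino-acid junction (standard codon table); failing rows are dropped, counted
and logged rather than aborting the load.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio.Seq import Seq

from .errors import ValidationError

logger = logging.getLogger(__name__)

ISOTYPES = ("IgM", "IgG", "IgA", "IgE", "IgD", "unknown")

#: Required columns per dialect. "airr" is the full schema the simulator
#: writes; "minimal" accepts bare annotation tables and fills defaults.
DIALECTS = {
    "airr": (
        "sequence_id",
        "subject",
        "timepoint",
        "replicate",
        "v_call",
        "j_call",
        "junction",
        "junction_aa",
        "isotype",
        "v_mutation_count",
        "duplicate_count",
    ),
    "minimal": ("sequence_id", "v_call", "j_call", "junction_aa"),
}

#: Optional columns carried through verbatim when present.
OPTIONAL_COLUMNS = ("d_call",)

_MINIMAL_DEFAULTS = {
    "subject": "",
    "timepoint": "",
    "replicate": "",
    "junction": "",
    "isotype": "unknown",
    "v_mutation_count": 0,
    "duplicate_count": 1,
}


def normalize_gene(call: str) -> str:
    """Gene-level name from a gene-or-allele call: truncate at the first ``*``."""
    return str(call).split("*", 1)[0].strip().upper()


def _translate(nt: str) -> str:
    if len(nt) % 3 != 0:
        return ""
    return str(Seq(nt).translate())


def add_derived_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Add ``v_gene``, ``j_gene``, ``cdrh3_aa`` and ``cdrh3_length`` in place."""
    df["v_gene"] = df["v_call"].map(normalize_gene)
    df["j_gene"] = df["j_call"].map(normalize_gene)
    df["cdrh3_aa"] = df["junction_aa"].str.slice(1, -1)
    df["cdrh3_length"] = df["cdrh3_aa"].str.len()
    return df


def validate_rearrangements(df: pd.DataFrame) -> pd.DataFrame:
    """Drop rows violating record invariants; the count is logged and stored.

    Checks, per row: non-empty junction_aa of length >= 3; isotype in the
    known set (unknown values are coerced to ``"unknown"``); non-negative
    v_mutation_count; positive duplicate_count; and, when a nucleotide
    junction is present, ``len(junction) == 3 * len(junction_aa)`` with
    translation consistency.

    The number of dropped rows is recorded in ``df.attrs["dropped_rows"]``.
    """
    df = df.copy()
    df["junction_aa"] = df["junction_aa"].astype(str).str.upper()
    df["junction"] = df["junction"].fillna("").astype(str).str.upper()
    df["isotype"] = df["isotype"].where(df["isotype"].isin(ISOTYPES), "unknown")
    df["v_mutation_count"] = pd.to_numeric(df["v_mutation_count"], errors="coerce")
    df["duplicate_count"] = pd.to_numeric(df["duplicate_count"], errors="coerce")

    ok = (
        (df["junction_aa"].str.len() >= 3)
        & df["v_mutation_count"].ge(0)
        & df["duplicate_count"].ge(1)
    )
    has_nt = df["junction"].str.len() > 0
    nt_len_ok = df["junction"].str.len() == 3 * df["junction_aa"].str.len()
    ok &= ~has_nt | nt_len_ok
    # translation check only where the length relation already holds
    check = (ok & has_nt).to_numpy()
    if check.any():
        sub = df.loc[check]
        translated = sub["junction"].map(_translate)
        ok.loc[check] = (translated == sub["junction_aa"]).to_numpy()

    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("dropped %d invalid rearrangement rows (of %d)", n_dropped, len(df))
    out = df.loc[ok].reset_index(drop=True)
    out["v_mutation_count"] = out["v_mutation_count"].astype(int)
    out["duplicate_count"] = out["duplicate_count"].astype(int)
    out.attrs["dropped_rows"] = n_dropped
    return add_derived_columns(out)


def read_rearrangements(path: str | Path, dialect: str = "airr") -> pd.DataFrame:
    """Read an AIRR-style rearrangement TSV into a validated DataFrame.

    Parameters
    ----------
    path : str or Path
        Tab-separated file with a header row.
    dialect : {"airr", "minimal"}
        Required-column set. ``minimal`` fills provenance and annotation
        columns with defaults.

    Raises
    ------
    ValidationError
        If the file is empty or a required column is missing (all missing
        names are listed).
    """
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"subject": str, "timepoint": str, "replicate": str})
    except pd.errors.EmptyDataError:
        raise ValidationError(f"empty rearrangement file: {path}") from None
    missing = [c for c in DIALECTS[dialect] if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns in {path}: {', '.join(missing)}")
    for col, default in _MINIMAL_DEFAULTS.items():
        if col not in df.columns:
            df[col] = default
    for col in ("subject", "timepoint", "replicate", "v_call", "j_call", "isotype"):
        df[col] = df[col].fillna("").astype(str)
    df = validate_rearrangements(df)
    if df.empty:
        raise ValidationError(f"no valid rearrangement rows in {path}")
    return df


_WRITE_COLUMNS = list(DIALECTS["airr"]) + ["d_call"]


def write_rearrangements(records: pd.DataFrame, path: str | Path) -> None:
    """Write records as a rearrangement TSV; round-trips through the reader."""
    cols = [c for c in _WRITE_COLUMNS if c in records.columns]
    records.loc[:, cols].to_csv(path, sep="\t", index=False)


def export_fasta(records: pd.DataFrame, path: str | Path, sequence_column: str = "junction") -> int:
    """Export one FASTA entry per record (id = sequence_id); returns the count."""
    n = 0
    with open(path, "w") as fh:
        for seq_id, seq in zip(records["sequence_id"], records[sequence_column]):
            fh.write(f">{seq_id}\n{seq}\n")
            n += 1
    return n


def concat_repertoires(frames: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate validated repertoire frames, preserving derived columns."""
    return pd.concat(list(frames), ignore_index=True)
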