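"""Library tables, count matrices, and spacer-based read counting.

An sgRNA library is a flat table: one row per guide, each either targeting a
gene's transcription start site (TSS) or a non-targeting control (NTC).
Counting assigns each sequencing read to the unique library spacer found in a
fixed window of the read, allowing at most one mismatch.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ConfigurationError, FormatError, ValidationError

LIBRARY_COLUMNS = ["sgrna_id", "target", "tss_id", "spacer", "library_id"]

#: value of the ``target`` column that marks a non-targeting control guide
NTC_TARGET = "NTC"

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class LibraryDesign:
    """An sgRNA catalogue: guide ids, targets (or NTC flag), spacers.

    ``entries`` has columns ``sgrna_id, target, tss_id, spacer, library_id``;
    guides with ``target == "NTC"`` are the non-targeting controls.  Within a
    library all spacers share one length and contain only A/C/G/T.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.entries
        missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"library table lacks columns: {missing}")
        if df["sgrna_id"].duplicated().any():
            dupes = df.loc[df["sgrna_id"].duplicated(), "sgrna_id"].tolist()
            raise FormatError(f"duplicated sgrna_id values: {dupes[:5]}")
        if len(df):
            bad = ~df["spacer"].map(lambda s: bool(s) and set(s) <= _VALID_BASES)
            if bad.any():
                raise FormatError(
                    f"non-ACGT spacer for {df.loc[bad, 'sgrna_id'].tolist()[:5]}"
                )
            for lib_id, group in df.groupby("library_id", sort=False):
                if group["spacer"].str.len().nunique() > 1:
                    raise FormatError(f"unequal spacer lengths in library {lib_id!r}")
        object.__setattr__(
            self, "entries", df.reset_index(drop=True)[LIBRARY_COLUMNS]
        )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def sgrna_ids(self) -> pd.Index:
        return pd.Index(self.entries["sgrna_id"])

    @property
    def is_ntc(self) -> pd.Series:
        """Boolean mask over entries, True for non-targeting controls."""
        return (self.entries["target"] == NTC_TARGET).set_axis(
            self.entries["sgrna_id"]
        )

    @property
    def ntc_ids(self) -> list[str]:
        mask = self.entries["target"] == NTC_TARGET
        return self.entries.loc[mask, "sgrna_id"].tolist()

    @property
    def n_ntc(self) -> int:
        return int((self.entries["target"] == NTC_TARGET).sum())

    @property
    def library_ids(self) -> list[str]:
        return self.entries["library_id"].unique().tolist()

    @property
    def spacer_length(self) -> int:
        if not len(self.entries):
            raise ConfigurationError("empty library has no spacer length")
        return len(self.entries["spacer"].iloc[0])

    def targets(self) -> pd.DataFrame:
        """Distinct gene-targeting (target, tss_id) pairs, sorted."""
        mask = self.entries["target"] != NTC_TARGET
        out = self.entries.loc[mask, ["target", "tss_id"]].drop_duplicates()
        return out.sort_values(["target", "tss_id"]).reset_index(drop=True)

    def subset(self, library_id: str) -> "LibraryDesign":
        sub = self.entries[self.entries["library_id"] == library_id]
        if not len(sub):
            raise ValidationError(f"no entries for library {library_id!r}")
        return LibraryDesign(sub.copy())


@dataclass(frozen=True)
class CountMatrix:
    """Non-negative integer sgRNA x sample counts for the sorted fractions."""

    counts: pd.DataFrame  # index sgrna_id, one integer column per sample
    library_id: str = ""

    def __post_init__(self) -> None:
        df = self.counts
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                raise FormatError("counts must be integral")
            df = df.astype(np.int64)
        if (df.to_numpy() < 0).any():
            raise FormatError("counts must be non-negative")
        if df.index.duplicated().any():
            raise FormatError("duplicate sgrna_id rows in count matrix")
        object.__setattr__(self, "counts", df)

    @property
    def sample_names(self) -> list[str]:
        return list(self.counts.columns)

    def align_to_library(self, library: LibraryDesign) -> "CountMatrix":
        """Reindex rows to the library's guide set, zero-filling absentees.

        Rows naming guides outside the library are a validation error.
        """
        lib_ids = library.sgrna_ids
        unknown = self.counts.index.difference(lib_ids)
        if len(unknown):
            raise ValidationError(f"counts for unknown sgRNAs: {list(unknown[:5])}")
        aligned = self.counts.reindex(lib_ids, fill_value=0)
        return CountMatrix(aligned, library_id=self.library_id)

    def restrict(self, library: LibraryDesign, library_id: str) -> "CountMatrix":
        sub = library.subset(library_id)
        rows = self.counts.reindex(sub.sgrna_ids, fill_value=0)
        return CountMatrix(rows, library_id=library_id)


@dataclass(frozen=True)
class CountingReport:
    """Read-assignment tally; the three categories partition all reads."""

    n_reads: int
    n_assigned: int
    n_unassigned: int
    n_ambiguous: int

    def __post_init__(self) -> None:
        if self.n_assigned + self.n_unassigned + self.n_ambiguous != self.n_reads:
            raise ValidationError("counting report categories do not sum to n_reads")


def read_library_table(path: Union[str, Path]) -> LibraryDesign:
    """Read a TSV library table (columns: sgrna_id, target, tss_id, spacer,
    library_id).  NTC rows carry target == "NTC"."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"library table {path} lacks columns {missing}")
    return LibraryDesign(df)


def write_library_table(library: LibraryDesign, path: Union[str, Path]) -> None:
    library.entries.to_csv(path, sep="\t", index=False)


def read_count_table(
    path: Union[str, Path], library: LibraryDesign | None = None
) -> CountMatrix:
    """Read a TSV count table (``sgrna_id`` column, one integer column per
    sample).  With ``library`` given, missing guides are zero-filled and
    unknown guides rejected."""
    df = pd.read_csv(path, sep="\t", dtype={"sgrna_id": str})
    if "sgrna_id" not in df.columns:
        raise FormatError(f"count table {path} lacks an sgrna_id column")
    df = df.set_index("sgrna_id")
    for col in df.columns:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.number):
            raise FormatError(f"non-numeric counts in column {col!r}")
        if (vals < 0).any() or (vals != np.floor(vals)).any():
            raise FormatError(f"negative or non-integer counts in column {col!r}")
    matrix = CountMatrix(df.astype(np.int64))
    if library is not None:
        matrix = CountMatrix(
            matrix.counts, library_id=library.library_ids[0] if len(library) else ""
        ).align_to_library(library)
    return matrix


def write_count_table(matrix: CountMatrix, path: Union[str, Path]) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="sgrna_id")


def _iter_read_sequences(
    reads: Union[str, Path, io.IOBase, Iterable]
) -> Iterator[str]:
    """Yield read sequences from a FASTQ path/handle or an iterable of
    sequences/SeqRecords.  Quality strings are ignored."""
    if isinstance(reads, (str, Path)):
        with open(reads) as handle:
            for record in SeqIO.parse(handle, "fastq"):
                yield str(record.seq)
        return
    if isinstance(reads, io.IOBase) or hasattr(reads, "read"):
        for record in SeqIO.parse(reads, "fastq"):
            yield str(record.seq)
        return
    for item in reads:
        yield item if isinstance(item, str) else str(item.seq)


def count_sgrnas(
    reads: Union[str, Path, io.IOBase, Iterable],
    library: LibraryDesign,
    crop_offset: int = 0,
    max_mismatch: int = 0,
) -> tuple[pd.Series, CountingReport]:
    """Assign reads to library spacers by (near-)exact matching on a cropped
    window and tally per-sgRNA counts.

    Each read is cropped to ``[crop_offset, crop_offset + spacer_length)`` and
    assigned to the unique spacer within ``max_mismatch`` Hamming distance
    (0 or 1).  Reads matching no spacer are unassigned; reads tied between
    several spacers at the minimal distance are ambiguous and discarded, which
    keeps counts integral and conservative.  Reads shorter than the window are
    unassigned.

    Returns a count Series indexed like the library plus a CountingReport.
    """
    if not len(library):
        raise ConfigurationError("cannot count reads against an empty library")
    if crop_offset < 0:
        raise ConfigurationError("crop_offset must be >= 0")
    if max_mismatch not in (0, 1):
        raise ConfigurationError("max_mismatch must be 0 or 1")

    length = library.spacer_length
    ids = library.entries["sgrna_id"].to_numpy()
    spacers = library.entries["spacer"].to_numpy()

    exact: dict[str, list[int]] = {}
    for i, sp in enumerate(spacers):
        exact.setdefault(sp, []).append(i)

    # one-mismatch lookup: (position, spacer with that position deleted)
    near: dict[tuple[int, str], set[int]] = {}
    if max_mismatch == 1:
        for i, sp in enumerate(spacers):
            for pos in range(length):
                near.setdefault((pos, sp[:pos] + sp[pos + 1 :]), set()).add(i)

    counts = np.zeros(len(library), dtype=np.int64)
    n_reads = n_assigned = n_unassigned = n_ambiguous = 0
    end = crop_offset + length
    for seq in _iter_read_sequences(reads):
        n_reads += 1
        if len(seq) < end:
            n_unassigned += 1
            continue
        window = seq[crop_offset:end]
        hit = exact.get(window)
        if hit is not None:
            if len(hit) == 1:
                counts[hit[0]] += 1
                n_assigned += 1
            else:
                n_ambiguous += 1
            continue
        if max_mismatch == 1:
            candidates: set[int] = set()
            for pos in range(length):
                found = near.get((pos, window[:pos] + window[pos + 1 :]))
                if found:
                    candidates |= found
            if len(candidates) == 1:
                counts[candidates.pop()] += 1
                n_assigned += 1
                continue
            if len(candidates) > 1:
                n_ambiguous += 1
                continue
        n_unassigned += 1

    report = CountingReport(n_reads, n_assigned, n_unassigned, n_ambiguous)
    return pd.Series(counts, index=pd.Index(ids, name="sgrna_id")), report
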