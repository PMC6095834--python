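"""Readers and writers for screen data, plus raw-read barcode counting.

All tabular formats are tab-separated UTF-8 text with a header row; lines
starting with ``#`` are comments.  The first column of a count table is the
hairpin identifier.  FASTQ input may be plain or gzip-compressed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError, LibraryError, ValidationError

_NUCLEOTIDES = frozenset("ACGT")

TIMEPOINTS = ("T0", "T1")


@dataclass(frozen=True)
class HairpinLibrary:
    """A short-hairpin library: unique hairpin ids mapped to gene symbols.

    Parameters
    ----------
    table
        DataFrame indexed by ``hairpin_id`` with column ``gene`` and an
        optional ``sequence`` column of A/C/G/T strings (length >= 18).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate hairpin ids: {dups[:5]}")
        if "gene" not in df.columns:
            raise ValidationError("library table must have a 'gene' column")
        if (df["gene"].astype(str).str.len() == 0).any():
            raise ValidationError("empty gene symbol in library")
        if "sequence" in df.columns:
            for hp, seq in df["sequence"].items():
                if pd.isna(seq):
                    continue
                seq = str(seq)
                if len(seq) < 18 or not set(seq) <= _NUCLEOTIDES:
                    raise ValidationError(
                        f"hairpin {hp}: sequence must be >=18 nt over A/C/G/T"
                    )

    @property
    def hairpin_ids(self) -> pd.Index:
        return self.table.index

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.table["gene"].unique())

    def gene_of(self) -> pd.Series:
        """hairpin_id -> gene symbol."""
        return self.table["gene"]

    @property
    def sequences(self) -> pd.Series | None:
        if "sequence" in self.table.columns:
            return self.table["sequence"]
        return None

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class CountTable:
    """Integer hairpin x sample abundance matrix with per-sample metadata.

    ``counts`` is indexed by hairpin_id with one column per sample_id;
    ``samples`` is indexed by sample_id with columns ``cell_line``,
    ``timepoint`` (T0/T1) and ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts, samples = self.counts, self.samples
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate hairpin ids in count table: {dups[:5]}")
        if not counts.columns.equals(samples.index):
            missing = counts.columns.difference(samples.index).tolist()
            if missing:
                raise ValidationError(
                    f"count columns without sample metadata: {missing[:5]}"
                )
            extra = samples.index.difference(counts.columns).tolist()
            raise ValidationError(f"metadata for absent samples: {extra[:5]}")
        for col in ("cell_line", "timepoint", "replicate"):
            if col not in samples.columns:
                raise ValidationError(f"sample metadata lacks column '{col}'")
        bad_tp = set(samples["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValidationError(f"unknown timepoints {sorted(bad_tp)}")
        key = samples[["cell_line", "timepoint", "replicate"]]
        if key.duplicated().any():
            raise ValidationError("duplicate (cell_line, timepoint, replicate)")
        # every cell line needs both T0 and T1 samples
        per_line = samples.groupby("cell_line")["timepoint"].agg(set)
        for line, tps in per_line.items():
            if tps != set(TIMEPOINTS):
                raise ValidationError(f"cell line {line!r} lacks both T0 and T1")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            frac, _ = np.modf(arr.astype(float))
            if np.any(frac != 0) or np.any(~np.isfinite(arr.astype(float))):
                i, j = np.argwhere(frac != 0)[0]
                raise FormatError(
                    f"non-integer count at hairpin {counts.index[i]!r}, "
                    f"sample {counts.columns[j]!r}"
                )
            self.counts = counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if np.any(arr < 0):
            i, j = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at hairpin {counts.index[i]!r}, "
                f"sample {counts.columns[j]!r}"
            )

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self.samples["cell_line"].unique())

    def samples_for(self, line: str, timepoint: str) -> list[str]:
        m = (self.samples["cell_line"] == line) & (
            self.samples["timepoint"] == timepoint
        )
        return self.samples.index[m].tolist()


# ---------------------------------------------------------------------------
# TSV readers / writers


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kw)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_library(path: str | Path) -> HairpinLibrary:
    df = _read_tsv(path, dtype=str)
    if "hairpin_id" not in df.columns:
        raise FormatError(f"{path}: missing 'hairpin_id' column")
    return HairpinLibrary(df.set_index("hairpin_id"))


def write_library(library: HairpinLibrary, path: str | Path) -> None:
    library.table.to_csv(path, sep="\t", index_label="hairpin_id")


def read_counts(path: str | Path, metadata_path: str | Path) -> CountTable:
    """Read a hairpin x sample count TSV plus its sample-metadata TSV."""
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: count table needs a key column and samples")
    key = raw.columns[0]
    counts = raw.set_index(key)
    # reject non-numeric or fractional entries with a precise message
    for col in counts.columns:
        numeric = pd.to_numeric(counts[col], errors="coerce")
        bad = numeric.isna() & counts[col].notna()
        if bad.any():
            row = counts.index[bad][0]
            raise FormatError(
                f"{path}: non-integer entry {counts.loc[row, col]!r} "
                f"at hairpin {row!r}, sample {col!r}"
            )
        counts[col] = numeric
    meta = _read_tsv(metadata_path)
    if "sample_id" not in meta.columns:
        raise FormatError(f"{metadata_path}: missing 'sample_id' column")
    meta = meta.set_index("sample_id")
    missing = counts.columns.difference(meta.index).tolist()
    if missing:
        raise ValidationError(
            f"{path}: count columns without sample metadata: {missing[:5]}"
        )
    return CountTable(counts, meta.loc[counts.columns])


def write_counts(
    table: CountTable, counts_path: str | Path, metadata_path: str | Path
) -> None:
    table.counts.to_csv(counts_path, sep="\t", index_label="hairpin_id")
    table.samples.to_csv(metadata_path, sep="\t", index_label="sample_id")


def read_genotypes(path: str | Path) -> pd.Series:
    """Read a two-column (cell_line, genotype) TSV into a Series."""
    df = _read_tsv(path, dtype=str)
    if not {"cell_line", "genotype"} <= set(df.columns):
        raise FormatError(f"{path}: need columns cell_line, genotype")
    return df.set_index("cell_line")["genotype"]


def write_genotypes(genotypes: pd.Series, path: str | Path) -> None:
    genotypes.rename("genotype").to_csv(path, sep="\t", index_label="cell_line")


# ---------------------------------------------------------------------------
# Barcode counting


@dataclass
class BarcodeCounts:
    """Per-hairpin read tallies plus the number of discarded reads."""

    counts: pd.Series
    discarded: int
    total_reads: int = field(default=0)

    def __post_init__(self) -> None:
        if self.total_reads == 0:
            self.total_reads = int(self.counts.sum()) + self.discarded


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def count_barcodes(
    reads: str | Path | Iterable[str],
    library: HairpinLibrary,
    match_len: int = 21,
) -> BarcodeCounts:
    """Assign reads to hairpins by exact substring match of a barcode prefix.

    Each library sequence contributes its first ``match_len`` bases as the
    barcode.  A read is assigned to a hairpin iff exactly one barcode occurs
    as a substring; reads matching zero or more than one hairpin are tallied
    as discarded.  Assigned + discarded always equals the reads processed.

    Parameters
    ----------
    reads
        Path to a FASTQ file (``.gz`` allowed) or an iterable of read
        sequences.
    library
        Library with sequences of length >= ``match_len``.
    match_len
        Barcode length used for matching (default 21, the TRC target length).
    """
    seqs = library.sequences
    if seqs is None:
        raise LibraryError("library has no sequences; cannot count barcodes")
    barcode_to_hairpin: dict[str, str] = {}
    for hp, seq in seqs.items():
        seq = str(seq)
        if len(seq) < match_len:
            raise LibraryError(f"hairpin {hp}: sequence shorter than match_len")
        bc = seq[:match_len]
        if bc in barcode_to_hairpin:
            raise LibraryError(
                f"ambiguous library: hairpins {barcode_to_hairpin[bc]!r} and "
                f"{hp!r} share the {match_len}-nt prefix {bc}"
            )
        barcode_to_hairpin[bc] = hp

    counts = pd.Series(0, index=library.hairpin_ids, dtype=np.int64)
    discarded = 0
    total = 0

    if isinstance(reads, (str, Path)):
        with _open_maybe_gzip(reads) as handle:
            read_seqs = [str(rec.seq) for rec in SeqIO.parse(handle, "fastq")]
    else:
        read_seqs = list(reads)

    for read in read_seqs:
        total += 1
        read = read.upper()
        matched: set[str] = set()
        for i in range(len(read) - match_len + 1):
            hp = barcode_to_hairpin.get(read[i : i + match_len])
            if hp is not None:
                matched.add(hp)
                if len(matched) > 1:
                    break
        if len(matched) == 1:
            counts[matched.pop()] += 1
        else:
            discarded += 1
    return BarcodeCounts(counts=counts, discarded=discarded, total_reads=total)


def write_barcode_counts(result: BarcodeCounts, path: str | Path) -> None:
    out = result.counts.rename("count")
    with open(path, "w") as fh:
        fh.write(f"# discarded\t{result.discarded}\n")
        fh.write(f"# total_reads\t{result.total_reads}\n")
        out.to_csv(fh, sep="\t", index_label="hairpin_id")
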