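"""Strand-aware average ChIP-signal profiles around transcription start
sites (TSS metaprofiles).

A coverage track (bedGraph, 0-based half-open, uncovered positions read as
zero) is averaged in fixed-width bins over windows centred on each TSS;
windows on the minus strand are mirrored so that "downstream of the TSS"
is always to the right.  The metaprofile is the per-bin mean across regions
with its standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError


@dataclass(frozen=True)
class TssRegion:
    """One transcription start site: chromosome, 0-based position, strand."""

    chrom: str
    tss: int
    strand: str
    name: str = "."

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ParameterError("tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ParameterError("strand must be '+' or '-'")


def read_bed_tss(path) -> list[TssRegion]:
    """Extract TSS positions from a BED6 file.

    BED intervals are 0-based half-open; the TSS is the interval start for
    '+' entries and ``end - 1`` for '-' entries.
    """
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 needs >= 6 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            strand = fields[5]
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            tss = start if strand == "+" else end - 1
            regions.append(TssRegion(fields[0], tss, strand, fields[3]))
    return regions


def write_bed_tss(regions: list[TssRegion], path, width: int = 1) -> None:
    """Write TSSs back as width-1 BED6 intervals (strand conventions kept)."""
    with open(path, "w") as fh:
        for r in regions:
            if r.strand == "+":
                start, end = r.tss, r.tss + width
            else:
                start, end = r.tss - width + 1, r.tss + 1
            fh.write(f"{r.chrom}\t{start}\t{end}\t{r.name}\t0\t{r.strand}\n")


class SignalTrack:
    """Per-chromosome coverage intervals (start, end, value), 0-based
    half-open, sorted and non-overlapping; positions not covered by any
    interval read as 0."""

    def __init__(self, intervals: dict[str, np.ndarray]):
        # each value: structured as (n, 3) float array [start, end, value]
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, arr in intervals.items():
            arr = np.asarray(arr, dtype=float)
            if arr.size == 0:
                continue
            order = np.argsort(arr[:, 0], kind="mergesort")
            arr = arr[order]
            starts, ends, values = arr[:, 0], arr[:, 1], arr[:, 2]
            if np.any(ends <= starts):
                raise FormatError("empty or inverted interval in track")
            if np.any(starts[1:] < ends[:-1]):
                raise FormatError("overlapping intervals in track")
            if np.any(values < 0):
                raise FormatError("negative track values")
            self._chroms[chrom] = (
                starts.astype(np.int64), ends.astype(np.int64), values
            )

    @classmethod
    def from_bedgraph(cls, path) -> "SignalTrack":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
        if df.isna().any().any():
            raise FormatError(f"{path}: malformed bedGraph line")
        chroms = {
            chrom: g[["start", "end", "value"]].to_numpy(dtype=float)
            for chrom, g in df.groupby("chrom")
        }
        return cls(chroms)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._chroms)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base signal over [start, end); positions off the covered
        intervals (or on an absent chromosome, or at negative coordinates)
        read 0."""
        out = np.zeros(end - start)
        if chrom not in self._chroms:
            return out
        starts, ends, vals = self._chroms[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        for i in range(lo, hi):
            a = max(int(starts[i]), start)
            b = min(int(ends[i]), end)
            if b > a:
                out[a - start : b - start] = vals[i]
        return out


@dataclass
class MetaProfile:
    """Per-bin mean signal and standard error over aligned TSS windows.

    ``offsets`` are bin start positions relative to the TSS (from -flank
    to +flank - bin_size, step bin_size)."""

    offsets: np.ndarray
    mean: np.ndarray
    stderr: np.ndarray
    n_regions: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "mean": self.mean,
             "stderr": self.stderr, "n": self.n_regions}
        )


def tss_matrix(
    track: SignalTrack,
    regions: list[TssRegion],
    flank: int = 3000,
    bin_size: int = 50,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Binned signal matrix (regions x bins) over +/- ``flank`` windows.

    Each bin holds the mean per-base value over ``bin_size`` positions of
    the window [tss - flank, tss + flank); minus-strand rows are reversed
    so downstream of the TSS is rightward.  Returns (matrix, bin offsets,
    number of regions whose chromosome was absent from the track).
    """
    if flank % bin_size != 0:
        raise ParameterError("flank must be a multiple of bin_size")
    if not regions:
        raise ParameterError("no regions given")
    n_bins = 2 * flank // bin_size
    matrix = np.zeros((len(regions), n_bins))
    missing = 0
    known = set(track.chromosomes)
    for i, r in enumerate(regions):
        if r.chrom not in known:
            missing += 1
            continue
        vals = track.values(r.chrom, r.tss - flank, r.tss + flank)
        binned = vals.reshape(n_bins, bin_size).mean(axis=1)
        matrix[i] = binned[::-1] if r.strand == "-" else binned
    offsets = np.arange(-flank, flank, bin_size)
    return matrix, offsets, missing


def average_profile(
    matrix: np.ndarray, offsets: np.ndarray | None = None
) -> MetaProfile:
    """Column means and standard errors (sd / sqrt(n)) of a TSS matrix."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise ParameterError("empty matrix")
    n = matrix.shape[0]
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1) if n > 1 else np.zeros(matrix.shape[1])
    if offsets is None:
        offsets = np.arange(matrix.shape[1])
    return MetaProfile(
        offsets=np.asarray(offsets), mean=mean,
        stderr=sd / np.sqrt(n), n_regions=n,
    )


def write_profile(profile: MetaProfile, path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)
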