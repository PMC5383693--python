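"""Genomic file formats used by the pipeline.

All in-memory coordinates are 0-based, half-open. Conversions to and from the
1-based conventions of wiggle files happen here and nowhere else.

Formats handled:

* two-column chromosome sizes text (``name<TAB>length``),
* BED6 for TSS annotations (the TSS of a minus-strand gene is ``end - 1``),
* bedGraph and fixedStep wiggle for per-base occupancy tracks
  (uncovered bases read as 0),
* BED3 for nucleosomal fragment intervals,
* tab-separated tables with a header row for everything tabular.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

__all__ = [
    "ChromSizes",
    "TssRecord",
    "OccupancyTrack",
    "FragmentSet",
    "read_chrom_sizes",
    "read_tss_bed",
    "write_tss_bed",
    "read_track",
    "write_track",
    "read_fragments_bed",
    "write_fragments_bed",
    "read_table",
    "write_table",
]


@dataclass(frozen=True)
class ChromSizes:
    """Ordered map of chromosome name to length in bp."""

    entries: Mapping[str, int]

    def __post_init__(self):
        if not self.entries:
            raise ValidationError("chromosome sizes are empty")
        for name, length in self.entries.items():
            if not name:
                raise ValidationError("empty chromosome name")
            if int(length) < 1:
                raise ValidationError(f"chromosome {name!r} has length {length} < 1")

    def __getitem__(self, name: str) -> int:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def names(self) -> list[str]:
        return list(self.entries)

    def total_length(self) -> int:
        return int(sum(self.entries.values()))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self.entries.items():
                fh.write(f"{name}\t{length}\n")


@dataclass(frozen=True)
class TssRecord:
    """A gene's transcription start site (0-based) with strand."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.tss < 0:
            raise ValidationError(f"gene {self.gene_id!r}: negative TSS {self.tss}")


@dataclass
class OccupancyTrack:
    """Dense per-base, non-negative occupancy, one float vector per chromosome."""

    data: dict[str, np.ndarray]

    @classmethod
    def zeros(cls, sizes: ChromSizes) -> "OccupancyTrack":
        return cls({name: np.zeros(length) for name, length in sizes.entries.items()})

    def validate(self, sizes: ChromSizes | None = None) -> None:
        for chrom, values in self.data.items():
            if values.ndim != 1:
                raise ValidationError(f"{chrom}: track vector must be 1-D")
            if not np.all(np.isfinite(values)):
                raise ValidationError(f"{chrom}: non-finite occupancy values")
            if np.any(values < 0):
                raise ValidationError(f"{chrom}: negative occupancy values")
            if sizes is not None and len(values) != sizes[chrom]:
                raise ValidationError(
                    f"{chrom}: track length {len(values)} != chromosome length {sizes[chrom]}"
                )

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def n_bases(self) -> int:
        return int(sum(len(v) for v in self.data.values()))

    def mean(self) -> float:
        return self.total() / self.n_bases()

    def equals(self, other: "OccupancyTrack") -> bool:
        return set(self.data) == set(other.data) and all(
            np.array_equal(self.data[c], other.data[c]) for c in self.data
        )


@dataclass
class FragmentSet:
    """Nucleosomal fragment intervals, 0-based half-open."""

    frame: pd.DataFrame  # columns: chrom, start, end

    def __post_init__(self):
        missing = {"chrom", "start", "end"} - set(self.frame.columns)
        if missing:
            raise SchemaError(f"fragment table missing columns: {sorted(missing)}")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def validate(self, sizes: ChromSizes) -> None:
        for chrom, sub in self.frame.groupby("chrom", sort=False):
            if chrom not in sizes:
                raise ValidationError(f"fragment on unknown chromosome {chrom!r}")
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if np.any(starts < 0) or np.any(starts >= ends) or np.any(ends > sizes[chrom]):
                raise ValidationError(f"fragment interval out of bounds on {chrom}")


# ---------------------------------------------------------------------------
# chrom sizes


def read_chrom_sizes(path) -> ChromSizes:
    entries: dict[str, int] = {}
    for lineno, fields in _rows(path):
        if len(fields) < 2:
            raise ParseError(path, lineno, "expected 'name<TAB>length'")
        name = fields[0]
        try:
            length = int(fields[1])
        except ValueError:
            raise ParseError(path, lineno, f"non-integer length {fields[1]!r}") from None
        if name in entries:
            raise ParseError(path, lineno, f"duplicate chromosome {name!r}")
        entries[name] = length
    if not entries:
        raise ParseError(path, 0, "no chromosomes found")
    return ChromSizes(entries)


def _rows(path) -> Iterator[tuple[int, list[str]]]:
    """Non-empty, non-comment lines as (1-based lineno, whitespace fields)."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split()


# ---------------------------------------------------------------------------
# BED6 TSS annotation


def read_tss_bed(path, sizes: ChromSizes) -> list[TssRecord]:
    """Read a BED6 TSS annotation.

    The TSS is the BED start for + strand genes and ``end - 1`` for − strand
    genes (the last covered base of a half-open interval is the 5′ end on the
    minus strand).
    """
    records: list[TssRecord] = []
    seen: set[str] = set()
    for lineno, fields in _rows(path):
        if fields[0] in ("track", "browser"):
            continue
        if len(fields) < 6:
            raise ParseError(path, lineno, f"expected 6 BED columns, got {len(fields)}")
        chrom, start_s, end_s, name, _score, strand = fields[:6]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(path, lineno, "non-integer coordinates") from None
        if strand not in ("+", "-"):
            raise ParseError(path, lineno, f"bad strand {strand!r}")
        if chrom not in sizes:
            raise ValidationError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        if not (0 <= start < end <= sizes[chrom]):
            raise ValidationError(f"{path}:{lineno}: interval [{start},{end}) out of bounds")
        if name in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate gene_id {name!r}")
        seen.add(name)
        tss = start if strand == "+" else end - 1
        records.append(TssRecord(name, chrom, tss, strand))
    return records


def write_tss_bed(records: Iterable[TssRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            start = r.tss if r.strand == "+" else r.tss  # single-base feature
            fh.write(f"{r.chrom}\t{start}\t{start + 1}\t{r.gene_id}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# tracks: bedGraph and fixedStep wiggle


def read_track(path, sizes: ChromSizes) -> OccupancyTrack:
    """Read a bedGraph or fixedStep wiggle file into a dense per-base track.

    The dialect is auto-detected: a ``fixedStep`` declaration marks a wiggle;
    otherwise 4-column lines are parsed as bedGraph. Uncovered bases are 0.
    Overlapping bedGraph intervals are an error.
    """
    track = OccupancyTrack.zeros(sizes)
    intervals: dict[str, list[tuple[int, int]]] = {}
    wig_chrom: str | None = None
    wig_pos = 0  # 0-based next position
    wig_step = 1
    wig_span = 1

    for lineno, fields in _rows(path):
        if fields[0] in ("track", "browser"):
            continue
        if fields[0] == "variableStep":
            raise ParseError(path, lineno, "variableStep wiggle is not supported")
        if fields[0] == "fixedStep":
            kv = dict(f.split("=", 1) for f in fields[1:] if "=" in f)
            if "chrom" not in kv or "start" not in kv:
                raise ParseError(path, lineno, "fixedStep needs chrom= and start=")
            wig_chrom = kv["chrom"]
            if wig_chrom not in sizes:
                raise ValidationError(f"{path}:{lineno}: unknown chromosome {wig_chrom!r}")
            try:
                start1 = int(kv["start"])
                wig_step = int(kv.get("step", 1))
                wig_span = int(kv.get("span", 1))
            except ValueError:
                raise ParseError(path, lineno, "non-integer fixedStep attribute") from None
            if start1 < 1:
                raise ParseError(path, lineno, "fixedStep start is 1-based and must be >= 1")
            wig_pos = start1 - 1  # 1-based -> 0-based
            continue
        if wig_chrom is not None and len(fields) == 1:
            try:
                value = float(fields[0])
            except ValueError:
                raise ParseError(path, lineno, f"non-numeric value {fields[0]!r}") from None
            if value < 0 or not np.isfinite(value):
                raise ParseError(path, lineno, f"invalid occupancy value {value}")
            hi = wig_pos + wig_span
            if hi > sizes[wig_chrom]:
                raise ValidationError(f"{path}:{lineno}: wiggle value past chromosome end")
            track.data[wig_chrom][wig_pos:hi] = value
            wig_pos += wig_step
            continue
        # bedGraph line
        if len(fields) < 4:
            raise ParseError(path, lineno, f"expected 4 bedGraph columns, got {len(fields)}")
        chrom, start_s, end_s, value_s = fields[:4]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(path, lineno, "non-integer coordinates") from None
        try:
            value = float(value_s)
        except ValueError:
            raise ParseError(path, lineno, f"non-numeric value {value_s!r}") from None
        if chrom not in sizes:
            raise ValidationError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        if not (0 <= start < end <= sizes[chrom]):
            raise ValidationError(f"{path}:{lineno}: interval [{start},{end}) out of bounds")
        if value < 0 or not np.isfinite(value):
            raise ParseError(path, lineno, f"invalid occupancy value {value}")
        intervals.setdefault(chrom, []).append((start, end))
        track.data[chrom][start:end] = value

    for chrom, ivs in intervals.items():
        ivs.sort()
        for (s0, e0), (s1, _e1) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValidationError(
                    f"{path}: overlapping bedGraph intervals on {chrom} at {s1} < {e0}"
                )
    return track


def _format_value(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_track(track: OccupancyTrack, path) -> None:
    """Write a track as bedGraph, merging runs of equal value, omitting zeros.

    ``read_track(write_track(t))`` reproduces ``t`` exactly (values are written
    with full float precision).
    """
    with open(path, "w") as fh:
        for chrom, values in track.data.items():
            if len(values) == 0:
                continue
            # run boundaries where the value changes
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(values)]])
            for s, e in zip(starts, ends):
                v = values[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{_format_value(v)}\n")


# ---------------------------------------------------------------------------
# fragments (BED3)


def read_fragments_bed(path, sizes: ChromSizes) -> FragmentSet:
    chroms, starts, ends = [], [], []
    for lineno, fields in _rows(path):
        if fields[0] in ("track", "browser"):
            continue
        if len(fields) < 3:
            raise ParseError(path, lineno, f"expected 3 BED columns, got {len(fields)}")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ParseError(path, lineno, "non-integer coordinates") from None
        chrom = fields[0]
        if chrom not in sizes:
            raise ValidationError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        if not (0 <= start < end <= sizes[chrom]):
            raise ValidationError(f"{path}:{lineno}: interval [{start},{end}) out of bounds")
        chroms.append(chrom)
        starts.append(start)
        ends.append(end)
    return FragmentSet(pd.DataFrame({"chrom": chroms, "start": starts, "end": ends}))


def write_fragments_bed(frags: FragmentSet, path) -> None:
    frags.frame.to_csv(path, sep="\t", header=False, index=False, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# tables


def read_table(path, required: Iterable[str] | None = None) -> pd.DataFrame:
    """Read a tab-separated table with a header row."""
    df = pd.read_csv(path, sep="\t")
    if required:
        missing = set(required) - set(df.columns)
        if missing:
            raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
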