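"""Shared genomic data model and plain-text format I/O.

Coordinates are 0-based half-open throughout (BED convention); 1-based
numbers appear only in human-readable reports.  In-memory bulk containers
are pandas DataFrames; the dataclasses below are the record-level API.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: column order of the on-disk read-pair table (one mate pair per row)
READPAIR_COLUMNS = [
    "chrom1", "start1", "end1", "strand1",
    "chrom2", "start2", "end2", "strand2",
    "unique1", "unique2", "adaptor1", "adaptor2",
]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

#: BEDPE dialect for chimeras; extra columns carry the analysis annotations
BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2",
    "span", "span_class", "combo", "orientation",
]


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Malformed record in a text format; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class ReadPair:
    """A mapped mate pair; flags mirror the aligner-derived filters."""

    mate1: GenomicInterval
    mate2: GenomicInterval
    unique1: bool = True
    unique2: bool = True
    adaptor1: bool = False
    adaptor2: bool = False

    @property
    def insert(self) -> int:
        """Distance between outermost mapped coordinates (intra-chrom)."""
        if self.mate1.chrom != self.mate2.chrom:
            raise ValueError("insert undefined for inter-chromosomal pair")
        return max(self.mate1.end, self.mate2.end) - min(
            self.mate1.start, self.mate2.start
        )


class GenomeSequence:
    """Per-chromosome nucleotide strings over {A,C,G,T,N}.

    Runs of N represent assembly gaps and are excluded from composition
    statistics.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self.sequences: Dict[str, str] = {
            c: str(s).upper() for c, s in sequences.items()
        }
        self.lengths: Dict[str, int] = {
            c: len(s) for c, s in self.sequences.items()
        }

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def fetch(self, interval: GenomicInterval) -> str:
        if interval.chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {interval.chrom!r}")
        if interval.end > self.lengths[interval.chrom]:
            raise ValueError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"exceeds chromosome length {self.lengths[interval.chrom]}"
            )
        return self.sequences[interval.chrom][interval.start:interval.end]

    def n_fraction(self, interval: GenomicInterval) -> float:
        seq = self.fetch(interval)
        return seq.count("N") / len(seq)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        if not records:
            raise FormatError(f"no FASTA records in {path}")
        return cls(records)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=chrom, description="")
            for chrom, seq in self.sequences.items()
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")


def gc_content(interval: GenomicInterval, genome: GenomeSequence) -> float:
    """G+C fraction over the interval, N bases excluded from the denominator.

    Raises ValueError for an all-N interval (GC undefined over a gap).
    """
    seq = genome.fetch(interval)
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError(
            f"GC content undefined: interval "
            f"{interval.chrom}:{interval.start}-{interval.end} is all N"
        )
    return gc / (gc + at)


def build_trees(df: pd.DataFrame) -> Dict[str, IntervalTree]:
    """Per-chromosome interval trees from a chrom/start/end DataFrame."""
    trees: Dict[str, IntervalTree] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            (s, e, i) for i, (s, e) in zip(sub.index, zip(sub.start, sub.end))
        )
    return trees


def overlap_flags(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """Boolean flag per interval of `a`: shares >=1 bp with any interval of `b`."""
    if len(a) == 0:
        return np.zeros(0, dtype=bool)
    if len(b) == 0:
        return np.zeros(len(a), dtype=bool)
    trees = build_trees(b)
    flags = np.zeros(len(a), dtype=bool)
    for i, (chrom, start, end) in enumerate(
        zip(a["chrom"], a["start"], a["end"])
    ):
        tree = trees.get(chrom)
        if tree is not None and tree.overlaps(start, end):
            flags[i] = True
    return flags


def overlap_fraction(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Fraction of intervals in `a` overlapping `b` (0.0 for empty `a`)."""
    if len(a) == 0:
        return 0.0
    return float(overlap_flags(a, b).mean())


# ---------------------------------------------------------------------------
# text formats


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 3- or 6-column BED file into a DataFrame.

    Malformed lines raise FormatError with the offending line number;
    records violating start < end are rejected.
    """
    rows: List[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError("fewer than 3 BED fields", lineno)
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError("non-integer coordinate", lineno) from None
            if not (0 <= start < end):
                raise FormatError(
                    f"invalid coordinates {start}-{end}", lineno
                )
            name = fields[3] if len(fields) > 3 else "."
            score = fields[4] if len(fields) > 4 else "0"
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in {"+", "-", "."}:
                raise FormatError(f"invalid strand {strand!r}", lineno)
            rows.append((chrom, start, end, name, float(score), strand))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in out.columns:
            out[col] = default
    out[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph; intervals must be sorted and non-overlapping."""
    rows: List[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError("bedGraph needs 4 fields", lineno)
            chrom = fields[0]
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError:
                raise FormatError("bad bedGraph record", lineno) from None
            if not (0 <= start < end):
                raise FormatError(f"invalid coordinates {start}-{end}", lineno)
            if rows and rows[-1][0] == chrom and start < rows[-1][2]:
                raise FormatError("bedGraph not sorted/non-overlapping", lineno)
            rows.append((chrom, start, end, value))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    out = df.sort_values(["chrom", "start"], kind="stable")
    out[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def coverage_to_bedgraph(coverage: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Run-length encode per-base coverage arrays; zero runs are dropped."""
    rows = []
    for chrom in coverage:
        arr = np.asarray(coverage[chrom])
        if arr.size == 0:
            continue
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [arr.size]))
        vals = arr[starts]
        keep = vals != 0
        for s, e, v in zip(starts[keep], ends[keep], vals[keep]):
            rows.append((chrom, int(s), int(e), float(v)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def read_pairs_table(path: str | Path) -> pd.DataFrame:
    """Read the tabular read-pair dialect emitted by the simulator.

    Columns: chrom/start/end/strand per mate plus per-mate uniqueness and
    5'-adaptor flags (0/1).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in READPAIR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"read-pair table missing columns {missing}")
    for col in ("unique1", "unique2", "adaptor1", "adaptor2"):
        df[col] = df[col].astype(bool)
    bad = (df.start1 >= df.end1) | (df.start2 >= df.end2)
    if bad.any():
        raise FormatError(
            f"coordinate violation in {int(bad.sum())} read-pair records "
            f"(first at data row {int(np.flatnonzero(bad)[0]) + 1})"
        )
    return df


def write_pairs_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in ("unique1", "unique2", "adaptor1", "adaptor2"):
        out[col] = out[col].astype(int)
    out[READPAIR_COLUMNS].to_csv(path, sep="\t", index=False)


def pairs_from_sam(path: str | Path) -> pd.DataFrame:
    """Optional SAM/BAM reader: collate primary mate pairs into the table.

    Uniqueness is taken from MAPQ>0 and absence of the XA tag; the 5'
    adaptor flag is not recoverable from SAM and is set to False.
    """
    import pysam  # optional dependency, imported lazily

    rows = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            unique = aln.mapping_quality > 0 and not aln.has_tag("XA")
            rec = (
                aln.reference_name,
                aln.reference_start,
                aln.reference_end,
                "-" if aln.is_reverse else "+",
                unique,
            )
            key = aln.query_name
            if key in rows:
                rows[key] = rows[key] + rec
            else:
                rows[key] = rec
    data = [v for v in rows.values() if len(v) == 10]
    df = pd.DataFrame(
        data,
        columns=[
            "chrom1", "start1", "end1", "strand1", "unique1",
            "chrom2", "start2", "end2", "strand2", "unique2",
        ],
    )
    df["adaptor1"] = False
    df["adaptor2"] = False
    return df[READPAIR_COLUMNS]


def read_bedpe(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in BEDPE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"BEDPE table missing columns {missing}")
    return df


def write_bedpe(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in BEDPE_COLUMNS:
        if col not in out.columns:
            out[col] = "."
    extra = [c for c in out.columns if c not in BEDPE_COLUMNS]
    out[BEDPE_COLUMNS + extra].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# interval arithmetic on sorted (start, end) arrays — used for region algebra


def merge_intervals(ivs: Sequence[tuple]) -> List[tuple]:
    """Merge overlapping/adjacent (start, end) tuples into maximal runs."""
    if not ivs:
        return []
    ivs = sorted(ivs)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


def subtract_intervals(
    a: Sequence[tuple], b: Sequence[tuple]
) -> List[tuple]:
    """Set difference a \\ b for merged, sorted (start, end) lists."""
    result = []
    b = list(b)
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                result.append((cur, bs))
            cur = max(cur, be)
            k += 1
        if cur < e:
            result.append((cur, e))
    return result


def total_length(ivs: Iterable[tuple]) -> int:
    return sum(e - s for s, e in ivs)
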