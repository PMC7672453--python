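"""Genomic file I/O with a single internal coordinate convention.

Everything in this package is 0-based, half-open (`start` inclusive, `end`
exclusive). Conversion to/from 1-based formats (SAM) happens only here, at
the file boundary. BED and bedGraph are already 0-based half-open; the TSS
annotation TSV stores a 0-based TSS position.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam


@dataclass(frozen=True)
class ReadRecord:
    """One aligned read or (for collapsed paired-end data) one fragment.

    ``is_fragment`` marks records that already span the full template, so
    window counting must not extend them to the nominal fragment length.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"
    mapq: int = 255
    is_duplicate: bool = False
    is_fragment: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


class GenomeDeclaration:
    """Ordered chromosome names with lengths."""

    def __init__(self, lengths: Mapping[str, int]):
        for name, ln in lengths.items():
            if ln <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {ln}")
        if len(set(lengths)) != len(lengths):
            raise ValueError("duplicate chromosome names")
        self._lengths = dict(lengths)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._lengths)

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def items(self):
        return self._lengths.items()

    def total_length(self) -> int:
        return sum(self._lengths.values())

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeDeclaration) and self._lengths == other._lengths

    def __repr__(self) -> str:
        return f"GenomeDeclaration({self._lengths!r})"


class TssAnnotation:
    """One TSS per gene: the promoter universe for Simes combination.

    Wraps a DataFrame with columns gene_id, chrom, tss (0-based), strand.
    """

    REQUIRED = ("gene_id", "chrom", "tss", "strand")

    def __init__(self, table: pd.DataFrame, genome: Optional[GenomeDeclaration] = None):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"TSS annotation missing columns: {missing}")
        if table["gene_id"].duplicated().any():
            dup = table.loc[table["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id {dup!r} in TSS annotation")
        if genome is not None:
            for chrom, sub in table.groupby("chrom"):
                if chrom not in genome:
                    raise ValueError(f"unknown chromosome {chrom!r} in TSS annotation")
                if (sub["tss"] < 0).any() or (sub["tss"] >= genome.length(chrom)).any():
                    raise ValueError(f"TSS outside chromosome bounds on {chrom}")
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def promoters(self, radius: int = 1000) -> pd.DataFrame:
        """Promoter intervals [tss - radius, tss + radius), clipped at 0."""
        out = self.table[["gene_id", "chrom", "tss", "strand"]].copy()
        out["start"] = np.maximum(out["tss"] - radius, 0)
        out["end"] = out["tss"] + radius
        return out

    @classmethod
    def from_tsv(cls, path, genome: Optional[GenomeDeclaration] = None) -> "TssAnnotation":
        table = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
        return cls(table, genome=genome)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _record_from_aligned_segment(aln, genome: Optional[GenomeDeclaration]):
    chrom = aln.reference_name
    if genome is not None and chrom not in genome:
        raise ValueError(f"unknown chromosome {chrom!r} in alignment file")
    if aln.is_paired and aln.is_proper_pair and aln.template_length > 0:
        # leftmost mate carries the template: collapse the pair to one fragment
        return ReadRecord(
            chrom=chrom,
            start=aln.reference_start,
            end=aln.reference_start + aln.template_length,
            strand="-" if aln.is_reverse else "+",
            mapq=aln.mapping_quality,
            is_duplicate=aln.is_duplicate,
            is_fragment=True,
        )
    if aln.is_paired and aln.is_proper_pair:
        return None  # rightmost mate of an already-collapsed pair
    return ReadRecord(
        chrom=chrom,
        start=aln.reference_start,
        end=aln.reference_end,
        strand="-" if aln.is_reverse else "+",
        mapq=aln.mapping_quality,
        is_duplicate=aln.is_duplicate,
        is_fragment=False,
    )


def read_alignments(
    path,
    min_mapq: int = 20,
    keep_duplicates: bool = True,
    genome: Optional[GenomeDeclaration] = None,
) -> Iterator[ReadRecord]:
    """Stream MAPQ-filtered ReadRecords from SAM/BAM or a read-BED table.

    The MAPQ filter is strict: only records with ``mapq > min_mapq`` pass.
    Duplicate-flagged records are kept by default (they are marked, not
    discarded, upstream); pass ``keep_duplicates=False`` to drop them.
    Proper pairs are collapsed to a single fragment spanning the outer
    template coordinates.
    """
    path = Path(path)
    if path.suffix.lower() in {".bed", ".tsv", ".txt"}:
        yield from _read_bed_reads(path, min_mapq, keep_duplicates, genome)
        return
    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality <= min_mapq:
                continue
            if aln.is_duplicate and not keep_duplicates:
                continue
            rec = _record_from_aligned_segment(aln, genome)
            if rec is not None:
                yield rec


def _read_bed_reads(path, min_mapq, keep_duplicates, genome):
    """BED-like read table: chrom start end [name] [mapq] [strand] [dup]."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed read line: {line!r}")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if genome is not None and chrom not in genome:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            mapq = int(parts[4]) if len(parts) > 4 and parts[4] not in (".", "") else 255
            strand = parts[5] if len(parts) > 5 else "+"
            dup = len(parts) > 6 and parts[6] in ("1", "dup", "True")
            if mapq <= min_mapq:
                continue
            if dup and not keep_duplicates:
                continue
            try:
                yield ReadRecord(chrom, start, end, strand, mapq, dup)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None


def reads_to_frame(reads: Iterable[ReadRecord]) -> pd.DataFrame:
    """Materialize a read stream as a DataFrame (the fast internal form)."""
    rows = [(r.chrom, r.start, r.end, r.strand, r.is_fragment) for r in reads]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "is_fragment"])


def read_intervals(path, dialect: str = "bed") -> list[GenomicInterval]:
    """Read intervals from BED (0-based half-open) or a headered TSV.

    Output is sorted by (chrom, start); inverted intervals raise with the
    offending line number.
    """
    if dialect not in {"bed", "tsv"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    out: list[GenomicInterval] = []
    if dialect == "tsv":
        table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        for i, row in table.iterrows():
            if row["start"] >= row["end"]:
                raise ValueError(f"{path} row {i}: start >= end")
            out.append(
                GenomicInterval(str(row["chrom"]), int(row["start"]), int(row["end"]),
                                name=str(row["name"]) if "name" in table.columns else None)
            )
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: malformed BED line")
                start, end = int(parts[1]), int(parts[2])
                if start >= end:
                    raise ValueError(f"{path}:{lineno}: start >= end")
                name = parts[3] if len(parts) > 3 else None
                score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else None
                out.append(GenomicInterval(parts[0], start, end, name=name, score=score))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def write_intervals(intervals: Sequence[GenomicInterval], path) -> None:
    """Write intervals as 6-column BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            score = f"{iv.score:g}" if iv.score is not None else "0"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t.\n")


def write_bedgraph(
    bins: Sequence[tuple[GenomicInterval, float]],
    path,
    merge_equal: bool = False,
    track_name: str = "coverage",
) -> None:
    """Write (interval, value) bins as bedGraph.

    Bins must be sorted and non-overlapping. With ``merge_equal`` adjacent
    bins carrying the same value are run-length merged; default off so the
    output is bit-exact with the input binning.
    """
    prev: Optional[GenomicInterval] = None
    for iv, _ in bins:
        if prev is not None and iv.chrom == prev.chrom:
            if iv.start < prev.end:
                raise ValueError(
                    f"overlapping/unsorted bins at {iv.chrom}:{iv.start}-{iv.end}"
                )
        prev = iv
    with open(path, "w") as fh:
        fh.write(f"track type=bedGraph name={track_name}\n")
        pending: Optional[list] = None  # [chrom, start, end, value]
        for iv, value in bins:
            if (
                merge_equal
                and pending is not None
                and pending[0] == iv.chrom
                and pending[2] == iv.start
                and pending[3] == value
            ):
                pending[2] = iv.end
                continue
            if pending is not None:
                fh.write(f"{pending[0]}\t{pending[1]}\t{pending[2]}\t{pending[3]:g}\n")
            pending = [iv.chrom, iv.start, iv.end, value]
        if pending is not None:
            fh.write(f"{pending[0]}\t{pending[1]}\t{pending[2]}\t{pending[3]:g}\n")


def read_fasta(path) -> dict[str, str]:
    """Plain FASTA reader returning name -> sequence (uppercased)."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                if name in seqs:
                    raise ValueError(f"duplicate FASTA record {name!r}")
                seqs[name] = []
            else:
                if name is None:
                    raise ValueError("FASTA sequence before header")
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
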