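"""Demultiplexing, UMI extraction and adapter/quality trimming.

iCLIP-style reads start with a mixed barcode: random bases (the UMI, used
later to collapse PCR duplicates) interleaved with fixed sample-barcode
bases, described by a 5'->3' layout string over ``{N, X}`` such as
``NNNXXXXNN``.  After the layout prefix comes the cDNA insert, which may run
into the 3' sequencing adapter when the insert is short.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "BarcodeSpec",
    "PreparedRead",
    "DemuxResult",
    "demultiplex",
    "trim_read",
    "read_fastq",
    "write_fastq",
]

UNASSIGNED = "unassigned"


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class BarcodeSpec:
    """Barcode layout and trimming parameters for one sequencing run.

    ``layout`` is read 5'->3'; ``N`` marks a UMI base and ``X`` a
    sample-barcode base.  Sample barcodes must be pairwise further apart
    than ``2 * max_mismatches`` so that assignment is unambiguous.
    """

    layout: str = "NNNXXXXNN"
    samples: dict[str, str] = field(default_factory=dict)
    max_mismatches: int = 1
    adapter: str = "AGATCGGAAGAGC"
    min_adapter_overlap: int = 3
    quality_cutoff: int = 20
    min_length: int = 18

    def __post_init__(self) -> None:
        if set(self.layout) - {"N", "X"}:
            raise ValueError("layout may contain only 'N' and 'X'")
        bc_len = self.layout.count("X")
        for name, bc in self.samples.items():
            if len(bc) != bc_len:
                raise ValueError(
                    f"barcode for sample {name!r} has length {len(bc)}, "
                    f"layout expects {bc_len}"
                )
        barcodes = list(self.samples.values())
        for i in range(len(barcodes)):
            for j in range(i + 1, len(barcodes)):
                if _hamming(barcodes[i], barcodes[j]) <= 2 * self.max_mismatches:
                    raise ValueError(
                        "sample barcodes too similar for unambiguous assignment "
                        f"(need pairwise Hamming distance > {2 * self.max_mismatches})"
                    )

    @property
    def umi_length(self) -> int:
        return self.layout.count("N")

    @property
    def barcode_positions(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.layout) if c == "X")

    @property
    def umi_positions(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.layout) if c == "N")


@dataclass
class PreparedRead:
    """A demultiplexed read: UMI extracted, layout prefix removed."""

    read_id: str
    sample: str
    umi: str
    sequence: str
    qualities: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DemuxResult:
    """Per-sample read bins plus the unassigned bin and a count report."""

    by_sample: dict[str, list[PreparedRead]]
    unassigned: int
    report: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.report.values())


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield ``(id, sequence, quality)`` from a FASTQ(.gz) file."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> int:
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    n = 0
    with opener(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def demultiplex(
    reads: Iterable[tuple[str, str, str]] | str | Path, spec: BarcodeSpec
) -> DemuxResult:
    """Assign reads to samples by barcode and extract UMIs.

    A read is assigned to the unique sample whose barcode is within
    ``spec.max_mismatches`` of the bases at the layout's X positions; the
    UMI is the concatenation of the N-position bases, and the whole layout
    prefix is removed from the insert.  Reads shorter than or equal to the
    layout, or without a close-enough barcode, land in the unassigned bin.
    """
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    layout_len = len(spec.layout)
    bc_pos = spec.barcode_positions
    umi_pos = spec.umi_positions
    by_sample: dict[str, list[PreparedRead]] = {name: [] for name in spec.samples}
    unassigned = 0
    for rid, seq, qual in reads:
        if len(seq) != len(qual):
            raise ValueError(f"malformed FASTQ record {rid!r}: seq/qual length differ")
        if len(seq) <= layout_len:
            unassigned += 1
            continue
        observed = "".join(seq[i] for i in bc_pos)
        hit = None
        for name, bc in spec.samples.items():
            if _hamming(observed, bc) <= spec.max_mismatches:
                hit = name
                break  # barcodes are pairwise >2*max_mismatches apart: unique
        if hit is None:
            unassigned += 1
            continue
        umi = "".join(seq[i] for i in umi_pos)
        by_sample[hit].append(
            PreparedRead(rid, hit, umi, seq[layout_len:], qual[layout_len:])
        )
    report = {name: len(v) for name, v in by_sample.items()}
    report[UNASSIGNED] = unassigned
    return DemuxResult(by_sample, unassigned, report)


def _find_adapter(seq: str, adapter: str, min_overlap: int, max_error_rate: float = 0.1) -> int | None:
    """Leftmost un-gapped adapter occurrence (internal or 3' suffix-prefix).

    At candidate start ``i`` the adapter is compared over
    ``min(len(adapter), len(seq) - i)`` bases and accepted when the overlap
    is at least ``min_overlap`` with a mismatch rate of at most
    ``max_error_rate``.  Returns the adapter start, or None.
    """
    n = len(seq)
    for i in range(0, n - min_overlap + 1):
        m = min(len(adapter), n - i)
        allowed = int(max_error_rate * m)
        mm = 0
        for a, b in zip(seq[i : i + m], adapter[:m]):
            if a != b:
                mm += 1
                if mm > allowed:
                    break
        else:
            return i
    return None


def _quality_trim_index(qualities: str, cutoff: int, offset: int = 33) -> int:
    """3' quality-trim cut index using the running-sum (BWA-style) rule."""
    s = 0
    max_s = 0
    cut = len(qualities)
    for i in range(len(qualities) - 1, -1, -1):
        s += cutoff - (ord(qualities[i]) - offset)
        if s < 0:
            break
        if s > max_s:
            max_s = s
            cut = i
    return cut


def trim_read(read: PreparedRead, spec: BarcodeSpec) -> PreparedRead | None:
    """Trim the 3' adapter, then low-quality 3' tail; drop short reads.

    Returns the trimmed read, or None when the remaining insert is shorter
    than ``spec.min_length`` (callers count discards).
    """
    seq, qual = read.sequence, read.qualities
    pos = _find_adapter(seq, spec.adapter, spec.min_adapter_overlap)
    if pos is not None:
        seq, qual = seq[:pos], qual[:pos]
    cut = _quality_trim_index(qual, spec.quality_cutoff)
    seq, qual = seq[:cut], qual[:cut]
    if len(seq) < spec.min_length:
        return None
    return PreparedRead(read.read_id, read.sample, read.umi, seq, qual)


def prepare_reads(
    reads: Iterable[tuple[str, str, str]] | str | Path, spec: BarcodeSpec
) -> tuple[dict[str, list[PreparedRead]], dict[str, int]]:
    """Demultiplex then trim; returns per-sample reads and a count report."""
    demux = demultiplex(reads, spec)
    out: dict[str, list[PreparedRead]] = {}
    discarded = 0
    for sample, rds in demux.by_sample.items():
        kept = []
        for r in rds:
            t = trim_read(r, spec)
            if t is None:
                discarded += 1
            else:
                kept.append(t)
        out[sample] = kept
    report = dict(demux.report)
    report["discarded_short"] = discarded
    return out, report
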