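"""UMI deduplication and per-nucleotide crosslink (truncation) calling.

In truncation-based CLIP the reverse transcriptase stops at the crosslinked
nucleotide, so the position immediately 5' of the cDNA start (start - 1)
is taken as the crosslink site.  This module collapses PCR duplicates by
UMI, histograms crosslink sites per reference, and applies the two
substrate-specific filters: masking the 5-nt window around the branch-point
adenosine (residual truncations at partially digested three-way lariat
junctions would otherwise masquerade as crosslinks) and removing intronic
signal for mRNA-bound (post-exon-ligation) complexes.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .mapping import AlignmentRecord, MappedLibrary, STATUS_UNIQUE
from .substrate import Substrate, TranscriptomeIndex

__all__ = [
    "CrosslinkTrack",
    "JunctionCallSummary",
    "deduplicate",
    "call_crosslinks",
    "mask_branchpoint",
    "remove_intron_crosslinks",
    "classify_junction_reads",
]


@dataclass
class CrosslinkTrack:
    """Deduplicated per-nucleotide cDNA truncation counts on one reference."""

    reference_name: str
    counts: np.ndarray
    mask: set = field(default_factory=set)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("crosslink counts must be non-negative")

    @property
    def n_cdnas(self) -> int:
        return int(self.counts.sum())

    def copy(self) -> "CrosslinkTrack":
        return CrosslinkTrack(
            self.reference_name, self.counts.copy(), set(self.mask), dict(self.meta)
        )


@dataclass(frozen=True)
class JunctionCallSummary:
    """Junction-spanning read fraction for one library."""

    n_mapped: int
    n_junction: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_junction <= self.n_mapped:
            raise ValueError("junction count outside [0, n_mapped]")

    @property
    def fraction_pct(self) -> float:
        return 100.0 * self.n_junction / self.n_mapped if self.n_mapped else 0.0


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _directional_clusters(umi_counts: Counter) -> list[str]:
    """Cluster UMIs at one position with the directional-adjacency rule.

    An edge runs from a higher-count UMI u to a neighbour v (Hamming
    distance 1) when count(u) >= 2*count(v) - 1; each connected component
    reached this way collapses into one cDNA.
    Returns one representative UMI per cluster.
    """
    order = sorted(umi_counts, key=lambda u: (-umi_counts[u], u))
    assigned: set[str] = set()
    reps = []
    for root in order:
        if root in assigned:
            continue
        reps.append(root)
        stack = [root]
        assigned.add(root)
        while stack:
            u = stack.pop()
            for v in order:
                if v in assigned or _hamming(u, v) != 1:
                    continue
                if umi_counts[u] >= 2 * umi_counts[v] - 1:
                    assigned.add(v)
                    stack.append(v)
    return reps


def deduplicate(
    alignments: list[AlignmentRecord], mode: str = "exact"
) -> list[AlignmentRecord]:
    """Collapse PCR duplicates sharing (reference, start, UMI).

    ``exact`` keeps one record per distinct key; ``directional``
    additionally merges near-identical UMIs at the same position (one
    sequencing error away, with the count-skew condition above), absorbing
    UMIs that arose from errors during amplification/sequencing.
    Idempotent in both modes.
    """
    if mode not in ("exact", "directional"):
        raise ValueError(f"unknown deduplication mode {mode!r}")
    groups: dict[tuple, Counter] = defaultdict(Counter)
    first_seen: dict[tuple, AlignmentRecord] = {}
    for rec in alignments:
        if not rec.umi:
            raise ValueError(f"read {rec.read_id!r} has no UMI; cannot deduplicate")
        key = (rec.sample, rec.reference_name, rec.start)
        groups[key][rec.umi] += 1
        first_seen.setdefault(key + (rec.umi,), rec)
    out: list[AlignmentRecord] = []
    for key, umi_counts in groups.items():
        if mode == "exact":
            keep = sorted(umi_counts)
        else:
            keep = _directional_clusters(umi_counts)
        for umi in keep:
            out.append(first_seen[key + (umi,)])
    return out


def call_crosslinks(
    alignments: list[AlignmentRecord],
    index: TranscriptomeIndex,
    include_mrna: bool = True,
) -> dict[str, CrosslinkTrack]:
    """Histogram crosslink sites (cDNA start - 1) per reference.

    cDNAs starting at reference position 0 are dropped (their crosslink
    would fall off the reference) and logged in track metadata.
    """
    tracks = {
        name: CrosslinkTrack(name, np.zeros(len(seq), dtype=np.int64))
        for name, seq in index.references.items()
        if include_mrna or name != index.mrna_name
    }
    dropped = Counter()
    for rec in alignments:
        if rec.status != STATUS_UNIQUE:
            continue
        if rec.reference_name not in tracks:
            continue
        if rec.start == 0:
            dropped[rec.reference_name] += 1
            continue
        tracks[rec.reference_name].counts[rec.start - 1] += 1
    for name, track in tracks.items():
        track.meta["dropped_start_zero"] = dropped.get(name, 0)
    return tracks


def mask_branchpoint(
    track: CrosslinkTrack, substrate: Substrate, halfwidth: int = 2
) -> CrosslinkTrack:
    """Zero the crosslink counts in the window around the branch point.

    With the default halfwidth of 2 this removes the five positions
    brA-2 .. brA+2 (clipped at the reference ends); removed totals are
    logged in metadata and the positions recorded in the track mask.
    """
    if track.reference_name != substrate.name:
        raise ValueError("branch-point masking applies to the substrate track only")
    out = track.copy()
    lo = max(0, substrate.brA - halfwidth)
    hi = min(len(out.counts), substrate.brA + halfwidth + 1)
    removed = int(out.counts[lo:hi].sum())
    out.counts[lo:hi] = 0
    out.mask.update(range(lo, hi))
    out.meta["masked_branchpoint_cdnas"] = removed
    out.meta["branchpoint_window"] = (lo, hi)
    return out


def remove_intron_crosslinks(
    track: CrosslinkTrack, substrate: Substrate
) -> CrosslinkTrack:
    """Zero all intronic crosslinks (used for mRNA-bound complex profiles)."""
    if track.reference_name != substrate.name:
        raise ValueError("intron removal applies to the substrate track only")
    out = track.copy()
    a, b = substrate.intron
    removed = int(out.counts[a:b].sum())
    out.counts[a:b] = 0
    out.mask.update(range(a, b))
    out.meta["removed_intron_cdnas"] = removed
    return out


def classify_junction_reads(
    library: MappedLibrary, index: TranscriptomeIndex, min_flank: int = 5
) -> JunctionCallSummary:
    """Count reads spanning the exon-exon junction of the spliced mRNA.

    A read counts as junction-spanning when it maps uniquely to the derived
    mRNA reference with at least ``min_flank`` aligned nucleotides on each
    side of the junction (exon-shared reads resolved to the substrate never
    qualify).  The fraction is over all uniquely mapped reads.
    """
    if index.mrna_name is None or index.junction is None:
        raise ValueError("transcriptome index has no derived mRNA reference")
    j = index.junction
    n_junction = 0
    for rec in library.alignments:
        if rec.reference_name != index.mrna_name or rec.exonic_shared:
            continue
        if rec.start <= j - min_flank and rec.start + rec.length >= j + min_flank:
            n_junction += 1
    return JunctionCallSummary(n_mapped=len(library.alignments), n_junction=n_junction)
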