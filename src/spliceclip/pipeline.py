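"""High-level orchestration: reads in, profiles and QC out.

Chains the stages in the canonical order — demultiplex/trim, two-pass
mapping, UMI deduplication, crosslink calling, branch-point masking,
background normalization, control subtraction, Gaussian smoothing — and
aggregates the per-stage numbers the run report prints.
"""

from __future__ import annotations

from dataclasses import dataclass

from .crosslinks import (
    CrosslinkTrack,
    JunctionCallSummary,
    call_crosslinks,
    classify_junction_reads,
    deduplicate,
    mask_branchpoint,
    remove_intron_crosslinks,
)
from .mapping import MappedLibrary, two_pass_map
from .profiles import NormalizedProfile, gaussian_smooth, normalize, subtract_control
from .readprep import PreparedRead
from .substrate import TranscriptomeIndex

__all__ = ["PipelineParams", "SampleResult", "process_sample", "substrate_profile"]


@dataclass(frozen=True)
class PipelineParams:
    """Stage parameters; every default mirrors the documented contract."""

    max_mismatches: int = 2
    dedup_mode: str = "exact"
    mask_halfwidth: int = 2
    smoothing_window: int = 10
    junction_min_flank: int = 5
    remove_intron: bool = False
    mask_branchpoint: bool = True


@dataclass
class SampleResult:
    """Everything the pipeline derives from one demultiplexed sample."""

    sample: str
    library: MappedLibrary
    tracks: dict[str, CrosslinkTrack]
    background_cdnas: int
    junction: JunctionCallSummary
    n_input_reads: int = 0

    def track(self, name: str) -> CrosslinkTrack:
        return self.tracks[name]


def process_sample(
    reads: list[PreparedRead],
    index: TranscriptomeIndex,
    background: TranscriptomeIndex | None,
    params: PipelineParams = PipelineParams(),
    sample: str = "sample",
) -> SampleResult:
    """Map, deduplicate and call crosslinks for one sample's reads."""
    lib = two_pass_map(reads, index, background, params.max_mismatches)
    dedup = deduplicate(lib.alignments, params.dedup_mode)
    bg_dedup = deduplicate(lib.background_alignments, params.dedup_mode)
    tracks = call_crosslinks(dedup, index)
    junction = classify_junction_reads(lib, index, params.junction_min_flank)
    sub = index.substrate
    if sub is not None and sub.name in tracks:
        track = tracks[sub.name]
        if params.mask_branchpoint:
            track = mask_branchpoint(track, sub, params.mask_halfwidth)
        if params.remove_intron:
            track = remove_intron_crosslinks(track, sub)
        tracks[sub.name] = track
    return SampleResult(
        sample=sample,
        library=lib,
        tracks=tracks,
        background_cdnas=len(bg_dedup),
        junction=junction,
        n_input_reads=len(reads),
    )


def substrate_profile(
    result: SampleResult,
    index: TranscriptomeIndex,
    control: SampleResult | None = None,
    params: PipelineParams = PipelineParams(),
) -> NormalizedProfile:
    """Normalized, control-subtracted, smoothed substrate profile."""
    sub = index.substrate
    profile = normalize(result.tracks[sub.name], result.background_cdnas)
    if control is not None:
        ctrl = normalize(control.tracks[sub.name], control.background_cdnas)
        profile = subtract_control(profile, ctrl)
    return gaussian_smooth(profile, params.smoothing_window)
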