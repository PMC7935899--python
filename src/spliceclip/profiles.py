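"""Normalization, smoothing, and the quantitative summaries of binding.

Crosslink counts from different libraries are not directly comparable:
library depth varies with input and PCR. Because every library also
captures endogenous (background) RNA, the background-mapping cDNA count
acts like a spike-in — signal is expressed per million background cDNAs.
Control libraries (untagged protein, or no UV) are subtracted pointwise,
and profiles are drawn as Gaussian-smoothed curves (default window 10 nt,
matching the ~9 nt of RNA spanned by a DEAH-box helicase's RecA domains).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .crosslinks import CrosslinkTrack
from .substrate import Substrate, TranscriptomeIndex

__all__ = [
    "NormalizedProfile",
    "PositionSummary",
    "TTestResult",
    "normalize",
    "subtract_control",
    "gaussian_smooth",
    "species_proportions",
    "snrna_enrichment",
    "weighted_position_summary",
    "find_main_peak",
    "compare_peak_positions",
]


@dataclass
class NormalizedProfile:
    """Per-nucleotide signal with provenance flags.

    Values are real (possibly negative after control subtraction);
    ``scale_factor`` is the reads-per-background-million multiplier and
    ``provenance`` accumulates the stages applied, in order.
    """

    reference_name: str
    values: np.ndarray
    scale_factor: float = 1.0
    window: int | None = None
    provenance: tuple[str, ...] = ("raw",)
    mask: set = field(default_factory=set)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def is_subtracted(self) -> bool:
        return "subtracted" in self.provenance

    @property
    def is_smoothed(self) -> bool:
        return "smoothed" in self.provenance


def normalize(track: CrosslinkTrack, background_cdna_count: int) -> NormalizedProfile:
    """Express counts per million background (endogenous-RNA) cDNAs."""
    if background_cdna_count <= 0:
        raise ValueError(
            "background cDNA count must be positive; for libraries without "
            "background reads run the pipeline in raw (unnormalized) mode"
        )
    scale = 1e6 / background_cdna_count
    return NormalizedProfile(
        track.reference_name,
        track.counts * scale,
        scale_factor=scale,
        provenance=("raw", "normalized"),
        mask=set(track.mask),
        meta=dict(track.meta),
    )


def subtract_control(
    signal: NormalizedProfile, control: NormalizedProfile
) -> NormalizedProfile:
    """Pointwise signal - control; negative values are retained and flagged."""
    if signal.reference_name != control.reference_name:
        raise ValueError("signal and control are on different references")
    if len(signal) != len(control):
        raise ValueError("signal and control lengths differ")
    values = signal.values - control.values
    out = replace(
        signal,
        values=values,
        provenance=signal.provenance + ("subtracted",),
        mask=set(signal.mask) | set(control.mask),
        meta=dict(signal.meta),
    )
    out.meta["has_negative"] = bool((values < 0).any())
    return out


def _gaussian_kernel(window: int) -> np.ndarray:
    """Truncated discrete Gaussian: sigma = window/4, support +-window//2."""
    if window < 1:
        raise ValueError("window must be >= 1")
    half = window // 2
    sigma = window / 4.0
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_smooth(profile: NormalizedProfile, window: int = 10) -> NormalizedProfile:
    """Gaussian-smooth a profile with a renormalized truncated kernel.

    Each position's signal is redistributed with kernel weights clipped to
    the reference and renormalized to sum 1, so total signal mass is
    conserved exactly (also at the boundaries) and a constant profile is
    unchanged at interior positions.
    """
    k = _gaussian_kernel(window)
    ones = np.ones_like(profile.values)
    z = np.convolve(ones, k, mode="same")  # per-source clipped kernel mass
    values = np.convolve(profile.values / z, k, mode="same")
    return replace(
        profile,
        values=values,
        window=window,
        provenance=profile.provenance + ("smoothed",),
    )


def species_proportions(
    tracks: Mapping[str, CrosslinkTrack] | Sequence[Mapping[str, CrosslinkTrack]],
    index: TranscriptomeIndex | None = None,
) -> pd.DataFrame:
    """Proportion of deduplicated cDNAs per reference (and class).

    Accepts one track set, or a sequence of replicate track sets which are
    summed before proportions are computed.
    """
    if not isinstance(tracks, Mapping):
        replicates = list(tracks)
        if not replicates:
            raise ValueError("no track sets given")
        totals: dict[str, int] = {}
        for rep in replicates:
            for name, tr in rep.items():
                totals[name] = totals.get(name, 0) + tr.n_cdnas
    else:
        totals = {name: tr.n_cdnas for name, tr in tracks.items()}
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError("all tracks are empty; proportions undefined")
    rows = []
    for name, n in totals.items():
        rows.append(
            {
                "reference": name,
                "class": index.classes.get(name, "?") if index else "?",
                "n_cdnas": n,
                "proportion": n / grand,
            }
        )
    return pd.DataFrame(rows).set_index("reference")


def snrna_enrichment(
    tagged: Mapping[str, CrosslinkTrack],
    untagged: Mapping[str, CrosslinkTrack],
    index: TranscriptomeIndex,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """snRNA enrichment of a tagged over an untagged library.

    Within each condition, per-snRNA cDNA counts (plus a pseudocount) are
    first normalized to the total snRNA crosslinks of that sample; the
    enrichment is the log2 ratio of those fractions.
    """
    names = index.snrna_names
    if not names:
        raise ValueError("index contains no snRNA references")
    for name in names:
        if name not in tagged or name not in untagged:
            raise KeyError(f"snRNA {name!r} missing from one condition")
    t = np.array([tagged[n].n_cdnas + pseudocount for n in names], dtype=float)
    u = np.array([untagged[n].n_cdnas + pseudocount for n in names], dtype=float)
    ft = t / t.sum()
    fu = u / u.sum()
    return pd.DataFrame(
        {
            "tagged_fraction": ft,
            "untagged_fraction": fu,
            "log2fc": np.log2(ft / fu),
            "pseudocount": pseudocount,
        },
        index=pd.Index(names, name="snRNA"),
    )


@dataclass(frozen=True)
class PositionSummary:
    """Weighted box-plot statistics of crosslink positions."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[int, ...]

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def _weighted_quantile(
    positions: np.ndarray, weights: np.ndarray, q: float
) -> float:
    """Inverted-CDF weighted quantile: smallest position with F(x) >= q.

    Equals ``np.quantile(expanded, q, method="inverted_cdf")`` on the
    weight-expanded sample for integer weights, and is invariant under
    rescaling all weights.
    """
    cw = np.cumsum(weights)
    total = cw[-1]
    idx = int(np.searchsorted(cw, q * total, side="left"))
    return float(positions[min(idx, len(positions) - 1)])


def weighted_position_summary(profile: NormalizedProfile) -> PositionSummary:
    """Box-plot summary of positions weighted by (non-negative) signal.

    Whiskers extend to the most extreme weighted positions within
    1.5 * IQR of the box; positions with weight outside that range are
    reported as outliers.  Subtracted profiles (which can be negative) are
    rejected: summaries are meant for raw or normalized counts.
    """
    w = profile.values
    if (w < 0).any():
        raise ValueError(
            "weighted summaries need non-negative weights; use a raw or "
            "normalized profile, not a control-subtracted one"
        )
    nz = np.nonzero(w)[0]
    if nz.size == 0:
        raise ValueError("profile has zero total weight")
    pos = nz.astype(float)
    wts = w[nz]
    q1 = _weighted_quantile(pos, wts, 0.25)
    med = _weighted_quantile(pos, wts, 0.5)
    q3 = _weighted_quantile(pos, wts, 0.75)
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = pos[(pos >= lo_fence) & (pos <= hi_fence)]
    outliers = tuple(int(p) for p in pos[(pos < lo_fence) | (pos > hi_fence)])
    return PositionSummary(
        median=med,
        q1=q1,
        q3=q3,
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
    )


def find_main_peak(
    profile: NormalizedProfile,
    substrate: Substrate,
    region: tuple[int, int] | None = None,
    anchor: str = "brA",
) -> int | None:
    """Position of the profile maximum, relative to a landmark.

    Only strictly positive values inside ``region`` (default: the whole
    reference) and outside the mask are candidates; ties break to the
    smallest coordinate.  Returns None when no positive signal exists
    ("no peak").
    """
    a, b = region if region is not None else (0, len(profile))
    if not (0 <= a < b <= len(profile)):
        raise ValueError(f"region [{a}, {b}) outside reference")
    values = profile.values.copy()
    if profile.mask:
        values[list(profile.mask)] = -np.inf
    window = values[a:b]
    best = int(np.argmax(window))
    if not window[best] > 0:
        return None
    return substrate.to_relative(a + best, anchor)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def compare_peak_positions(
    group_a: Sequence[float], group_b: Sequence[float]
) -> TTestResult:
    """Student's unpaired two-sided t test on replicate peak positions.

    Pooled-variance statistic with df = n_a + n_b - 2.  Degenerate inputs
    (zero pooled variance) are handled explicitly: equal means give
    t=0, p=1; unequal means give p -> 0, flagged.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two replicate values per group")
    df = len(a) + len(b) - 2
    pooled = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    if pooled == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, df, 1.0)
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return TTestResult(sign * math.inf, df, 0.0, degenerate=True)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(t), df, float(p))
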