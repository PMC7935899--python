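"""Independent reference implementations used to check the pipeline.

Everything here is deliberately naive (brute force, enumeration, closed
form) and shares no code with the package internals it validates.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_align(seq: str, references: dict[str, str], max_mismatches: int = 2):
    """Hamming scan over every offset of every reference, forward strand.

    Returns (status, reference, start, mismatches) with the same
    conventions as the mapper: a single strictly-best placement is
    'unique'; a tie at the minimum is 'ambiguous' (-1 start); no placement
    within max_mismatches is 'unmapped' (-1 start, -1 mismatches).
    """
    best = max_mismatches + 1
    placements = []
    for name, ref in references.items():
        for off in range(len(ref) - len(seq) + 1):
            mm = 0
            for a, b in zip(seq, ref[off : off + len(seq)]):
                if a != b:
                    mm += 1
                    if mm > max_mismatches:
                        break
            else:
                placements.append((name, off, mm))
                if mm < best:
                    best = mm
    if best > max_mismatches:
        return ("unmapped", None, -1, -1)
    top = [(n, s) for n, s, m in placements if m == best]
    if len(top) > 1:
        return ("ambiguous", None, -1, best)
    return ("unique", top[0][0], top[0][1], best)


def naive_gaussian_smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Direct O(n*w) smoothing: each source's clipped kernel renormalized."""
    half = window // 2
    sigma = window / 4.0
    offsets = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (offsets / sigma) ** 2)
    kernel = kernel / kernel.sum()
    n = len(values)
    out = np.zeros(n)
    for j in range(n):
        lo = max(0, j - half)
        hi = min(n, j + half + 1)
        k = kernel[(lo - j) + half : (hi - j) + half]
        out[lo:hi] += values[j] * k / k.sum()
    return out


def best_adapter_overlap(seq: str, adapter: str, min_overlap: int,
                         max_error_rate: float = 0.1) -> int | None:
    """Leftmost acceptable adapter start by exhaustive overlap enumeration."""
    for i in range(len(seq) - min_overlap + 1):
        m = min(len(adapter), len(seq) - i)
        mm = sum(a != b for a, b in zip(seq[i : i + m], adapter[:m]))
        if m >= min_overlap and mm <= int(max_error_rate * m):
            return i
    return None


def fragment_pmf(fmin: int, fmean: float, fmax: int) -> dict[int, float]:
    """PMF of the truncated-geometric fragment length the simulator draws."""
    p = 1.0 / (fmean - fmin + 1.0)
    pmf = {}
    for k in range(fmin, fmax):
        pmf[k] = (1 - p) ** (k - fmin) * p
    pmf[fmax] = (1 - p) ** (fmax - fmin)
    return pmf


def expected_junction_fraction(index, model, design, min_flank: int = 5,
                               background=None) -> float:
    """Closed-form expected junction-read fraction of custom-mapped reads.

    Derived purely from the generator's parameters and read geometry: the
    binding model's components lie in the intron, so spliced-mRNA
    crosslinks are uniform along the mRNA; a read spans the junction when
    its start s (= crosslink + 1) satisfies j+min_flank-f <= s <= j-min_flank.
    The denominator excludes background-derived reads and reads whose
    insert (clipped at the reference 3' end) falls below the length filter.
    """
    sub = index.substrate
    j = index.junction
    mrna_len = index.length(index.mrna_name)
    min_len = 18
    pmf = fragment_pmf(design.fragment_min, design.fragment_mean, design.fragment_max)

    species = ["substrate"] + index.snrna_names
    w = np.array([model.species_propensity.get(s, 0.0) for s in species])
    w = w / w.sum()
    p_bg = model.background_fraction if background is not None else 0.0

    def p_short_uniform(n_positions: int) -> float:
        # crosslink uniform on [0, L-2]; insert length L-1-xl; short iff < min_len
        return (min_len - 1) / (n_positions - 1)

    # probability a custom-transcriptome read fails the length filter
    p_short = 0.0
    for name, ws in zip(species, w):
        if name == "substrate":
            continue
        p_short += (1 - p_bg) * float(ws) * p_short_uniform(index.length(name))
    p_sub = (1 - p_bg) * float(w[0])
    mix = design.molecule_mix
    ns = model.nonspecific_rate
    sub_len = len(sub)
    intron_positions = sub_len - sub.intron[0]
    p_short += p_sub * mix.get("pre_mrna", 0.0) * ns * p_short_uniform(sub_len)
    p_short += (
        p_sub
        * mix.get("lariat", 0.0)
        * (1 - design.branch_artifact_rate)
        * ns
        * p_short_uniform(intron_positions)
    )
    p_short += p_sub * mix.get("mrna", 0.0) * p_short_uniform(mrna_len)

    # junction-spanning probability (mRNA reads are uniform; never clipped
    # in the junction window because mrna_len - (j - min_flank) > fmax)
    e_starts = sum(p * max(0, f - (2 * min_flank - 1)) for f, p in pmf.items())
    p_junction = p_sub * mix.get("mrna", 0.0) * e_starts / (mrna_len - 1)

    p_mapped_custom = (1 - p_bg) - p_short
    return p_junction / p_mapped_custom


def binomial_ci(p: float, n: int, z: float = 1.96) -> tuple[float, float]:
    """Normal-approximation 95% CI for a binomial proportion."""
    half = z * math.sqrt(p * (1 - p) / n)
    return p - half, p + half


def pooled_t(a, b):
    """Closed-form pooled-variance two-sample t statistic and df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t, df
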