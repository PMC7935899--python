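"""Synthetic psiCLIP-style library generator with per-read ground truth.

The generator emulates what the wet assay hands to the pipeline: cDNAs
that truncate at a protein crosslink site, drawn from a configurable
binding model over the substrate and snRNAs; a mixture of molecule species
(intact pre-mRNA, post-branching lariat intermediate, spliced mRNA);
residual branch-point truncation artifacts from incompletely debranched
lariats; PCR duplicates sharing a UMI; uniform sequencing errors; reads of
endogenous background RNA; and matched control libraries (untagged protein
or no UV) containing only background and a non-specific floor.

Every emitted FASTQ record has exactly one ground-truth row, so each
pipeline stage can be scored against what the generator actually did.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .crosslinks import CrosslinkTrack
from .readprep import BarcodeSpec
from .substrate import Substrate, TranscriptomeIndex, background_index

__all__ = [
    "GaussianComponent",
    "UniformComponent",
    "BindingModel",
    "LibraryDesign",
    "simulate_library",
    "truth_compare",
    "demo_transcriptome",
    "default_barcode_spec",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

MOLECULE_PRE_MRNA = "pre_mrna"
MOLECULE_LARIAT = "lariat"
MOLECULE_MRNA = "mrna"


@dataclass(frozen=True)
class GaussianComponent:
    """Gaussian binding component centred ``mu`` nt from ``anchor``."""

    mu: float
    sd: float
    weight: float = 1.0
    anchor: str = "brA"


@dataclass(frozen=True)
class UniformComponent:
    """Uniform binding over relative offsets [a, b] (inclusive) from ``anchor``."""

    a: int
    b: int
    weight: float = 1.0
    anchor: str = "brA"


@dataclass
class BindingModel:
    """Where crosslinks fall, and on which RNA species.

    ``species_propensity`` gives relative crosslink rates for the substrate
    (key ``"substrate"``) and each snRNA by name; snRNA crosslinks are
    uniform along the snRNA.  ``background_fraction`` is the probability a
    template derives from endogenous background RNA; ``nonspecific_rate``
    is a uniform crosslink floor on the profiled references.
    """

    components: Sequence[GaussianComponent | UniformComponent]
    species_propensity: dict[str, float] = field(
        default_factory=lambda: {"substrate": 1.0}
    )
    background_fraction: float = 0.15
    nonspecific_rate: float = 0.02

    def __post_init__(self) -> None:
        w = sum(c.weight for c in self.components)
        if self.components and not np.isclose(w, 1.0):
            raise ValueError(f"component weights must sum to 1 (got {w})")
        for p in (self.background_fraction, self.nonspecific_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class LibraryDesign:
    """Library-level parameters: molecule mix, digestion, PCR, errors.

    Fragment lengths follow a truncated geometric between ``fragment_min``
    and ``fragment_max`` with the given mean, emulating controlled RNase
    digestion; PCR copy numbers are geometric with mean
    ``pcr_duplicate_mean``.  ``control_mode`` other than ``tagged_uv``
    yields background + non-specific floor reads only.
    """

    n_reads: int = 10_000
    seed: int = 0
    molecule_mix: dict[str, float] = field(
        default_factory=lambda: {
            MOLECULE_PRE_MRNA: 1.0,
            MOLECULE_LARIAT: 0.0,
            MOLECULE_MRNA: 0.0,
        }
    )
    branch_artifact_rate: float = 0.05
    fragment_min: int = 20
    fragment_mean: float = 35.0
    fragment_max: int = 60
    pcr_duplicate_mean: float = 2.0
    seq_error_rate: float = 1e-3
    read_length: int = 76
    quality_char: str = "I"
    control_mode: str = "tagged_uv"

    def __post_init__(self) -> None:
        total = sum(self.molecule_mix.get(m, 0.0) for m in
                    (MOLECULE_PRE_MRNA, MOLECULE_LARIAT, MOLECULE_MRNA))
        if not np.isclose(total, 1.0):
            raise ValueError(f"molecule_mix must sum to 1 (got {total})")
        if not self.fragment_min <= self.fragment_mean <= self.fragment_max:
            raise ValueError("need fragment_min <= fragment_mean <= fragment_max")
        if self.control_mode not in ("tagged_uv", "no_tag", "no_uv"):
            raise ValueError(f"unknown control_mode {self.control_mode!r}")


def _fragment_length(rng: np.random.Generator, design: LibraryDesign) -> int:
    p = 1.0 / (design.fragment_mean - design.fragment_min + 1.0)
    return min(design.fragment_min + int(rng.geometric(p)) - 1, design.fragment_max)


def _draw_component_position(
    rng: np.random.Generator,
    model: BindingModel,
    substrate: Substrate,
    accessible: tuple[int, int],
) -> int:
    """Absolute substrate crosslink position from the component mixture.

    Rejection-sampled into the accessible half-open interval; after 100
    failed draws, falls back to a uniform position (degenerate models).
    """
    lo, hi = accessible
    weights = np.array([c.weight for c in model.components])
    for _ in range(100):
        comp = model.components[rng.choice(len(model.components), p=weights)]
        base = substrate.brA if comp.anchor == "brA" else substrate.ss3
        if isinstance(comp, GaussianComponent):
            pos = base + int(round(rng.normal(comp.mu, comp.sd)))
        else:
            pos = base + int(rng.integers(comp.a, comp.b + 1))
        if lo <= pos < hi:
            return pos
    return int(rng.integers(lo, hi))


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n_err = rng.binomial(len(arr), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(arr), size=n_err, replace=False)
    for i in pos:
        choices = BASES[BASES != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode("ascii")


def _layout_prefix(layout: str, umi: str, barcode: str) -> str:
    it_u, it_b = iter(umi), iter(barcode)
    return "".join(next(it_u) if c == "N" else next(it_b) for c in layout)


def simulate_library(
    index: TranscriptomeIndex,
    model: BindingModel,
    design: LibraryDesign,
    spec: BarcodeSpec,
    sample: str,
    background: TranscriptomeIndex | None = None,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Generate one library: FASTQ records plus a ground-truth table.

    Templates (cDNAs) are drawn until the requested number of reads,
    duplicates included, has been emitted; a single seeded generator makes
    reruns byte-identical.  Truth rows record, per emitted read, the
    molecule class, source reference, crosslink position (the position the
    pipeline should call), UMI, duplicate lineage, and artifact/background
    flags.
    """
    if sample not in spec.samples:
        raise ValueError(f"sample {sample!r} not in the barcode spec")
    sub = index.substrate
    if sub is None:
        raise ValueError("index has no substrate annotation")
    rng = np.random.default_rng(design.seed)
    barcode = spec.samples[sample]
    mrna_name, junction = index.mrna_name, index.junction
    mrna_len = index.length(mrna_name) if mrna_name else 0
    intron_len = sub.intron[1] - sub.intron[0]
    snrna_names = index.snrna_names
    species = ["substrate"] + snrna_names
    sp_w = np.array(
        [model.species_propensity.get(s, 0.0) for s in species], dtype=float
    )
    if sp_w.sum() <= 0:
        raise ValueError("species_propensity gives zero total rate")
    sp_w = sp_w / sp_w.sum()
    molecules = [MOLECULE_PRE_MRNA, MOLECULE_LARIAT, MOLECULE_MRNA]
    mol_w = np.array([design.molecule_mix.get(m, 0.0) for m in molecules])
    bg_names = list(background.references) if background is not None else []
    bg_w = None
    if bg_names:
        bg_w = np.array([background.length(n) for n in bg_names], dtype=float)
        bg_w /= bg_w.sum()
    specific = design.control_mode == "tagged_uv"

    records: list[tuple[str, str, str]] = []
    truth_rows: list[dict] = []
    lineage = 0
    while len(records) < design.n_reads:
        lineage += 1
        is_background = bool(bg_names) and rng.random() < model.background_fraction
        is_artifact = False
        molecule = None
        if is_background:
            ref_name = bg_names[rng.choice(len(bg_names), p=bg_w)]
            ref_seq = background.references[ref_name]
            xl = int(rng.integers(0, len(ref_seq) - 1))
            start = xl + 1
        else:
            sp = species[rng.choice(len(species), p=sp_w)]
            if sp != "substrate":
                ref_name = sp
                ref_seq = index.references[sp]
                xl = int(rng.integers(0, len(ref_seq) - 1))
                start = xl + 1
                molecule = None
            else:
                molecule = (
                    molecules[rng.choice(3, p=mol_w)] if specific else MOLECULE_PRE_MRNA
                )
                nonspecific = (not specific) or rng.random() < model.nonspecific_rate
                if molecule == MOLECULE_MRNA:
                    ref_name, ref_seq = mrna_name, index.references[mrna_name]
                    if nonspecific:
                        xl = int(rng.integers(0, mrna_len - 1))
                    else:
                        xl = None
                        for _ in range(100):
                            p = _draw_component_position(
                                rng, model, sub, (0, len(sub) - 1)
                            )
                            if p < sub.exon1[1]:
                                xl = p
                                break
                            if p >= sub.exon2[0]:
                                xl = p - intron_len
                                break
                        if xl is None or xl >= mrna_len - 1:
                            xl = int(rng.integers(0, mrna_len - 1))
                    start = xl + 1
                else:
                    ref_name, ref_seq = sub.name, index.references[sub.name]
                    lo = sub.intron[0] if molecule == MOLECULE_LARIAT else 0
                    if nonspecific:
                        xl = int(rng.integers(lo, len(ref_seq) - 1))
                    else:
                        xl = _draw_component_position(
                            rng, model, sub, (lo, len(ref_seq) - 1)
                        )
                    start = xl + 1
                    if (
                        molecule == MOLECULE_LARIAT
                        and rng.random() < design.branch_artifact_rate
                    ):
                        # truncation at the partially digested three-way
                        # lariat junction: apparent cDNA start = brA + 1
                        is_artifact = True
                        start = sub.brA + 1
                        xl = sub.brA
        frag = _fragment_length(rng, design)
        insert = ref_seq[start : start + frag]
        umi = "".join(
            "ACGT"[i] for i in rng.integers(0, 4, size=spec.umi_length)
        )
        prefix = _layout_prefix(spec.layout, umi, barcode)
        template = (prefix + insert + spec.adapter)[: design.read_length]
        copies = int(rng.geometric(1.0 / design.pcr_duplicate_mean))
        for c in range(copies):
            if len(records) >= design.n_reads:
                break
            seq = _apply_errors(rng, template, design.seq_error_rate)
            read_id = f"{sample}:t{lineage}:c{c}"
            records.append((read_id, seq, design.quality_char * len(seq)))
            truth_rows.append(
                {
                    "read_id": read_id,
                    "sample": sample,
                    "molecule": molecule if molecule else ("background" if is_background else "snRNA"),
                    "reference": ref_name,
                    "crosslink": xl,
                    "rel_brA": (xl - sub.brA) if ref_name == sub.name else np.nan,
                    "umi": umi,
                    "lineage": lineage,
                    "insert_len": len(insert),
                    "is_background": is_background,
                    "is_artifact": is_artifact,
                }
            )
    truth = pd.DataFrame(truth_rows)
    return records, truth


def truth_compare(
    truth: pd.DataFrame,
    tracks: dict[str, CrosslinkTrack],
    index: TranscriptomeIndex,
    junction_summary=None,
    min_flank: int = 5,
) -> dict:
    """Score called crosslink tracks against the generator's truth table.

    Reports the exact per-position recovery rate for non-artifact,
    non-background cDNAs (duplicates collapsed via lineage ids), the
    duplicate-collapse accuracy, and — when a junction summary is given —
    the junction-read confusion counts.  Truth crosslinks of spliced-mRNA
    reads that lie fully within one exon are projected onto the substrate,
    mirroring how the mapper resolves exon-shared placements.
    """
    sub = index.substrate
    j, mrna_name = index.junction, index.mrna_name
    intron_len = sub.intron[1] - sub.intron[0]
    cdnas = truth[~truth.is_background & ~truth.is_artifact].drop_duplicates(
        subset=["lineage"]
    )
    expected: dict[str, np.ndarray] = {
        name: np.zeros(index.length(name), dtype=np.int64) for name in tracks
    }
    # distinct (reference, position, UMI) triples: what exact-mode UMI
    # deduplication should leave — colliding UMIs at one position collapse
    seen: set[tuple[str, int, str]] = set()
    for row in cdnas.itertuples():
        ref, xl = row.reference, int(row.crosslink)
        if ref == mrna_name:
            start, end = xl + 1, xl + 1 + row.insert_len
            if end <= j:
                ref, xl = sub.name, xl
            elif start >= j:
                ref, xl = sub.name, xl + intron_len
        key = (ref, xl, row.umi)
        if ref in expected and xl >= 0 and key not in seen:
            seen.add(key)
            expected[ref][xl] += 1
    n_expected = sum(int(e.sum()) for e in expected.values())
    n_called = int(sum(t.n_cdnas for t in tracks.values()))
    n_recovered = sum(
        int(np.minimum(expected[name], tracks[name].counts).sum()) for name in tracks
    )
    report = {
        "n_truth_cdnas": n_expected,
        "n_recovered": n_recovered,
        "exact_recovery_rate": n_recovered / n_expected if n_expected else float("nan"),
        "called_correct_rate": n_recovered / n_called if n_called else float("nan"),
        "n_called_cdnas": n_called,
        "n_truth_lineages": int(truth.lineage.nunique()),
    }
    if junction_summary is not None:
        is_j = (
            (truth.reference == mrna_name)
            & (truth.crosslink + 1 <= j - min_flank)
            & (truth.crosslink + 1 + truth.insert_len >= j + min_flank)
        )
        report["n_junction_truth"] = int(is_j.sum())
        report["n_junction_called"] = junction_summary.n_junction
    return report


# ---------------------------------------------------------------------------
# Ready-made study conditions (a realistic yeast-scale toy transcriptome)

#: snRNA lengths of the S. cerevisiae spliceosomal snRNAs.
SNRNA_LENGTHS = {"U1": 568, "U2": 1175, "U4": 160, "U5": 214, "U6": 112}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def demo_transcriptome(
    seed: int = 7,
    exon1_len: int = 120,
    intron_len: int = 380,
    exon2_len: int = 120,
    bra_to_ss3: int = 39,
) -> tuple[TranscriptomeIndex, TranscriptomeIndex]:
    """A synthetic substrate + snRNA index and a background decoy index.

    The substrate mimics an ACT1-scale splicing reporter: exon1-intron-exon2
    with the branch-point adenosine ``bra_to_ss3`` nucleotides upstream of
    the 3' splice site.  Sequences are random (seeded); the background is a
    pair of unrelated decoy transcripts standing in for endogenous RNA.
    """
    rng = np.random.default_rng(seed)
    n = exon1_len + intron_len + exon2_len
    seq = _random_seq(rng, n)
    intron = (exon1_len, exon1_len + intron_len)
    bra = intron[1] - 1 - bra_to_ss3
    seq = seq[:bra] + "A" + seq[bra + 1 :]  # the branch point is an adenosine
    substrate = Substrate(
        name="substrate",
        sequence=seq,
        exon1=(0, exon1_len),
        intron=intron,
        exon2=(intron[1], n),
        brA=bra,
    )
    refs = {"substrate": seq}
    for name, length in SNRNA_LENGTHS.items():
        refs[name] = _random_seq(rng, length)
    index = TranscriptomeIndex.from_sequences(refs, substrate)
    bg = background_index(
        {"decoy1": _random_seq(rng, 1500), "decoy2": _random_seq(rng, 1500)}
    )
    return index, bg


def default_barcode_spec() -> BarcodeSpec:
    """Standard iCLIP-style layout with three well-separated sample barcodes."""
    return BarcodeSpec(
        layout="NNNXXXXNN",
        samples={"uv": "ACGT", "no_tag": "TGCA", "no_uv": "GATC"},
    )
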