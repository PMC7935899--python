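"""Ready-made synthetic study conditions for benchmarking the pipeline.

Each function bundles a binding model + library design that emulates one
of the canonical experiment types — a C-complex-like helicase peak
downstream of the branch point with a matched no-tag control, a
P-complex-like library rich in spliced mRNA (junction reads), and a
tagged/untagged pair for snRNA enrichment — so the same conditions can be
run from tests, scripts, or a notebook with one call.
"""

from __future__ import annotations

from .pipeline import PipelineParams, SampleResult, process_sample, substrate_profile
from .profiles import find_main_peak, snrna_enrichment
from .readprep import prepare_reads
from .simulate import (
    BindingModel,
    GaussianComponent,
    LibraryDesign,
    default_barcode_spec,
    demo_transcriptome,
    simulate_library,
)

__all__ = [
    "helicase_model",
    "control_model",
    "run_sample",
    "detected_peak",
    "junction_conditions",
    "enrichment_propensities",
]


def helicase_model(mu: float = 20.0, sd: float = 3.0) -> BindingModel:
    """Prp16-like binding: one Gaussian downstream of the brA, plus snRNA
    contacts on the catalytic-core snRNAs (U2/U5/U6)."""
    return BindingModel(
        components=[GaussianComponent(mu, sd, anchor="brA")],
        species_propensity={"substrate": 0.7, "U2": 0.1, "U5": 0.1, "U6": 0.1},
        background_fraction=0.15,
        nonspecific_rate=0.02,
    )


def control_model() -> BindingModel:
    """No-tag/no-UV control: dominated by endogenous background RNA."""
    return BindingModel(
        components=[GaussianComponent(20, 3, anchor="brA")],
        species_propensity={"substrate": 0.7, "U2": 0.1, "U5": 0.1, "U6": 0.1},
        background_fraction=0.9,
        nonspecific_rate=0.02,
    )


def run_sample(
    index, background, spec, model, design, sample
) -> tuple[SampleResult, "pd.DataFrame"]:
    """Simulate one library and push it through demux -> map -> crosslinks."""
    records, truth = simulate_library(index, model, design, spec, sample, background)
    by_sample, _ = prepare_reads(iter(records), spec)
    result = process_sample(by_sample[sample], index, background, sample=sample)
    return result, truth


def detected_peak(
    seed: int,
    n_reads: int = 50_000,
    mu: float = 20.0,
    sd: float = 3.0,
    index=None,
    background=None,
) -> int | None:
    """Full-pipeline main-peak position (relative to brA) for one seed.

    Simulates a tagged library plus a matched no-tag control, maps both,
    deduplicates, calls and masks crosslinks, normalizes to background,
    subtracts the control, smooths, and returns the main peak.
    """
    if index is None:
        index, background = demo_transcriptome()
    spec = default_barcode_spec()
    signal, _ = run_sample(
        index, background, spec, helicase_model(mu, sd),
        LibraryDesign(n_reads=n_reads, seed=seed), "uv",
    )
    control, _ = run_sample(
        index, background, spec, control_model(),
        LibraryDesign(n_reads=n_reads // 5, seed=seed + 10_000,
                      control_mode="no_tag"), "no_tag",
    )
    profile = substrate_profile(signal, index, control, PipelineParams())
    return find_main_peak(profile, index.substrate, anchor="brA")


def junction_conditions(
    mrna_fraction: float, n_reads: int = 20_000, seed: int = 0
) -> tuple[BindingModel, LibraryDesign]:
    """P-complex-like library: lariat + mRNA mixture, no PCR duplication.

    Duplicate-free so that junction counts are binomial over independent
    templates; the intronic binding model means spliced-mRNA crosslinks
    fall uniformly along the mRNA.
    """
    model = helicase_model()
    rest = 1.0 - mrna_fraction
    design = LibraryDesign(
        n_reads=n_reads,
        seed=seed,
        molecule_mix={
            "pre_mrna": rest / 2,
            "lariat": rest / 2,
            "mrna": mrna_fraction,
        },
        pcr_duplicate_mean=1.0,
    )
    return model, design


def enrichment_propensities() -> tuple[dict, dict]:
    """Tagged vs untagged snRNA crosslink rates for the enrichment assay.

    The untagged floor touches all five snRNAs (U6 heavily, as the most
    crosslinkable core snRNA).  The tagged catalytic-stage complex has
    released U1 and U4 (gone before the C complex forms), contacts U2/U5
    at four times their floor rate, and leaves U6 unchanged — so the
    within-sample snRNA totals of the two conditions coincide and the
    expected per-snRNA log2 fold changes are +2 (U2/U5), 0 (U6), and
    strongly negative (U1/U4).
    """
    tagged = {"substrate": 0.5, "U1": 0.0, "U2": 0.1, "U4": 0.0,
              "U5": 0.1, "U6": 0.3}
    untagged = {"substrate": 0.5, "U1": 0.075, "U2": 0.025, "U4": 0.075,
                "U5": 0.025, "U6": 0.3}
    return tagged, untagged


def run_enrichment(seed: int, n_reads: int = 30_000, index=None, background=None):
    """Tagged/untagged pair -> per-snRNA enrichment table."""
    if index is None:
        index, background = demo_transcriptome()
    spec = default_barcode_spec()
    tag_p, untag_p = enrichment_propensities()
    tagged_model = BindingModel(
        components=[GaussianComponent(20, 3)], species_propensity=tag_p,
        background_fraction=0.15, nonspecific_rate=0.02,
    )
    untagged_model = BindingModel(
        components=[GaussianComponent(20, 3)], species_propensity=untag_p,
        background_fraction=0.5, nonspecific_rate=0.02,
    )
    tagged, _ = run_sample(index, background, spec, tagged_model,
                           LibraryDesign(n_reads=n_reads, seed=seed), "uv")
    untagged, _ = run_sample(index, background, spec, untagged_model,
                             LibraryDesign(n_reads=n_reads, seed=seed + 10_000,
                                           control_mode="no_tag"), "no_tag")
    return snrna_enrichment(tagged.tracks, untagged.tracks, index)
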