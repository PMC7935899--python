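"""Splicing substrate and custom-transcriptome model.

A psiCLIP-style experiment maps reads not to a genome but to a tiny custom
transcriptome: one pre-mRNA splicing substrate (exon1–intron–exon2, with a
branch-point adenosine, brA) plus the five spliceosomal snRNAs, and a
background reference standing in for endogenous RNA.  This module holds the
coordinate conventions every downstream stage relies on.

Conventions
-----------
* All internal coordinates are 0-based, half-open.  SAM output is converted
  to 1-based at the I/O boundary; bedGraph stays 0-based half-open.
* Sequences are stored in the DNA alphabet (T, not U) for FASTQ/SAM
  compatibility.
* Relative coordinates: anchored on the brA, the brA itself is 0; anchored
  on the 3' splice site, the last intron nucleotide is 0 and the first
  exon2 nucleotide is +1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AnnotationError",
    "MissingSubstrateError",
    "LandmarkError",
    "DuplicateReferenceError",
    "Substrate",
    "TranscriptomeIndex",
    "load_references",
    "load_annotation",
    "spliced_mrna",
]


class AnnotationError(ValueError):
    """Base class for substrate / transcriptome configuration errors."""


class MissingSubstrateError(AnnotationError):
    """The annotated substrate record is absent from the FASTA."""


class LandmarkError(AnnotationError):
    """A splicing landmark lies outside its permitted interval."""


class DuplicateReferenceError(AnnotationError):
    """Two FASTA records share a reference name."""


def _rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class Substrate:
    """A pre-mRNA splicing substrate with its landmarks.

    ``exon1``, ``intron`` and ``exon2`` are 0-based half-open intervals that
    must tile a contiguous span of the sequence; ``brA`` is the branch-point
    adenosine position (inside the intron, upstream of the 3'-SS).
    """

    name: str
    sequence: str
    exon1: tuple[int, int]
    intron: tuple[int, int]
    exon2: tuple[int, int]
    brA: int
    features: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _rna_to_dna(self.sequence))
        n = len(self.sequence)
        for label, (a, b) in (
            ("exon1", self.exon1),
            ("intron", self.intron),
            ("exon2", self.exon2),
        ):
            if not (0 <= a < b <= n):
                raise LandmarkError(
                    f"{label} interval [{a}, {b}) invalid for sequence of length {n}"
                )
        if self.exon1[1] != self.intron[0] or self.intron[1] != self.exon2[0]:
            raise LandmarkError(
                "exon1, intron and exon2 must be contiguous and non-overlapping"
            )
        if not (self.intron[0] <= self.brA < self.intron[1]):
            raise LandmarkError(
                f"landmark outside intron: brA={self.brA} not in "
                f"[{self.intron[0]}, {self.intron[1]})"
            )
        if self.brA >= self.ss3:
            raise LandmarkError("brA must lie strictly upstream of the 3'-SS")
        for label, (a, b) in self.features.items():
            if not (0 <= a <= b <= n):
                raise LandmarkError(f"feature {label!r} outside sequence bounds")

    @property
    def ss5(self) -> int:
        """First intron nucleotide (the 5' splice site)."""
        return self.intron[0]

    @property
    def ss3(self) -> int:
        """Last intron nucleotide (the 3' splice site)."""
        return self.intron[1] - 1

    def __len__(self) -> int:
        return len(self.sequence)

    def to_relative(self, pos: int, anchor: str = "brA") -> int:
        """Signed offset of ``pos`` from a landmark.

        With ``anchor="brA"`` the brA is 0.  With ``anchor="ss3"`` the last
        intron nucleotide is 0 and the first exon2 nucleotide is +1.
        """
        if not 0 <= pos < len(self.sequence):
            raise IndexError(f"position {pos} outside substrate of length {len(self)}")
        if anchor == "brA":
            return pos - self.brA
        if anchor == "ss3":
            return pos - self.ss3
        raise ValueError(f"unknown anchor {anchor!r} (expected 'brA' or 'ss3')")

    def from_relative(self, offset: int, anchor: str = "brA") -> int:
        """Inverse of :meth:`to_relative`."""
        base = self.brA if anchor == "brA" else self.ss3
        if anchor not in ("brA", "ss3"):
            raise ValueError(f"unknown anchor {anchor!r}")
        pos = base + offset
        if not 0 <= pos < len(self.sequence):
            raise IndexError(f"relative offset {offset} maps outside the substrate")
        return pos

    def intron_positions(self) -> range:
        return range(self.intron[0], self.intron[1])


def spliced_mrna(substrate: Substrate) -> tuple[str, int]:
    """Exon1+exon2 sequence of the spliced message and its junction position.

    The junction position is the 0-based index of the first exon2 nucleotide
    on the spliced reference (= exon1 length).
    """
    e1 = substrate.sequence[substrate.exon1[0] : substrate.exon1[1]]
    e2 = substrate.sequence[substrate.exon2[0] : substrate.exon2[1]]
    return e1 + e2, len(e1)


#: Reference classes used throughout the pipeline.
CLASS_SUBSTRATE = "substrate"
CLASS_SNRNA = "snRNA"
CLASS_MRNA = "mRNA"
CLASS_BACKGROUND = "background"


@dataclass
class TranscriptomeIndex:
    """Named references partitioned into classes, plus the substrate annotation.

    The spliced-mRNA reference is derived from the substrate at construction
    time so that junction-spanning reads can map competitively.
    """

    references: dict[str, str]
    classes: dict[str, str]
    substrate: Substrate | None = None
    mrna_name: str | None = None
    junction: int | None = None

    @classmethod
    def from_sequences(
        cls,
        sequences: Mapping[str, str],
        substrate: Substrate | None = None,
        *,
        derive_mrna: bool = True,
        background: bool = False,
    ) -> "TranscriptomeIndex":
        refs: dict[str, str] = {}
        classes: dict[str, str] = {}
        for name, seq in sequences.items():
            if name in refs:
                raise DuplicateReferenceError(f"duplicate reference name {name!r}")
            if not seq:
                raise AnnotationError(f"reference {name!r} has an empty sequence")
            refs[name] = _rna_to_dna(str(seq))
            classes[name] = CLASS_BACKGROUND if background else CLASS_SNRNA
        idx = cls(refs, classes)
        if substrate is not None:
            if substrate.name not in refs:
                raise MissingSubstrateError(
                    f"substrate record {substrate.name!r} not found among references"
                )
            if refs[substrate.name] != substrate.sequence:
                raise AnnotationError(
                    "substrate annotation sequence differs from the FASTA record"
                )
            classes[substrate.name] = CLASS_SUBSTRATE
            idx.substrate = substrate
            if derive_mrna:
                mrna_seq, junction = spliced_mrna(substrate)
                mrna_name = f"{substrate.name}_mRNA"
                if mrna_name in refs:
                    raise DuplicateReferenceError(
                        f"derived mRNA name {mrna_name!r} collides with a reference"
                    )
                refs[mrna_name] = mrna_seq
                classes[mrna_name] = CLASS_MRNA
                idx.mrna_name = mrna_name
                idx.junction = junction
        return idx

    def __contains__(self, name: str) -> bool:
        return name in self.references

    def length(self, name: str) -> int:
        return len(self.references[name])

    def names_of_class(self, cls_name: str) -> list[str]:
        return [n for n, c in self.classes.items() if c == cls_name]

    @property
    def snrna_names(self) -> list[str]:
        return self.names_of_class(CLASS_SNRNA)

    def write_fasta(self, path: str | Path, include_mrna: bool = True) -> None:
        records = []
        for name, seq in self.references.items():
            if not include_mrna and name == self.mrna_name:
                continue
            records.append(SeqRecord(Seq(seq), id=name, description=""))
        SeqIO.write(records, str(path), "fasta")


def load_annotation(path: str | Path) -> dict:
    """Read a substrate annotation config (YAML key-value file).

    Required keys: ``substrate`` (record name), ``exon1``, ``intron``,
    ``exon2`` (each a ``[start, end)`` pair) and ``brA``.  Optional:
    ``features`` (mapping name -> ``[start, end]``).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    required = {"substrate", "exon1", "intron", "exon2", "brA"}
    missing = required - set(cfg)
    if missing:
        raise AnnotationError(f"annotation missing keys: {sorted(missing)}")
    return cfg


def load_references(
    fasta_path: str | Path, annotation: Mapping | str | Path
) -> TranscriptomeIndex:
    """Build a validated :class:`TranscriptomeIndex` from FASTA + annotation.

    The annotation may be a path to a YAML config or an already-parsed
    mapping.  The spliced-mRNA reference is derived and registered.
    """
    if isinstance(annotation, (str, Path)):
        annotation = load_annotation(annotation)
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in sequences:
            raise DuplicateReferenceError(f"duplicate reference name {rec.id!r}")
        sequences[rec.id] = str(rec.seq)
    sub_name = annotation["substrate"]
    if sub_name not in sequences:
        raise MissingSubstrateError(
            f"substrate record {sub_name!r} not present in {fasta_path}"
        )
    substrate = Substrate(
        name=sub_name,
        sequence=sequences[sub_name],
        exon1=tuple(annotation["exon1"]),
        intron=tuple(annotation["intron"]),
        exon2=tuple(annotation["exon2"]),
        brA=int(annotation["brA"]),
        features={k: tuple(v) for k, v in annotation.get("features", {}).items()},
    )
    return TranscriptomeIndex.from_sequences(sequences, substrate)


def load_background(fasta_path: str | Path) -> TranscriptomeIndex:
    """Load a background (endogenous-RNA decoy) reference set."""
    sequences = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    return TranscriptomeIndex.from_sequences(sequences, background=True)


def background_index(sequences: Mapping[str, str]) -> TranscriptomeIndex:
    """Build a background index directly from sequences."""
    return TranscriptomeIndex.from_sequences(sequences, background=True)
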