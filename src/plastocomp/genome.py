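"""Core data model: annotated genomes and their typed features.

Coordinates are 0-based half-open everywhere inside the package; reports
and on-disk formats (GenBank, GFF3) use 1-based inclusive coordinates.
Conversion happens only at the I/O boundary (see :mod:`plastocomp.io`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

VALID_BASES = frozenset("ACGTN")
FEATURE_KINDS = ("gene", "CDS", "tRNA", "rRNA", "intron", "exon")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def check_sequence(seq: str) -> None:
    """Reject ambiguity codes other than N with a clear error."""
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(
            f"sequence contains unsupported characters {sorted(bad)}; "
            "only A, C, G, T and N are accepted"
        )


@dataclass(frozen=True)
class Feature:
    """One annotated feature (gene, CDS, tRNA, rRNA, intron or exon).

    ``parts`` holds the ordered exon sub-intervals for multi-exon or
    trans-spliced features; for a simple feature it has one entry equal to
    the feature's interval.  All intervals are 0-based half-open.
    """

    name: str
    kind: str
    parts: tuple[tuple[int, int], ...]
    strand: str = "+"
    pseudo: bool = False
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.parts:
            raise ValueError(f"feature {self.name!r} has no parts")
        for start, end in self.parts:
            if end <= start:
                raise ValueError(
                    f"feature {self.name!r}: empty or inverted part [{start},{end})"
                )
        spans = sorted(self.parts)
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"feature {self.name!r}: overlapping parts")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.parts)

    @property
    def end(self) -> int:
        return max(e for _, e in self.parts)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        """Total length of all parts (the spliced length for a CDS)."""
        return sum(e - s for s, e in self.parts)

    def extract(self, sequence: str) -> str:
        """Spliced feature sequence in the annotated strand orientation."""
        joined = "".join(sequence[s:e] for s, e in self.parts)
        return revcomp(joined) if self.strand == "-" else joined


@dataclass
class AnnotatedGenome:
    """One specimen's sequence plus typed features and sample labels."""

    species: str
    specimen_id: str
    sequence: str
    circular: bool = False
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")
        check_sequence(self.sequence)
        n = len(self.sequence)
        for feat in self.features:
            if feat.start < 0 or feat.end > n:
                raise ValueError(
                    f"feature {feat.name!r} interval {feat.interval} outside [0,{n})"
                )
            if feat.kind == "CDS" and not feat.pseudo and feat.length % 3 != 0:
                warnings.warn(
                    f"CDS {feat.name!r} has length {feat.length} not divisible "
                    "by 3 and is not marked pseudogene; flagging",
                    stacklevel=2,
                )
                idx = self.features.index(feat)
                self.features[idx] = replace(
                    feat, notes=feat.notes + ("length_not_multiple_of_3",)
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def features_of_kind(self, *kinds: str) -> list[Feature]:
        return [f for f in self.features if f.kind in kinds]

    def feature_by_name(self, name: str, kind: str | None = None) -> Feature:
        hits = [
            f
            for f in self.features
            if f.name == name and (kind is None or f.kind == kind)
        ]
        if not hits:
            raise KeyError(f"no feature named {name!r}")
        return hits[0]

    def reverse_complement(self) -> "AnnotatedGenome":
        n = self.length
        feats = []
        for f in self.features:
            parts = tuple(sorted((n - e, n - s) for s, e in f.parts))
            strand = "-" if f.strand == "+" else "+"
            feats.append(replace(f, parts=parts, strand=strand))
        return AnnotatedGenome(
            species=self.species,
            specimen_id=self.specimen_id,
            sequence=revcomp(self.sequence),
            circular=self.circular,
            features=feats,
        )


def check_unique_labels(genomes: Iterable[AnnotatedGenome]) -> None:
    """Enforce uniqueness of (species, specimen_id) pairs in a dataset."""
    seen: set[tuple[str, str]] = set()
    for g in genomes:
        key = (g.species, g.specimen_id)
        if key in seen:
            raise ValueError(f"duplicate specimen label {key}")
        seen.add(key)


def to_one_based(interval: tuple[int, int]) -> tuple[int, int]:
    """Internal [start, end) -> reported 1-based inclusive (GenBank style)."""
    start, end = interval
    return (start + 1, end)


def from_one_based(interval: tuple[int, int]) -> tuple[int, int]:
    """Reported 1-based inclusive -> internal [start, end)."""
    start, end = interval
    return (start - 1, end)


def species_map(genomes: Sequence[AnnotatedGenome]) -> dict[str, str]:
    """specimen_id -> species mapping for a dataset."""
    return {g.specimen_id: g.species for g in genomes}
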