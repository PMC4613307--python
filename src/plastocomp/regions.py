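"""Decompose annotated genomes into named analysis regions.

Every genome is cut into coding regions (CDS/tRNA/rRNA), introns and
intergenic spacers over its single-copy + IRa portion; the second inverted
repeat (IRb) is excluded so duplicated loci are counted once.  Homologous
regions are then collated by name across specimens: a region enters
downstream analysis only when present in every specimen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .genome import AnnotatedGenome, Feature, revcomp
from .quadripartite import QuadripartiteStructure, arc_length

logger = logging.getLogger(__name__)

REGION_KINDS = ("CDS", "tRNA", "rRNA", "intron", "spacer")


@dataclass(frozen=True)
class Region:
    """One named analysis region of one specimen.

    Naming: gene name for coding regions, ``geneA-geneB`` for the spacer
    between them (flanks in ascending genome coordinate), and
    ``gene.intronN`` for the N-th intron in transcription order.
    """

    name: str
    kind: str
    parts: tuple[tuple[int, int], ...]
    strand: str
    specimen: str
    sequence: str

    @property
    def start(self) -> int:
        return self.parts[0][0]

    @property
    def end(self) -> int:
        return self.parts[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.parts)


class RegionSet:
    """Homologous regions collated across specimens, keyed by name."""

    def __init__(self, regions: Mapping[str, Mapping[str, Region]],
                 excluded: Sequence[str] = ()):
        self.regions = {n: dict(per) for n, per in regions.items()}
        self.excluded = list(excluded)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, name: str) -> dict[str, Region]:
        return self.regions[name]

    @property
    def specimens(self) -> list[str]:
        for per in self.regions.values():
            return list(per)
        return []

    def sequences(self, name: str) -> dict[str, str]:
        return {sp: r.sequence for sp, r in self.regions[name].items()}

    def kind(self, name: str) -> str:
        return next(iter(self.regions[name].values())).kind


def _within_arc(feature: Feature, arc: tuple[int, int], n: int) -> bool:
    """True if the feature's span lies inside the (possibly wrapping) arc."""
    length = arc_length(arc, n)
    if length == 0:
        return False
    start = arc[0]
    rel_s = (feature.start - start) % n
    rel_e = (feature.end - 1 - start) % n
    return rel_s < length and rel_e < length and rel_s <= rel_e


def extract_regions(
    genome: AnnotatedGenome,
    structure: QuadripartiteStructure | None = None,
) -> list[Region]:
    """Cut one genome into coding regions, introns and spacers.

    Features inside IRb are dropped.  Every gap of >= 1 bp between
    consecutive retained features becomes a spacer named after its flanks;
    gaps at the analysed arc's edges use the flank name ``start`` or
    ``end``.  Overlapping genes produce no spacer between them (logged).
    CDS and intron sequences are reported in the annotated strand
    orientation, spacers in genome orientation.
    """
    n = genome.length
    seq = genome.sequence
    regions: list[Region] = []

    feats = [f for f in genome.features if f.kind in ("CDS", "tRNA", "rRNA")]
    if structure is not None and not structure.no_ir:
        feats = [f for f in feats if not _within_arc(f, structure.irb, n)]
        span_end = structure.irb[0]
        span_start = (structure.irb[0] + structure.ir_length) % n
    else:
        span_start, span_end = 0, n
    feats.sort(key=lambda f: f.start)

    for f in feats:
        label = f.name + (".pseudo" if f.pseudo else "")
        seq_parts = "".join(seq[s:e] for s, e in f.parts)
        regions.append(
            Region(
                name=label,
                kind=f.kind,
                parts=f.parts,
                strand=f.strand,
                specimen=genome.specimen_id,
                sequence=revcomp(seq_parts) if f.strand == "-" else seq_parts,
            )
        )
        if len(f.parts) > 1:
            gaps = [
                (e1, s2) for (_, e1), (s2, _) in zip(f.parts, f.parts[1:])
            ]
            if f.strand == "-":
                numbered = list(enumerate(reversed(gaps), 1))
                numbered = [(i, g) for i, g in numbered]
            else:
                numbered = list(enumerate(gaps, 1))
            for i, (gs, ge) in numbered:
                if ge <= gs:
                    continue
                intron_seq = seq[gs:ge]
                regions.append(
                    Region(
                        name=f"{f.name}.intron{i}",
                        kind="intron",
                        parts=((gs, ge),),
                        strand=f.strand,
                        specimen=genome.specimen_id,
                        sequence=revcomp(intron_seq) if f.strand == "-"
                        else intron_seq,
                    )
                )

    # intergenic spacers over the analysed span (single-copy + IRa)
    def add_spacer(gs: int, ge: int, left: str, right: str) -> None:
        if ge <= gs:
            return
        regions.append(
            Region(
                name=f"{left}-{right}",
                kind="spacer",
                parts=((gs, ge),),
                strand="+",
                specimen=genome.specimen_id,
                sequence=seq[gs:ge],
            )
        )

    if feats:
        first, last = feats[0], feats[-1]
        if span_start <= first.start:
            add_spacer(span_start, first.start, "start", first.name)
        for f1, f2 in zip(feats, feats[1:]):
            if f2.start < f1.end:
                logger.info(
                    "%s: genes %s and %s overlap; no spacer emitted",
                    genome.specimen_id, f1.name, f2.name,
                )
                continue
            add_spacer(f1.end, f2.start, f1.name, f2.name)
        if span_end >= last.end:
            add_spacer(last.end, span_end, last.name, "end")
    else:
        add_spacer(span_start, span_end, "start", "end")
    return regions


def collate_regions(
    per_specimen: Mapping[str, Sequence[Region]],
) -> RegionSet:
    """Collate extracted regions across specimens by name.

    Regions missing in any specimen are excluded (logged).  Duplicate
    region names within one specimen — the signature of both IR copies
    being present — raise an error instructing IRb removal first.
    """
    if len(per_specimen) < 2:
        raise ValueError("homology collation requires >= 2 specimens")
    names_per: dict[str, dict[str, Region]] = {}
    for specimen, regions in per_specimen.items():
        seen: dict[str, Region] = {}
        for r in regions:
            if r.name in seen:
                raise ValueError(
                    f"duplicate region name {r.name!r} in specimen "
                    f"{specimen!r}; remove the second inverted repeat (IRb) "
                    "before collation"
                )
            seen[r.name] = r
        names_per[specimen] = seen
    specimens = list(per_specimen)
    common = set(names_per[specimens[0]])
    union = set()
    for specimen in specimens:
        common &= set(names_per[specimen])
        union |= set(names_per[specimen])
    excluded = sorted(union - common)
    for name in excluded:
        logger.info("region %s missing in some specimen; excluded", name)
    # order regions by coordinate in the first (representative) specimen
    ordered = sorted(common, key=lambda n: names_per[specimens[0]][n].start)
    return RegionSet(
        {n: {sp: names_per[sp][n] for sp in specimens} for n in ordered},
        excluded=excluded,
    )


def collate_homologs(
    genomes: Sequence[AnnotatedGenome],
    structures: Mapping[str, QuadripartiteStructure] | None = None,
) -> RegionSet:
    """Extract and collate homologous regions for a set of genomes."""
    per: dict[str, list[Region]] = {}
    for g in genomes:
        st = structures.get(g.specimen_id) if structures else None
        per[g.specimen_id] = extract_regions(g, st)
    return collate_regions(per)


def region_table(region_set: RegionSet):
    """Summary table: one row per homologous region (1-based coordinates)."""
    import pandas as pd

    rows = []
    rep = region_set.specimens[0] if region_set.specimens else None
    for name in region_set:
        r = region_set[name][rep]
        rows.append(
            {
                "region": name,
                "kind": r.kind,
                "start": r.start + 1,
                "end": r.end,
                "strand": r.strand,
                "length": r.length,
            }
        )
    return pd.DataFrame(rows)
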