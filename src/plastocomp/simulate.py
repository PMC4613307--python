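"""Synthetic annotated plastomes and rRNA clusters with a truth manifest.

The generator emulates the study design the analysis assumes: three
species (two sister species plus an outgroup, tree ((A,B),C)) with two
specimens each, derived from one ancestor that carries a circular
quadripartite plastome (LSC + IRa + SSC + IRb, IRb an exact reverse
complement of IRa) and, separately, a linear 18S-ITS1-5.8S-ITS2-26S rRNA
cluster.  Mutations are of two scopes: *branch* mutations shared by every
specimen of a species (or of the A+B clade) — these are the diagnostic,
species-specific characters — and *specimen* mutations private to one
individual, which can never be diagnostic.  All mutation footprints are
disjoint by construction, so the truth manifest can score every
downstream detector exactly.

Gene names, gene sizes and the planted showcase events (a 39 bp in-frame
insertion in ndhF, a 21 bp insertion in accD, a dense block of diagnostic
characters in the ndhD-ccsA spacer, 1810/200/164/211/3410 bp rRNA
cluster regions) mirror the kind of signal reported for closely related
pasque-flower (Pulsatilla) plastomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome import AnnotatedGenome, Feature, revcomp

STOP_CODONS = ("TAA", "TAG", "TGA")
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS and a + b + c != "ATG"
]
_BASES = np.frombuffer(b"ACGT", dtype="S1")

# ----------------------------------------------------------------------
# configuration

SPECIES_A, SPECIES_B, SPECIES_C = "P_patens", "P_vernalis", "P_pratensis"


@dataclass
class PlantedSSM:
    """Planted diagnostic characters for one species in one region."""

    region: str
    species: str  # "A" | "B" | "C" (clade codes, mapped to labels)
    substitutions: int = 0
    indels: int = 0


@dataclass
class PlantedCDSIndel:
    gene: str
    species: str
    length: int  # bp; a multiple of 3 keeps the fixture translatable
    insertion: bool = True


@dataclass
class PlantedSSR:
    motif: str
    count: int
    region: str
    species: str | None = None  # None = ancestral (shared); else the run
    # reaches threshold only on that species' branch via a 1 bp insertion


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Substitution rates are per site per branch; the defaults emulate an
    asymmetric three-species design in which the outgroup species C has
    accumulated several-fold more diagnostic variation than the two
    sister species, and conspecific specimens differ by only a handful of
    sites.  Indels occur in noncoding sequence at ``indel_factor`` times
    the substitution rate with geometric lengths; coding indels are only
    ever planted explicitly so fixtures stay translatable.
    """

    lsc_target: int = 90_300
    ir_target: int = 26_350
    ssc_target: int = 18_800
    species_names: tuple[str, str, str] = (SPECIES_A, SPECIES_B, SPECIES_C)
    branch_sub_rates: dict = field(
        default_factory=lambda: {
            "A": 3.0e-4, "B": 2.5e-4, "C": 1.8e-3, "AB": 1.0e-4,
        }
    )
    specimen_sub_rate: float = 1.5e-5
    indel_factor: float = 0.5  # indel rate = factor * substitution rate
    indel_length_p: float = 0.5  # geometric length parameter (mean 2 bp)
    max_indel_length: int = 8
    cds_synonymous_fraction: float = 0.40
    gc_content: float = 0.38
    planted_ssms: list = field(default_factory=lambda: list(DEFAULT_SSMS))
    planted_cds_indels: list = field(
        default_factory=lambda: list(DEFAULT_CDS_INDELS)
    )
    planted_ssrs: list = field(default_factory=lambda: list(DEFAULT_SSRS))

    def __post_init__(self) -> None:
        for rate in (*self.branch_sub_rates.values(), self.specimen_sub_rate):
            if not 0.0 <= rate <= 0.05:
                raise ValueError(f"rate {rate} outside [0, 0.05]")

    def species_label(self, code: str) -> str:
        return dict(zip("ABC", self.species_names))[code]


DEFAULT_SSMS = (
    # the showcase spacer: dense diagnostic block for all three species
    PlantedSSM("ndhD-ccsA", "A", substitutions=5, indels=2),
    PlantedSSM("ndhD-ccsA", "B", substitutions=2, indels=0),
    PlantedSSM("ndhD-ccsA", "C", substitutions=18, indels=9),
    PlantedSSM("rps4-rps16", "A", substitutions=4, indels=0),
    PlantedSSM("rps4-rps16", "B", substitutions=3, indels=1),
    PlantedSSM("rps4-rps16", "C", substitutions=6, indels=5),
    PlantedSSM("clpP.intron2", "A", substitutions=2, indels=1),
    PlantedSSM("clpP.intron2", "B", substitutions=1, indels=1),
    PlantedSSM("clpP.intron2", "C", substitutions=5, indels=2),
    PlantedSSM("rps15.intron1", "A", substitutions=2, indels=1),
    PlantedSSM("rps15.intron1", "B", substitutions=0, indels=1),
    PlantedSSM("rps15.intron1", "C", substitutions=10, indels=4),
    PlantedSSM("trnH-psbA", "A", substitutions=0, indels=1),
    PlantedSSM("trnH-psbA", "B", substitutions=1, indels=0),
    PlantedSSM("trnH-psbA", "C", substitutions=1, indels=0),
)

DEFAULT_CDS_INDELS = (
    PlantedCDSIndel("ndhF", "C", 39, insertion=True),   # +13 aa
    PlantedCDSIndel("accD", "C", 21, insertion=True),   # +7 aa
    PlantedCDSIndel("rpl22", "C", 6, insertion=True),   # +2 aa
)

DEFAULT_SSRS = (
    PlantedSSR("A", 12, "psbA-matK"),
    PlantedSSR("T", 11, "atpA-rpoB"),
    PlantedSSR("C", 10, "matK-atpA"),
    PlantedSSR("A", 10, "ccsA-rps15"),
    PlantedSSR("AT", 7, "rpoC2-psbD"),
    PlantedSSR("AG", 6, "psbD-accD"),
    PlantedSSR("TA", 6, "rpl22-clpP"),
    PlantedSSR("AAT", 5, "rps8-trnI"),
    PlantedSSR("AAG", 4, "ndhF-rpl32"),
    PlantedSSR("GAA", 4, "trnI-rrn16"),
    # species-specific: an ancestral 9-mer run crosses the mono threshold
    # only on the named species' branch (a 1 bp diagnostic insertion)
    PlantedSSR("A", 9, "ndhK-rps4", species="A"),
    PlantedSSR("T", 9, "rpoB-rpoC2", species="A"),
    PlantedSSR("A", 9, "rpl32-ndhD", species="B"),
    PlantedSSR("T", 9, "rps12.5p-rps12.3p", species="C"),
    PlantedSSR("A", 9, "rps15-ycf1", species="C"),
)

# gene roster: (gene, kind, strand, exon lengths in transcription order,
# intron lengths in transcription order); single-exon genes have one exon
_LSC_GENES = (
    ("trnH", "tRNA", "+", (74,), ()),
    ("psbA", "CDS", "-", (1062,), ()),
    ("matK", "CDS", "+", (1530,), ()),
    ("atpA", "CDS", "-", (1524,), ()),
    ("rpoB", "CDS", "-", (3213,), ()),
    ("rpoC2", "CDS", "-", (4185,), ()),
    ("psbD", "CDS", "+", (1062,), ()),
    ("accD", "CDS", "+", (1476,), ()),
    ("rpl22", "CDS", "+", (420,), ()),
    ("clpP", "CDS", "-", (69, 291, 228), (640, 745)),
    ("rps12.5p", "CDS", "-", (114,), ()),
    ("rps12.3p", "CDS", "-", (231, 27), (536,)),
    ("trnV", "tRNA", "+", (72,), ()),
    ("ndhK", "CDS", "-", (678,), ()),
    ("rps4", "CDS", "+", (606,), ()),
    ("rps16", "CDS", "-", (42, 225), (860,)),
    ("rps8", "CDS", "+", (405,), ()),
)
_IRA_GENES = (
    ("trnI", "tRNA", "+", (74,), ()),
    ("rrn16", "rRNA", "+", (1491,), ()),
    ("trnA", "tRNA", "+", (73,), ()),
    ("rrn23", "rRNA", "+", (2810,), ()),
    ("rrn4.5", "rRNA", "+", (103,), ()),
    ("rrn5", "rRNA", "+", (121,), ()),
    ("ycf2", "CDS", "-", (6621,), ()),
    ("ycf1", "CDS", "+", (1120,), ()),  # pseudogene fragment at the border
)
_SSC_GENES = (
    ("ndhF", "CDS", "-", (2235,), ()),
    ("rpl32", "CDS", "+", (171,), ()),
    ("ndhD", "CDS", "-", (1503,), ()),
    ("ccsA", "CDS", "+", (969,), ()),
    ("rps15", "CDS", "-", (81, 195), (310,)),
    ("ycf1", "CDS", "+", (5577,), ()),
)
_PSEUDO = {("IRa", "ycf1")}
_FIXED_SPACERS = {
    "trnH-psbA": 465,
    "rps4-rps16": 817,
    "ndhD-ccsA": 611,
    "rps12.3p-trnV": 1213,
    "trnV-ndhK": 1345,
}

# rRNA cluster roster: three rRNA genes; ITS1 and ITS2 arise as the
# spacers between them (regions "18S-5.8S" and "5.8S-26S")
_RRNA_GENES = (
    ("18S", "rRNA", "+", (1810,), ()),
    ("5.8S", "rRNA", "+", (164,), ()),
    ("26S", "rRNA", "+", (3410,), ()),
)
_RRNA_SPACERS = {"18S-5.8S": 200, "5.8S-26S": 211}
ITS1, ITS2 = "18S-5.8S", "5.8S-26S"

DEFAULT_RRNA_SSMS = (
    PlantedSSM("18S", "C", substitutions=1),
    PlantedSSM(ITS1, "C", substitutions=2),
    PlantedSSM(ITS2, "A", substitutions=1),
    PlantedSSM(ITS2, "B", substitutions=1),
    PlantedSSM(ITS2, "C", substitutions=4),
    PlantedSSM("26S", "C", substitutions=5),
)
# singletons: private SNPs of single specimens (region, specimen index 0-5)
DEFAULT_RRNA_SINGLETONS = ((ITS1, 0), (ITS1, 2), (ITS1, 4), ("26S", 3))


# ----------------------------------------------------------------------
# internal genome representation


@dataclass
class Segment:
    """One building block of the linearized ancestor (genome orientation)."""

    name: str  # region name: gene for exons, gene.intronN, or spacer name
    kind: str  # "exon" | "intron" | "tRNA" | "rRNA" | "spacer"
    seq: str
    gene: str | None = None
    strand: str = "+"
    compartment: str = "LSC"
    pseudo: bool = False


def _rand_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    at = (1 - gc) / 2
    probs = [at, gc / 2, gc / 2, at]
    return rng.choice(_BASES, size=length, p=probs).tobytes().decode()


def _rand_orf(rng: np.random.Generator, length: int) -> str:
    assert length % 3 == 0 and length >= 9
    inner = rng.choice(np.array(_CODONS), size=length // 3 - 2)
    stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    return "ATG" + "".join(inner) + stop


def _gene_segments(rng, entry, compartment, gc) -> list[Segment]:
    gene, kind, strand, exons, introns = entry
    pseudo = (compartment, gene) in _PSEUDO
    if kind == "CDS" and not pseudo:
        cds = _rand_orf(rng, sum(exons))
    else:
        cds = _rand_seq(rng, sum(exons), gc)
    # split the transcript into exons (transcription order), then lay the
    # pieces down in genome order (reversed and complemented for '-')
    pieces = []
    off = 0
    for ln in exons:
        pieces.append(cds[off : off + ln])
        off += ln
    if strand == "-":
        pieces = [revcomp(p) for p in reversed(pieces)]
        intron_names = [
            f"{gene}.intron{i}" for i in range(len(introns), 0, -1)
        ]
        intron_lens = list(reversed(introns))
    else:
        intron_names = [f"{gene}.intron{i + 1}" for i in range(len(introns))]
        intron_lens = list(introns)
    segs = []
    for i, piece in enumerate(pieces):
        segkind = "exon" if kind == "CDS" else kind
        segs.append(
            Segment(name=gene if kind == "CDS" else gene, kind=segkind,
                    seq=piece, gene=gene, strand=strand,
                    compartment=compartment, pseudo=pseudo)
        )
        if i < len(pieces) - 1:
            segs.append(
                Segment(name=intron_names[i], kind="intron",
                        seq=_rand_seq(rng, intron_lens[i], gc), gene=gene,
                        strand=strand, compartment=compartment)
            )
    return segs


def _layout_compartment(rng, roster, compartment, target, config,
                        lead_name, tail_name) -> list[Segment]:
    gene_blocks = [
        _gene_segments(rng, entry, compartment, config.gc_content)
        for entry in roster
    ]
    gene_len = sum(len(s.seq) for block in gene_blocks for s in block)
    spacer_names = [lead_name] if lead_name else []
    for (g1, *_), (g2, *_) in zip(roster, roster[1:]):
        spacer_names.append(f"{g1}-{g2}")
    if tail_name:
        spacer_names.append(tail_name)
    fixed = {n: _FIXED_SPACERS[n] for n in spacer_names if n in _FIXED_SPACERS}
    free = [n for n in spacer_names if n not in fixed]
    remaining = target - gene_len - sum(fixed.values())
    if remaining < 30 * len(free):
        raise ValueError(
            f"{compartment}: target {target} too small for its gene roster"
        )
    weights = rng.gamma(2.0, 1.0, size=len(free))
    raw = weights / weights.sum() * (remaining - 30 * len(free))
    lengths = dict(zip(free, (30 + int(x) for x in raw)))
    # absorb rounding in the last free spacer so the target is hit exactly
    lengths[free[-1]] = remaining - sum(lengths[n] for n in free[:-1])
    lengths.update(fixed)
    segs: list[Segment] = []
    names = iter(spacer_names)
    if lead_name:
        nm = next(names)
        segs.append(Segment(nm, "spacer", _rand_seq(rng, lengths[nm],
                    config.gc_content), compartment=compartment))
    for block in gene_blocks:
        segs.extend(block)
        try:
            nm = next(names)
        except StopIteration:
            break
        segs.append(Segment(nm, "spacer", _rand_seq(rng, lengths[nm],
                    config.gc_content), compartment=compartment))
    return segs


def _plant_ssrs(rng, segments, planted: Sequence[PlantedSSR], gc):
    """Embed SSR runs mid-spacer; returns locations for the manifest."""
    by_name = {}
    for seg in segments:
        by_name.setdefault(seg.name, seg)
    placed = []
    for p in planted:
        seg = by_name.get(p.region)
        if seg is None or seg.kind not in ("spacer", "intron"):
            raise ValueError(f"planted SSR region {p.region!r} not a spacer")
        run = p.motif * p.count
        pos = len(seg.seq) // 2
        # guard the run: flanking bases differing from the motif edge keep
        # the run maximal and the 20 bp anchors clean
        left_guard = "C" if p.motif[-1] != "C" else "G"
        right_guard = "C" if p.motif[0] != "C" else "G"
        seg.seq = (
            seg.seq[:pos] + left_guard + run + right_guard + seg.seq[pos:]
        )
        placed.append(
            {"motif": p.motif, "count": p.count, "region": p.region,
             "offset": pos + 1, "species": p.species}
        )
    return placed


# ----------------------------------------------------------------------
# coding-coordinate helpers


class _GeneIndex:
    """Maps CDS (reading frame) coordinates to segment coordinates."""

    def __init__(self, segments: list[Segment], gene: str):
        # pseudogene fragments (e.g. the truncated IR copy of ycf1) share
        # the gene name but are not part of the reading frame
        self.exons = [
            (i, len(s.seq))
            for i, s in enumerate(segments)
            if s.gene == gene and s.kind == "exon" and not s.pseudo
        ]
        self.strand = next(
            s.strand
            for s in segments
            if s.gene == gene and s.kind == "exon" and not s.pseudo
        )
        self.segments = segments
        self.length = sum(ln for _, ln in self.exons)

    def spliced_genome_orientation(self) -> str:
        return "".join(self.segments[i].seq for i, _ in self.exons)

    def cds(self) -> str:
        s = self.spliced_genome_orientation()
        return revcomp(s) if self.strand == "-" else s

    def _s_offset(self, s_pos: int) -> tuple[int, int]:
        off = s_pos
        for i, ln in self.exons:
            if off < ln:
                return i, off
            off -= ln
        raise IndexError(s_pos)

    def sub_site(self, cds_idx: int, alt: str) -> tuple[int, int, str]:
        """(segment index, offset, genome-orientation alt base)."""
        if self.strand == "-":
            s_pos = self.length - 1 - cds_idx
            alt = revcomp(alt)
        else:
            s_pos = cds_idx
        seg, off = self._s_offset(s_pos)
        return seg, off, alt

    def insertion_site(self, cds_pos: int, insert: str) -> tuple[int, int, str]:
        """(segment index, offset, genome-orientation insert sequence).

        ``cds_pos`` must lie strictly inside one exon.
        """
        if self.strand == "-":
            s_pos = self.length - cds_pos
            insert = revcomp(insert)
        else:
            s_pos = cds_pos
        off = s_pos
        for i, ln in self.exons:
            if 0 < off < ln:
                return i, off, insert
            off -= ln
        raise ValueError("insertion point must be strictly inside one exon")


# ----------------------------------------------------------------------
# mutation sampling


class _Registry:
    """Disjoint-footprint bookkeeping per segment (ancestor coordinates)."""

    def __init__(self):
        self.occupied: dict[int, list[tuple[int, int]]] = {}

    def reserve(self, seg: int, start: int, end: int) -> bool:
        spans = self.occupied.setdefault(seg, [])
        for s, e in spans:
            if start < e and s < end:
                return False
        spans.append((start, end))
        return True


def _scope_specimens(scope: str, specimens_by_code: dict[str, list[str]]):
    if scope in ("A", "B", "C"):
        return list(specimens_by_code[scope])
    if scope == "AB":
        return specimens_by_code["A"] + specimens_by_code["B"]
    return [scope]  # a single specimen label


def _expected_ssm(scope: str, config: SimulationConfig):
    if scope in ("A", "B"):
        return config.species_label(scope)
    if scope in ("C", "AB"):
        # an A+B clade character and a C character are indistinguishable
        # in an unrooted three-species comparison: both diagnose C
        return config.species_label("C")
    return None


def _geom_length(rng, p, cap):
    return int(min(rng.geometric(p), cap))


class _Sampler:
    def __init__(self, segments: list[Segment], rng, config):
        self.segments = segments
        self.rng = rng
        self.config = config
        self.registry = _Registry()
        self.events: list[dict] = []
        self._gene_index: dict[str, _GeneIndex] = {}
        self.total_length = sum(len(s.seq) for s in segments)

    def gene_index(self, gene: str) -> _GeneIndex:
        if gene not in self._gene_index:
            self._gene_index[gene] = _GeneIndex(self.segments, gene)
        return self._gene_index[gene]

    def _pick_segment(self, eligible: list[int]) -> int:
        lens = np.array([len(self.segments[i].seq) for i in eligible],
                        dtype=float)
        return int(self.rng.choice(eligible, p=lens / lens.sum()))

    def segment_by_region(self, region: str) -> int:
        for i, s in enumerate(self.segments):
            if s.name == region and s.kind in ("spacer", "intron",
                                               "tRNA", "rRNA"):
                return i
        raise KeyError(f"no noncoding region named {region!r}")

    # -- substitutions ------------------------------------------------

    def add_substitution(self, scope: str, seg_idx: int | None = None,
                         origin: str = "background"):
        rng = self.rng
        for _ in range(40):
            i = (seg_idx if seg_idx is not None
                 else self._pick_segment(list(range(len(self.segments)))))
            seg = self.segments[i]
            if len(seg.seq) < 10:
                continue
            if seg.kind == "exon" and not seg.pseudo:
                # decide the target effect once, then hunt for a site that
                # supports it, so the realised syn/nonsyn mix matches the
                # configured fraction
                want_syn = rng.random() < self.config.cds_synonymous_fraction
                for _ in range(80):
                    pos = int(rng.integers(2, len(seg.seq) - 2))
                    if self._coding_substitution(i, pos, scope, origin,
                                                 want_syn):
                        return
            else:
                pos = int(rng.integers(2, len(seg.seq) - 2))
                if self._plain_substitution(i, pos, scope, origin):
                    return
        raise RuntimeError("could not place substitution (region saturated)")

    def _plain_substitution(self, i, pos, scope, origin) -> bool:
        if not self.registry.reserve(i, pos - 2, pos + 3):
            return False
        ref = self.segments[i].seq[pos]
        alt = str(self.rng.choice([b for b in "ACGT" if b != ref]))
        self._record("substitution", i, pos, scope, origin,
                     alt=alt, expected_effect=None)
        return True

    def _coding_substitution(self, i, pos, scope, origin, want_syn) -> bool:
        from .cds import translate

        seg = self.segments[i]
        gi = self.gene_index(seg.gene)
        s_pos = sum(ln for e, ln in gi.exons if e < i) + pos
        cds_idx = (gi.length - 1 - s_pos) if gi.strand == "-" else s_pos
        cds = gi.cds()
        codon_i = cds_idx // 3
        codon = cds[3 * codon_i : 3 * codon_i + 3]
        choices = [b for b in "ACGT" if b != cds[cds_idx]]
        self.rng.shuffle(choices)
        for alt in choices:
            new = (codon[: cds_idx % 3] + alt + codon[cds_idx % 3 + 1 :])
            syn = translate(codon) == translate(new)
            if syn != want_syn:
                continue
            if not self.registry.reserve(i, pos - 2, pos + 3):
                return False
            seg_i, off, genome_alt = gi.sub_site(cds_idx, alt)
            assert seg_i == i and off == pos
            self._record(
                "substitution", i, pos, scope, origin, alt=genome_alt,
                expected_effect="synonymous" if syn else "nonsynonymous",
            )
            return True
        return False

    # -- indels -------------------------------------------------------

    def add_indel(self, scope: str, seg_idx: int | None = None,
                  origin: str = "background", length: int | None = None,
                  insertion: bool | None = None):
        rng = self.rng
        noncoding = [
            i for i, s in enumerate(self.segments)
            if s.kind in ("spacer", "intron")
        ]
        for _ in range(40):
            i = seg_idx if seg_idx is not None else self._pick_segment(noncoding)
            seg = self.segments[i]
            ln = (length if length is not None else
                  _geom_length(rng, self.config.indel_length_p,
                               self.config.max_indel_length))
            ins = insertion if insertion is not None else bool(
                rng.integers(2))
            if len(seg.seq) < ln + 12:
                continue
            pos = int(rng.integers(3, len(seg.seq) - ln - 3))
            span = (pos - 6, pos + 6) if ins else (pos - 6, pos + ln + 6)
            if not self.registry.reserve(i, *span):
                continue
            seq = _rand_seq(rng, ln, self.config.gc_content) if ins else None
            self._record("indel", i, pos, scope, origin,
                         indel_length=ln, insertion=ins, insert_seq=seq,
                         expected_effect=None)
            return
        raise RuntimeError("could not place indel (region saturated)")

    def add_cds_indel(self, planted: PlantedCDSIndel):
        gi = self.gene_index(planted.gene)
        # place at a codon boundary inside the largest exon
        seg_i, seg_len = max(gi.exons, key=lambda e: e[1])
        s_start = sum(ln for e, ln in gi.exons if e < seg_i)
        if gi.strand == "-":
            lo = gi.length - (s_start + seg_len)
            hi = gi.length - s_start
        else:
            lo, hi = s_start, s_start + seg_len
        mid_codon = ((lo + hi) // 2) // 3
        cds_pos = max(3 * mid_codon, lo + 3)
        ln = planted.length
        if planted.insertion:
            n_codons = -(-ln // 3)
            insert = "".join(
                self.rng.choice(np.array(_CODONS), size=n_codons)
            )[:ln]
            seg_idx, off, genome_seq = gi.insertion_site(cds_pos, insert)
            if not self.registry.reserve(seg_idx, off - 6, off + 6):
                raise RuntimeError("planted CDS insertion collides")
            expected = ("inframe_insertion" if ln % 3 == 0 else "frameshift")
            self._record("indel", seg_idx, off, planted.species,
                         "planted_cds", indel_length=ln, insertion=True,
                         insert_seq=genome_seq, expected_effect=expected,
                         protein_length_delta=(ln // 3 if ln % 3 == 0
                                               else None))
        else:
            seg_idx, off, _ = gi.insertion_site(cds_pos, "")
            if off + ln > len(self.segments[seg_idx].seq) - 3:
                raise RuntimeError("planted CDS deletion exceeds exon")
            if not self.registry.reserve(seg_idx, off - 6, off + ln + 6):
                raise RuntimeError("planted CDS deletion collides")
            expected = ("inframe_deletion" if ln % 3 == 0 else "frameshift")
            self._record("indel", seg_idx, off, planted.species,
                         "planted_cds", indel_length=ln, insertion=False,
                         expected_effect=expected,
                         protein_length_delta=(-(ln // 3) if ln % 3 == 0
                                               else None))

    def _record(self, kind, seg_idx, pos, scope, origin, alt=None,
                indel_length=None, insertion=None, insert_seq=None,
                expected_effect=None, protein_length_delta=None):
        seg = self.segments[seg_idx]
        self.events.append(
            {
                "kind": kind,
                "segment": seg_idx,
                "region": seg.name,
                "region_kind": ("CDS" if seg.kind == "exon" else seg.kind),
                "pos": pos,
                "scope": scope,
                "origin": origin,
                "alt": alt,
                "indel_length": indel_length,
                "insertion": insertion,
                "insert_seq": insert_seq,
                "expected_effect": expected_effect,
                "protein_length_delta": protein_length_delta,
                "expected_ssm_species": _expected_ssm(scope, self.config),
                "pseudo": seg.pseudo,
            }
        )


def _apply_events(segments: list[Segment], events: list[dict],
                  carrier: str, specimens_by_code) -> list[Segment]:
    out = [Segment(**{**s.__dict__}) for s in segments]
    mine = [
        ev for ev in events
        if carrier in _scope_specimens(ev["scope"], specimens_by_code)
    ]
    by_seg: dict[int, list[dict]] = {}
    for ev in mine:
        by_seg.setdefault(ev["segment"], []).append(ev)
    for seg_idx, evs in by_seg.items():
        seq = out[seg_idx].seq
        for ev in sorted(evs, key=lambda e: -e["pos"]):
            pos = ev["pos"]
            if ev["kind"] == "substitution":
                seq = seq[:pos] + ev["alt"] + seq[pos + 1 :]
            elif ev["insertion"]:
                seq = seq[:pos] + ev["insert_seq"] + seq[pos:]
            else:
                seq = seq[:pos] + seq[pos + ev["indel_length"] :]
        out[seg_idx].seq = seq
    return out


# ----------------------------------------------------------------------
# assembly


def _assemble(segments: list[Segment], species: str, specimen: str,
              circular: bool, with_ir: bool) -> AnnotatedGenome:
    parts: list[str] = []
    features: list[Feature] = []
    offset = 0
    gene_parts: dict[tuple[str, str], dict] = {}
    ira_span = [None, None]
    for seg in segments:
        start, end = offset, offset + len(seg.seq)
        if seg.compartment == "IRa":
            if ira_span[0] is None:
                ira_span[0] = start
            ira_span[1] = end
        if seg.kind == "exon":
            key = (seg.compartment, seg.gene)
            info = gene_parts.setdefault(
                key, {"parts": [], "strand": seg.strand,
                      "pseudo": seg.pseudo, "order": start}
            )
            info["parts"].append((start, end))
        elif seg.kind in ("tRNA", "rRNA"):
            features.append(
                Feature(name=seg.name, kind=seg.kind,
                        parts=((start, end),), strand=seg.strand)
            )
        parts.append(seg.seq)
        offset = end
    for (_, gene), info in sorted(gene_parts.items(),
                                  key=lambda kv: kv[1]["order"]):
        features.append(
            Feature(name=gene, kind="CDS", parts=tuple(info["parts"]),
                    strand=info["strand"], pseudo=info["pseudo"])
        )
    seq = "".join(parts)
    if with_ir:
        ira_start, ira_end = ira_span
        ir_len = ira_end - ira_start
        irb_start = len(seq)
        seq = seq + revcomp(seq[ira_start:ira_end])
        mirrored = []
        for f in features:
            if not (ira_start <= f.start and f.end <= ira_end):
                continue
            parts2 = tuple(sorted(
                (irb_start + ir_len - (e - ira_start),
                 irb_start + ir_len - (s - ira_start))
                for s, e in f.parts
            ))
            strand = "-" if f.strand == "+" else "+"
            mirrored.append(
                Feature(name=f.name, kind=f.kind, parts=parts2,
                        strand=strand, pseudo=f.pseudo)
            )
        features.extend(mirrored)
    features.sort(key=lambda f: f.start)
    return AnnotatedGenome(
        species=species, specimen_id=specimen, sequence=seq,
        circular=circular, features=features,
    )


# ----------------------------------------------------------------------
# public API


def _build_plastome_segments(config: SimulationConfig, rng):
    # boundary spacers belong to the downstream compartment: rps8-trnI
    # opens IRa (and is therefore part of the repeat), ycf1-ndhF opens
    # the SSC; each compartment hits its length target exactly
    segs: list[Segment] = []
    segs += _layout_compartment(rng, _LSC_GENES, "LSC", config.lsc_target,
                                config, "start-trnH", None)
    segs += _layout_compartment(rng, _IRA_GENES, "IRa", config.ir_target,
                                config, "rps8-trnI", None)
    segs += _layout_compartment(rng, _SSC_GENES, "SSC", config.ssc_target,
                                config, "ycf1-ndhF", "ycf1-end")
    return segs


def generate_ancestor(config: SimulationConfig | None = None,
                      seed: int = 0) -> AnnotatedGenome:
    """Build the ancestral circular quadripartite plastome.

    The returned genome carries the generator's internal segment list on
    ``._segments`` so that :func:`evolve_specimens` can mutate per region.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    segments = _build_plastome_segments(config, rng)
    ancestor = _assemble(segments, "ancestor", "ancestor",
                         circular=True, with_ir=True)
    ancestor._segments = segments  # type: ignore[attr-defined]
    return ancestor


def evolve_specimens(ancestor: AnnotatedGenome,
                     config: SimulationConfig | None = None,
                     seed: int = 0):
    """Evolve six specimens (3 species x 2) from the ancestor.

    Returns ``(genomes, manifest)``; the manifest records every mutation
    event with its expected detector outcome, all generator parameters
    and the seed, sufficient to score precision/recall of every detector.
    """
    config = config or SimulationConfig()
    segments = getattr(ancestor, "_segments", None)
    if segments is None:
        raise ValueError("ancestor must come from generate_ancestor()")
    rng = np.random.default_rng(seed + 1)
    return _evolve(segments, config, rng, seed, circular=True, with_ir=True,
                   planted_ssms=config.planted_ssms,
                   planted_cds=config.planted_cds_indels,
                   planted_ssrs=config.planted_ssrs,
                   singletons=())


def simulate_plastome_dataset(config: SimulationConfig | None = None,
                              seed: int = 0):
    """Ancestor + specimens in one call: ``(genomes, manifest)``."""
    config = config or SimulationConfig()
    ancestor = generate_ancestor(config, seed)
    return evolve_specimens(ancestor, config, seed)


def simulate_rrna_dataset(config: SimulationConfig | None = None,
                          seed: int = 0,
                          planted_ssms=DEFAULT_RRNA_SSMS,
                          singletons=DEFAULT_RRNA_SINGLETONS):
    """Linear 18S-ITS1-5.8S-ITS2-26S cluster for the same six specimens.

    ITS1 and ITS2 are the spacer regions between the rRNA genes (region
    names ``18S-5.8S`` and ``5.8S-26S``).  By default variation is pure
    substitution (diagnostic SNPs plus single-specimen singletons), so
    the cluster length is identical in all specimens.
    """
    config = config or SimulationConfig(
        branch_sub_rates={"A": 0.0, "B": 0.0, "C": 0.0, "AB": 0.0},
        specimen_sub_rate=0.0,
        planted_ssms=[], planted_cds_indels=[], planted_ssrs=[],
    )
    rng = np.random.default_rng(seed + 2)
    gene_blocks = [
        _gene_segments(rng, entry, "rRNA", config.gc_content)
        for entry in _RRNA_GENES
    ]
    segs: list[Segment] = []
    for i, block in enumerate(gene_blocks):
        segs.extend(block)
        if i < len(gene_blocks) - 1:
            name = f"{_RRNA_GENES[i][0]}-{_RRNA_GENES[i + 1][0]}"
            segs.append(Segment(name, "spacer",
                                _rand_seq(rng, _RRNA_SPACERS[name],
                                          config.gc_content),
                                compartment="rRNA"))
    return _evolve(segs, config, rng, seed, circular=False, with_ir=False,
                   planted_ssms=list(planted_ssms), planted_cds=[],
                   planted_ssrs=[], singletons=list(singletons))


def _evolve(segments, config, rng, seed, circular, with_ir,
            planted_ssms, planted_cds, planted_ssrs, singletons):
    specimens_by_code = {
        code: [f"{config.species_label(code)}_{k}" for k in (1, 2)]
        for code in "ABC"
    }
    all_specimens = [
        sp for code in "ABC" for sp in specimens_by_code[code]
    ]
    sampler = _Sampler(segments, rng, config)

    # planted SSRs: embed ancestral runs, reserve their anchors, and add
    # the diagnostic 1 bp run-extension for species-conditional loci
    placed_ssrs = _plant_ssrs(rng, segments, planted_ssrs, config.gc_content)
    sampler.total_length = sum(len(s.seq) for s in segments)
    for p, rec in zip(planted_ssrs, placed_ssrs):
        i = sampler.segment_by_region(p.region)
        run_start = rec["offset"]  # guard base sits at offset - ... run after
        run_len = len(p.motif) * p.count
        sampler.registry.reserve(i, run_start - 25, run_start + run_len + 27)
        if p.species is not None:
            pos = run_start + 1 + len(p.motif) * (p.count // 2)
            sampler._record("indel", i, pos, p.species, "planted_ssr",
                            indel_length=len(p.motif), insertion=True,
                            insert_seq=p.motif, expected_effect=None)

    for p in planted_cds:
        sampler.add_cds_indel(p)
    for p in planted_ssms:
        i = sampler.segment_by_region(p.region)
        for _ in range(p.substitutions):
            sampler.add_substitution(p.species, seg_idx=i,
                                     origin="planted_ssm")
        for _ in range(p.indels):
            sampler.add_indel(p.species, seg_idx=i, origin="planted_ssm")

    total = sampler.total_length
    for code, rate in config.branch_sub_rates.items():
        for _ in range(int(rng.poisson(rate * total))):
            sampler.add_substitution(code)
        ind_rate = rate * config.indel_factor
        for _ in range(int(rng.poisson(ind_rate * total))):
            sampler.add_indel(code)
    for specimen in all_specimens:
        for _ in range(int(rng.poisson(config.specimen_sub_rate * total))):
            sampler.add_substitution(specimen)
        ind_rate = config.specimen_sub_rate * config.indel_factor
        for _ in range(int(rng.poisson(ind_rate * total))):
            sampler.add_indel(specimen)
    for region, spec_idx in singletons:
        i = sampler.segment_by_region(region)
        sampler.add_substitution(all_specimens[spec_idx], seg_idx=i,
                                 origin="planted_singleton")

    genomes = []
    for code in "ABC":
        label = config.species_label(code)
        for specimen in specimens_by_code[code]:
            mutated = _apply_events(segments, sampler.events, specimen,
                                    specimens_by_code)
            genomes.append(_assemble(mutated, label, specimen,
                                     circular=circular, with_ir=with_ir))
    manifest = {
        "seed": seed,
        "species": {code: config.species_label(code) for code in "ABC"},
        "specimens": all_specimens,
        "parameters": {
            "branch_sub_rates": dict(config.branch_sub_rates),
            "specimen_sub_rate": config.specimen_sub_rate,
            "indel_factor": config.indel_factor,
            "cds_synonymous_fraction": config.cds_synonymous_fraction,
        },
        "regions": _region_census(segments),
        "events": [
            {k: v for k, v in ev.items() if k not in ("segment",)}
            | {"specimens": _scope_specimens(ev["scope"], specimens_by_code)}
            for ev in sampler.events
        ],
        "planted_ssrs": placed_ssrs,
    }
    return genomes, manifest


def _region_census(segments: list[Segment]) -> list[dict]:
    census: dict[str, dict] = {}
    for seg in segments:
        name = seg.name + (".pseudo" if seg.pseudo and seg.kind == "exon"
                           else "")
        kind = "CDS" if seg.kind == "exon" else seg.kind
        entry = census.setdefault(name, {"region": name, "kind": kind,
                                         "length": 0})
        entry["length"] += len(seg.seq)
    return list(census.values())


def expected_event_counts(manifest: dict) -> dict[str, dict[str, int]]:
    """Per-region expected substitution/indel event counts."""
    out: dict[str, dict[str, int]] = {}
    for ev in manifest["events"]:
        region = ev["region"] + (".pseudo" if ev.get("pseudo") and
                                 ev["region_kind"] == "CDS" else "")
        c = out.setdefault(region, {"substitution": 0, "indel": 0})
        c[ev["kind"]] += 1
    return out


def expected_ssm_counts(manifest: dict):
    """(species -> kind -> count) and ((region, species) -> kind -> count)."""
    per_species: dict[str, dict[str, int]] = {}
    per_region: dict[tuple[str, str], dict[str, int]] = {}
    for ev in manifest["events"]:
        target = ev["expected_ssm_species"]
        if target is None:
            continue
        c = per_species.setdefault(target, {"substitution": 0, "indel": 0})
        c[ev["kind"]] += 1
        region = ev["region"] + (".pseudo" if ev.get("pseudo") and
                                 ev["region_kind"] == "CDS" else "")
        r = per_region.setdefault((region, target),
                                  {"substitution": 0, "indel": 0})
        r[ev["kind"]] += 1
    return per_species, per_region


def write_manifest(manifest: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path


def score_ssm_detection(manifest: dict, records) -> tuple[float, float]:
    """Precision and recall of detected SSM records against the manifest.

    Detection and truth are matched as (region, species, kind) count
    multisets: each expected diagnostic event must be found in its region
    with its kind and diagnostic species, and nothing else may be called.
    """
    _, per_region = expected_ssm_counts(manifest)
    expected: dict[tuple, int] = {}
    for (region, species), kinds in per_region.items():
        for kind, n in kinds.items():
            if n:
                expected[(region, species, kind)] = n
    detected: dict[tuple, int] = {}
    for r in records:
        key = (r.region, r.species, r.kind)
        detected[key] = detected.get(key, 0) + 1
    matched = sum(
        min(n, detected.get(key, 0)) for key, n in expected.items()
    )
    n_expected = sum(expected.values())
    n_detected = sum(detected.values())
    precision = matched / n_detected if n_detected else 1.0
    recall = matched / n_expected if n_expected else 1.0
    return precision, recall
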