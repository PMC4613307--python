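"""Synonymous/nonsynonymous classification of CDS mutation events.

CDS region alignments hold spliced coding sequences in reading-frame
orientation, so codon arithmetic is direct: the reference frame is the
per-column majority consensus, a substitution's codon index is its
ungapped consensus position // 3, and translation uses the bacterial/
plastid genetic code (NCBI table 11).  When several substitutions hit one
codon in one specimen the codon change is evaluated jointly, but each SNP
event keeps its own classified record so per-event totals remain
comparable across tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from Bio.Seq import Seq

from .alignment import GAP, RegionAlignment
from .variation import MutationEvent

PLASTID_TABLE = 11

EFFECTS = (
    "synonymous",
    "nonsynonymous",
    "inframe_insertion",
    "inframe_deletion",
    "frameshift",
    "splice_region",
    "not_applicable",
)


@dataclass(frozen=True)
class CDSEffect:
    """Classified effect of one mutation event on one coding gene."""

    gene: str
    event: MutationEvent
    effect: str
    codon_index: int | None = None  # 0-based codon in the reference frame
    ref_aa: str | None = None
    alt_aa: str | None = None
    protein_length_delta: int | None = None  # amino acids, inframe only
    subtype: str | None = None  # stop_gain / stop_loss for nonsynonymous

    def __post_init__(self) -> None:
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        if self.effect == "synonymous":
            assert self.ref_aa == self.alt_aa
        if self.effect.startswith("inframe"):
            assert self.event.indel_length is not None
            assert self.event.indel_length % 3 == 0
            assert abs(self.protein_length_delta) * 3 == self.event.indel_length
        if self.effect == "frameshift":
            assert self.event.indel_length % 3 != 0


def translate(codon_or_cds: str) -> str:
    """Translate a coding string with the plastid code (table 11)."""
    return str(Seq(codon_or_cds).translate(table=PLASTID_TABLE))


def _reference_frame(aln: RegionAlignment) -> tuple[str, list[int]]:
    """Majority consensus and per-column ungapped reference position.

    A column belongs to the reference frame when non-gap rows are the
    strict majority; insertion columns (gap majority) map to -1.
    """
    n_rows = len(aln.rows)
    consensus = []
    ref_pos: list[int] = []
    pos = 0
    for col in range(aln.length):
        column = aln.column(col)
        gaps = sum(1 for c in column if c == GAP)
        if gaps * 2 < n_rows:
            counts: dict[str, int] = {}
            for c in column:
                if c != GAP:
                    counts[c] = counts.get(c, 0) + 1
            consensus.append(max(sorted(counts), key=counts.get))
            ref_pos.append(pos)
            pos += 1
        else:
            consensus.append(GAP)
            ref_pos.append(-1)
    return "".join(consensus), ref_pos


def classify_substitution(
    event: MutationEvent,
    aln: RegionAlignment,
    gene: str | None = None,
    pseudo: bool = False,
) -> CDSEffect:
    """Classify one CDS substitution event as synonymous or nonsynonymous.

    The alternative codon is read from the carrier specimen's full row
    over the codon's columns, so several substitutions hitting one codon
    in one specimen are automatically evaluated as a single joint codon
    change while each event keeps its own record.
    """
    gene = gene or event.region
    if pseudo:
        return CDSEffect(gene=gene, event=event, effect="not_applicable")
    consensus, ref_pos = _reference_frame(aln)
    col = event.column
    if ref_pos[col] < 0:
        # substitution inside an insertion private to some specimens: no
        # reference codon exists; fold into the insertion's account
        return CDSEffect(gene=gene, event=event, effect="not_applicable",
                         subtype="inside_insertion")
    codon_idx = ref_pos[col] // 3
    carriers = [
        sp
        for sp, a in event.alleles.items()
        if a not in (GAP, "N") and a != consensus[col]
    ]
    # columns of this codon altered in a carrier (joint codon evaluation)
    codon_cols = [
        c
        for c in range(aln.length)
        if ref_pos[c] >= 0 and ref_pos[c] // 3 == codon_idx
    ]
    carrier = carriers[0] if carriers else None
    ref_codon = "".join(
        consensus[c] for c in codon_cols
    )
    if carrier is None or len(ref_codon) < 3:
        return CDSEffect(gene=gene, event=event, effect="not_applicable",
                         subtype="degenerate_codon")
    row = aln.row(carrier)
    alt_codon = "".join(
        row[c] if row[c] not in (GAP, "N") else consensus[c]
        for c in codon_cols
    )
    ref_aa = translate(ref_codon)
    alt_aa = translate(alt_codon)
    if ref_aa == alt_aa:
        effect, subtype = "synonymous", None
    else:
        effect = "nonsynonymous"
        subtype = (
            "stop_gain" if alt_aa == "*" else
            "stop_loss" if ref_aa == "*" else None
        )
    return CDSEffect(
        gene=gene,
        event=event,
        effect=effect,
        codon_index=codon_idx,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        subtype=subtype,
    )


def classify_indel(
    event: MutationEvent,
    gene: str | None = None,
    pseudo: bool = False,
    exon_junctions: Sequence[int] = (),
    aln: RegionAlignment | None = None,
) -> CDSEffect:
    """Classify a CDS indel as in-frame (with protein-length delta) or
    frameshift.

    ``exon_junctions`` are ungapped reference positions where spliced
    exons join; an indel whose reference footprint spans one is reported
    as ``splice_region`` with no delta.  The sign of the delta follows the
    gap-pattern majority: when the gapped rows are the majority the
    non-gap rows carry an insertion (+length/3), otherwise the gapped rows
    carry a deletion (-length/3).
    """
    gene = gene or event.region
    if pseudo:
        return CDSEffect(gene=gene, event=event, effect="not_applicable")
    length = event.indel_length
    if exon_junctions and aln is not None:
        _, ref_pos = _reference_frame(aln)
        start, end = event.columns
        span = [ref_pos[c] for c in range(start, end) if ref_pos[c] >= 0]
        if span:
            # deletion: flag when the removed reference span crosses a
            # spliced exon junction
            lo, hi = min(span), max(span) + 1
            if any(lo < j < hi for j in exon_junctions):
                return CDSEffect(gene=gene, event=event,
                                 effect="splice_region")
        else:
            # insertion: flag when the insertion point coincides with a
            # junction (material inserted between two exons)
            point = next(
                (ref_pos[c] for c in range(end, aln.length)
                 if ref_pos[c] >= 0),
                max((p for p in ref_pos if p >= 0), default=-1) + 1,
            )
            if point in exon_junctions:
                return CDSEffect(gene=gene, event=event,
                                 effect="splice_region")
    if length % 3 != 0:
        return CDSEffect(gene=gene, event=event, effect="frameshift")
    gapped = sum(1 for a in event.alleles.values() if set(a) == {GAP})
    total = len(event.alleles)
    if gapped * 2 > total:  # non-gap minority carries an insertion
        effect, delta = "inframe_insertion", length // 3
    else:
        effect, delta = "inframe_deletion", -(length // 3)
    return CDSEffect(
        gene=gene,
        event=event,
        effect=effect,
        protein_length_delta=delta,
    )


def classify_events(
    aln: RegionAlignment,
    events: Sequence[MutationEvent],
    gene: str | None = None,
    pseudo: bool = False,
    exon_junctions: Sequence[int] = (),
) -> list[CDSEffect]:
    """Classify all events of one CDS region alignment."""
    out: list[CDSEffect] = []
    for ev in events:
        if ev.kind == "substitution":
            out.append(
                classify_substitution(ev, aln, gene=gene, pseudo=pseudo)
            )
        else:
            out.append(
                classify_indel(
                    ev, gene=gene, pseudo=pseudo,
                    exon_junctions=exon_junctions, aln=aln,
                )
            )
    return out


def gene_effect_census(effects: Sequence[CDSEffect]) -> pd.DataFrame:
    """Per-gene and total counts of classified CDS effects.

    The final ``TOTAL`` row equals the column-wise sum over genes.
    """
    cols = ["synonymous", "nonsynonymous", "inframe_insertion",
            "inframe_deletion", "frameshift", "splice_region",
            "not_applicable"]
    per_gene: dict[str, dict[str, int]] = {}
    for eff in effects:
        row = per_gene.setdefault(eff.gene, {c: 0 for c in cols})
        row[eff.effect] += 1
    rows = [
        {"gene": gene, **counts} for gene, counts in sorted(per_gene.items())
    ]
    total = {"gene": "TOTAL"}
    for c in cols:
        total[c] = sum(r[c] for r in rows)
    rows.append(total)
    return pd.DataFrame(rows, columns=["gene", *cols])


def effects_table(effects: Sequence[CDSEffect]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": e.gene,
                "column": e.event.column + 1,
                "event_kind": e.event.kind,
                "effect": e.effect,
                "subtype": e.subtype or "",
                "codon_index": -1 if e.codon_index is None else e.codon_index,
                "ref_aa": e.ref_aa or "",
                "alt_aa": e.alt_aa or "",
                "protein_length_delta": (
                    0 if e.protein_length_delta is None
                    else e.protein_length_delta
                ),
            }
            for e in effects
        ],
        columns=[
            "gene", "column", "event_kind", "effect", "subtype",
            "codon_index", "ref_aa", "alt_aa", "protein_length_delta",
        ],
    )
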