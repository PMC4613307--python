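"""Variation scoring on region alignments.

Mutation events follow an indel-as-single-character convention: a maximal
run of alignment columns sharing one gap/non-gap row pattern (with at
least one gapped row) is ONE indel event regardless of its width, and
every column with two or more distinct bases among its non-gap rows is one
substitution event — including columns inside indel runs, scored among the
non-gap rows only.  The potentially-informative-character (PIC) tally of a
region is the number of substitution events plus the number of indel
events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import GAP, RegionAlignment


@dataclass(frozen=True)
class MutationEvent:
    """One substitution or indel event in a region alignment.

    ``alleles`` maps each specimen to its observed state: the base at the
    column for a substitution (``N`` = missing), or the row slice over the
    event's columns for an indel (all-gap for deletion carriers).
    """

    kind: str  # "substitution" | "indel"
    region: str
    columns: tuple[int, int]  # [start, end) in alignment coordinates
    alleles: dict[str, str]
    indel_length: int | None = None
    parsimony_informative: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "indel"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        start, end = self.columns
        if self.kind == "substitution" and end - start != 1:
            raise ValueError("a substitution spans exactly one column")
        if self.kind == "indel" and (end - start < 1 or
                                     self.indel_length != end - start):
            raise ValueError("indel length must equal its column span")

    @property
    def column(self) -> int:
        return self.columns[0]

    def states(self) -> dict[str, str]:
        """Per-specimen comparable state; missing specimens omitted.

        Substitutions: the base (N and gap are missing data).  Indels:
        ``gap`` vs ``present`` (the gap pattern is shared by construction).
        """
        if self.kind == "substitution":
            return {
                sp: a
                for sp, a in self.alleles.items()
                if a not in (GAP, "N")
            }
        return {
            sp: ("gap" if set(a) == {GAP} else "present")
            for sp, a in self.alleles.items()
        }


def _informative(states: dict[str, str]) -> bool:
    counts: dict[str, int] = {}
    for s in states.values():
        counts[s] = counts.get(s, 0) + 1
    return sum(1 for c in counts.values() if c >= 2) >= 2


def call_mutation_events(aln: RegionAlignment) -> list[MutationEvent]:
    """Score substitution and indel events on one region alignment."""
    events: list[MutationEvent] = []
    length = aln.length
    rows = aln.rows
    # indels: maximal runs of a constant gap/non-gap pattern with >=1 gap
    run_start = 0
    prev_pattern = None
    for col in range(length + 1):
        pattern = (
            tuple(r[col] == GAP for r in rows) if col < length else None
        )
        if pattern != prev_pattern:
            if prev_pattern is not None and any(prev_pattern):
                events.append(_indel_event(aln, run_start, col))
            run_start = col
            prev_pattern = pattern
    # substitutions: one per polymorphic column, non-gap rows only
    for col in range(length):
        column = aln.column(col)
        bases = {c for c in column if c not in (GAP, "N")}
        if len(bases) >= 2:
            alleles = dict(zip(aln.specimens, column))
            ev = MutationEvent(
                kind="substitution",
                region=aln.region,
                columns=(col, col + 1),
                alleles=alleles,
            )
            object.__setattr__(ev, "parsimony_informative",
                               _informative(ev.states()))
            events.append(ev)
    events.sort(key=lambda e: (e.columns, e.kind))
    return events


def _indel_event(aln: RegionAlignment, start: int, end: int) -> MutationEvent:
    alleles = {
        sp: row[start:end] for sp, row in zip(aln.specimens, aln.rows)
    }
    ev = MutationEvent(
        kind="indel",
        region=aln.region,
        columns=(start, end),
        alleles=alleles,
        indel_length=end - start,
    )
    object.__setattr__(ev, "parsimony_informative", _informative(ev.states()))
    return ev


def variable_columns(aln: RegionAlignment) -> set[int]:
    """Union of substitution columns and indel-run columns."""
    cols: set[int] = set()
    for ev in call_mutation_events(aln):
        cols.update(range(*ev.columns))
    return cols


def percent_variable(aln: RegionAlignment) -> float:
    """Percentage of alignment columns that are variable.

    A column is variable if it is polymorphic among non-gap rows or lies
    inside an indel run.  Undefined (error) for a zero-length alignment.
    """
    if aln.length == 0:
        raise ValueError("percent variable is undefined for an empty alignment")
    return 100.0 * len(variable_columns(aln)) / aln.length


def odonnell_proportion(
    n_substitutions: int,
    n_indels: int,
    aligned_length: int,
    variant: str = "aligned_length",
) -> float:
    """Proportion of mutational events for a (noncoding) region.

    The default divides the event tally (substitutions + indels) by the
    aligned region length; ``variant="per_event_site"`` divides by the
    number of variable event sites + invariant sites, i.e. treats each
    multi-column indel as one character (aligned length minus indel columns
    plus indel events).  The variant used is recorded in output metadata
    by the pipeline.
    """
    if n_substitutions < 0 or n_indels < 0:
        raise ValueError("event counts must be non-negative")
    if aligned_length <= 0:
        raise ValueError("aligned length must be positive")
    if variant not in ("aligned_length", "per_event_site"):
        raise ValueError(f"unknown O'Donnell variant {variant!r}")
    return (n_substitutions + n_indels) / aligned_length


@dataclass(frozen=True)
class VariationSummary:
    """Per-region variation summary (PIC = substitutions + indels)."""

    region: str
    kind: str
    aligned_length: int
    n_substitutions: int
    n_indels: int
    pic: int
    percent_variable: float
    odonnell: float

    def __post_init__(self) -> None:
        assert self.pic == self.n_substitutions + self.n_indels
        assert 0.0 <= self.percent_variable <= 100.0
        assert self.odonnell >= 0.0


def summarize_region(
    aln: RegionAlignment,
    kind: str = "",
    events: list[MutationEvent] | None = None,
    odonnell_variant: str = "aligned_length",
) -> VariationSummary:
    if events is None:
        events = call_mutation_events(aln)
    ns = sum(1 for e in events if e.kind == "substitution")
    nid = sum(1 for e in events if e.kind == "indel")
    return VariationSummary(
        region=aln.region,
        kind=kind,
        aligned_length=aln.length,
        n_substitutions=ns,
        n_indels=nid,
        pic=ns + nid,
        percent_variable=percent_variable(aln),
        odonnell=odonnell_proportion(ns, nid, aln.length, odonnell_variant),
    )


def variation_table(summaries: list[VariationSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region": s.region,
                "kind": s.kind,
                "aligned_length": s.aligned_length,
                "n_substitutions": s.n_substitutions,
                "n_indels": s.n_indels,
                "pic": s.pic,
                "percent_variable": round(s.percent_variable, 4),
                "odonnell_proportion": round(s.odonnell, 6),
            }
            for s in summaries
        ]
    )


def pairwise_p_distances(
    alignments: list[RegionAlignment],
) -> dict[tuple[str, str], float]:
    """Uncorrected p-distances over concatenated region alignments.

    Columns where either member of a pair carries a gap or N are excluded
    for that pair; the distance is mismatches / compared columns.
    """
    if not alignments:
        raise ValueError("need at least one alignment")
    specimens = alignments[0].specimens
    diff: dict[tuple[str, str], int] = {}
    comp: dict[tuple[str, str], int] = {}
    for aln in alignments:
        if aln.specimens != specimens:
            raise ValueError("alignments cover different specimen sets")
        for i, sp1 in enumerate(specimens):
            r1 = aln.rows[i]
            for j in range(i + 1, len(specimens)):
                sp2 = specimens[j]
                r2 = aln.rows[j]
                key = (sp1, sp2)
                d = c = 0
                for a, b in zip(r1, r2):
                    if a in (GAP, "N") or b in (GAP, "N"):
                        continue
                    c += 1
                    if a != b:
                        d += 1
                diff[key] = diff.get(key, 0) + d
                comp[key] = comp.get(key, 0) + c
    return {k: diff[k] / comp[k] if comp[k] else 0.0 for k in diff}


def sliding_identity(
    aln: RegionAlignment,
    window: int = 100,
    step: int = 25,
    reference: str | None = None,
) -> pd.DataFrame:
    """mVISTA-style percent-identity profile against a reference row.

    Each window of ``window`` columns advanced by ``step`` yields, per
    specimen, the percentage of columns identical to the reference row;
    gap columns count as mismatches.  Profile length is
    ``floor((L - window) / step) + 1``.
    """
    if not (window >= step >= 1):
        raise ValueError("require window >= step >= 1")
    if window > aln.length:
        raise ValueError(
            f"window ({window}) exceeds alignment length ({aln.length})"
        )
    ref = reference if reference is not None else aln.specimens[0]
    ref_row = np.frombuffer(aln.row(ref).encode(), dtype="S1")
    starts = np.arange(0, aln.length - window + 1, step)
    data = {"window_start": starts + 1}  # 1-based reported
    for sp in aln.specimens:
        row = np.frombuffer(aln.row(sp).encode(), dtype="S1")
        match = (row == ref_row) & (row != b"-") & (ref_row != b"-")
        csum = np.concatenate([[0], np.cumsum(match)])
        data[sp] = 100.0 * (csum[starts + window] - csum[starts]) / window
    return pd.DataFrame(data)
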