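"""Species-specific mutation (SSM) detection and barcode-region ranking.

An event is species-specific (diagnostic) when exactly two allele states
exist, one carried by all specimens of exactly one species and the other
(the consensus) by all remaining specimens.  Intraspecific variation,
three or more states, or missing data at the site all disqualify an event
— with two specimens per species this is the strictest certifiable notion
of a barcode character.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .alignment import GAP
from .regions import Region
from .variation import MutationEvent


@dataclass(frozen=True)
class SSMRecord:
    """A mutation event certified diagnostic for exactly one species."""

    region: str
    event: MutationEvent
    species: str
    diagnostic_allele: str
    consensus_allele: str
    kind: str  # "substitution" | "indel"


def _check_species_map(
    events_specimens: set[str], species_of: Mapping[str, str]
) -> dict[str, list[str]]:
    unassigned = events_specimens - set(species_of)
    if unassigned:
        raise ValueError(
            f"specimens without species assignment: {sorted(unassigned)}"
        )
    by_species: dict[str, list[str]] = {}
    for specimen in sorted(events_specimens):
        by_species.setdefault(species_of[specimen], []).append(specimen)
    if len(by_species) < 2:
        raise ValueError("SSM detection requires >= 2 species")
    thin = [sp for sp, members in by_species.items() if len(members) < 2]
    if thin:
        raise ValueError(
            f"species with a single specimen: {sorted(thin)}; intraspecific "
            "invariance cannot be verified with fewer than 2 specimens"
        )
    return by_species


def detect_ssm(
    events: Sequence[MutationEvent],
    species_of: Mapping[str, str],
) -> tuple[list[SSMRecord], list[MutationEvent]]:
    """Partition events into SSM records and non-diagnostic events.

    Sites where any specimen carries N are excluded from SSM calling
    (missing data cannot certify intraspecific invariance) and land in the
    non-diagnostic list.
    """
    records: list[SSMRecord] = []
    non_diagnostic: list[MutationEvent] = []
    by_species: dict[str, list[str]] | None = None
    for ev in events:
        if by_species is None:
            by_species = _check_species_map(set(ev.alleles), species_of)
        if ev.kind == "substitution" and any(
            "N" in a for a in ev.alleles.values()
        ):
            non_diagnostic.append(ev)
            continue
        states = ev.states()
        if len(states) != len(ev.alleles):  # gap rows at a substitution site
            non_diagnostic.append(ev)
            continue
        distinct = set(states.values())
        if len(distinct) != 2:
            non_diagnostic.append(ev)
            continue
        hit = None
        for species, members in by_species.items():
            member_states = {states[m] for m in members}
            others = [m for m in states if species_of[m] != species]
            other_states = {states[m] for m in others}
            if (
                len(member_states) == 1
                and len(other_states) == 1
                and member_states != other_states
            ):
                hit = (species, member_states.pop(), other_states.pop())
                break
        if hit is None:
            non_diagnostic.append(ev)
            continue
        species, diag_state, cons_state = hit
        if ev.kind == "indel":
            carrier = by_species[species][0]
            other = next(m for m in states if species_of[m] != species)
            diag_allele = ev.alleles[carrier]
            cons_allele = ev.alleles[other]
        else:
            diag_allele, cons_allele = diag_state, cons_state
        records.append(
            SSMRecord(
                region=ev.region,
                event=ev,
                species=species,
                diagnostic_allele=diag_allele,
                consensus_allele=cons_allele,
                kind=ev.kind,
            )
        )
    return records, non_diagnostic


@dataclass(frozen=True)
class BarcodeReport:
    """Per-region barcode utility report."""

    table: pd.DataFrame

    def discriminating_regions(self) -> list[str]:
        return list(self.table.loc[self.table["discriminates_all"], "region"])


def rank_barcode_regions(
    records: Sequence[SSMRecord],
    regions: Mapping[str, Region] | Mapping[str, int],
    species: Sequence[str],
    max_practical_length: int = 1000,
) -> BarcodeReport:
    """Rank regions by barcoding utility.

    Sort order: regions diagnosing all species first, then by total SSM
    count (descending), then by length (ascending — shorter regions are
    easier to assay).  Regions longer than ``max_practical_length`` bp are
    flagged impractical for routine tests.
    """
    lengths = {
        name: (r.length if isinstance(r, Region) else int(r))
        for name, r in regions.items()
    }
    rows = []
    for name in lengths:
        here = [r for r in records if r.region == name]
        row: dict = {"region": name, "length": lengths[name]}
        total = 0
        discriminates = True
        for sp in species:
            subs = sum(
                1 for r in here if r.species == sp and r.kind == "substitution"
            )
            inds = sum(1 for r in here if r.species == sp and r.kind == "indel")
            row[f"{sp}_substitutions"] = subs
            row[f"{sp}_indels"] = inds
            total += subs + inds
            if subs + inds == 0:
                discriminates = False
        row["total_ssm"] = total
        row["discriminates_all"] = discriminates
        row["impractical_length"] = lengths[name] > max_practical_length
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["discriminates_all", "total_ssm", "length", "region"],
        ascending=[False, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return BarcodeReport(table=df)


def species_delimitation_table(
    records: Sequence[SSMRecord],
    region: str,
    specimen_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Diagnostic-site table for one region (ITS2-figure style).

    One row per SSM with the reported 1-based alignment column, the
    diagnostic species, and each specimen's allele in input order.  A
    region without SSMs yields an empty table (with a notice column set).
    """
    here = [r for r in records if r.region == region]
    if not here:
        return pd.DataFrame(
            columns=["region", "column", "kind", "species", "notice"]
        )
    if specimen_order is None:
        specimen_order = list(here[0].event.alleles)
    rows = []
    for r in sorted(here, key=lambda r: r.event.columns):
        row = {
            "region": region,
            "column": r.event.column + 1,
            "kind": r.kind,
            "species": r.species,
            "diagnostic_allele": r.diagnostic_allele,
            "consensus_allele": r.consensus_allele,
        }
        for specimen in specimen_order:
            row[specimen] = r.event.alleles[specimen]
        rows.append(row)
    return pd.DataFrame(rows)


def ssm_table(records: Sequence[SSMRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region": r.region,
                "column": r.event.column + 1,
                "kind": r.kind,
                "species": r.species,
                "diagnostic_allele": r.diagnostic_allele,
                "consensus_allele": r.consensus_allele,
                "indel_length": r.event.indel_length or 0,
            }
            for r in records
        ],
        columns=[
            "region", "column", "kind", "species", "diagnostic_allele",
            "consensus_allele", "indel_length",
        ],
    )


def ssm_census(records: Sequence[SSMRecord]) -> pd.DataFrame:
    """Genome-wide SSM counts per species (substitutions / indels)."""
    counts: dict[str, dict[str, int]] = {}
    for r in records:
        c = counts.setdefault(r.species, {"substitution": 0, "indel": 0})
        c[r.kind] += 1
    return pd.DataFrame(
        [
            {"species": sp, "substitutions": c["substitution"],
             "indels": c["indel"]}
            for sp, c in sorted(counts.items())
        ],
        columns=["species", "substitutions", "indels"],
    )
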