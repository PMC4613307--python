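"""Microsatellite (SSR) scanning and cross-specimen comparison.

Scans for maximal tandem repeats of 1-3 bp motifs at MSATCOMMANDER-style
thresholds (defaults: mononucleotide >= 10 repeats, dinucleotide >= 6,
trinucleotide >= 4).  A run qualifying at several unit lengths is reported
once at the smallest unit; motifs are canonicalized to their
lexicographically minimal rotation; runs are broken at N.  Scanning is
intended for IRb-free sequences so duplicated loci count once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {1: 10, 2: 6, 3: 4}


def canonical_rotation(motif: str) -> str:
    """Lexicographically minimal rotation of a motif."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _minimal_period(motif: str) -> int:
    for p in range(1, len(motif)):
        if len(motif) % p == 0 and motif == motif[:p] * (len(motif) // p):
            return p
    return len(motif)


@dataclass(frozen=True)
class SSRLocus:
    """One maximal microsatellite run in one specimen."""

    motif: str  # canonical rotation
    observed_motif: str  # as read at the locus start
    unit: int
    count: int
    start: int  # 0-based half-open interval on the source sequence
    end: int
    specimen: str = ""

    def __post_init__(self) -> None:
        if self.unit != len(self.observed_motif) or self.unit not in (1, 2, 3):
            raise ValueError("unit length must be 1-3 and match the motif")
        if self.end - self.start != self.unit * self.count:
            raise ValueError("locus interval must equal unit * count")


def scan_ssrs(
    sequence: str,
    thresholds: Mapping[int, int] | None = None,
    specimen: str = "",
) -> list[SSRLocus]:
    """Find all qualifying SSR loci in a sequence (maximal runs only)."""
    thresholds = dict(thresholds or DEFAULT_THRESHOLDS)
    loci: list[SSRLocus] = []
    # break at N: scan each N-free segment with its offset
    offset = 0
    for segment in sequence.split("N"):
        if segment:
            loci.extend(_scan_segment(segment, offset, thresholds, specimen))
        offset += len(segment) + 1
    loci.sort(key=lambda l: (l.start, l.unit))
    return loci


def _scan_segment(seq, offset, thresholds, specimen):
    n = len(seq)
    out = []
    for unit, min_count in sorted(thresholds.items()):
        i = 0
        while i + unit <= n:
            if _minimal_period(seq[i : i + unit]) != unit:
                i += 1
                continue
            # maximal periodic extension: seq[i:j] has period `unit`
            j = i + unit
            while j < n and seq[j] == seq[j - unit]:
                j += 1
            count = (j - i) // unit
            if count >= min_count:
                motif = seq[i : i + unit]
                # maximality check against a longer partial context is
                # inherent: seq[i-1] != seq[i-1+unit] (else i-1 would have
                # started the run) and seq[j] != seq[j-unit]
                out.append(
                    SSRLocus(
                        motif=canonical_rotation(motif),
                        observed_motif=motif,
                        unit=unit,
                        count=count,
                        start=offset + i,
                        end=offset + i + unit * count,
                        specimen=specimen,
                    )
                )
            if count >= 2:
                i = j - unit + 1
            else:
                i += 1
    return out


def ssr_table(loci: Sequence[SSRLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "specimen": l.specimen,
                "motif": l.motif,
                "unit": l.unit,
                "count": l.count,
                "start": l.start + 1,
                "end": l.end,
            }
            for l in loci
        ],
        columns=["specimen", "motif", "unit", "count", "start", "end"],
    )


def compare_ssr_sets(
    loci_per_specimen: Mapping[str, Sequence[SSRLocus]],
    species_of: Mapping[str, str],
    sequences: Mapping[str, str],
    flank: int = 20,
) -> pd.DataFrame:
    """Match loci across specimens and flag species-specific ones.

    Loci are anchored by their exact ``flank``-bp left and right context
    (coordinate matching fails between specimens because indels shift
    positions).  A flank pair matching two loci within one specimen is
    ambiguous and excluded (logged).  A locus present in all specimens of
    exactly one species and absent in all others — including present but
    below threshold, which the scanner never reports — is species-specific.
    """
    specimens = list(loci_per_specimen)
    anchors: dict[tuple[str, str], dict] = {}
    ambiguous: set[tuple[str, str]] = set()
    for specimen in specimens:
        seq = sequences[specimen]
        seen: set[tuple[str, str]] = set()
        for locus in loci_per_specimen[specimen]:
            left = seq[max(locus.start - flank, 0) : locus.start]
            right = seq[locus.end : locus.end + flank]
            key = (left, right)
            if key in seen:
                ambiguous.add(key)
                logger.info(
                    "ambiguous SSR anchoring in %s at %d; excluded",
                    specimen, locus.start,
                )
                continue
            seen.add(key)
            entry = anchors.setdefault(
                key, {"motif": locus.motif, "unit": locus.unit,
                      "counts": {}, "order": locus.start}
            )
            entry["counts"][specimen] = locus.count
    by_species: dict[str, list[str]] = {}
    for specimen in specimens:
        by_species.setdefault(species_of[specimen], []).append(specimen)
    rows = []
    for key, entry in sorted(anchors.items(), key=lambda kv: kv[1]["order"]):
        if key in ambiguous:
            continue
        carriers = set(entry["counts"])
        specific = ""
        for species, members in by_species.items():
            if carriers == set(members):
                specific = species
        rows.append(
            {
                "motif": entry["motif"],
                "unit": entry["unit"],
                "n_specimens": len(carriers),
                "specimens": ",".join(
                    sp for sp in specimens if sp in carriers
                ),
                "shared_by_all": carriers == set(specimens),
                "species_specific": specific,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["motif", "unit", "n_specimens", "specimens",
                 "shared_by_all", "species_specific"],
    )


def ssr_census(
    loci_per_specimen: Mapping[str, Sequence[SSRLocus]],
    species_of: Mapping[str, str],
    comparison: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-specimen locus counts plus per-species deduplicated counts."""
    rows = []
    per_species_specimens: dict[str, list[str]] = {}
    for specimen, loci in loci_per_specimen.items():
        per_species_specimens.setdefault(
            species_of[specimen], []
        ).append(specimen)
        counts = {u: 0 for u in (1, 2, 3)}
        for l in loci:
            counts[l.unit] += 1
        rows.append(
            {
                "level": "specimen",
                "label": specimen,
                "species": species_of[specimen],
                "mono": counts[1],
                "di": counts[2],
                "tri": counts[3],
                "total": sum(counts.values()),
            }
        )
    if comparison is not None and len(comparison):
        for species, members in per_species_specimens.items():
            mask = comparison["specimens"].apply(
                lambda s: bool(set(s.split(",")) & set(members))
            )
            sub = comparison[mask]
            counts = {u: int((sub["unit"] == u).sum()) for u in (1, 2, 3)}
            rows.append(
                {
                    "level": "species",
                    "label": species,
                    "species": species,
                    "mono": counts[1],
                    "di": counts[2],
                    "tri": counts[3],
                    "total": sum(counts.values()),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["level", "label", "species", "mono", "di", "tri", "total"],
    )
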