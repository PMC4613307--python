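"""Multiple alignment of homologous regions across specimens.

The built-in aligner is a deterministic progressive scheme over pairwise
global alignments (Needleman-Wunsch with affine gaps: match +1, mismatch
-1, gap open -4, gap extend -1), adding sequences in input order against
the majority representative of the growing alignment.  For conspecific
organelle regions (>98% identity) this is ample; an external aligner's
output can be imported from aligned FASTA instead and is validated against
the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import check_sequence

GAP = "-"


@dataclass(frozen=True)
class RegionAlignment:
    """One homologous region aligned across all specimens."""

    region: str
    specimens: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.specimens) != len(self.rows):
            raise ValueError("specimen labels and rows differ in number")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(
                f"alignment rows of unequal length in {self.region!r}: "
                f"{sorted(lengths)} — aligner contract violation"
            )
        for col in range(self.length):
            if all(r[col] == GAP for r in self.rows):
                raise ValueError(
                    f"all-gap column {col} in {self.region!r}; the aligner "
                    "must not emit such columns"
                )

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, specimen: str) -> str:
        return self.rows[self.specimens.index(specimen)]

    def degapped(self, specimen: str) -> str:
        return self.row(specimen).replace(GAP, "")

    def column(self, col: int) -> tuple[str, ...]:
        return tuple(r[col] for r in self.rows)


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


def _consensus(rows: Sequence[str]) -> str:
    """Majority non-gap character per column (ties by base order A<C<G<T)."""
    out = []
    for col in zip(*rows):
        counts: dict[str, int] = {}
        for c in col:
            if c != GAP:
                counts[c] = counts.get(c, 0) + 1
        out.append(max(sorted(counts), key=counts.get))
    return "".join(out)


def align_region(
    sequences: Mapping[str, str],
    region: str = "region",
    aligner=None,
) -> RegionAlignment:
    """Align per-specimen region sequences into a RegionAlignment.

    ``aligner`` may be a callable ``(dict specimen->seq) -> dict
    specimen->aligned seq`` to plug in an external tool; the default is the
    built-in progressive aligner.  The result always satisfies the
    RegionAlignment invariants (equal row lengths, no all-gap column,
    de-gapping reproduces the inputs).
    """
    if len(sequences) < 2:
        raise ValueError("alignment requires >= 2 sequences")
    for name, s in sequences.items():
        if not s:
            raise ValueError(f"empty sequence for specimen {name!r}")
        check_sequence(s)
    if aligner is not None:
        aligned = aligner(dict(sequences))
        aln = RegionAlignment(
            region=region,
            specimens=tuple(aligned),
            rows=tuple(aligned.values()),
        )
    else:
        aln = _progressive_align(sequences, region)
    for specimen in aln.specimens:
        if aln.degapped(specimen) != sequences[specimen]:
            raise ValueError(
                f"aligner contract violation: de-gapped row for "
                f"{specimen!r} does not reproduce its input sequence"
            )
    return aln


def _progressive_align(sequences: Mapping[str, str], region: str):
    pw = _make_aligner()
    specimens = list(sequences)
    rows = [sequences[specimens[0]]]
    for specimen in specimens[1:]:
        rep = _consensus(rows)
        aln = pw.align(rep, sequences[specimen])[0]
        rep_aln, new_aln = str(aln[0]), str(aln[1])
        # positions where the representative gained a gap are new columns
        # to be inserted into every existing row
        rows = _merge(rows, rep_aln)
        rows.append(new_aln)
    return RegionAlignment(region=region, specimens=tuple(specimens),
                           rows=tuple(rows))


def _merge(rows: list[str], rep_aligned: str) -> list[str]:
    out = [[] for _ in rows]
    col = 0
    for ch in rep_aligned:
        if ch == GAP:
            for acc in out:
                acc.append(GAP)
        else:
            for acc, row in zip(out, rows):
                acc.append(row[col])
            col += 1
    return ["".join(acc) for acc in out]


def read_alignment_fasta(path: str | Path, region: str | None = None):
    """Import a pre-aligned FASTA (e.g. from MUSCLE/MAFFT)."""
    path = Path(path)
    records = list(SeqIO.parse(path, "fasta"))
    if len(records) < 2:
        raise ValueError(f"{path}: alignment needs >= 2 sequences")
    return RegionAlignment(
        region=region or path.stem,
        specimens=tuple(r.id for r in records),
        rows=tuple(str(r.seq).upper() for r in records),
    )


def write_alignment_fasta(aln: RegionAlignment, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = [
        SeqRecord(Seq(row), id=sp, description="")
        for sp, row in zip(aln.specimens, aln.rows)
    ]
    SeqIO.write(records, path, "fasta")
    return path
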