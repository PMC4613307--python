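"""Inverted-repeat detection and quadripartite partitioning.

A plastome typically consists of a large single-copy region (LSC), a small
single-copy region (SSC) and two inverted repeats (IRa/IRb) that are exact
reverse complements of one another.  Detection here finds the longest pair
of disjoint, reverse-complementary intervals; by default the match must be
exact, with an optional substitution-mismatch budget.

Arcs of the circle are stored as (start, end) with modular semantics: an
arc whose ``end <= start`` wraps through the sequence origin.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .genome import AnnotatedGenome, revcomp

_SEED = 24  # seed k-mer length; any repeat >= min_ir (>=100) contains one


def arc_length(interval: tuple[int, int], n: int) -> int:
    start, end = interval
    if interval == (0, n):
        return n
    return (end - start) % n


@dataclass(frozen=True)
class QuadripartiteStructure:
    """LSC/IRa/SSC/IRb intervals of one plastome, on the input orientation."""

    lsc: tuple[int, int]
    ira: tuple[int, int]
    ssc: tuple[int, int]
    irb: tuple[int, int]
    ir_length: int
    genome_length: int
    no_ir: bool = False
    mismatches: int = 0

    def validate(self, sequence: str | None = None) -> None:
        """Check the tiling invariant and (if exact) IR sequence identity."""
        n = self.genome_length
        if self.no_ir:
            if self.ir_length != 0 or arc_length(self.lsc, n) != n:
                raise AssertionError("no-IR structure must be LSC-only")
            return
        total = (
            arc_length(self.lsc, n)
            + arc_length(self.ssc, n)
            + 2 * self.ir_length
        )
        if total != n:
            raise AssertionError(
                f"quadripartite tiling violated: {total} != {n}"
            )
        if arc_length(self.ira, n) != self.ir_length or arc_length(
            self.irb, n
        ) != self.ir_length:
            raise AssertionError("IR interval lengths disagree with ir_length")
        if sequence is not None and self.mismatches == 0:
            if revcomp(_slice(sequence, self.ira)) != _slice(sequence, self.irb):
                raise AssertionError("IRa is not the reverse complement of IRb")

    def single_copy_plus_ira_length(self) -> int:
        return self.genome_length - self.ir_length


def _slice(seq: str, interval: tuple[int, int]) -> str:
    start, end = interval
    if end > start:
        return seq[start:end]
    return seq[start:] + seq[:end]


def detect_quadripartite(
    genome: AnnotatedGenome,
    min_ir: int = 1000,
    max_mismatch: int = 0,
) -> QuadripartiteStructure:
    """Partition a circular genome into LSC, IRa, SSC and IRb.

    Finds the longest pair of disjoint intervals whose sequences are exact
    reverse complements (up to ``max_mismatch`` substitutions) and of
    length >= ``min_ir``.  The longer of the two remaining arcs is the LSC
    and the shorter the SSC; IRa is the repeat copy that follows the LSC in
    circular order.  If no qualifying repeat exists the structure is
    flagged ``no_ir`` with the LSC covering the whole circle.
    """
    if not genome.circular:
        raise ValueError("quadripartite detection requires a circular genome")
    if min_ir < 100:
        raise ValueError("min_ir must be >= 100")
    seq = genome.sequence
    n = len(seq)
    best = _longest_ir_pair(seq, min_ir, max_mismatch)
    if best is None:
        return QuadripartiteStructure(
            lsc=(0, n), ira=(0, 0), ssc=(0, 0), irb=(0, 0),
            ir_length=0, genome_length=n, no_ir=True,
        )
    (a_start, a_end), (b_start, b_end), mism = best
    ir_len = a_end - a_start
    arc1 = (a_end, b_start)          # between first and second copy
    arc2 = (b_end % n, a_start)      # wraps through the origin (or not)
    if arc_length(arc1, n) >= arc_length(arc2, n):
        lsc, ssc = arc1, arc2
        ira, irb = (b_start, b_end), (a_start, a_end)
    else:
        lsc, ssc = arc2, arc1
        ira, irb = (a_start, a_end), (b_start, b_end)
    structure = QuadripartiteStructure(
        lsc=lsc, ira=ira, ssc=ssc, irb=irb,
        ir_length=ir_len, genome_length=n, mismatches=mism,
    )
    structure.validate(seq if max_mismatch == 0 else None)
    return structure


def _longest_ir_pair(seq: str, min_ir: int, max_mismatch: int):
    """Longest disjoint pair of reverse-complementary intervals.

    Seed-and-extend on the diagonals of seq vs revcomp(seq): a repeat pair
    (S[a:b], S[c:d]) with revcomp(S[c:d]) == S[a:b] appears as a run of
    matching k-mers on one diagonal ``i - j`` of S against R = revcomp(S),
    where j = n - d.  All k-mer hits are grouped per diagonal, runs are
    merged across at most ``max_mismatch`` substitutions, and the longest
    run mapping to disjoint intervals wins.  Ties break toward the
    smallest start coordinate.
    """
    n = len(seq)
    k = min(_SEED, min_ir)
    rc = revcomp(seq)
    kmer_pos: dict[str, list[int]] = defaultdict(list)
    for j in range(n - k + 1):
        kmer_pos[rc[j : j + k]].append(j)
    diagonals: dict[int, list[int]] = defaultdict(list)
    for i in range(n - k + 1):
        for j in kmer_pos.get(seq[i : i + k], ()):
            diagonals[i - j].append(i)
    best = None  # (length, a_start, b_start, mismatches)
    for diag, positions in diagonals.items():
        for i0, i1, mism in _diagonal_runs(seq, rc, diag, positions, k,
                                           max_mismatch):
            length = i1 - i0
            if length < min_ir:
                continue
            # S interval [i0, i1); partner in S is [n - (j0 + L), n - j0)
            j0 = i0 - diag
            p_start, p_end = n - j0 - length, n - j0
            a, b = sorted([(i0, i1), (p_start, p_end)])
            if a[1] > b[0]:  # overlapping: a self-palindrome, not an IR pair
                continue
            cand = (length, -a[0], a, b, mism)
            if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                best = cand
    if best is None:
        return None
    _, _, a, b, mism = best
    return a, b, mism


def _diagonal_runs(seq, rc, diag, positions, k, max_mismatch):
    """Maximal matching runs on one diagonal, allowing substitutions.

    ``positions`` are the seed start offsets i with seq[i:i+k] == rc[i-diag:
    ...].  Consecutive seeds are first collapsed into exact segments
    [i, i + run + k); with a mismatch budget the segments are re-scanned
    character-wise over their envelope with a two-pointer window.
    """
    segments = []
    positions.sort()
    start = prev = positions[0]
    for i in positions[1:]:
        if i == prev + 1:
            prev = i
        else:
            segments.append((start, prev + k))
            start = prev = i
    segments.append((start, prev + k))
    if max_mismatch == 0:
        return [(s, e, 0) for s, e in segments]
    # widen across mismatches: scan the envelope of all segments on this
    # diagonal plus a margin, and find the longest window with at most
    # max_mismatch mismatching characters
    n = len(seq)
    lo = max(segments[0][0] - max_mismatch, 0, diag)
    hi = min(segments[-1][1] + max_mismatch, n, n + diag)
    match = [seq[i] == rc[i - diag] for i in range(lo, hi)]
    runs = []
    left = 0
    bad = 0
    best_len = 0
    best = None
    for right, ok in enumerate(match):
        if not ok:
            bad += 1
        while bad > max_mismatch:
            if not match[left]:
                bad -= 1
            left += 1
        if right - left + 1 > best_len:
            best_len = right - left + 1
            best = (lo + left, lo + right + 1, bad)
    if best is not None:
        s, e, bad = best
        # trim flanking mismatches so the run starts and ends on a match
        while s < e and seq[s] != rc[s - diag]:
            s, bad = s + 1, bad - 1
        while e > s and seq[e - 1] != rc[e - 1 - diag]:
            e, bad = e - 1, bad - 1
        runs.append((s, e, bad))
    return runs


def structure_table(structures: dict[str, QuadripartiteStructure]):
    """One row per specimen with 1-based inclusive reported coordinates."""
    import pandas as pd

    rows = []
    for specimen, st in structures.items():
        row = {"specimen": specimen, "genome_length": st.genome_length,
               "ir_length": st.ir_length, "no_ir": st.no_ir}
        for part in ("lsc", "ira", "ssc", "irb"):
            start, end = getattr(st, part)
            length = arc_length((start, end), st.genome_length)
            row[f"{part}_start"] = start + 1 if length else 0
            row[f"{part}_end"] = ((start + length - 1) % st.genome_length + 1
                                  if length else 0)
            row[f"{part}_length"] = length
        rows.append(row)
    return pd.DataFrame(rows)
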