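"""Shared test utilities: small builders and independent oracles.

The oracles here deliberately re-derive results by brute force (full
enumeration, regex scanning, translate-and-diff) so the implementation
under test is never checked against itself.
"""

from __future__ import annotations

import itertools
import re

import numpy as np

from plastocomp.alignment import RegionAlignment
from plastocomp.genome import revcomp


def make_aln(rows, specimens=None, region="test"):
    rows = tuple(rows)
    if specimens is None:
        specimens = tuple(f"s{i}" for i in range(len(rows)))
    return RegionAlignment(region=region, specimens=tuple(specimens),
                           rows=rows)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


# ----------------------------------------------------------------------
# oracle: longest pair of disjoint reverse-complementary intervals
# (dense LCP dynamic programme, O(n^2) memory — small sequences only)


def brute_force_ir(seq: str, min_ir: int):
    """Return (length, interval_a, interval_b) of the longest disjoint
    exactly reverse-complementary interval pair, or None."""
    n = len(seq)
    assert n <= 4000, "oracle is quadratic; use small fixtures"
    s = np.frombuffer(seq.encode(), dtype="S1")
    r = np.frombuffer(revcomp(seq).encode(), dtype="S1")
    match = s[:, None] == r[None, :]
    lcp = np.zeros((n + 1, n + 1), dtype=np.int32)
    for i in range(n - 1, -1, -1):
        lcp[i, :n] = np.where(match[i], lcp[i + 1, 1 : n + 1] + 1, 0)
    best = None
    for i in range(n):
        for j in range(n):
            length = int(lcp[i, j])
            if length < min_ir:
                continue
            a = (i, i + length)
            b = (n - j - length, n - j)
            lo, hi = sorted([a, b])
            if lo[1] > hi[0]:  # overlapping (palindrome) — not an IR pair
                continue
            if best is None or length > best[0] or (
                length == best[0] and lo[0] < best[1][0]
            ):
                best = (length, lo, hi)
    return best


# ----------------------------------------------------------------------
# oracle: mutation events by direct column enumeration


def oracle_events(rows):
    """(n_substitution_events, n_indel_events, substitution_columns)."""
    ncol = len(rows[0])
    sub_cols = []
    for c in range(ncol):
        bases = {r[c] for r in rows if r[c] not in "-N"}
        if len(bases) >= 2:
            sub_cols.append(c)
    indels = 0
    for pattern, cols in itertools.groupby(
        range(ncol), key=lambda c: tuple(r[c] == "-" for r in rows)
    ):
        if any(pattern):
            indels += 1
    return len(sub_cols), indels, sub_cols


# ----------------------------------------------------------------------
# oracle: SSR scanning by per-motif regex


def oracle_ssrs(seq: str, thresholds={1: 10, 2: 6, 3: 4}):
    """Set of (start, end, unit) of maximal qualifying repeat runs."""
    found = set()
    for unit, minc in thresholds.items():
        for motif_t in itertools.product("ACGT", repeat=unit):
            motif = "".join(motif_t)
            if any(
                motif == motif[:p] * (unit // p)
                for p in range(1, unit)
                if unit % p == 0
            ):
                continue  # not a primitive motif
            for m in re.finditer(
                f"(?:{motif}){{{minc},}}", seq
            ):
                s = m.start()
                # left char-maximality: s must be the true run start
                if s >= unit and seq[s - 1] == seq[s - 1 + unit]:
                    continue
                count = (m.end() - s) // unit
                found.add((s, s + unit * count, unit))
    return found
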