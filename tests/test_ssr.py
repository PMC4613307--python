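"""Microsatellite scanning and cross-specimen comparison."""

import numpy as np
import pytest

from plastocomp.genome import revcomp
from plastocomp.ssr import (
    canonical_rotation,
    compare_ssr_sets,
    scan_ssrs,
    ssr_census,
)

from helpers import oracle_ssrs, random_dna


def _guard(run):
    """Two bases absent from the run, so the planted run stays maximal."""
    g = next(b for b in "TCGA" if b not in run)
    return g * 2


def _embed(rng, run, n=300):
    left = random_dna(rng, n // 2)
    right = random_dna(rng, n // 2)
    g = _guard(run)
    return left + g + run + g + right, len(left) + 2


def test_mononucleotide_threshold_ten():
    rng = np.random.default_rng(40)
    seq, start = _embed(rng, "A" * 10)
    loci = [l for l in scan_ssrs(seq) if l.start == start]
    assert len(loci) == 1
    assert (loci[0].motif, loci[0].unit, loci[0].count) == ("A", 1, 10)
    # nine repeats stay below threshold
    seq9, start9 = _embed(rng, "A" * 9)
    assert not [l for l in scan_ssrs(seq9) if l.start == start9]


def test_trinucleotide_threshold_four():
    rng = np.random.default_rng(41)
    seq, start = _embed(rng, "AGC" * 4)
    loci = [l for l in scan_ssrs(seq) if l.start == start]
    assert len(loci) == 1
    assert (loci[0].motif, loci[0].unit, loci[0].count) == ("AGC", 3, 4)


def test_homopolymer_reported_once_at_smallest_unit():
    rng = np.random.default_rng(42)
    seq, start = _embed(rng, "A" * 12)
    hits = [l for l in scan_ssrs(seq) if start <= l.start < start + 12]
    assert len(hits) == 1
    assert hits[0].unit == 1


def test_runs_break_at_n():
    seq = "A" * 6 + "N" + "A" * 6
    assert scan_ssrs(seq) == []
    seq2 = "A" * 10 + "N" + "A" * 10
    assert len(scan_ssrs(seq2)) == 2


def test_motif_canonicalization():
    assert canonical_rotation("GA") == "AG"
    rng = np.random.default_rng(43)
    seq, start = _embed(rng, "GA" * 6)
    (locus,) = [l for l in scan_ssrs(seq) if l.start == start]
    assert locus.motif == "AG"
    assert locus.observed_motif == "GA"
    # invariant: the locus sequence is the observed motif repeated
    assert seq[locus.start : locus.end] == "GA" * 6


@pytest.mark.parametrize("seed", range(4))
def test_scanner_matches_regex_oracle_on_random_10kb(seed):
    """The scanner agrees with a per-motif regex oracle on 10 kb random
    fixtures with planted runs of every unit length."""
    rng = np.random.default_rng(100 + seed)
    seq = random_dna(rng, 10_000)
    for run, at in (("A" * 11, 1000), ("CT" * 7, 3000), ("AAG" * 5, 5000),
                    ("T" * 10, 7000), ("GA" * 6, 9000)):
        seq = seq[:at] + "CC" + run + "GG" + seq[at:]
    got = {(l.start, l.end, l.unit) for l in scan_ssrs(seq)}
    assert got == oracle_ssrs(seq)


def test_reverse_complement_preserves_locus_count():
    rng = np.random.default_rng(44)
    seq = random_dna(rng, 5000)
    seq = seq[:1000] + "CC" + "A" * 11 + "GG" + seq[1000:]
    seq = seq[:3000] + "CC" + "AAG" * 5 + "GG" + seq[3000:]
    fwd = scan_ssrs(seq)
    rev = scan_ssrs(revcomp(seq))
    assert len(fwd) == len(rev)
    assert sorted(canonical_rotation(revcomp(l.observed_motif))
                  for l in fwd) == sorted(l.motif for l in rev)


def test_count_invariant_to_scanning_order():
    rng = np.random.default_rng(45)
    seq = random_dna(rng, 2000) + "CC" + "A" * 10 + "GG"
    assert scan_ssrs(seq) == scan_ssrs(seq)


def _trio_sequences(rng):
    """Six specimens; one mono run is at threshold only in species C."""
    base = random_dna(rng, 400) + "CC" + "T" * 11 + "GG" + random_dna(rng, 400)
    at = 200
    seqs = {}
    species_of = {"a1": "spA", "a2": "spA", "b1": "spB", "b2": "spB",
                  "c1": "spC", "c2": "spC"}
    for sp, species in species_of.items():
        run = "A" * (10 if species == "spC" else 9)
        seqs[sp] = base[:at] + "CC" + run + "GG" + base[at:]
    return seqs, species_of


def test_species_specific_ssr_by_threshold_presence():
    """A locus at count 10 in one species and 9 in the others is present
    only in that species, hence species-specific."""
    rng = np.random.default_rng(46)
    seqs, species_of = _trio_sequences(rng)
    loci = {sp: scan_ssrs(s, specimen=sp) for sp, s in seqs.items()}
    table = compare_ssr_sets(loci, species_of, seqs)
    specific = table[table["species_specific"] != ""]
    assert list(specific["species_specific"]) == ["spC"]
    assert specific.iloc[0]["motif"] == "A"
    # the shared T-run is carried by everyone
    shared = table[table["motif"] == "T"]
    assert bool(shared.iloc[0]["shared_by_all"])
    census = ssr_census(loci, species_of, table)
    by = census.set_index(["level", "label"])
    assert by.loc[("specimen", "c1"), "mono"] == 2
    assert by.loc[("specimen", "a1"), "mono"] == 1


def test_identical_complements_have_no_unique_loci(plastome_sim):
    genomes, _ = plastome_sim
    seq = genomes[0].sequence[:20_000]
    seqs = {f"s{i}": seq for i in range(4)}
    species_of = {"s0": "x", "s1": "x", "s2": "y", "s3": "y"}
    loci = {sp: scan_ssrs(s, specimen=sp) for sp, s in seqs.items()}
    table = compare_ssr_sets(loci, species_of, seqs)
    assert (table["species_specific"] == "").all()
    assert table["shared_by_all"].all()


def test_planted_ssr_recovery_from_manifest(plastome_sim):
    """Every ancestral planted SSR is recovered in all six specimens and
    each species-conditional planted SSR is species-specific."""
    from plastocomp.pipeline import irb_free_sequence
    from plastocomp.quadripartite import detect_quadripartite

    genomes, manifest = plastome_sim
    seqs, loci = {}, {}
    for g in genomes:
        st = detect_quadripartite(g)
        seqs[g.specimen_id] = irb_free_sequence(g, st)
        loci[g.specimen_id] = scan_ssrs(seqs[g.specimen_id],
                                        specimen=g.specimen_id)
    species_of = {g.specimen_id: g.species for g in genomes}
    table = compare_ssr_sets(loci, species_of, seqs)
    shared = table[table["shared_by_all"]]
    specific = dict(
        table[table["species_specific"] != ""]["species_specific"]
        .value_counts()
    )
    planted_shared = [p for p in manifest["planted_ssrs"]
                      if p["species"] is None]
    expected_specific: dict[str, int] = {}
    for p in manifest["planted_ssrs"]:
        if p["species"] is not None:
            label = manifest["species"][p["species"]]
            expected_specific[label] = expected_specific.get(label, 0) + 1
    shared_motifs = list(shared["motif"])
    for p in planted_shared:
        from plastocomp.ssr import canonical_rotation as canon

        assert canon(p["motif"]) in shared_motifs
    for label, count in expected_specific.items():
        assert specific.get(label, 0) >= count
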