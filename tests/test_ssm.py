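"""Species-specific mutation detection and barcode ranking."""

import pytest

from plastocomp.ssm import (
    detect_ssm,
    rank_barcode_regions,
    species_delimitation_table,
)
from plastocomp.variation import call_mutation_events

from helpers import make_aln

SPECIES = {
    "a1": "spA", "a2": "spA",
    "b1": "spB", "b2": "spB",
    "c1": "spC", "c2": "spC",
}
ORDER = list(SPECIES)


def _events(rows, region="r"):
    return call_mutation_events(make_aln(rows, specimens=ORDER,
                                         region=region))


def test_two_state_column_diagnostic_for_one_species():
    """A A | A A | G G is a species-specific substitution for spC."""
    records, rest = detect_ssm(_events(["A", "A", "A", "A", "G", "G"]),
                               SPECIES)
    assert len(records) == 1 and not rest
    r = records[0]
    assert r.species == "spC"
    assert r.diagnostic_allele == "G"
    assert r.consensus_allele == "A"


def test_intraspecific_variation_is_non_diagnostic():
    """A G | A A | A A violates species-level invariance."""
    records, rest = detect_ssm(_events(["A", "G", "A", "A", "A", "A"]),
                               SPECIES)
    assert records == [] and len(rest) == 1


def test_three_state_column_is_non_diagnostic():
    records, rest = detect_ssm(_events(["A", "A", "G", "G", "T", "T"]),
                               SPECIES)
    assert records == [] and len(rest) == 1


def test_n_anywhere_excludes_the_site():
    records, rest = detect_ssm(_events(["A", "A", "A", "A", "G", "N"]),
                               SPECIES)
    assert records == [] and len(rest) == 1


def test_indel_ssm_uses_gap_pattern_identity():
    rows = ["ACGTA", "ACGTA", "ACGTA", "ACGTA", "AC--A", "AC--A"]
    records, rest = detect_ssm(_events(rows), SPECIES)
    assert len(records) == 1
    assert records[0].kind == "indel"
    assert records[0].species == "spC"
    assert records[0].diagnostic_allele == "--"


def test_specimen_order_permutation_invariance():
    rows = dict(zip(ORDER, ["A", "A", "G", "G", "A", "A"]))
    perm = ["c2", "a1", "b1", "a2", "c1", "b2"]
    ev1 = call_mutation_events(make_aln([rows[s] for s in ORDER],
                                        specimens=ORDER))
    ev2 = call_mutation_events(make_aln([rows[s] for s in perm],
                                        specimens=perm))
    rec1, _ = detect_ssm(ev1, SPECIES)
    rec2, _ = detect_ssm(ev2, SPECIES)
    assert [(r.species, r.kind, r.diagnostic_allele) for r in rec1] == \
           [(r.species, r.kind, r.diagnostic_allele) for r in rec2]


def test_single_specimen_species_refused():
    species = dict(SPECIES, c2="spD")
    with pytest.raises(ValueError, match="single specimen"):
        detect_ssm(_events(["A", "A", "A", "A", "G", "G"]), species)
    with pytest.raises(ValueError, match="without species"):
        detect_ssm(_events(["A", "A", "A", "A", "G", "G"]),
                   {k: v for k, v in SPECIES.items() if k != "c2"})


def test_barcode_ranking_prefers_short_fully_discriminating_regions():
    """A 600 bp region with SSMs for all three species ranks first; a
    region diagnosing only two species ranks below any fully
    discriminating one; >1000 bp carries the impractical flag."""
    cols = {
        # region "good600": one SSM per species
        "good600": [["G", "G", "A", "A", "A", "A"],
                    ["A", "A", "G", "G", "A", "A"],
                    ["A", "A", "A", "A", "G", "G"]],
        # region "partial": spA and spC only
        "partial": [["G", "G", "A", "A", "A", "A"],
                    ["A", "A", "A", "A", "G", "G"],
                    ["A", "A", "A", "A", "T", "T"]],
        # region "big": all species but 1200 bp long
        "big": [["G", "G", "A", "A", "A", "A"],
                ["A", "A", "G", "G", "A", "A"],
                ["A", "A", "A", "A", "G", "G"]],
    }
    records = []
    for region, columns in cols.items():
        rows = ["".join(col[i] for col in columns) for i in range(6)]
        recs, _ = detect_ssm(_events(rows, region=region), SPECIES)
        records.extend(recs)
    lengths = {"good600": 600, "partial": 800, "big": 1200}
    report = rank_barcode_regions(records, lengths,
                                  ["spA", "spB", "spC"]).table
    assert list(report["region"]) == ["good600", "big", "partial"]
    assert report.loc[0, "discriminates_all"]
    assert not report.loc[2, "discriminates_all"]
    assert bool(report.loc[report["region"] == "big",
                           "impractical_length"].iloc[0])
    assert not report.loc[0, "impractical_length"]


def test_delimitation_table_round_trips_alleles():
    columns = [
        ["G", "G", "A", "A", "A", "A"],  # spA
        ["A", "A", "T", "T", "A", "A"],  # spB
        ["A", "A", "A", "A", "C", "C"],  # spC
        ["A", "A", "A", "A", "G", "G"],  # spC
    ]
    rows = ["".join(col[i] for col in columns) for i in range(6)]
    records, _ = detect_ssm(_events(rows, region="ITS2"), SPECIES)
    table = species_delimitation_table(records, "ITS2",
                                       specimen_order=ORDER)
    assert len(table) == 4
    assert list(table.columns[-6:]) == ORDER  # input order preserved
    # alleles in the table re-derive the SSM set
    for _, row in table.iterrows():
        rec = next(r for r in records if r.event.column + 1 == row["column"])
        for sp in ORDER:
            assert row[sp] == rec.event.alleles[sp]
    empty = species_delimitation_table(records, "nothing-here")
    assert empty.empty and "notice" in empty.columns


def test_planted_ssm_recovery_with_zero_background(plastome_sim):
    """Detected SSM per-region/species/kind counts equal the manifest's
    expectation exactly (precision = recall = 1)."""
    from plastocomp.quadripartite import detect_quadripartite
    from plastocomp.regions import collate_homologs
    from plastocomp.alignment import align_region
    from plastocomp.simulate import expected_ssm_counts

    genomes, manifest = plastome_sim
    # restrict to the showcase spacer to keep this unit test fast; the
    # genome-wide check runs in the acceptance suite
    structures = {g.specimen_id: detect_quadripartite(g) for g in genomes}
    rs = collate_homologs(list(genomes), structures)
    aln = align_region(rs.sequences("ndhD-ccsA"), region="ndhD-ccsA")
    events = call_mutation_events(aln)
    species_of = {g.specimen_id: g.species for g in genomes}
    records, _ = detect_ssm(events, species_of)
    _, per_region = expected_ssm_counts(manifest)
    for code, label in manifest["species"].items():
        expected = per_region.get(("ndhD-ccsA", label),
                                  {"substitution": 0, "indel": 0})
        got = {
            "substitution": sum(1 for r in records
                                if r.species == label
                                and r.kind == "substitution"),
            "indel": sum(1 for r in records
                         if r.species == label and r.kind == "indel"),
        }
        assert got == expected, label
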