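"""Synonymous/nonsynonymous classification and protein-length effects."""

import numpy as np
import pytest

from plastocomp.cds import (
    classify_events,
    classify_indel,
    classify_substitution,
    gene_effect_census,
    translate,
)
from plastocomp.variation import call_mutation_events

from helpers import make_aln

# a short reference CDS: ATG GAA AAA CCT TGA
REF = "ATGGAAAAACCTTGA"


def _cds_aln(variants, region="geneZ"):
    """Six-row CDS alignment: reference rows plus explicit variants."""
    rows = [REF] * (6 - len(variants)) + list(variants)
    return make_aln(rows, region=region)


def _events(aln):
    return call_mutation_events(aln)


def test_third_position_substitution_is_synonymous():
    """GAA -> GAG keeps Glu (E): synonymous."""
    aln = _cds_aln(["ATGGAGAAACCTTGA"])
    (ev,) = _events(aln)
    eff = classify_substitution(ev, aln)
    assert eff.effect == "synonymous"
    assert eff.ref_aa == eff.alt_aa == "E"
    assert eff.codon_index == 1


def test_second_position_substitution_is_nonsynonymous():
    """GAA -> GTA changes Glu to Val."""
    aln = _cds_aln(["ATGGTAAAACCTTGA"])
    (ev,) = _events(aln)
    eff = classify_substitution(ev, aln)
    assert eff.effect == "nonsynonymous"
    assert (eff.ref_aa, eff.alt_aa) == ("E", "V")


def test_two_snps_in_one_codon_evaluated_jointly():
    """AAA -> AGG in one specimen: one codon change (Lys->Arg), two SNP
    events, each classified nonsynonymous against the joint codon."""
    aln = _cds_aln(["ATGGAAAGGCCTTGA"])
    events = _events(aln)
    assert len(events) == 2
    effects = [classify_substitution(ev, aln) for ev in events]
    assert all(e.effect == "nonsynonymous" for e in effects)
    assert all((e.ref_aa, e.alt_aa) == ("K", "R") for e in effects)
    assert all(e.codon_index == 2 for e in effects)
    # single-base AAA->AGA alone would also be K->R; the joint evaluation
    # matters for AAA->AGG where naive per-SNP gives K->R and K->K
    assert translate("AAG") == "K"  # the naive second call would be wrong


def test_stop_gain_reported_as_nonsynonymous_subtype():
    aln = _cds_aln(["ATGTAAAAACCTTGA"])
    (ev,) = _events(aln)
    eff = classify_substitution(ev, aln)
    assert eff.effect == "nonsynonymous"
    assert eff.subtype == "stop_gain"


def test_pseudogene_events_not_applicable():
    aln = _cds_aln(["ATGGAGAAACCTTGA"])
    (ev,) = _events(aln)
    assert classify_substitution(ev, aln, pseudo=True).effect == \
        "not_applicable"


@pytest.mark.parametrize(
    "length,effect,delta",
    [(39, "inframe_insertion", 13), (21, "inframe_insertion", 7),
     (6, "inframe_insertion", 2)],
)
def test_inframe_insertion_elongates_protein(length, effect, delta):
    """An in-frame insertion of 3k bp elongates the protein by k amino
    acids (39 bp -> +13 aa, 21 bp -> +7 aa, 6 bp -> +2 aa)."""
    rng = np.random.default_rng(30)
    from plastocomp.simulate import _CODONS

    insert = "".join(rng.choice(np.array(_CODONS), size=length // 3))
    carrier = REF[:6] + insert + REF[6:]
    rows = [REF[:6] + "-" * length + REF[6:]] * 4 + [carrier] * 2
    aln = make_aln(rows, region="geneZ")
    events = _events(aln)
    indels = [e for e in events if e.kind == "indel"]
    assert len(indels) == 1
    eff = classify_indel(indels[0])
    assert eff.effect == effect
    assert eff.protein_length_delta == delta
    # translate-and-diff confirms the delta
    prot_ref = translate(REF)
    prot_alt = translate(carrier)
    assert len(prot_alt) - len(prot_ref) == delta


def test_inframe_deletion_and_frameshift():
    rows = [REF] * 4 + [REF[:6] + REF[9:]] * 2  # 3 bp deletion in spC
    aln = align_rows(rows)
    (ev,) = [e for e in _events(aln) if e.kind == "indel"]
    eff = classify_indel(ev)
    assert eff.effect == "inframe_deletion"
    assert eff.protein_length_delta == -1
    # 5 bp deletion: frameshift, no delta
    rows = [REF] * 4 + [REF[:6] + REF[11:]] * 2
    aln = align_rows(rows)
    (ev,) = [e for e in _events(aln) if e.kind == "indel"]
    eff = classify_indel(ev)
    assert eff.effect == "frameshift"
    assert eff.protein_length_delta is None


def align_rows(rows):
    """Align explicit variant sequences with the built-in aligner."""
    from plastocomp.alignment import align_region

    return align_region({f"s{i}": r for i, r in enumerate(rows)},
                        region="geneZ")


def test_splice_region_indel_flagged():
    rows = ["ATGGAA---CCTTGA"] * 4 + ["ATGGAAGGGCCTTGA"] * 2
    aln = make_aln(rows, region="geneZ")
    (ev,) = [e for e in _events(aln) if e.kind == "indel"]
    # pretend the spliced exon junction falls after 6 reference bases,
    # exactly at the insertion point
    eff = classify_indel(ev, exon_junctions=[6], aln=aln)
    assert eff.effect == "splice_region"
    # a junction outside the footprint leaves the call in-frame
    eff2 = classify_indel(ev, exon_junctions=[3], aln=aln)
    assert eff2.effect == "inframe_insertion"


def test_census_totals_and_permutation_invariance():
    aln = _cds_aln(["ATGGAGAAACCTTGA", "ATGGTAAAACCTTGA"])
    events = _events(aln)
    effects = classify_events(aln, events)
    census = gene_effect_census(effects)
    total = census[census["gene"] == "TOTAL"].iloc[0]
    per_gene = census[census["gene"] != "TOTAL"]
    for col in ("synonymous", "nonsynonymous"):
        assert total[col] == per_gene[col].sum()
    # order permutation leaves the census unchanged
    census2 = gene_effect_census(list(reversed(effects)))
    assert census.equals(census2)
    assert gene_effect_census([]).iloc[-1]["nonsynonymous"] == 0


def test_classification_agrees_with_translate_and_diff_oracle(plastome_sim):
    """On substitution-only CDS alignments, the set of codons with a
    nonsynonymous call equals the set of positions at which any
    specimen's translated protein differs from the consensus protein
    (brute-force translate-and-diff oracle, plastid code)."""
    from collections import Counter

    from plastocomp.alignment import align_region
    from plastocomp.quadripartite import detect_quadripartite
    from plastocomp.regions import collate_homologs

    genomes, _ = plastome_sim
    structures = {g.specimen_id: detect_quadripartite(g) for g in genomes}
    rs = collate_homologs(list(genomes), structures)
    checked = 0
    for name in rs:
        if rs.kind(name) != "CDS" or name.endswith(".pseudo"):
            continue
        aln = align_region(rs.sequences(name), region=name)
        degapped = {sp: aln.degapped(sp) for sp in aln.specimens}
        lengths = {len(s) for s in degapped.values()}
        if len(lengths) != 1:
            continue  # indel-bearing genes are covered by delta tests
        events = call_mutation_events(aln)
        if not events:
            continue
        effects = classify_events(aln, events, gene=name)
        # independent consensus: per-position majority over raw sequences
        n = lengths.pop()
        consensus = "".join(
            Counter(s[i] for s in degapped.values()).most_common(1)[0][0]
            for i in range(n)
        )
        cons_prot = translate(consensus)
        diff_codons = set()
        for s in degapped.values():
            prot = translate(s)
            diff_codons |= {
                i for i, (a, b) in enumerate(zip(cons_prot, prot)) if a != b
            }
        nonsyn = {e.codon_index for e in effects
                  if e.effect == "nonsynonymous"}
        syn = {e.codon_index for e in effects if e.effect == "synonymous"}
        assert nonsyn == diff_codons, name
        assert not (syn & diff_codons), name
        checked += 1
    assert checked >= 5
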