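"""Alignment, mutation-event calling and variation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastocomp.alignment import (
    align_region,
    read_alignment_fasta,
    write_alignment_fasta,
)
from plastocomp.variation import (
    call_mutation_events,
    odonnell_proportion,
    pairwise_p_distances,
    percent_variable,
    sliding_identity,
    summarize_region,
)

from helpers import make_aln, oracle_events, random_dna


# ----------------------------------------------------------------------
# alignment


def test_identical_sequences_align_without_gaps():
    aln = align_region({"a": "ACGTACGT", "b": "ACGTACGT", "c": "ACGTACGT"})
    assert aln.rows == ("ACGTACGT",) * 3
    assert percent_variable(aln) == 0.0


def test_single_deletion_yields_one_indel_event():
    """ACGTACGT vs ACGACGT aligns with one 1 bp indel under the built-in
    scores (match +1, mismatch -1, gap open -4, extend -1)."""
    aln = align_region({"a": "ACGTACGT", "b": "ACGACGT"})
    events = call_mutation_events(aln)
    indels = [e for e in events if e.kind == "indel"]
    assert len(indels) == 1
    assert indels[0].indel_length == 1
    assert not [e for e in events if e.kind == "substitution"]


def test_degap_reproduces_inputs(plastome_sim):
    genomes, _ = plastome_sim
    seqs = {g.specimen_id: g.sequence[1000:1400] for g in genomes}
    aln = align_region(seqs)
    for sp, s in seqs.items():
        assert aln.degapped(sp) == s


def test_aligned_fasta_round_trip(tmp_path):
    aln = make_aln(["AC-GT", "ACAGT", "AC-GT"], region="r1")
    path = write_alignment_fasta(aln, tmp_path / "r1.fasta")
    back = read_alignment_fasta(path, region="r1")
    assert back == aln


def test_external_aligner_contract_violation():
    def bad_aligner(seqs):
        return {k: v + "-" * i for i, (k, v) in enumerate(seqs.items())}

    with pytest.raises(ValueError, match="unequal length|contract"):
        align_region({"a": "ACGT", "b": "ACGTT"}, aligner=bad_aligner)


# ----------------------------------------------------------------------
# event calling


def test_indel_run_is_one_event_regardless_of_width():
    """One specimen carrying a 3-column gap run among six rows scores a
    single indel event of length 3."""
    rows = ["ACGTACGT"] * 5 + ["ACG---GT"]
    events = call_mutation_events(make_aln(rows))
    indels = [e for e in events if e.kind == "indel"]
    assert len(indels) == 1
    assert indels[0].indel_length == 3
    assert indels[0].columns == (3, 6)
    # 2 vs 4 specimens: parsimony-informative
    rows2 = ["ACGTACGT"] * 4 + ["ACG---GT"] * 2
    ev2 = [e for e in call_mutation_events(make_aln(rows2))
           if e.kind == "indel"]
    assert ev2[0].parsimony_informative
    assert not indels[0].parsimony_informative


def test_substitution_informativeness():
    # {A x5, G x1}: one substitution, not parsimony-informative
    rows = ["AAAA"] * 5 + ["AGAA"]
    events = call_mutation_events(make_aln(rows))
    assert len(events) == 1
    assert events[0].kind == "substitution"
    assert not events[0].parsimony_informative
    # {A x3, G x3}: parsimony-informative
    rows = ["AAAA"] * 3 + ["AGAA"] * 3
    (event,) = call_mutation_events(make_aln(rows))
    assert event.parsimony_informative
    # N is missing data: {A x2, G x2, N x2} still informative; {A x4, G,
    # N} is a substitution but not informative
    (event,) = call_mutation_events(make_aln(["A"] * 2 + ["G"] * 2
                                             + ["N"] * 2))
    assert event.parsimony_informative
    (event,) = call_mutation_events(make_aln(["A"] * 4 + ["G", "N"]))
    assert not event.parsimony_informative


def test_substitutions_inside_indel_runs_are_scored_independently():
    """A polymorphic column inside a gap run counts as its own
    substitution event among the non-gap rows."""
    rows = ["ACGTA", "ACGTA", "A---A", "A-C-A"]
    # the gap pattern changes at every one of columns 1, 2, 3, so the
    # maximal-constant-pattern rule yields three indel events; column 2
    # has bases {G, G, C} among non-gap rows -> one substitution on top
    events = call_mutation_events(make_aln(rows))
    kinds = sorted(e.kind for e in events)
    assert kinds == ["indel", "indel", "indel", "substitution"]
    sub = next(e for e in events if e.kind == "substitution")
    assert sub.columns == (2, 3)


@settings(max_examples=300, deadline=None)
@given(st.data())
def test_event_caller_matches_exhaustive_oracle(data):
    """On alignments of <= 8 columns x <= 4 rows the caller's event and
    column counts equal a direct column-enumeration oracle."""
    n_rows = data.draw(st.integers(2, 4))
    n_cols = data.draw(st.integers(1, 8))
    cols = []
    for _ in range(n_cols):
        col = data.draw(
            st.lists(
                st.sampled_from("ACGTN-"),
                min_size=n_rows, max_size=n_rows,
            ).filter(lambda c: any(ch != "-" for ch in c))
        )
        cols.append(col)
    rows = ["".join(r) for r in zip(*cols)]
    aln = make_aln(rows)
    events = call_mutation_events(aln)
    n_sub = sum(1 for e in events if e.kind == "substitution")
    n_ind = sum(1 for e in events if e.kind == "indel")
    o_sub, o_ind, o_cols = oracle_events(rows)
    assert (n_sub, n_ind) == (o_sub, o_ind)
    assert sorted(e.column for e in events
                  if e.kind == "substitution") == o_cols


def test_event_allele_states_reconstruct_rows():
    """Per-event alleles agree with the row content they were called
    from (de-gap round trip at the event level)."""
    rows = ["ACGTACGT", "ACG--CGT", "ATGTACGT", "ACGTACGA"]
    aln = make_aln(rows)
    for ev in call_mutation_events(aln):
        s, e = ev.columns
        for sp, allele in ev.alleles.items():
            assert aln.row(sp)[s:e] == allele


# ----------------------------------------------------------------------
# metrics


def test_percent_variable_counts_substitution_and_indel_columns():
    """2 substitution columns + one 3-column indel in 100 columns = 5%."""
    base = list("A" * 100)
    rows = ["".join(base) for _ in range(5)]
    variant = base.copy()
    variant[10] = "G"
    variant[50] = "T"
    variant[70:73] = "---"
    rows.append("".join(variant))
    aln = make_aln(rows)
    assert percent_variable(aln) == pytest.approx(5.0)
    summary = summarize_region(aln)
    assert summary.n_substitutions == 2
    assert summary.n_indels == 1
    assert summary.pic == 3


def test_percent_variable_monotone_under_added_substitution():
    rows = ["A" * 40, "A" * 40]
    before = percent_variable(make_aln(rows))
    rows2 = [rows[0], "G" + rows[1][1:]]
    after = percent_variable(make_aln(rows2))
    assert after >= before
    with pytest.raises(ValueError):
        percent_variable(make_aln([]))  # type: ignore[arg-type]


def test_odonnell_proportion_arithmetic():
    assert odonnell_proportion(0, 0, 100) == 0.0
    # the showcase spacer tally: 18 substitutions + 9 indels over 611 bp
    assert odonnell_proportion(18, 9, 611) == pytest.approx(27 / 611)
    # halving property
    assert odonnell_proportion(18, 9, 1222) == pytest.approx(27 / 1222)
    with pytest.raises(ValueError):
        odonnell_proportion(-1, 0, 100)
    with pytest.raises(ValueError):
        odonnell_proportion(1, 0, 100, variant="bogus")


def test_sliding_identity_profile():
    rows = ["A" * 1000, "A" * 1000]
    aln = make_aln(rows)
    prof = sliding_identity(aln, window=100, step=25)
    assert len(prof) == 37  # floor((1000-100)/25)+1
    assert (prof["s1"] == 100.0).all()
    # a divergent segment dips below its flanks
    div = list("A" * 1000)
    for i in range(500, 520):
        div[i] = "C"
    aln2 = make_aln(["A" * 1000, "".join(div)])
    prof2 = sliding_identity(aln2, window=100, step=25)
    inside = prof2.loc[prof2["window_start"].between(450, 500), "s1"]
    flank = prof2.loc[prof2["window_start"] < 300, "s1"]
    assert inside.min() < flank.min()
    with pytest.raises(ValueError, match="window"):
        sliding_identity(make_aln(["ACGT", "ACGT"]), window=10, step=2)


def test_p_distthan_gaps_excluded():
    aln = make_aln(["ACGT-C", "ACGTAC", "TCGTAC"])
    d = pairwise_p_distances([aln])
    assert d[("s0", "s1")] == pytest.approx(0.0)
    assert d[("s0", "s2")] == pytest.approx(1 / 5)
    assert d[("s1", "s2")] == pytest.approx(1 / 6)
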