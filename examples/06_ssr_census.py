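"""Scan for microsatellites and compare complements across species.

Thresholds follow common practice for plastomes: mononucleotide runs of
>= 10 repeats, dinucleotide >= 6, trinucleotide >= 4.  Loci are matched
across specimens by their exact 20 bp flanking context (indels shift
coordinates), and a locus present in all specimens of exactly one
species is species-specific.
"""

from plastocomp import (
    detect_quadripartite,
    scan_ssrs,
    compare_ssr_sets,
    simulate_plastome_dataset,
)
from plastocomp.pipeline import irb_free_sequence
from plastocomp.ssr import ssr_census

genomes, _ = simulate_plastome_dataset(seed=1)
species_of = {g.specimen_id: g.species for g in genomes}

seqs, loci = {}, {}
for g in genomes:
    seq = irb_free_sequence(g, detect_quadripartite(g))
    seqs[g.specimen_id] = seq
    loci[g.specimen_id] = scan_ssrs(seq, specimen=g.specimen_id)
    print(f"{g.specimen_id:18s} {len(loci[g.specimen_id])} SSR loci")

comparison = compare_ssr_sets(loci, species_of, seqs)
specific = comparison[comparison["species_specific"] != ""]
print(f"\n{len(specific)} species-specific loci:")
print(specific.to_string(index=False))

print("\nper-species deduplicated census:")
census = ssr_census(loci, species_of, comparison)
print(census[census["level"] == "species"].to_string(index=False))
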