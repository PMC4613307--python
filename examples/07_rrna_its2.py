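"""The nuclear rRNA cluster: ITS2 as a species-delimitation marker.

The 18S-ITS1-5.8S-ITS2-26S cluster (5795 bp) is generated as a linear
sequence; ITS1 and ITS2 are the spacers between the rRNA genes.  Only
ITS2 carries diagnostic characters for all three species.
"""

from plastocomp import (
    align_region,
    call_mutation_events,
    collate_homologs,
    detect_ssm,
    species_delimitation_table,
)
from plastocomp.simulate import ITS1, ITS2, simulate_rrna_dataset

genomes, _ = simulate_rrna_dataset(seed=1)
regions = collate_homologs(genomes, {})
species_of = {g.specimen_id: g.species for g in genomes}

print(f"cluster length: {genomes[0].length} bp; regions:")
for name in regions:
    rep = next(iter(regions[name].values()))
    pretty = {ITS1: "ITS1", ITS2: "ITS2"}.get(name, name)
    aln = align_region(regions.sequences(name), region=name)
    events = call_mutation_events(aln)
    records, _ = detect_ssm(events, species_of)
    discriminated = {r.species for r in records}
    print(f"  {pretty:6s} {rep.length:5d} bp  {len(events):2d} SNPs  "
          f"SSMs for {sorted(discriminated) if discriminated else 'none'}")

aln = align_region(regions.sequences(ITS2), region=ITS2)
records, _ = detect_ssm(call_mutation_events(aln), species_of)
print("\nITS2 diagnostic table:")
print(species_delimitation_table(records, ITS2).to_string(index=False))
# Only ITS2 diagnoses all three species, mirroring the typical pattern
# in closely related plant groups where ITS2 outperforms ITS1, 5.8S and
# the large rRNA genes.
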