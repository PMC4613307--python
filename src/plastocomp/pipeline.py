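"""End-to-end orchestration: structure -> regions -> alignment ->
variation -> SSM -> CDS effects -> SSR, with a combined report bundle.

The pipeline is fully deterministic: rerunning with the same inputs and
configuration writes bit-identical tables.  Seven tables plus a JSON
manifest are produced: structure, variation, ssm, barcode, effects,
census and ssr.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .alignment import RegionAlignment, align_region
from .cds import classify_events, effects_table, gene_effect_census
from .genome import AnnotatedGenome, check_unique_labels
from .io import read_genome, write_tables
from .quadripartite import (
    QuadripartiteStructure,
    detect_quadripartite,
    structure_table,
)
from .regions import RegionSet, collate_homologs
from .ssm import SSMRecord, detect_ssm, rank_barcode_regions, ssm_table
from .ssr import compare_ssr_sets, scan_ssrs, ssr_table
from .variation import (
    MutationEvent,
    call_mutation_events,
    summarize_region,
    variation_table,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    inputs: list[str] = field(default_factory=list)
    input_format: str = "genbank"
    species_map: dict[str, str] = field(default_factory=dict)
    out_dir: str = "plastocomp_out"
    min_ir: int = 1000
    max_mismatch: int = 0
    ssr_thresholds: dict[int, int] = field(
        default_factory=lambda: {1: 10, 2: 6, 3: 4}
    )
    identity_window: int = 100
    identity_step: int = 25
    odonnell_variant: str = "aligned_length"
    max_practical_length: int = 1000
    seed: int | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "ssr_thresholds" in raw:
            raw["ssr_thresholds"] = {
                int(k): int(v) for k, v in raw["ssr_thresholds"].items()
            }
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ssr_thresholds"] = {str(k): v for k, v in
                               d["ssr_thresholds"].items()}
        return d


@dataclass
class PipelineResult:
    tables: dict[str, pd.DataFrame]
    paths: dict[str, Path]
    alignments: dict[str, RegionAlignment]
    events: dict[str, list[MutationEvent]]
    ssm_records: list[SSMRecord]
    structures: dict[str, QuadripartiteStructure | None]
    region_set: RegionSet
    notices: list[str]
    ssr_comparison: pd.DataFrame | None = None


def _load_genomes(config: RunConfig) -> list[AnnotatedGenome]:
    genomes = []
    for path in config.inputs:
        g = read_genome(path, format=config.input_format)
        if g.specimen_id in config.species_map:
            g.species = config.species_map[g.specimen_id]
        genomes.append(g)
    return genomes


def irb_free_sequence(
    genome: AnnotatedGenome, structure: QuadripartiteStructure | None
) -> str:
    """Genome sequence with the second inverted repeat removed."""
    if structure is None or structure.no_ir:
        return genome.sequence
    s, e = structure.irb
    if e >= s:
        return genome.sequence[:s] + genome.sequence[e:]
    logger.warning(
        "%s: IRb wraps the origin; scanning the full sequence",
        genome.specimen_id,
    )
    return genome.sequence


def run_pipeline(
    config: RunConfig | None = None,
    genomes: Sequence[AnnotatedGenome] | None = None,
) -> PipelineResult:
    """Run the full comparative analysis and write the report bundle.

    Genomes may be passed in memory (tests, simulations) or read from
    ``config.inputs``.  Species with fewer than two specimens cause the
    SSM/barcode stage to be skipped with a notice; every other stage
    still runs.
    """
    config = config or RunConfig()
    notices: list[str] = []
    if genomes is None:
        genomes = _load_genomes(config)
    if len(genomes) < 2:
        raise ValueError("pipeline requires >= 2 genomes")
    check_unique_labels(genomes)
    species_of = {g.specimen_id: g.species for g in genomes}
    for specimen, species in species_of.items():
        if not species:
            raise ValueError(f"specimen {specimen!r} has no species label")

    logger.info("stage 1/6: quadripartite structure")
    structures: dict[str, QuadripartiteStructure | None] = {}
    for g in genomes:
        if g.circular:
            structures[g.specimen_id] = detect_quadripartite(
                g, min_ir=config.min_ir, max_mismatch=config.max_mismatch
            )
        else:
            structures[g.specimen_id] = None
    circ = {sp: st for sp, st in structures.items() if st is not None}
    st_table = structure_table(circ) if circ else pd.DataFrame(
        columns=["specimen", "genome_length", "ir_length", "no_ir"]
    )

    logger.info("stage 2/6: region extraction and collation")
    region_set = collate_homologs(list(genomes), structures)
    logger.info("  %d homologous regions (%d excluded)",
                len(region_set), len(region_set.excluded))

    logger.info("stage 3/6: alignment and variation scoring")
    alignments: dict[str, RegionAlignment] = {}
    events: dict[str, list[MutationEvent]] = {}
    summaries = []
    for name in region_set:
        aln = align_region(region_set.sequences(name), region=name)
        alignments[name] = aln
        events[name] = call_mutation_events(aln)
        summaries.append(
            summarize_region(
                aln,
                kind=region_set.kind(name),
                events=events[name],
                odonnell_variant=config.odonnell_variant,
            )
        )
    var_table = variation_table(summaries)

    logger.info("stage 4/6: species-specific mutations")
    counts: dict[str, int] = {}
    for sp in species_of.values():
        counts[sp] = counts.get(sp, 0) + 1
    ssm_records: list[SSMRecord] = []
    if len(counts) >= 2 and all(c >= 2 for c in counts.values()):
        all_events = [ev for evs in events.values() for ev in evs]
        ssm_records, _ = detect_ssm(all_events, species_of)
        lengths = {
            name: next(iter(region_set[name].values())).length
            for name in region_set
        }
        barcode = rank_barcode_regions(
            ssm_records, lengths, sorted(counts),
            max_practical_length=config.max_practical_length,
        ).table
    else:
        notices.append(
            "SSM stage skipped: needs >= 2 species with >= 2 specimens each"
        )
        logger.warning(notices[-1])
        barcode = pd.DataFrame(
            columns=["region", "length", "total_ssm", "discriminates_all",
                     "impractical_length"]
        )
    ssm_tab = ssm_table(ssm_records)

    logger.info("stage 5/6: CDS effect classification")
    effects = []
    for name in region_set:
        if region_set.kind(name) != "CDS":
            continue
        rep = next(iter(region_set[name].values()))
        pseudo = name.endswith(".pseudo")
        exon_lens = [e - s for s, e in rep.parts]
        if rep.strand == "-":
            exon_lens = list(reversed(exon_lens))
        junctions = []
        acc = 0
        for ln in exon_lens[:-1]:
            acc += ln
            junctions.append(acc)
        effects.extend(
            classify_events(
                alignments[name], events[name], gene=name, pseudo=pseudo,
                exon_junctions=junctions,
            )
        )
    eff_table = effects_table(effects)
    census = gene_effect_census(effects)

    logger.info("stage 6/6: SSR scan")
    loci = {}
    seqs = {}
    for g in genomes:
        seq = irb_free_sequence(g, structures[g.specimen_id])
        seqs[g.specimen_id] = seq
        loci[g.specimen_id] = scan_ssrs(
            seq, thresholds=config.ssr_thresholds, specimen=g.specimen_id
        )
    ssr_tab = ssr_table([l for ls in loci.values() for l in ls])
    ssr_comparison = compare_ssr_sets(loci, species_of, seqs)

    tables = {
        "structure": st_table,
        "variation": var_table,
        "ssm": ssm_tab,
        "barcode": barcode,
        "effects": eff_table,
        "census": census,
        "ssr": ssr_tab,
    }
    paths = write_tables(
        tables, config.out_dir, parameters=config.to_dict(), seed=config.seed
    )
    logger.info("wrote %d tables to %s", len(tables), config.out_dir)
    result = PipelineResult(
        tables=tables,
        paths=paths,
        alignments=alignments,
        events=events,
        ssm_records=ssm_records,
        structures=structures,
        region_set=region_set,
        notices=notices,
        ssr_comparison=ssr_comparison,
    )
    return result
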