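"""Reading and writing annotated genomes and derived result tables.

GenBank records are handled through Biopython.  GFF3 in/out covers the
9-column subset this pipeline produces and consumes (gene/CDS/tRNA/rRNA
features with ``Parent``-free flat attributes); coordinates are converted
between GFF3/GenBank 1-based inclusive and the internal 0-based half-open
convention at this boundary only.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from . import __version__
from .genome import AnnotatedGenome, Feature

_GB_KINDS = {"gene", "CDS", "tRNA", "rRNA"}


def read_genome(
    path: str | Path,
    format: str = "genbank",
    gff_path: str | Path | None = None,
    species: str | None = None,
    specimen_id: str | None = None,
) -> AnnotatedGenome:
    """Read one annotated genome from GenBank or a FASTA + GFF3 pair.

    Parameters
    ----------
    path:
        GenBank flat file, or the FASTA file of a FASTA+GFF3 pair.
    format:
        ``"genbank"`` or ``"fasta+gff3"``.
    gff_path:
        GFF3 path for the ``fasta+gff3`` format; defaults to ``path`` with
        a ``.gff3`` suffix.
    species, specimen_id:
        Sample labels; default to the record's organism annotation and id.
    """
    path = Path(path)
    if format == "genbank":
        return _read_genbank(path, species, specimen_id)
    if format == "fasta+gff3":
        gff = Path(gff_path) if gff_path is not None else path.with_suffix(".gff3")
        return _read_fasta_gff3(path, gff, species, specimen_id)
    raise ValueError(f"unknown format {format!r}; use 'genbank' or 'fasta+gff3'")


def _read_genbank(path: Path, species: str | None, specimen_id: str | None):
    try:
        record = SeqIO.read(path, "genbank")
    except ValueError as exc:
        raise ValueError(f"malformed GenBank record in {path}: {exc}") from exc
    circular = record.annotations.get("topology", "linear") == "circular"
    feats: list[Feature] = []
    for sf in record.features:
        if sf.type not in _GB_KINDS:
            continue
        feats.append(_feature_from_seqfeature(sf))
    return AnnotatedGenome(
        species=species or record.annotations.get("organism", "unknown"),
        specimen_id=specimen_id or record.id,
        sequence=str(record.seq).upper(),
        circular=circular,
        features=feats,
    )


def _feature_from_seqfeature(sf: SeqFeature) -> Feature:
    name = (
        sf.qualifiers.get("gene", [None])[0]
        or sf.qualifiers.get("locus_tag", [None])[0]
        or sf.type
    )
    parts = tuple(
        sorted((int(loc.start), int(loc.end)) for loc in sf.location.parts)
    )
    strand = "-" if sf.location.strand == -1 else "+"
    pseudo = "pseudo" in sf.qualifiers or "pseudogene" in sf.qualifiers
    return Feature(name=name, kind=sf.type, parts=parts, strand=strand, pseudo=pseudo)


def _read_fasta_gff3(fasta: Path, gff: Path, species, specimen_id):
    record = SeqIO.read(fasta, "fasta")
    circular = False
    feats: list[Feature] = []
    # exon lines are grouped under their parent feature by the ID/Parent
    # attributes; plain features become single-part Features directly
    pending: dict[str, dict] = {}
    with open(gff) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                if line.startswith("##sequence-region") or "circular=true" in line:
                    circular = circular or "circular=true" in line
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{gff}:{lineno}: expected 9 columns, got {len(cols)}")
            _, _, ftype, start, end, _, strand, _, attrs = cols
            attrd = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            interval = (int(start) - 1, int(end))
            if ftype == "region" and attrd.get("Is_circular") == "true":
                circular = True
                continue
            if ftype == "exon":
                parent = attrd.get("Parent", "")
                if parent in pending:
                    pending[parent]["parts"].append(interval)
                continue
            if ftype not in _GB_KINDS:
                continue
            fid = attrd.get("ID", f"{ftype}:{lineno}")
            pending[fid] = {
                "name": attrd.get("Name", attrd.get("gene", fid)),
                "kind": ftype,
                "parts": [],
                "interval": interval,
                "strand": strand if strand in "+-" else "+",
                "pseudo": attrd.get("pseudo", "false") == "true",
            }
    for info in pending.values():
        parts = tuple(sorted(info["parts"])) or (info["interval"],)
        feats.append(
            Feature(
                name=info["name"],
                kind=info["kind"],
                parts=parts,
                strand=info["strand"],
                pseudo=info["pseudo"],
            )
        )
    feats.sort(key=lambda f: f.start)
    return AnnotatedGenome(
        species=species or "unknown",
        specimen_id=specimen_id or record.id,
        sequence=str(record.seq).upper(),
        circular=circular,
        features=feats,
    )


def write_genome(genome: AnnotatedGenome, out_prefix: str | Path) -> dict[str, Path]:
    """Write a genome as GenBank plus FASTA+GFF3; returns the paths."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.specimen_id,
        name=genome.specimen_id[:16],
        description=f"{genome.species} {genome.specimen_id}",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
            "organism": genome.species,
        },
    )
    for f in genome.features:
        locs = [
            FeatureLocation(s, e, strand=1 if f.strand == "+" else -1)
            for s, e in f.parts
        ]
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        quals = {"gene": [f.name]}
        if f.pseudo:
            quals["pseudo"] = [""]
        record.features.append(SeqFeature(location, type=f.kind, qualifiers=quals))
    gb = out_prefix.with_suffix(".gb")
    SeqIO.write(record, gb, "genbank")
    fasta = out_prefix.with_suffix(".fasta")
    SeqIO.write(SeqRecord(Seq(genome.sequence), id=genome.specimen_id,
                          description=genome.species), fasta, "fasta")
    gff = out_prefix.with_suffix(".gff3")
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.specimen_id} 1 {genome.length}\n")
        if genome.circular:
            fh.write(
                f"{genome.specimen_id}\tplastocomp\tregion\t1\t{genome.length}"
                f"\t.\t+\t.\tID=region0;Is_circular=true\n"
            )
        for i, f in enumerate(genome.features):
            fid = f"f{i}"
            attrs = f"ID={fid};Name={f.name}"
            if f.pseudo:
                attrs += ";pseudo=true"
            fh.write(
                f"{genome.specimen_id}\tplastocomp\t{f.kind}\t{f.start + 1}"
                f"\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )
            if len(f.parts) > 1:
                for s, e in f.parts:
                    fh.write(
                        f"{genome.specimen_id}\tplastocomp\texon\t{s + 1}\t{e}"
                        f"\t.\t{f.strand}\t.\tParent={fid}\n"
                    )
    return {"genbank": gb, "fasta": fasta, "gff3": gff}


def write_tables(
    results: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    parameters: Mapping | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write each result table as TSV plus a JSON run manifest.

    The manifest records table names, row counts, run parameters, package
    version and the RNG seed, which together make a run reproducible.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        manifest_tables = []
        for name, df in results.items():
            p = out_dir / f"{name}.tsv"
            df.to_csv(p, sep="\t", index=False)
            paths[name] = p
            manifest_tables.append({"name": name, "rows": int(len(df)),
                                    "path": p.name})
        manifest = {
            "tables": manifest_tables,
            "parameters": dict(parameters or {}),
            "version": __version__,
            "seed": seed,
        }
        mpath = out_dir / "manifest.json"
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        paths["manifest"] = mpath
    except OSError as exc:
        raise OSError(f"cannot write tables to {out_dir}: {exc}") from exc
    return paths


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_tables`."""
    return pd.read_csv(path, sep="\t")

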