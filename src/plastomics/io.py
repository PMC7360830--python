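"""GenBank / FASTA readers and writers plus TSV/JSON report helpers.

Biopython handles the flat-file formats; this module converts between
Biopython's location objects and the internal circular-interval model.
GenBank files use 1-based inclusive coordinates externally, but Biopython
already exposes them as 0-based half-open, matching the internal convention.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .model import GeneFeature, Interval, Plastome, make_interval, normalize_seq

log = logging.getLogger(__name__)

_KIND_BY_FTYPE = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


class FormatError(ValueError):
    """Raised when an input file cannot be parsed."""


class ContentError(ValueError):
    """Raised when a parsed file is missing required content."""


def _feature_name(feat: SeqFeature) -> str | None:
    for key in ("gene", "locus_tag", "product"):
        if key in feat.qualifiers:
            return feat.qualifiers[key][0]
    return None


def _location_to_exons(loc, genome_length: int) -> tuple[list[Interval], str]:
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    strand = "-" if (loc.strand or 1) < 0 else "+"
    exons = [make_interval(int(p.start), int(p.end), genome_length) for p in parts]
    if strand == "-":
        # Biopython lists complement(join(...)) parts in transcription order
        # already; keep genomic order ascending for the internal model and
        # restore transcription order via the strand at extraction time.
        exons = sorted(exons, key=lambda e: e.start)
    return exons, strand


def read_genbank(path: str) -> Plastome:
    """Read one GenBank record into a :class:`Plastome`.

    gene/CDS/tRNA/rRNA features become :class:`GeneFeature` entries; when a
    gene has a typed child feature (CDS/tRNA/rRNA) the typed location wins
    and the bare ``gene`` feature is dropped.  IR-duplicated genes stay as
    distinct same-name features.
    """
    try:
        record = next(SeqIO.parse(path, "genbank"))
    except StopIteration:
        raise ContentError(f"{path}: no GenBank record found")
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    seq = str(record.seq)
    if not seq or set(seq) == {"N"} and len(seq) < 10:
        raise ContentError(f"{path}: record has no sequence")
    n = len(seq)

    typed: list[GeneFeature] = []
    typed_keys: set[tuple[str, int]] = set()
    bare_genes: list[tuple[str, SeqFeature]] = []
    for feat in record.features:
        name = _feature_name(feat)
        if name is None:
            continue
        if feat.type in _KIND_BY_FTYPE:
            exons, strand = _location_to_exons(feat.location, n)
            typed.append(GeneFeature(name, _KIND_BY_FTYPE[feat.type], exons, strand))
            typed_keys.add((name, min(e.start for e in exons)))
        elif feat.type == "gene":
            bare_genes.append((name, feat))

    features = list(typed)
    for name, feat in bare_genes:
        exons, strand = _location_to_exons(feat.location, n)
        start = min(e.start for e in exons)
        # drop the bare gene if a typed feature with the same name overlaps it
        covered = any(
            t.name == name and abs(t.start - start) <= 50 for t in typed
        )
        if not covered:
            features.append(GeneFeature(name, "other", exons, strand))

    circular = record.annotations.get("topology", "circular") == "circular"
    return Plastome(
        id=record.id or record.name,
        seq=seq,
        circular=circular,
        features=features,
        description=record.description or "",
    )


def _exons_to_location(feat: GeneFeature, genome_length: int):
    strand = -1 if feat.strand == "-" else 1
    parts = []
    for e in feat.exons:
        if e.wrap:
            parts.append(SimpleLocation(e.start, genome_length, strand))
            parts.append(SimpleLocation(0, e.end, strand))
        else:
            parts.append(SimpleLocation(e.start, e.end, strand))
    if strand < 0:
        parts = parts[::-1]
    return parts[0] if len(parts) == 1 else CompoundLocation(parts)


def write_genbank(plastome: Plastome, path: str) -> None:
    record = SeqRecord(
        Seq(plastome.seq),
        id=plastome.id,
        name=plastome.id.split(".")[0][:16],
        description=plastome.description or f"{plastome.id} plastome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if plastome.circular else "linear",
        },
    )
    n = len(plastome.seq)
    for f in plastome.features:
        loc = _exons_to_location(f, n)
        ftype = f.kind if f.kind in ("CDS", "tRNA", "rRNA") else "gene"
        record.features.append(
            SeqFeature(loc, type=ftype, qualifiers={"gene": [f.name]})
        )
    SeqIO.write([record], path, "genbank")


def read_fasta(path: str) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence); uppercased, U->T."""
    records = [(r.id, normalize_seq(str(r.seq))) for r in SeqIO.parse(path, "fasta")]
    if not records:
        raise ContentError(f"{path}: empty FASTA file")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_tsv(rows: Sequence[dict], path: str, columns: Sequence[str] | None = None) -> None:
    """Write a list of dict rows as TSV (header from the first row)."""
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")


def write_run_sidecar(path: str, params: dict) -> None:
    """JSON sidecar recording run parameters for provenance."""
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
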