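"""GenBank / FASTA / newick I/O for the pipeline's data model.

GenBank flat files use 1-based inclusive coordinates; the data model is
0-based half-open. The conversion happens here and nowhere else. Exon
intervals are stored in transcription order, so minus-strand compound
locations are reversed relative to their order in the flat file.
"""

from __future__ import annotations

import os
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from ._model import GeneFeature, PlastomeRecord
from .tree import Tree

_KINDS = ("CDS", "tRNA", "rRNA")


def read_genbank(path) -> list[PlastomeRecord]:
    """Read every LOCUS of a GenBank flat file into PlastomeRecords.

    Only CDS / tRNA / rRNA features carrying a ``/gene`` qualifier are
    retained; ``/pseudo`` and ``/pseudogene`` qualifiers set the pseudo
    flag. Raises ValueError on malformed records or out-of-range features.
    """
    records = []
    try:
        seq_records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:
        raise ValueError(f"GenBank parse error in {path}: {exc}") from exc
    if not seq_records:
        raise ValueError(f"{path}: no LOCUS records found")
    for sr in seq_records:
        records.append(_from_seqrecord(sr))
    ids = [r.id for r in records]
    if len(ids) != len(set(ids)):
        raise ValueError(f"{path}: duplicate record ids")
    return records


def _from_seqrecord(sr: SeqRecord) -> PlastomeRecord:
    circular = sr.annotations.get("topology", "linear") == "circular"
    taxon = sr.annotations.get("organism") or sr.description or sr.id
    features = []
    for ft in sr.features:
        if ft.type not in _KINDS:
            continue
        gene = ft.qualifiers.get("gene", [None])[0]
        if gene is None:
            continue
        parts = list(ft.location.parts)
        strand = "-" if ft.location.strand == -1 else "+"
        if strand == "-":
            parts = parts[::-1]  # file order -> transcription order
        loc = tuple((int(p.start), int(p.end)) for p in parts)
        pseudo = "pseudo" in ft.qualifiers or "pseudogene" in ft.qualifiers
        features.append(GeneFeature(gene=gene, kind=ft.type, strand=strand, location=loc, pseudo=pseudo))
    try:
        return PlastomeRecord(
            id=sr.id, taxon=taxon, sequence=str(sr.seq), features=features, circular=circular
        )
    except ValueError as exc:
        raise ValueError(f"LOCUS {sr.id}: {exc}") from exc


def write_genbank(records: PlastomeRecord | Iterable[PlastomeRecord], path) -> None:
    """Write one or more records as a GenBank flat file (coordinates 1-based)."""
    if isinstance(records, PlastomeRecord):
        records = [records]
    out = []
    for rec in records:
        sr = SeqRecord(Seq(rec.sequence), id=rec.id, name=rec.id[:16], description=rec.taxon)
        sr.annotations["molecule_type"] = "DNA"
        sr.annotations["topology"] = "circular" if rec.circular else "linear"
        sr.annotations["organism"] = rec.taxon
        for f in rec.features:
            strand = -1 if f.strand == "-" else 1
            parts = list(f.location)
            if f.strand == "-":
                parts = parts[::-1]  # transcription order -> file order
            simple = [SimpleLocation(a, b, strand=strand) for a, b in parts]
            loc = simple[0] if len(simple) == 1 else CompoundLocation(simple)
            quals = {"gene": [f.gene]}
            if f.pseudo:
                quals["pseudo"] = [None]
            sr.features.append(SeqFeature(loc, type=f.kind, qualifiers=quals))
        out.append(sr)
    with open(path, "w") as fh:
        SeqIO.write(out, fh, "genbank")


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> {id: upper-case sequence}."""
    seqs = {}
    for sr in SeqIO.parse(str(path), "fasta"):
        if sr.id in seqs:
            raise ValueError(f"{path}: duplicate FASTA id {sr.id}")
        seqs[sr.id] = str(sr.seq).upper()
    if not seqs:
        raise ValueError(f"{path}: no FASTA records")
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_newick(source) -> Tree:
    """Parse a newick string (or read a file path) into a rooted Tree."""
    text = source
    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        with open(source) as fh:
            text = fh.read()
    return Tree.from_newick(text)


def write_newick(tree: Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
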