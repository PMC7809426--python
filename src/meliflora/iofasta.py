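"""Reference-library FASTA round-tripping (headers ``taxon_id|marker``)."""

from __future__ import annotations

from Bio import SeqIO

from .simulate.refdb import ReferenceDB
from .taxonomy import Taxonomy


def read_reference_db(fasta_path, taxonomy_path) -> ReferenceDB:
    taxonomy = Taxonomy.from_tsv(taxonomy_path)
    sequences: dict[tuple[str, str], str] = {}
    markers: list[str] = []
    for rec in SeqIO.parse(fasta_path, "fasta"):
        taxon_id, _, marker = rec.id.partition("|")
        if not marker:
            raise ValueError(f"reference header {rec.id!r} lacks a |marker suffix")
        if taxon_id not in taxonomy:
            raise ValueError(f"reference taxon {taxon_id!r} not in taxonomy")
        if marker not in markers:
            markers.append(marker)
        sequences[(taxon_id, marker)] = str(rec.seq).upper()
    return ReferenceDB(taxonomy=taxonomy, sequences=sequences, markers=tuple(markers))
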