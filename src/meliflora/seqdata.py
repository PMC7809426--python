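"""In-memory containers for amplicon read data and FASTQ round-tripping.

Reads are held as fixed-width numpy byte arrays (sequence) and integer
arrays (Phred quality), which keeps trimming/merging vectorisable across a
whole library.  FASTQ serialisation uses Biopython (4-line records,
Phred+33).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMP = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMP[a] = b


def seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp_array(arr: np.ndarray) -> np.ndarray:
    """Reverse complement along the last axis."""
    return _COMP[arr][..., ::-1]


def revcomp(seq: str) -> str:
    return array_to_seq(revcomp_array(seq_to_array(seq)))


@dataclass
class ReadPairBatch:
    """A set of equal-length paired-end reads for one sample and marker.

    ``fwd``/``rev`` are (n, read_length) uint8 ASCII arrays;
    ``fwd_qual``/``rev_qual`` are matching integer Phred arrays.
    ``source_taxon`` carries the simulation ground truth (None entries for
    reads of unknown origin, e.g. parsed from external FASTQ).
    """

    ids: list[str]
    fwd: np.ndarray
    fwd_qual: np.ndarray
    rev: np.ndarray
    rev_qual: np.ndarray
    source_taxon: list[str | None] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.ids)
        for arr in (self.fwd, self.fwd_qual, self.rev, self.rev_qual):
            if arr.shape[0] != n:
                raise ValueError("ragged read batch")
        if self.fwd.shape != self.fwd_qual.shape or self.rev.shape != self.rev_qual.shape:
            raise ValueError("sequence/quality shape mismatch")
        if not self.source_taxon:
            self.source_taxon = [None] * n

    def __len__(self) -> int:
        return len(self.ids)

    def pair(self, i: int) -> tuple[str, str, np.ndarray, str, np.ndarray]:
        return (
            self.ids[i],
            array_to_seq(self.fwd[i]),
            self.fwd_qual[i],
            array_to_seq(self.rev[i]),
            self.rev_qual[i],
        )


def _records(ids, seqs, quals, taxa):
    for i, rid in enumerate(ids):
        rec = SeqRecord(Seq(array_to_seq(seqs[i])), id=rid, description="")
        if taxa[i] is not None:
            rec.description = f"taxon={taxa[i]}"
        rec.letter_annotations["phred_quality"] = [int(q) for q in quals[i]]
        yield rec


def write_fastq_pair(batch: ReadPairBatch, fwd_path, rev_path) -> None:
    SeqIO.write(
        _records(batch.ids, batch.fwd, batch.fwd_qual, batch.source_taxon),
        fwd_path,
        "fastq",
    )
    SeqIO.write(
        _records(batch.ids, batch.rev, batch.rev_qual, batch.source_taxon),
        rev_path,
        "fastq",
    )


def read_fastq_pair(fwd_path, rev_path) -> ReadPairBatch:
    """Load a paired FASTQ file set; reads must share length within a file."""
    ids, taxa = [], []
    fwd, fq, rev, rq = [], [], [], []
    for rec_f, rec_r in zip(
        SeqIO.parse(fwd_path, "fastq"), SeqIO.parse(rev_path, "fastq"), strict=True
    ):
        if rec_f.id != rec_r.id:
            raise ValueError(f"unpaired reads: {rec_f.id} vs {rec_r.id}")
        ids.append(rec_f.id)
        taxon = None
        for token in rec_f.description.split():
            if token.startswith("taxon="):
                taxon = token.removeprefix("taxon=")
        taxa.append(taxon)
        fwd.append(seq_to_array(str(rec_f.seq)))
        fq.append(np.asarray(rec_f.letter_annotations["phred_quality"], dtype=np.uint8))
        rev.append(seq_to_array(str(rec_r.seq)))
        rq.append(np.asarray(rec_r.letter_annotations["phred_quality"], dtype=np.uint8))
    if not ids:
        empty = np.empty((0, 0), dtype=np.uint8)
        return ReadPairBatch(ids=[], fwd=empty, fwd_qual=empty, rev=empty, rev_qual=empty)
    return ReadPairBatch(
        ids=ids,
        fwd=np.vstack(fwd),
        fwd_qual=np.vstack(fq),
        rev=np.vstack(rev),
        rev_qual=np.vstack(rq),
        source_taxon=taxa,
    )
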