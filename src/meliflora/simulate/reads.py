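"""Paired-end amplicon read simulator for the two-marker library design.

Per marker, reads per taxon are multinomial around the sample composition
reweighted by per-taxon amplification bias (PCR efficiency differs between
taxa and markers, which is why metabarcoding is only semi-quantitative).
Forward and reverse reads are taken from the two ends of the reference
amplicon and overlap in the middle, so merging can reconstruct the
amplicon.  Errors are i.i.d. substitutions; error positions are written
with a lower Phred score than correct positions.
"""

from __future__ import annotations

import numpy as np

from ..seqdata import ReadPairBatch, revcomp_array, seq_to_array
from .communities import TrueComposition
from .refdb import ReferenceDB

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

QUAL_GOOD = 35  #: Phred score written at correct positions
QUAL_ERROR = 15  #: Phred score written at substituted positions


def _apply_errors(seqs, quals, rate, rng):
    """In-place i.i.d. substitutions (never to the same base) + quality drop."""
    if rate == 0 or seqs.size == 0:
        return
    mask = rng.random(seqs.shape) < rate
    idx = np.nonzero(mask)
    if idx[0].size:
        shift = rng.integers(1, 4, size=idx[0].size)
        base_idx = np.searchsorted(_BASES, seqs[idx])
        seqs[idx] = _BASES[(base_idx + shift) % 4]
        quals[idx] = QUAL_ERROR


def simulate_reads(
    comp: TrueComposition,
    db: ReferenceDB,
    n_pairs: int,
    read_length: int = 300,
    substitution_rate: float = 0.005,
    marker_bias: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
) -> dict[str, ReadPairBatch]:
    """Simulate one sample's paired reads for every marker in ``db``.

    Parameters
    ----------
    marker_bias
        ``{marker: {taxon_id: amplification factor}}``; missing entries
        default to 1.  Per marker the effective taxon weights are
        proportions x bias, renormalised.
    Returns
    -------
    dict marker -> ReadPairBatch (with ground-truth source taxa).
    """
    if not (0 <= substitution_rate < 0.25):
        raise ValueError("substitution_rate must be in [0, 0.25)")
    min_ref = min(len(s) for s in db.sequences.values())
    if read_length >= min_ref:
        raise ValueError("read_length must be shorter than the reference amplicons")
    rng = np.random.default_rng(seed)
    taxa = [t for t, p in comp.proportions.items() if p > 0]
    probs = np.array([comp.proportions[t] for t in taxa])

    out: dict[str, ReadPairBatch] = {}
    for marker in db.markers:
        bias = (marker_bias or {}).get(marker, {})
        w = probs * np.array([bias.get(t, 1.0) for t in taxa])
        if w.sum() <= 0:
            raise ValueError(f"all taxa have zero weight for marker {marker}")
        w = w / w.sum()
        counts = rng.multinomial(n_pairs, w) if n_pairs > 0 else np.zeros(len(taxa), int)

        ids: list[str] = []
        source: list[str | None] = []
        fwd_parts, rev_parts = [], []
        for t, k in zip(taxa, counts):
            if k == 0:
                continue
            amplicon = seq_to_array(db.sequence(t, marker))
            fwd_parts.append(np.tile(amplicon[:read_length], (k, 1)))
            rev_parts.append(np.tile(revcomp_array(amplicon[-read_length:]), (k, 1)))
            source.extend([t] * k)
        n = int(counts.sum())
        if n:
            fwd = np.vstack(fwd_parts)
            rev = np.vstack(rev_parts)
        else:
            fwd = np.empty((0, read_length), dtype=np.uint8)
            rev = np.empty((0, read_length), dtype=np.uint8)
        fwd_qual = np.full(fwd.shape, QUAL_GOOD, dtype=np.uint8)
        rev_qual = np.full(rev.shape, QUAL_GOOD, dtype=np.uint8)
        _apply_errors(fwd, fwd_qual, substitution_rate, rng)
        _apply_errors(rev, rev_qual, substitution_rate, rng)
        ids = [f"{comp.sample_id}:{marker}:{i:06d}" for i in range(n)]
        out[marker] = ReadPairBatch(
            ids=ids, fwd=fwd, fwd_qual=fwd_qual, rev=rev, rev_qual=rev_qual,
            source_taxon=source,
        )
    return out
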