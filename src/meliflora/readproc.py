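"""Paired-read processing: quality trimming, overlap merging, dereplication
and cross-sample 100%-identity clustering with singleton removal.

These are deliberately simple, fully specified equivalents of the usual
trim/merge/cluster tool chain:

* trimming slides a quality window in from the 3' end and keeps the longest
  prefix free of any window whose mean Phred quality falls below threshold;
* merging picks the maximal-length forward-suffix / reverse-complement-prefix
  overlap whose mismatch fraction is within a cap, taking the higher-quality
  base at overlap mismatches; merged sequences shorter than a floor
  (default 450 bp) are discarded;
* clustering keys on exact string identity across all samples, and unique
  sequences seen exactly once across the whole run (singletons) are removed
  after clustering.

Every discard carries a reason code collected in a :class:`DiscardLog`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqdata import ReadPairBatch, array_to_seq, revcomp_array, seq_to_array

DEFAULT_MIN_MERGED_LEN = 450

# discard reason codes
TOO_SHORT_AFTER_TRIM = "too_short_after_trim"
NO_OVERLAP = "no_overlap"
MERGED_TOO_SHORT = "merged_too_short"


@dataclass
class DiscardLog:
    """Counts of discarded read pairs by reason code."""

    counts: Counter = field(default_factory=Counter)

    def add(self, reason: str, n: int = 1) -> None:
        self.counts[reason] += n

    @property
    def total(self) -> int:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# trimming
# ---------------------------------------------------------------------------

def trim_cut_position(quals: np.ndarray, window: int, min_mean_q: float) -> int:
    """Length to keep after 3'-window trimming of one quality vector.

    The retained read is the longest prefix that contains no complete
    window of ``window`` bases with mean quality below ``min_mean_q``
    (sliding in from the 3' end, the cut lands just before the first
    failing window).  A remainder shorter than the window is treated as a
    single window: it is kept only if its own mean passes.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    L = len(quals)
    if L == 0:
        return 0
    if L < window:
        return L if float(np.mean(quals)) >= min_mean_q else 0
    means = np.convolve(quals, np.ones(window), mode="valid") / window
    bad = np.nonzero(means < min_mean_q)[0]
    if not bad.size:
        return L
    cut = int(bad[0]) + window - 1
    if cut == 0:
        return 0
    if cut < window and float(np.mean(quals[:cut])) < min_mean_q:
        return 0
    return cut


def trim_read(
    seq: str,
    quals,
    window: int = 4,
    min_mean_q: float = 20.0,
    min_len: int = 100,
) -> tuple[str, np.ndarray] | None:
    """Trim one read; returns (sequence, qualities) or None if discarded."""
    q = np.asarray(quals)
    cut = trim_cut_position(q, window, min_mean_q)
    if cut < min_len:
        return None
    return seq[:cut], q[:cut]


def trim_batch(
    quals: np.ndarray, window: int = 4, min_mean_q: float = 20.0
) -> np.ndarray:
    """Vectorised :func:`trim_cut_position` over an (n, L) quality array."""
    n, L = quals.shape
    if L < window:
        keep = quals.mean(axis=1) >= min_mean_q
        return np.where(keep, L, 0)
    csum = np.cumsum(np.pad(quals, ((0, 0), (1, 0))), axis=1, dtype=np.int64)
    means = (csum[:, window:] - csum[:, :-window]) / window  # (n, L-window+1)
    bad = means < min_mean_q
    has_bad = bad.any(axis=1)
    cut = np.where(has_bad, np.argmax(bad, axis=1) + window - 1, L)
    # remainder shorter than one window: keep only if its own mean passes
    short = has_bad & (cut < window) & (cut > 0)
    if short.any():
        idx = np.nonzero(short)[0]
        prefix_mean = csum[idx, cut[idx]] / cut[idx]
        cut[idx[prefix_mean < min_mean_q]] = 0
    return cut


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

@dataclass
class MergeResult:
    sequence: str | None
    quality: np.ndarray | None
    reason: str | None  # discard reason when sequence is None
    overlap: int | None = None


def _consensus(f, fq, rc, rcq, L):
    """Merged sequence/quality given overlap length L (higher quality wins)."""
    lf = len(f)
    ov_f, ov_fq = f[lf - L:], fq[lf - L:]
    ov_r, ov_rq = rc[:L], rcq[:L]
    take_rev = (ov_f != ov_r) & (ov_rq > ov_fq)
    ov = np.where(take_rev, ov_r, ov_f)
    ovq = np.maximum(ov_fq, ov_rq)
    seq = np.concatenate([f[: lf - L], ov, rc[L:]])
    qual = np.concatenate([fq[: lf - L], ovq, rcq[L:]])
    return seq, qual


def merge_pair(
    fwd: str,
    fwd_qual,
    rev: str,
    rev_qual,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
    min_merged_len: int = DEFAULT_MIN_MERGED_LEN,
) -> MergeResult:
    """Merge one read pair by its best 3'(fwd)/5'(revcomp) overlap.

    The best overlap is the maximal admissible length: candidate lengths are
    scanned from ``min(len(fwd), len(rev))`` downward and the first whose
    mismatch fraction is <= ``max_mismatch_frac`` wins.  At overlap
    mismatches the higher-quality base is taken (ties keep the forward
    base).  Merged reads shorter than ``min_merged_len`` are discarded.
    """
    if min_overlap < 10:
        raise ValueError("min_overlap must be >= 10")
    f = seq_to_array(fwd)
    r = seq_to_array(rev)
    fq = np.asarray(fwd_qual)
    rc = revcomp_array(r)
    rcq = np.asarray(rev_qual)[::-1]
    max_L = min(len(f), len(rc))
    for L in range(max_L, min_overlap - 1, -1):
        mism = int(np.count_nonzero(f[len(f) - L:] != rc[:L]))
        if mism / L <= max_mismatch_frac:
            seq, qual = _consensus(f, fq, rc, rcq, L)
            if len(seq) < min_merged_len:
                return MergeResult(None, None, MERGED_TOO_SHORT, overlap=L)
            return MergeResult(array_to_seq(seq), qual, None, overlap=L)
    return MergeResult(None, None, NO_OVERLAP)


def _merge_block(F, RC, min_overlap, max_mismatch_frac):
    """Best overlap length per pair for equal-width blocks; -1 = none."""
    n, lf = F.shape
    lr = RC.shape[1]
    best = np.full(n, -1, dtype=np.int64)
    active = np.ones(n, dtype=bool)
    for L in range(min(lf, lr), min_overlap - 1, -1):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        mism = np.count_nonzero(F[idx, lf - L:] != RC[idx, :L], axis=1)
        ok = mism <= max_mismatch_frac * L
        best[idx[ok]] = L
        active[idx[ok]] = False
    return best


def merge_batch(
    batch: ReadPairBatch,
    trim_window: int = 4,
    trim_min_mean_q: float = 20.0,
    trim_min_len: int = 100,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
    min_merged_len: int = DEFAULT_MIN_MERGED_LEN,
    log: DiscardLog | None = None,
) -> list[str]:
    """Trim then merge a whole batch; returns merged sequences.

    Semantics are identical to :func:`trim_read` + :func:`merge_pair`
    applied per pair (property-tested); computation is vectorised across
    pairs sharing post-trim lengths.
    """
    log = log if log is not None else DiscardLog()
    n = len(batch)
    if n == 0:
        return []
    cut_f = trim_batch(batch.fwd_qual, trim_window, trim_min_mean_q)
    cut_r = trim_batch(batch.rev_qual, trim_window, trim_min_mean_q)
    keep = (cut_f >= trim_min_len) & (cut_r >= trim_min_len)
    log.add(TOO_SHORT_AFTER_TRIM, int(n - keep.sum()))

    merged: list[str] = []
    df = pd.DataFrame({"i": np.arange(n)[keep], "lf": cut_f[keep], "lr": cut_r[keep]})
    for (lf, lr), grp in df.groupby(["lf", "lr"]):
        idx = grp["i"].to_numpy()
        F = batch.fwd[idx, :lf]
        FQ = batch.fwd_qual[idx, :lf]
        R = batch.rev[idx, :lr]
        RC = revcomp_array(R)
        RCQ = batch.rev_qual[idx, :lr][:, ::-1]
        best = _merge_block(F, RC, min_overlap, max_mismatch_frac)
        log.add(NO_OVERLAP, int((best == -1).sum()))
        for L in np.unique(best[best > 0]):
            L = int(L)
            rows = np.nonzero(best == L)[0]
            if lf + lr - L < min_merged_len:
                log.add(MERGED_TOO_SHORT, len(rows))
                continue
            ov_f, ov_fq = F[rows, lf - L:], FQ[rows, lf - L:]
            ov_r, ov_rq = RC[rows, :L], RCQ[rows, :L]
            ov = np.where((ov_f != ov_r) & (ov_rq > ov_fq), ov_r, ov_f)
            seqs = np.concatenate([F[rows, : lf - L], ov, RC[rows, L:]], axis=1)
            merged.extend(array_to_seq(s) for s in seqs)
    return merged


# ---------------------------------------------------------------------------
# dereplication and clustering
# ---------------------------------------------------------------------------

def dereplicate(sequences: list[str]) -> dict[str, int]:
    """Within-sample exact dereplication: sequence -> multiplicity."""
    return dict(Counter(sequences))


def cluster_and_filter(per_sample: dict[str, dict[str, int]]) -> pd.DataFrame:
    """Cross-sample 100%-identity clustering with singleton removal.

    Parameters
    ----------
    per_sample
        Map sample_id -> (sequence -> count), i.e. the per-sample
        dereplicated tables.

    Returns
    -------
    DataFrame indexed by sequence with one integer count column per
    sample; rows whose total count across all samples is 1 (singletons)
    are removed.
    """
    if not per_sample:
        return pd.DataFrame()
    table = pd.DataFrame(per_sample).fillna(0).astype(np.int64)
    table.index.name = "sequence"
    table = table[table.sum(axis=1) > 1]
    return table


def unique_table_to_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def unique_table_to_fasta(table: pd.DataFrame, path) -> None:
    """Representative FASTA: one record per unique sequence (id = uniqNNN)."""
    with open(path, "w") as fh:
        for i, seq in enumerate(table.index):
            fh.write(f">uniq{i:06d};size={int(table.loc[seq].sum())}\n{seq}\n")


def process_samples(
    batches: dict[str, ReadPairBatch],
    log: DiscardLog | None = None,
    **params,
) -> pd.DataFrame:
    """Full read-processing stage for one marker across samples.

    ``batches`` maps sample_id -> paired reads.  Returns the cross-sample
    singleton-free unique-sequence table (see :func:`cluster_and_filter`).
    """
    per_sample = {
        sid: dereplicate(merge_batch(b, log=log, **params))
        for sid, b in batches.items()
    }
    return cluster_and_filter(per_sample)
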