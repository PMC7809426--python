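"""Similarity search and top-hit consensus taxonomic assignment.

The assignment rule mirrors standard practice for plant barcode markers:
for each query sequence, take the set of reference taxa tied at the
query's maximum bit score; if they are a single species the query is
identified to species, multiple species in one genus give a genus-level
identification, multiple genera in one family a family-level one, and
ties spanning families are excluded.  Queries whose best bit score falls
below the 1st percentile of best scores in the run are excluded up front.

Hits come either from the built-in aligner (edit-distance alignment via
edlib, rescored with declared match/mismatch/gap values and converted to
bit scores with Karlin–Altschul-style constants) or from an imported
12-column BLAST tabular file, which is the fidelity path.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .taxonomy import Taxonomy

logger = logging.getLogger(__name__)

HIT_COLUMNS = ["query_id", "subject_id", "pident", "length", "bit_score"]

#: 12-column BLAST tabular (outfmt 6) layout
BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

# assignment status codes
ASSIGNED = "assigned"
EXCLUDED_LOW_SCORE = "excluded_low_score"
EXCLUDED_CROSS_CLADE = "excluded_cross_clade"
NO_HIT = "no_hit"


@dataclass(frozen=True)
class ScoringScheme:
    """Raw alignment scoring and bit-score conversion constants."""

    match: int = 2
    mismatch: int = -3
    gap: int = -5  # per gap column (linear)
    lam: float = 0.625
    k: float = 0.41

    def bits(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.k)) / math.log(2.0)


DEFAULT_SCORING = ScoringScheme()

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


def _score_alignment(query: str, subject: str, scoring: ScoringScheme):
    """Globally align and rescore; returns (raw, pident, columns) or None."""
    res = edlib.align(query, subject, mode="NW", task="path")
    counts = {"=": 0, "X": 0, "I": 0, "D": 0}
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        counts[op] += int(n)
    ncols = sum(counts.values())
    raw = (
        scoring.match * counts["="]
        + scoring.mismatch * counts["X"]
        + scoring.gap * (counts["I"] + counts["D"])
    )
    pident = 100.0 * counts["="] / ncols if ncols else 0.0
    return raw, pident, ncols


def align_queries(
    queries: dict[str, str],
    references: dict[str, str],
    scoring: ScoringScheme = DEFAULT_SCORING,
    raw_score_floor: float = 0.0,
    max_ambiguous_frac: float = 0.1,
) -> pd.DataFrame:
    """Score every query against every reference; return a hit table.

    Hits with raw score <= ``raw_score_floor`` are omitted.  Queries with
    more than ``max_ambiguous_frac`` non-ACGT symbols are skipped (logged).
    Returns a DataFrame with columns ``query_id, subject_id, pident,
    length, bit_score``.
    """
    if not references:
        raise ValueError("empty reference set")
    rows = []
    acgt = set("ACGT")
    for qid, qseq in queries.items():
        bad = sum(1 for c in qseq if c not in acgt)
        if qseq and bad / len(qseq) > max_ambiguous_frac:
            logger.warning("skipping query %s: %.0f%% ambiguous symbols",
                           qid, 100 * bad / len(qseq))
            continue
        for sid, sseq in references.items():
            raw, pident, ncols = _score_alignment(qseq, sseq, scoring)
            if raw <= raw_score_floor:
                continue
            rows.append((qid, sid, pident, ncols, scoring.bits(raw)))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


# ---------------------------------------------------------------------------
# BLAST tabular interchange
# ---------------------------------------------------------------------------

def _subject_taxon(subject_id: str) -> str:
    """Reference ids may carry a ``|marker`` suffix; strip it."""
    return subject_id.split("|")[0]


def read_hit_table(path, taxonomy: Taxonomy | None = None) -> pd.DataFrame:
    """Read 12-column BLAST tabular hits into the internal hit table.

    With a taxonomy, rows whose subject does not resolve are dropped
    (count logged).
    """
    try:
        raw = pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, header=None)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=HIT_COLUMNS)
    hits = pd.DataFrame(
        {
            "query_id": raw["qseqid"].astype(str),
            "subject_id": raw["sseqid"].astype(str),
            "pident": raw["pident"].astype(float),
            "length": raw["length"].astype(int),
            "bit_score": raw["bitscore"].astype(float),
        }
    )
    if taxonomy is not None:
        ok = hits["subject_id"].map(lambda s: _subject_taxon(s) in taxonomy)
        if (~ok).any():
            logger.warning("dropped %d hits with unresolvable subjects", int((~ok).sum()))
        hits = hits[ok].reset_index(drop=True)
    return hits


def write_hit_table(hits: pd.DataFrame, path) -> None:
    """Write the internal hit table as 12-column BLAST tabular.

    Columns not tracked internally (mismatch counts, coordinates, evalue)
    are filled with neutral values; a round-trip preserves the tracked
    columns exactly.
    """
    out = pd.DataFrame(
        {
            "qseqid": hits["query_id"],
            "sseqid": hits["subject_id"],
            "pident": hits["pident"],
            "length": hits["length"],
            "mismatch": 0,
            "gapopen": 0,
            "qstart": 1,
            "qend": hits["length"],
            "sstart": 1,
            "send": hits["length"],
            "evalue": 0.0,
            "bitscore": hits["bit_score"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# filtering and consensus
# ---------------------------------------------------------------------------

def filter_low_scores(
    hits: pd.DataFrame, percentile: float = 0.01
) -> tuple[pd.DataFrame, set[str]]:
    """Exclude queries whose best bit score is below the run percentile.

    The percentile is computed over per-query best bit scores across the
    whole table (global scope per marker per run).  Returns the retained
    hit table and the set of excluded query ids.
    """
    if not (0 <= percentile < 1):
        raise ValueError("percentile must be in [0, 1)")
    if hits.empty:
        return hits, set()
    best = hits.groupby("query_id")["bit_score"].max()
    threshold = float(np.quantile(best.to_numpy(), percentile))
    excluded = set(best.index[best < threshold])
    return hits[~hits["query_id"].isin(excluded)].reset_index(drop=True), excluded


@dataclass(frozen=True)
class Assignment:
    query_id: str
    name: str | None
    rank: str | None  # species | genus | family, present iff assigned
    status: str

    def __post_init__(self):
        if (self.status == ASSIGNED) != (self.rank is not None):
            raise ValueError("rank must be present iff status == assigned")


def consensus_assign(
    query_hits: pd.DataFrame,
    taxonomy: Taxonomy,
    top_bits_tolerance: float = 0.0,
) -> Assignment:
    """Collapse one query's tied top hits to their lowest shared rank.

    The tied-top set contains subjects whose bit score is within
    ``top_bits_tolerance`` of the query maximum (default: exact ties).
    Single species -> species; one genus -> genus; one family -> family;
    multiple families -> excluded (cross-clade rule; any multi-family tie
    is excluded, and the clade is retained only for reporting).
    """
    if query_hits.empty:
        return Assignment("", None, None, NO_HIT)
    qid = str(query_hits["query_id"].iloc[0])
    top = query_hits["bit_score"].max()
    tied = query_hits[query_hits["bit_score"] >= top - top_bits_tolerance]
    taxa = {_subject_taxon(s) for s in tied["subject_id"]}
    lineages = [taxonomy.lineage(t) for t in taxa]
    for rank in ("species", "genus", "family"):
        names = {lin[rank] for lin in lineages}
        if len(names) == 1:
            return Assignment(qid, names.pop(), rank, ASSIGNED)
    return Assignment(qid, None, None, EXCLUDED_CROSS_CLADE)


def assign_queries(
    hits: pd.DataFrame,
    taxonomy: Taxonomy,
    all_query_ids: list[str] | None = None,
    percentile: float = 0.01,
    top_bits_tolerance: float = 0.0,
) -> pd.DataFrame:
    """Full assignment stage: percentile filter then per-query consensus.

    ``all_query_ids`` lets callers record ``no_hit`` rows for queries that
    produced no hits at all.  Returns a DataFrame indexed by query_id with
    columns name, rank, status.
    """
    retained, low = filter_low_scores(hits, percentile)
    records: dict[str, Assignment] = {}
    for qid in low:
        records[qid] = Assignment(qid, None, None, EXCLUDED_LOW_SCORE)
    if not retained.empty:
        for qid, grp in retained.groupby("query_id", sort=False):
            records[str(qid)] = consensus_assign(grp, taxonomy, top_bits_tolerance)
    for qid in all_query_ids or []:
        records.setdefault(qid, Assignment(qid, None, None, NO_HIT))
    out = pd.DataFrame(
        {
            "query_id": list(records),
            "name": [a.name for a in records.values()],
            "rank": [a.rank for a in records.values()],
            "status": [a.status for a in records.values()],
        }
    ).set_index("query_id")
    return out.sort_index()


# ---------------------------------------------------------------------------
# count tabulation and marker combination
# ---------------------------------------------------------------------------

def tabulate_counts(
    assignments: pd.DataFrame, query_counts: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Aggregate per-query per-sample counts into a samples x taxa layer.

    ``query_counts`` is indexed by query_id with one column per sample.
    Returns (count layer, per-status read totals); assigned + excluded +
    no_hit totals equal the input total (conservation).
    """
    joined = query_counts.join(assignments, how="left")
    joined["status"] = joined["status"].fillna(NO_HIT)
    sample_cols = list(query_counts.columns)
    status_totals = joined.groupby("status")[sample_cols].sum().sum(axis=1)
    assigned = joined[joined["status"] == ASSIGNED]
    if assigned.empty:
        layer = pd.DataFrame(
            np.zeros((len(sample_cols), 0), dtype=np.int64), index=sample_cols
        )
    else:
        layer = assigned.groupby("name")[sample_cols].sum().T.astype(np.int64)
    layer.index.name = "sample_id"
    layer.columns.name = "taxon"
    return layer, status_totals


def combine_markers(*layers: pd.DataFrame) -> pd.DataFrame:
    """Cellwise sum of per-marker count layers (union of taxa, missing=0)."""
    if not layers:
        raise ValueError("no layers given")
    axis = set(layers[0].index)
    for layer in layers[1:]:
        if set(layer.index) != axis:
            raise ValueError("count layers must share the sample axis")
    combined = layers[0]
    for layer in layers[1:]:
        combined = combined.add(layer, fill_value=0)
    return combined.fillna(0).astype(np.int64)
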