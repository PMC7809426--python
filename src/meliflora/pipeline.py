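"""End-to-end orchestration: reads -> unique sequences -> assignments ->
dual-marker count matrix -> abundance profile.

Mirrors the full metabarcoding workflow on in-memory read batches; each
stage is the corresponding module function, so the pipeline here is just
plumbing plus bookkeeping of discards and ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import assign as _assign
from . import readproc
from .profiles import SurveyProfile, classify, profile_from_counts
from .seqdata import ReadPairBatch
from .simulate.communities import TrueComposition
from .simulate.refdb import ReferenceDB
from .simulate.reads import simulate_reads
from .taxonomy import Taxonomy


@dataclass
class PipelineResult:
    marker_layers: dict[str, pd.DataFrame]
    combined: pd.DataFrame
    profile: SurveyProfile
    assignments: dict[str, pd.DataFrame]
    discard_logs: dict[str, readproc.DiscardLog]
    status_totals: dict[str, pd.Series] = field(default_factory=dict)


def process_and_assign(
    batches_by_marker: dict[str, dict[str, ReadPairBatch]],
    db: ReferenceDB,
    year: int = 2017,
    percentile: float = 0.01,
    top_bits_tolerance: float = 0.0,
    min_merged_len: int = readproc.DEFAULT_MIN_MERGED_LEN,
    **readproc_params,
) -> PipelineResult:
    """Run read processing, assignment and profiling for every marker.

    ``batches_by_marker`` maps marker -> {sample_id -> ReadPairBatch}.
    Sample ids must agree across markers (samples absent for one marker
    get zero counts).
    """
    all_samples = sorted(
        {s for batches in batches_by_marker.values() for s in batches}
    )
    layers: dict[str, pd.DataFrame] = {}
    assignments: dict[str, pd.DataFrame] = {}
    logs: dict[str, readproc.DiscardLog] = {}
    status_totals: dict[str, pd.Series] = {}
    for marker, batches in batches_by_marker.items():
        log = readproc.DiscardLog()
        unique = readproc.process_samples(
            batches, log=log, min_merged_len=min_merged_len, **readproc_params
        )
        logs[marker] = log
        qids = [f"{marker}_u{i:06d}" for i in range(len(unique))]
        queries = dict(zip(qids, unique.index))
        hits = _assign.align_queries(queries, db.marker_sequences(marker))
        asg = _assign.assign_queries(
            hits, db.taxonomy, all_query_ids=qids,
            percentile=percentile, top_bits_tolerance=top_bits_tolerance,
        )
        assignments[marker] = asg
        query_counts = unique.set_axis(qids, axis=0)
        query_counts = query_counts.reindex(columns=all_samples, fill_value=0)
        layer, totals = _assign.tabulate_counts(asg, query_counts)
        layers[marker] = layer
        status_totals[marker] = totals
    combined = _assign.combine_markers(*layers.values())
    profile = profile_from_counts(combined, year=year)
    return PipelineResult(
        marker_layers=layers,
        combined=combined,
        profile=profile,
        assignments=assignments,
        discard_logs=logs,
        status_totals=status_totals,
    )


def simulate_and_run(
    db: ReferenceDB,
    comps: list[TrueComposition],
    n_pairs: int = 2000,
    read_length: int = 300,
    substitution_rate: float = 0.005,
    marker_bias: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    **pipeline_params,
) -> PipelineResult:
    """Simulate paired reads for every composition and run the pipeline."""
    batches_by_marker: dict[str, dict[str, ReadPairBatch]] = {
        m: {} for m in db.markers
    }
    for i, comp in enumerate(comps):
        per_marker = simulate_reads(
            comp, db, n_pairs=n_pairs, read_length=read_length,
            substitution_rate=substitution_rate, marker_bias=marker_bias,
            seed=seed + i,
        )
        for marker, batch in per_marker.items():
            batches_by_marker[marker][comp.sample_id] = batch
    return process_and_assign(batches_by_marker, db, **pipeline_params)


def class_recovery_rate(
    profile: SurveyProfile,
    comps: list[TrueComposition],
    taxonomy: Taxonomy,
    min_true_proportion: float = 0.15,
) -> float:
    """Fraction of (sample, taxon) cases whose abundance class is recovered.

    For every simulated sample and every taxon whose true proportion is at
    least ``min_true_proportion``, the recovered class (from the combined
    count matrix, at the taxon's species name) must equal the class of the
    true proportion.  A taxon missing from the recovered profile counts as
    a failure.
    """
    classes = profile.wide("abundance_class")
    hits = 0
    total = 0
    for comp in comps:
        for tid, p in comp.proportions.items():
            if p < min_true_proportion:
                continue
            total += 1
            name = taxonomy.rank_of(tid, "species")
            if (
                comp.sample_id in classes.index
                and name in classes.columns
                and classes.at[comp.sample_id, name] == classify(p).value
            ):
                hits += 1
    if total == 0:
        raise ValueError("no (sample, taxon) cases above the proportion floor")
    return hits / total
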