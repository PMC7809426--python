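"""Per-sample abundance profiles and melissopalynology abundance classes.

Honey composition is reported per sample as the proportion of sequence
reads (or pollen grains) per plant taxon, quantized into the four classes
used in classical melissopalynology:

* predominant      > 45% of reads/grains in the sample
* secondary        15–45%
* important minor  1–15%
* minor            < 1%

Boundary convention: predominant is (0.45, 1], secondary [0.15, 0.45],
important_minor [0.01, 0.15), minor (0, 0.01) — ">45%" strict, no gaps.
"Major" taxa are those at predominant or secondary level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class AbundanceClass(str, Enum):
    PREDOMINANT = "predominant"
    SECONDARY = "secondary"
    IMPORTANT_MINOR = "important_minor"
    MINOR = "minor"


MAJOR_CLASSES = frozenset({AbundanceClass.PREDOMINANT.value, AbundanceClass.SECONDARY.value})

#: class boundaries as (lower, upper, label); lower-inclusive flags per docstring
_BOUNDS = (
    (0.45, AbundanceClass.PREDOMINANT),
    (0.15, AbundanceClass.SECONDARY),
    (0.01, AbundanceClass.IMPORTANT_MINOR),
)


def classify(p: float) -> AbundanceClass:
    """Quantize a within-sample proportion into an abundance class."""
    if not (0 < p <= 1):
        raise ValueError(f"proportion must be in (0, 1], got {p}")
    if p > 0.45:
        return AbundanceClass.PREDOMINANT
    if p >= 0.15:
        return AbundanceClass.SECONDARY
    if p >= 0.01:
        return AbundanceClass.IMPORTANT_MINOR
    return AbundanceClass.MINOR


def classify_series(p: pd.Series) -> pd.Series:
    """Vectorised :func:`classify`."""
    out = pd.Series(AbundanceClass.MINOR.value, index=p.index, dtype=object)
    out[p >= 0.01] = AbundanceClass.IMPORTANT_MINOR.value
    out[p >= 0.15] = AbundanceClass.SECONDARY.value
    out[p > 0.45] = AbundanceClass.PREDOMINANT.value
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("proportions must be in (0, 1]")
    return out


def to_proportions(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalise a samples x taxa count matrix.

    Samples with zero total are flagged in the log and omitted.
    """
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.warning("omitting %d zero-total samples: %s",
                       int(zero.sum()), list(counts.index[zero]))
    kept = counts.loc[~zero]
    return kept.div(kept.sum(axis=1), axis=0)


@dataclass
class SurveyProfile:
    """Long-format per-sample abundance profile for one survey.

    ``table`` columns: sample_id, taxon, proportion, abundance_class.
    ``n_samples`` is the survey denominator (it may exceed the number of
    samples with rows, e.g. if some samples detected nothing).
    """

    table: pd.DataFrame
    year: int
    method: str  # "metabarcoding" | "melissopalynology"
    n_samples: int = 0

    def __post_init__(self):
        required = {"sample_id", "taxon", "proportion", "abundance_class"}
        if not required <= set(self.table.columns):
            raise ValueError(f"profile table needs columns {sorted(required)}")
        if self.n_samples == 0:
            self.n_samples = self.table["sample_id"].nunique()
        sums = self.table.groupby("sample_id")["proportion"].sum()
        if len(sums) and (np.abs(sums - 1.0) > 1e-9).any():
            bad = sums[np.abs(sums - 1.0) > 1e-9].index[0]
            raise ValueError(f"per-sample proportions must sum to 1 (sample {bad})")

    @property
    def taxa(self) -> list[str]:
        return sorted(self.table["taxon"].unique())

    def wide(self, value: str = "proportion") -> pd.DataFrame:
        """Samples x taxa matrix (absent taxa as 0 / NA for classes)."""
        fill = 0.0 if value == "proportion" else None
        return self.table.pivot_table(
            index="sample_id", columns="taxon", values=value,
            aggfunc="first", fill_value=fill,
        )

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def profile_from_counts(
    counts: pd.DataFrame, year: int, method: str = "metabarcoding"
) -> SurveyProfile:
    """Build a profile from a samples x taxa count (or proportion) matrix."""
    props = to_proportions(counts)
    long = props.stack().rename("proportion").reset_index()
    long.columns = ["sample_id", "taxon", "proportion"]
    long = long[long["proportion"] > 0].copy()
    long["abundance_class"] = classify_series(long["proportion"])
    return SurveyProfile(table=long, year=year, method=method,
                         n_samples=len(props))


def frequency_of_occurrence(
    profile: SurveyProfile, class_filter: set[str] | None = None
) -> pd.DataFrame:
    """Per-taxon number and fraction of samples containing the taxon.

    ``class_filter`` restricts to samples where the taxon occurs at one of
    the given classes (e.g. ``MAJOR_CLASSES`` for predominant+secondary).
    """
    t = profile.table
    if class_filter is not None:
        filt = {c.value if isinstance(c, AbundanceClass) else c for c in class_filter}
        t = t[t["abundance_class"].isin(filt)]
    if t.empty:
        return pd.DataFrame(columns=["count", "fraction"])
    counts = t.groupby("taxon")["sample_id"].nunique().rename("count")
    out = counts.to_frame()
    out["fraction"] = out["count"] / profile.n_samples
    return out.sort_values("count", ascending=False)


def seasonal_summary(
    profile: SurveyProfile,
    metadata: pd.DataFrame,
    min_samples: int = 10,
) -> pd.DataFrame:
    """Per-month fraction of samples containing each taxon at each class.

    Months with fewer than ``min_samples`` samples are excluded from the
    table (low-coverage months at the season edges are uninformative).
    Returns a long DataFrame (month, taxon, abundance_class, n_samples,
    count, fraction).
    """
    meta = metadata.set_index("sample_id")
    months = meta["month"]
    month_sizes = months.value_counts()
    keep_months = month_sizes[month_sizes >= min_samples].index
    t = profile.table.copy()
    t["month"] = t["sample_id"].map(months)
    t = t[t["month"].isin(keep_months)]
    if t.empty:
        return pd.DataFrame(
            columns=["month", "taxon", "abundance_class", "n_samples", "count", "fraction"]
        )
    grp = (
        t.groupby(["month", "taxon", "abundance_class"])["sample_id"]
        .nunique()
        .rename("count")
        .reset_index()
    )
    grp["n_samples"] = grp["month"].map(month_sizes)
    grp["fraction"] = grp["count"] / grp["n_samples"]
    return grp


def rarefy(counts: pd.DataFrame, depth: int, seed: int = 0) -> pd.DataFrame:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped (logged).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = counts.sum(axis=1)
    drop = totals < depth
    if drop.any():
        logger.warning("rarefy: dropping %d samples below depth %d",
                       int(drop.sum()), depth)
    if drop.all():
        logger.warning("rarefy: no sample reaches depth %d; empty matrix", depth)
    kept = counts.loc[~drop]
    out = np.empty(kept.shape, dtype=np.int64)
    for i, (_, row) in enumerate(kept.iterrows()):
        out[i] = rng.multivariate_hypergeometric(row.to_numpy().astype(np.int64), depth)
    return pd.DataFrame(out, index=kept.index, columns=kept.columns)
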