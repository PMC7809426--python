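"""Harmonization and statistics for comparing two honey surveys.

A metabarcoding survey resolves many taxa to species while a microscopy
(melissopalynology) survey often stops at genus, so the two are harmonized
conservatively: each matched taxon pair is compared at the coarser of the
two recorded ranks, with within-sample proportions re-aggregated (summed)
before abundance classes are re-derived.  The historical comparison then
uses Kendall rank correlation of occurrence frequencies, per-taxon 2x2
chi-squared tests of major-taxon frequency with Bonferroni correction, and
percent change in vegetation plot frequency.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .profiles import MAJOR_CLASSES, SurveyProfile, classify_series
from .taxonomy import RANK_ORDER, Taxonomy

_HARMONIZE_RANKS = ("species", "genus", "family")


def _nested(lin_a: dict[str, str], lin_b: dict[str, str]) -> bool:
    """True when one lineage is an ancestor of (or equal to) the other."""
    shared = [r for r in lin_a if r in lin_b]
    return all(lin_a[r] == lin_b[r] for r in shared)


def harmonize(
    profile_a: SurveyProfile,
    profile_b: SurveyProfile,
    taxonomy: Taxonomy,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Match two survey profiles at the coarser of the recorded ranks.

    Returns (matched table, unmatched-in-A, unmatched-in-B).  The matched
    table has one row per harmonized taxon with occurrence and
    major-occurrence frequencies per survey (columns ``freq_a``,
    ``freq_b``, ``major_freq_a``, ``major_count_a``, ... , ``n_a``,
    ``n_b``).  Taxon names that do not resolve in the taxonomy are
    reported as unmatched.
    """
    lineages: dict[str, dict[str, str]] = {}
    unmatched_a: list[str] = []
    unmatched_b: list[str] = []
    names_a, names_b = [], []
    for names, taxa, unmatched in (
        (names_a, profile_a.taxa, unmatched_a),
        (names_b, profile_b.taxa, unmatched_b),
    ):
        for name in taxa:
            lin = taxonomy.lineage_of_name(name)
            if lin is None:
                unmatched.append(name)
            else:
                lineages[name] = lin
                names.append(name)

    consumed_a: set[str] = set()
    consumed_b: set[str] = set()
    units: list[tuple[str, str, list[str], list[str]]] = []
    for rank in _HARMONIZE_RANKS:
        groups: dict[str, tuple[set[str], set[str]]] = {}
        for a, b in itertools.product(names_a, names_b):
            if a in consumed_a or b in consumed_b:
                continue
            lin_a, lin_b = lineages[a], lineages[b]
            coarser = max(
                min(lin_a, key=lambda r: RANK_ORDER[r]),
                min(lin_b, key=lambda r: RANK_ORDER[r]),
                key=lambda r: RANK_ORDER[r],
            )
            if coarser != rank or not _nested(lin_a, lin_b):
                continue
            key = lin_a.get(rank) or lin_b[rank]
            ga, gb = groups.setdefault(key, (set(), set()))
            ga.add(a)
            gb.add(b)
        for key, (ga, gb) in groups.items():
            units.append((key, rank, sorted(ga), sorted(gb)))
            consumed_a |= ga
            consumed_b |= gb

    unmatched_a += sorted(set(names_a) - consumed_a)
    unmatched_b += sorted(set(names_b) - consumed_b)

    rows = []
    for key, rank, members_a, members_b in sorted(units):
        row = {"taxon": key, "rank": rank,
               "n_a": profile_a.n_samples, "n_b": profile_b.n_samples}
        for suffix, profile, members in (
            ("a", profile_a, members_a),
            ("b", profile_b, members_b),
        ):
            sub = profile.table[profile.table["taxon"].isin(members)]
            collapsed = sub.groupby("sample_id")["proportion"].sum()
            collapsed = collapsed[collapsed > 0]
            classes = classify_series(collapsed)
            row[f"count_{suffix}"] = len(collapsed)
            row[f"freq_{suffix}"] = len(collapsed) / profile.n_samples
            n_major = int(classes.isin(MAJOR_CLASSES).sum())
            row[f"major_count_{suffix}"] = n_major
            row[f"major_freq_{suffix}"] = n_major / profile.n_samples
        rows.append(row)
    matched = pd.DataFrame(
        rows,
        columns=["taxon", "rank", "count_a", "freq_a", "major_count_a",
                 "major_freq_a", "count_b", "freq_b", "major_count_b",
                 "major_freq_b", "n_a", "n_b"],
    )
    return matched, unmatched_a, unmatched_b


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def _tau_b_parts(x: np.ndarray, y: np.ndarray):
    """Sign matrices and tie-corrected denominator for tau-b."""
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    n = len(x)
    n0 = n * (n - 1) / 2
    tie = lambda v: sum(c * (c - 1) / 2 for c in pd.Series(v).value_counts())
    denom = np.sqrt((n0 - tie(x)) * (n0 - tie(y)))
    return dx, dy, denom


def kendall_correlation(x, y) -> tuple[float, float]:
    """Kendall tau-b with two-sided p.

    Tie-corrected tau-b; the p-value uses the normal approximation, except
    for n <= 8 where the exact permutation distribution (all n! orderings
    of y) is enumerated — scipy's exact method refuses ties, which are the
    norm for occurrence frequencies.
    Raises on constant input (tau undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau undefined for constant input")
    tau, p_normal = scipy.stats.kendalltau(x, y)
    n = len(x)
    if n > 8:
        return float(tau), float(p_normal)
    dx, dy, denom = _tau_b_parts(x, y)
    perms = np.array(list(itertools.permutations(range(n))))
    dy_perm = dy[perms[:, :, None], perms[:, None, :]]
    s = (dx[None, :, :] * dy_perm).sum(axis=(1, 2)) / 2.0
    taus = s / denom
    p_exact = float(np.mean(np.abs(taus) >= abs(tau) - 1e-12))
    return float(tau), p_exact


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p: float
    low_expected: bool  # any expected cell count < 1


def chi2_contingency(table, yates: bool = False) -> Chi2Result:
    """Pearson chi-squared test of independence on an r x c count table.

    ``yates`` applies the continuity correction (2x2 only, as in scipy).
    Expected counts below 1 set a warning flag on the result.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("table must be 2-D with positive row and column sums")
    stat, p, df, expected = scipy.stats.chi2_contingency(obs, correction=yates)
    return Chi2Result(float(stat), int(df), float(p), bool((expected < 1).any()))


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p), m defaulting to len(p)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must be in [0, 1]")
    m = len(p) if m is None else m
    return np.minimum(1.0, m * p)


def major_change_table(
    matched: pd.DataFrame,
    min_major_frac: float = 0.01,
    yates: bool = False,
) -> pd.DataFrame:
    """Per-taxon change tests for major-taxon frequency between surveys.

    Restricts to taxa whose major (predominant or secondary) frequency
    exceeds ``min_major_frac`` in both surveys; for each, a 2x2 table
    (major vs not-major x survey) is tested with chi-squared, and p-values
    are Bonferroni-corrected across the retained taxa.  ``direction`` is
    the sign of the change from survey A to survey B.
    """
    keep = matched[
        (matched["major_freq_a"] > min_major_frac)
        & (matched["major_freq_b"] > min_major_frac)
    ]
    rows = []
    for _, r in keep.iterrows():
        tbl = np.array(
            [
                [r["major_count_a"], r["n_a"] - r["major_count_a"]],
                [r["major_count_b"], r["n_b"] - r["major_count_b"]],
            ]
        )
        if (tbl.sum(axis=0) == 0).any():
            # major in all samples (or none) of both surveys: no evidence
            # of change by convention
            res = Chi2Result(0.0, 1, 1.0, bool((tbl < 1).any()))
        else:
            res = chi2_contingency(tbl, yates=yates)
        rows.append(
            {
                "taxon": r["taxon"],
                "chi2": res.statistic,
                "df": res.df,
                "p": res.p,
                "direction": int(np.sign(r["major_freq_b"] - r["major_freq_a"])),
                "low_expected": res.low_expected,
            }
        )
    out = pd.DataFrame(rows, columns=["taxon", "chi2", "df", "p", "direction", "low_expected"])
    if len(out):
        out["p_adjusted"] = bonferroni(out["p"].to_numpy())
    else:
        out["p_adjusted"] = pd.Series(dtype=float)
    return out


def plot_frequency_change(freq_t1: float, freq_t2: float) -> float:
    """Percent change in vegetation plot frequency between two time points."""
    if freq_t1 <= 0:
        raise ValueError("percent change undefined for zero baseline frequency")
    return 100.0 * (freq_t2 - freq_t1) / freq_t1
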