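"""Ground-truth validation experiments for the whole pipeline.

Each function sets up a synthetic experiment with known truth, runs the
relevant part of the package, and returns the measured quantities.  They
are used both by the test suite and by ``scripts/acceptance.py``; problem
sizes reflect the study design being emulated (a 441-sample modern survey
against an 855-sample historical one, 2-km landscape radii, ~200-grain
pollen counts) scaled to a single-machine synthetic rerun.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from . import compare
from .assign import ASSIGNED, EXCLUDED_CROSS_CLADE, HIT_COLUMNS, consensus_assign
from .pipeline import class_recovery_rate, simulate_and_run
from .profiles import SurveyProfile, classify_series, profile_from_counts, rarefy
from .simulate import generate_reference_db, simulate_communities
from .spatial import moran_screen


def end_to_end_recovery(
    seed: int,
    n_samples: int = 50,
    n_taxa: int = 20,
    n_pairs: int = 2000,
    substitution_rate: float = 0.005,
) -> dict:
    """Simulate a two-marker survey and measure abundance-class recovery.

    Full pipeline (reads -> merge/cluster -> assign -> profile) on
    ``n_samples`` honey samples over ``n_taxa`` taxa with ``n_pairs`` read
    pairs per sample per marker; returns the fraction of (sample, taxon)
    cases with true proportion >= 0.15 whose abundance class is recovered.
    """
    db = generate_reference_db(n_taxa=n_taxa, seq_length=500, seed=seed)
    comps, _ = simulate_communities(n_samples, db.taxon_ids, seed=seed + 1)
    result = simulate_and_run(
        db, comps, n_pairs=n_pairs, read_length=300,
        substitution_rate=substitution_rate, seed=seed + 2,
    )
    rate = class_recovery_rate(result.profile, comps, db.taxonomy)
    return {"recovery_rate": rate, "n_samples": n_samples, "n_taxa": n_taxa}


def consensus_oracle_agreement(seed: int, n_tables: int = 200) -> dict:
    """Consensus assignment vs an independent tied-top-set taxonomy walk.

    Randomized hit tables over a 4-level synthetic taxonomy; the oracle
    enumerates the subjects tied at the maximum bit score and walks
    species -> genus -> family by set cardinality.
    """
    db = generate_reference_db(n_taxa=16, seq_length=500, seed=seed)
    taxonomy = db.taxonomy
    rng = np.random.default_rng(seed + 1)
    agree = 0
    for _ in range(n_tables):
        n = int(rng.integers(1, 8))
        subjects = rng.choice(taxonomy.taxon_ids, size=n)
        scores = rng.choice([500.0, 499.5, 499.0, 450.0], size=n)
        hits = pd.DataFrame(
            [("q", s, 99.0, 500, b) for s, b in zip(subjects, scores)],
            columns=HIT_COLUMNS,
        )
        got = consensus_assign(hits, taxonomy)

        tied = {s for s, b in zip(subjects, scores) if b == scores.max()}
        lineages = [taxonomy.lineage(t) for t in tied]
        expected = None
        for rank in ("species", "genus", "family"):
            names = {lin[rank] for lin in lineages}
            if len(names) == 1:
                expected = (names.pop(), rank, ASSIGNED)
                break
        if expected is None:
            expected = (None, None, EXCLUDED_CROSS_CLADE)
        agree += (got.name, got.rank, got.status) == expected
    return {"agreement": agree / n_tables, "n_tables": n_tables}


def stats_closed_form_checks(
    seed: int, n_chi2: int = 1000, n_kendall: int = 500
) -> dict:
    """Chi-squared, Kendall tau and Bonferroni vs closed forms/enumeration."""
    rng = np.random.default_rng(seed)

    chi2_err = 0.0
    for _ in range(n_chi2):
        a, b, c, d = (int(v) for v in rng.integers(1, 500, size=4))
        res = compare.chi2_contingency([[a, b], [c, d]])
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        if closed > 0:
            chi2_err = max(chi2_err, abs(res.statistic - closed) / closed)
        else:
            chi2_err = max(chi2_err, abs(res.statistic))

    tau_err = 0.0
    done = 0
    while done < n_kendall:
        n = int(rng.integers(3, 9))
        x = rng.integers(0, 6, size=n).astype(float)
        y = rng.integers(0, 6, size=n).astype(float)
        if len(set(x)) == 1 or len(set(y)) == 1:
            continue
        tau, _ = compare.kendall_correlation(x, y)
        s = sum(
            np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
            for i, j in itertools.combinations(range(n), 2)
        )
        n0 = n * (n - 1) / 2
        tx = sum(c * (c - 1) / 2 for c in pd.Series(x).value_counts())
        ty = sum(c * (c - 1) / 2 for c in pd.Series(y).value_counts())
        tau_err = max(tau_err, abs(tau - s / np.sqrt((n0 - tx) * (n0 - ty))))
        done += 1

    p = rng.random(50)
    bonf_err = float(np.max(np.abs(compare.bonferroni(p) - np.minimum(1.0, 50 * p))))
    return {
        "chi2_max_rel_err": chi2_err,
        "kendall_max_abs_err": tau_err,
        "bonferroni_max_abs_err": bonf_err,
        "n_chi2": n_chi2,
        "n_kendall": n_kendall,
    }


def survey_test_calibration(
    seed: int,
    n_replicates: int = 500,
    n1: int = 855,
    n2: int = 441,
    n_taxa: int = 20,
) -> dict:
    """Type-I error and power of the major-taxon change test.

    Null: both surveys draw per-taxon major-occurrence counts from the same
    binomial frequencies (spread across the 5-70% range typical of major
    honey taxa) at the historical (855) and modern (441) sample sizes.
    Reports the unadjusted false-positive rate at alpha = 0.05 and the
    Bonferroni family-wise error rate.  Power: a 74% -> 31% drop (the white
    clover scale of change) embedded in a 9-taxon family must reach
    adjusted p < 0.001.
    """
    rng = np.random.default_rng(seed)
    qs = np.linspace(0.05, 0.7, n_taxa)
    n_false = 0
    n_family_err = 0
    for _ in range(n_replicates):
        ps = np.empty(n_taxa)
        for t, q in enumerate(qs):
            k1 = rng.binomial(n1, q)
            k2 = rng.binomial(n2, q)
            res = compare.chi2_contingency([[k1, n1 - k1], [k2, n2 - k2]])
            ps[t] = res.p
        n_false += int((ps < 0.05).sum())
        n_family_err += bool((compare.bonferroni(ps) < 0.05).any())

    stable_q = np.linspace(0.1, 0.6, 8)
    n_power = 0
    for _ in range(n_replicates):
        rows = []
        k1 = rng.binomial(n1, 0.74)
        k2 = rng.binomial(n2, 0.31)
        rows.append(_matched_row("drop", k1, n1, k2, n2))
        for t, q in enumerate(stable_q):
            rows.append(
                _matched_row(f"t{t}", rng.binomial(n1, q), n1, rng.binomial(n2, q), n2)
            )
        table = compare.major_change_table(pd.DataFrame(rows))
        p_adj = table.set_index("taxon").at["drop", "p_adjusted"]
        n_power += p_adj < 0.001
    return {
        "false_positive_rate": n_false / (n_replicates * n_taxa),
        "family_wise_error_rate": n_family_err / n_replicates,
        "power_large_drop": n_power / n_replicates,
        "n_tests": n_replicates * n_taxa,
        "n_replicates": n_replicates,
    }


def _matched_row(taxon, k1, n1, k2, n2):
    return {
        "taxon": taxon, "rank": "genus",
        "count_a": k1, "freq_a": k1 / n1,
        "major_count_a": k1, "major_freq_a": k1 / n1,
        "count_b": k2, "freq_b": k2 / n2,
        "major_count_b": k2, "major_freq_b": k2 / n2,
        "n_a": n1, "n_b": n2,
    }


def _dirichlet_profile(rng, n_samples: int, n_taxa: int, alpha: float = 0.5):
    props = rng.dirichlet([alpha] * n_taxa, size=n_samples)
    samples = np.repeat([f"s{i}" for i in range(n_samples)], n_taxa)
    taxa = np.tile([f"t{j}" for j in range(n_taxa)], n_samples)
    df = pd.DataFrame(
        {"sample_id": samples, "taxon": taxa, "proportion": props.ravel()}
    )
    df = df[df["proportion"] > 0].copy()
    df["abundance_class"] = classify_series(df["proportion"])
    return SurveyProfile(df, year=2017, method="metabarcoding")


def moran_screen_calibration(
    seed: int,
    n_replicates: int = 100,
    n_taxa: int = 150,
    n_sites: int = 200,
    n_permutations: int = 199,
) -> dict:
    """Moran screen on spatially unstructured profiles, plus planted signal.

    Null: taxon proportions independent of hive location; reports the
    fraction of replicates with zero post-Bonferroni significant taxa.
    Planted: one strongly clustered taxon among 50 null taxa, screened
    with 9999 permutations so that family-wise significance is reachable;
    reports whether it is flagged before and after correction.
    """
    rng = np.random.default_rng(seed)
    clean = 0
    for rep in range(n_replicates):
        meta = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n_sites)],
                "x": rng.uniform(0, 100, size=n_sites),
                "y": rng.uniform(0, 100, size=n_sites),
            }
        )
        profile = _dirichlet_profile(rng, n_sites, n_taxa)
        screen = moran_screen(
            profile, meta, n_permutations=n_permutations, seed=seed + 1000 + rep
        )
        clean += screen.attrs["n_significant_adjusted"] == 0

    meta = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n_sites)],
            "x": rng.uniform(0, 100, size=n_sites),
            "y": rng.uniform(0, 100, size=n_sites),
        }
    )
    coords = meta[["x", "y"]].to_numpy()
    props = rng.dirichlet([1.0] * 51, size=n_sites)
    inside = ((coords - 50.0) ** 2).sum(axis=1) < 25.0**2
    props[inside, 0] += 3.0
    props /= props.sum(axis=1, keepdims=True)
    df = pd.DataFrame(
        {
            "sample_id": np.repeat(meta["sample_id"].to_numpy(), 51),
            "taxon": np.tile([f"t{j}" for j in range(51)], n_sites),
            "proportion": props.ravel(),
        }
    )
    df["abundance_class"] = classify_series(df["proportion"])
    planted_profile = SurveyProfile(df, year=2017, method="metabarcoding")
    screen = moran_screen(planted_profile, meta, n_permutations=9999, seed=seed + 7)
    planted = screen.set_index("taxon").loc["t0"]
    return {
        "null_clean_fraction": clean / n_replicates,
        "planted_detected": bool(
            planted["p"] < 0.05 and planted["p_adjusted"] < 0.05
        ),
        "n_replicates": n_replicates,
    }


def rarefaction_concordance(
    seed: int,
    n_samples: int = 100,
    n_taxa: int = 15,
    depth: int = 5000,
    total: int = 20000,
    boundary_margin: float = 0.005,
) -> dict:
    """Abundance-class agreement between full and rarefied count matrices.

    Counts are drawn multinomially at ``total`` reads per sample; cells
    whose full-depth proportion sits within ``boundary_margin`` of a class
    boundary are excluded (classes are undefined up to sampling noise
    there), all others must agree between the full and rarefied profiles.
    """
    rng = np.random.default_rng(seed)
    props = rng.dirichlet([2.0] * n_taxa, size=n_samples)
    counts = pd.DataFrame(
        np.vstack([rng.multinomial(total, p) for p in props]),
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"t{j}" for j in range(n_taxa)],
    )
    full = profile_from_counts(counts, year=2017)
    shallow = profile_from_counts(rarefy(counts, depth, seed=seed + 1), year=2017)
    full_wide = full.wide("proportion")
    full_cls = full.wide("abundance_class")
    thin_cls = shallow.wide("abundance_class")

    boundaries = np.array([0.01, 0.15, 0.45])
    n_cells = 0
    n_agree = 0
    for s in full_wide.index:
        for t in full_wide.columns:
            p = full_wide.at[s, t]
            if p <= 0 or np.min(np.abs(p - boundaries)) < boundary_margin:
                continue
            n_cells += 1
            got = thin_cls.at[s, t] if (s in thin_cls.index and t in thin_cls.columns) else None
            n_agree += got == full_cls.at[s, t]
    return {"concordance": n_agree / n_cells, "n_cells": n_cells, "depth": depth}
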