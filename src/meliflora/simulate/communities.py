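"""Seasonal community compositions with known ground truth.

Each honey sample is a point on the simplex over the taxon pool.  Seasonal
structure follows a Gaussian bump per taxon: a taxon peaks in one month of
the April–October season and its expected share decays with month distance.
Sample-to-sample noise comes from a symmetric Dirichlet scaled by the
seasonal weights, so E[p_i | month] = w_i(month) / sum_j w_j(month).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SEASON_MONTHS = range(4, 11)  # April..October

# rough UK bounding box for synthetic hive coordinates
_UK_LAT = (50.0, 58.5)
_UK_LON = (-5.5, 1.5)


@dataclass
class TrueComposition:
    """Ground-truth taxon proportions for one simulated honey sample."""

    sample_id: str
    month: int
    year: int
    proportions: dict[str, float]

    def __post_init__(self):
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, not 1")
        if any(p < 0 for p in self.proportions.values()):
            raise ValueError("negative proportion")

    def collapse(self, taxonomy, rank: str) -> dict[str, float]:
        """Aggregate proportions to a coarser rank (sums within groups)."""
        out: dict[str, float] = {}
        for tid, p in self.proportions.items():
            name = taxonomy.rank_of(tid, rank)
            out[name] = out.get(name, 0.0) + p
        return out


def seasonal_weight(month, peak, width: float = 1.5):
    """Gaussian month kernel: exp(-(month-peak)^2 / (2 width^2))."""
    m = np.asarray(month, dtype=float)
    return np.exp(-((m - peak) ** 2) / (2.0 * width**2))


def expected_proportions(
    taxon_ids: list[str],
    month: int,
    seasonality: dict[str, tuple[float, float]],
    base_weights: dict[str, float] | None = None,
) -> np.ndarray:
    """Analytic mean composition for one month (the Dirichlet mean)."""
    w = np.array(
        [
            (base_weights.get(t, 1.0) if base_weights else 1.0)
            * seasonal_weight(month, *seasonality[t])
            for t in taxon_ids
        ]
    )
    total = w.sum()
    if total <= 0:
        raise ValueError("all taxa have zero weight in this month")
    return w / total


def simulate_communities(
    n_samples: int,
    taxon_ids: list[str],
    months=SEASON_MONTHS,
    seasonality: dict[str, tuple[float, float]] | None = None,
    base_weights: dict[str, float] | None = None,
    concentration: float = 30.0,
    year: int = 2017,
    seed: int = 0,
) -> tuple[list[TrueComposition], pd.DataFrame]:
    """Draw ``n_samples`` compositions plus hive metadata.

    Parameters
    ----------
    seasonality
        Map taxon_id -> (peak_month, width).  Drawn uniformly over the
        season with width 1.5 months when omitted.
    base_weights
        Optional per-taxon overall abundance weights (default uniform).
        A taxon with weight 0 never appears.
    concentration
        Dirichlet concentration: samples are drawn from
        Dirichlet(concentration * normalised seasonal weights).  Larger
        values concentrate samples around the seasonal expectation.

    Returns
    -------
    (compositions, metadata)
        metadata has columns sample_id, latitude, longitude, month, year.
    """
    if not taxon_ids:
        raise ValueError("empty taxon pool")
    months = sorted(set(int(m) for m in months))
    if not months or not set(months) <= set(SEASON_MONTHS):
        raise ValueError("months must lie within April(4)..October(10)")
    rng = np.random.default_rng(seed)

    if seasonality is None:
        seasonality = {
            t: (float(rng.uniform(months[0], months[-1])), 1.5) for t in taxon_ids
        }

    comps: list[TrueComposition] = []
    meta_rows = []
    for i in range(n_samples):
        sample_id = f"S{i:03d}"
        month = int(rng.choice(months))
        mean = expected_proportions(taxon_ids, month, seasonality, base_weights)
        alpha = concentration * mean
        active = alpha > 0
        p = np.zeros(len(taxon_ids))
        if active.sum() == 1:
            p[active] = 1.0
        else:
            p[active] = rng.dirichlet(alpha[active])
        p /= p.sum()
        comps.append(
            TrueComposition(
                sample_id=sample_id,
                month=month,
                year=year,
                proportions=dict(zip(taxon_ids, p.tolist())),
            )
        )
        meta_rows.append(
            {
                "sample_id": sample_id,
                "latitude": float(rng.uniform(*_UK_LAT)),
                "longitude": float(rng.uniform(*_UK_LON)),
                "month": month,
                "year": year,
            }
        )
    return comps, pd.DataFrame(meta_rows)


def compositions_to_csv(comps: list[TrueComposition], path) -> None:
    """Long-format ground-truth CSV (sample_id, taxon_id, proportion)."""
    rows = [
        {"sample_id": c.sample_id, "taxon_id": t, "proportion": p}
        for c in comps
        for t, p in c.proportions.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
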