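"""Melissopalynology-style pollen count simulator.

Emulates the historical survey protocol: ~200 pollen grains per honey
sample identified under the microscope.  Microscopy cannot always separate
congeneric species, so compositions are collapsed to an identification
rank (genus by default) before the multinomial draw, and abundance classes
are derived from grain proportions with the same quantizer used for
sequence reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..profiles import classify
from ..taxonomy import RANKS, Taxonomy
from .communities import TrueComposition

DEFAULT_N_GRAINS = 200


@dataclass
class PollenRecord:
    """Grain counts and abundance classes for one surveyed honey sample."""

    sample_id: str
    year: int
    counts: dict[str, int]
    classes: dict[str, str]

    @property
    def n_grains(self) -> int:
        return sum(self.counts.values())

    def proportions(self) -> dict[str, float]:
        total = self.n_grains
        return {t: c / total for t, c in self.counts.items() if c > 0}


def simulate_pollen_counts(
    comp: TrueComposition,
    taxonomy: Taxonomy,
    n_grains: int = DEFAULT_N_GRAINS,
    id_rank: str = "genus",
    seed: int = 0,
) -> PollenRecord:
    """Multinomial grain counts on the composition collapsed to ``id_rank``."""
    if n_grains < 1:
        raise ValueError("n_grains must be >= 1")
    if id_rank not in RANKS:
        raise ValueError(f"unknown identification rank {id_rank!r}")
    rng = np.random.default_rng(seed)
    collapsed = comp.collapse(taxonomy, id_rank)
    names = sorted(collapsed)
    probs = np.array([collapsed[n] for n in names])
    counts = rng.multinomial(n_grains, probs / probs.sum())
    count_map = {n: int(k) for n, k in zip(names, counts) if k > 0}
    classes = {n: classify(k / n_grains).value for n, k in count_map.items()}
    return PollenRecord(
        sample_id=comp.sample_id, year=comp.year, counts=count_map, classes=classes
    )
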