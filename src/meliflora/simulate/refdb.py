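"""Synthetic dual-marker barcode reference library.

Emulates a curated national plant barcode collection: every taxon carries one
rbcL and one ITS2 sequence, and sequence divergence is structured by the
taxonomy.  Sequences are built by mutating rank-ancestor sequences at
per-rank substitution rates, so pairwise identity is ordered
within-genus > within-family > within-clade — the ordering the top-hit
consensus assignment relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..taxonomy import Taxonomy

MARKERS = ("rbcL", "ITS2")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ReferenceDB:
    """Barcode reference sequences joined to a four-rank taxonomy."""

    taxonomy: Taxonomy
    sequences: dict[tuple[str, str], str] = field(default_factory=dict)
    markers: tuple[str, ...] = MARKERS

    def sequence(self, taxon_id: str, marker: str) -> str:
        return self.sequences[(taxon_id, marker)]

    def marker_sequences(self, marker: str) -> dict[str, str]:
        if marker not in self.markers:
            raise ValueError(f"unknown marker {marker!r}")
        return {
            tid: seq for (tid, m), seq in self.sequences.items() if m == marker
        }

    @property
    def taxon_ids(self) -> list[str]:
        return self.taxonomy.taxon_ids

    def to_fasta(self, path, marker: str | None = None) -> None:
        """Write reference sequences as FASTA, headers ``taxon_id|marker``."""
        with open(path, "w") as fh:
            for tid in self.taxon_ids:
                for m in self.markers:
                    if marker is not None and m != marker:
                        continue
                    fh.write(f">{tid}|{m}\n{self.sequences[(tid, m)]}\n")


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each site with probability ``rate`` (always to a new base)."""
    out = seq.copy()
    hit = np.nonzero(rng.random(seq.size) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return out


def generate_reference_db(
    n_taxa: int,
    species_per_genus: int = 2,
    genera_per_family: int = 2,
    families_per_clade: int = 2,
    seq_length: int = 500,
    seed: int = 0,
    divergence: dict[str, float] | None = None,
    n_genera: int | None = None,
    n_families: int | None = None,
    n_clades: int | None = None,
) -> ReferenceDB:
    """Generate a taxonomy and two marker sequences per taxon.

    Parameters
    ----------
    n_taxa
        Number of species (each gets one rbcL and one ITS2 sequence).
    species_per_genus, genera_per_family, families_per_clade
        Shape of the nested taxonomy; higher-rank counts are derived by
        ceiling division unless given explicitly.
    divergence
        Per-rank substitution rates applied when deriving a child sequence
        from its rank ancestor.  Defaults: species 0.02, genus 0.05,
        family 0.08 — within-genus identity (~96%) exceeds between-genus
        identity (~86%), which the assignment tests require.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if seq_length < 100:
        raise ValueError("seq_length must be >= 100")
    div = {"species": 0.02, "genus": 0.05, "family": 0.08}
    if divergence:
        div.update(divergence)

    if n_genera is None:
        n_genera = math.ceil(n_taxa / species_per_genus)
    if n_families is None:
        n_families = math.ceil(n_genera / genera_per_family)
    if n_clades is None:
        n_clades = math.ceil(n_families / families_per_clade)
    if n_taxa > n_genera * species_per_genus:
        raise ValueError(
            f"taxonomy shape not nestable: {n_taxa} species exceed "
            f"{n_genera} genera x {species_per_genus} species/genus"
        )
    if n_genera > n_families * genera_per_family:
        raise ValueError("taxonomy shape not nestable at the family rank")
    if n_families > n_clades * families_per_clade:
        raise ValueError("taxonomy shape not nestable at the clade rank")

    rng = np.random.default_rng(seed)

    rows = []
    for s in range(n_taxa):
        g = s // species_per_genus
        f = g // genera_per_family
        c = f // families_per_clade
        rows.append(
            {
                "taxon_id": f"t{s:04d}",
                "species": f"Genus{g:03d} sp{s:04d}",
                "genus": f"Genus{g:03d}",
                "family": f"Family{f:02d}",
                "clade": f"clade{c:02d}",
            }
        )
    taxonomy = Taxonomy(pd.DataFrame(rows))

    sequences: dict[tuple[str, str], str] = {}
    for marker in MARKERS:
        clade_anc = {c: _random_seq(rng, seq_length) for c in range(n_clades)}
        family_anc = {
            f: _mutate(rng, clade_anc[f // families_per_clade], div["family"])
            for f in range(n_families)
        }
        genus_anc = {
            g: _mutate(rng, family_anc[g // genera_per_family], div["genus"])
            for g in range(n_genera)
        }
        for s in range(n_taxa):
            seq = _mutate(rng, genus_anc[s // species_per_genus], div["species"])
            sequences[(f"t{s:04d}", marker)] = seq.tobytes().decode("ascii")

    return ReferenceDB(taxonomy=taxonomy, sequences=sequences)
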