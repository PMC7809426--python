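"""Four-rank plant taxonomy (species, genus, family, clade).

The reference library assigns every barcode sequence to a species, and the
consensus-assignment rules walk upward through genus and family, excluding
conflicts that span families.  Ranks are strictly nested: a species belongs
to exactly one genus, a genus to one family, a family to one clade.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

RANKS = ("species", "genus", "family", "clade")
#: rank order from finest to coarsest, used by consensus assignment
RANK_ORDER = {rank: i for i, rank in enumerate(RANKS)}


@dataclass(frozen=True)
class TaxonomyRecord:
    taxon_id: str
    species: str
    genus: str
    family: str
    clade: str


class Taxonomy:
    """Lookup table mapping taxon ids and names to nested ranks.

    Backed by a DataFrame indexed by ``taxon_id`` with columns
    ``species, genus, family, clade``.  Construction validates strict
    nesting (each species maps to one genus, etc.).
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in RANKS if c not in table.columns]
        if missing:
            raise ValueError(f"taxonomy table missing columns: {missing}")
        if table.index.name != "taxon_id":
            if "taxon_id" in table.columns:
                table = table.set_index("taxon_id")
            else:
                raise ValueError("taxonomy table needs a taxon_id index or column")
        self.table = table[list(RANKS)].copy()
        for child, parent in zip(RANKS[:-1], RANKS[1:]):
            n_parents = self.table.groupby(child)[parent].nunique()
            bad = n_parents[n_parents > 1]
            if len(bad):
                raise ValueError(
                    f"rank nesting violated: {child} {bad.index[0]!r} maps to "
                    f"{bad.iloc[0]} distinct {child}->{parent} parents"
                )

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.table.index

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.table.index)

    def record(self, taxon_id: str) -> TaxonomyRecord:
        row = self.table.loc[taxon_id]
        return TaxonomyRecord(taxon_id, row.species, row.genus, row.family, row.clade)

    def rank_of(self, taxon_id: str, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return self.table.at[taxon_id, rank]

    def lineage(self, taxon_id: str) -> dict[str, str]:
        """Mapping rank -> name for one taxon, finest to coarsest."""
        row = self.table.loc[taxon_id]
        return {rank: row[rank] for rank in RANKS}

    def name_rank(self, name: str) -> str | None:
        """Infer the rank at which ``name`` is recorded in this taxonomy."""
        for rank in RANKS:
            if (self.table[rank] == name).any():
                return rank
        return None

    def lineage_of_name(self, name: str) -> dict[str, str] | None:
        """Lineage (at and above the name's rank) for a rank-ambiguous name."""
        rank = self.name_rank(name)
        if rank is None:
            return None
        row = self.table[self.table[rank] == name].iloc[0]
        idx = RANK_ORDER[rank]
        return {r: row[r] for r in RANKS[idx:]}

    def collapse(self, taxon_id: str, rank: str) -> str:
        """Name of the ancestor of ``taxon_id`` at ``rank``."""
        return self.rank_of(taxon_id, rank)

    # -- IO ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "Taxonomy":
        return cls(pd.read_csv(path, sep="\t", dtype=str))
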