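"""Taxonomic coverage and non-target specificity reports.

Aggregates virtual-PCR hit tables into three report shapes:

* rank-wise coverage — the proportion of database taxa at each rank
  (phylum .. species) with at least one virtually amplified member, per
  primer set and mismatch budget;
* a per-phylum mismatch-sweep matrix — distinct amplified species per
  phylum as the budget grows, with per-phylum database totals;
* a non-target specificity table — amplified / total species per
  non-target database and phylum.

A taxon counts as amplified as soon as one member sequence amplifies.
Taxa are keyed by their full lineage path, so homonymous labels under
different parents never collapse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .pcr import DEFAULT_LENGTH_BOUNDS, AmplificationResult, ReferenceRecord, amplify_database
from .primers import PrimerSet

__all__ = [
    "RANKS",
    "Lineage",
    "taxa_amplified",
    "coverage_by_rank",
    "phylum_mismatch_matrix",
    "specificity_screen",
]

#: Taxonomic ranks, shallow to deep.
RANKS: tuple[str, ...] = ("phylum", "class", "order", "family", "genus", "species")


@dataclass(frozen=True)
class Lineage:
    """A phylum -> species taxonomy path; deeper ranks may be unassigned.

    Assigned ranks must form a contiguous prefix: a record cannot carry a
    species label without a genus.
    """

    phylum: str | None = None
    class_: str | None = None
    order: str | None = None
    family: str | None = None
    genus: str | None = None
    species: str | None = None

    def __post_init__(self) -> None:
        labels = self.labels()
        seen_gap = False
        for lab in labels:
            if lab is None or lab == "":
                seen_gap = True
            elif seen_gap:
                raise ValueError(
                    f"assigned ranks must form a contiguous prefix, got {labels}"
                )

    def labels(self) -> tuple[str | None, ...]:
        return (self.phylum, self.class_, self.order, self.family, self.genus, self.species)

    def path(self, rank: str) -> tuple[str, ...] | None:
        """Full-path key down to ``rank``, or None if unassigned there.

        The path key namespaces each label by all its ancestors, which is
        what keeps homonymous genus names under different phyla distinct.
        """
        idx = RANKS.index(rank)
        labels = self.labels()[: idx + 1]
        if any(lab is None or lab == "" for lab in labels):
            return None
        return tuple(labels)  # type: ignore[return-value]

    @classmethod
    def from_labels(cls, labels: Sequence[str | None]) -> "Lineage":
        labels = list(labels) + [None] * (len(RANKS) - len(labels))
        clean = [None if (x is None or (isinstance(x, float))) else str(x) or None
                 for x in labels[: len(RANKS)]]
        return cls(*clean)


Taxonomy = Mapping[str, Lineage]


def _check_taxonomy(record_ids: Iterable[str], taxonomy: Taxonomy) -> None:
    missing = sorted(set(record_ids) - set(taxonomy))
    if missing:
        shown = ", ".join(missing[:10])
        more = "" if len(missing) <= 10 else f" (+{len(missing) - 10} more)"
        raise KeyError(f"amplified records missing from taxonomy: {shown}{more}")


def taxa_amplified(
    result: AmplificationResult, taxonomy: Taxonomy, rank: str
) -> set[tuple[str, ...]]:
    """Distinct rank-level taxa (full-path keys) with >=1 amplified record.

    Records unassigned at ``rank`` are skipped; amplified records absent
    from the taxonomy raise with the offending ids listed.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    ids = result.amplified_record_ids
    _check_taxonomy(ids, taxonomy)
    out: set[tuple[str, ...]] = set()
    for rid in ids:
        p = taxonomy[rid].path(rank)
        if p is not None:
            out.add(p)
    return out


def _rank_denominators(taxonomy: Taxonomy, ranks: Sequence[str]) -> dict[str, set]:
    denom: dict[str, set] = {r: set() for r in ranks}
    for lin in taxonomy.values():
        for r in ranks:
            p = lin.path(r)
            if p is not None:
                denom[r].add(p)
    return denom


def coverage_by_rank(
    results: Mapping[int, AmplificationResult],
    taxonomy: Taxonomy,
    ranks: Sequence[str] = RANKS,
) -> pd.DataFrame:
    """Rank x budget coverage table.

    Denominators count taxa represented in the database at each rank
    (taxa with >=1 record carrying that rank), read from the taxonomy —
    not taxa amplified.  Proportions are percentages at full precision;
    round on export.
    """
    if not taxonomy:
        raise ValueError("empty database: taxonomy has no records")
    denom = _rank_denominators(taxonomy, ranks)
    rows = []
    for budget in sorted(results):
        res = results[budget]
        for rank in ranks:
            total = len(denom[rank])
            amped = len(taxa_amplified(res, taxonomy, rank))
            rows.append(
                {
                    "primer_set": res.primer_set,
                    "rank": rank,
                    "budget": budget,
                    "n_taxa_total": total,
                    "n_taxa_amplified": amped,
                    "proportion": 100.0 * amped / total if total else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def phylum_mismatch_matrix(
    results: Mapping[int, AmplificationResult],
    taxonomy: Taxonomy,
    normalize: bool = False,
) -> pd.DataFrame:
    """Distinct amplified species per phylum as the budget grows.

    Returns a phylum x budget count matrix with a ``species_total``
    companion column (the per-phylum database denominator).  With
    ``normalize=True`` each budget column is divided by the row maximum —
    the per-row shading convention of mismatch-sweep heatmaps.
    """
    species_total: dict[str, set] = {}
    for lin in taxonomy.values():
        sp = lin.path("species")
        if sp is not None:
            species_total.setdefault(sp[0], set()).add(sp)
    phyla = sorted(species_total)
    budgets = sorted(results)
    mat = pd.DataFrame(0, index=pd.Index(phyla, name="phylum"), columns=budgets)
    for b in budgets:
        for sp in taxa_amplified(results[b], taxonomy, "species"):
            mat.loc[sp[0], b] += 1
    mat["species_total"] = [len(species_total[p]) for p in phyla]
    if normalize:
        counts = mat[budgets].astype(float)
        rowmax = counts.max(axis=1).replace(0, 1)
        mat[budgets] = counts.div(rowmax, axis=0)
    return mat


def specificity_screen(
    nontarget_dbs: Mapping[str, tuple[Sequence[ReferenceRecord], Taxonomy]],
    primer_sets: Sequence[PrimerSet],
    budgets: Sequence[int],
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
) -> pd.DataFrame:
    """Species amplified / total per non-target database, phylum, primer
    set and budget.

    Each non-target database carries its own taxonomy; a bacterial
    database passed here simply reproduces its species-rank coverage
    counts (the computation is identical).
    """
    rows = []
    for db_name, (records, taxonomy) in nontarget_dbs.items():
        species_total: dict[str, set] = {}
        for lin in taxonomy.values():
            sp = lin.path("species")
            if sp is not None:
                species_total.setdefault(sp[0], set()).add(sp)
        for pset in primer_sets:
            results = amplify_database(records, pset, budgets, length_bounds)
            for b in sorted(results):
                amped_by_phylum: dict[str, set] = {p: set() for p in species_total}
                for sp in taxa_amplified(results[b], taxonomy, "species"):
                    amped_by_phylum.setdefault(sp[0], set()).add(sp)
                for phylum in sorted(species_total):
                    rows.append(
                        {
                            "database": db_name,
                            "phylum": phylum,
                            "primer_set": pset.name,
                            "budget": b,
                            "species_amplified": len(amped_by_phylum[phylum]),
                            "species_total": len(species_total[phylum]),
                        }
                    )
    return pd.DataFrame(rows)
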