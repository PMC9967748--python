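"""Direction-concordant partitioning of significant taxa across comparisons.

Given differential-abundance tables for k cohort comparisons, each taxon
significant in at least one of them is assigned to exactly one Venn region:
the subset of cohorts in which it is significant — provided its direction
of dysregulation agrees across all of them.  Taxa significant in several
cohorts with conflicting directions are quarantined in ``discordant``
rather than forced into a region, keeping the partition lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd


@dataclass
class OverlapPartition:
    """Strict Venn partition of concordant significant taxa.

    ``regions`` maps every non-empty cohort subset (a tuple in cohort input
    order) to its (taxon, direction) members; subsets with no members map to
    empty lists.  ``discordant`` holds taxa whose significant directions
    conflict, with their per-cohort directions.
    """

    cohort_names: list[str]
    regions: dict[tuple[str, ...], list[tuple[str, str]]]
    discordant: list[tuple[str, dict[str, str]]] = field(default_factory=list)

    def region_of(self, taxon: str) -> tuple[str, ...] | None:
        for key, members in self.regions.items():
            if any(t == taxon for t, _ in members):
                return key
        return None


def _all_subsets(names: Sequence[str]) -> list[tuple[str, ...]]:
    subsets: list[tuple[str, ...]] = []
    for r in range(1, len(names) + 1):
        subsets.extend(combinations(names, r))
    return subsets


def partition_by_direction(
    tables: Sequence[tuple[str, pd.DataFrame]]
) -> OverlapPartition:
    """Partition taxa by the exact set of cohorts calling them significant.

    All tables must share one taxon universe.  A taxon lands in region S
    iff it is significant with one common direction in every cohort of S
    and in no cohort outside S; conflicting directions send it to
    ``discordant``.
    """
    if not tables:
        raise ValueError("at least one differential-abundance table required")
    names = [name for name, _ in tables]
    if len(set(names)) != len(names):
        raise ValueError("cohort names must be unique")
    universe = list(tables[0][1].index)
    for name, table in tables[1:]:
        if set(table.index) != set(universe):
            raise ValueError(f"taxa universe of {name!r} differs from the first table")

    regions: dict[tuple[str, ...], list[tuple[str, str]]] = {
        key: [] for key in _all_subsets(names)
    }
    discordant: list[tuple[str, dict[str, str]]] = []
    for taxon in universe:
        sig_in: list[str] = []
        directions: dict[str, str] = {}
        for name, table in tables:
            row = table.loc[taxon]
            if bool(row["significant"]):
                sig_in.append(name)
                directions[name] = str(row["direction"])
        if not sig_in:
            continue
        if len(set(directions.values())) == 1:
            key = tuple(n for n in names if n in set(sig_in))
            regions[key].append((taxon, directions[sig_in[0]]))
        else:
            discordant.append((taxon, directions))
    return OverlapPartition(cohort_names=names, regions=regions,
                            discordant=discordant)


def summarize_partition(
    partition: OverlapPartition,
    domains: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Counts per (region, direction[, domain]); rows sum to the number of
    concordant significant taxa."""
    rows = []
    for key, members in partition.regions.items():
        region = "&".join(key)
        for taxon, direction in members:
            rows.append({
                "region": region,
                "direction": direction,
                "domain": domains.get(taxon, "unknown") if domains else "all",
            })
    if not rows:
        return pd.DataFrame(columns=["region", "direction", "domain", "n"])
    frame = pd.DataFrame(rows)
    summary = (
        frame.groupby(["region", "direction", "domain"], sort=True)
        .size().rename("n").reset_index()
    )
    return summary


def partition_table(
    partition: OverlapPartition,
    domains: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Flat per-taxon view: region key, direction, domain; discordant taxa
    carry region 'discordant' and their per-cohort directions."""
    rows = []
    for key, members in partition.regions.items():
        for taxon, direction in members:
            rows.append({
                "taxon_id": taxon,
                "domain": domains.get(taxon, "unknown") if domains else "all",
                "region": "&".join(key),
                "direction": direction,
            })
    for taxon, directions in partition.discordant:
        rows.append({
            "taxon_id": taxon,
            "domain": domains.get(taxon, "unknown") if domains else "all",
            "region": "discordant",
            "direction": ";".join(f"{c}:{d}" for c, d in sorted(directions.items())),
        })
    return pd.DataFrame(rows, columns=["taxon_id", "domain", "region", "direction"])
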