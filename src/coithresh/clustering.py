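"""Single-linkage threshold clustering into MOTUs.

Two records fall in the same molecular operational taxonomic unit (MOTU) iff
they are connected in the graph with an edge for every pair whose distance is
strictly below the threshold — i.e. connected components, the behaviour of
threshold OTU-pickers on distance matrices.  The comparison operator is
strict ``<`` by default; clustering *at* the minimum interspecific distance
minus a tiny correction then guarantees the closest heterospecific pair stays
apart (see :func:`coithresh.thresholds.mininter_threshold`).  A ``"le"``
switch is provided for sensitivity analysis of that boundary choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix
from .errors import DataError


@dataclass(frozen=True)
class Partition:
    """Assignment of record ids to MOTU ids.

    MOTU ids are consecutive integers starting at 0, ordered by each MOTU's
    lexicographically smallest member, so a partition is reproducible from
    the matrix and threshold alone.
    """

    assignment: Mapping[str, int] = field(default_factory=dict)

    @property
    def n_motus(self) -> int:
        return len(set(self.assignment.values()))

    def motus(self) -> dict[int, frozenset[str]]:
        groups: dict[int, set[str]] = {}
        for rid, motu in self.assignment.items():
            groups.setdefault(motu, set()).add(rid)
        return {m: frozenset(members) for m, members in groups.items()}

    def member_sets(self) -> set[frozenset[str]]:
        return set(self.motus().values())

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.assignment.items())
        return pd.DataFrame(rows, columns=["record_id", "motu_id"])

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path


def threshold_cluster(
    matrix: DistanceMatrix, threshold: float, comparison: str = "lt"
) -> Partition:
    """Cluster a distance matrix at a threshold (single linkage).

    ``comparison='lt'`` links pairs with distance strictly below the
    threshold; ``'le'`` links at-or-below.  Undefined cells are an error —
    the quality filters must run first.
    """
    if threshold < 0:
        raise DataError("threshold must be non-negative")
    if matrix.has_undefined:
        raise DataError(
            "distance matrix contains undefined cells; apply the undefined-distance "
            "filter before clustering"
        )
    if comparison == "lt":
        adjacency = matrix.values < threshold
    elif comparison == "le":
        adjacency = matrix.values <= threshold
    else:
        raise DataError(f"unknown comparison {comparison!r} (expected 'lt' or 'le')")
    np.fill_diagonal(adjacency, True)
    _, component = connected_components(csr_matrix(adjacency), directed=False)
    # Renumber components by their lexicographically smallest member.
    smallest: dict[int, str] = {}
    for label, comp in zip(matrix.labels, component):
        if comp not in smallest or label < smallest[comp]:
            smallest[comp] = label
    order = sorted(smallest, key=smallest.get)
    renumber = {comp: rank for rank, comp in enumerate(order)}
    return Partition(
        {label: renumber[comp] for label, comp in zip(matrix.labels, component)}
    )


def cluster_count(partition: Partition) -> int:
    """Number of distinct MOTUs in a partition."""
    return partition.n_motus


def species_partition(species_of: Mapping[str, str]) -> Partition:
    """The partition induced by taxonomy: one MOTU per species."""
    order: dict[str, int] = {}
    smallest: dict[str, str] = {}
    for rid, sp in species_of.items():
        if sp not in smallest or rid < smallest[sp]:
            smallest[sp] = rid
    for rank, sp in enumerate(sorted(smallest, key=smallest.get)):
        order[sp] = rank
    return Partition({rid: order[sp] for rid, sp in species_of.items()})


def species_motu_sets(
    partition: Partition, species_of: Mapping[str, str]
) -> dict[str, set[int]]:
    """Per species, the set of MOTU ids its records occupy."""
    occupancy: dict[str, set[int]] = {}
    for rid, motu in partition.assignment.items():
        occupancy.setdefault(species_of[rid], set()).add(motu)
    return occupancy


def multi_cluster_species(per_species_partitions: Mapping[str, Partition]) -> int:
    """Count species whose own records split into two or more MOTUs."""
    return sum(1 for p in per_species_partitions.values() if p.n_motus >= 2)
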