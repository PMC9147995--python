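"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from coithresh import (
    DistanceMatrix,
    SequenceDataset,
    SequenceRecord,
    SimulationConfig,
    generate_dataset,
)


def make_record(
    rid: str,
    species: str = "Apis mellifera",
    genus: str | None = None,
    family: str = "Apidae",
    order: str = "Hymenoptera",
    marker: str = "COI-5P",
    sequence: str = "ACGTACGTACGT",
) -> SequenceRecord:
    if genus is None:
        tokens = species.split()
        genus = tokens[0] if tokens else ""
    return SequenceRecord(rid, species, genus, family, order, marker, sequence)


def make_dataset(records) -> SequenceDataset:
    return SequenceDataset(list(records), provenance="test")


def random_distance_matrix(
    rng: np.random.Generator, n: int, scale: float = 0.2, decimals: int = 4
) -> DistanceMatrix:
    """Random symmetric matrix; values rounded so exact boundary ties occur."""
    v = np.round(rng.uniform(0.0, scale, (n, n)), decimals)
    v = (v + v.T) / 2.0
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix(tuple(f"r{i:03d}" for i in range(n)), v)


def random_species_labels(
    rng: np.random.Generator, labels, max_species: int = 5
) -> dict[str, str]:
    k = int(rng.integers(1, max_species + 1))
    return {lab: f"sp{int(rng.integers(k)):02d}" for lab in labels}


class UnionFind:
    """Independent component finder for cross-checking the clustering."""

    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def component_sets(self):
        groups: dict[str, set[str]] = {}
        for x in self.parent:
            groups.setdefault(self.find(x), set()).add(x)
        return {frozenset(members) for members in groups.values()}


def union_find_components(matrix: DistanceMatrix, threshold: float,
                          comparison: str = "lt") -> set[frozenset[str]]:
    uf = UnionFind(matrix.labels)
    n = matrix.n
    for i in range(n):
        for j in range(i + 1, n):
            d = matrix.values[i, j]
            linked = d < threshold if comparison == "lt" else d <= threshold
            if linked:
                uf.union(matrix.labels[i], matrix.labels[j])
    return uf.component_sets()


def brute_force_errors(matrix: DistanceMatrix, species_of, threshold: float):
    """Straight per-record reimplementation of the identification-error
    taxonomy, independent of the vectorised one under test."""
    labels = matrix.labels
    from collections import Counter

    counts = Counter(species_of[lab] for lab in labels)
    tp = fp = fn = tn = 0
    for i, lab in enumerate(labels):
        neighbours = [
            labels[j]
            for j in range(len(labels))
            if j != i and matrix.values[i, j] < threshold
        ]
        if not neighbours:
            if counts[species_of[lab]] == 1:
                tn += 1
            else:
                fn += 1
        elif all(species_of[nb] == species_of[lab] for nb in neighbours):
            tp += 1
        else:
            fp += 1
    return tp, fp, fn, tn


@pytest.fixture(scope="session")
def clean_sim():
    """A small clean simulated dataset with ground truth (session-cached)."""
    config = SimulationConfig(
        n_genera=4, species_per_genus=3, sequences_per_species=5, seed=11
    )
    return generate_dataset(config)
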